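"""Spectral containers and plain-text I/O.

The pipeline's universal currency is the :class:`Spectrum` — one wavenumber
axis plus one intensity trace, tagged with the acquisition modality (NIR
reflectance or Raman scattering), the sample it came from, the scan position
on that sample, and how the sample was presented to the probe (loose powder,
compressed square, or laser-sintered disc).  A :class:`SpectrumSet` bundles
spectra that share one axis exactly; anything needing alignment must be
resampled explicitly upstream — the set constructor never interpolates.

Readers/writers cover a simple wide CSV layout (axis column + one intensity
column per scan position) and the AFFN subset of JCAMP-DX, the plain-number
dialect most FT spectrometers can export.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Modality",
    "Presentation",
    "PolymerGrade",
    "Spectrum",
    "SpectrumSet",
    "MixtureComposition",
    "SpectraFormatError",
    "DegenerateInputError",
    "AxisMismatchError",
    "UnsupportedJcampError",
    "read_spectra_csv",
    "write_spectra_csv",
    "read_jcamp",
    "read_metadata_json",
    "write_metadata_json",
    "average_replicates",
]


class Modality(str, Enum):
    NIR = "nir"
    RAMAN = "raman"


class Presentation(str, Enum):
    POWDER = "powder"
    COMPRESSED_SQUARE = "compressed_square"
    PRINTED_DISC = "printed_disc"


class PolymerGrade(str, Enum):
    """Hydroxypropyl cellulose grades, ordered by molecular weight."""

    HPC_SSL = "HPC-SSL"   # MW ~60,000
    HPC_SL = "HPC-SL"     # MW ~100,000
    HPC_L = "HPC-L"       # MW ~140,000


#: Nominal acquisition ranges per modality (cm^-1).  Axes outside these
#: bounds are accepted with a warning — the instrument contract, not a hard
#: physical limit.
EXPECTED_AXIS_RANGE: dict[Modality, tuple[float, float]] = {
    Modality.NIR: (3600.0, 12500.0),
    Modality.RAMAN: (100.0, 2000.0),
}

#: Delimiter between sample id and scan-position id in CSV column headers.
POSITION_DELIMITER = "__"


class SpectraFormatError(ValueError):
    """A file violated the documented CSV/JCAMP layout."""


class DegenerateInputError(ValueError):
    """Input is structurally valid but degenerate for the requested operation."""


class AxisMismatchError(ValueError):
    """Wavenumber axes that must agree exactly do not."""


class UnsupportedJcampError(SpectraFormatError):
    """JCAMP-DX dialect outside the supported AFFN XYDATA/XYPOINTS subset."""


@dataclass(frozen=True)
class Spectrum:
    """One spectral trace on a strictly monotone wavenumber axis.

    Axes are normalised to ascending order on construction (descending input
    is accepted and flipped together with its intensities).
    """

    axis: np.ndarray
    intensities: np.ndarray
    modality: Modality
    sample_id: str = "sample"
    position_id: int = 1
    presentation: Presentation = Presentation.POWDER

    def __post_init__(self) -> None:
        axis = np.asarray(self.axis, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if axis.ndim != 1 or y.ndim != 1:
            raise ValueError("axis and intensities must be one-dimensional")
        if axis.size != y.size:
            raise ValueError(
                f"axis ({axis.size}) and intensities ({y.size}) lengths differ"
            )
        if axis.size < 2:
            raise ValueError("a spectrum needs at least 2 points")
        d = np.diff(axis)
        if np.all(d > 0):
            pass
        elif np.all(d < 0):
            axis = axis[::-1].copy()
            y = y[::-1].copy()
        else:
            raise ValueError("axis must be strictly monotone")
        if self.position_id < 0:
            raise ValueError("position_id must be >= 0")
        lo, hi = EXPECTED_AXIS_RANGE[Modality(self.modality)]
        if axis[0] < lo - 1e-9 or axis[-1] > hi + 1e-9:
            warnings.warn(
                f"{Modality(self.modality).value} axis [{axis[0]:g}, {axis[-1]:g}] "
                f"extends outside the nominal range [{lo:g}, {hi:g}]",
                stacklevel=2,
            )
        object.__setattr__(self, "axis", axis)
        object.__setattr__(self, "intensities", y)

    @property
    def n_points(self) -> int:
        return int(self.axis.size)

    def with_data(self, axis: np.ndarray | None = None,
                  intensities: np.ndarray | None = None) -> "Spectrum":
        """Copy of this spectrum with replaced axis and/or intensities."""
        return replace(
            self,
            axis=self.axis if axis is None else axis,
            intensities=self.intensities if intensities is None else intensities,
        )


@dataclass(frozen=True)
class MixtureComposition:
    """Mass-fraction composition (% w/w) of a four-component formulation.

    The calibration design of interest keeps total drug (crystalline +
    amorphous) at 20% w/w in 77% polymer + 3% colourant; that specific split
    is not enforced here, only non-negativity and a total of 100%.
    """

    crystalline_drug: float
    amorphous_drug: float
    polymer: float
    colourant: float
    polymer_grade: PolymerGrade = PolymerGrade.HPC_L

    def __post_init__(self) -> None:
        parts = (self.crystalline_drug, self.amorphous_drug,
                 self.polymer, self.colourant)
        if any(p < 0 for p in parts):
            raise ValueError("mass fractions must be non-negative")
        total = sum(parts)
        if abs(total - 100.0) > 1e-9:
            raise ValueError(f"mass fractions must sum to 100, got {total!r}")

    @property
    def total_drug(self) -> float:
        return self.crystalline_drug + self.amorphous_drug


@dataclass
class SpectrumSet:
    """Ordered collection of spectra sharing one axis exactly.

    ``compositions`` optionally maps sample_id -> :class:`MixtureComposition`
    (the synthetic ground truth, or the sidecar metadata of real scans).
    """

    spectra: list[Spectrum]
    compositions: dict[str, MixtureComposition] | None = None

    def __post_init__(self) -> None:
        if self.spectra:
            ref = self.spectra[0].axis
            for s in self.spectra[1:]:
                if s.axis.size != ref.size or not np.array_equal(s.axis, ref):
                    raise AxisMismatchError(
                        f"spectrum {s.sample_id!r} pos {s.position_id} does not "
                        "share the set axis exactly; resample explicitly"
                    )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def axis(self) -> np.ndarray:
        if not self.spectra:
            raise DegenerateInputError("empty SpectrumSet has no axis")
        return self.spectra[0].axis

    @property
    def sample_ids(self) -> list[str]:
        """Sample ids in first-occurrence order."""
        seen: list[str] = []
        for s in self.spectra:
            if s.sample_id not in seen:
                seen.append(s.sample_id)
        return seen

    def intensity_matrix(self) -> np.ndarray:
        """(n_spectra, n_points) matrix in collection order."""
        if not self.spectra:
            raise DegenerateInputError("empty SpectrumSet")
        return np.vstack([s.intensities for s in self.spectra])

    def y_vector(self, attribute: str = "amorphous_drug") -> np.ndarray:
        """Response vector (one entry per spectrum) from the compositions map."""
        if self.compositions is None:
            raise DegenerateInputError("SpectrumSet carries no compositions")
        return np.array(
            [getattr(self.compositions[s.sample_id], attribute) for s in self.spectra],
            dtype=float,
        )


# ---------------------------------------------------------------------------
# CSV I/O
#
# Layout: first column = wavenumber axis (header names the axis); every
# further column is one scan position, header "sampleid__pos".  Comma
# separator, "." decimal, UTF-8, header row mandatory; full repr precision on
# write so a write->read round trip is value-identical.
# ---------------------------------------------------------------------------

def _axis_column_name(modality: Modality) -> str:
    return ("wavenumber_cm-1" if Modality(modality) is Modality.NIR
            else "raman_shift_cm-1")


def _parse_column_header(name: str) -> tuple[str, int]:
    if POSITION_DELIMITER in name:
        sid, _, pos = name.rpartition(POSITION_DELIMITER)
        try:
            return sid, int(pos)
        except ValueError as exc:
            raise SpectraFormatError(
                f"column {name!r}: position id after "
                f"{POSITION_DELIMITER!r} is not an integer"
            ) from exc
    return name, 1


def read_spectra_csv(path: str | Path, modality: Modality) -> SpectrumSet:
    """Read a wide spectra CSV into a :class:`SpectrumSet`.

    Column order is preserved as collection order; a descending axis is
    normalised to ascending (intensities reversed consistently).
    """
    path = Path(path)
    df = pd.read_csv(path, header=0, dtype=str, skipinitialspace=True)
    if df.shape[1] < 2:
        raise SpectraFormatError(f"{path}: need an axis column plus >= 1 intensity column")
    # cells go through Python's float() — correctly rounded, so repr-written
    # files round-trip exactly — with per-cell error locations
    numeric = pd.DataFrame(index=df.index)
    for col in df.columns:
        values = np.empty(len(df), dtype=float)
        for row, cell in enumerate(df[col]):
            if cell is None or (isinstance(cell, float) and np.isnan(cell)) \
                    or (isinstance(cell, str) and not cell.strip()):
                raise SpectraFormatError(
                    f"{path}: missing value in column {col!r}, data row {row} "
                    "(mismatched column lengths?)"
                )
            try:
                values[row] = float(cell)
            except ValueError as exc:
                raise SpectraFormatError(
                    f"{path}: non-numeric value {cell!r} in column {col!r}, "
                    f"data row {row}"
                ) from exc
        numeric[col] = values
    axis = numeric.iloc[:, 0].to_numpy(dtype=float)
    spectra = []
    for col in numeric.columns[1:]:
        sid, pos = _parse_column_header(col)
        spectra.append(
            Spectrum(axis=axis, intensities=numeric[col].to_numpy(dtype=float),
                     modality=Modality(modality), sample_id=sid, position_id=pos)
        )
    return SpectrumSet(spectra)


def write_spectra_csv(sset: SpectrumSet, path: str | Path) -> Path:
    """Write a :class:`SpectrumSet` as a wide CSV; round-trips via read_spectra_csv."""
    if not sset.spectra:
        raise DegenerateInputError("refusing to write an empty SpectrumSet")
    path = Path(path)
    modality = sset.spectra[0].modality
    data: dict[str, np.ndarray] = {_axis_column_name(modality): sset.axis}
    for s in sset.spectra:
        if POSITION_DELIMITER in s.sample_id:
            raise SpectraFormatError(
                f"sample_id {s.sample_id!r} contains the reserved "
                f"delimiter {POSITION_DELIMITER!r}"
            )
        col = f"{s.sample_id}{POSITION_DELIMITER}{s.position_id}"
        if col in data:
            raise SpectraFormatError(f"duplicate (sample_id, position_id): {col!r}")
        data[col] = s.intensities
    # repr() on Python floats is the shortest round-trip representation, so a
    # write -> read cycle is bit-stable; pandas' default float formatting is not.
    columns = list(data)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(",".join(columns) + "\n")
        for i in range(sset.axis.size):
            fh.write(",".join(repr(float(data[c][i])) for c in columns) + "\n")
    return path


# ---------------------------------------------------------------------------
# Metadata sidecar JSON
# ---------------------------------------------------------------------------

def read_metadata_json(path: str | Path) -> tuple[dict[str, MixtureComposition],
                                                  dict[str, Presentation]]:
    """Read the sidecar {sample_id: {crystalline, amorphous, ...}} mapping."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    comps: dict[str, MixtureComposition] = {}
    pres: dict[str, Presentation] = {}
    for sid, rec in raw.items():
        comps[sid] = MixtureComposition(
            crystalline_drug=float(rec["crystalline"]),
            amorphous_drug=float(rec["amorphous"]),
            polymer=float(rec["polymer"]),
            colourant=float(rec["colourant"]),
            polymer_grade=PolymerGrade(rec.get("polymer_grade", "HPC-L")),
        )
        pres[sid] = Presentation(rec.get("presentation", "powder"))
    return comps, pres


def write_metadata_json(path: str | Path,
                        compositions: dict[str, MixtureComposition],
                        presentations: dict[str, Presentation] | None = None) -> Path:
    path = Path(path)
    out = {}
    for sid, c in compositions.items():
        rec = {
            "crystalline": c.crystalline_drug,
            "amorphous": c.amorphous_drug,
            "polymer": c.polymer,
            "colourant": c.colourant,
            "polymer_grade": c.polymer_grade.value,
        }
        if presentations and sid in presentations:
            rec["presentation"] = presentations[sid].value
        out[sid] = rec
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)
    return path


# ---------------------------------------------------------------------------
# JCAMP-DX (AFFN subset)
# ---------------------------------------------------------------------------

# Characters legal inside AFFN numeric tables.  Anything else (SQZ/DIF/DUP
# pseudo-digit alphabets such as @A-Ia-i%J-Rj-r S-Zs-z) marks a compressed
# dialect we deliberately do not decode.
_AFFN_LINE = re.compile(r"^[0-9.+\-Ee,;\s]*$")


def _affn_tokens(line: str) -> list[float]:
    return [float(tok) for tok in re.split(r"[,;\s]+", line.strip()) if tok]


def read_jcamp(path: str | Path, modality: Modality | None = None) -> Spectrum:
    """Read a single-spectrum JCAMP-DX file (AFFN ``XYDATA``/``XYPOINTS`` only).

    Compressed tables (SQZ/DIF/DUP/PAC pseudo-digits) raise
    :class:`UnsupportedJcampError`.  If ``modality`` is omitted it is inferred
    from the axis range (<= 2500 cm^-1 -> Raman, else NIR).
    """
    path = Path(path)
    headers: dict[str, str] = {}
    data_lines: list[str] = []
    mode: str | None = None
    with open(path, encoding="utf-8", errors="replace") as fh:
        for rawline in fh:
            line = rawline.split("$$", 1)[0].rstrip()
            if not line:
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper().replace(" ", "")
                value = value.strip()
                if key in ("XYDATA", "XYPOINTS"):
                    if mode is not None:
                        break  # only the first data table is read
                    mode = key
                    headers[key] = value
                elif key == "END":
                    break
                else:
                    headers[key] = value
            elif mode is not None:
                data_lines.append(line)
    if mode is None:
        raise UnsupportedJcampError(
            f"{path}: no ##XYDATA or ##XYPOINTS table found"
        )
    for line in data_lines:
        if not _AFFN_LINE.match(line):
            raise UnsupportedJcampError(
                f"{path}: compressed JCAMP dialect detected in {line[:40]!r}; "
                "only plain AFFN tables are supported"
            )
    xfactor = float(headers.get("XFACTOR", 1.0))
    yfactor = float(headers.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    if mode == "XYPOINTS":
        for line in data_lines:
            vals = _affn_tokens(line)
            if len(vals) % 2:
                raise SpectraFormatError(f"{path}: odd token count in XYPOINTS line")
            xs.extend(vals[0::2])
            ys.extend(vals[1::2])
    else:  # XYDATA=(X++(Y..Y))
        deltax = headers.get("DELTAX")
        step = float(deltax) if deltax is not None else None
        if step is None and "FIRSTX" in headers and "LASTX" in headers \
                and "NPOINTS" in headers and int(headers["NPOINTS"]) > 1:
            step = ((float(headers["LASTX"]) - float(headers["FIRSTX"]))
                    / (int(headers["NPOINTS"]) - 1))
        rows = [_affn_tokens(line) for line in data_lines if line.strip()]
        for i, vals in enumerate(rows):
            if len(vals) < 2:
                raise SpectraFormatError(f"{path}: XYDATA line with no Y values")
            x0, yvals = vals[0], vals[1:]
            if step is None:
                # infer from the next row's X start
                if i + 1 < len(rows):
                    step = (rows[i + 1][0] - x0) / len(yvals)
                else:
                    raise SpectraFormatError(
                        f"{path}: cannot infer DELTAX for a single XYDATA line"
                    )
            xs.extend(x0 + k * step for k in range(len(yvals)))
            ys.extend(yvals)
    axis = np.asarray(xs, dtype=float) * xfactor
    intens = np.asarray(ys, dtype=float) * yfactor
    if modality is None:
        modality = Modality.RAMAN if np.max(axis) <= 2500.0 else Modality.NIR
    title = headers.get("TITLE", path.stem) or path.stem
    return Spectrum(axis=axis, intensities=intens, modality=Modality(modality),
                    sample_id=title)


# ---------------------------------------------------------------------------
# Replicate averaging
# ---------------------------------------------------------------------------

def average_replicates(sset: SpectrumSet) -> SpectrumSet:
    """Average scan positions per sample: the final spectrum for each sample is
    the arithmetic per-point mean over its recorded positions.

    The averaged spectrum carries ``position_id = 0``; a single-position sample
    passes through with unchanged values.  Idempotent.
    """
    groups: dict[str, list[Spectrum]] = {}
    order: list[str] = []
    for s in sset.spectra:
        if s.sample_id not in groups:
            groups[s.sample_id] = []
            order.append(s.sample_id)
        groups[s.sample_id].append(s)
    averaged = []
    for sid in order:
        members = groups[sid]
        mean = np.mean(np.vstack([m.intensities for m in members]), axis=0)
        first = members[0]
        averaged.append(
            Spectrum(axis=first.axis, intensities=mean, modality=first.modality,
                     sample_id=sid, position_id=0, presentation=first.presentation)
        )
    return SpectrumSet(averaged, compositions=sset.compositions)
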