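"""Spectral preprocessing operators and the two reference chains.

NIR chain:   region-select (4000-6200 cm^-1, moisture band 4800-5200
             excluded) -> 2nd-derivative Savitzky-Golay (21-point window,
             2nd-order polynomial) -> standard normal variate -> mean-center.
Raman chain: region-select (1000-1700 cm^-1) -> Whittaker asymmetric-least-
             squares baseline (lambda = 100,000, p = 0.001) -> normalisation
             to the 1614 cm^-1 peak area -> mean-center.

All per-spectrum operators are stateless; the only fitted statistic in a
chain is the per-wavenumber column mean, frozen on the calibration set and
reapplied — never refit — to validation or prediction spectra.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import solveh_banded
from scipy.signal import savgol_filter

from .spectra import (
    AxisMismatchError,
    DegenerateInputError,
    Modality,
    Spectrum,
    SpectrumSet,
)

__all__ = [
    "SavGolParams",
    "WhittakerParams",
    "RegionSpec",
    "PeakAreaParams",
    "PreprocessChain",
    "ChainState",
    "ChainStepError",
    "savgol_derivative",
    "snv",
    "whittaker_baseline",
    "normalize_to_peak_area",
    "select_region",
    "mean_center",
    "apply_chain",
    "nir_default_chain",
    "raman_default_chain",
]


class ChainStepError(RuntimeError):
    """A chain step failed; message carries the step index and name."""


@dataclass(frozen=True)
class SavGolParams:
    """Savitzky-Golay derivative filter: 21-point window, 2nd-order
    polynomial, 2nd derivative by default."""

    window: int = 21
    polyorder: int = 2
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if self.window < 5 or self.window % 2 == 0:
            raise ValueError("window must be an odd integer >= 5")
        if not 0 <= self.polyorder < self.window:
            raise ValueError("polyorder must satisfy 0 <= polyorder < window")
        if not 0 <= self.deriv_order <= self.polyorder:
            raise ValueError("deriv_order must satisfy 0 <= deriv_order <= polyorder")


@dataclass(frozen=True)
class WhittakerParams:
    """Asymmetric-least-squares baseline: smoothness lambda, asymmetry p."""

    lam: float = 1e5
    p: float = 1e-3
    max_iter: int = 10
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not 0.0 < self.p < 1.0:
            raise ValueError("p must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")


@dataclass(frozen=True)
class RegionSpec:
    """Closed keep/exclude wavenumber intervals; exclusion wins on overlap."""

    keep: tuple[tuple[float, float], ...] = ()
    exclude: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        for lo, hi in (*self.keep, *self.exclude):
            if lo > hi:
                raise ValueError(f"interval ({lo}, {hi}) has lower > upper")
        object.__setattr__(self, "keep", tuple(tuple(map(float, iv)) for iv in self.keep))
        object.__setattr__(self, "exclude",
                           tuple(tuple(map(float, iv)) for iv in self.exclude))


@dataclass(frozen=True)
class PeakAreaParams:
    """Normalisation window: closed [center - half_width, center + half_width]."""

    center: float = 1614.0
    half_width: float = 15.0

    def __post_init__(self) -> None:
        if self.half_width <= 0:
            raise ValueError("half_width must be > 0")


# ---------------------------------------------------------------------------
# Per-spectrum operators
# ---------------------------------------------------------------------------

def _uniform_segments(axis: np.ndarray) -> list[slice]:
    """Maximal contiguous runs of constant step.

    A step that breaks the run (e.g. the jump across an excluded region) ends
    the left run at its left endpoint and starts the right run at its right
    endpoint — the jump itself belongs to neither run.
    """
    d = np.diff(axis)
    segments: list[slice] = []
    seg_start = 0
    step: float | None = None
    for i in range(d.size):
        if step is None:
            step = d[i]
        elif not np.isclose(d[i], step, rtol=1e-6, atol=1e-9 * max(abs(step), 1.0)):
            segments.append(slice(seg_start, i + 1))
            seg_start = i + 1
            step = None
    segments.append(slice(seg_start, axis.size))
    return segments


def savgol_derivative(s: Spectrum, p: SavGolParams = SavGolParams()) -> Spectrum:
    """Savitzky-Golay derivative per unit axis step, edges trimmed.

    Interior points carry the ``deriv_order``-th derivative (with respect to
    the sample index, i.e. per grid step) of the local least-squares
    polynomial of degree ``polyorder`` over the centred window; the filter
    therefore reproduces polynomials of degree <= polyorder exactly.
    (window-1)/2 points are trimmed at each end rather than padded.

    The axis must be uniformly spaced in contiguous runs of at least
    ``window`` points (region exclusion leaves such piecewise-uniform axes);
    each run is filtered and trimmed independently.
    """
    half = (p.window - 1) // 2
    axes, vals = [], []
    for seg in _uniform_segments(s.axis):
        ax = s.axis[seg]
        if ax.size < p.window:
            raise DegenerateInputError(
                "axis is not uniformly spaced in runs of at least "
                f"{p.window} points (run of {ax.size} found); resample the "
                "spectrum explicitly before differentiation"
            )
        dy = savgol_filter(s.intensities[seg], p.window, p.polyorder,
                           deriv=p.deriv_order, delta=1.0, mode="interp")
        axes.append(ax[half:-half])
        vals.append(dy[half:-half])
    return s.with_data(axis=np.concatenate(axes), intensities=np.concatenate(vals))


def snv(s: Spectrum) -> Spectrum:
    """Standard normal variate: per-spectrum (x - mean) / sd, sd with n-1."""
    y = s.intensities
    sdev = float(np.std(y, ddof=1))
    if sdev < 1e-15:
        raise DegenerateInputError(
            f"SNV undefined for constant spectrum {s.sample_id!r}"
        )
    return s.with_data(intensities=(y - np.mean(y)) / sdev)


def _penalty_diagonals(n: int, lam: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Diagonals (main, first, second) of lam * D2' D2 for second differences."""
    main = np.full(n, 6.0)
    main[[0, -1]] = 1.0
    main[[1, -2]] = 5.0
    first = np.full(n - 1, -4.0)
    first[[0, -1]] = -2.0
    second = np.full(n - 2, 1.0)
    return lam * main, lam * first, lam * second


def whittaker_baseline(
    s: Spectrum, w: WhittakerParams = WhittakerParams()
) -> tuple[Spectrum, Spectrum]:
    """Asymmetric-least-squares baseline estimate and the corrected spectrum.

    The baseline z minimises sum_i w_i (x_i - z_i)^2 + lam * sum (D2 z)^2 with
    weights iteratively reset to p where x > z and 1-p where x <= z, starting
    from all ones, until the weights stabilise (relative change < tol) or
    ``max_iter`` solves.  The pentadiagonal normal equations are solved in
    banded form.
    """
    x = s.intensities
    n = x.size
    if n < 4:
        raise DegenerateInputError("Whittaker baseline needs >= 4 points")
    d0, d1, d2 = _penalty_diagonals(n, w.lam)
    weights = np.ones(n)
    ab = np.zeros((3, n))
    ab[0, 2:] = d2
    ab[1, 1:] = d1
    z = x
    for _ in range(w.max_iter):
        ab[2] = d0 + weights
        z = solveh_banded(ab, weights * x, lower=False)
        new_weights = np.where(x > z, w.p, 1.0 - w.p)
        delta = np.linalg.norm(new_weights - weights) / np.linalg.norm(weights)
        weights = new_weights
        if delta < w.tol:
            ab[2] = d0 + weights
            z = solveh_banded(ab, weights * x, lower=False)
            break
    baseline = s.with_data(intensities=z)
    corrected = s.with_data(intensities=x - z)
    return baseline, corrected


def normalize_to_peak_area(
    s: Spectrum, params: PeakAreaParams = PeakAreaParams()
) -> Spectrum:
    """Divide the whole trace by the trapezoidal area over the closed window
    [center - half_width, center + half_width]; the recomputed window area of
    the result is 1."""
    lo = params.center - params.half_width
    hi = params.center + params.half_width
    mask = (s.axis >= lo) & (s.axis <= hi)
    if int(mask.sum()) < 3:
        raise DegenerateInputError(
            f"peak-area window [{lo:g}, {hi:g}] covers fewer than 3 axis points"
        )
    area = float(np.trapezoid(s.intensities[mask], s.axis[mask]))
    if area <= 1e-15:
        raise DegenerateInputError(
            f"zero or negative trapezoidal area over window [{lo:g}, {hi:g}]"
        )
    return s.with_data(intensities=s.intensities / area)


def select_region(s: Spectrum, r: RegionSpec) -> Spectrum:
    """Retain points inside any keep interval (closed) and outside every
    exclude interval (closed); order preserved; empty result is an error."""
    x = s.axis
    if r.keep:
        mask = np.zeros(x.size, dtype=bool)
        for lo, hi in r.keep:
            mask |= (x >= lo) & (x <= hi)
    else:
        mask = np.ones(x.size, dtype=bool)
    for lo, hi in r.exclude:
        mask &= ~((x >= lo) & (x <= hi))
    if not mask.any():
        raise DegenerateInputError("region selection removed every point")
    return s.with_data(axis=x[mask], intensities=s.intensities[mask])


# ---------------------------------------------------------------------------
# Set-level operator and chain composition
# ---------------------------------------------------------------------------

def mean_center(sset: SpectrumSet) -> tuple[SpectrumSet, np.ndarray]:
    """Subtract the per-wavenumber column mean; the returned means let new
    spectra be centred against the same frozen statistics."""
    if len(sset) < 2:
        raise DegenerateInputError("mean-centering needs >= 2 spectra to fit")
    X = sset.intensity_matrix()
    means = X.mean(axis=0)
    centered = [s.with_data(intensities=s.intensities - means) for s in sset]
    return SpectrumSet(centered, compositions=sset.compositions), means


#: step name -> (callable, takes-parameters?)
_PER_SPECTRUM_STEPS = {
    "select_region": select_region,
    "savgol": savgol_derivative,
    "snv": lambda s, _=None: snv(s),
    "whittaker": lambda s, p: whittaker_baseline(s, p or WhittakerParams())[1],
    "normalize_peak_area": lambda s, p: normalize_to_peak_area(s, p or PeakAreaParams()),
}
_NORMALIZATION_STEPS = {"snv", "normalize_peak_area"}
_KNOWN_STEPS = set(_PER_SPECTRUM_STEPS) | {"mean_center"}


@dataclass(frozen=True)
class PreprocessChain:
    """Ordered, parameterised preprocessing steps for one modality."""

    steps: tuple[tuple[str, object], ...]
    modality: Modality

    def __post_init__(self) -> None:
        names = [name for name, _ in self.steps]
        unknown = [n for n in names if n not in _KNOWN_STEPS]
        if unknown:
            raise ValueError(f"unknown chain steps: {unknown}; known: {sorted(_KNOWN_STEPS)}")
        if sum(n in _NORMALIZATION_STEPS for n in names) > 1:
            raise ValueError("a chain may contain at most one normalization step")
        object.__setattr__(self, "steps", tuple(self.steps))


@dataclass
class ChainState:
    """Frozen statistics fitted on the calibration set."""

    axis: np.ndarray              # processed axis after per-spectrum steps
    column_means: np.ndarray | None  # None when the chain has no mean_center


def nir_default_chain() -> PreprocessChain:
    return PreprocessChain(
        steps=(
            ("select_region", RegionSpec(keep=((4000.0, 6200.0),),
                                         exclude=((4800.0, 5200.0),))),
            ("savgol", SavGolParams()),
            ("snv", None),
            ("mean_center", None),
        ),
        modality=Modality.NIR,
    )


def raman_default_chain() -> PreprocessChain:
    return PreprocessChain(
        steps=(
            ("select_region", RegionSpec(keep=((1000.0, 1700.0),))),
            ("whittaker", WhittakerParams()),
            ("normalize_peak_area", PeakAreaParams()),
            ("mean_center", None),
        ),
        modality=Modality.RAMAN,
    )


def _apply_per_spectrum(s: Spectrum, name: str, params) -> Spectrum:
    func = _PER_SPECTRUM_STEPS[name]
    if name in ("select_region", "savgol"):
        return func(s, params)
    return func(s, params)


def apply_chain(
    sset: SpectrumSet,
    chain: PreprocessChain,
    state: ChainState | None = None,
) -> tuple[SpectrumSet, ChainState]:
    """Apply the chain in order.

    With ``state=None`` the chain is FITTED: column means are computed from
    this (calibration) set and frozen in the returned state.  With a fitted
    ``state`` the stored statistics are reused — never refit — so validation
    and prediction spectra see exactly the calibration-frozen transform.
    """
    fitting = state is None
    current = sset
    means = state.column_means if state is not None else None
    for idx, (name, params) in enumerate(chain.steps):
        try:
            if name == "mean_center":
                if fitting:
                    current, means = mean_center(current)
                else:
                    if means is None:
                        raise DegenerateInputError(
                            "chain state carries no column means for mean_center"
                        )
                    if current.axis.size != means.size:
                        raise AxisMismatchError(
                            f"processed axis has {current.axis.size} points but "
                            f"frozen means have {means.size}"
                        )
                    current = SpectrumSet(
                        [s.with_data(intensities=s.intensities - means)
                         for s in current],
                        compositions=current.compositions,
                    )
            else:
                current = SpectrumSet(
                    [_apply_per_spectrum(s, name, params) for s in current],
                    compositions=current.compositions,
                )
        except Exception as exc:
            raise ChainStepError(f"chain step {idx} ({name}): {exc}") from exc
    if state is not None and not np.array_equal(current.axis, state.axis):
        raise AxisMismatchError(
            "processed axis does not match the axis frozen in the chain state"
        )
    new_state = state if state is not None else ChainState(
        axis=current.axis.copy(), column_means=means
    )
    return current, new_state
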