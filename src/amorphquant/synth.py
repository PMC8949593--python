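"""Seeded synthetic NIR / Raman mixture-spectrum generator.

Emulates the measurement campaign every downstream stage needs: a six-level
crystalline:amorphous calibration design at constant 20% w/w drug load in
77% polymer + 3% colourant, replicate scan positions per sample, and
laser-sintered test discs whose true amorphous content follows a per-grade
conversion fraction.

The physical model is deliberately simple — linear mixing of per-component
signatures by mass fraction, pseudo-Voigt bands, an exponentially decaying
fluorescence background (Raman), a hard-supported moisture band (NIR), and a
noise model of per-spectrum multiplicative scatter, random linear baseline
drift, and i.i.d. additive noise.  Linear mixing is exactly the regime a
linear PLS calibration presumes; see docs/methods.md for what this generator
does and does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np

from . import signature_defaults as sd
from .spectra import (
    MixtureComposition,
    Modality,
    PolymerGrade,
    Presentation,
    Spectrum,
    SpectrumSet,
    average_replicates,
)

__all__ = [
    "Component",
    "PeakSpec",
    "ComponentSignature",
    "NoiseModel",
    "SimulationConfig",
    "default_axis",
    "default_signatures",
    "render_signature",
    "simulate_mixture",
    "generate_calibration_design",
    "generate_disc_set",
    "CALIBRATION_LEVELS",
    "DEFAULT_DISC_CONVERSIONS",
]


class Component(str, Enum):
    CRYSTALLINE_DRUG = "crystalline_drug"
    AMORPHOUS_DRUG = "amorphous_drug"
    POLYMER = "polymer"
    COLOURANT = "colourant"


#: Six-level calibration design: (crystalline %, amorphous %) at 20% w/w
#: total drug, 77% polymer, 3% colourant.
CALIBRATION_LEVELS: tuple[tuple[float, float], ...] = (
    (20.0, 0.0),
    (16.0, 4.0),
    (12.0, 8.0),
    (8.0, 12.0),
    (4.0, 16.0),
    (0.0, 20.0),
)

#: Invented default fractions of the 20% w/w drug load converted to amorphous
#: during sintering, per polymer grade (higher MW sinters more uniformly).
DEFAULT_DISC_CONVERSIONS: dict[PolymerGrade, float] = {
    PolymerGrade.HPC_L: 0.90,
    PolymerGrade.HPC_SL: 0.85,
    PolymerGrade.HPC_SSL: 0.65,
}


@dataclass(frozen=True)
class PeakSpec:
    """One pseudo-Voigt band: FWHM-parameterised Gaussian/Lorentzian blend."""

    center: float
    width: float          # full width at half maximum, cm^-1
    height: float
    shape_mix: float = 0.0  # 0 = Gaussian, 1 = Lorentzian

    def __post_init__(self) -> None:
        if self.width <= 0:
            raise ValueError("peak width (FWHM) must be > 0")
        if self.height < 0:
            raise ValueError("peak height must be >= 0")
        if not 0.0 <= self.shape_mix <= 1.0:
            raise ValueError("shape_mix must lie in [0, 1]")


@dataclass(frozen=True)
class ComponentSignature:
    """Spectral signature of one formulation component in one modality."""

    name: Component
    modality: Modality
    peaks: tuple[PeakSpec, ...]
    fluorescence_amplitude: float = 0.0  # Raman only
    water_band_amplitude: float = 0.0    # NIR only

    def __post_init__(self) -> None:
        if self.fluorescence_amplitude < 0 or self.water_band_amplitude < 0:
            raise ValueError("background amplitudes must be >= 0")
        if Modality(self.modality) is Modality.NIR and self.fluorescence_amplitude:
            raise ValueError("NIR signatures must have fluorescence_amplitude = 0")
        if Modality(self.modality) is Modality.RAMAN and self.water_band_amplitude:
            raise ValueError("Raman signatures must have water_band_amplitude = 0")


@dataclass(frozen=True)
class NoiseModel:
    """Per-spectrum artefact model (all standard deviations, all >= 0).

    ``multiplicative_sd`` is the log-scale sd of one scatter factor applied
    to the whole trace; ``disc_extra_scatter`` inflates it for sintered-disc
    presentations.  ``water_band_jitter_sd`` is the log-scale sd of a
    per-spectrum scale factor on the moisture band only (ambient-moisture
    variability; NIR only).
    """

    additive_sd: float = sd.DEFAULT_NOISE["additive_sd"]
    multiplicative_sd: float = sd.DEFAULT_NOISE["multiplicative_sd"]
    baseline_offset_sd: float = sd.DEFAULT_NOISE["baseline_offset_sd"]
    baseline_slope_sd: float = sd.DEFAULT_NOISE["baseline_slope_sd"]
    disc_extra_scatter: float = sd.DEFAULT_NOISE["disc_extra_scatter"]
    water_band_jitter_sd: float = sd.DEFAULT_NOISE["water_band_jitter_sd"]

    def __post_init__(self) -> None:
        for name in ("additive_sd", "multiplicative_sd", "baseline_offset_sd",
                     "baseline_slope_sd", "disc_extra_scatter",
                     "water_band_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @classmethod
    def noiseless(cls) -> "NoiseModel":
        return cls(0.0, 0.0, 0.0, 0.0, 0.0, 0.0)


def default_axis(modality: Modality) -> np.ndarray:
    """Default acquisition grid: NIR 3600..12496 step 8; Raman 100..2000 step 1."""
    if Modality(modality) is Modality.NIR:
        return np.arange(3600.0, 12500.0 + 1e-6, 8.0)
    return np.arange(100.0, 2000.0 + 1e-6, 1.0)


def default_signatures(modality: Modality) -> dict[Component, ComponentSignature]:
    """Built-in component signatures (centers literature-anchored, intensities
    invented defaults; see :mod:`amorphquant.signature_defaults`)."""
    modality = Modality(modality)
    if modality is Modality.NIR:
        peak_table, water, fluor = sd.NIR_PEAKS, sd.NIR_WATER_AMPLITUDE, None
    else:
        peak_table, water, fluor = sd.RAMAN_PEAKS, None, sd.RAMAN_FLUORESCENCE_AMPLITUDE
    out: dict[Component, ComponentSignature] = {}
    for comp in Component:
        peaks = tuple(PeakSpec(*row) for row in peak_table[comp.value])
        out[comp] = ComponentSignature(
            name=comp,
            modality=modality,
            peaks=peaks,
            fluorescence_amplitude=(fluor[comp.value] if fluor else 0.0),
            water_band_amplitude=(water[comp.value] if water else 0.0),
        )
    return out


@dataclass(frozen=True)
class SimulationConfig:
    """Grids, signatures, noise and replication for one simulated campaign."""

    modality: Modality
    axis: np.ndarray | None = None
    signatures: dict[Component, ComponentSignature] | None = None
    noise: NoiseModel = field(default_factory=NoiseModel)
    replicates_per_sample: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        axis = self.axis
        if axis is None:
            axis = default_axis(self.modality)
        axis = np.asarray(axis, dtype=float)
        steps = np.diff(axis)
        if axis.size < 2 or not np.all(steps > 0):
            raise ValueError("simulation axis must be strictly ascending")
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
            raise ValueError("simulation axis must have a uniform step")
        if self.replicates_per_sample < 1:
            raise ValueError("replicates_per_sample must be >= 1")
        object.__setattr__(self, "axis", axis)
        if self.signatures is None:
            object.__setattr__(self, "signatures", default_signatures(self.modality))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

_4LN2 = 4.0 * np.log(2.0)


def _pseudo_voigt(axis: np.ndarray, peak: PeakSpec) -> np.ndarray:
    """Unit-height pseudo-Voigt scaled by peak.height.

    Both limbs share the FWHM, so the blend has value ``height`` at the
    center and ``height/2`` at center +- FWHM/2 for any shape_mix.
    """
    d2 = (axis - peak.center) ** 2
    gauss = np.exp(-_4LN2 * d2 / peak.width**2)
    lorentz = 1.0 / (1.0 + 4.0 * d2 / peak.width**2)
    return peak.height * ((1.0 - peak.shape_mix) * gauss + peak.shape_mix * lorentz)


def _water_band(axis: np.ndarray, amplitude: float) -> np.ndarray:
    """Moisture band: Gaussian at 5000 cm^-1, exactly zero outside its support."""
    band = amplitude * np.exp(
        -_4LN2 * (axis - sd.WATER_BAND_CENTER) ** 2 / sd.WATER_BAND_FWHM**2
    )
    lo, hi = sd.WATER_BAND_SUPPORT
    band[(axis < lo) | (axis > hi)] = 0.0
    return band


def _fluorescence(axis: np.ndarray, amplitude: float) -> np.ndarray:
    return amplitude * np.exp(-axis / sd.FLUORESCENCE_TAU)


def _render_parts(sig: ComponentSignature, axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(peaks + fluorescence, water band) — split so the moisture band can be
    jittered independently by the noise model."""
    core = np.zeros_like(axis)
    for peak in sig.peaks:
        core += _pseudo_voigt(axis, peak)
    if sig.fluorescence_amplitude:
        core += _fluorescence(axis, sig.fluorescence_amplitude)
    water = (_water_band(axis, sig.water_band_amplitude)
             if sig.water_band_amplitude else np.zeros_like(axis))
    return core, water


def render_signature(sig: ComponentSignature, axis: np.ndarray) -> np.ndarray:
    """Render one component signature on a monotone ascending axis."""
    axis = np.asarray(axis, dtype=float)
    if axis.ndim != 1 or (axis.size > 1 and not np.all(np.diff(axis) > 0)):
        raise ValueError("axis must be monotone ascending")
    core, water = _render_parts(sig, axis)
    return core + water


# ---------------------------------------------------------------------------
# Mixture simulation
# ---------------------------------------------------------------------------

def simulate_mixture(
    comp: MixtureComposition,
    cfg: SimulationConfig,
    presentation: Presentation = Presentation.POWDER,
    rng: np.random.Generator | None = None,
    sample_id: str = "sample",
    position_id: int = 1,
) -> Spectrum:
    """Simulate one scan position of a mixture.

    Noiseless core = sum over components of (mass fraction / 100) x rendered
    signature; then per-spectrum multiplicative scatter, random linear
    baseline, and i.i.d. additive noise.  With every noise sd at zero the
    output is exactly the linear combination.
    """
    if rng is None:
        rng = cfg.rng()
    axis = cfg.axis
    noise = cfg.noise
    fractions = {
        Component.CRYSTALLINE_DRUG: comp.crystalline_drug,
        Component.AMORPHOUS_DRUG: comp.amorphous_drug,
        Component.POLYMER: comp.polymer,
        Component.COLOURANT: comp.colourant,
    }
    clean = np.zeros_like(axis)
    water = np.zeros_like(axis)
    for component, frac in fractions.items():
        core_part, water_part = _render_parts(cfg.signatures[component], axis)
        clean += (frac / 100.0) * core_part
        water += (frac / 100.0) * water_part
    # Fixed draw order keeps the stream reproducible regardless of parameters.
    water_jitter = np.exp(rng.normal(0.0, noise.water_band_jitter_sd)) \
        if Modality(cfg.modality) is Modality.NIR else 1.0
    scatter_sd = noise.multiplicative_sd * (
        noise.disc_extra_scatter if presentation is Presentation.PRINTED_DISC else 1.0
    )
    scatter = np.exp(rng.normal(0.0, scatter_sd))
    offset = rng.normal(0.0, noise.baseline_offset_sd)
    slope = rng.normal(0.0, noise.baseline_slope_sd)
    additive = rng.normal(0.0, noise.additive_sd, axis.size)
    half_span = 0.5 * (axis[-1] - axis[0])
    ramp = (axis - 0.5 * (axis[0] + axis[-1])) / half_span  # -1..1 across the axis
    intensities = (clean + water_jitter * water) * scatter \
        + offset + slope * ramp + additive
    return Spectrum(axis=axis, intensities=intensities, modality=cfg.modality,
                    sample_id=sample_id, position_id=position_id,
                    presentation=presentation)


# ---------------------------------------------------------------------------
# Study designs
# ---------------------------------------------------------------------------

def _simulate_sample(comp, cfg, presentation, rng, sample_id) -> list[Spectrum]:
    return [
        simulate_mixture(comp, cfg, presentation, rng,
                         sample_id=sample_id, position_id=pos)
        for pos in range(1, cfg.replicates_per_sample + 1)
    ]


def generate_calibration_design(
    cfg: SimulationConfig,
    preparations_per_level: int = 3,
    n_validation: int = 4,
    rng: np.random.Generator | None = None,
    presentation: Presentation = Presentation.POWDER,
) -> tuple[SpectrumSet, SpectrumSet, dict[str, MixtureComposition]]:
    """Simulate the six-level calibration design and split off an internal
    validation subset.

    Each of the 6 composition levels is prepared ``preparations_per_level``
    times; every preparation is scanned at ``cfg.replicates_per_sample``
    positions which are then averaged.  ``n_validation`` preparations are
    drawn without replacement (seeded) for internal validation; the defaults
    give the 14-calibration / 4-validation split.
    """
    total = 6 * preparations_per_level
    if n_validation >= total:
        raise ValueError(
            f"n_validation ({n_validation}) must be < total samples ({total})"
        )
    if rng is None:
        rng = cfg.rng()
    spectra: list[Spectrum] = []
    comps: dict[str, MixtureComposition] = {}
    for level, (cryst, amorph) in enumerate(CALIBRATION_LEVELS, start=1):
        for prep in range(1, preparations_per_level + 1):
            sid = f"cal{level}_prep{prep}"
            comps[sid] = MixtureComposition(cryst, amorph, 77.0, 3.0,
                                            PolymerGrade.HPC_L)
            spectra.extend(_simulate_sample(comps[sid], cfg, presentation, rng, sid))
    averaged = average_replicates(SpectrumSet(spectra, compositions=comps))
    ids = averaged.sample_ids
    val_idx = set(rng.choice(total, size=n_validation, replace=False).tolist())
    cal_spectra = [s for i, s in enumerate(averaged.spectra) if i not in val_idx]
    val_spectra = [s for i, s in enumerate(averaged.spectra) if i in val_idx]
    cal = SpectrumSet(cal_spectra,
                      compositions={s.sample_id: comps[s.sample_id] for s in cal_spectra})
    val = SpectrumSet(val_spectra,
                      compositions={s.sample_id: comps[s.sample_id] for s in val_spectra})
    assert len(ids) == total
    return cal, val, comps


def generate_disc_set(
    cfg: SimulationConfig,
    amorphous_conversion: dict[PolymerGrade, float] | None = None,
    n_discs_per_grade: int = 3,
    rng: np.random.Generator | None = None,
) -> SpectrumSet:
    """Simulate sintered-disc test spectra with known amorphous conversion.

    ``amorphous_conversion`` maps polymer grade to the fraction of the 20%
    w/w drug load converted to amorphous; the true amorphous content (ground
    truth retained in ``compositions``) is 20 x conversion.  Disc presentation
    activates the extra scatter term of the noise model.
    """
    if amorphous_conversion is None:
        amorphous_conversion = dict(DEFAULT_DISC_CONVERSIONS)
    for grade, conv in amorphous_conversion.items():
        if not 0.0 <= conv <= 1.0:
            raise ValueError(f"conversion for {grade} must be in [0, 1], got {conv}")
    if rng is None:
        rng = cfg.rng()
    spectra: list[Spectrum] = []
    comps: dict[str, MixtureComposition] = {}
    for grade in (PolymerGrade.HPC_L, PolymerGrade.HPC_SL, PolymerGrade.HPC_SSL):
        if grade not in amorphous_conversion:
            continue
        amorph = 20.0 * amorphous_conversion[grade]
        for k in range(1, n_discs_per_grade + 1):
            sid = f"disc_{grade.name.lower()}_{k}"
            comps[sid] = MixtureComposition(20.0 - amorph, amorph, 77.0, 3.0, grade)
            spectra.extend(
                _simulate_sample(comps[sid], cfg, Presentation.PRINTED_DISC, rng, sid)
            )
    return average_replicates(SpectrumSet(spectra, compositions=comps))
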