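"""Powder-flow characterisation: bulk/tapped density, compressibility
(Carr) index, Hausner ratio, and the pharmacopoeial flow-character scale.

    rho_b = M / V_bulk          rho_t = M / V_tapped
    CI    = 100 (rho_t - rho_b) / rho_t          HR = rho_t / rho_b

so CI and HR are tied by CI = 100 (1 - 1/HR).  Replicates are summarised by
computing the indices per replicate first and then averaging (mean of
ratios), matching how replicate standard deviations of the indices arise.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

__all__ = [
    "FlowClass",
    "PowderMeasurement",
    "FlowIndices",
    "FlowSummary",
    "bulk_density",
    "tapped_density",
    "carr_index",
    "hausner_ratio",
    "classify_flow",
    "compute_indices",
    "summarize_replicates",
    "HAUSNER_BANDS",
]


class FlowClass(IntEnum):
    """Flow character in increasing severity."""

    EXCELLENT = 0
    GOOD = 1
    FAIR = 2
    PASSABLE = 3
    POOR = 4
    VERY_POOR = 5

    @property
    def label(self) -> str:
        return self.name.replace("_", " ").capitalize()


#: Compressibility-index bands (%), half-open [lo, hi).
_CI_BANDS: tuple[tuple[float, float, FlowClass], ...] = (
    (0.0, 11.0, FlowClass.EXCELLENT),
    (11.0, 16.0, FlowClass.GOOD),
    (16.0, 21.0, FlowClass.FAIR),
    (21.0, 26.0, FlowClass.PASSABLE),
    (26.0, 32.0, FlowClass.POOR),
    (32.0, float("inf"), FlowClass.VERY_POOR),
)

#: Companion Hausner-ratio ranges, reported informationally (classification
#: is keyed on CI alone).
HAUSNER_BANDS: dict[FlowClass, tuple[float, float]] = {
    FlowClass.EXCELLENT: (1.00, 1.11),
    FlowClass.GOOD: (1.12, 1.18),
    FlowClass.FAIR: (1.19, 1.25),
    FlowClass.PASSABLE: (1.26, 1.34),
    FlowClass.POOR: (1.35, 1.45),
    FlowClass.VERY_POOR: (1.46, float("inf")),
}


def bulk_density(mass_g: float, bulk_volume_ml: float) -> float:
    """rho_b = M / V (g/mL)."""
    if mass_g <= 0 or bulk_volume_ml <= 0:
        raise ValueError("mass and bulk volume must be positive")
    return mass_g / bulk_volume_ml


def tapped_density(mass_g: float, tapped_volume_ml: float) -> float:
    """rho_t = M / V_f (g/mL), V_f the constant volume after tapping."""
    if mass_g <= 0 or tapped_volume_ml <= 0:
        raise ValueError("mass and tapped volume must be positive")
    return mass_g / tapped_volume_ml


def carr_index(rho_b: float, rho_t: float) -> float:
    """Compressibility index CI = 100 (rho_t - rho_b) / rho_t, in %."""
    if rho_b <= 0 or rho_t <= 0:
        raise ValueError("densities must be positive")
    if rho_t < rho_b:
        raise ValueError(
            "tapped density below bulk density: tapping cannot decrease density"
        )
    return 100.0 * (rho_t - rho_b) / rho_t


def hausner_ratio(rho_b: float, rho_t: float) -> float:
    """HR = rho_t / rho_b."""
    if rho_b <= 0 or rho_t <= 0:
        raise ValueError("densities must be positive")
    return rho_t / rho_b


def classify_flow(ci: float) -> FlowClass:
    """Flow character from the compressibility index (half-open CI bands)."""
    if ci < 0:
        raise ValueError("compressibility index cannot be negative")
    for lo, hi, cls in _CI_BANDS:
        if lo <= ci < hi:
            return cls
    raise AssertionError("unreachable: CI bands cover [0, inf)")


@dataclass(frozen=True)
class PowderMeasurement:
    """One replicate: mass (g), poured volume and constant tapped volume (mL)."""

    mass_g: float
    bulk_volume_ml: float
    tapped_volume_ml: float
    replicate_id: int = 1

    def __post_init__(self) -> None:
        if self.mass_g <= 0:
            raise ValueError("mass must be positive")
        if not self.bulk_volume_ml >= self.tapped_volume_ml > 0:
            raise ValueError("volumes must satisfy V_bulk >= V_tapped > 0")


@dataclass(frozen=True)
class FlowIndices:
    bulk_density: float
    tapped_density: float
    carr_index: float
    hausner_ratio: float
    flow_class: FlowClass


@dataclass(frozen=True)
class FlowSummary:
    """Replicate summary: mean +- sd (n-1) per index, class from the mean CI."""

    n: int
    bulk_density_mean: float
    bulk_density_sd: float
    tapped_density_mean: float
    tapped_density_sd: float
    carr_index_mean: float
    carr_index_sd: float
    hausner_ratio_mean: float
    hausner_ratio_sd: float
    flow_class: FlowClass


def compute_indices(m: PowderMeasurement) -> FlowIndices:
    rb = bulk_density(m.mass_g, m.bulk_volume_ml)
    rt = tapped_density(m.mass_g, m.tapped_volume_ml)
    ci = carr_index(rb, rt)
    return FlowIndices(
        bulk_density=rb,
        tapped_density=rt,
        carr_index=ci,
        hausner_ratio=hausner_ratio(rb, rt),
        flow_class=classify_flow(ci),
    )


def summarize_replicates(measurements: list[PowderMeasurement]) -> FlowSummary:
    """Per-replicate indices first, then mean +- sd of each quantity."""
    if not measurements:
        raise ValueError("need at least one replicate")
    indices = [compute_indices(m) for m in measurements]

    def _stats(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        sd = float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0
        return float(arr.mean()), sd

    rb_m, rb_s = _stats([i.bulk_density for i in indices])
    rt_m, rt_s = _stats([i.tapped_density for i in indices])
    ci_m, ci_s = _stats([i.carr_index for i in indices])
    hr_m, hr_s = _stats([i.hausner_ratio for i in indices])
    return FlowSummary(
        n=len(indices),
        bulk_density_mean=rb_m, bulk_density_sd=rb_s,
        tapped_density_mean=rt_m, tapped_density_sd=rt_s,
        carr_index_mean=ci_m, carr_index_sd=ci_s,
        hausner_ratio_mean=hr_m, hausner_ratio_sd=hr_s,
        flow_class=classify_flow(ci_m),
    )
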