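"""End-to-end calibration workflow.

Simulate (or load) calibration + validation + disc spectra, apply the
modality's preset preprocessing chain (fitted on calibration only), select
the latent-variable count by leave-one-out cross-validation, fit the final
PLS model, validate it ICH-style (specificity = LV1 % X-variance, linearity
= R^2 over the 0-20% w/w range, accuracy = RMSEP), check score-space
admissibility against the 95% Hotelling ellipse, and report per-grade
predicted amorphous content mean +- sd for sintered test discs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .pls import (
    CrossValResult,
    PLSModel,
    ScoresEllipse,
    ValidationReport,
    fit_pls,
    hotelling_ellipse,
    loocv,
    predict,
    project_scores,
    serialize_model,
    validation_metrics,
)
from .preprocess import (
    ChainState,
    PreprocessChain,
    apply_chain,
    nir_default_chain,
    raman_default_chain,
)
from .spectra import (
    Modality,
    Presentation,
    SpectrumSet,
    average_replicates,
    read_metadata_json,
    read_spectra_csv,
)
from .synth import SimulationConfig, generate_calibration_design

__all__ = [
    "PipelineConfig",
    "CalibrationRun",
    "PredictionRecord",
    "default_chain",
    "run_calibration",
    "calibrate_from_sets",
    "run_prediction",
    "ich_report",
    "report_to_markdown",
    "validate_report",
    "REPORT_SCHEMA",
]

#: Amorphous-content calibration range of the reference design (% w/w).
CALIBRATION_RANGE = (0.0, 20.0)


def default_chain(modality: Modality) -> PreprocessChain:
    return (nir_default_chain() if Modality(modality) is Modality.NIR
            else raman_default_chain())


@dataclass
class PipelineConfig:
    """One calibration run: exactly one of ``sim`` or ``spectra_path`` feeds it."""

    modality: Modality
    sim: SimulationConfig | None = None
    spectra_path: str | Path | None = None
    metadata_path: str | Path | None = None
    chain: PreprocessChain | None = None
    max_lv: int = 6
    alpha: float = 0.05
    preparations_per_level: int = 3
    n_validation: int = 4
    out_dir: str | Path | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.sim is None) == (self.spectra_path is None):
            raise ValueError(
                "provide exactly one of a simulation config or an input spectra path"
            )
        if self.spectra_path is not None and self.metadata_path is None:
            raise ValueError("file input needs a metadata sidecar path")


@dataclass
class CalibrationRun:
    """All artifacts of one calibration: enough for exact re-use."""

    model: PLSModel
    cv: CrossValResult
    report: ValidationReport
    ellipse: ScoresEllipse
    ellipse_model: PLSModel  # == model when n_lv >= 2; else auxiliary 2-LV fit
    chain: PreprocessChain
    chain_state: ChainState
    cal_set: SpectrumSet
    val_set: SpectrumSet
    y_cal: np.ndarray
    y_val: np.ndarray
    yhat_cal: np.ndarray
    yhat_val: np.ndarray


@dataclass
class PredictionRecord:
    """Per-grade tabular prediction summary for sintered discs."""

    sample_id: str
    presentation: Presentation
    predicted_amorphous_mean: float
    predicted_amorphous_sd: float
    inside_95_ellipse: bool
    true_amorphous: float | None = None


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def calibrate_from_sets(
    cal_set: SpectrumSet,
    val_set: SpectrumSet,
    chain: PreprocessChain,
    max_lv: int = 6,
    alpha: float = 0.05,
) -> CalibrationRun:
    """Fit and validate a PLS calibration from already-averaged spectrum sets.

    The preprocessing chain and all fitted statistics are computed on the
    calibration set only; validation spectra see the frozen transform and
    never influence the model (no leakage).
    """
    processed_cal, state = apply_chain(cal_set, chain)
    X = processed_cal.intensity_matrix()
    y = cal_set.y_vector("amorphous_drug")
    cv = loocv(X, y, max_lv)
    model = fit_pls(X, y, cv.selected_n_lv, axis=state.axis, chain_state=state)
    yhat_cal = predict(model, X)
    cal_metrics = validation_metrics(y, yhat_cal, "CAL")
    processed_val, _ = apply_chain(val_set, chain, state=state)
    X_val = processed_val.intensity_matrix()
    y_val = val_set.y_vector("amorphous_drug")
    yhat_val = predict(model, X_val, axis=state.axis)
    val_metrics = validation_metrics(y_val, yhat_val, "PRED")
    ellipse_model = model if model.n_lv >= 2 else fit_pls(
        X, y, 2, axis=state.axis, chain_state=state, strict=False
    )
    ellipse = hotelling_ellipse(ellipse_model, alpha=alpha)
    report = ValidationReport(
        r2_cal=cal_metrics["r2"],
        r2_pred=val_metrics["r2"],
        rmsec=cal_metrics["rmse"],
        rmsecv=float(cv.rmsecv_by_nlv[cv.selected_n_lv - 1]),
        rmsep=val_metrics["rmse"],
        lv1_percent_x_variance=float(model.x_variance_explained[0]),
        bias=val_metrics["bias"],
    )
    return CalibrationRun(
        model=model, cv=cv, report=report, ellipse=ellipse,
        ellipse_model=ellipse_model, chain=chain, chain_state=state,
        cal_set=cal_set, val_set=val_set, y_cal=y, y_val=y_val,
        yhat_cal=yhat_cal, yhat_val=yhat_val,
    )


def _resolve_input_sets(cfg: PipelineConfig) -> tuple[SpectrumSet, SpectrumSet]:
    if cfg.sim is not None:
        rng = np.random.default_rng(cfg.seed)
        cal, val, _ = generate_calibration_design(
            cfg.sim, cfg.preparations_per_level, cfg.n_validation, rng=rng
        )
        return cal, val
    sset = read_spectra_csv(cfg.spectra_path, cfg.modality)
    comps, _pres = read_metadata_json(cfg.metadata_path)
    averaged = average_replicates(
        SpectrumSet(sset.spectra, compositions=comps)
    )
    n = len(averaged)
    if cfg.n_validation >= n:
        raise ValueError(f"n_validation ({cfg.n_validation}) must be < samples ({n})")
    rng = np.random.default_rng(cfg.seed)
    val_idx = set(rng.choice(n, size=cfg.n_validation, replace=False).tolist())
    cal = SpectrumSet([s for i, s in enumerate(averaged.spectra) if i not in val_idx],
                      compositions=comps)
    val = SpectrumSet([s for i, s in enumerate(averaged.spectra) if i in val_idx],
                      compositions=comps)
    return cal, val


def run_calibration(cfg: PipelineConfig) -> CalibrationRun:
    """Resolve inputs, calibrate, and (optionally) serialize all artifacts."""
    chain = cfg.chain if cfg.chain is not None else default_chain(cfg.modality)
    cal_set, val_set = _resolve_input_sets(cfg)
    run = calibrate_from_sets(cal_set, val_set, chain,
                              max_lv=cfg.max_lv, alpha=cfg.alpha)
    if cfg.out_dir is not None:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        serialize_model(run.model, out / "model.json")
        doc = ich_report(run.report, run.cv, run.ellipse, modality=cfg.modality,
                         seed=cfg.seed)
        (out / "report.json").write_text(report_json(doc), encoding="utf-8")
        (out / "report.md").write_text(report_to_markdown(doc), encoding="utf-8")
    return run


# ---------------------------------------------------------------------------
# Prediction on sintered discs
# ---------------------------------------------------------------------------

def run_prediction(
    run: CalibrationRun, disc_set: SpectrumSet
) -> tuple[list[PredictionRecord], pd.DataFrame]:
    """Predict amorphous content of sintered discs, grouped by polymer grade.

    Returns grade-level records (mean +- sd over the discs of that grade;
    ``inside_95_ellipse`` true iff every disc of the grade passes the
    Hotelling test) plus a per-disc table with individual predictions,
    T^2 values and flags.
    """
    processed, _ = apply_chain(disc_set, run.chain, state=run.chain_state)
    X = processed.intensity_matrix()
    yhat = predict(run.model, X, axis=run.chain_state.axis)
    scores = project_scores(run.ellipse_model, X)
    pair_cols = [k - 1 for k in run.ellipse.lv_pair]
    t2 = run.ellipse.t2(scores[:, pair_cols])
    inside = t2 <= run.ellipse.t2_limit
    rows = []
    for s, pred, t2_i, ok in zip(disc_set.spectra, yhat, t2, inside):
        comp = (disc_set.compositions or {}).get(s.sample_id)
        rows.append({
            "sample_id": s.sample_id,
            "presentation": s.presentation.value,
            "polymer_grade": comp.polymer_grade.value if comp else "",
            "true_amorphous": comp.amorphous_drug if comp else np.nan,
            "predicted_amorphous": float(pred),
            "t2": float(t2_i),
            "inside_95_ellipse": bool(ok),
        })
    per_disc = pd.DataFrame(rows)
    records: list[PredictionRecord] = []
    for grade, grp in per_disc.groupby("polymer_grade", sort=False):
        preds = grp["predicted_amorphous"].to_numpy()
        sd = float(np.std(preds, ddof=1)) if preds.size > 1 else 0.0
        truth = grp["true_amorphous"].to_numpy()
        records.append(PredictionRecord(
            sample_id=str(grade),
            presentation=Presentation(grp["presentation"].iloc[0]),
            predicted_amorphous_mean=float(np.mean(preds)),
            predicted_amorphous_sd=sd,
            inside_95_ellipse=bool(grp["inside_95_ellipse"].all()),
            true_amorphous=(float(truth[0]) if np.all(np.isfinite(truth)) else None),
        ))
    return records, per_disc


# ---------------------------------------------------------------------------
# ICH-style report
# ---------------------------------------------------------------------------

REPORT_SCHEMA = {
    "required": {
        "modality": str,
        "seed": int,
        "calibration_range_percent_ww": list,
        "specificity": dict,
        "linearity": dict,
        "accuracy": dict,
        "lv_selection": dict,
        "score_ellipse": dict,
    },
    "specificity": {"lv1_percent_x_variance": float},
    "linearity": {"r2_cal": float, "r2_pred": float},
    "accuracy": {"rmsec": float, "rmsecv": float, "rmsep": float, "bias": float},
    "lv_selection": {"selected_n_lv": int, "rmsecv_by_nlv": list,
                     "selection_rule": str},
    "score_ellipse": {"alpha": float, "t2_limit": float, "n_cal": int},
}


def ich_report(v: ValidationReport, c: CrossValResult, e: ScoresEllipse,
               modality: Modality | str = Modality.NIR, seed: int = 0) -> dict:
    """Machine-readable validation report: specificity / linearity / accuracy
    plus the LV-selection trace and ellipse parameters."""
    return {
        "modality": Modality(modality).value,
        "seed": int(seed),
        "calibration_range_percent_ww": list(CALIBRATION_RANGE),
        "specificity": {
            "lv1_percent_x_variance": float(v.lv1_percent_x_variance),
        },
        "linearity": {
            "r2_cal": float(v.r2_cal),
            "r2_pred": float(v.r2_pred),
        },
        "accuracy": {
            "rmsec": float(v.rmsec),
            "rmsecv": float(v.rmsecv),
            "rmsep": float(v.rmsep),
            "bias": float(v.bias),
        },
        "lv_selection": {
            "selected_n_lv": int(c.selected_n_lv),
            "rmsecv_by_nlv": [None if not np.isfinite(x) else float(x)
                              for x in c.rmsecv_by_nlv],
            "selection_rule": c.selection_rule,
        },
        "score_ellipse": {
            "alpha": float(e.alpha),
            "t2_limit": float(e.t2_limit),
            "n_cal": int(e.n_cal),
        },
    }


def report_json(doc: dict) -> str:
    """Canonical (byte-reproducible) JSON serialization of a report."""
    return json.dumps(doc, sort_keys=True, indent=2) + "\n"


def report_hash(doc: dict) -> str:
    return hashlib.sha256(report_json(doc).encode("utf-8")).hexdigest()


def validate_report(doc: dict) -> None:
    """Validate a report against :data:`REPORT_SCHEMA`; raises ValueError."""
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in doc:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(doc[key], typ):
            raise ValueError(f"report key {key!r} must be {typ.__name__}")
    for section in ("specificity", "linearity", "accuracy", "lv_selection",
                    "score_ellipse"):
        for key, typ in REPORT_SCHEMA[section].items():
            if key not in doc[section]:
                raise ValueError(f"report section {section!r} missing {key!r}")
            val = doc[section][key]
            if typ is float and isinstance(val, int):
                continue
            if not isinstance(val, typ):
                raise ValueError(
                    f"report field {section}.{key} must be {typ.__name__}"
                )
    lo, hi = doc["calibration_range_percent_ww"]
    if [lo, hi] != list(CALIBRATION_RANGE):
        raise ValueError("calibration range must be the reference 0-20% w/w design")


def report_to_markdown(doc: dict) -> str:
    """Human-readable rendering of an ICH-style report."""
    lines = [
        f"# PLS calibration report ({doc['modality'].upper()})",
        "",
        f"Calibration range: {doc['calibration_range_percent_ww'][0]:g}-"
        f"{doc['calibration_range_percent_ww'][1]:g}% w/w amorphous content; "
        f"seed {doc['seed']}.",
        "",
        "| Criterion | Metric | Value |",
        "|---|---|---|",
        "| Specificity | LV1 % X-variance | "
        f"{doc['specificity']['lv1_percent_x_variance']:.2f} |",
        f"| Linearity | R2 (calibration) | {doc['linearity']['r2_cal']:.4f} |",
        f"| Linearity | R2 (prediction) | {doc['linearity']['r2_pred']:.4f} |",
        f"| Accuracy | RMSEC (% w/w) | {doc['accuracy']['rmsec']:.3f} |",
        f"| Accuracy | RMSECV (% w/w) | {doc['accuracy']['rmsecv']:.3f} |",
        f"| Accuracy | RMSEP (% w/w) | {doc['accuracy']['rmsep']:.3f} |",
        f"| Accuracy | Bias (% w/w) | {doc['accuracy']['bias']:+.3f} |",
        "",
        f"Latent variables: {doc['lv_selection']['selected_n_lv']} "
        f"({doc['lv_selection']['selection_rule']}).",
        "",
        f"Score-space admissibility: Hotelling T2 limit "
        f"{doc['score_ellipse']['t2_limit']:.3f} at alpha = "
        f"{doc['score_ellipse']['alpha']:g} "
        f"(n = {doc['score_ellipse']['n_cal']} calibration samples).",
        "",
    ]
    return "\n".join(lines)
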