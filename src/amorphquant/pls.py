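"""Single-response partial least squares (PLS1) by NIPALS, with leave-one-out
cross-validation, ICH-style validation metrics, explained-variance accounting
and Hotelling T^2 score-space diagnostics.

For each latent variable k on the centred data (X, y):

    w_k = X' y / ||X' y||        (weights)
    t_k = X w_k                  (scores)
    p_k = X' t_k / t_k' t_k      (X loadings)
    q_k = y' t_k / t_k' t_k      (y loading)
    X  <- X - t_k p_k',  y <- y - q_k t_k   (deflation)

The regression vector in the centred frame is b = W (P'W)^-1 q, so
predictions are yhat = (X_new - x_mean) b + y_mean.  Fitting is fully
deterministic; only the simulator consumes randomness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import f as f_dist

from .preprocess import ChainState
from .spectra import AxisMismatchError, DegenerateInputError

__all__ = [
    "PLSModel",
    "CrossValResult",
    "ValidationReport",
    "ScoresEllipse",
    "DegenerateFitError",
    "fit_pls",
    "predict",
    "project_scores",
    "loocv",
    "loo_predictions",
    "validation_metrics",
    "hotelling_ellipse",
    "explained_variance",
    "serialize_model",
    "load_model",
]

_MODEL_FORMAT = "amorphquant-pls"
_MODEL_VERSION = 1


class DegenerateFitError(ValueError):
    """y is (numerically) orthogonal to X; no latent variable can be extracted."""


@dataclass
class PLSModel:
    n_lv: int
    x_mean: np.ndarray
    y_mean: float
    weights: np.ndarray              # W, (n_vars, n_lv)
    x_loadings: np.ndarray           # P, (n_vars, n_lv)
    y_loadings: np.ndarray           # q, (n_lv,)
    regression_vector: np.ndarray    # b, (n_vars,), centred frame
    scores: np.ndarray               # T, (n_samples, n_lv)
    x_variance_explained: np.ndarray  # % per LV
    y_variance_explained: np.ndarray  # % per LV
    axis: np.ndarray | None = None   # retained wavenumbers, if known
    chain_state: ChainState | None = None


@dataclass
class CrossValResult:
    rmsecv_by_nlv: np.ndarray  # index k-1 -> RMSECV at k LVs (NaN = unavailable)
    selected_n_lv: int
    selection_rule: str


@dataclass
class ValidationReport:
    """ICH-style summary: specificity (LV1 %), linearity (R^2), accuracy
    (RMSE*, % w/w amorphous content), and mean signed bias."""

    r2_cal: float
    r2_pred: float
    rmsec: float
    rmsecv: float
    rmsep: float
    lv1_percent_x_variance: float
    bias: float


@dataclass
class ScoresEllipse:
    """Hotelling T^2 admissibility ellipse over one pair of latent variables."""

    t2_limit: float
    score_variances: np.ndarray  # per-LV variances from calibration scores (n-1)
    n_cal: int
    lv_pair: tuple[int, int] = (1, 2)
    alpha: float = 0.05

    def t2(self, scores: np.ndarray) -> np.ndarray:
        """T^2 for (n, 2) score rows over the ellipse's LV pair."""
        scores = np.atleast_2d(np.asarray(scores, dtype=float))
        return np.sum(scores**2 / self.score_variances, axis=1)

    def contains(self, scores: np.ndarray) -> np.ndarray:
        return self.t2(scores) <= self.t2_limit


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _nipals(Xc: np.ndarray, yc: np.ndarray, n_lv: int,
            tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                                         np.ndarray, int]:
    """Run NIPALS PLS1 for up to n_lv components; returns (W, P, q, T, achieved)."""
    n, p = Xc.shape
    W = np.zeros((p, n_lv))
    P = np.zeros((p, n_lv))
    q = np.zeros(n_lv)
    T = np.zeros((n, n_lv))
    X = Xc.copy()
    y = yc.copy()
    scale = max(np.linalg.norm(Xc) * np.linalg.norm(yc), 1.0)
    achieved = 0
    for k in range(n_lv):
        w = X.T @ y
        nw = np.linalg.norm(w)
        if nw <= tol * scale:
            break
        w /= nw
        t = X @ w
        tt = float(t @ t)
        if tt <= tol * scale:
            break
        W[:, k] = w
        P[:, k] = X.T @ t / tt
        q[k] = float(y @ t) / tt
        T[:, k] = t
        X = X - np.outer(t, P[:, k])
        y = y - q[k] * t
        achieved = k + 1
    return (W[:, :achieved], P[:, :achieved], q[:achieved],
            T[:, :achieved], achieved)


def _regression_vector(W: np.ndarray, P: np.ndarray, q: np.ndarray,
                       k: int | None = None) -> np.ndarray:
    """b = W (P'W)^-1 q using the leading k components (nested in k)."""
    if k is None:
        k = W.shape[1]
    Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
    return Wk @ np.linalg.solve(Pk.T @ Wk, qk)


def fit_pls(X: np.ndarray, y: np.ndarray, n_lv: int,
            axis: np.ndarray | None = None,
            chain_state: ChainState | None = None,
            strict: bool = True) -> PLSModel:
    """Fit a PLS1 model with ``n_lv`` latent variables (centering internal).

    With ``strict=True`` (default) failing to extract all requested
    components raises :class:`DegenerateFitError`; with ``strict=False`` the
    model is returned with however many components were achievable (>= 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree on the number of samples")
    if n_lv < 1:
        raise ValueError("n_lv must be >= 1")
    if n < n_lv + 1:
        raise ValueError(f"need >= n_lv + 1 = {n_lv + 1} samples, got {n}")
    if p < n_lv:
        raise ValueError(f"need >= n_lv = {n_lv} variables, got {p}")
    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    W, P, q, T, achieved = _nipals(Xc, yc, n_lv)
    if achieved == 0:
        raise DegenerateFitError(
            "response is numerically orthogonal to the spectra; no latent "
            "variable can be extracted"
        )
    if strict and achieved < n_lv:
        raise DegenerateFitError(
            f"only {achieved} of {n_lv} requested latent variables are "
            "extractable from this data"
        )
    ssx = float(np.sum(Xc**2))
    ssy = float(np.sum(yc**2))
    tt = np.sum(T**2, axis=0)
    pp = np.sum(P**2, axis=0)
    xve = 100.0 * tt * pp / ssx if ssx > 0 else np.zeros(achieved)
    yve = 100.0 * q**2 * tt / ssy if ssy > 0 else np.zeros(achieved)
    b = _regression_vector(W, P, q)
    return PLSModel(
        n_lv=achieved, x_mean=x_mean, y_mean=y_mean,
        weights=W, x_loadings=P, y_loadings=q,
        regression_vector=b, scores=T,
        x_variance_explained=xve, y_variance_explained=yve,
        axis=None if axis is None else np.asarray(axis, dtype=float),
        chain_state=chain_state,
    )


def _check_axis(m: PLSModel, X_new: np.ndarray,
                axis: np.ndarray | None) -> np.ndarray:
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != m.x_mean.size:
        raise AxisMismatchError(
            f"model retains {m.x_mean.size} wavenumbers but input has "
            f"{X_new.shape[1]} columns"
        )
    if axis is not None and m.axis is not None and not np.array_equal(
            np.asarray(axis, dtype=float), m.axis):
        raise AxisMismatchError("input wavenumber axis differs from the model's")
    return X_new


def predict(m: PLSModel, X_new: np.ndarray,
            axis: np.ndarray | None = None) -> np.ndarray:
    """yhat = (X_new - x_mean) b + y_mean on the model's retained wavenumbers."""
    X_new = _check_axis(m, X_new, axis)
    return (X_new - m.x_mean) @ m.regression_vector + m.y_mean


def project_scores(m: PLSModel, X_new: np.ndarray,
                   axis: np.ndarray | None = None) -> np.ndarray:
    """Latent-variable scores of new samples: (X_new - x_mean) W (P'W)^-1."""
    X_new = _check_axis(m, X_new, axis)
    R = np.linalg.solve((m.x_loadings.T @ m.weights).T, m.weights.T).T
    return (X_new - m.x_mean) @ R


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def loo_predictions(X: np.ndarray, y: np.ndarray, max_lv: int) -> np.ndarray:
    """(max_lv, n) held-out predictions: row k-1 = LOO predictions at k LVs.

    Each fold refits (with re-centering) on the remaining samples only; the
    held-out sample never enters centering or weights.  NIPALS components are
    nested, so one fit per fold yields every k.  Unavailable (degenerate)
    components are NaN.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    preds = np.full((max_lv, n), np.nan)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        try:
            m = fit_pls(X[mask], y[mask], max_lv, strict=False)
        except DegenerateFitError:
            continue
        xc = X[i] - m.x_mean
        for k in range(1, m.n_lv + 1):
            b_k = _regression_vector(m.weights, m.x_loadings, m.y_loadings, k)
            preds[k - 1, i] = float(xc @ b_k) + m.y_mean
    return preds


def loocv(X: np.ndarray, y: np.ndarray, max_lv: int,
          parsimony_tolerance: float = 0.02) -> CrossValResult:
    """Leave-one-out cross-validation with a parsimony selection rule.

    RMSECV(k) is the root mean squared held-out error over the n folds;
    the selected component count is the smallest k whose RMSECV is within
    ``parsimony_tolerance`` (relative) of the minimum.
    """
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if max_lv > n - 2:
        raise ValueError(f"max_lv must be <= n_samples - 2 = {n - 2}")
    preds = loo_predictions(X, y, max_lv)
    rmsecv = np.full(max_lv, np.nan)
    for k in range(max_lv):
        if np.all(np.isfinite(preds[k])):
            rmsecv[k] = float(np.sqrt(np.mean((preds[k] - y) ** 2)))
    if not np.any(np.isfinite(rmsecv)):
        raise DegenerateFitError("no latent-variable count is available under LOOCV")
    best = float(np.nanmin(rmsecv))
    threshold = (1.0 + parsimony_tolerance) * best
    selected = int(np.flatnonzero(np.isfinite(rmsecv) & (rmsecv <= threshold))[0]) + 1
    rule = (f"smallest n_lv with RMSECV <= {1.0 + parsimony_tolerance:g} x "
            f"min RMSECV (min {best:.6g} at "
            f"{int(np.nanargmin(rmsecv)) + 1} LV)")
    return CrossValResult(rmsecv_by_nlv=rmsecv, selected_n_lv=selected,
                          selection_rule=rule)


# ---------------------------------------------------------------------------
# Metrics and diagnostics
# ---------------------------------------------------------------------------

def validation_metrics(y_true: np.ndarray, y_pred: np.ndarray,
                       context: str = "CAL") -> dict:
    """RMSE, coefficient of determination (1 - SSE/SST) and mean signed bias."""
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.size != y_pred.size or y_true.size < 2:
        raise ValueError("y_true and y_pred must share a length >= 2")
    sst = float(np.sum((y_true - y_true.mean()) ** 2))
    if sst <= 0:
        raise DegenerateInputError("r^2 undefined: y_true has zero variance")
    sse = float(np.sum((y_true - y_pred) ** 2))
    return {
        "context": context,
        "rmse": float(np.sqrt(np.mean((y_true - y_pred) ** 2))),
        "r2": 1.0 - sse / sst,
        "bias": float(np.mean(y_pred - y_true)),
    }


def hotelling_ellipse(m: PLSModel, lv_pair: tuple[int, int] = (1, 2),
                      alpha: float = 0.05) -> ScoresEllipse:
    """95% (by default) confidence ellipse over a pair of latent variables.

    T^2(t) = sum over the pair of t_k^2 / var(t_k), with variances from the
    calibration scores (n-1 denominator) and the F-based small-sample limit
    2(n-1)/(n-2) * F(1-alpha; 2, n-2).
    """
    n = m.scores.shape[0]
    if n < 4:
        raise DegenerateInputError("Hotelling ellipse needs >= 4 calibration samples")
    if max(lv_pair) > m.n_lv:
        raise DegenerateInputError(
            f"LV pair {lv_pair} not available in a {m.n_lv}-LV model"
        )
    cols = [k - 1 for k in lv_pair]
    variances = np.var(m.scores[:, cols], axis=0, ddof=1)
    if np.any(variances <= 0):
        raise DegenerateInputError("zero score variance; ellipse is degenerate")
    limit = 2.0 * (n - 1) / (n - 2) * float(f_dist.ppf(1.0 - alpha, 2, n - 2))
    return ScoresEllipse(t2_limit=limit, score_variances=variances,
                         n_cal=n, lv_pair=tuple(lv_pair), alpha=alpha)


def explained_variance(m: PLSModel) -> np.ndarray:
    """Per-LV % of (centred) X variance captured; entries sum to <= 100."""
    return m.x_variance_explained


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _arr(x) -> list:
    return np.asarray(x, dtype=float).tolist()


def serialize_model(m: PLSModel, path: str | Path) -> Path:
    """JSON round-trip preserving all numeric fields exactly (shortest-repr
    doubles survive a JSON round trip bit-for-bit)."""
    path = Path(path)
    doc = {
        "format": _MODEL_FORMAT,
        "version": _MODEL_VERSION,
        "n_lv": m.n_lv,
        "x_mean": _arr(m.x_mean),
        "y_mean": m.y_mean,
        "weights": _arr(m.weights),
        "x_loadings": _arr(m.x_loadings),
        "y_loadings": _arr(m.y_loadings),
        "regression_vector": _arr(m.regression_vector),
        "scores": _arr(m.scores),
        "x_variance_explained": _arr(m.x_variance_explained),
        "y_variance_explained": _arr(m.y_variance_explained),
        "axis": None if m.axis is None else _arr(m.axis),
        "chain_state": None if m.chain_state is None else {
            "axis": _arr(m.chain_state.axis),
            "column_means": (None if m.chain_state.column_means is None
                             else _arr(m.chain_state.column_means)),
        },
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh, sort_keys=True)
    return path


def load_model(path: str | Path) -> PLSModel:
    path = Path(path)
    try:
        with open(path, encoding="utf-8") as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise ValueError(f"{path}: not a readable model file ({exc})") from exc
    if not isinstance(doc, dict) or doc.get("format") != _MODEL_FORMAT:
        raise ValueError(f"{path}: not an {_MODEL_FORMAT} model file")
    if doc.get("version") != _MODEL_VERSION:
        raise ValueError(
            f"{path}: model version {doc.get('version')!r} unsupported "
            f"(expected {_MODEL_VERSION})"
        )
    cs = doc.get("chain_state")
    chain_state = None
    if cs is not None:
        chain_state = ChainState(
            axis=np.asarray(cs["axis"], dtype=float),
            column_means=(None if cs["column_means"] is None
                          else np.asarray(cs["column_means"], dtype=float)),
        )
    return PLSModel(
        n_lv=int(doc["n_lv"]),
        x_mean=np.asarray(doc["x_mean"], dtype=float),
        y_mean=float(doc["y_mean"]),
        weights=np.asarray(doc["weights"], dtype=float),
        x_loadings=np.asarray(doc["x_loadings"], dtype=float),
        y_loadings=np.asarray(doc["y_loadings"], dtype=float),
        regression_vector=np.asarray(doc["regression_vector"], dtype=float),
        scores=np.asarray(doc["scores"], dtype=float),
        x_variance_explained=np.asarray(doc["x_variance_explained"], dtype=float),
        y_variance_explained=np.asarray(doc["y_variance_explained"], dtype=float),
        axis=None if doc["axis"] is None else np.asarray(doc["axis"], dtype=float),
        chain_state=chain_state,
    )
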