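"""Per-subject response-scale calibration and the tempo-shift statistic.

A participant's 0-100 ratings are regressed on log2 relative tempo, yielding
an intercept ``beta0`` (expected rating at the reference tempo) and slope
``beta1`` (rating points per tempo doubling).  Trials with Cook's distance
above 4/n on the initial fit are flagged and the line is refit once without
them.  Residual ratings ``rho = r - r_hat`` are converted to a perceived
tempo shift ``tau = 100 * rho / beta1`` in log2-percent units: tau = 100
means the tone was rated as if its tempo had doubled.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFitError, InvalidArgumentError, UndefinedShiftError

__all__ = [
    "GroundTruth",
    "CalibrationModel",
    "ground_truth_rating",
    "log2_relative_tempo",
    "fit_calibration",
    "cooks_distance",
    "residual_rating",
    "tempo_shift",
    "perceived_tempo",
    "score_participant",
    "score_study",
]

#: Intercept and slope of the response scale implied by the slider labels:
#: 50 at the reference tempo, +50 points per doubling.
GroundTruth = (50.0, 50.0)


@dataclass(frozen=True)
class CalibrationModel:
    """Outlier-screened linear map from log2 relative tempo to rating."""

    beta0: float
    beta1: float
    cooks_threshold: float
    outlier_mask: np.ndarray  # True where the trial was flagged
    cooks_d: np.ndarray
    n_used: int

    @property
    def n_outliers(self) -> int:
        return int(self.outlier_mask.sum())

    def predict(self, log2_rel_tempo) -> np.ndarray:
        return self.beta0 + self.beta1 * np.asarray(log2_rel_tempo, dtype=float)


def ground_truth_rating(t, t_ref) -> "float | np.ndarray":
    """Rating implied by the slider labels: 50 + 50*log2(t/t_ref).

    Not clipped to [0, 100].
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0) or t_ref <= 0:
        raise InvalidArgumentError("tempos must be positive")
    out = 50.0 + 50.0 * np.log2(t / t_ref)
    return float(out) if out.ndim == 0 else out


def log2_relative_tempo(ioi_ms, ref_ioi_ms) -> np.ndarray:
    """log2(t/t_ref) computed from intervals as log2(ref_ioi/ioi)."""
    ioi = np.asarray(ioi_ms, dtype=float)
    if np.any(ioi <= 0) or ref_ioi_ms <= 0:
        raise InvalidArgumentError("intervals must be positive")
    return np.log2(ref_ioi_ms / ioi)


def _ols(x: np.ndarray, y: np.ndarray):
    X = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    return X, coef


def cooks_distance(x, y, coef=None) -> np.ndarray:
    """Per-observation Cook's distance for a simple linear regression.

    D_i = (e_i^2 / (p s^2)) * (h_ii / (1 - h_ii)^2) with p = 2 parameters,
    s^2 the residual mean square, and h_ii the leverage.  Observations with
    leverage 1 get D = inf.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise InvalidArgumentError("need at least 3 observations")
    X = np.column_stack([np.ones_like(x), x])
    if coef is None:
        coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    e = y - X @ coef
    p = X.shape[1]
    XtX_inv = np.linalg.inv(X.T @ X)
    h = np.einsum("ij,jk,ik->i", X, XtX_inv, X)
    sse = e @ e
    # numerically perfect fits: residuals at rounding level, D defined as 0
    sst = float(np.sum((y - y.mean()) ** 2))
    if sse <= 1e-20 * max(1.0, sst):
        return np.zeros(n)
    s2 = sse / (n - p)
    with np.errstate(divide="ignore", invalid="ignore"):
        d = (e**2 / (p * s2)) * (h / (1.0 - h) ** 2)
    d[np.isclose(h, 1.0)] = np.inf
    return d


def fit_calibration(
    ioi_ms, ratings, ref_ioi_ms, cooks_threshold: float | None = None
) -> CalibrationModel:
    """Calibrate a participant's response scale with one outlier pass.

    OLS of rating on log2 relative tempo; trials with Cook's distance above
    the threshold (default 4/n) on this initial fit are flagged; the model is
    refit once on the remaining trials.
    """
    x = log2_relative_tempo(ioi_ms, ref_ioi_ms)
    y = np.asarray(ratings, dtype=float)
    if x.size != y.size:
        raise InvalidArgumentError("ioi_ms and ratings length mismatch")
    if x.size < 3 or np.unique(x).size < 2:
        raise DegenerateFitError("need >= 3 trials spanning >= 2 tempos")
    if cooks_threshold is None:
        cooks_threshold = 4.0 / x.size
    d = cooks_distance(x, y)
    mask = d > cooks_threshold
    keep = ~mask
    if np.unique(x[keep]).size < 2:
        raise DegenerateFitError("outlier exclusion left a single tempo")
    _, coef = _ols(x[keep], y[keep])
    return CalibrationModel(
        beta0=float(coef[0]),
        beta1=float(coef[1]),
        cooks_threshold=float(cooks_threshold),
        outlier_mask=mask,
        cooks_d=d,
        n_used=int(keep.sum()),
    )


def residual_rating(ioi_ms, ratings, model: CalibrationModel, ref_ioi_ms) -> np.ndarray:
    """Observed minus predicted rating, rho = r - r_hat."""
    x = log2_relative_tempo(ioi_ms, ref_ioi_ms)
    return np.asarray(ratings, dtype=float) - model.predict(x)


def tempo_shift(rho, beta1: float) -> "float | np.ndarray":
    """Perceived-tempo shift in log2-percent: tau = 100 * rho / beta1."""
    if beta1 == 0:
        raise UndefinedShiftError("calibration slope is zero")
    out = 100.0 * np.asarray(rho, dtype=float) / beta1
    return float(out) if out.ndim == 0 else out


def perceived_tempo(rating, model: CalibrationModel, t_ref: float) -> "float | np.ndarray":
    """Tempo implied by a rating under the subject's own scale:
    t_hat = t_ref * 2**((r - beta0) / beta1)."""
    if model.beta1 == 0:
        raise UndefinedShiftError("calibration slope is zero")
    r = np.asarray(rating, dtype=float)
    out = t_ref * 2.0 ** ((r - model.beta0) / model.beta1)
    return float(out) if out.ndim == 0 else out


def score_participant(trials, ref_ioi_ms, cooks_threshold: float | None = None):
    """Calibrate and score one participant's trial table.

    Parameters
    ----------
    trials : pandas.DataFrame
        Must contain ``ioi_ms`` and ``rating`` columns.

    Returns
    -------
    (scored, model) : (pandas.DataFrame, CalibrationModel)
        Copy of ``trials`` with ``is_outlier``, ``rho`` and ``tau`` columns;
        rho/tau are NaN on outlier trials, which are excluded downstream.
    """
    model = fit_calibration(
        trials["ioi_ms"].to_numpy(),
        trials["rating"].to_numpy(),
        ref_ioi_ms,
        cooks_threshold=cooks_threshold,
    )
    rho = residual_rating(
        trials["ioi_ms"].to_numpy(), trials["rating"].to_numpy(), model, ref_ioi_ms
    )
    tau = tempo_shift(rho, model.beta1)
    scored = trials.copy()
    scored["is_outlier"] = model.outlier_mask
    scored["rho"] = np.where(model.outlier_mask, np.nan, rho)
    scored["tau"] = np.where(model.outlier_mask, np.nan, tau)
    return scored, model


def score_study(trials, ref_ioi_ms, cooks_threshold: float | None = None):
    """Score every participant; returns (scored table, {pid: model})."""
    import pandas as pd

    frames, models = [], {}
    for pid, grp in trials.groupby("participant_id", sort=True):
        scored, model = score_participant(grp, ref_ioi_ms, cooks_threshold)
        frames.append(scored)
        models[pid] = model
    return pd.concat(frames).sort_index(), models
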