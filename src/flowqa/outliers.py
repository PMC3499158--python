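"""Robust outlier-detection functions for stratified population statistics.

Four families of calls:

* ``outlier_cutoff`` — fixed thresholds on the statistic itself;
* ``outlier_norm``  — robust-normal z-scores (median / 1.4826·MAD), with a
  z cutoff or a significance level, one- or two-sided;
* ``qoutlier``      — the boxplot rule, flags beyond 1.5×IQR of the quartiles;
* ``between_group_outliers`` — groups whose spread (log IQR) is larger than
  expected relative to the other groups;
* ``robust_regression`` / ``residual_outliers`` — Huber M-estimation by IRLS
  and calls on standardized residuals.

All cutoffs use strict inequalities; a degenerate robust scale (all values
equal) yields zero flags rather than dividing by zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

__all__ = [
    "OutlierResult",
    "RobustFit",
    "outlier_cutoff",
    "outlier_norm",
    "qoutlier",
    "between_group_outliers",
    "robust_regression",
    "residual_outliers",
    "OUTLIER_REGISTRY",
    "MAD_CONSISTENCY",
]

MAD_CONSISTENCY = 1.4826  # makes the MAD consistent for the normal sd


@dataclass
class OutlierResult:
    """Flags plus per-value scores and the cutoffs that produced them."""

    flags: np.ndarray
    scores: np.ndarray
    method: str
    cutoffs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        self.scores = np.asarray(self.scores, dtype=float)
        if self.flags.shape != self.scores.shape:
            raise ValueError("flags and scores must have the same length")

    @property
    def n_flagged(self) -> int:
        return int(self.flags.sum())


def _as_values(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    if v.ndim != 1:
        v = v.ravel()
    return v


def robust_location_scale(values: np.ndarray) -> tuple[float, float]:
    """Median and 1.4826-scaled MAD."""
    med = float(np.median(values))
    mad = float(np.median(np.abs(values - med)))
    return med, MAD_CONSISTENCY * mad


def outlier_cutoff(values, lBound: float | None = None,
                   uBound: float | None = None) -> OutlierResult:
    """Threshold calls: flag value < lBound or value > uBound (strict).

    The score is the signed distance to the nearest violated bound
    (negative below lBound, positive above uBound, 0 when inside).
    """
    if lBound is None and uBound is None:
        raise ValueError("outlier_cutoff: at least one of lBound/uBound required")
    if lBound is not None and uBound is not None and lBound > uBound:
        raise ValueError("outlier_cutoff: lBound must be <= uBound")
    v = _as_values(values)
    flags = np.zeros(v.shape, dtype=bool)
    scores = np.zeros(v.shape, dtype=float)
    if lBound is not None:
        low = v < lBound
        flags |= low
        scores[low] = v[low] - lBound
    if uBound is not None:
        high = v > uBound
        flags |= high
        scores[high] = v[high] - uBound
    return OutlierResult(flags, scores, "cutoff", {"lBound": lBound, "uBound": uBound})


def _resolve_z_cutoff(z_cutoff: float, alpha: float | None, sides: str) -> float:
    if alpha is not None:
        if not 0 < alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        q = 1 - alpha / 2 if sides == "two" else 1 - alpha
        return float(sps.norm.ppf(q))
    return float(z_cutoff)


def outlier_norm(values, z_cutoff: float = 3.0, alpha: float | None = None,
                 sides: str = "two") -> OutlierResult:
    """Robust-normal calls: z = (value - median) / (1.4826 MAD).

    Two-sided flags |z| > cutoff; 'lower'/'upper' flag the signed tail.
    ``alpha`` converts a normal significance level into the cutoff
    (1 - alpha/2 quantile two-sided, 1 - alpha one-sided). All values equal
    (zero robust scale) yields zero flags.
    """
    if sides not in ("two", "lower", "upper"):
        raise ValueError("sides must be 'two', 'lower' or 'upper'")
    v = _as_values(values)
    if v.size < 3:
        raise ValueError(f"outlier_norm requires >= 3 values, got {v.size}")
    cut = _resolve_z_cutoff(z_cutoff, alpha, sides)
    loc, scale = robust_location_scale(v)
    if scale == 0:
        z = np.zeros(v.shape)
    else:
        z = (v - loc) / scale
    if sides == "two":
        flags = np.abs(z) > cut
    elif sides == "upper":
        flags = z > cut
    else:
        flags = z < -cut
    return OutlierResult(flags, z, "norm",
                         {"z_cutoff": cut, "sides": sides, "location": loc,
                          "scale": scale})


def quartiles(values: np.ndarray) -> tuple[float, float]:
    """Q1/Q3 by linear interpolation between order statistics (h=(n-1)p+1)."""
    q1, q3 = np.quantile(_as_values(values), [0.25, 0.75], method="linear")
    return float(q1), float(q3)


def qoutlier(values, k: float = 1.5) -> OutlierResult:
    """Boxplot rule: flag beyond Q1 - k·IQR or Q3 + k·IQR (k = 1.5).

    Scores are the signed distance past the violated fence, in IQR units
    (0 for values inside; sign marks the tail). Zero IQR yields zero flags.
    """
    v = _as_values(values)
    if v.size < 3:
        raise ValueError(f"qoutlier requires >= 3 values, got {v.size}")
    q1, q3 = quartiles(v)
    iqr = q3 - q1
    lo, hi = q1 - k * iqr, q3 + k * iqr
    if iqr == 0:
        flags = np.zeros(v.shape, dtype=bool)
        scores = np.zeros(v.shape)
    else:
        flags = (v < lo) | (v > hi)
        scores = np.where(v < lo, (v - lo) / iqr, np.where(v > hi, (v - hi) / iqr, 0.0))
    return OutlierResult(flags, scores, "qoutlier",
                         {"Q1": q1, "Q3": q3, "lower": lo, "upper": hi})


def between_group_outliers(groups: dict, z_cutoff: float = 3.0) -> dict:
    """Flag groups with larger-than-expected spread via log-IQR robust z.

    For each group with a computable IQR, compute log(IQR + eps) (eps scaled
    to the largest IQR so zero-spread groups stay finite), then apply the
    one-sided upper robust-normal test across groups. Returns
    ``{group_key: OutlierResult-like dict}`` for the eligible groups; fewer
    than 3 eligible groups produces no calls.
    """
    keys, iqrs = [], []
    for key in groups:
        v = _as_values(groups[key])
        if v.size < 2:
            continue
        q1, q3 = quartiles(v)
        keys.append(key)
        iqrs.append(q3 - q1)
    if len(keys) < 3:
        return {}
    iqrs = np.asarray(iqrs, dtype=float)
    eps = 1e-12 * (iqrs.max() if iqrs.max() > 0 else 1.0)
    log_iqr = np.log(iqrs + eps)
    res = outlier_norm(log_iqr, z_cutoff=z_cutoff, sides="upper")
    return {
        key: {"flagged": bool(res.flags[i]), "score": float(res.scores[i]),
              "iqr": float(iqrs[i])}
        for i, key in enumerate(keys)
    }


@dataclass
class RobustFit:
    """Huber straight-line fit: estimates, robust scale and IRLS diagnostics."""

    slope: float
    intercept: float
    scale: float
    weights: np.ndarray
    converged: bool
    iterations: int

    def predict(self, x) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def residuals(self, x, y) -> np.ndarray:
        return np.asarray(y, dtype=float) - self.predict(x)


def robust_regression(x, y, c: float = 1.345, tol: float = 1e-8,
                      max_iter: int = 50) -> RobustFit:
    """Huber M-estimation of a straight line by IRLS.

    The tuning constant c = 1.345 gives 95% efficiency under normal errors;
    the residual scale is re-estimated each iteration as 1.4826·median|r|.
    Convergence: max coefficient change < ``tol``. A constant x leaves the
    slope unidentifiable and is an error; non-convergence returns the last
    iterate with ``converged=False``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("robust_regression requires matched x/y with n >= 4")
    if np.ptp(x) == 0:
        raise ValueError("robust_regression: x is constant, slope unidentifiable")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    w = np.ones_like(x)
    converged = False
    scale = 0.0
    it = 0
    for it in range(1, max_iter + 1):
        r = y - X @ beta
        scale = MAD_CONSISTENCY * float(np.median(np.abs(r)))
        if scale == 0:
            converged = True
            break
        z = np.abs(r) / scale
        with np.errstate(divide="ignore"):
            w = np.minimum(1.0, c / np.maximum(z, 1e-300))
        sw = np.sqrt(w)
        beta_new, *_ = np.linalg.lstsq(X * sw[:, None], y * sw, rcond=None)
        if np.max(np.abs(beta_new - beta)) < tol:
            beta = beta_new
            converged = True
            break
        beta = beta_new
    r = y - X @ beta
    scale = MAD_CONSISTENCY * float(np.median(np.abs(r)))
    return RobustFit(slope=float(beta[1]), intercept=float(beta[0]), scale=scale,
                     weights=w, converged=converged, iterations=it)


def residual_outliers(fit: RobustFit, x, y, z_cutoff: float = 3.0) -> OutlierResult:
    """Flag |residual| / robust scale > z_cutoff against a robust line fit."""
    r = fit.residuals(x, y)
    if fit.scale == 0:
        z = np.zeros_like(r)
    else:
        z = r / fit.scale
    return OutlierResult(np.abs(z) > z_cutoff, z, "residual",
                         {"z_cutoff": z_cutoff, "scale": fit.scale})


# registry used by the task CSV ("outlier_func" column)
OUTLIER_REGISTRY = {
    "cutoff": outlier_cutoff,
    "norm": outlier_norm,
    "qoutlier": qoutlier,
}
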