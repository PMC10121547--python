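"""Confidence intervals, prediction intervals and coverage summaries.

Conditional on covariates x (with a leading 1 for the intercept) the fitted
model gives a full Gaussian distribution with mean ``mu(x) = x' beta`` and
variance ``sigma^2(x) = exp(x' alpha)``, so nominal prediction intervals are
``mu(x) +/- z * sigma(x)``.  The 95% quantile is fixed at 1.96 (the value
conventionally used when reporting such intervals); other levels use the
exact normal quantile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .estimator import FitResult
from .model import MPRParams

__all__ = [
    "PredictionInterval",
    "conditional_moments",
    "prediction_interval",
    "wald_cis",
    "pcp",
]

Z_95 = 1.96


def _z_quantile(level: float) -> float:
    if not 0.0 < level < 1.0:
        raise ValueError("level must lie in (0, 1)")
    if level == 0.95:
        return Z_95
    return float(stats.norm.ppf(0.5 * (1.0 + level)))


@dataclass(frozen=True)
class PredictionInterval:
    """Symmetric interval ``center +/- half_width`` at the given level."""

    center: float
    half_width: float
    level: float = 0.95

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")

    @property
    def lower(self) -> float:
        return self.center - self.half_width

    @property
    def upper(self) -> float:
        return self.center + self.half_width

    def contains(self, y: float) -> bool:
        return self.lower <= y <= self.upper


def conditional_moments(x, params: MPRParams):
    """Conditional mean and variance ``(x' beta, exp(x' alpha))``.

    ``x`` must include the intercept entry 1 in position 0.
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != params.beta.shape[0]:
        raise ValueError("covariate vector and coefficients have different lengths")
    return float(x @ params.beta), float(np.exp(x @ params.alpha))


def prediction_interval(x, params: MPRParams, level: float = 0.95) -> PredictionInterval:
    """Nominal prediction interval ``x'beta +/- z * sqrt(exp(x'alpha))``."""
    mu, var = conditional_moments(x, params)
    return PredictionInterval(center=mu, half_width=_z_quantile(level) * np.sqrt(var), level=level)


def wald_cis(result: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Wald intervals ``estimate +/- z*SE`` for every active coefficient.

    Returns a tidy frame with one row per active coefficient of each
    component (intercepts included), on the scaled-predictor scale.
    """
    z = _z_quantile(level)
    se = result.se()
    p1 = result.params_hat.beta.size
    rows = []
    for comp, active, coefs, offset in (
        ("location", result.active_beta, result.params_hat.beta, 0),
        ("dispersion", result.active_alpha, result.params_hat.alpha, p1),
    ):
        for j in active:
            est = coefs[j]
            s = se[offset + j]
            rows.append(
                {
                    "component": comp,
                    "index": int(j),
                    "estimate": est,
                    "se": s,
                    "lower": est - z * s,
                    "upper": est + z * s,
                    "level": level,
                }
            )
    return pd.DataFrame(rows)


def pcp(intervals, y_new, sigma_true=None, thresholds=(1.0, 2.2)) -> dict:
    """Prediction coverage probability, overall and by variability category.

    ``intervals`` is a sequence of :class:`PredictionInterval` (or an
    ``(m, 2)`` array of lower/upper bounds).  When the true per-observation
    residual SDs ``sigma_true`` are supplied, coverage is also reported in
    the low (sigma <= thresholds[0]), medium (in (thresholds[0],
    thresholds[1]]) and high (> thresholds[1]) categories; an empty category
    is reported as ``None`` rather than 0.
    """
    y_new = np.asarray(y_new, dtype=float).ravel()
    if isinstance(intervals, np.ndarray) and intervals.ndim == 2:
        lower, upper = intervals[:, 0], intervals[:, 1]
    else:
        lower = np.array([iv.lower for iv in intervals])
        upper = np.array([iv.upper for iv in intervals])
    if lower.shape[0] != y_new.shape[0]:
        raise ValueError("intervals and y_new have different lengths")
    inside = (y_new >= lower) & (y_new <= upper)
    out = {"overall": float(np.mean(inside)) if inside.size else None}
    if sigma_true is not None:
        sigma_true = np.asarray(sigma_true, dtype=float).ravel()
        if sigma_true.shape[0] != y_new.shape[0]:
            raise ValueError("sigma_true and y_new have different lengths")
        lo, hi = thresholds
        cats = {
            "low": sigma_true <= lo,
            "medium": (sigma_true > lo) & (sigma_true <= hi),
            "high": sigma_true > hi,
        }
        for name, mask in cats.items():
            out[name] = float(np.mean(inside[mask])) if np.any(mask) else None
    return out
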