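"""Synthetic data generation and the Monte-Carlo selection/inference study.

The reference design has 12 covariates with deliberately mixed marginals —
two skewed Exponential(1) variables, two unbalanced Bernoulli(0.75)
indicators, four independent standard normals, and a block of four
correlated normals with AR(1) correlation ``0.8**|j-k|`` — and true
coefficient values 0 / 0.5 / 1 (none, weak, strong) arranged so covariates
enter both components, the mean only, the log-variance only, or neither:

    beta  = (0, 1, 0.5, 0.5, 1, 0.5, 1, 0, 0, 0, 0, 0, 0)
    alpha = (0, 0.5, 1, 0.5, 1, 0, 0, 0.5, 1, 0, 0, 0, 0)

Responses are drawn as ``y = x'beta + sigma * z`` with ``sigma =
exp(x'alpha / 2)``.  :func:`run_study` replicates the full pipeline —
generate, scale predictors to unit training SD, fit, evaluate — and
aggregates selection (C / IC / PT), accuracy (MSE), inference (estimate
mean, SE, SEE, CP) and out-of-sample prediction coverage (PCP) metrics.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .estimator import FitResult, fit_mpr_sic, fit_spr_sic
from .exceptions import NumericalFailure
from .inference import pcp as compute_pcp
from .model import Dataset
from .penalty import TelescopeSchedule

__all__ = [
    "SimulationDesign",
    "StudyMetrics",
    "gen_covariates",
    "gen_response",
    "run_study",
    "DEFAULT_BETA",
    "DEFAULT_ALPHA",
]

DEFAULT_BETA = np.array([0.0, 1.0, 0.5, 0.5, 1.0, 0.5, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
DEFAULT_ALPHA = np.array([0.0, 0.5, 1.0, 0.5, 1.0, 0.0, 0.0, 0.5, 1.0, 0.0, 0.0, 0.0, 0.0])

# 0-based predictor columns (X1..X12 -> 0..11) by marginal distribution
_EXP_COLS = (0, 10)  # X1, X11 ~ Exponential(1)
_BERN_COLS = (2, 9)  # X3, X10 ~ Bernoulli(0.75)
_NORM_COLS = (3, 4, 6, 7)  # X4, X5, X7, X8 ~ N(0, 1) independent
_MVN_COLS = (1, 5, 8, 11)  # X2, X6, X9, X12 = Z1..Z4, corr 0.8**|j-k|
_AR1_RHO = 0.8
_BERN_P = 0.75
_SIGMA_THRESHOLDS = (1.0, 2.2)


@dataclass
class SimulationDesign:
    """Sample size, truth vectors and seed for the reference design."""

    n: int = 1000
    beta_true: np.ndarray = field(default_factory=lambda: DEFAULT_BETA.copy())
    alpha_true: np.ndarray = field(default_factory=lambda: DEFAULT_ALPHA.copy())
    seed: int = 0

    def __post_init__(self):
        self.beta_true = np.asarray(self.beta_true, dtype=float).ravel()
        self.alpha_true = np.asarray(self.alpha_true, dtype=float).ravel()
        if self.beta_true.shape != (13,) or self.alpha_true.shape != (13,):
            raise ValueError("truth vectors must have length 13 (intercept + 12 covariates)")
        if self.n < 2:
            raise ValueError("n must be at least 2")

    def to_dict(self) -> dict:
        return {
            "n": int(self.n),
            "beta_true": self.beta_true.tolist(),
            "alpha_true": self.alpha_true.tolist(),
            "seed": int(self.seed),
        }


def _ar1_cholesky(k: int, rho: float) -> np.ndarray:
    idx = np.arange(k)
    corr = rho ** np.abs(idx[:, None] - idx[None, :])
    return np.linalg.cholesky(corr)


def gen_covariates(design: SimulationDesign, rng: np.random.Generator | None = None, n: int | None = None) -> np.ndarray:
    """Draw the n x 12 unscaled covariate matrix for the reference design."""
    rng = np.random.default_rng(design.seed) if rng is None else rng
    n = design.n if n is None else int(n)
    X = np.empty((n, 12))
    X[:, _EXP_COLS] = rng.exponential(1.0, size=(n, len(_EXP_COLS)))
    X[:, _BERN_COLS] = rng.binomial(1, _BERN_P, size=(n, len(_BERN_COLS))).astype(float)
    X[:, _NORM_COLS] = rng.standard_normal((n, len(_NORM_COLS)))
    L = _ar1_cholesky(len(_MVN_COLS), _AR1_RHO)
    X[:, _MVN_COLS] = rng.standard_normal((n, len(_MVN_COLS))) @ L.T
    return X


def gen_response(X_with_intercept, beta_true, alpha_true, seed=None) -> np.ndarray:
    """Draw ``y_i = x_i'beta + sigma_i z_i`` with ``sigma_i = exp(x_i'alpha / 2)``.

    ``seed`` may be an integer or an ``np.random.Generator``.
    """
    X = np.asarray(X_with_intercept, dtype=float)
    beta_true = np.asarray(beta_true, dtype=float).ravel()
    alpha_true = np.asarray(alpha_true, dtype=float).ravel()
    if X.shape[1] != beta_true.size or X.shape[1] != alpha_true.size:
        raise ValueError("design and truth vectors have inconsistent dimensions")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = np.exp(0.5 * (X @ alpha_true))
    return X @ beta_true + sigma * rng.standard_normal(X.shape[0])


@dataclass
class StudyMetrics:
    """Aggregated Monte-Carlo metrics for one method at one sample size.

    ``C``/``IC``/``PT``/``MSE`` are per-component dictionaries (keys "beta",
    "alpha"); ``coef_table`` holds per-coefficient truth, mean estimate,
    empirical SE, mean estimated SE (SEE, over replicates where the
    coefficient is active) and coverage (CP); ``pcp`` holds overall and
    per-variability-category out-of-sample coverage.
    """

    method: str
    n: int
    n_replicates: int
    n_failed: int
    C: dict
    IC: dict
    PT: dict
    MSE: dict
    coef_table: pd.DataFrame
    pcp: dict
    seed: int

    def to_tidy(self) -> pd.DataFrame:
        """One row per metric, suitable for CSV export."""
        rows = []
        for comp in ("beta", "alpha"):
            for metric, store in (("C", self.C), ("IC", self.IC), ("PT", self.PT), ("MSE", self.MSE)):
                rows.append(
                    {"method": self.method, "n": self.n, "metric": metric, "component": comp,
                     "index": None, "value": store[comp]}
                )
        for _, r in self.coef_table.iterrows():
            for metric in ("truth", "est_mean", "SE", "SEE", "CP"):
                rows.append(
                    {"method": self.method, "n": self.n, "metric": metric,
                     "component": r["component"], "index": int(r["index"]), "value": r[metric]}
                )
        for cat, val in self.pcp.items():
            rows.append(
                {"method": self.method, "n": self.n, "metric": f"PCP_{cat}",
                 "component": None, "index": None, "value": val}
            )
        return pd.DataFrame(rows)


def _mse_quadform(X: np.ndarray, diff: np.ndarray) -> float:
    """In-sample MSE quadratic form ``diff' X'X diff / n``."""
    v = X @ diff
    return float(v @ v) / X.shape[0]


def run_study(
    design: SimulationDesign,
    n_replicates: int,
    method="mpr",
    holdout_fraction: float = 0.2,
    schedule: TelescopeSchedule | None = None,
    zero_tol: float = 1e-8,
    cp_active_only: bool = False,
) -> StudyMetrics:
    """Run the full Monte-Carlo study for one method at one sample size.

    Each replicate draws a fresh training set of size ``design.n`` and a
    fresh holdout of size ``ceil(holdout_fraction * n)`` from the same
    truth; predictors are scaled by the training-sample SD (holdout scaled
    with the training factors) and estimates are mapped back to the
    generated covariate scale before comparison with the truth.  ``method``
    is ``"mpr"``, ``"spr"`` or a callable ``fitter(data) -> FitResult``
    (useful for plugging in an oracle).  Replicate-level numerical failures
    are skipped and counted; more than 5% failures aborts the study.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if callable(method):
        fitter, method_name = method, getattr(method, "__name__", "custom")
    elif method == "mpr":
        fitter, method_name = (lambda d: fit_mpr_sic(d, schedule=schedule, zero_tol=zero_tol)), "mpr"
    elif method == "spr":
        fitter, method_name = (lambda d: fit_spr_sic(d, schedule=schedule, zero_tol=zero_tol)), "spr"
    else:
        raise ValueError("method must be 'mpr', 'spr' or a callable")

    n = design.n
    m_hold = math.ceil(holdout_fraction * n)
    beta_t, alpha_t = design.beta_true, design.alpha_true
    nonzero_b = beta_t[1:] != 0
    nonzero_a = alpha_t[1:] != 0
    p1 = 13

    children = np.random.SeedSequence(design.seed).spawn(n_replicates)
    acc = {
        "C": {"beta": [], "alpha": []},
        "IC": {"beta": [], "alpha": []},
        "PT": {"beta": [], "alpha": []},
        "MSE": {"beta": [], "alpha": []},
    }
    est_rows, se_rows, cover_rows, active_rows = [], [], [], []
    pcp_rows = []
    n_failed = 0

    for child in children:
        rng = np.random.default_rng(child)
        X_tr = gen_covariates(design, rng=rng)
        X_tr_int = np.column_stack([np.ones(n), X_tr])
        y_tr = gen_response(X_tr_int, beta_t, alpha_t, rng)
        X_ho = gen_covariates(design, rng=rng, n=m_hold)
        X_ho_int = np.column_stack([np.ones(m_hold), X_ho])
        y_ho = gen_response(X_ho_int, beta_t, alpha_t, rng)
        try:
            data = Dataset.from_arrays(y_tr, X_tr)
            fit = fitter(data)
        except (NumericalFailure, FloatingPointError, np.linalg.LinAlgError, ValueError):
            n_failed += 1
            if n_failed > 0.05 * n_replicates:
                raise RuntimeError(
                    f"more than 5% of replicates failed ({n_failed}/{n_replicates})"
                )
            continue

        sd = data.scale_factors
        # truth on the scaled-predictor scale (coefficients absorb the SD)
        beta_ts = beta_t.copy()
        beta_ts[1:] *= sd
        alpha_ts = alpha_t.copy()
        alpha_ts[1:] *= sd

        sb = fit.params_sparse.beta
        sa = fit.params_sparse.alpha
        zero_b = sb[1:] == 0.0
        zero_a = sa[1:] == 0.0
        acc["C"]["beta"].append(np.sum(zero_b & ~nonzero_b))
        acc["C"]["alpha"].append(np.sum(zero_a & ~nonzero_a))
        acc["IC"]["beta"].append(np.sum(zero_b & nonzero_b))
        acc["IC"]["alpha"].append(np.sum(zero_a & nonzero_a))
        acc["PT"]["beta"].append(float(np.array_equal(~zero_b, nonzero_b)))
        acc["PT"]["alpha"].append(float(np.array_equal(~zero_a, nonzero_a)))
        acc["MSE"]["beta"].append(_mse_quadform(data.X, sb - beta_ts))
        acc["MSE"]["alpha"].append(_mse_quadform(data.X, sa - alpha_ts))

        # per-coefficient inference on the generated (original) scale
        est = np.concatenate([data.unscale_coefs(sb), data.unscale_coefs(sa)])
        se_scaled = fit.se()
        unscale = np.concatenate([[1.0], sd])
        se = np.concatenate([se_scaled[:p1] / unscale, se_scaled[p1:] / unscale])
        truth = np.concatenate([beta_t, alpha_t])
        active = est != 0.0
        active[[0, p1]] = True
        cover = np.where(
            active,
            np.abs(est - truth) <= 1.96 * se,
            truth == 0.0,
        )
        est_rows.append(est)
        se_rows.append(np.where(active, se, np.nan))
        cover_rows.append(cover)
        active_rows.append(active)

        # out-of-sample prediction coverage with true-sigma categories
        X_ho_s = np.column_stack([np.ones(m_hold), X_ho / sd])
        mu = X_ho_s @ sb
        half = 1.96 * np.exp(0.5 * np.clip(X_ho_s @ sa, -700, 700))
        bounds = np.column_stack([mu - half, mu + half])
        sigma_true = np.exp(0.5 * (X_ho_int @ alpha_t))
        pcp_rows.append(compute_pcp(bounds, y_ho, sigma_true, _SIGMA_THRESHOLDS))

    n_ok = n_replicates - n_failed
    if n_ok == 0:
        raise RuntimeError("all replicates failed")

    est_mat = np.asarray(est_rows)
    se_mat = np.asarray(se_rows)
    cover_mat = np.asarray(cover_rows, dtype=float)
    active_mat = np.asarray(active_rows, dtype=bool)
    truth = np.concatenate([beta_t, alpha_t])
    coef_rows = []
    for k in range(2 * p1):
        comp = "beta" if k < p1 else "alpha"
        j = k % p1
        act = active_mat[:, k]
        if cp_active_only:
            cp_val = float(np.mean(cover_mat[act, k])) if np.any(act) else np.nan
        else:
            cp_val = float(np.mean(cover_mat[:, k]))
        coef_rows.append(
            {
                "component": comp,
                "index": j,
                "truth": truth[k],
                "est_mean": float(np.mean(est_mat[:, k])),
                "SE": float(np.std(est_mat[:, k], ddof=1)) if n_ok > 1 else np.nan,
                "SEE": float(np.nanmean(se_mat[:, k])) if np.any(act) else np.nan,
                "CP": cp_val,
                "n_active": int(np.sum(act)),
            }
        )

    pcp_out = {}
    for cat in ("overall", "low", "medium", "high"):
        vals = [r[cat] for r in pcp_rows if r.get(cat) is not None]
        pcp_out[cat] = float(np.mean(vals)) if vals else None

    summarize = lambda store: {c: float(np.mean(store[c])) for c in ("beta", "alpha")}
    return StudyMetrics(
        method=method_name,
        n=n,
        n_replicates=n_ok,
        n_failed=n_failed,
        C=summarize(acc["C"]),
        IC=summarize(acc["IC"]),
        PT=summarize(acc["PT"]),
        MSE=summarize(acc["MSE"]),
        coef_table=pd.DataFrame(coef_rows),
        pcp=pcp_out,
        seed=design.seed,
    )
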