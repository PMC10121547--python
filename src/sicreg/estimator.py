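"""SIC-penalised estimation: block Newton-Raphson with eps-telescoping.

The optimiser follows the RS scheme: the location and log-dispersion blocks
are updated from two decoupled Newton systems (cross-derivatives dropped
from the left-hand side), with step-halving so the SIC objective never
decreases across accepted iterations.  The smoothing parameter eps is then
"telescoped" through a geometric schedule with warm starts; at the final
eps, coefficients whose magnitude falls below ``zero_tol`` (default 1e-8)
are treated as exactly zero.  Standard errors come from the sandwich
covariance I(theta)^{-1} I0(theta) I(theta)^{-1} evaluated at the raw
(pre-threshold) estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import DegenerateResponseError, NumericalFailure, SingularDesignError
from .model import (
    Dataset,
    MPRParams,
    count_clips,
    full_information,
    info_weights,
    mpr_loglik,
    penalized_score,
    penalty_curvature,
    sic_objective,
)
from .penalty import TelescopeSchedule, make_schedule

__all__ = [
    "FitResult",
    "init_params",
    "newton_step",
    "fit_mpr_sic",
    "fit_spr_sic",
    "sandwich_cov",
    "delta_bic",
]

MAX_INNER_ITER = 100
INNER_TOL = 1e-8
MAX_HALVINGS = 20
COND_LIMIT = 1e12
RIDGE_SCALE = 1e-8


@dataclass
class TraceStep:
    """State recorded after the inner Newton loop at one telescope step."""

    eps: float
    beta: np.ndarray
    alpha: np.ndarray
    objective: float
    n_iter: int
    converged: bool


@dataclass
class FitResult:
    """Outcome of a telescoped SIC fit.

    ``params_hat`` holds the raw estimates at the final eps; ``params_sparse``
    is the same vector with sub-``zero_tol`` entries set to exactly zero.
    ``bic`` is computed at the sparse estimate with the active-coefficient
    counts; ``sic`` is the IC-scale smooth objective ``-2 l^SIC`` at the raw
    estimate and final eps.  ``cov_hat`` is the (2p+2)-square sandwich
    covariance (rows/columns of coefficients excluded from the fit are zero).
    """

    params_hat: MPRParams
    params_sparse: MPRParams
    active_beta: np.ndarray
    active_alpha: np.ndarray
    cov_hat: np.ndarray
    loglik: float
    sic: float
    bic: float
    trace: list[TraceStep]
    converged: bool
    n_clips: int
    penalty_weight: float
    zero_tol: float
    schedule: TelescopeSchedule
    beta_mask: np.ndarray = field(repr=False, default=None)
    alpha_mask: np.ndarray = field(repr=False, default=None)

    @property
    def n_params(self) -> int:
        return 2 * self.params_hat.beta.size

    def se(self) -> np.ndarray:
        """Standard errors (sqrt of the sandwich diagonal), full length 2p+2."""
        return np.sqrt(np.clip(np.diag(self.cov_hat), 0.0, None))


def init_params(data: Dataset) -> MPRParams:
    """OLS initial values: ``beta = (X'X)^{-1}X'y``, ``alpha = (log s^2, 0, ..., 0)``.

    ``s^2`` is the classical residual variance with divisor ``n - p``.
    """
    X, y = data.X, data.y
    beta0, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        raise SingularDesignError("design matrix is rank deficient")
    resid = y - X @ beta0
    dof = data.n - data.p
    if dof <= 0:
        raise SingularDesignError("need n > p observations for the residual variance")
    s2 = float(resid @ resid) / dof
    # exact-fit residuals are numerically ~0 rather than exactly 0
    if s2 <= 1e-12 * max(1.0, float(np.mean(y * y))) or not np.isfinite(np.log(s2)):
        raise DegenerateResponseError("response is an exact linear function of the design (s^2 = 0)")
    alpha0 = np.zeros_like(beta0)
    alpha0[0] = np.log(s2)
    return MPRParams(beta0, alpha0)


def _full_masks(p1: int, beta_mask, alpha_mask):
    bm = np.ones(p1, dtype=bool) if beta_mask is None else np.asarray(beta_mask, dtype=bool).copy()
    am = np.ones(p1, dtype=bool) if alpha_mask is None else np.asarray(alpha_mask, dtype=bool).copy()
    bm[0] = True
    am[0] = True
    return bm, am


def _solve_block(A_unpen: np.ndarray, pen_diag: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve ``(A_unpen + diag(pen_diag)) d = rhs`` with curvature safeguards.

    If the penalised block is not positive definite, the penalty curvature is
    replaced by its absolute value (a standard Newton safeguard; the
    objective check still decides acceptance).  An ill-conditioned block gets
    a small ridge on its diagonal.
    """
    for diag in (pen_diag, np.abs(pen_diag)):
        A = A_unpen + np.diag(diag)
        try:
            np.linalg.cholesky(A)
        except np.linalg.LinAlgError:
            continue
        if np.linalg.cond(A) > COND_LIMIT:
            A = A + RIDGE_SCALE * np.mean(np.diag(A)) * np.eye(A.shape[0])
        return np.linalg.solve(A, rhs)
    A = A_unpen + np.diag(np.abs(pen_diag))
    A = A + RIDGE_SCALE * max(np.mean(np.abs(np.diag(A))), 1.0) * np.eye(A.shape[0])
    try:
        return np.linalg.solve(A, rhs)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - extreme degeneracy
        raise NumericalFailure(f"singular Newton block: {exc}") from exc


def newton_step(
    params: MPRParams,
    data: Dataset,
    eps: float,
    penalty_weight=None,
    beta_mask=None,
    alpha_mask=None,
    components=("beta", "alpha"),
) -> MPRParams:
    """One RS block Newton-Raphson update with step-halving.

    Solves the two decoupled systems
    ``(X'W X + lam Sigma/2) d = X'z - lam nu/2`` for the requested
    ``components``, then halves the joint step (at most ``MAX_HALVINGS``
    times) until the SIC objective does not decrease; if no step length
    improves the objective the parameters are returned unchanged.  Masks
    restrict the update to a subset of columns (intercepts always free).
    """
    lam = float(np.log(data.n)) if penalty_weight is None else float(penalty_weight)
    p1 = params.beta.size
    bm, am = _full_masks(p1, beta_mask, alpha_mask)
    g_beta, g_alpha = penalized_score(params, data, eps, lam)
    w_beta, w_alpha, _ = info_weights(params, data)
    sig_beta, sig_alpha = penalty_curvature(params, eps)

    d_beta = np.zeros(p1)
    d_alpha = np.zeros(p1)
    if "beta" in components:
        Xb = data.X[:, bm]
        A_un = Xb.T @ (w_beta[:, None] * Xb)
        d_beta[bm] = _solve_block(A_un, 0.5 * lam * sig_beta[bm], g_beta[bm])
    if "alpha" in components:
        Xa = data.X[:, am]
        A_un = Xa.T @ (w_alpha[:, None] * Xa)
        d_alpha[am] = _solve_block(A_un, 0.5 * lam * sig_alpha[am], g_alpha[am])

    obj_old = sic_objective(params, data, eps, lam)
    scale = 1.0
    for _ in range(MAX_HALVINGS + 1):
        cand = MPRParams(params.beta + scale * d_beta, params.alpha + scale * d_alpha)
        try:
            obj_new = sic_objective(cand, data, eps, lam)
        except FloatingPointError:
            obj_new = -np.inf
        if obj_new >= obj_old - 1e-12 * (1.0 + abs(obj_old)):
            return cand
        scale *= 0.5
    return params.copy()


def _fit_core(
    data: Dataset,
    schedule: TelescopeSchedule | None,
    penalty_weight,
    zero_tol: float,
    beta_mask=None,
    alpha_mask=None,
) -> FitResult:
    schedule = schedule if schedule is not None else make_schedule()
    lam = float(np.log(data.n)) if penalty_weight is None else float(penalty_weight)
    p1 = data.X.shape[1]
    bm, am = _full_masks(p1, beta_mask, alpha_mask)

    # OLS init on the location columns actually in play
    Xb = data.X[:, bm]
    sub = Dataset(
        y=data.y,
        X=Xb,
        scale_factors=data.scale_factors[bm[1:]] if data.p else data.scale_factors,
        names=[nm for nm, keep in zip(data.names, bm) if keep],
    )
    start = init_params(sub)
    params = MPRParams(np.zeros(p1), np.zeros(p1))
    params.beta[bm] = start.beta
    params.alpha[0] = start.alpha[0]

    trace: list[TraceStep] = []
    all_converged = True
    n_clips = 0
    for t, eps in enumerate(schedule.values):
        converged = False
        n_iter = 0
        for n_iter in range(1, MAX_INNER_ITER + 1):
            try:
                new_params = newton_step(params, data, eps, lam, bm, am)
            except NumericalFailure as exc:
                raise NumericalFailure(str(exc), eps_index=t) from exc
            delta = max(
                np.max(np.abs(new_params.beta - params.beta)),
                np.max(np.abs(new_params.alpha - params.alpha)),
            )
            params = new_params
            if delta < INNER_TOL:
                converged = True
                break
        n_clips += count_clips(params, data)
        all_converged &= converged
        trace.append(
            TraceStep(
                eps=float(eps),
                beta=params.beta.copy(),
                alpha=params.alpha.copy(),
                objective=sic_objective(params, data, eps, lam),
                n_iter=n_iter,
                converged=converged,
            )
        )

    eps_T = float(schedule.values[-1])
    params_hat = params.copy()
    sparse_beta = params_hat.beta.copy()
    sparse_alpha = params_hat.alpha.copy()
    sparse_beta[1:] = np.where(np.abs(sparse_beta[1:]) > zero_tol, sparse_beta[1:], 0.0)
    sparse_alpha[1:] = np.where(np.abs(sparse_alpha[1:]) > zero_tol, sparse_alpha[1:], 0.0)
    params_sparse = MPRParams(sparse_beta, sparse_alpha)

    active_beta = np.flatnonzero(np.concatenate([[1.0], sparse_beta[1:]]) != 0.0)
    active_alpha = np.flatnonzero(np.concatenate([[1.0], sparse_alpha[1:]]) != 0.0)

    ll_sparse = mpr_loglik(params_sparse, data)
    k = (active_beta.size - 1) + (active_alpha.size - 1) + 2
    bic = -2.0 * ll_sparse + lam * k
    sic = -2.0 * sic_objective(params_hat, data, eps_T, lam)

    free = np.concatenate([bm, am])
    cov = _sandwich(params_hat, data, eps_T, lam, free)

    return FitResult(
        params_hat=params_hat,
        params_sparse=params_sparse,
        active_beta=active_beta,
        active_alpha=active_alpha,
        cov_hat=cov,
        loglik=ll_sparse,
        sic=sic,
        bic=bic,
        trace=trace,
        converged=all_converged,
        n_clips=n_clips,
        penalty_weight=lam,
        zero_tol=zero_tol,
        schedule=schedule,
        beta_mask=bm,
        alpha_mask=am,
    )


def fit_mpr_sic(
    data: Dataset,
    schedule: TelescopeSchedule | None = None,
    penalty_weight=None,
    zero_tol: float = 1e-8,
    beta_mask=None,
    alpha_mask=None,
) -> FitResult:
    """Fit the two-component (mean and log-variance) model with the SIC telescope.

    Defaults follow the recommended settings: schedule 10 -> 1e-5 in 100
    steps, ``penalty_weight = log(n)`` (BIC), ``zero_tol = 1e-8``.  Optional
    masks exclude individual columns from one component (used by
    :func:`delta_bic`); intercepts are always retained and never penalised.
    """
    return _fit_core(data, schedule, penalty_weight, zero_tol, beta_mask, alpha_mask)


def fit_spr_sic(
    data: Dataset,
    schedule: TelescopeSchedule | None = None,
    penalty_weight=None,
    zero_tol: float = 1e-8,
    beta_mask=None,
) -> FitResult:
    """Single-parameter variant: constant error variance (alpha intercept only)."""
    p1 = data.X.shape[1]
    alpha_mask = np.zeros(p1, dtype=bool)
    alpha_mask[0] = True
    return _fit_core(data, schedule, penalty_weight, zero_tol, beta_mask, alpha_mask)


def _sandwich(params: MPRParams, data: Dataset, eps: float, lam: float, free: np.ndarray) -> np.ndarray:
    I_pen, I0 = full_information(params, data, eps, lam)
    Is = I_pen[np.ix_(free, free)]
    I0s = I0[np.ix_(free, free)]
    try:
        Iinv = np.linalg.inv(Is)
    except np.linalg.LinAlgError as exc:
        raise NumericalFailure(f"singular penalised information: {exc}") from exc
    C = Iinv @ I0s @ Iinv
    C = 0.5 * (C + C.T)
    full = np.zeros((free.size, free.size))
    full[np.ix_(free, free)] = C
    return full


def sandwich_cov(result: FitResult, data: Dataset, eps: float | None = None, penalty_weight=None) -> np.ndarray:
    """Sandwich covariance ``I^{-1} I0 I^{-1}`` at the raw estimate.

    By default evaluated at the fit's final eps and penalty weight; symmetric
    PSD, with zero rows/columns for coefficients excluded from the fit.
    """
    eps = float(result.schedule.values[-1]) if eps is None else float(eps)
    lam = result.penalty_weight if penalty_weight is None else float(penalty_weight)
    free = np.concatenate([result.beta_mask, result.alpha_mask])
    return _sandwich(result.params_hat, data, eps, lam, free)


def delta_bic(
    data: Dataset,
    result: FitResult,
    index: int,
    component: str,
    schedule: TelescopeSchedule | None = None,
    penalty_weight=None,
) -> float:
    """BIC increase from dropping predictor ``index`` from one component.

    The restricted model excludes that column from the location
    (``component='location'``) or log-dispersion (``'dispersion'``) design
    and re-runs the full telescope; the other component is unrestricted
    (beyond any masks already in force).  Returns ``BIC(restricted) -
    BIC(full)``; a coefficient already at zero returns 0 with a warning.
    """
    if component not in ("location", "dispersion"):
        raise ValueError("component must be 'location' or 'dispersion'")
    if index < 1 or index >= result.params_hat.beta.size:
        raise ValueError("index must refer to a non-intercept predictor column")
    active = result.active_beta if component == "location" else result.active_alpha
    if index not in active:
        warnings.warn(
            f"{component} coefficient {index} is already (effectively) zero; delta BIC = 0",
            stacklevel=2,
        )
        return 0.0
    schedule = schedule if schedule is not None else result.schedule
    lam = result.penalty_weight if penalty_weight is None else float(penalty_weight)
    bm = result.beta_mask.copy()
    am = result.alpha_mask.copy()
    if component == "location":
        bm[index] = False
    else:
        am[index] = False
    restricted = _fit_core(data, schedule, lam, result.zero_tol, bm, am)
    return restricted.bic - result.bic
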