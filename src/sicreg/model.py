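"""Normal location-scale ("multiparameter") regression model.

The model is ``y_i = x_i' beta + e_i`` with ``Var(e_i) = exp(x_i' alpha)``:
the same design row (intercept plus p scaled predictors) enters both the
mean and the log-variance, and a coefficient of exactly zero removes a
predictor from that component.  This module provides the log-likelihood, the
smooth-IC (SIC) objective

    l(theta) - (lambda/2) * [ ||beta~||_{0,eps} + ||alpha~||_{0,eps} + 2 ],

(intercepts unpenalised, lambda = log n for the BIC flavour), and the
score/information pieces consumed by the block Newton-Raphson estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import SingularDesignError
from .penalty import smooth_l0, smooth_l0_grad, smooth_l0_hess

__all__ = [
    "Dataset",
    "MPRParams",
    "mpr_loglik",
    "sic_objective",
    "penalized_score",
    "penalized_information",
    "full_information",
    "LINPRED_CLAMP",
]

#: bound on the log-variance linear predictor before exponentiation;
#: exp(+-30) brackets any realistic variance at double precision.
LINPRED_CLAMP = 30.0


@dataclass
class Dataset:
    """Response vector plus design matrix with a leading intercept column.

    ``X`` is n x (p+1) with column 0 identically one; columns 1..p hold the
    predictors, normally scaled to unit sample standard deviation, with the
    scaling divisors recorded in ``scale_factors`` (length p) so estimates
    can be mapped back to the original predictor scale.
    """

    y: np.ndarray
    X: np.ndarray
    scale_factors: np.ndarray
    names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.asarray(self.X, dtype=float)
        self.scale_factors = np.asarray(self.scale_factors, dtype=float).ravel()
        n, pp1 = self.X.shape
        if self.y.shape[0] != n:
            raise ValueError("y and X have inconsistent lengths")
        if not np.allclose(self.X[:, 0], 1.0):
            raise ValueError("column 0 of X must be the intercept (all ones)")
        if self.scale_factors.shape[0] != pp1 - 1:
            raise ValueError("scale_factors must have one entry per predictor")
        if np.any(self.scale_factors <= 0):
            raise ValueError("scale_factors must be strictly positive")
        if not self.names:
            self.names = ["intercept"] + [f"x{j}" for j in range(1, pp1)]

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1] - 1

    @classmethod
    def from_arrays(cls, y, X_pred, scale: bool = True, scale_factors=None, names=None) -> "Dataset":
        """Assemble a Dataset from a raw predictor block (no intercept).

        When ``scale`` is true each predictor column is divided by its sample
        standard deviation (ddof=1); alternatively pre-computed
        ``scale_factors`` (e.g. from a training set) may be supplied.
        """
        y = np.asarray(y, dtype=float).ravel()
        X_pred = np.atleast_2d(np.asarray(X_pred, dtype=float))
        if X_pred.shape[0] != y.shape[0]:
            raise ValueError("y and predictor block have inconsistent lengths")
        p = X_pred.shape[1]
        if scale_factors is not None:
            sf = np.asarray(scale_factors, dtype=float).ravel()
        elif scale and p > 0:
            sf = X_pred.std(axis=0, ddof=1)
            if np.any(sf <= 0):
                bad = [j for j in range(p) if sf[j] <= 0]
                raise ValueError(f"constant predictor column(s) {bad}: cannot scale to unit variance")
        else:
            sf = np.ones(p)
        Xs = X_pred / sf if p > 0 else X_pred
        X = np.column_stack([np.ones(y.shape[0]), Xs]) if p > 0 else np.ones((y.shape[0], 1))
        full_names = None
        if names is not None:
            full_names = ["intercept"] + list(names)
        ds = cls(y=y, X=X, scale_factors=sf, names=full_names or [])
        if np.linalg.matrix_rank(ds.X) < ds.X.shape[1]:
            raise SingularDesignError("design matrix is rank deficient")
        return ds

    def unscale_coefs(self, coefs: np.ndarray) -> np.ndarray:
        """Map coefficients on the scaled-predictor scale back to the original scale."""
        coefs = np.asarray(coefs, dtype=float).copy()
        coefs[1:] = coefs[1:] / self.scale_factors
        return coefs


@dataclass
class MPRParams:
    """Paired coefficient vectors: ``beta`` (location) and ``alpha`` (log-dispersion)."""

    beta: np.ndarray
    alpha: np.ndarray

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float).ravel()
        self.alpha = np.asarray(self.alpha, dtype=float).ravel()
        if self.beta.shape != self.alpha.shape or self.beta.size < 1:
            raise ValueError("beta and alpha must share a common length >= 1")

    @property
    def theta(self) -> np.ndarray:
        return np.concatenate([self.beta, self.alpha])

    def copy(self) -> "MPRParams":
        return MPRParams(self.beta.copy(), self.alpha.copy())


def _resolve_weight(data: Dataset, penalty_weight) -> float:
    return float(np.log(data.n)) if penalty_weight is None else float(penalty_weight)


def _residual_pieces(params: MPRParams, data: Dataset):
    """Return (residuals, clamped eta_alpha, exp(-eta_alpha), clip count)."""
    eta_a = data.X @ params.alpha
    clipped = np.clip(eta_a, -LINPRED_CLAMP, LINPRED_CLAMP)
    n_clips = int(np.count_nonzero(eta_a != clipped))
    r = data.y - data.X @ params.beta
    return r, clipped, np.exp(-clipped), n_clips


def count_clips(params: MPRParams, data: Dataset) -> int:
    """Number of observations whose log-variance linear predictor is clamped."""
    return _residual_pieces(params, data)[3]


def mpr_loglik(params: MPRParams, data: Dataset) -> float:
    """Gaussian log-likelihood with mean ``X beta`` and variance ``exp(X alpha)``."""
    r, eta_a, inv_var, _ = _residual_pieces(params, data)
    n = data.n
    ll = -0.5 * n * np.log(2.0 * np.pi) - 0.5 * np.sum(eta_a) - 0.5 * np.sum(inv_var * r * r)
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite log-likelihood")
    return float(ll)


def _penalty_sum(params: MPRParams, eps: float) -> float:
    # intercepts (index 0) are never penalised; the +2 accounts for them in the IC
    return float(
        np.sum(smooth_l0(params.beta[1:], eps)) + np.sum(smooth_l0(params.alpha[1:], eps)) + 2.0
    )


def sic_objective(params: MPRParams, data: Dataset, eps: float, penalty_weight=None) -> float:
    """Smooth-IC penalised log-likelihood (to be maximised).

    ``penalty_weight`` defaults to ``log(n)`` (BIC); ``2`` gives the AIC
    flavour.  The constant "+2" intercept term is included so reported values
    line up with ``-BIC/2`` at eps -> 0.
    """
    lam = _resolve_weight(data, penalty_weight)
    return mpr_loglik(params, data) - 0.5 * lam * _penalty_sum(params, eps)


def score_blocks(params: MPRParams, data: Dataset, eps: float):
    """Raw per-observation score vectors and penalty gradients.

    Returns ``(z_beta, z_alpha, nu_beta, nu_alpha)`` where
    ``z_beta_i = exp(-x_i'alpha)(y_i - x_i'beta)``,
    ``z_alpha_i = (exp(-x_i'alpha)(y_i - x_i'beta)^2 - 1)/2`` and the nu
    vectors hold the smooth-L0 gradients with first entry forced to zero.
    """
    r, _, inv_var, _ = _residual_pieces(params, data)
    z_beta = inv_var * r
    z_alpha = 0.5 * (inv_var * r * r - 1.0)
    nu_beta = np.concatenate([[0.0], np.atleast_1d(smooth_l0_grad(params.beta[1:], eps))])
    nu_alpha = np.concatenate([[0.0], np.atleast_1d(smooth_l0_grad(params.alpha[1:], eps))])
    return z_beta, z_alpha, nu_beta, nu_alpha


def penalized_score(params: MPRParams, data: Dataset, eps: float, penalty_weight=None):
    """Gradient of the SIC objective: ``(d/dbeta, d/dalpha)``."""
    lam = _resolve_weight(data, penalty_weight)
    z_beta, z_alpha, nu_beta, nu_alpha = score_blocks(params, data, eps)
    g_beta = data.X.T @ z_beta - 0.5 * lam * nu_beta
    g_alpha = data.X.T @ z_alpha - 0.5 * lam * nu_alpha
    return g_beta, g_alpha


def info_weights(params: MPRParams, data: Dataset):
    """Diagonal weights of the observed information: (W_beta, W_alpha, W_alphabeta)."""
    r, _, inv_var, _ = _residual_pieces(params, data)
    return inv_var, 0.5 * inv_var * r * r, inv_var * r


def penalty_curvature(params: MPRParams, eps: float):
    """Penalty-curvature diagonals (Sigma_beta, Sigma_alpha), first entries zero."""
    sig_beta = np.concatenate([[0.0], np.atleast_1d(smooth_l0_hess(params.beta[1:], eps))])
    sig_alpha = np.concatenate([[0.0], np.atleast_1d(smooth_l0_hess(params.alpha[1:], eps))])
    return sig_beta, sig_alpha


def penalized_information(params: MPRParams, data: Dataset, eps: float, penalty_weight=None):
    """Diagonal blocks of the RS Newton system (cross block omitted).

    Returns ``(A_beta, A_alpha)`` with
    ``A_beta = X' W_beta X + lam * Sigma_beta / 2`` and likewise for alpha.
    """
    lam = _resolve_weight(data, penalty_weight)
    w_beta, w_alpha, _ = info_weights(params, data)
    sig_beta, sig_alpha = penalty_curvature(params, eps)
    A_beta = data.X.T @ (w_beta[:, None] * data.X) + 0.5 * lam * np.diag(sig_beta)
    A_alpha = data.X.T @ (w_alpha[:, None] * data.X) + 0.5 * lam * np.diag(sig_alpha)
    return A_beta, A_alpha


def full_information(params: MPRParams, data: Dataset, eps: float, penalty_weight=None):
    """Full penalised information I(theta) and unpenalised I0(theta).

    Both are (2p+2) x (2p+2) and include the ``X' W_alphabeta X`` cross
    blocks; I is I0 plus the penalty-curvature diagonal and is the matrix
    inverted in the sandwich covariance.
    """
    lam = _resolve_weight(data, penalty_weight)
    w_beta, w_alpha, w_ab = info_weights(params, data)
    X = data.X
    I_bb = X.T @ (w_beta[:, None] * X)
    I_aa = X.T @ (w_alpha[:, None] * X)
    I_ab = X.T @ (w_ab[:, None] * X)
    I0 = np.block([[I_bb, I_ab], [I_ab.T, I_aa]])
    sig_beta, sig_alpha = penalty_curvature(params, eps)
    pen = 0.5 * lam * np.concatenate([sig_beta, sig_alpha])
    return I0 + np.diag(pen), I0
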