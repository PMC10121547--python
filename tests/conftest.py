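"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the package's own likelihood/Newton
machinery: log-likelihoods are summed from ``scipy.stats.norm`` densities
and restricted maximum-likelihood fits use a generic quasi-Newton optimiser,
so they can serve as independent cross-checks of the telescoped SIC fits.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from scipy import optimize, stats

from sicreg.model import Dataset


def oracle_loglik(beta, alpha, data: Dataset) -> float:
    """Per-observation normal density sum, independent of the package formula."""
    mu = data.X @ beta
    sd = np.sqrt(np.exp(data.X @ alpha))
    return float(np.sum(stats.norm.logpdf(data.y, mu, sd)))


def oracle_restricted_mle(data: Dataset, beta_support, alpha_support):
    """Unpenalised MLE with the given non-intercept supports (1 = included).

    Returns ``(beta, alpha, negloglik)`` as full-length vectors with zeros in
    the excluded positions.
    """
    p = data.p
    bidx = [0] + [j + 1 for j in range(p) if beta_support[j]]
    aidx = [0] + [j + 1 for j in range(p) if alpha_support[j]]

    def nll(th):
        b = np.zeros(p + 1)
        a = np.zeros(p + 1)
        b[bidx] = th[: len(bidx)]
        a[aidx] = th[len(bidx):]
        mu = data.X @ b
        var = np.exp(np.clip(data.X @ a, -30, 30))
        return -np.sum(stats.norm.logpdf(data.y, mu, np.sqrt(var)))

    x0 = np.zeros(len(bidx) + len(aidx))
    res = optimize.minimize(nll, x0, method="BFGS", options={"gtol": 1e-9, "maxiter": 2000})
    b = np.zeros(p + 1)
    a = np.zeros(p + 1)
    b[bidx] = res.x[: len(bidx)]
    a[aidx] = res.x[len(bidx):]
    return b, a, float(res.fun)


def oracle_best_subset(data: Dataset, lam: float, spr: bool = False):
    """Exhaustive BIC minimisation over all support patterns.

    Enumerates 2^(2p) (or 2^p when ``spr``) supports, fits the unpenalised
    restricted model for each, and returns ``(beta_support, alpha_support,
    bic)`` of the minimiser, preferring the smaller support on near-ties.
    """
    p = data.p
    alpha_patterns = [(0,) * p] if spr else list(itertools.product([0, 1], repeat=p))
    best = None
    for sb in itertools.product([0, 1], repeat=p):
        for sa in alpha_patterns:
            _, _, negll = oracle_restricted_mle(data, sb, sa)
            bic = 2.0 * negll + lam * (sum(sb) + sum(sa) + 2)
            key = (round(bic, 10), sum(sb) + sum(sa))
            if best is None or key < best[0]:
                best = (key, sb, sa, bic)
    return best[1], best[2], best[3]


def make_instance(seed: int, n: int = 50, p: int = 3, beta=None, alpha=None):
    """Random heteroscedastic dataset plus the truth used to generate it."""
    rng = np.random.default_rng(seed)
    Xp = rng.standard_normal((n, p))
    beta = np.asarray(beta, dtype=float) if beta is not None else rng.normal(0, 1, p + 1)
    alpha = np.asarray(alpha, dtype=float) if alpha is not None else rng.normal(0, 0.5, p + 1)
    Xint = np.column_stack([np.ones(n), Xp])
    y = Xint @ beta + np.exp(0.5 * np.clip(Xint @ alpha, -30, 30)) * rng.standard_normal(n)
    return Dataset.from_arrays(y, Xp), beta, alpha


@pytest.fixture
def small_data():
    data, _, _ = make_instance(seed=11, n=50, p=3)
    return data
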