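"""Smooth L0 penalty and the eps-telescope schedule.

The L0 "norm" (the number of non-zero coefficients) is approximated by the
smooth unit-dent function

    phi_eps(x) = x^2 / (x^2 + eps^2),

which is even, lies in [0, 1), and converges pointwise to the zero-indicator
as ``eps -> 0``.  Because a single very small eps is numerically unstable
(the surrogate is then nearly discontinuous at the origin), optimisation
telescopes through a geometrically decaying sequence of eps values; this
module provides that schedule together with the penalty and its first two
derivatives, all as pure vectorised numerics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "smooth_l0",
    "smooth_l0_grad",
    "smooth_l0_hess",
    "TelescopeSchedule",
    "make_schedule",
]


def _check_eps(eps: float) -> float:
    eps = float(eps)
    if not np.isfinite(eps) or eps <= 0.0:
        raise ValueError(f"eps must be a positive real, got {eps!r}")
    return eps


def smooth_l0(x, eps: float):
    """Smooth approximation ``x^2 / (x^2 + eps^2)`` of the zero-indicator.

    Parameters
    ----------
    x : array_like
        Coefficient value(s).
    eps : float
        Smoothing parameter, strictly positive.

    Returns
    -------
    ndarray or float in ``[0, 1)``, even in ``x``.
    """
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=float)
    x2 = x * x
    out = x2 / (x2 + eps * eps)
    return out if out.ndim else float(out)


def smooth_l0_grad(x, eps: float):
    """First derivative ``2 x eps^2 / (x^2 + eps^2)^2`` of :func:`smooth_l0`."""
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=float)
    e2 = eps * eps
    denom = (x * x + e2) ** 2
    out = 2.0 * x * e2 / denom
    return out if out.ndim else float(out)


def smooth_l0_hess(x, eps: float):
    """Second derivative ``2 eps^2 (eps^2 - 3 x^2) / (x^2 + eps^2)^3``.

    Equals ``2/eps^2`` at the origin and is negative for ``|x| > eps/sqrt(3)``,
    so penalty curvature can be indefinite away from zero.
    """
    eps = _check_eps(eps)
    x = np.asarray(x, dtype=float)
    e2 = eps * eps
    x2 = x * x
    out = 2.0 * e2 * (e2 - 3.0 * x2) / (x2 + e2) ** 3
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TelescopeSchedule:
    """Geometrically decaying sequence of smoothing parameters.

    ``values[t] = eps_start * decay_rate**t`` for ``t = 0 .. n_steps-1``
    (0-based internally), ending at ``eps_end``.
    """

    eps_start: float
    eps_end: float
    n_steps: int
    decay_rate: float
    values: np.ndarray = field(repr=False)

    def __len__(self) -> int:
        return self.n_steps

    def __iter__(self):
        return iter(self.values)


def make_schedule(eps_start: float = 10.0, eps_end: float = 1e-5, n_steps: int = 100) -> TelescopeSchedule:
    """Build the eps-telescope ``eps_start * r**t`` hitting ``eps_end`` at the last step.

    The decay rate is ``r = (eps_end/eps_start)**(1/(n_steps-1))``; with the
    default settings (10 down to 1e-5 in 100 steps) r is approximately 0.87.

    Raises
    ------
    ValueError
        If ``eps_end > eps_start``, either endpoint is non-positive, or
        ``n_steps == 1`` with distinct endpoints.
    """
    eps_start = _check_eps(eps_start)
    eps_end = _check_eps(eps_end)
    n_steps = int(n_steps)
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    if eps_end > eps_start:
        raise ValueError("eps_end must not exceed eps_start")
    if n_steps == 1:
        if not np.isclose(eps_start, eps_end, rtol=1e-12):
            raise ValueError("a single-step schedule requires eps_start == eps_end")
        return TelescopeSchedule(eps_start, eps_end, 1, 1.0, np.array([eps_start]))
    r = float(np.exp(np.log(eps_end / eps_start) / (n_steps - 1)))
    values = eps_start * r ** np.arange(n_steps, dtype=float)
    return TelescopeSchedule(eps_start, eps_end, n_steps, r, values)
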