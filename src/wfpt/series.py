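"""Series representations of the symmetric-boundary first-passage time density.

The canonical (unit) diffusion model is ``dx = mu dt + dW`` started at 0 with
absorbing boundaries at -1 and +1.  The density of the first-passage time
``T`` (irrespective of which boundary is hit) admits two classical infinite
series:

* the **short-time** (method-of-images) series,

  .. math::

     g(t) = 2\\cosh(\\mu)\\, e^{-\\mu^2 t/2}\\, (2\\pi t^3)^{-1/2}
            \\sum_{k\\ge 0} (-1)^k (2k+1) e^{-(2k+1)^2/(2t)},

* the **long-time** (Fourier / eigenfunction) series,

  .. math::

     g(t) = 2\\cosh(\\mu)\\, e^{-\\mu^2 t/2}\\, \\frac{\\pi}{4}
            \\sum_{k\\ge 0} (-1)^k (2k+1) e^{-(2k+1)^2 \\pi^2 t/8}.

Both are exact; they differ only in how fast they converge.  Factoring the
``k = 0`` exponential out of either sum leaves a *relative* alternating sum

.. math::  S_n(q) = \\sum_{k=0}^{n} (-1)^k (2k+1)\\, q^{k(k+1)/2},

with ``q = e^{-4/t}`` (short) or ``q = e^{-\\pi^2 t}`` (long), whose partial
sums alternately upper-bound (even ``n``) and lower-bound (odd ``n``) the
limit as long as term magnitudes are non-increasing.  That property holds for
``t <= 4/ln 3`` (short) and ``t >= ln 3 / pi^2`` (long), and it is what makes
the accept/reject decision of the sampler possible without ever evaluating
the full series.

The time marginal depends on the drift only through ``|mu|``; the sign of the
drift enters only through the boundary-choice probability ``upper_prob``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import special

__all__ = [
    "UnitModel",
    "upper_prob",
    "validity_window",
    "short_partial",
    "long_partial",
    "density",
    "log_bound_short",
    "log_bound_long",
    "rel_partial",
]

#: Cap on series terms for oracle-grade evaluation; the series are
#: guaranteed convergent inside their validity ranges, so this only
#: guards against implementation bugs.
MAX_TERMS = 1_000_000


@dataclass(frozen=True)
class UnitModel:
    """Canonical diffusion model: boundaries at ±1, unit variance, start 0.

    Parameters
    ----------
    mu : float
        Dimensionless drift.  All time-marginal formulas depend on it only
        through ``|mu|``; its sign only affects which boundary is more likely.
    """

    mu: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError(f"drift must be finite, got {self.mu!r}")


def upper_prob(mu: float) -> float:
    """Probability that the upper (+1) boundary is reached first.

    Equals ``(e^{2mu} - 1) / (e^{2mu} - e^{-2mu}) = 1 / (1 + e^{-2mu})``,
    the classical scale-function hitting probability; evaluated through the
    logistic function so it is overflow-free for any finite drift.
    """
    if not np.all(np.isfinite(mu)):
        raise ValueError("drift must be finite")
    return special.expit(2.0 * np.asarray(mu, dtype=float))[()]


def validity_window() -> tuple[float, float]:
    """Range of times on which *both* series have the alternating-bound property.

    The long series' term magnitudes are non-increasing for all ``n`` iff
    ``ln((2k+3)/(2k+1)) <= (k+1) pi^2 t`` for every ``k >= 0`` (binding at
    ``k = 0``), giving the floor ``ln 3 / pi^2``.  The short series requires
    ``ln((2k+3)/(2k+1)) <= 4(k+1)/t``, giving the ceiling ``4 / ln 3``.
    Any series-selection threshold must lie inside this window.
    """
    return math.log(3.0) / math.pi**2, 4.0 / math.log(3.0)


def _log2cosh(mu: float | np.ndarray) -> float | np.ndarray:
    # log(2 cosh(mu)) = log(e^mu + e^-mu), overflow-free
    return np.logaddexp(mu, -np.asarray(mu, dtype=float))


def log_bound_short(t, mu):
    """Log of the one-term (``n = 0``) short-series upper bound on g(t).

    ``b_s(t) = 2 cosh(mu) e^{-mu^2 t/2} (2 pi t^3)^{-1/2} e^{-1/(2t)}``.
    Stable in log space down to arbitrarily small ``t``.
    """
    t = np.asarray(t, dtype=float)
    mu = abs(mu)
    return (
        _log2cosh(mu)
        - mu**2 * t / 2.0
        - 1.5 * np.log(t)
        - 0.5 * math.log(2.0 * math.pi)
        - 1.0 / (2.0 * t)
    )


def log_bound_long(t, mu):
    """Log of the one-term long-series upper bound on g(t).

    ``b_l(t) = cosh(mu) (pi/2) e^{-lambda t}`` with
    ``lambda = mu^2/2 + pi^2/8``.
    """
    t = np.asarray(t, dtype=float)
    mu = abs(mu)
    lam = mu**2 / 2.0 + math.pi**2 / 8.0
    return _log2cosh(mu) - math.log(2.0) + math.log(math.pi / 2.0) - lam * t


def rel_partial(t: float, n: int, branch: str) -> float:
    """Truncated relative alternating sum ``S_n(q)`` for one branch.

    ``q = e^{-4/t}`` for ``branch='short'``, ``q = e^{-pi^2 t}`` for
    ``branch='long'``.  Computed by the cheap recursion
    ``m_k = m_{k-1} q``, ``f_k = f_{k-1} m_k`` (so ``f_k = q^{k(k+1)/2}``),
    which never re-exponentiates a full term.  Within the branch's validity
    range, even-``n`` values upper-bound the limit and odd-``n`` values
    lower-bound it.
    """
    if t <= 0.0:
        raise ValueError(f"time must be positive, got {t!r}")
    if n < 0:
        raise ValueError(f"truncation index must be >= 0, got {n!r}")
    q = _branch_q(t, branch)
    s = 1.0
    m = 1.0
    f = 1.0
    for k in range(1, n + 1):
        m *= q
        f *= m
        term = (2 * k + 1) * f
        s = s - term if k % 2 else s + term
    return s


def _branch_q(t: float, branch: str) -> float:
    if branch == "short":
        return math.exp(-4.0 / t)
    if branch == "long":
        return math.exp(-(math.pi**2) * t)
    raise ValueError(f"branch must be 'short' or 'long', got {branch!r}")


def short_partial(t: float, mu: float, n: int) -> float:
    """``n``-term truncation of g(t) under the method-of-images series."""
    rel = rel_partial(t, n, "short")  # validates t and n
    return math.exp(log_bound_short(t, mu)) * rel


def long_partial(t: float, mu: float, n: int) -> float:
    """``n``-term truncation of g(t) under the Fourier series."""
    rel = rel_partial(t, n, "long")
    return math.exp(log_bound_long(t, mu)) * rel


def _rel_limit(t: float, branch: str, tol: float, max_terms: int = MAX_TERMS) -> float:
    """Relative sum to relative accuracy ``tol`` (adaptive truncation)."""
    q = _branch_q(t, branch)
    s = 1.0
    m = 1.0
    f = 1.0
    for k in range(1, max_terms + 1):
        m *= q
        f *= m
        term = (2 * k + 1) * f
        s = s - term if k % 2 else s + term
        if term < tol * abs(s):
            return s
    raise ArithmeticError(
        f"series did not converge within {max_terms} terms (t={t}, branch={branch})"
    )


def density(t: float, mu: float, tol: float = 1e-12) -> float:
    """First-passage time density g(t) of the unit model, to relative accuracy.

    Selects the series branch at the midpoint of :func:`validity_window` and
    sums until the next term magnitude drops below ``tol`` times the running
    value.  Oracle-grade evaluation for tests and the CDF oracle; the
    sampler's accept loop never calls it.
    """
    if t <= 0.0:
        raise ValueError(f"time must be positive, got {t!r}")
    if not 0.0 < tol < 1.0:
        raise ValueError(f"tol must be in (0, 1), got {tol!r}")
    t_lo, t_hi = validity_window()
    branch = "short" if t <= 0.5 * (t_lo + t_hi) else "long"
    log_pre = log_bound_short(t, mu) if branch == "short" else log_bound_long(t, mu)
    if log_pre < -745.0:  # density underflows double precision
        return 0.0
    return math.exp(log_pre) * _rel_limit(t, branch, tol)
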