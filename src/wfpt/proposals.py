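"""Proposal envelopes for rejection sampling of first-passage times.

Two envelopes are constructed, each dominating the one-term (``n = 0``)
series bounds on g(t) — and hence g(t) itself, since those truncations are
upper bounds inside their validity ranges:

* ``f1`` (tight for small drift): a stretched ``1/(aX^2)``-of-a-Gaussian
  density on the short-time part, joined at the branch threshold ``t~`` to an
  exponential with rate ``lambda = mu^2/2 + pi^2/8`` on the long-time part.
  Sampled by the inversion method through ``erfc`` / ``erfcinv``.

* ``f2`` (tight for large drift): a rescaled inverse-Gaussian with mean
  ``1/mu`` and shape 1 — the single-boundary first-passage law, which the
  two-boundary density approaches as the drift grows.  The base scale
  ``1 + e^{-2 mu}`` makes it equal the short-time bound *exactly* for all t;
  domination of the long-time bound is free for ``t~ >= t_x = 2/pi`` and
  otherwise bought by a numerically maximized extra rescale.

The envelope construction for ``f1``: the short bound is proportional to
``t^{-3/2} e^{-1/(2t) - mu^2 t/2}`` whose mode solves
``mu^2 t^2 + 3t - 1 = 0``; stretching the drift-free curve
``t^{-3/2} e^{-1/(2at)}`` by ``1/a = 3 t_mode`` makes the two touch
tangentially at that mode, and ``C_s = 2 cosh(mu) sqrt(a) e^{-mu^2 t_mode}``
scales the stretched curve onto the bound there.
"""

from __future__ import annotations

import functools
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, special

from .series import log_bound_long, log_bound_short, validity_window

__all__ = [
    "F1Constants",
    "F2Constants",
    "f1_build",
    "f1_cdf",
    "f1_invcdf",
    "f1_sample",
    "f1_log_envelope",
    "f2_build",
    "f2_sample",
    "f2_log_envelope",
    "crossing_time",
    "invgauss_sample",
]


@dataclass(frozen=True)
class F1Constants:
    """Precomputed constants of the small-drift Gaussian/exponential envelope.

    Attributes
    ----------
    mu : float
        Drift magnitude the envelope was built for.
    t_tilde : float
        Time below/above which the short/long pieces apply.
    a : float
        Tangency stretch factor, >= 1.
    t_mode : float
        Mode of the short-time one-term bound; the tangency point.
    lam : float
        Exponential rate of the long piece, ``mu^2/2 + pi^2/8``.
    C_s, C_l : float
        Scales of the short and long pieces.
    F_split : float
        Unnormalized cumulative mass below ``t_tilde``.
    F_tot : float
        Total unnormalized mass; the acceptance rate is ``1 / F_tot``.
    """

    mu: float
    t_tilde: float
    a: float
    t_mode: float
    lam: float
    C_s: float
    C_l: float
    F_split: float
    F_tot: float


@dataclass(frozen=True)
class F2Constants:
    """Precomputed constants of the large-drift inverse-Gaussian envelope."""

    mu: float
    t_tilde: float
    C_f: float
    extra: float  # extra rescale beyond the base 1 + e^{-2 mu}; 1 when free


def f1_build(mu: float, t_tilde: float) -> F1Constants:
    """Build the small-drift envelope constants for drift magnitude ``|mu|``."""
    mu = abs(float(mu))
    t_lo, t_hi = validity_window()
    if not t_lo < t_tilde < t_hi:
        raise ValueError(
            f"t_tilde={t_tilde} outside the series validity window ({t_lo:.6f}, {t_hi:.6f})"
        )
    t_mode = 2.0 / (3.0 + math.sqrt(9.0 + 4.0 * mu**2))
    a = 1.0 / (3.0 * t_mode)  # 1/a = 1 - mu^2 t_mode^2 = 3 t_mode
    lam = mu**2 / 2.0 + math.pi**2 / 8.0
    C_s = 2.0 * math.cosh(mu) * math.sqrt(a) * math.exp(-(mu**2) * t_mode)
    C_l = math.cosh(mu) * math.pi / (2.0 * lam)
    F_split = C_s * special.erfc(1.0 / math.sqrt(2.0 * a * t_tilde))
    F_tot = F_split + C_l * math.exp(-lam * t_tilde)
    return F1Constants(mu, float(t_tilde), a, t_mode, lam, C_s, C_l, F_split, F_tot)


def f1_cdf(t, c: F1Constants):
    """Unnormalized cumulative mass of the f1 envelope at time ``t``.

    ``C_s erfc(1/sqrt(2at))`` below the join, plus the exponential tail piece
    above; continuous, non-decreasing, with limit ``F_tot``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t <= 0.0):
        raise ValueError("time must be positive")
    short = c.C_s * special.erfc(1.0 / np.sqrt(2.0 * c.a * t))
    long_ = c.F_split + c.C_l * (np.exp(-c.lam * c.t_tilde) - np.exp(-c.lam * t))
    return np.where(t <= c.t_tilde, short, long_)[()]


def f1_invcdf(P, c: F1Constants):
    """Exact inverse of :func:`f1_cdf` on ``(0, F_tot)``."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0.0) or np.any(P >= c.F_tot):
        raise ValueError(f"cumulative mass must lie in (0, {c.F_tot})")
    on_short = P <= c.F_split
    # short piece: P = C_s erfc(1/sqrt(2at))  =>  t = 1/(2a erfcinv(P/C_s)^2)
    z = special.erfcinv(np.clip(P / c.C_s, None, 1.0))
    with np.errstate(divide="ignore"):
        t_short = 1.0 / (2.0 * c.a * z**2)
    # long piece: P = F_split + C_l (e^{-lam t~} - e^{-lam t})
    arg = np.exp(-c.lam * c.t_tilde) - (P - c.F_split) / c.C_l
    with np.errstate(invalid="ignore", divide="ignore"):
        t_long = -np.log(np.where(on_short, 1.0, arg)) / c.lam
    return np.where(on_short, t_short, t_long)[()]


def f1_log_envelope(t, c: F1Constants):
    """Log of the f1 envelope *density* at ``t`` (branch chosen by ``t_tilde``).

    Short piece: ``C_s (2 pi a)^{-1/2} t^{-3/2} e^{-1/(2at)}``; long piece:
    ``C_l lam e^{-lam t}``.
    """
    t = np.asarray(t, dtype=float)
    log_short = (
        math.log(c.C_s)
        - 0.5 * math.log(2.0 * math.pi * c.a)
        - 1.5 * np.log(t)
        - 1.0 / (2.0 * c.a * t)
    )
    log_long = math.log(c.C_l * c.lam) - c.lam * t
    return np.where(t <= c.t_tilde, log_short, log_long)[()]


def f1_sample(c: F1Constants, rng: np.random.Generator, size: int | None = None):
    """Draw from the f1 envelope by inversion; returns ``(t_star, envelope)``.

    ``envelope`` is the scaled proposal density at ``t_star`` — the quantity
    the accept step compares ``u * envelope`` against g.
    """
    P = rng.uniform(0.0, c.F_tot, size)
    t = f1_invcdf(P, c)
    return t, np.exp(f1_log_envelope(t, c))


@functools.lru_cache(maxsize=1)
def crossing_time() -> float:
    """Time where the short and long one-term bounds cross (drift-free ratio).

    Solves ``(2 pi t^3)^{-1/2} e^{-1/(2t)} = (pi/4) e^{-pi^2 t/8}``; the
    drift-dependent factors of the two bounds are identical so the crossing
    is drift-independent.  Numerically this root is 2/pi.
    """
    f = lambda t: log_bound_short(t, 0.0) - log_bound_long(t, 0.0)
    return float(optimize.brentq(f, 0.2, 2.0, xtol=1e-14))


def f2_build(mu: float, t_tilde: float) -> F2Constants:
    """Build the large-drift inverse-Gaussian envelope constants.

    The base scale ``1 + e^{-2 mu}`` makes the scaled IG(1/mu, 1) density
    equal the short-time bound for every ``t``.  If ``t_tilde`` falls below
    the bound-crossing time the envelope must additionally dominate the long
    bound on ``[t_tilde, t_x]``; the required inflation is found by
    maximizing the bound/envelope log-ratio there.
    """
    mu = float(mu)
    if mu <= 0.0:
        raise ValueError("the inverse-Gaussian envelope requires mu > 0")
    base = 1.0 + math.exp(-2.0 * mu)
    t_x = crossing_time()
    extra = 1.0
    if t_tilde < t_x:
        # maximize b_l(t)/b_s(t) on [t_tilde, t_x]; drift cancels in the ratio
        neg_log_ratio = lambda t: -(log_bound_long(t, 0.0) - log_bound_short(t, 0.0))
        res = optimize.minimize_scalar(
            neg_log_ratio, bounds=(t_tilde, t_x), method="bounded"
        )
        # the ratio peaks at the lower endpoint; keep endpoints as candidates
        best = min(res.fun, neg_log_ratio(t_tilde), neg_log_ratio(t_x))
        extra = float(math.exp(-best))
    return F2Constants(mu, float(t_tilde), base * extra, extra)


def invgauss_sample(mean: float, shape: float, rng: np.random.Generator, size=None):
    """Inverse-Gaussian variates by the chi-square transform with uniform root choice.

    Exact, constant cost per draw: square a standard normal, solve the
    quadratic for the two candidate roots, pick the smaller with probability
    ``mean / (mean + root)``.
    """
    y = rng.standard_normal(size) ** 2
    w = mean * y / shape
    x1 = mean * (1.0 + w / 2.0 - np.sqrt(w + w * w / 4.0))
    u = rng.random(size)
    return np.where(u <= mean / (mean + x1), x1, mean * mean / x1)


def _log_ig_pdf(t, mu: float):
    # inverse-Gaussian(mean 1/mu, shape 1) log-density:
    # (2 pi t^3)^{-1/2} exp(-(1 - mu t)^2 / (2t))
    t = np.asarray(t, dtype=float)
    return (
        -0.5 * math.log(2.0 * math.pi)
        - 1.5 * np.log(t)
        - 1.0 / (2.0 * t)
        + mu
        - mu**2 * t / 2.0
    )


def f2_log_envelope(t, c: F2Constants):
    """Log of the scaled inverse-Gaussian envelope density at ``t``."""
    return math.log(c.C_f) + _log_ig_pdf(t, c.mu)


def f2_sample(c: F2Constants, rng: np.random.Generator, size: int | None = None):
    """Draw from the f2 envelope; returns ``(t_star, envelope)``."""
    t = invgauss_sample(1.0 / c.mu, 1.0, rng, size)
    return t, np.exp(f2_log_envelope(t, c))
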