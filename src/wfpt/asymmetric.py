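"""First-passage sampling with asymmetric boundaries.

The symmetric sampler is used as a building block: at each stage the largest
symmetric model centered on the current particle location is inscribed in the
asymmetric one (half-width equal to the distance to the nearer boundary), one
symmetric (time, boundary) pair is drawn, and the particle jumps to the inner
boundary it hit.  When that inner boundary coincides with a true outer
boundary the accumulated time and that boundary are returned; otherwise a new
symmetric model is inscribed at the new location.  Every stage draw is exact,
so the staged composition is exact as well.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .sampler import FptDraw, SamplerConfig, sample_unit
from .series import upper_prob

__all__ = ["AsymSpec", "sample_asym", "sample_asym_many"]


@dataclass(frozen=True)
class AsymSpec:
    """Diffusion model with boundaries at ``+theta_up`` and ``-theta_lo``."""

    mu_hat: float
    theta_up: float
    theta_lo: float
    sigma2: float

    def __post_init__(self) -> None:
        for name in ("mu_hat", "theta_up", "theta_lo", "sigma2"):
            if not math.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.theta_up <= 0.0 or self.theta_lo <= 0.0 or self.sigma2 <= 0.0:
            raise ValueError("theta_up, theta_lo and sigma2 must be > 0")


def sample_asym(
    spec: AsymSpec,
    cfg: SamplerConfig = SamplerConfig(),
    rng: np.random.Generator | None = None,
    max_stages: int = 1_000_000,
) -> FptDraw:
    """One exact (T, X) draw from the asymmetric model by nested symmetric models."""
    rng = np.random.default_rng() if rng is None else rng
    x = 0.0
    total_t = 0.0
    for _ in range(max_stages):
        d_up = spec.theta_up - x
        d_lo = spec.theta_lo + x
        w = min(d_up, d_lo)
        mu = spec.mu_hat * w / spec.sigma2
        # same association as DiffusionSpec.time_scale, so the degenerate
        # symmetric case reproduces the symmetric sampler bit-for-bit
        total_t += sample_unit(mu, cfg, rng) * (w**2 / spec.sigma2)
        hit_upper = rng.random() < upper_prob(mu)
        if hit_upper:
            if d_up <= d_lo:  # inner upper boundary is the true upper boundary
                return FptDraw(T=total_t, X=1)
            x += w
        else:
            if d_lo <= d_up:
                return FptDraw(T=total_t, X=0)
            x -= w
    raise ArithmeticError(f"no boundary hit within {max_stages} stages")


def sample_asym_many(
    spec: AsymSpec,
    n: int,
    cfg: SamplerConfig = SamplerConfig(),
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """``n`` independent asymmetric draws; returns (times, boundaries)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng() if rng is None else rng
    T = np.empty(n)
    X = np.empty(n, dtype=np.int8)
    for i in range(n):
        d = sample_asym(spec, cfg, rng)
        T[i] = d.T
        X[i] = d.X
    return T, X
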