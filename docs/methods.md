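# Methods

## Model

The canonical Wiener diffusion model is `dx = μ dt + dW`, `x(0) = 0`, with
absorbing boundaries at −1 and +1. The observable is the pair
(first-passage time `T`, boundary `X`). For symmetric boundaries the joint
density factorizes: the densities of reaching the upper and lower boundary
at time `t` are rescaled versions of one another (the Girsanov tilting
factor `e^{±μ−μ²t/2}` applied to the zero-drift density depends on the
boundary only through a time-independent constant), so `T` is independent of
`X`, `X ~ Bernoulli(1/(1+e^{−2μ}))`, and sampling reduces to the time
marginal `g(t)`. A general model `(μ̂, θ, σ²)` maps onto the canonical one
by rescaling space by `1/θ` and time by `σ²/θ²`: the canonical drift is
`μ = μ̂θ/σ²` and a canonical time `t` corresponds to `T = tθ²/σ²`.

`g(t)` has two exact series forms: the method-of-images (short-time) series,
with terms `(2k+1) e^{−(2k+1)²/(2t)}` and prefactor
`2cosh(μ)e^{−μ²t/2}(2πt³)^{−1/2}`, and the Fourier (long-time) series, terms
`(2k+1) e^{−(2k+1)²π²t/8}` with prefactor `2cosh(μ)e^{−μ²t/2}(π/4)`. The
time marginal depends on the drift only through `|μ|`; the implementation
takes absolute values everywhere except in the boundary probability.

## The series method

Factoring the `k = 0` exponential out of either sum leaves the relative
alternating sum `S_n(q) = Σ_{k≤n} (−1)^k (2k+1) q^{k(k+1)/2}` with
`q = e^{−4/t}` (short) or `q = e^{−π²t}` (long) — the only quantity the
accept loop ever iterates, advanced by two multiplications per term
(`m ← mq`, `f ← fm`), never by re-exponentiation. Partial sums alternately
bound the limit provided term magnitudes are non-increasing, which holds for
`t ≤ 4/ln 3 ≈ 3.641` (short) and `t ≥ ln 3/π² ≈ 0.1113` (long); any
branch-selection threshold `t̃` must lie in this window. A proposal `t*` is
accepted iff `u·f(t*) ≤ g(t*)` where `f` is the scaled envelope and `u`
uniform; dividing by the branch's one-term bound turns this into comparing
`r = u·f(t*)/bound(t*)` against `S_n(q)`: reject when `r` reaches an even
partial, accept when it falls to an odd one. The decision is exact and
terminates almost surely; in practice it resolves within a couple of terms
(the diagnostics report ~0.5–1.5 terms per decision at the default
thresholds). `r` is formed in log space, so extreme proposals (tiny `t*`
with an underflowing density) are handled without special cases.

## Envelopes

**Small drift (f1).** The long-time one-term bound is proportional to an
exponential density with rate `λ = μ²/2 + π²/8`, scaled by
`C_l = cosh(μ)·π/(2λ)`. The short-time one-term bound, proportional to
`t^{−3/2}e^{−1/(2t)−μ²t/2}`, is bounded by the density of `1/(aX²)`
(`X` standard normal) stretched by `a ≥ 1`: the bound's mode solves
`μ²t² + 3t − 1 = 0`, i.e. `t_mode = 2/(3+√(9+4μ²))`, the tangency condition
gives `1/a = 1 − μ²t_mode² = 3t_mode`, and matching the curves at the mode
gives `C_s = 2cosh(μ)√a·e^{−μ²t_mode}`. The log-ratio of envelope to bound
is `μ²(t_mode/√(2t) − √(t/2))² ≥ 0` with equality exactly at `t_mode`, which
proves domination and tangency in one line. The two pieces are joined at
`t̃`; sampling is by inversion of the piecewise closed-form cumulative
(`erfc`/`erfcinv` below the join, exponential above), so one uniform yields
one proposal.

**Large drift (f2).** The short-time bound equals `(1+e^{−2μ})` times the
inverse-Gaussian(mean `1/μ`, shape 1) density — exactly, for every `t` — so
that scaled inverse-Gaussian *is* the short-branch envelope with acceptance
ratio independent of `t`. The long-time bound crosses the short-time bound
at a drift-independent time `t_x` (numerically `2/π ≈ 0.6366`; the package
computes it by root finding and tests pin it against the closed form);
for `t ≥ t_x` the short bound dominates the long one, so with `t̃ ≥ t_x` no
further scaling is needed. If a user sets `t̃ < t_x`, the build step
inflates the constant by the maximal long-bound/short-bound ratio on
`[t̃, t_x]` (maximized numerically, endpoints included — the ratio peaks at
`t̃`). Inverse-Gaussian variates use the chi-square-transform method with
the uniform root choice. The zero-drift case is never routed here (the mean
`1/μ` degenerates), which the `μ̃ > 0` threshold enforces.

## Tunable parameters

| parameter | default | units | role |
|---|---|---|---|
| `t_tilde_small(μ)` | `0.12 + 0.5e^{−μ/3}` | canonical time | f1 series split; matches the tuned endpoints 0.62 (small μ) → 0.12 (large μ) |
| `t_tilde_large` | 0.64 | canonical time | f2 series split; chosen ≥ `t_x` so the extra rescale vanishes |
| `mu_tilde` | 1.0 | canonical drift | f1/f2 selection; the envelopes' efficiencies cross near 1 |
| `max_reject`, `max_terms` | 10⁴, 10⁶ | — | guards that only trip on broken domination |

All thresholds affect speed only; the sampled law is invariant to them
(tested by two-sample KS across threshold settings). `wfpt tune` re-runs the
timing protocol (trimmed means over repetitions, monotonic clock) to
recalibrate them on new hardware; its output is advisory.

## Validation oracles

The oracle layer never reuses the sampler's recursions. `density` sums the
series directly with adaptive truncation; `cdf_oracle` integrates it by
adaptive quadrature; `mean_analytic` is `tanh(μ)/μ`. For KS tests at scale,
`cdf_series` evaluates the CDF through term-wise analytic integrals — the
survival series `Σ(−1)^k(2k+1)(π/2)cosh(μ)e^{−r_k t}/r_k`
(`r_k = μ²/2+(2k+1)²π²/8`) for `t ≥ 0.15`, and for smaller `t` the images
series integrated into single-boundary Gaussian hitting CDFs, stabilized
with `erfcx` — and the tests pin it to the quadrature oracle at 10⁻⁸.
One-sample KS uses the asymptotic α = 0.01 critical value `1.628/√n`.

The Euler–Maruyama baseline steps `x ← x + μ̂Δ + √(σ²Δ)·η` until `|x| ≥ θ`,
in the caller's units (so it independently checks the exact sampler's
rescaling algebra). It is block-vectorized: each trajectory consumes one
Gaussian per step in order, but blocks of steps are generated and scanned at
once; within a block positions accumulate in single precision (re-anchored
in double at block ends), a ~10⁻⁷ positional error that is negligible
against the O(√Δ) discretization bias the baseline exists to exhibit.

## Asymmetric boundaries

For boundaries `+θ_up/−θ_lo` the long-time series loses the alternating
bound property, so the symmetric sampler is used as a stage primitive: at
each stage the largest symmetric model centered on the current location is
inscribed (half-width = distance to the nearer boundary, no shrink factor),
one symmetric pair is drawn, and the walk jumps to the hit inner boundary;
it returns when that boundary is shared with the asymmetric model. Each
stage is exact, so the composition is exact; the expected stage count is
small (the shared boundary is hit with probability ≥ the symmetric hitting
probability at each stage). Validated against zero-drift martingale
identities (`P(upper) = θ_lo/(θ_up+θ_lo)`, `E[T] = θ_up·θ_lo`) and against
Euler–Maruyama with and without drift.

## Problem sizes and numerical choices

Moment checks use 10⁶ exact draws (zero-drift mean tolerance
`3·√(2/3)/1000 ≈ 0.0024`); distributional checks use 10⁵ exact draws against
the CDF oracle at α = 0.01. Euler–Maruyama comparison runs are sized for
desk time on one core: 2×10⁴ trajectories at Δ = 10⁻⁵ for the near-continuum
cross-validation (two-sample KS critical values account for the unequal
sample sizes), 5×10⁴ per cell for the bias table over
Δ ∈ {10⁻⁴, 10⁻³, 10⁻², 5×10⁻²}, and 3–5×10⁴ at Δ = 10⁻⁴ for the asymmetric
comparison. At these resolutions the Δ = 10⁻⁵ bias (~0.4% in the mean) is
invisible to KS, while Δ = 0.05 fails decisively — the intended
demonstration of both exactness and bias.

Degenerate and edge inputs: `t ≤ 0` and invalid parameters raise
`ValueError`; exhausted iteration guards raise `ArithmeticError` (they
indicate a broken envelope, not a user error). Ties in the accept
comparison (`r` exactly on a partial sum) resolve conservatively
(reject on even, accept on odd) and occur with probability zero. The
cumulative-inverse branch join is exact at `P = F_split` by construction.

## Limitations

- Symmetric-boundary core: starting-point bias requires the staged
  asymmetric extension, which is sequential (Python-loop) and slower.
- Constant drift, boundaries and variance within a trial; across-trial
  variability is layered by the caller (draw parameters, then sample).
- No leaky/Ornstein–Uhlenbeck accumulation.
- Timing comparisons (the benchmark and tuning harnesses) are
  hardware-dependent and deliberately excluded from assertions.
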