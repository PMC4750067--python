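"""Proposal envelopes: constants, inversion, domination, sampling laws."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, special, stats

from wfpt.proposals import (
    crossing_time,
    f1_build,
    f1_cdf,
    f1_invcdf,
    f1_log_envelope,
    f1_sample,
    f2_build,
    f2_log_envelope,
    f2_sample,
    invgauss_sample,
)
from wfpt.series import log_bound_long, log_bound_short, validity_window

KS_CRIT_1E5 = 1.63 / math.sqrt(1e5)  # alpha = 0.01


class TestF1Build:
    def test_zero_drift_degenerates(self):
        c = f1_build(0.0, 0.62)
        assert c.a == pytest.approx(1.0, rel=1e-14)
        assert c.t_mode == pytest.approx(1.0 / 3.0, rel=1e-14)
        assert c.C_l == pytest.approx(4.0 / math.pi, rel=1e-14)

    def test_unit_drift_constants(self):
        c = f1_build(1.0, 0.5)
        assert c.t_mode == pytest.approx(2.0 / (3.0 + math.sqrt(13.0)), rel=1e-14)
        assert c.a == pytest.approx((3.0 + math.sqrt(13.0)) / 6.0, rel=1e-14)
        assert c.a == pytest.approx(1.100925, abs=1e-6)
        # tangency identity 1/a = 1 - mu^2 t_mode^2
        assert 1.0 / c.a == pytest.approx(1.0 - c.t_mode**2, rel=1e-12)

    def test_mode_solves_quadratic(self):
        for mu in (0.0, 0.7, 2.5):
            c = f1_build(mu, 0.4)
            assert mu**2 * c.t_mode**2 + 3 * c.t_mode - 1 == pytest.approx(0, abs=1e-14)

    def test_invariants(self):
        for mu in (0.0, 0.5, 1.5):
            c = f1_build(mu, 0.45)
            assert c.a >= 1.0 and 0.0 < c.t_mode <= 1.0 / 3.0
            assert 0.0 < c.F_split < c.F_tot

    def test_threshold_outside_window_rejected(self):
        with pytest.raises(ValueError):
            f1_build(0.5, 0.05)
        with pytest.raises(ValueError):
            f1_build(0.5, 4.0)


class TestF1Cdf:
    def test_total_mass_and_continuity(self):
        c = f1_build(0.8, 0.5)
        assert f1_cdf(1e9, c) == pytest.approx(c.F_tot, rel=1e-12)
        eps = 1e-12
        assert f1_cdf(c.t_tilde - eps, c) == pytest.approx(
            f1_cdf(c.t_tilde + eps, c), rel=1e-9
        )
        assert f1_cdf(c.t_tilde, c) == pytest.approx(c.F_split, rel=1e-12)

    def test_nondecreasing(self):
        c = f1_build(1.2, 0.3)
        t = np.geomspace(1e-3, 50, 500)
        assert np.all(np.diff(f1_cdf(t, c)) >= 0)

    def test_erfc_value_zero_drift(self):
        c = f1_build(0.0, 0.62)
        assert f1_cdf(1.0 / 3.0, c) / c.C_s == pytest.approx(0.083265, abs=1e-6)

    def test_matches_numeric_integral_of_envelope(self):
        from scipy import integrate

        c = f1_build(0.6, 0.5)
        for t in (0.1, 0.5, 2.0):
            val, _ = integrate.quad(
                lambda s: math.exp(f1_log_envelope(s, c)), 0, t, limit=200
            )
            assert f1_cdf(t, c) == pytest.approx(val, rel=1e-8)


class TestF1InvCdf:
    def test_join_point(self):
        c = f1_build(0.9, 0.44)
        assert f1_invcdf(c.F_split, c) == pytest.approx(c.t_tilde, rel=1e-9)

    def test_roundtrip(self):
        rng = np.random.default_rng(3)
        c = f1_build(0.4, 0.55)
        P = rng.uniform(1e-12, c.F_tot * (1 - 1e-12), 1000)
        back = f1_cdf(f1_invcdf(P, c), c)
        assert np.max(np.abs(back - P)) < 1e-9 * c.F_tot

    def test_inverts_erfc_example(self):
        c = f1_build(0.0, 0.62)
        P = c.C_s * special.erfc(math.sqrt(1.5))
        assert f1_invcdf(P, c) == pytest.approx(1.0 / 3.0, rel=1e-12)

    def test_domain_errors(self):
        c = f1_build(0.0, 0.62)
        with pytest.raises(ValueError):
            f1_invcdf(0.0, c)
        with pytest.raises(ValueError):
            f1_invcdf(c.F_tot, c)

    @given(
        mu=st.floats(min_value=0.0, max_value=3.0),
        t_tilde=st.floats(min_value=0.15, max_value=1.5),
        frac=st.floats(min_value=1e-9, max_value=1.0 - 1e-9),
    )
    def test_roundtrip_property(self, mu, t_tilde, frac):
        c = f1_build(mu, t_tilde)
        P = frac * c.F_tot
        assert f1_cdf(f1_invcdf(P, c), c) == pytest.approx(P, abs=1e-9 * c.F_tot)


class TestF1Sample:
    def test_reproducible(self):
        c = f1_build(0.3, 0.55)
        t1, e1 = f1_sample(c, np.random.default_rng(9), 100)
        t2, e2 = f1_sample(c, np.random.default_rng(9), 100)
        assert np.array_equal(t1, t2) and np.array_equal(e1, e2)

    def test_distribution_matches_cdf(self, rng):
        c = f1_build(0.5, 0.5)
        t, _ = f1_sample(c, rng, 100_000)
        stat = stats.kstest(t, lambda x: f1_cdf(x, c) / c.F_tot).statistic
        assert stat < KS_CRIT_1E5

    def test_mass_split(self, rng):
        c = f1_build(0.5, 0.5)
        t, _ = f1_sample(c, rng, 100_000)
        p = c.F_split / c.F_tot
        se = math.sqrt(p * (1 - p) / 1e5)
        assert np.mean(t <= c.t_tilde) == pytest.approx(p, abs=3 * se)


class TestF2:
    def test_base_scale(self):
        c = f2_build(1.0, 0.64)
        assert c.C_f == pytest.approx(1.0 + math.exp(-2.0), rel=1e-14)
        assert c.extra == 1.0

    def test_crossing_time_matches_independent_bisection(self):
        def diff(t):
            return (2 * math.pi * t**3) ** -0.5 * math.exp(-1 / (2 * t)) - (
                math.pi / 4
            ) * math.exp(-math.pi**2 * t / 8)

        t_x = optimize.bisect(diff, 0.2, 2.0, xtol=1e-12)
        assert crossing_time() == pytest.approx(t_x, abs=1e-9)
        assert 0.62 < t_x < 0.65

    def test_extra_rescale_below_crossing(self):
        c = f2_build(2.0, 0.3)
        assert c.extra > 1.0
        # with the inflation, the envelope dominates the long bound on [t~, t_x]
        t = np.linspace(0.3, crossing_time(), 500)
        assert np.all(f2_log_envelope(t, c) >= log_bound_long(t, 2.0) - 1e-12)

    def test_requires_positive_drift(self):
        with pytest.raises(ValueError):
            f2_build(0.0, 0.64)
        with pytest.raises(ValueError):
            f2_build(-1.0, 0.64)

    def test_inverse_gaussian_moments(self, rng):
        x = invgauss_sample(0.5, 1.0, rng, 1_000_000)
        se = math.sqrt(0.5**3 / 1.0) / 1e3
        assert x.mean() == pytest.approx(0.5, abs=3 * se)

    def test_inverse_gaussian_distribution(self, rng):
        # independent oracle: scipy's inverse-Gaussian CDF
        mean, shape = 1.0 / 2.0, 1.0
        x = invgauss_sample(mean, shape, rng, 100_000)
        stat = stats.kstest(x, stats.invgauss(mu=mean / shape, scale=shape).cdf).statistic
        assert stat < KS_CRIT_1E5

    def test_f2_sample_reproducible(self):
        c = f2_build(2.0, 0.64)
        t1, e1 = f2_sample(c, np.random.default_rng(4), 50)
        t2, e2 = f2_sample(c, np.random.default_rng(4), 50)
        assert np.array_equal(t1, t2) and np.array_equal(e1, e2)


class TestEnvelopeDomination:
    t_grid = np.geomspace(1e-3, 30.0, 1000)

    @pytest.mark.parametrize("mu", [0.0, 0.3, 1.0])
    def test_f1_dominates_series_bounds(self, mu):
        c = f1_build(mu, 0.5)
        env = f1_log_envelope(self.t_grid, c)
        short = self.t_grid <= c.t_tilde
        assert np.all(env[short] >= log_bound_short(self.t_grid[short], mu) - 1e-10)
        assert np.all(env[~short] >= log_bound_long(self.t_grid[~short], mu) - 1e-10)

    @pytest.mark.parametrize("mu", [1.0, 2.0, 5.0])
    def test_f2_dominates_series_bounds(self, mu):
        c = f2_build(mu, 0.64)
        env = f2_log_envelope(self.t_grid, c)
        short = self.t_grid <= c.t_tilde
        assert np.all(env[short] >= log_bound_short(self.t_grid[short], mu) - 1e-10)
        assert np.all(env[~short] >= log_bound_long(self.t_grid[~short], mu) - 1e-10)

    @pytest.mark.parametrize("mu", [0.0, 0.4, 1.3])
    def test_f1_tangency_at_mode(self, mu):
        c = f1_build(mu, 0.5)
        # ratio envelope/bound attains its minimum 1 exactly at t_mode
        assert f1_log_envelope(c.t_mode, c) == pytest.approx(
            float(log_bound_short(c.t_mode, mu)), abs=1e-6
        )
        t = np.geomspace(1e-3, c.t_tilde, 400)
        ratios = f1_log_envelope(t, c) - log_bound_short(t, mu)
        assert np.all(ratios >= -1e-10)

    def test_acceptance_efficiency(self):
        # regression guard: target mass (=1) over envelope mass >= 0.5
        for mu in (0.0, 0.3, 0.99):
            assert 1.0 / f1_build(mu, 0.5).F_tot >= 0.5
        for mu in (1.0, 2.0, 5.0):
            assert 1.0 / f2_build(mu, 0.64).C_f >= 0.5
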