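"""Unit and property tests of the latent grid and log-likelihood kernels."""

import mpmath as mp
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bimod.kernels import (TAIL_SWITCH, log_diff_exp, log_norm_cdf,
                           loglik_grad, loglik_improved, loglik_naive,
                           loglik_oracle, make_grid, pmf, tail_bounds)

# 60-digit reference values (normal quantile / log-tail probabilities)
Q_25 = -0.6744897501960817432
LOG_TAIL = {1: -1.8410216450092635058, 2: -3.7831843336820319488,
            4: -10.360101486527290828, 6: -20.736768949974705655,
            10: -53.231285150512470578}
LOG_PHI_M20 = -203.9171553710972639368
LOG_PHI_M300 = -45006.62273211866335985

# eta grid of the small-sigma stress regime (observed score 10 on 0..60)
STRESS_ETA = np.arange(-4.0, 4.001, 0.5)


def mp_log_phi(z, dps=60):
    with mp.workdps(dps):
        return float(mp.log(mp.ncdf(z)))


class TestGrid:
    def test_endpoints_and_median(self):
        g = make_grid(1)
        assert np.isneginf(g.cutpoints[0]) and np.isposinf(g.cutpoints[-1])
        assert g.cutpoints[1] == pytest.approx(0.0, abs=1e-15)

    def test_quartile_cutpoint(self):
        g = make_grid(3)
        assert g.cutpoints[1] == pytest.approx(Q_25, abs=1e-12)
        assert g.cutpoints[2] == pytest.approx(0.0, abs=1e-15)

    @given(S=st.integers(min_value=1, max_value=120))
    @settings(deadline=None, max_examples=25)
    def test_antisymmetric_and_increasing(self, S):
        g = make_grid(S)
        q = g.cutpoints
        assert len(q) == S + 2
        assert np.all(np.diff(q[1:-1]) > 0)
        np.testing.assert_allclose(q[1:-1], -q[1:-1][::-1], atol=1e-12)

    @pytest.mark.parametrize("bad", [0, -3, 1.5, True])
    def test_invalid_max_score(self, bad):
        with pytest.raises((ValueError, TypeError)):
            make_grid(bad)


class TestLogNormCdf:
    def test_special_points(self):
        assert log_norm_cdf(0.0) == pytest.approx(np.log(0.5), abs=1e-15)
        assert log_norm_cdf(np.inf) == 0.0
        assert np.isneginf(log_norm_cdf(-np.inf))

    def test_deep_tail_accuracy(self):
        # the asymptotic tail formula's log-scale error decays like
        # 0.18/(z^2/2)^2 relative: a few 1e-6 at z=-20, ~1e-10 at z=-300
        v20 = log_norm_cdf(-20.0)
        assert abs(v20 - LOG_PHI_M20) / abs(LOG_PHI_M20) < 1e-5
        v300 = log_norm_cdf(-300.0)
        assert np.isfinite(v300)
        assert abs(v300 - LOG_PHI_M300) / abs(LOG_PHI_M300) < 1e-6

    def test_moderate_range_matches_reference(self):
        for z in np.linspace(-6, 6, 25):
            assert log_norm_cdf(z) == pytest.approx(mp_log_phi(z), rel=1e-12, abs=1e-12)

    def test_monotone_including_branch_switch(self):
        # the hard switch at z = -6 introduces a documented ~8.8e-3 jump
        # (the tail formula overestimates); elsewhere the curve is monotone
        z = np.concatenate([np.arange(-400, -6.5, 0.05),
                            np.arange(-6.5, 6.5, 0.01),
                            np.arange(6.5, 400, 0.5)])
        v = log_norm_cdf(z)
        d = np.diff(v)
        switch = (z[:-1] < -5.9) & (z[:-1] > -6.2)
        assert np.all(d[~switch] >= 0)
        assert np.all(d >= -1e-2)

    def test_extreme_overflow_guard(self):
        assert np.isneginf(log_norm_cdf(-1e200))
        assert log_norm_cdf(1e200) == 0.0


class TestTailBounds:
    @pytest.mark.parametrize("z", [1, 2, 4, 6, 10])
    def test_sandwich(self, z):
        lower, upper = tail_bounds(float(z))
        assert lower < LOG_TAIL[z] <= upper

    def test_gap_positive_and_small_at_six(self):
        z = np.array([0.5, 1.0, 2.0, 6.0])
        lower, upper = tail_bounds(z)
        assert np.all(upper - lower > 0)
        gap6 = (upper - lower)[-1]
        assert gap6 < 0.01

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            tail_bounds(0.0)
        with pytest.raises(ValueError):
            tail_bounds(np.array([1.0, -2.0]))


class TestLogDiffExp:
    def test_exact_small_numbers(self):
        assert log_diff_exp(np.log(0.75), np.log(0.25)) == pytest.approx(np.log(0.5), abs=1e-15)
        assert log_diff_exp(-1.3, -np.inf) == -1.3
        assert np.isneginf(log_diff_exp(-2.0, -2.0))
        assert np.isneginf(log_diff_exp(-np.inf, -np.inf))

    def test_contract_violation(self):
        with pytest.raises(ValueError):
            log_diff_exp(-2.0, -1.0)

    def test_against_direct_arithmetic(self, rng):
        la = rng.uniform(-700, 0, size=1000)
        lb = la - rng.uniform(0.0, 50.0, size=1000)
        la, lb = np.maximum(la, lb), np.minimum(la, lb)
        got = log_diff_exp(la, lb)
        a, b = np.exp(la), np.exp(lb)
        representable = (a - b) > 5e-324 * 1e3
        direct = np.log(a[representable] - b[representable])
        np.testing.assert_allclose(got[representable], direct, atol=1e-12, rtol=1e-12)


class TestKernels:
    def test_halves_for_binary_score(self):
        g = make_grid(1)
        for fn in (loglik_naive, loglik_improved):
            assert fn(0, g, 0.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-12)

    def test_naive_underflow_is_not_masked(self, grid60):
        assert not np.isfinite(loglik_naive(10, grid60, 4.0, 0.01))

    def test_naive_matches_oracle_in_benign_regime(self, grid60):
        got = loglik_naive(10, grid60, 0.0, 1.0)
        ref = loglik_oracle(10, grid60, 0.0, 1.0)
        assert got == pytest.approx(ref, rel=1e-10)

    def test_improved_finite_and_accurate_where_naive_dies(self, grid60):
        got = loglik_improved(10, grid60, 4.0, 0.01)
        assert np.isfinite(got)
        ref = loglik_oracle(10, grid60, 4.0, 0.01)
        assert got == pytest.approx(ref, rel=1e-6)

    @pytest.mark.parametrize("eta", STRESS_ETA)
    def test_improved_oracle_equivalence_stress(self, grid60, eta):
        got = loglik_improved(10, grid60, eta, 0.01)
        ref = loglik_oracle(10, grid60, eta, 0.01)
        assert np.isfinite(got)
        assert got == pytest.approx(ref, rel=1e-6)

    def test_breakdown_regime(self, grid60):
        naive = loglik_naive(10, grid60, STRESS_ETA, 0.01)
        improved = loglik_improved(10, grid60, STRESS_ETA, 0.01)
        assert np.any(~np.isfinite(naive))
        assert np.all(np.isfinite(improved))

    def test_agreement_regime(self, grid60, rng):
        # wherever both CDF values are comfortably inside (0, 1) -- i.e.
        # every |z| stays below the z = 6 branch switch -- the two kernels
        # agree to high absolute accuracy
        from scipy.special import ndtr
        eta = rng.uniform(-4, 4, 300)
        sigma = rng.uniform(0.5, 2.0, 300)
        scores = rng.integers(0, 61, 300)
        z_lo = (grid60.lower(scores) - eta) / sigma
        z_hi = (grid60.upper(scores) - eta) / sigma
        inside = ((ndtr(z_lo) > 1e-8) & (ndtr(z_lo) < 1 - 1e-8)
                  & (ndtr(z_hi) > 1e-8) & (ndtr(z_hi) < 1 - 1e-8))
        naive = loglik_naive(scores[inside], grid60, eta[inside], sigma[inside])
        improved = loglik_improved(scores[inside], grid60, eta[inside], sigma[inside])
        assert inside.sum() > 50
        np.testing.assert_allclose(improved, naive, atol=1e-9)

    def test_reflection_symmetry(self, grid60, rng):
        s = rng.integers(0, 61, 50)
        eta = rng.uniform(-3, 3, 50)
        sigma = rng.uniform(0.01, 2.0, 50)
        left = loglik_improved(s, grid60, eta, sigma)
        right = loglik_improved(60 - s, grid60, -eta, sigma)
        np.testing.assert_allclose(left, right, rtol=1e-12, atol=1e-12)

    def test_validation(self, grid60):
        with pytest.raises(ValueError):
            loglik_improved(61, grid60, 0.0, 1.0)
        with pytest.raises(ValueError):
            loglik_improved(5, grid60, 0.0, -1.0)

    @pytest.mark.parametrize("s,eta,sig,tol", [
        (10, 0.3, 1.0, 2e-4), (0, -1.0, 0.5, 2e-4), (60, 2.0, 0.3, 2e-4),
        # near the z = 6 switch the analytic gradient (exact mathematics)
        # and the FD slope of the approximated surface differ by up to ~1%
        (10, -1.04, 0.01, 2e-2),
    ])
    def test_grad_matches_finite_differences(self, grid60, s, eta, sig, tol):
        h = 1e-6
        de, ds = loglik_grad(s, grid60, eta, sig)
        fd_e = (loglik_improved(s, grid60, eta + h, sig)
                - loglik_improved(s, grid60, eta - h, sig)) / (2 * h)
        fd_s = (loglik_improved(s, grid60, eta, sig + h * sig)
                - loglik_improved(s, grid60, eta, sig - h * sig)) / (2 * h * sig)
        assert de == pytest.approx(fd_e, rel=tol, abs=1e-6)
        assert ds == pytest.approx(fd_s, rel=tol, abs=1e-6)


class TestOracle:
    def test_binary_exact(self):
        g = make_grid(1)
        assert loglik_oracle(0, g, 0.0, 1.0) == pytest.approx(np.log(0.5), abs=1e-15)

    def test_precision_saturation(self, grid60):
        a = loglik_oracle(10, grid60, 1.5, 0.05, digits=30)
        b = loglik_oracle(10, grid60, 1.5, 0.05, digits=60)
        assert a == pytest.approx(b, abs=1e-12)

    def test_requires_enough_digits(self, grid60):
        with pytest.raises(ValueError):
            loglik_oracle(10, grid60, 0.0, 1.0, digits=10)


class TestPmf:
    def test_binary_and_wide_sigma_limits(self):
        np.testing.assert_allclose(pmf(make_grid(1), 0.0, 1.0), [0.5, 0.5], atol=1e-12)
        # as sigma -> infinity the interior z-scores collapse to 0, so all
        # mass drains to the two boundary categories (each half)
        np.testing.assert_allclose(pmf(make_grid(3), 0.0, 1e6),
                                   [0.5, 0.0, 0.0, 0.5], atol=1e-5)

    @pytest.mark.parametrize("S,eta,sigma", [
        (1, 0.0, 1.0), (3, 2.0, 0.5), (60, 0.0, 1.0), (60, -4.0, 0.01),
        (100, 10.0, 1e-3), (100, -10.0, 1e3), (70, 3.0, 0.1),
    ])
    def test_normalization(self, S, eta, sigma):
        p = pmf(make_grid(S), eta, sigma)
        assert np.all(p >= 0)
        assert p.sum() == pytest.approx(1.0, abs=1e-9)

    def test_boundary_masses_are_pure_tails(self, grid60):
        p = pmf(grid60, 0.0, 1.0)
        from scipy.special import ndtr
        assert p[0] == pytest.approx(ndtr(grid60.cutpoints[1]), rel=1e-12)
        assert p[-1] == pytest.approx(1 - ndtr(grid60.cutpoints[-2]), rel=1e-12)
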