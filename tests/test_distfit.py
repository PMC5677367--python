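"""Truncated power-law MLE, likelihood tests, bootstrap machinery."""

import numpy as np
import pytest
from scipy import optimize, stats

from avapipe import distfit


@pytest.fixture(scope="module")
def pl_sample():
    """1e5 draws from p(s) ∝ s^-1.5 exp[-(s/100)^2] on [1, 300]."""
    rng = np.random.default_rng(77)
    return distfit.sample_truncated_powerlaw(100_000, 1.5, 100.0, 2.0, 1, 300, rng)


class TestPowerLawFit:
    def test_parameter_recovery_at_1e5(self, pl_sample):
        fit = distfit.fit_truncated_powerlaw(pl_sample, s_max=300)
        assert fit.alpha == pytest.approx(1.5, abs=0.05)
        assert fit.s0 == pytest.approx(100.0, rel=0.15)
        assert fit.converged

    def test_normalization_constant(self, pl_sample):
        fit = distfit.fit_truncated_powerlaw(pl_sample, s_max=300)
        support = np.arange(fit.s_min, fit.s_max + 1)
        total = fit.C * np.sum(
            support ** (-fit.alpha) * np.exp(-((support / fit.s0) ** fit.gamma))
        )
        assert total == pytest.approx(1.0, abs=1e-10)
        assert fit.pmf(support).sum() == pytest.approx(1.0, abs=1e-10)

    def test_bias_shrinks_with_sample_size(self):
        rng = np.random.default_rng(5)
        errs = []
        for n in (1000, 10_000, 100_000):
            reps = [
                abs(
                    distfit.fit_truncated_powerlaw(
                        distfit.sample_truncated_powerlaw(n, 1.5, 80.0, 2.0, 1, 300, rng),
                        s_max=300,
                    ).alpha
                    - 1.5
                )
                for _ in range(3)
            ]
            errs.append(np.mean(reps))
        assert errs[2] < 0.05
        assert errs[2] <= errs[0] + 0.01

    def test_matches_closed_form_pure_powerlaw_mle(self):
        """On pure power-law data the 3-parameter fit agrees with the 1-parameter MLE."""
        rng = np.random.default_rng(9)
        support = np.arange(1, 201)
        p = support ** -1.5
        sample = rng.choice(support, size=50_000, p=p / p.sum())

        def neg_ll(alpha):
            w = support ** -alpha
            return alpha * np.log(sample).sum() + sample.size * np.log(w.sum())

        ref = optimize.minimize_scalar(neg_ll, bounds=(0.5, 3.0), method="bounded").x
        fit = distfit.fit_truncated_powerlaw(sample, s_max=200)
        assert fit.alpha == pytest.approx(ref, abs=0.03)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            distfit.fit_truncated_powerlaw(np.full(100, 7))

    def test_mle_dominates_other_parameterizations(self, pl_sample):
        fit = distfit.fit_truncated_powerlaw(pl_sample, s_max=300)
        for alpha in (1.2, 1.5, 1.8):
            for s0 in (50.0, 100.0, 200.0):
                other = distfit.PowerLawFit(
                    alpha=alpha, s0=s0, gamma=2.0, logL=0.0, s_min=1, s_max=300, C=1.0
                )
                assert fit.logL >= other.loglik_of(pl_sample) - 1e-6


class TestExponentialFit:
    def test_lambda_recovery(self):
        rng = np.random.default_rng(4)
        support = np.arange(1, 101)
        lam = 0.2
        p = np.exp(-lam * support)
        sample = rng.choice(support, size=50_000, p=p / p.sum())
        fit = distfit.fit_exponential(sample, s_max=100)
        assert fit.lam == pytest.approx(lam, abs=0.01)

    def test_powerlaw_sample_prefers_powerlaw(self, pl_sample):
        pl = distfit.fit_truncated_powerlaw(pl_sample, s_max=300)
        ex = distfit.fit_exponential(pl_sample, s_max=300)
        assert pl.logL > ex.logL

    def test_single_value_degenerate(self):
        with pytest.raises(ValueError):
            distfit.fit_exponential(np.array([3]))


class TestLikelihoodTest:
    def test_equal_likelihoods_give_p_one(self):
        lt = distfit.likelihood_test(-100.0, -100.0, df=2)
        assert lt.D == 0.0
        assert lt.p == pytest.approx(1.0)
        assert lt.favored == "tie"

    def test_directionality(self):
        better_pl = distfit.likelihood_test(-100.0, -150.0, df=2)
        assert better_pl.p < 1e-5 and better_pl.favored == "power_law"
        better_alt = distfit.likelihood_test(-150.0, -100.0, df=2)
        assert 1.0 - better_alt.p < 1e-5 and better_alt.favored == "alternative"

    def test_critical_sizes_favor_powerlaw_massively(self, critical_sizes):
        pl = distfit.fit_truncated_powerlaw(critical_sizes)
        ex = distfit.fit_exponential(critical_sizes, s_max=pl.s_max)
        lt = distfit.likelihood_test(pl.logL, ex.logL, df=2)
        assert lt.p < 1e-5


class TestBootstrap:
    def test_ci_width_shrinks_with_n(self, rng):
        support = np.arange(1, 51)
        p = support ** -1.5
        p /= p.sum()
        widths = []
        for n in (2000, 8000):
            s = rng.choice(support, size=n, p=p)
            d = distfit.bootstrap_ci(s, B=300, rng=rng)
            widths.append(np.nanmean(d.ci_high - d.ci_low))
        assert widths[1] < widths[0]
        assert widths[1] == pytest.approx(widths[0] / 2, rel=0.35)  # ~1/sqrt(4)

    def test_point_mass_collapses(self, rng):
        s = np.full(500, 4)
        d = distfit.bootstrap_ci(s, B=200, rng=rng)
        assert d.ci_low[0] == d.ci_high[0] == 1.0

    def test_coverage_near_95_percent(self, rng):
        support = np.arange(1, 41)
        p_true = support ** -1.5 * np.exp(-((support / 20) ** 2))
        p_true /= p_true.sum()
        s = rng.choice(support, size=5000, p=p_true)
        d = distfit.bootstrap_ci(s, B=500, rng=rng)
        lo = np.minimum(d.ci_low, d.ci_high)
        hi = np.maximum(d.ci_low, d.ci_high)
        truth = p_true[np.searchsorted(support, d.support)]
        m = d.density > 0
        covered = ((truth[m] >= lo[m] - 1e-12) & (truth[m] <= hi[m] + 1e-12)).mean()
        assert covered >= 0.85


class TestNormalizedCurve:
    def test_flat_for_matching_exponent(self, rng):
        support = np.arange(1, 101)
        p = support ** -1.5
        s = rng.choice(support, size=200_000, p=p / p.sum())
        d = distfit.size_distribution(s)
        res = distfit.normalized_curve_and_auc(d, alpha_ref=1.5, s_threshold=20)
        c = res["curve"][(d.support > 20) & (d.density > 0)]
        assert c.std() / c.mean() < 0.25  # flat up to sampling noise

    def test_area_scales_with_support_on_flat_curve(self):
        support = np.arange(1, 201)
        density = support ** -1.5  # exactly reference slope -> flat curve
        density /= density.sum()
        d = distfit.SizeDistribution(support=support, density=density, n=10_000)
        a20 = distfit.normalized_curve_and_auc(d, 1.5, s_threshold=20)["area"]
        a110 = distfit.normalized_curve_and_auc(d, 1.5, s_threshold=110)["area"]
        assert a110 == pytest.approx(a20 / 2, rel=0.05)  # half the support length

    def test_empty_tail_errors(self):
        d = distfit.size_distribution(np.array([1, 2, 3, 2, 1]))
        with pytest.raises(ValueError):
            distfit.normalized_curve_and_auc(d, 1.5, s_threshold=20)


class TestCompareToReference:
    def test_self_consistent_sample_not_rejected(self, rng):
        fit_a = distfit.PowerLawFit(
            alpha=1.5, s0=80.0, gamma=2.0, logL=0.0, s_min=1, s_max=300, C=1.0
        )
        sizes_b = distfit.sample_truncated_powerlaw(20_000, 1.5, 80.0, 2.0, 1, 300, rng)
        res = distfit.compare_to_reference(sizes_b, fit_a)
        assert res.p < 0.95  # similarity not rejected

    def test_shifted_exponent_rejected(self, rng):
        fit_a = distfit.fit_truncated_powerlaw(
            distfit.sample_truncated_powerlaw(20_000, 1.5, 80.0, 2.0, 1, 300, rng), s_max=300
        )
        sizes_b = distfit.sample_truncated_powerlaw(10_000, 2.0, 80.0, 2.0, 1, 300, rng)
        res = distfit.compare_to_reference(sizes_b, fit_a)
        assert res.p > 0.999  # reference fit cannot explain B
        assert res.favored == "different"

    def test_statistic_nonnegative_by_mle_optimality(self, rng):
        s = distfit.sample_truncated_powerlaw(5000, 1.4, 60.0, 2.0, 1, 200, rng)
        fit_a = distfit.PowerLawFit(
            alpha=1.4, s0=60.0, gamma=2.0, logL=0.0, s_min=1, s_max=200, C=1.0
        )
        res = distfit.compare_to_reference(s, fit_a)
        assert -res.D >= 0.0

    def test_support_outside_reference_errors(self, rng):
        fit_a = distfit.PowerLawFit(
            alpha=1.5, s0=50.0, gamma=2.0, logL=0.0, s_min=1, s_max=50, C=1.0
        )
        with pytest.raises(ValueError):
            distfit.compare_to_reference(np.array([1, 2, 60]), fit_a)
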