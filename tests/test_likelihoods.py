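"""Likelihood algebra: conditioning schemes, nesting, symmetry, mass extinction."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

from bdphylo import likelihoods as lk, models as m, simulate as sm, transitions as tr


def _random_ltt(rng, n=6, t0=5.0, lam=0.6):
    return sm.sample_yule_order_stats(n, t0, lam, seed=rng)


class TestYuleJoint:
    def test_single_lineage(self):
        d = m.LTTData([], stem_age=4.0)
        assert lk.yule_joint_loglik(d, 0.7).value == pytest.approx(-2.8)

    def test_hand_computed_product(self, small_ltt):
        # term-by-term: log 2! + 2 log lam - lam (t0 + t1 + t2)
        expected = math.log(2) + 2 * math.log(0.5) - 0.5 * (3 + 2 + 1)
        assert lk.yule_joint_loglik(small_ltt, 0.5).value == pytest.approx(expected)

    def test_zero_rate_with_speciations_impossible(self, small_ltt):
        assert lk.yule_joint_loglik(small_ltt, 0.0).value == -math.inf

    def test_stem_age_required(self):
        with pytest.raises(m.ModelError):
            lk.yule_joint_loglik(m.LTTData([2.0, 1.0]), 0.5)


class TestTipCountLaws:
    def test_stem_law_equals_transition_law(self):
        for n, t0, lam in [(1, 2.0, 0.3), (4, 1.5, 0.8), (12, 3.0, 0.4)]:
            assert lk.yule_prob_n_given_stem(n, t0, lam) == pytest.approx(
                tr.yule_pn(n, t0, lam), rel=1e-12
            )

    def test_stem_law_monte_carlo(self):
        """Forward-simulated tip-count frequency matches the geometric law."""
        lam, t0, n, reps = 1.0, 1.0, 3, 20_000
        mod = m.make_constant_model(lam, 0.0, 1.0)
        rng = np.random.default_rng(7)
        hits = sum(
            sm.simulate_forward(mod, t0=t0, seed=rng).n_sampled == n
            for _ in range(reps)
        )
        p = lk.yule_prob_n_given_stem(n, t0, lam)
        se = math.sqrt(p * (1 - p) / reps)
        assert abs(hits / reps - p) < 3 * se

    def test_root_law_equals_convolution(self):
        for n in (2, 3, 7, 25, 50):
            closed = lk.yule_prob_n_given_root(n, 1.3, 0.7)
            brute = lk.yule_prob_n_given_root_convolution(n, 1.3, 0.7)
            assert closed == pytest.approx(brute, rel=1e-10)

    def test_root_law_two_tips(self):
        assert lk.yule_prob_n_given_root(2, 2.0, 0.6) == pytest.approx(
            math.exp(-2 * 0.6 * 2.0), rel=1e-12
        )

    def test_root_law_normalizes_over_n(self):
        total = sum(lk.yule_prob_n_given_root(n, 1.0, 0.8) for n in range(2, 4000))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_root_law_requires_two_tips(self):
        with pytest.raises(ValueError):
            lk.yule_prob_n_given_root(1, 1.0, 1.0)


class TestStemConditioned:
    def test_two_routes_agree(self, rng):
        for _ in range(25):
            d = _random_ltt(rng, n=int(rng.integers(2, 15)))
            lam = float(rng.uniform(0.05, 2.0))
            a = lk.yule_loglik_given_stem(d, lam, route="conditioned").value
            b = lk.yule_loglik_given_stem(d, lam, route="orderstats").value
            assert abs(a - b) <= 1e-12 * max(1.0, abs(a))

    def test_equals_joint_minus_marginal(self, small_ltt):
        lam = 0.5
        expected = (
            lk.yule_joint_loglik(small_ltt, lam).value
            - lk.yule_log_prob_n_given_stem(small_ltt.n, small_ltt.stem_age, lam)
        )
        assert lk.yule_loglik_given_stem(small_ltt, lam).value == pytest.approx(expected)

    def test_kernel_density_normalizes(self):
        val, _ = quad(lambda x: math.exp(lk.truncated_exp_logpdf(x, 3.0, 0.8)), 0, 3.0)
        assert val == pytest.approx(1.0, abs=1e-10)

    @pytest.mark.parametrize("n", [3, 4, 5])
    def test_density_integrates_to_one_monte_carlo(self, n):
        """MC integral of the order-statistics form over the age cube is 1."""
        t0, lam, reps = 2.0, 0.9, 200_000
        rng = np.random.default_rng(11)
        x = rng.uniform(0.0, t0, size=(reps, n - 1))
        logf = (
            lk.truncated_exp_logpdf(x, t0, lam).sum(axis=1)
        )  # the (n-1)! and the ordering volume 1/(n-1)! cancel
        vals = np.exp(logf) * t0 ** (n - 1)
        est, se = vals.mean(), vals.std(ddof=1) / math.sqrt(reps)
        assert abs(est - 1.0) < 3 * se

    def test_orderstats_equivalence(self, rng):
        """The conditioned density is (n-1)! x i.i.d. kernel densities."""
        d = _random_ltt(rng, n=7)
        lam = 0.45
        direct = lk.yule_loglik_given_stem(d, lam).value
        kernels = lk.truncated_exp_logpdf(d.ages, d.stem_age, lam).sum()
        assert direct == pytest.approx(math.lgamma(7) + kernels, rel=1e-12)


class TestRootConditioned:
    def test_conditioning_identity(self, rng):
        """Printed form == rank-product numerator minus log Pr(n | t1)."""
        d = _random_ltt(rng, n=8)
        lam = 0.7
        n = d.n
        numer = math.lgamma(n) + (n - 1) * math.log(lam) - lam * d.ages.sum()
        expected = numer - lk.yule_log_prob_n_given_root(n, d.root_age, lam)
        assert lk.yule_loglik_given_root(d, lam).value == pytest.approx(expected)

    def test_two_tip_case(self):
        d = m.LTTData([1.5])
        # only the root-age factor survives: lam e^{+lam t1}
        assert lk.yule_loglik_given_root(d, 0.4).value == pytest.approx(
            math.log(0.4) + 0.4 * 1.5
        )

    def test_normalization_structure_monte_carlo(self):
        """Integrating the younger ages over [0, t1] leaves lam e^{lam t1}."""
        n, t1, lam, reps = 5, 1.2, 0.8, 200_000
        rng = np.random.default_rng(3)
        younger = rng.uniform(0.0, t1, size=(reps, n - 2))
        vals = np.empty(reps)
        for k in range(reps):
            ages = np.concatenate([[t1], younger[k]])
            vals[k] = math.exp(lk.yule_loglik_given_root(m.LTTData(ages), lam).value)
        vals *= t1 ** (n - 2) / math.factorial(n - 2)
        est, se = vals.mean(), vals.std(ddof=1) / math.sqrt(reps)
        assert abs(est - lam * math.exp(lam * t1)) < 3 * se

    def test_conditional_younger_ages_are_iid_kernel(self):
        """Given (n, t1), younger ages from the forward simulator follow the
        truncated-exponential kernel on [0, t1]."""
        from scipy.stats import kstest

        lam, t0, n = 1.0, 2.0, 5
        mod = m.make_constant_model(lam, 0.0, 1.0)
        datas, _ = sm.forward_conditional_on_n(mod, t0, n, size=400, seed=9)
        # transform each younger age by its replicate's kernel CDF -> U(0,1)
        u = []
        for d in datas:
            t1 = d.root_age
            u.extend(np.expm1(-lam * d.ages[1:]) / np.expm1(-lam * t1))
        assert kstest(np.asarray(u), "uniform").pvalue > 0.01


class TestGeneralizedLikelihoods:
    def test_yule_special_case(self, small_ltt):
        mod = m.make_constant_model(0.5, 0.0, 1.0)
        assert lk.gbdp_loglik(small_ltt, mod).value == pytest.approx(
            lk.yule_joint_loglik(small_ltt, 0.5).value, rel=1e-12
        )

    def test_survival_vs_joint_conditioning(self, small_ltt):
        mod = m.make_constant_model(1.0, 0.5, 1.0)
        joint = lk.gbdp_loglik(small_ltt, mod, conditioning="none").value
        cond = lk.gbdp_loglik(small_ltt, mod, conditioning="survival").value
        p0 = tr.gbdp_p0(small_ltt.stem_age, mod)
        assert cond == pytest.approx(joint - math.log1p(-p0), rel=1e-12)

    def test_zero_rate_at_observed_age(self):
        mod = m.make_piecewise_model([1.5], [0.0, 0.5], [0.0, 0.0], 1.0)
        d = m.LTTData([2.0, 1.0], stem_age=3.0)  # age 1.0 sits in the zero-rate epoch
        assert lk.gbdp_loglik(d, mod).value == -math.inf

    def test_gyp_constant_rate_equals_yule(self, small_ltt):
        assert lk.gyp_loglik(small_ltt, 0.5).value == pytest.approx(
            lk.yule_joint_loglik(small_ltt, 0.5).value, rel=1e-12
        )

    def test_gyp_single_lineage(self):
        d = m.LTTData([], stem_age=2.0)
        assert lk.gyp_loglik(d, 0.7).value == pytest.approx(-1.4)

    def test_gyp_accepts_plain_callable(self, small_ltt):
        val = lk.gyp_loglik(small_ltt, lambda t: 0.5).value
        assert val == pytest.approx(lk.yule_joint_loglik(small_ltt, 0.5).value, rel=1e-9)


class TestLabelSwitching:
    def test_conditioned_invariance(self, rng):
        for cond in ("stem", "root"):
            for _ in range(10):
                d = _random_ltt(rng, n=int(rng.integers(3, 10)))
                lam, mu = float(rng.uniform(0.2, 1.5)), float(rng.uniform(0.05, 1.5))
                assert lk.label_switch_check(d, lam, mu, cond) <= 1e-10

    def test_symmetric_point_exactly_zero(self, small_ltt):
        assert lk.label_switch_check(small_ltt, 0.8, 0.8, "stem") == 0.0

    def test_joint_likelihood_is_not_symmetric(self, small_ltt):
        a = lk.bdp_joint_loglik(small_ltt, 1.0, 0.5).value
        b = lk.bdp_joint_loglik(small_ltt, 0.5, 1.0).value
        assert abs(a - b) > 0.1


class TestTwoEpoch:
    def test_equal_rates_reduce_to_single_rate_yule(self, two_epoch_example):
        lam, T = 0.6, 1.0
        model = m.TwoEpochModel(lam, lam, T, t0=5.0)
        kernel = lk.two_epoch_loglik(two_epoch_example, model, form="kernel").value
        pooled = two_epoch_example.pooled(stem_age=5.0)
        joint = lk.yule_joint_loglik(pooled, lam).value
        # joint = log (n-1)! + kernel - lam t0
        assert joint == pytest.approx(math.lgamma(5) + kernel - lam * 5.0, rel=1e-12)

    def test_gradient_vanishes_at_mle(self, two_epoch_example):
        lam0, lam1, T = 2.0 / 3.0, 8.0 / 11.0, 1.0

        def ll(a, b):
            return lk.two_epoch_loglik(
                two_epoch_example, m.TwoEpochModel(a, b, T, t0=9.0), "kernel"
            ).value

        h = 1e-6
        g0 = (ll(lam0 + h, lam1) - ll(lam0 - h, lam1)) / (2 * h)
        g1 = (ll(lam0, lam1 + h) - ll(lam0, lam1 - h)) / (2 * h)
        assert abs(g0) < 1e-6 and abs(g1) < 1e-6

    def test_empty_old_epoch_leaves_lambda0_flat(self):
        data = m.TwoEpochData([], [0.5, 0.25])
        model_a = m.TwoEpochModel(0.1, 0.7, 1.0, 5.0)
        model_b = m.TwoEpochModel(3.0, 0.7, 1.0, 5.0)
        # with I = 0 every lambda0-bearing term carries a factor I or t_i^0
        assert lk.two_epoch_loglik(data, model_a).value == pytest.approx(
            lk.two_epoch_loglik(data, model_b).value, rel=1e-14
        )

    def test_age_outside_epoch_is_impossible(self):
        data = m.TwoEpochData([0.8], [0.5])  # "old" age below T = 1
        model = m.TwoEpochModel(0.5, 0.5, 1.0, 5.0)
        assert lk.two_epoch_loglik(data, model).value == -math.inf

    def test_full_form_adds_constant(self, two_epoch_example):
        model = m.TwoEpochModel(0.5, 0.9, 1.0, 5.0)
        k = lk.two_epoch_loglik(two_epoch_example, model, "kernel").value
        f = lk.two_epoch_loglik(two_epoch_example, model, "full").value
        assert f - k == pytest.approx(math.lgamma(5), rel=1e-12)


class TestMassExtinction:
    def test_frozen_series_value(self):
        # frozen from the truncated-series oracle
        model = m.TwoEpochModel(0.1, 0.1, 1.0, 9.0, 0.5)
        assert lk.massext_p1star(2.0, model) == pytest.approx(0.451290, abs=5e-7)

    def test_series_equals_closed_form(self):
        grid = [
            (t, T, l0, l1, p)
            for t in (1.5, 3.0, 8.0)
            for T in (1.0,)
            for l0 in (0.05, 0.4)
            for l1 in (0.1, 0.9)
            for p in (0.1, 0.5, 0.95)
        ]
        for t, T, l0, l1, p in grid:
            model = m.TwoEpochModel(l0, l1, T, 10.0, p)
            assert lk.massext_p1star(t, model) == pytest.approx(
                lk.massext_p1star_series(t, model), abs=1e-12
            )

    def test_complete_survival_equal_rates_reduces_to_exponential(self):
        model = m.TwoEpochModel(0.3, 0.3, 1.0, 9.0, 1.0)
        assert lk.massext_p1star(2.5, model) == pytest.approx(
            math.exp(-0.3 * 2.5), rel=1e-12
        )

    def test_monotone_in_survival_probability(self):
        vals = [
            lk.massext_p1star(2.0, m.TwoEpochModel(0.2, 0.4, 1.0, 9.0, p))
            for p in np.linspace(0.05, 1.0, 25)
        ]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_young_lineage_is_an_error(self):
        with pytest.raises(m.ModelError):
            lk.massext_p1star(0.5, m.TwoEpochModel(0.2, 0.4, 1.0, 9.0, 0.5))

    def test_p_to_one_limit_recovers_two_epoch(self, two_epoch_example):
        base = m.TwoEpochModel(0.5, 0.9, 1.0, 9.0, 1.0)
        near = m.TwoEpochModel(0.5, 0.9, 1.0, 9.0, 1.0 - 1e-8)
        a = lk.two_epoch_loglik(two_epoch_example, base, "full").value
        b = lk.massext_loglik(two_epoch_example, near, "full").value
        assert abs(a - b) <= 1e-6

    def test_empty_young_epoch_slope_in_lambda1(self):
        """With J = 0 the young rate enters only through the e^{-lam1 T}
        factor of p1*, so the log-likelihood is linear with slope -I T."""
        data = m.TwoEpochData([3.0, 2.0], [])
        T = 1.0

        def ll(lam1):
            return lk.massext_loglik(
                data, m.TwoEpochModel(0.5, lam1, T, 9.0, 0.4), "kernel"
            ).value

        # d logL / d lam1 should be -I*T ... plus the J log lam1 term absent
        slope = (ll(0.8) - ll(0.4)) / 0.4
        assert slope == pytest.approx(-2 * T, rel=1e-9)
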