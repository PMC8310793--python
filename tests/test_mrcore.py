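"""MR estimators, heterogeneity statistics, model selection, diagnostics."""

import numpy as np
import pytest
import statsmodels.api as sm

from conftest import make_hset, random_hset
from mremploy import mrcore
from mremploy.mrcore import (egger, fit_method, i2gx, ivw, max_likelihood,
                             q_statistics, radial_outliers, rucker_select,
                             sensitivity, wald_ratio, weighted_median,
                             ModelSelection)


class TestWaldRatio:
    def test_exact_arithmetic(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert r.estimate == pytest.approx(0.5)
        assert r.se == pytest.approx(0.2)

    def test_null_numerator(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.02).estimate == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError, match="beta_x"):
            wald_ratio(0.0, 0.01, 0.05, 0.02)

    def test_first_order_se_close_to_second_order(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            bx = rng.uniform(0.05, 0.2)
            sx = rng.uniform(0.001, 0.01)
            by = rng.uniform(-0.02, 0.02)
            sy = rng.uniform(0.005, 0.03)
            r = wald_ratio(bx, sx, by, sy)
            se2 = np.sqrt(sy ** 2 / bx ** 2 + by ** 2 * sx ** 2 / bx ** 4)
            # agreement up to the O(se_x^2) correction term
            assert r.se <= se2 + 1e-15
            assert (se2 - r.se) / se2 <= (by * sx / (bx * sy)) ** 2 + 1e-12


class TestIvw:
    def test_single_snp_reduces_to_wald(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.02])
        r = ivw(hs)
        w = wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert (r.estimate, r.se) == (w.estimate, w.se)

    def test_identical_ratios_give_zero_q(self):
        hs = make_hset([0.1, 0.2], [0.01, 0.01], [0.05, 0.10], [0.02, 0.02])
        assert ivw(hs).estimate == pytest.approx(0.5)
        ms_q = np.sum((hs.beta_y - 0.5 * hs.beta_x) ** 2 / hs.se_y ** 2)
        assert ms_q == pytest.approx(0.0, abs=1e-14)

    def test_recovery_and_closed_form(self):
        rng = np.random.default_rng(1)
        hs = random_hset(rng, k=20, theta=0.07)
        r = ivw(hs)
        w = 1 / hs.se_y ** 2
        oracle = np.sum(w * hs.beta_x * hs.beta_y) / np.sum(w * hs.beta_x ** 2)
        assert r.estimate == pytest.approx(oracle, abs=1e-10)
        assert abs(r.estimate - 0.07) < 2 * r.se

    def test_mre_same_estimate_se_scaled(self):
        rng = np.random.default_rng(2)
        hs = random_hset(rng, k=30, theta=0.05, alpha_sd=0.03)
        fe, mre = ivw(hs, "fixed"), ivw(hs, "multiplicative_random")
        assert fe.estimate == mre.estimate
        ms = q_statistics(hs)
        if ms.Q / ms.df_Q >= 1:
            assert mre.se >= fe.se

    def test_all_zero_bx_rejected(self):
        hs = make_hset([0.0, 0.0], [0.01, 0.01], [0.1, 0.1], [0.02, 0.02])
        with pytest.raises(ValueError, match="zero"):
            ivw(hs)


class TestEgger:
    def test_exact_collinear_recovery(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        by = 0.01 + 0.4 * bx
        hs = make_hset(bx, np.full(4, 0.01), by, np.full(4, 0.02))
        r = egger(hs)
        assert r.estimate == pytest.approx(0.4, abs=1e-12)
        assert r.intercept == pytest.approx(0.01, abs=1e-12)
        assert q_statistics(hs).Q_prime == pytest.approx(0.0, abs=1e-12)

    def test_constrained_intercept_equals_ivw(self):
        rng = np.random.default_rng(3)
        hs = random_hset(rng, k=15)
        r = egger(hs, constrain_intercept=True)
        assert r.estimate == pytest.approx(ivw(hs).estimate, abs=1e-10)

    def test_directional_pleiotropy_recovered(self):
        rng = np.random.default_rng(4)
        hs = random_hset(rng, k=50, theta=0.05, alpha_mean=0.02, alpha_sd=0.005)
        r = egger(hs)
        assert abs(r.intercept - 0.02) < 2 * r.intercept_se

    def test_matches_wls_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            hs = random_hset(rng, k=12, alpha_sd=0.01)
            r = egger(hs)
            s = np.where(hs.beta_x < 0, -1, 1)
            bx, by = s * hs.beta_x, s * hs.beta_y
            fit = sm.WLS(by, sm.add_constant(bx), weights=1 / hs.se_y ** 2).fit()
            assert r.intercept == pytest.approx(fit.params[0], abs=1e-10)
            assert r.estimate == pytest.approx(fit.params[1], abs=1e-10)

    def test_too_few_snps(self):
        hs = make_hset([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.02] * 2)
        with pytest.raises(ValueError, match=">= 3"):
            egger(hs)


class TestWeightedMedian:
    def test_degenerate_all_equal(self):
        hs = make_hset([0.1, 0.2, 0.4], [0.01] * 3,
                       [0.03, 0.06, 0.12], [0.02] * 3)
        assert weighted_median(hs, 100, seed=0).estimate == pytest.approx(0.3)

    def test_middle_element_equal_weights(self):
        # equal ratio variances: ratios 0.1, 0.5, 0.9 -> median 0.5
        hs = make_hset([0.1, 0.1, 0.1], [0.01] * 3,
                       [0.01, 0.05, 0.09], [0.02] * 3)
        assert weighted_median(hs, 100, seed=0).estimate == pytest.approx(0.5)

    def test_requires_seed(self):
        hs = make_hset([0.1] * 3, [0.01] * 3, [0.05] * 3, [0.02] * 3)
        with pytest.raises(ValueError, match="seed"):
            weighted_median(hs, 100)

    def test_breakdown_robustness(self):
        # 30% of SNPs grossly pleiotropic: median stays near theta, IVW drifts
        rng = np.random.default_rng(6)
        k, theta = 30, 0.05
        beta = rng.normal(0.1, 0.03, k)
        sx, sy = np.full(k, 0.005), np.full(k, 0.01)
        alpha = np.zeros(k)
        alpha[:9] = 0.08
        bx = beta + rng.normal(0, sx)
        by = theta * beta + alpha + rng.normal(0, sy)
        hs = make_hset(bx, sx, by, sy)
        wm = weighted_median(hs, 500, seed=7)
        assert abs(wm.estimate - theta) < 2 * wm.se
        assert abs(ivw(hs).estimate - theta) > abs(wm.estimate - theta)


class TestMaxLikelihood:
    def test_single_snp_reduces_to_wald(self):
        hs = make_hset([0.1], [0.01], [0.05], [0.02])
        r = max_likelihood(hs)
        assert r.estimate == pytest.approx(0.5)

    def test_limit_equals_ivw_as_sx_vanishes(self):
        rng = np.random.default_rng(7)
        hs = random_hset(rng, k=25, sx_scale=1e-8)
        assert max_likelihood(hs).estimate == pytest.approx(
            ivw(hs).estimate, abs=1e-6)

    def test_less_dilution_than_ivw(self):
        # noisy exposure betas dilute IVW toward zero; ML corrects
        theta = 0.1
        biases_ml, biases_ivw = [], []
        for rep in range(100):
            rng = np.random.default_rng(800 + rep)
            hs = random_hset(rng, k=30, theta=theta, sx_scale=0.03,
                             sy_scale=0.01)
            biases_ml.append(max_likelihood(hs).estimate - theta)
            biases_ivw.append(ivw(hs).estimate - theta)
        assert abs(np.mean(biases_ml)) <= abs(np.mean(biases_ivw))


class TestQStatistics:
    def test_q_dominates_q_prime(self):
        rng = np.random.default_rng(8)
        for _ in range(300):
            hs = random_hset(rng, k=int(rng.integers(3, 25)),
                             alpha_sd=float(rng.uniform(0, 0.05)))
            ms = q_statistics(hs)
            assert ms.Q >= ms.Q_prime >= 0
            assert ms.Q_diff >= 0

    def test_null_p_uniform(self):
        from scipy import stats
        ps = []
        for rep in range(200):
            rng = np.random.default_rng(3000 + rep)
            ps.append(q_statistics(random_hset(rng, k=20)).p_Q)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_collinear_closed_form(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        by = 0.02 + 0.5 * bx
        sy = np.full(4, 0.01)
        hs = make_hset(bx, np.full(4, 0.01), by, sy)
        ms = q_statistics(hs)
        assert ms.Q_prime == pytest.approx(0.0, abs=1e-12)
        th = ivw(hs).estimate
        expected_q = np.sum((by - th * bx) ** 2 / sy ** 2)
        assert ms.Q == pytest.approx(expected_q, rel=1e-12)


class TestRuckerSelect:
    def _ms(self, p_q, p_qp, p_qdiff):
        return ModelSelection(10, 8, 9, 8, p_q, p_qp, 2, p_qdiff)

    def test_rule_application(self):
        assert rucker_select(self._ms(0.4, 0.5, 0.6)) == "ivw_fe"
        assert rucker_select(self._ms(0.01, 0.5, 0.6)) == "ivw_mre"
        assert rucker_select(self._ms(0.01, 0.5, 0.001)) == "egger_fe"
        assert rucker_select(self._ms(0.01, 0.01, 0.001)) == "egger_mre"
        # hierarchy: without significant heterogeneity the intercept test
        # is never consulted
        assert rucker_select(self._ms(0.4, 0.5, 0.001)) == "ivw_fe"

    def test_power_under_directional_pleiotropy(self):
        # directional pleiotropy of mean 0.03 varying across SNPs (sd half
        # the mean, the usual shape in MR simulation designs)
        egger_count = 0
        for rep in range(100):
            rng = np.random.default_rng(4000 + rep)
            hs = random_hset(rng, k=50, theta=0.05, alpha_mean=0.03,
                             alpha_sd=0.015)
            choice = rucker_select(q_statistics(hs))
            egger_count += choice.startswith("egger")
        assert egger_count > 50

    def test_fit_method_dispatch(self):
        rng = np.random.default_rng(9)
        hs = random_hset(rng, k=10)
        assert fit_method(hs, "ivw_fe").estimate == ivw(hs).estimate
        assert fit_method(hs, "egger_mre").estimate == egger(
            hs, "multiplicative_random").estimate


class TestI2gx:
    def test_limit_is_one(self):
        bx = np.array([0.05, 0.1, 0.15, 0.2])
        hs = make_hset(bx, np.full(4, 1e-6), bx * 0.5, np.full(4, 0.01))
        assert i2gx(hs).i2gx == pytest.approx(1.0, abs=1e-6)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(10)
        hs = random_hset(rng, k=40)
        v = 1 / hs.se_x ** 2
        bw = np.sum(v * hs.beta_x) / np.sum(v)
        q = np.sum(v * (hs.beta_x - bw) ** 2)
        assert i2gx(hs).i2gx == pytest.approx((q - 39) / q, abs=1e-12)

    def test_weak_instrument_flag(self):
        # exposure-side noise comparable to effect spread -> I2_GX < 0.9
        rng = np.random.default_rng(11)
        hs = random_hset(rng, k=30, sx_scale=0.1)
        stats_ = i2gx(hs)
        assert stats_.i2gx < 0.9 and stats_.threshold_flag

    def test_degenerate_rejected(self):
        hs = make_hset([0.1, 0.1], [0.01, 0.01], [0.05, 0.05], [0.02, 0.02])
        with pytest.raises(ValueError, match="degenerate"):
            i2gx(hs)


class TestRadialOutliers:
    def test_homogeneous_no_flags(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = make_hset(bx, np.full(3, 0.01), 0.5 * bx, np.full(3, 0.02))
        flagged, contrib, _ = radial_outliers(hs)
        assert flagged == [] and np.allclose(contrib, 0.0)

    def test_injected_outlier_flagged_with_largest_contribution(self):
        rng = np.random.default_rng(12)
        hs = random_hset(rng, k=20, theta=0.05)
        hs.beta_y[7] += 10 * np.median(hs.se_y) * 3
        flagged, contrib, _ = radial_outliers(hs)
        assert hs.snp_ids[7] in flagged
        assert np.argmax(contrib) == 7

    def test_null_false_positive_rate(self):
        counts = []
        for rep in range(100):
            rng = np.random.default_rng(5000 + rep)
            flagged, _, _ = radial_outliers(random_hset(rng, k=77), alpha=0.05)
            counts.append(len(flagged))
        assert abs(np.mean(counts) - 0.05 * 77) < 2.0


class TestSensitivity:
    def test_cardinality(self):
        rng = np.random.default_rng(13)
        hs = random_hset(rng, k=5)
        res = sensitivity(hs)
        assert len(res.single_snp) == 5 and len(res.leave_one_out) == 5

    def test_loo_stability_on_homogeneous_data(self):
        rng = np.random.default_rng(14)
        hs = random_hset(rng, k=30, theta=0.05)
        res = sensitivity(hs)
        full = res.full
        for loo in res.leave_one_out:
            assert abs(loo.estimate - full.estimate) < 2 * full.se

    def test_removing_outlier_moves_estimate_toward_truth(self):
        theta = 0.05
        rng = np.random.default_rng(15)
        hs = random_hset(rng, k=20, theta=theta)
        hs.beta_y[3] += 0.3
        flagged, _, _ = radial_outliers(hs)
        assert hs.snp_ids[3] in flagged
        est_full = ivw(hs).estimate
        est_clean = ivw(hs.drop(flagged)).estimate
        assert abs(est_clean - theta) < abs(est_full - theta)


class TestEstimatorInvariants:
    def test_scale_equivariance(self):
        rng = np.random.default_rng(16)
        hs = random_hset(rng, k=15, alpha_sd=0.01)
        c = 3.7
        hs_c = make_hset(hs.beta_x, hs.se_x, c * hs.beta_y, c * hs.se_y)
        for fn in (lambda h: ivw(h), lambda h: egger(h),
                   lambda h: max_likelihood(h),
                   lambda h: weighted_median(h, 200, seed=3)):
            a, b = fn(hs), fn(hs_c)
            assert b.estimate == pytest.approx(c * a.estimate, rel=1e-6)
            assert b.se == pytest.approx(c * a.se, rel=0.2)

    def test_orientation_invariance(self):
        rng = np.random.default_rng(17)
        hs = random_hset(rng, k=15, alpha_sd=0.01)
        s = np.where(rng.random(15) < 0.5, -1.0, 1.0)
        hs_f = make_hset(s * hs.beta_x, hs.se_x, s * hs.beta_y, hs.se_y)
        assert ivw(hs_f).estimate == pytest.approx(ivw(hs).estimate, abs=1e-12)
        assert egger(hs_f).estimate == pytest.approx(egger(hs).estimate, abs=1e-12)

    def test_ci_round_trip(self):
        rng = np.random.default_rng(18)
        r = ivw(random_hset(rng, k=10))
        lo, hi = r.ci95
        assert (hi - lo) / (2 * 1.959964) == pytest.approx(r.se, abs=1e-12)
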