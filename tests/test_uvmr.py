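import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import mrmediate as mm
from mrmediate.uvmr import _mode_point, _weighted_median_point


class TestWaldRatio:
    def test_first_order_closed_form(self):
        est = mm.wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(0.5)
        assert est.se == pytest.approx(0.2)

    def test_zero_outcome_effect(self):
        assert mm.wald_ratio(0.1, 0.01, 0.0, 0.02).beta == 0.0

    def test_second_order_hand_formula(self):
        bx, sx, by, sy = 0.1, 0.01, 0.05, 0.02
        est = mm.wald_ratio(bx, sx, by, sy, second_order=True)
        expect = np.sqrt(sy**2 / bx**2 + by**2 * sx**2 / bx**4)
        assert est.se == pytest.approx(expect, rel=1e-12)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ValueError):
            mm.wald_ratio(0.0, 0.01, 0.05, 0.02)


class TestIvw:
    def test_single_instrument_reduces_to_wald_ratio(self):
        h = mm.HarmonizedSet.from_arrays([0.1], [0.01], [0.05], [0.02])
        est = mm.ivw(h)
        wr = mm.wald_ratio(0.1, 0.01, 0.05, 0.02)
        assert est.beta == pytest.approx(wr.beta)
        assert est.se == pytest.approx(wr.se)

    def test_identical_ratios_give_zero_q_and_fixed_model(self):
        h = mm.HarmonizedSet.from_arrays(
            [0.1, 0.2, 0.4], [0.01] * 3, [0.05, 0.10, 0.20], [0.02] * 3)
        est = mm.ivw(h, model="auto")
        assert est.beta == pytest.approx(0.5)
        assert est.method == "ivw_fixed"
        het = mm.cochran_q(h)
        assert het.q_statistic == pytest.approx(0.0, abs=1e-20)
        assert het.pvalue == pytest.approx(1.0)

    def test_three_instrument_direct_summation_oracle(self, toy_hset):
        bx = toy_hset.beta_exposure
        by = toy_hset.beta_outcome
        sy = toy_hset.se_outcome
        # term-by-term weighted average of the per-SNP ratios
        w = [bx[j] ** 2 / sy[j] ** 2 for j in range(3)]
        ratios = [by[j] / bx[j] for j in range(3)]
        beta = sum(wi * ri for wi, ri in zip(w, ratios)) / sum(w)
        se = (1.0 / sum(w)) ** 0.5
        est = mm.ivw(toy_hset, model="fixed")
        assert est.beta == pytest.approx(beta, abs=1e-10)
        assert est.se == pytest.approx(se, abs=1e-10)

    def test_ivw_equals_origin_wls(self, null_hset):
        # IVW slope == WLS of beta_Y on beta_X through origin, weights 1/se_Y^2
        import statsmodels.api as sm
        fit = sm.WLS(null_hset.beta_outcome,
                     null_hset.beta_exposure[:, None],
                     weights=1.0 / null_hset.se_outcome**2).fit()
        assert mm.ivw(null_hset).beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_se_at_least_fixed(self, null_hset):
        fixed = mm.ivw(null_hset, model="fixed")
        random = mm.ivw(null_hset, model="random")
        assert random.beta == pytest.approx(fixed.beta)
        assert random.se >= fixed.se

    def test_empty_set_raises(self, toy_hset):
        with pytest.raises(ValueError):
            mm.ivw(toy_hset.subset([]))


class TestCochranQ:
    def test_three_instrument_hand_summation(self, toy_hset):
        bx, by, sy = (toy_hset.beta_exposure, toy_hset.beta_outcome,
                      toy_hset.se_outcome)
        w = bx**2 / sy**2
        r = by / bx
        beta = np.sum(w * r) / np.sum(w)
        q = float(np.sum(w * (r - beta) ** 2))
        het = mm.cochran_q(toy_hset)
        assert het.q_statistic == pytest.approx(q, abs=1e-12)
        assert het.df == 2

    def test_chisq_tail_helper_matches_scipy(self):
        assert mm.chisq_upper_tail(10.0, 5) == pytest.approx(
            stats.chi2.sf(10.0, 5))

    def test_needs_two_instruments(self, toy_hset):
        with pytest.raises(ValueError):
            mm.cochran_q(toy_hset.subset([0]))


class TestEgger:
    def test_noiseless_line_recovered_exactly(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.3 * bx + 0.01
        h = mm.HarmonizedSet.from_arrays(bx, [0.01] * 4, by, [0.02] * 4)
        slope, intercept = mm.egger(h)
        assert slope.beta == pytest.approx(0.3, abs=1e-12)
        assert intercept.beta == pytest.approx(0.01, abs=1e-12)

    def test_normal_equations_oracle(self):
        rng = np.random.default_rng(4)
        bx = rng.uniform(0.05, 0.3, 4)
        by = 0.25 * bx + 0.005 + rng.normal(0, 0.01, 4)
        sy = rng.uniform(0.01, 0.03, 4)
        h = mm.HarmonizedSet.from_arrays(bx, [0.01] * 4, by, sy)
        slope, intercept = mm.egger(h)
        # explicit 2x2 weighted normal equations
        w = 1.0 / sy**2
        xtx = np.array([[np.sum(w), np.sum(w * bx)],
                        [np.sum(w * bx), np.sum(w * bx**2)]])
        xty = np.array([np.sum(w * by), np.sum(w * bx * by)])
        a, b = np.linalg.solve(xtx, xty)
        assert intercept.beta == pytest.approx(a, abs=1e-10)
        assert slope.beta == pytest.approx(b, abs=1e-10)

    def test_matches_statsmodels_wls_with_overdispersion(self, null_hset):
        import statsmodels.api as sm
        bx = null_hset.beta_exposure
        by = null_hset.beta_outcome
        sy = null_hset.se_outcome
        sign = np.where(bx < 0, -1, 1)
        x = sm.add_constant(bx * sign)
        fit = sm.WLS(by * sign, x, weights=1 / sy**2).fit()
        slope, intercept = mm.egger(null_hset)
        assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
        assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
        # statsmodels scales by RSS/(n-2) without the floor at 1
        n = null_hset.n_snp
        scale_ratio = max(1.0, fit.scale) / fit.scale
        assert slope.se == pytest.approx(
            fit.bse[1] * np.sqrt(scale_ratio), rel=1e-8)

    def test_two_instruments_raise_naming_minimum(self, toy_hset):
        with pytest.raises(ValueError, match="3"):
            mm.egger(toy_hset.subset([0, 1]))


class TestWeightedMedian:
    def test_equal_weight_odd_count_is_middle_ratio(self):
        bx = np.ones(5)
        by = np.array([0.1, 0.5, 0.3, 0.9, 0.2])
        h = mm.HarmonizedSet.from_arrays(bx, [0.01] * 5, by, [0.02] * 5)
        est = mm.weighted_median(h, weights="equal", reps=100, seed=0)
        assert est.method == "simple_median"
        assert est.beta == pytest.approx(0.3)

    def test_identical_ratios_and_shrinking_bootstrap_se(self):
        bx = np.array([0.1, 0.2, 0.3])
        h_wide = mm.HarmonizedSet.from_arrays(bx, [0.01] * 3, 0.4 * bx,
                                              [0.02] * 3)
        h_tight = mm.HarmonizedSet.from_arrays(bx, [0.001] * 3, 0.4 * bx,
                                               [0.002] * 3)
        est_wide = mm.weighted_median(h_wide, reps=300, seed=1)
        est_tight = mm.weighted_median(h_tight, reps=300, seed=1)
        assert est_wide.beta == pytest.approx(0.4)
        assert est_tight.se < est_wide.se

    def test_manual_cumulative_weight_trace(self):
        # 4 ratios with unequal weights, hand-executed interpolation
        ratios = np.array([0.1, 0.2, 0.4, 0.8])
        weights = np.array([1.0, 2.0, 3.0, 2.0])
        s = (np.cumsum(weights) - weights / 2) / weights.sum()
        # 0.5 falls between S_2=0.25 and S_3=0.5625 -> interpolate
        expect = 0.2 + (0.4 - 0.2) * (0.5 - s[1]) / (s[2] - s[1])
        assert _weighted_median_point(ratios, weights) == pytest.approx(
            expect, abs=1e-12)
        # invariance to input ordering
        perm = np.array([2, 0, 3, 1])
        assert _weighted_median_point(ratios[perm], weights[perm]) == (
            pytest.approx(expect, abs=1e-12))

    def test_bootstrap_reproducible(self, null_hset):
        a = mm.weighted_median(null_hset, reps=200, seed=42)
        b = mm.weighted_median(null_hset, reps=200, seed=42)
        assert a.beta == b.beta and a.se == b.se

    def test_needs_three_instruments(self, toy_hset):
        with pytest.raises(ValueError):
            mm.weighted_median(toy_hset.subset([0, 1]))


class TestWeightedMode:
    def test_identical_ratios_return_common_value(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = mm.HarmonizedSet.from_arrays(bx, [0.01] * 3, 0.7 * bx, [0.02] * 3)
        assert mm.weighted_mode(h, reps=100, seed=0).beta == pytest.approx(0.7)

    def test_majority_cluster_wins(self):
        ratios = np.array([0.3] * 7 + [1.0] * 3)
        ratios = ratios + np.linspace(-0.01, 0.01, 10)  # break exact ties
        bx = np.ones(10)
        h = mm.HarmonizedSet.from_arrays(bx, [0.01] * 10, ratios, [0.02] * 10)
        est = mm.weighted_mode(h, reps=100, seed=0)
        # independent dense-grid oracle over the kernel density
        w = np.ones(10) / 10
        sd = np.std(ratios, ddof=1)
        mad = np.median(np.abs(ratios - np.median(ratios))) / 0.6745
        hband = 0.9 * min(sd, mad) * 10 ** (-0.2)
        grid = np.linspace(ratios.min() - 3 * hband, ratios.max() + 3 * hband,
                           20001)
        dens = (w[None, :] * np.exp(
            -0.5 * ((grid[:, None] - ratios[None, :]) / hband) ** 2)).sum(axis=1)
        oracle = grid[np.argmax(dens)]
        assert abs(est.beta - oracle) < 1e-3
        assert abs(est.beta - 0.3) < hband + 0.011

    def test_phi_varies_estimate_continuously(self):
        rng = np.random.default_rng(8)
        ratios = np.concatenate([rng.normal(0.3, 0.02, 7),
                                 rng.normal(1.0, 0.02, 3)])
        bx = np.ones(10)
        h = mm.HarmonizedSet.from_arrays(bx, [0.01] * 10, ratios, [0.02] * 10)
        phis = np.linspace(0.5, 2.0, 7)
        betas = [mm.weighted_mode(h, phi=p, reps=100, seed=0).beta
                 for p in phis]
        gaps = np.abs(np.diff(betas))
        assert np.all(gaps <= 0.7 + 1e-9)  # never jumps more than cluster gap
        assert np.max(np.abs(np.array(betas) - 0.3)) < 0.2

    def test_bootstrap_reproducible(self, null_hset):
        a = mm.weighted_mode(null_hset, reps=150, seed=9)
        b = mm.weighted_mode(null_hset, reps=150, seed=9)
        assert (a.beta, a.se) == (b.beta, b.se)


class TestTransformToOr:
    def test_null_beta_gives_unit_or_and_p_one(self):
        orp, orl, oru, p = mm.transform_to_or(0.0, 0.1)
        assert orp == 1.0
        assert p == pytest.approx(1.0)
        assert orl < 1.0 < oru

    def test_ci_level_changes_width(self):
        _, l95, u95, _ = mm.transform_to_or(0.2, 0.1, 0.95)
        _, l80, u80, _ = mm.transform_to_or(0.2, 0.1, 0.80)
        assert l95 < l80 and u80 < u95


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=49),
       st.integers(min_value=0, max_value=2**31 - 1))
def test_estimators_invariant_to_joint_negation(flip_index, seed):
    """Jointly negating (beta_X, beta_Y) of any instrument leaves every
    estimator unchanged (allele-coding invariance)."""
    rng = np.random.default_rng(seed)
    n = 8
    bx = rng.uniform(0.05, 0.3, n)
    by = 0.2 * bx + rng.normal(0, 0.02, n)
    sx = rng.uniform(0.005, 0.02, n)
    sy = rng.uniform(0.01, 0.04, n)
    h1 = mm.HarmonizedSet.from_arrays(bx, sx, by, sy)
    j = flip_index % n
    bx2, by2 = bx.copy(), by.copy()
    bx2[j] *= -1
    by2[j] *= -1
    h2 = mm.HarmonizedSet.from_arrays(bx2, sx, by2, sy)
    assert mm.ivw(h1).beta == pytest.approx(mm.ivw(h2).beta, abs=1e-12)
    assert mm.egger(h1)[0].beta == pytest.approx(mm.egger(h2)[0].beta,
                                                 abs=1e-12)
    assert mm.weighted_median(h1, reps=100, seed=1).beta == pytest.approx(
        mm.weighted_median(h2, reps=100, seed=1).beta, abs=1e-12)
    assert mm.weighted_mode(h1, reps=100, seed=1).beta == pytest.approx(
        mm.weighted_mode(h2, reps=100, seed=1).beta, abs=1e-12)
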