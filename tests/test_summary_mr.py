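"""Two-sample MR estimators against brute-force and closed-form oracles."""

import numpy as np
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st

from triomr.summary_mr import (
    HarmonizedSet,
    cochrans_q,
    ivw,
    mode_estimator,
    mr_egger,
    mvmr_ivw,
    two_estimate_heterogeneity,
    wald_ratio,
    weighted_median,
)


def hset(bx, by, se_y, se_x=None):
    bx = np.asarray(bx, dtype=float)
    if se_x is None:
        se_x = np.full_like(bx, 1e-6)
    return HarmonizedSet(bx, se_x, by, se_y)


def random_hset(rng, L=8):
    bx = rng.uniform(0.05, 0.3, L)
    by = 0.4 * bx + rng.normal(0, 0.02, L)
    se_y = rng.uniform(0.01, 0.05, L)
    se_x = rng.uniform(0.005, 0.02, L)
    return HarmonizedSet(bx, se_x, by, se_y)


class TestWaldRatio:
    def test_ratio_and_first_order_se(self):
        r = wald_ratio(0.1, 0.01, 0.05, 0.01)
        assert r.beta == pytest.approx(0.5)
        assert r.se == pytest.approx(0.1)

    def test_zero_outcome_beta(self):
        assert wald_ratio(0.1, 0.01, 0.0, 0.01).beta == 0.0

    def test_sign_flip_of_exposure_flips_estimate(self):
        a = wald_ratio(0.1, 0.01, 0.05, 0.01)
        b = wald_ratio(-0.1, 0.01, 0.05, 0.01)
        assert b.beta == pytest.approx(-a.beta)

    def test_second_order_se_exceeds_first_order(self):
        r1 = wald_ratio(0.1, 0.05, 0.05, 0.01)
        r2 = wald_ratio(0.1, 0.05, 0.05, 0.01, second_order=True)
        assert r2.se > r1.se

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.01, 0.05, 0.01)


class TestIVW:
    def test_single_variant_reduces_to_wald(self):
        hs = hset([0.1], [0.05], [0.01])
        r = ivw(hs)
        w = wald_ratio(0.1, 1e-6, 0.05, 0.01)
        assert r.beta == pytest.approx(w.beta) and r.se == pytest.approx(w.se)

    def test_two_variant_hand_computation(self):
        hs = hset([0.1, 0.2], [0.05, 0.08], [0.01, 0.02])
        r = ivw(hs, model="fixed")
        assert r.beta == pytest.approx(0.45)
        assert r.se == pytest.approx(1 / np.sqrt(200), abs=1e-6)

    def test_exact_proportionality_gives_q_zero(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = hset(bx, 0.7 * bx, [0.01] * 3)
        r = ivw(hs)
        assert r.beta == pytest.approx(0.7) and r.Q == pytest.approx(0.0, abs=1e-12)

    def test_matches_weighted_regression_through_origin_oracle(self, rng):
        for _ in range(100):
            hs = random_hset(rng)
            mine = ivw(hs, model="fixed")
            fit = sm.WLS(hs.by, hs.bx[:, None], weights=1 / hs.se_y**2).fit()
            assert mine.beta == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        hs = random_hset(rng)
        assert ivw(hs, "multiplicative_random").se >= ivw(hs, "fixed").se


class TestEgger:
    def test_exact_linear_construction(self):
        bx = np.array([0.1, 0.2, 0.3])
        hs = hset(bx, 0.01 + 0.5 * bx, [0.02] * 3)
        r = mr_egger(hs)
        assert r.beta == pytest.approx(0.5, abs=1e-10)
        assert r.egger_intercept == pytest.approx(0.01, abs=1e-10)

    def test_proportional_data_zero_intercept(self):
        bx = np.array([0.1, 0.25, 0.4])
        r = mr_egger(hset(bx, 0.3 * bx, [0.02] * 3))
        assert r.egger_intercept == pytest.approx(0.0, abs=1e-12)
        # with an exactly zero intercept the slope equals IVW's
        assert r.beta == pytest.approx(ivw(hset(bx, 0.3 * bx, [0.02] * 3)).beta,
                                       abs=1e-10)

    def test_orientation_invariance(self):
        bx = np.array([0.1, -0.2, 0.3])
        by = np.array([0.06, -0.09, 0.17])
        a = mr_egger(hset(bx, by, [0.02] * 3))
        bx2, by2 = bx.copy(), by.copy()
        bx2[0], by2[0] = -bx2[0], -by2[0]
        b = mr_egger(hset(bx2, by2, [0.02] * 3))
        assert a.beta == pytest.approx(b.beta, abs=1e-12)
        assert a.egger_intercept == pytest.approx(b.egger_intercept, abs=1e-12)

    def test_matches_wls_oracle_after_orientation(self, rng):
        hs = random_hset(rng, L=10)
        mine = mr_egger(hs)
        X = sm.add_constant(hs.bx)
        fit = sm.WLS(hs.by, X, weights=1 / hs.se_y**2).fit()
        assert mine.beta == pytest.approx(float(fit.params[1]), abs=1e-10)

    def test_fewer_than_three_rejected(self):
        with pytest.raises(ValueError):
            mr_egger(hset([0.1, 0.2], [0.05, 0.1], [0.01, 0.01]))


class TestWeightedMedian:
    def test_equal_weights_middle_ratio(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = bx * np.array([0.2, 0.5, 0.9])
        r = weighted_median(hset(bx, by, [0.01] * 3), n_boot=200, seed=1)
        assert r.beta == pytest.approx(0.5)

    def test_identical_ratios(self):
        bx = np.array([0.1, 0.2, 0.3])
        r = weighted_median(hset(bx, 0.7 * bx, [0.01, 0.02, 0.03]),
                            n_boot=100, seed=1)
        assert r.beta == pytest.approx(0.7)

    def test_bootstrap_se_deterministic_under_seed(self, rng):
        hs = random_hset(rng)
        a = weighted_median(hs, n_boot=300, seed=7)
        b = weighted_median(hs, n_boot=300, seed=7)
        assert a.se == b.se

    def test_estimate_within_ratio_range(self, rng):
        for _ in range(20):
            hs = random_hset(rng)
            r = weighted_median(hs, n_boot=50, seed=3)
            assert hs.ratios.min() - 1e-12 <= r.beta <= hs.ratios.max() + 1e-12

    def test_cumulative_weight_interpolation_oracle(self, rng):
        # independent oracle: dense scan of the weighted empirical CDF
        hs = random_hset(rng, L=9)
        ratios, w = hs.ratios, hs.ratio_weights
        order = np.argsort(ratios)
        r_s, w_s = ratios[order], w[order]
        p = (np.cumsum(w_s) - w_s / 2) / w_s.sum()
        expected = float(np.interp(0.5, p, r_s))
        mine = weighted_median(hs, n_boot=10, seed=0)
        assert mine.beta == pytest.approx(expected, abs=1e-12)


class TestMode:
    def test_majority_ratio_is_mode(self):
        bx = np.array([0.1, 0.1, 0.1, 0.1])
        by = bx * np.array([0.5, 0.5, 0.5, 0.9])
        r = mode_estimator(hset(bx, by, [0.01] * 4), "simple", n_boot=50, seed=2)
        assert r.beta == pytest.approx(0.5, abs=0.02)

    def test_identical_ratios_exact(self):
        bx = np.array([0.1, 0.2, 0.4])
        r = mode_estimator(hset(bx, 0.3 * bx, [0.01] * 3), "simple", n_boot=20, seed=2)
        assert r.beta == pytest.approx(0.3, abs=1e-6)

    def test_weighted_mode_pulled_to_dominant_weight(self):
        bx = np.array([0.5, 0.1, 0.1])
        by = bx * np.array([0.2, 0.8, 0.85])
        se_y = np.array([0.002, 0.05, 0.05])  # first variant dominates weights
        rw = mode_estimator(hset(bx, by, se_y), "weighted", n_boot=20, seed=2)
        rs = mode_estimator(hset(bx, by, se_y), "simple", n_boot=20, seed=2)
        assert abs(rw.beta - 0.2) < abs(rs.beta - 0.2)

    def test_grid_density_oracle(self, rng):
        hs = random_hset(rng, L=12)
        mine = mode_estimator(hs, "simple", n_boot=10, seed=0)
        # oracle: independent fine-grid Gaussian KDE maximum
        r = hs.ratios
        mad = np.median(np.abs(r - np.median(r))) * 1.4826
        h = 0.9 * min(r.std(ddof=1), mad) / len(r) ** 0.2
        grid = np.linspace(r.min() - 3 * h, r.max() + 3 * h, 40_001)
        dens = np.exp(-0.5 * ((grid[:, None] - r) / h) ** 2).sum(1)
        expected = grid[np.argmax(dens)]
        assert mine.beta == pytest.approx(expected, abs=2e-3)

    def test_invalid_phi_rejected(self, rng):
        with pytest.raises(ValueError):
            mode_estimator(random_hset(rng), phi=0.0)


class TestHeterogeneity:
    def test_identical_estimates_q_zero(self):
        q, df, p = cochrans_q([0.3, 0.3, 0.3], [0.1, 0.2, 0.1])
        assert q == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_hand_computed_q(self):
        q, df, p = cochrans_q([0.0, 1.0], [1.0, 1.0])
        assert q == pytest.approx(0.5)
        assert df == 1
        assert p == pytest.approx(0.47950012, abs=1e-7)

    def test_scaling_ses_scales_q(self):
        q1, _, _ = cochrans_q([0.0, 1.0, 0.4], [0.1, 0.1, 0.1])
        q2, _, _ = cochrans_q([0.0, 1.0, 0.4], [0.2, 0.2, 0.2])
        assert q1 == pytest.approx(4 * q2)

    def test_two_estimate_gxe_strata_values(self):
        # printed consumer/non-consumer stratified estimates
        q, p = two_estimate_heterogeneity(0.153, 0.071, 0.107, 0.134)
        assert q == pytest.approx(0.0920120, abs=1e-6)
        assert p == pytest.approx(0.7616347, abs=1e-6)

    def test_p_decreases_with_gap(self):
        ps = [two_estimate_heterogeneity(0.0, 0.1, gap, 0.1)[1]
              for gap in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestMVMR:
    def test_single_exposure_equals_ivw(self, rng):
        hs = random_hset(rng)
        mv = mvmr_ivw(hs.bx, hs.by, hs.se_y)[0]
        uni = ivw(hs, "multiplicative_random")
        assert mv.beta == pytest.approx(uni.beta, abs=1e-12)
        assert mv.se == pytest.approx(uni.se, rel=1e-6)

    def test_exact_two_exposure_construction(self, rng):
        bx1 = rng.uniform(0.05, 0.3, 10)
        bx2 = rng.uniform(0.05, 0.3, 10)
        by = 0.3 * bx1 + 0.0 * bx2
        res = mvmr_ivw(np.column_stack([bx1, bx2]), by, np.full(10, 0.02))
        assert res[0].beta == pytest.approx(0.3, abs=1e-10)
        assert res[1].beta == pytest.approx(0.0, abs=1e-10)

    def test_row_permutation_invariance(self, rng):
        bx = rng.uniform(0.05, 0.3, (8, 2))
        by = rng.normal(0, 0.05, 8)
        se = rng.uniform(0.01, 0.03, 8)
        a = mvmr_ivw(bx, by, se)
        perm = rng.permutation(8)
        b = mvmr_ivw(bx[perm], by[perm], se[perm])
        assert a[0].beta == pytest.approx(b[0].beta, abs=1e-12)

    def test_underidentified_rejected(self, rng):
        with pytest.raises(ValueError):
            mvmr_ivw(rng.normal(size=(2, 2)), [0.1, 0.2], [0.01, 0.01])


@given(st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=20)
def test_all_estimators_invariant_to_simultaneous_sign_flip(seed):
    rng = np.random.default_rng(seed)
    hs = random_hset(rng, L=6)
    flip = rng.random(6) < 0.5
    s = np.where(flip, -1.0, 1.0)
    hs2 = HarmonizedSet(hs.bx * s, hs.se_x, hs.by * s, hs.se_y)
    assert ivw(hs2).beta == pytest.approx(ivw(hs).beta, abs=1e-12)
    assert mr_egger(hs2).beta == pytest.approx(mr_egger(hs).beta, abs=1e-12)
    assert weighted_median(hs2, 10, 0).beta == pytest.approx(
        weighted_median(hs, 10, 0).beta, abs=1e-12
    )
    assert mode_estimator(hs2, "simple", 1.0, 10, 0).beta == pytest.approx(
        mode_estimator(hs, "simple", 1.0, 10, 0).beta, abs=1e-9
    )
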