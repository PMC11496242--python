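"""Instruments: PGS orientation, strength diagnostics, harmonization, clumping,
collider screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_sumstats
from triomr.instruments import (
    PGSWeights,
    benchmark_instrument,
    build_pgs,
    collider_screen,
    greedy_clump,
    harmonize,
    i2_gx,
)
from triomr.simulate import HurdleConfig, SimConfig, simulate_trios


def pgsw(weights, mode="weighted"):
    n = len(weights)
    return PGSWeights(
        tuple(f"v{i}" for i in range(n)), tuple("A" * n), tuple(weights), mode
    )


class TestBuildPgs:
    def test_weighted_sum(self):
        score = build_pgs(np.array([[0, 1, 2]]), pgsw([0.1, 0.1, 0.1]))
        assert score[0] == pytest.approx(0.3)

    def test_unweighted_orients_to_increasing_allele(self):
        # negative weight at dosage 2 contributes 2 - 2 = 0 increasing alleles
        score = build_pgs(np.array([[2, 1]]), pgsw([-0.1, 0.2], "unweighted"))
        assert score[0] == pytest.approx(0.0 + 1.0)

    def test_zero_dosages_zero_weighted_score(self):
        assert build_pgs(np.zeros((3, 2)), pgsw([0.5, -0.5]))[0] == 0

    def test_missing_variant_raises(self):
        with pytest.raises(KeyError):
            build_pgs(np.zeros((2, 1)), pgsw([0.1, 0.2]), variant_ids=["v0"])

    def test_id_matching_reorders_columns(self, rng):
        d = rng.integers(0, 3, size=(20, 2)).astype(float)
        w = PGSWeights(("b", "a"), ("A", "A"), (0.2, 0.1))
        by_id = build_pgs(d, w, variant_ids=["a", "b"])
        manual = 0.2 * d[:, 1] + 0.1 * d[:, 0]
        np.testing.assert_allclose(by_id, manual)

    @given(st.lists(st.floats(-1, 1), min_size=3, max_size=3),
           st.lists(st.floats(-1, 1), min_size=3, max_size=3))
    @settings(deadline=None, max_examples=25)
    def test_weighted_mode_is_linear_in_weights(self, w1, w2):
        d = np.array([[0.0, 1.0, 2.0], [2.0, 2.0, 0.0]])
        s12 = build_pgs(d, pgsw([a + b for a, b in zip(w1, w2)]))
        s1 = build_pgs(d, pgsw(w1))
        s2 = build_pgs(d, pgsw(w2))
        np.testing.assert_allclose(s12, s1 + s2, atol=1e-9)


class TestBenchmark:
    def test_f_is_squared_t(self, rng):
        score = rng.normal(size=300)
        exposure = 0.2 * score + rng.normal(size=300)
        d = benchmark_instrument(score, exposure)
        assert d.F == pytest.approx((d.beta_gx / d.se) ** 2)

    def test_recovers_simulated_instrument_effect(self):
        cfg = SimConfig(seed=31, n=20_000, hurdle=HurdleConfig(base_rate=1.0),
                        exposure_intercept=6.0)  # keep truncation inactive
        t = simulate_trios(cfg)
        d = benchmark_instrument(t.phenos["pgs_m"].to_numpy(),
                                 t.phenos["coffee_pre"].to_numpy())
        # exposure carries the weighted PGS with unit loading
        assert abs(d.beta_gx - 1.0) < 2 * d.se

    def test_null_f_chi2_calibration(self, rng):
        # independent score: P(F > 3.84) should be ~5%
        hits = 0
        reps = 400
        for _ in range(reps):
            score = rng.normal(size=150)
            exposure = rng.normal(size=150)
            if benchmark_instrument(score, exposure).F > 3.84:
                hits += 1
        rate = hits / reps
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / reps)

    def test_constant_score_rejected(self):
        with pytest.raises(ValueError):
            benchmark_instrument(np.ones(10), np.arange(10.0))


class TestI2gx:
    def test_hand_computed_example(self):
        assert i2_gx([0.1, 0.2, 0.3], [0.01] * 3) == pytest.approx(0.99)

    def test_identical_betas_truncate_to_zero(self):
        assert i2_gx([0.2, 0.2, 0.2], [0.01] * 3) == 0.0

    def test_larger_se_decreases_i2(self):
        lo = i2_gx([0.1, 0.2, 0.3], [0.1] * 3)
        hi = i2_gx([0.1, 0.2, 0.3], [0.01] * 3)
        assert lo < hi

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            i2_gx([0.1, 0.2], [0.01, 0.0])


class TestHarmonize:
    def test_effect_allele_swap_flips_outcome_beta(self):
        exp = make_sumstats(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = make_sumstats(["rs1"], ["G"], ["A"], [-0.05], [0.02])
        hs, log = harmonize(exp, out)
        assert hs.loc[0, "by"] == pytest.approx(0.05)
        assert ("rs1", "flipped", "effect-allele-swap") in log

    def test_palindromic_removed(self):
        exp = make_sumstats(["rs1", "rs2"], ["A", "A"], ["T", "G"], [0.1, 0.2], [0.01, 0.01])
        out = make_sumstats(["rs1", "rs2"], ["A", "A"], ["T", "G"], [0.1, 0.2], [0.01, 0.01])
        hs, log = harmonize(exp, out)
        assert list(hs["SNP"]) == ["rs2"]
        assert ("rs1", "removed", "palindromic") in log

    def test_unmatched_variant_logged(self):
        exp = make_sumstats(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = make_sumstats(["rs9"], ["A"], ["G"], [0.1], [0.01])
        hs, log = harmonize(exp, out)
        assert hs.empty
        assert ("rs1", "removed", "unmatched") in log

    def test_strand_complement_resolved(self):
        exp = make_sumstats(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = make_sumstats(["rs1"], ["T"], ["C"], [0.07], [0.02])
        hs, _ = harmonize(exp, out)
        assert hs.loc[0, "by"] == pytest.approx(0.07)

    def test_allele_mismatch_removed(self):
        exp = make_sumstats(["rs1"], ["A"], ["G"], [0.1], [0.01])
        out = make_sumstats(["rs1"], ["A"], ["C"], [0.1], [0.01])
        hs, log = harmonize(exp, out)
        assert hs.empty and ("rs1", "removed", "allele-mismatch") in log

    def test_idempotence(self):
        exp = make_sumstats(["rs1", "rs2"], ["A", "C"], ["G", "T"], [0.1, -0.2], [0.01, 0.02])
        out = make_sumstats(["rs1", "rs2"], ["G", "C"], ["A", "T"], [0.05, 0.04], [0.02, 0.02])
        hs1, _ = harmonize(exp, out)
        again_exp = hs1.rename(columns={"bx": "BETA", "se_x": "SE"})
        again_out = hs1.rename(columns={"by": "BETA", "se_y": "SE"})
        hs2, _ = harmonize(again_exp, again_out)
        pd.testing.assert_frame_equal(hs1, hs2)

    def test_duplicate_ids_rejected(self):
        exp = make_sumstats(["rs1", "rs1"], ["A", "A"], ["G", "G"], [0.1, 0.1], [0.01, 0.01])
        with pytest.raises(ValueError):
            harmonize(exp, exp)


class TestClump:
    def test_ld_partner_of_kept_row_dropped(self):
        rows = make_sumstats(["a", "b"], ["A", "C"], ["G", "T"], [0.1, 0.1],
                             [0.01, 0.01], P=[1e-10, 1e-9])
        ld = np.array([[1.0, 0.5], [0.5, 1.0]])
        kept = greedy_clump(rows, ld)
        assert list(kept["SNP"]) == ["a"]

    def test_independent_rows_all_kept(self):
        rows = make_sumstats(["a", "b", "c"], ["A"] * 3, ["G"] * 3,
                             [0.1] * 3, [0.01] * 3, P=[1e-10, 1e-9, 1e-12])
        kept = greedy_clump(rows, np.eye(3))
        assert sorted(kept["SNP"]) == ["a", "b", "c"]

    def test_p_threshold_applied_before_clumping(self):
        rows = make_sumstats(["a", "b"], ["A", "C"], ["G", "T"], [0.1, 0.1],
                             [0.01, 0.01], P=[1e-9, 1e-7])
        kept = greedy_clump(rows, np.eye(2), p_thresh=5e-8)
        assert list(kept["SNP"]) == ["a"]

    def test_row_order_invariance_with_tied_p(self):
        rows = make_sumstats(["b", "a"], ["A", "C"], ["G", "T"], [0.1, 0.1],
                             [0.01, 0.01], P=[1e-10, 1e-10])
        ld = np.array([[1.0, 0.5], [0.5, 1.0]])
        kept_fwd = greedy_clump(rows, ld)
        rev = rows.iloc[::-1].reset_index(drop=True)
        kept_rev = greedy_clump(rev, ld[::-1, ::-1])
        assert list(kept_fwd["SNP"]) == list(kept_rev["SNP"]) == ["a"]


class TestColliderScreen:
    def test_strong_hurdle_loading_detected(self):
        loadings = (2.0, 0, 0, 0, 0, 0, 0, 0)
        cfg = SimConfig(seed=41, n=20_000,
                        hurdle=HurdleConfig(base_rate=0.6, snp_loadings=loadings))
        t = simulate_trios(cfg)
        table, excluded = collider_screen(
            t.dosage_m, [v.id for v in cfg.variants],
            t.phenos["consumer"].to_numpy(), alpha=0.05,
        )
        assert cfg.variants[0].id in excluded

    def test_null_exclusion_rate_matches_alpha(self, rng):
        reps, n, hits, total = 120, 800, 0, 0
        for _ in range(reps):
            d = rng.binomial(2, 0.3, size=(n, 2)).astype(float)
            flag = rng.random(n) < 0.7
            _, excluded = collider_screen(d, ["a", "b"], flag, alpha=0.05)
            hits += len(excluded)
            total += 2
        rate = hits / total
        assert abs(rate - 0.05) < 3 * np.sqrt(0.05 * 0.95 / total)

    def test_alpha_zero_excludes_nothing(self, base_cohort, base_config):
        _, excluded = collider_screen(
            base_cohort.dosage_m, [v.id for v in base_config.variants],
            base_cohort.phenos["consumer"].to_numpy(), alpha=0.0,
        )
        assert excluded == []

    def test_constant_flag_rejected(self, base_cohort, base_config):
        with pytest.raises(ValueError):
            collider_screen(base_cohort.dosage_m,
                            [v.id for v in base_config.variants],
                            np.ones(base_config.n), 0.05)

    def test_logistic_link_agrees_on_exclusions(self):
        loadings = (2.0, 0, 0, 0, 0, 0, 0, 0)
        cfg = SimConfig(seed=43, n=10_000,
                        hurdle=HurdleConfig(base_rate=0.6, snp_loadings=loadings))
        t = simulate_trios(cfg)
        ids = [v.id for v in cfg.variants]
        flag = t.phenos["consumer"].to_numpy()
        _, ex_lin = collider_screen(t.dosage_m, ids, flag, 0.05, link="linear")
        _, ex_log = collider_screen(t.dosage_m, ids, flag, 0.05, link="logistic")
        assert ids[0] in ex_lin and ids[0] in ex_log


def test_pgs_weights_drop_excluded_variants():
    w = pgsw([0.1, 0.2, 0.3])
    reduced = w.drop({"v1"})
    assert reduced.variant_ids == ("v0", "v2")
    with pytest.raises(ValueError):
        w.drop({"v0", "v1", "v2"})
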