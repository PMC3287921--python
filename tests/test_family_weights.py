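"""Sib-pair scoring, standardization and top-quartile truncation."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import famburden as fb
from famburden.family_weights import panel_maf

from conftest import oracle_weights, random_small_panel

CFG = fb.PairScoreConfig()


class TestPairGenotypeScore:
    def test_common_variant_always_zero(self):
        for g1, g2 in [(0, 0), (1, 2), (2, 2)]:
            assert fb.pair_genotype_score(g1, g2, fb.CONCORDANT_AFFECTED, 0, CFG, is_rare=False) == 0.0

    @pytest.mark.parametrize(
        "g1,g2,K,expected",
        [
            (0, 0, 0, 0.0),  # neither carries
            (2, 1, 5, 2.0),  # both carry
            (1, 0, 0, 1.0),  # ambiguous, no other rare alleles
            (1, 0, 3, 0.25),  # ambiguous, discounted by K
            (0, 2, 1, 0.5),
        ],
    )
    def test_affected_pair_cases(self, g1, g2, K, expected):
        assert fb.pair_genotype_score(g1, g2, fb.CONCORDANT_AFFECTED, K, CFG) == expected

    @pytest.mark.parametrize(
        "g1,g2,K,expected",
        [
            (1, 0, 9, 2.0),  # affected carries, unaffected does not
            (0, 0, 0, 0.0),  # affected does not carry
            (0, 2, 0, 0.0),
            (1, 1, 0, 1.0),  # both carry: ambiguous
            (2, 1, 3, 0.25),
        ],
    )
    def test_discordant_pair_cases(self, g1, g2, K, expected):
        assert fb.pair_genotype_score(g1, g2, fb.DISCORDANT, K, CFG) == expected

    def test_invalid_pair_type(self):
        with pytest.raises(ValueError, match="pair_type"):
            fb.pair_genotype_score(1, 1, "cousins", 0, CFG)


class TestCountOtherRareCarried:
    @pytest.mark.parametrize(
        "row,j,rare,expected",
        [
            ([0, 0, 0, 0], 0, [1, 1, 1, 1], 0),
            ([1, 0, 2, 1], 0, [1, 1, 1, 1], 2),
            ([1, 1], 0, [True, False], 0),  # common variant not counted
            ([1, 1, 1], 1, [1, 1, 1], 2),
        ],
    )
    def test_hand_counts(self, row, j, rare, expected):
        assert fb.count_other_rare_carried(np.array(row), j, np.array(rare, bool)) == expected


class TestMeanPairScores:
    def test_all_zero_genotypes(self):
        dos = np.zeros((2, 4))
        pairs = fb.SibPairSet([fb.SibPair(0, 1, fb.CONCORDANT_AFFECTED)])
        np.testing.assert_array_equal(
            fb.mean_pair_scores(dos, pairs, np.ones(4, bool), CFG), np.zeros(4)
        )

    def test_all_carriers_mean_is_score_both(self):
        dos = np.ones((4, 1))
        pairs = fb.SibPairSet(
            [fb.SibPair(0, 1, fb.CONCORDANT_AFFECTED), fb.SibPair(2, 3, fb.CONCORDANT_AFFECTED)]
        )
        s = fb.mean_pair_scores(dos, pairs, np.ones(1, bool), CFG)
        assert s[0] == CFG.score_both

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            fb.mean_pair_scores(np.zeros((0, 2)), fb.SibPairSet([]), np.ones(2, bool), CFG)

    def test_mixed_pair_types_rejected(self):
        pairs = fb.SibPairSet(
            [fb.SibPair(0, 1, fb.CONCORDANT_AFFECTED), fb.SibPair(2, 3, fb.DISCORDANT)]
        )
        with pytest.raises(ValueError, match="single pair_type"):
            fb.mean_pair_scores(np.zeros((4, 2)), pairs, np.ones(2, bool), CFG)

    @pytest.mark.parametrize("pair_type", [fb.CONCORDANT_AFFECTED, fb.DISCORDANT])
    def test_matches_scalar_enumeration_on_toy_panel(self, pair_type):
        rng = np.random.default_rng(5)
        dos = rng.integers(0, 3, size=(6, 4)).astype(float)
        rare = np.array([True, True, False, True])
        pairs = fb.SibPairSet([fb.SibPair(2 * i, 2 * i + 1, pair_type) for i in range(3)])
        got = fb.mean_pair_scores(dos, pairs, rare, CFG)
        for j in range(4):
            expected = 0.0
            for p in pairs:
                if pair_type == fb.CONCORDANT_AFFECTED:
                    c1, c2 = dos[p.sib1, j] > 0, dos[p.sib2, j] > 0
                    krow = p.sib2 if (c1 and not c2) else p.sib1
                else:
                    krow = p.sib1
                K = fb.count_other_rare_carried(dos[krow], j, rare)
                expected += fb.pair_genotype_score(
                    dos[p.sib1, j], dos[p.sib2, j], pair_type, K, CFG, is_rare=bool(rare[j])
                )
            assert got[j] == pytest.approx(expected / 3)

    def test_invariant_under_pair_permutation(self):
        rng = np.random.default_rng(11)
        dos = rng.integers(0, 3, size=(10, 5)).astype(float)
        rare = np.ones(5, bool)
        plist = [fb.SibPair(2 * i, 2 * i + 1, fb.CONCORDANT_AFFECTED) for i in range(5)]
        a = fb.mean_pair_scores(dos, fb.SibPairSet(plist), rare, CFG)
        b = fb.mean_pair_scores(dos, fb.SibPairSet(plist[::-1]), rare, CFG)
        np.testing.assert_allclose(a, b)


class TestStandardizeScores:
    def test_zero_mean_score_gives_zero(self):
        b = fb.standardize_scores(np.array([0.0]), np.array([0.005]), CFG)
        assert b[0] == 0.0

    def test_direct_evaluation(self):
        b = fb.standardize_scores(np.array([0.5]), np.array([0.01]), CFG)
        assert b[0] == pytest.approx(0.5 / np.sqrt(0.01 * 0.99), rel=1e-12)

    def test_monomorphic_site_no_division_error(self):
        b = fb.standardize_scores(np.array([0.3]), np.array([0.0]), CFG)
        assert b[0] == 0.0

    def test_common_variant_zeroed(self):
        b = fb.standardize_scores(np.array([0.3]), np.array([0.2]), CFG)
        assert b[0] == 0.0


class TestTruncateToTopQuartile:
    def test_eight_variants_two_slots(self):
        b = np.array([4.0, 3.0, 2.0, 1.0, 0.0, 0.0, 0.0, 0.0])
        w, rank = fb.truncate_to_top_quartile(b, CFG)
        np.testing.assert_array_equal(w, [4.0, 3.0, 0, 0, 0, 0, 0, 0])
        assert rank[0] == 1 and rank[1] == 2

    def test_all_zero_scores_keep_nothing(self):
        w, _ = fb.truncate_to_top_quartile(np.zeros(8), CFG)
        assert (w == 0).all()

    def test_single_eligible_variant(self):
        w, _ = fb.truncate_to_top_quartile(np.array([2.5]), CFG)
        assert w[0] == 2.5

    def test_boundary_ties_broken_by_ascending_index(self):
        b = np.array([3.0, 2.0, 2.0, 2.0, 1.0, 1.0, 1.0, 1.0])
        w, _ = fb.truncate_to_top_quartile(b, CFG)  # 2 slots
        np.testing.assert_array_equal(w > 0, [True, True, False, False, False, False, False, False])

    def test_ineligible_never_weighted(self):
        b = np.array([5.0, 1.0])
        w, rank = fb.truncate_to_top_quartile(b, CFG, eligible=np.array([False, True]))
        assert w[0] == 0.0 and w[1] == 1.0
        assert rank[0] == 0


class TestComputeWeights:
    def test_only_common_variants_all_zero(self):
        fam = fb.GenotypeMatrix(["a", "b"], ["v1", "v2"], np.array([[1, 1], [1, 0]]))
        cc = fb.GenotypeMatrix(
            ["c1", "c2"], ["v1", "v2"], np.array([[1, 1], [1, 1]])
        )  # MAF 0.5 both
        pairs = fb.SibPairSet([fb.SibPair(0, 1, fb.CONCORDANT_AFFECTED)])
        vw = fb.compute_weights(fam, pairs, cc, np.array([0, 1]))
        assert vw.n_weighted == 0 and (vw.w == 0).all()

    def test_maf_just_above_alpha_excluded(self):
        # MAF 0.011 > alpha = 0.01: never weighted even with perfect sharing
        n_cc = 1000
        cc_counts = np.zeros((n_cc, 1), dtype=np.int8)
        cc_counts[:22, 0] = 1  # 22/2000 = 0.011
        cc = fb.GenotypeMatrix([f"c{k}" for k in range(n_cc)], ["v1"], cc_counts)
        fam = fb.GenotypeMatrix(["a", "b"], ["v1"], np.array([[1], [1]]))
        pairs = fb.SibPairSet([fb.SibPair(0, 1, fb.CONCORDANT_AFFECTED)])
        vw = fb.compute_weights(fam, pairs, cc, np.array([0]))
        assert vw.maf[0] == pytest.approx(0.011)
        assert vw.w[0] == 0.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("pair_type", [fb.CONCORDANT_AFFECTED, fb.DISCORDANT])
    def test_matches_exhaustive_oracle(self, seed, pair_type):
        rng = np.random.default_rng(seed)
        fam_counts, plist, cc_counts = random_small_panel(rng, pair_type)
        fam = fb.GenotypeMatrix(
            [f"f{k}" for k in range(fam_counts.shape[0])],
            [f"v{j}" for j in range(fam_counts.shape[1])],
            fam_counts,
        )
        cc = fb.GenotypeMatrix(
            [f"c{k}" for k in range(cc_counts.shape[0])], fam.variant_ids, cc_counts
        )
        pairs = fb.SibPairSet([fb.SibPair(*p) for p in plist])
        vw = fb.compute_weights(fam, pairs, cc, np.arange(fam.n_variants))
        maf, s_bar, b, w = oracle_weights(fam_counts, plist, cc_counts)
        np.testing.assert_allclose(vw.maf, maf, atol=1e-15)
        np.testing.assert_allclose(vw.s_bar, s_bar, atol=1e-12)
        np.testing.assert_allclose(vw.b, b, atol=1e-12)
        np.testing.assert_allclose(vw.w, w, atol=1e-12)

    @given(c=st.floats(min_value=0.1, max_value=10.0))
    @settings(deadline=None, max_examples=25, derandomize=True)
    def test_scale_equivariance_of_case_values(self, c):
        """Scaling all three case values by c scales b and positive w by c
        and leaves the retained set unchanged."""
        rng = np.random.default_rng(77)
        fam_counts, plist, cc_counts = random_small_panel(rng, fb.CONCORDANT_AFFECTED)
        fam = fb.GenotypeMatrix(
            [f"f{k}" for k in range(fam_counts.shape[0])],
            [f"v{j}" for j in range(fam_counts.shape[1])],
            fam_counts,
        )
        cc = fb.GenotypeMatrix(
            [f"c{k}" for k in range(cc_counts.shape[0])], fam.variant_ids, cc_counts
        )
        pairs = fb.SibPairSet([fb.SibPair(*p) for p in plist])
        cols = np.arange(fam.n_variants)
        base = fb.compute_weights(fam, pairs, cc, cols)
        scaled_cfg = fb.PairScoreConfig(
            score_both=2.0 * c,
            score_neither=0.0,
            score_mixed_rule=lambda K: c / (1.0 + K),
        )
        scaled = fb.compute_weights(fam, pairs, cc, cols, scaled_cfg)
        np.testing.assert_allclose(scaled.b, c * base.b, rtol=1e-10)
        np.testing.assert_allclose(scaled.w, c * base.w, rtol=1e-10)
        np.testing.assert_array_equal(scaled.w > 0, base.w > 0)


def test_panel_maf_caps_at_half():
    dos = np.full((4, 1), 2.0)
    assert panel_maf(dos)[0] == 0.5
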