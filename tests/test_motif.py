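import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from mhcmotif import (
    ALPHABET,
    MotifCaller,
    MotifConfig,
    ScoringMatrix,
    build_motif,
    classify_anchor,
    classify_nonanchor,
    identify_anchors,
    planted_anchor_matrix,
    spread_factors,
)
from mhcmotif.motif import CLASSES, DELETERIOUS, PREFERRED, TOLERATED

columns = hnp.arrays(
    float,
    20,
    elements=st.floats(min_value=-5, max_value=5, allow_nan=False, width=32),
)


def _matrix(values, allele="TEST"):
    return ScoringMatrix(allele=allele, values=np.asarray(values, float), intercept=2.0)


class TestSpreadFactors:
    def test_constant_column_has_zero_spread(self, zero_matrix):
        assert np.all(spread_factors(zero_matrix).sf == 0.0)

    def test_max_minus_min(self):
        values = np.zeros((20, 9))
        values[0, 3], values[5, 3] = 0.8, -1.2
        assert spread_factors(_matrix(values)).sf[3] == pytest.approx(2.0)

    def test_agrees_with_per_column_scan(self, random_matrix):
        sf = spread_factors(random_matrix).sf
        for p in range(9):
            col = random_matrix.values[:, p]
            assert sf[p] == pytest.approx(max(col) - min(col))

    def test_invariant_to_column_shift(self, random_matrix):
        shifted = random_matrix.values.copy()
        shifted[:, 4] += 7.3
        np.testing.assert_allclose(
            spread_factors(_matrix(shifted)).sf, spread_factors(random_matrix).sf
        )


class TestIdentifyAnchors:
    def test_canonical_p2_p9_pattern(self):
        sf = np.array([0.2, 2.5, 0.3, 0.1, 0.2, 0.3, 0.2, 0.1, 2.2])
        assert identify_anchors(sf) == {2, 9}

    def test_uniform_small_spread_fails_absolute_floor(self):
        assert identify_anchors(np.full(9, 0.5)) == set()

    def test_all_zero_profile_yields_empty_set(self):
        assert identify_anchors(np.zeros(9)) == set()

    def test_relative_threshold_prunes_moderate_columns(self):
        # 1.1 passes sf_abs but fails 0.5 * 3.0
        sf = np.array([0.1, 3.0, 1.1, 0.1, 0.1, 0.1, 0.1, 0.1, 0.1])
        assert identify_anchors(sf) == {2}

    def test_thresholds_are_closed_boundaries(self):
        sf = np.array([1.0, 2.0, 0.0])
        assert identify_anchors(sf, MotifConfig(sf_abs=1.0, sf_rel=0.5)) == {1, 2}

    @given(hnp.arrays(float, 9, elements=st.floats(0, 5, width=32)), st.floats(1.1, 3))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_scaling_columns_up_never_shrinks_anchor_set(self, sf, k):
        before = identify_anchors(sf)
        assert before <= identify_anchors(sf * k)


class TestClassifyAnchor:
    def test_low_value_residues_preferred(self):
        col = np.zeros(20)
        col[ALPHABET.index("L")] = -2.0
        col[ALPHABET.index("M")] = -1.7
        classes = classify_anchor(col)
        assert classes["L"] == classes["M"] == PREFERRED
        assert all(
            classes[aa] == DELETERIOUS for aa in ALPHABET if aa not in ("L", "M")
        )

    def test_tolerated_band_between_pref_and_tol(self):
        col = np.full(20, 2.0)
        col[0], col[1], col[2] = 0.0, 0.7, 1.2  # A best, C within 1.0, D beyond
        classes = classify_anchor(col)
        assert classes["A"] == PREFERRED
        assert classes["C"] == TOLERATED
        assert classes["D"] == DELETERIOUS

    @given(columns)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_best_residue_always_preferred(self, col):
        if col.max() - col.min() <= 0:
            return
        classes = classify_anchor(col)
        assert classes[ALPHABET[int(np.argmin(col))]] == PREFERRED

    @given(columns, st.floats(-3, 3, allow_nan=False))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_shift_invariance(self, col, c):
        if col.max() - col.min() <= 0:
            return
        assert classify_anchor(col) == classify_anchor(col + c)

    def test_flat_column_is_an_error(self):
        with pytest.raises(ValueError, match="flat"):
            classify_anchor(np.zeros(20))


class TestClassifyNonanchor:
    def test_flat_column_all_tolerated(self):
        assert set(classify_nonanchor(np.zeros(20)).values()) == {TOLERATED}

    def test_single_outlier_above_median_deleterious(self):
        col = np.zeros(20)
        col[ALPHABET.index("W")] = 1.0
        classes = classify_nonanchor(col)
        assert classes["W"] == DELETERIOUS
        assert all(classes[aa] == TOLERATED for aa in ALPHABET if aa != "W")

    @given(columns)
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_agrees_with_direct_inequalities(self, col):
        cfg = MotifConfig()
        m = np.median(col)
        classes = classify_nonanchor(col, cfg)
        for aa, v in zip(ALPHABET, col):
            if v - m >= cfg.delta_del:
                assert classes[aa] == DELETERIOUS
            elif m - v >= cfg.delta_pref_nonanchor:
                assert classes[aa] == PREFERRED
            else:
                assert classes[aa] == TOLERATED

    def test_median_is_mean_of_middle_order_statistics(self):
        col = np.arange(20, dtype=float)  # median = 9.5
        classes = classify_nonanchor(col, MotifConfig(delta_del=10.0))
        assert classes[ALPHABET[9]] == PREFERRED  # 9.5 - 9 >= 0.5


class TestBuildMotif:
    def test_planted_anchors_and_best_residues_recovered(self):
        truth = planted_anchor_matrix(seed=13)
        motif = build_motif(_matrix(truth))
        assert motif.anchors == {2, 9}
        for p in (2, 9):
            best = ALPHABET[int(np.argmin(truth[:, p - 1]))]
            assert best in motif.preferred(p)

    def test_zero_matrix_has_no_anchors_all_tolerated(self, zero_matrix):
        motif = build_motif(zero_matrix)
        assert motif.anchors == set()
        for pc in motif.positions:
            assert set(pc.classes.values()) == {TOLERATED}

    def test_shared_anchor_across_8mer_and_9mer_matrices(self):
        # H-2-Kb-like pattern: P3 anchors both lengths; the C-terminal
        # anchor moves from P5 (8-mer) to P9 (9-mer).
        m8 = _matrix(planted_anchor_matrix(length=8, anchors=(3, 5), seed=3))
        m9 = _matrix(planted_anchor_matrix(length=9, anchors=(3, 9), seed=3))
        assert 3 in build_motif(m8).anchors
        assert 3 in build_motif(m9).anchors
        assert build_motif(m8).anchors == {3, 5}
        assert build_motif(m9).anchors == {3, 9}

    def test_classes_partition_alphabet_everywhere(self, random_matrix):
        motif = build_motif(random_matrix)
        for pc in motif.positions:
            total = sum(len(pc.residues(c)) for c in CLASSES)
            assert total == 20
            assert set().union(*(pc.residues(c) for c in CLASSES)) == set(ALPHABET)

    @given(hnp.arrays(float, (20, 9), elements=st.floats(-3, 3, width=32)),
           hnp.arrays(float, 9, elements=st.floats(-5, 5, width=32)))
    @settings(derandomize=True, max_examples=40, deadline=None)
    def test_pipeline_invariant_under_per_column_shifts(self, values, shifts):
        m1 = build_motif(_matrix(values))
        m2 = build_motif(_matrix(values + shifts))
        assert m1.anchors == m2.anchors
        for pc1, pc2 in zip(m1.positions, m2.positions):
            assert pc1.classes == pc2.classes

    def test_deterministic_for_fixed_input(self, random_matrix):
        a, b = build_motif(random_matrix), build_motif(random_matrix)
        assert a.anchors == b.anchors
        assert [pc.classes for pc in a.positions] == [pc.classes for pc in b.positions]


class TestMotifCaller:
    def test_transform_matches_build_motif(self, random_matrix):
        caller = MotifCaller(sf_abs=0.8)
        via_caller = caller.transform(random_matrix)
        direct = build_motif(random_matrix, MotifConfig(sf_abs=0.8))
        assert via_caller.anchors == direct.anchors

    def test_get_set_params_protocol(self):
        caller = MotifCaller().set_params(sf_rel=0.4)
        assert caller.get_params()["sf_rel"] == 0.4
        assert caller.config().sf_rel == 0.4
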