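"""Normalization, differential abundance, fold changes, clustering, overlaps."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as st
from hypothesis import given, settings
from hypothesis import strategies as hst

from protnet import (
    CountMatrix,
    cluster_profiles,
    detection_overlap,
    differential_abundance,
    fold_change,
    normalize_total_signal,
    scale_to_0_100,
    select_daps,
    two_group_f,
)


class TestNormalizeTotalSignal:
    def test_two_sample_scaling_factors(self):
        counts = pd.DataFrame({"s1": [4, 6], "s2": [8, 12]}, index=["p1", "p2"])
        design = pd.DataFrame(
            {"condition": ["A", "A"], "batch": [1, 1], "replicate": [1, 2]},
            index=["s1", "s2"],
        )
        out = normalize_total_signal(CountMatrix(counts, design))
        # totals 10 and 20 -> factors 1.5 and 0.75, both columns sum to 15
        assert np.allclose(out.counts["s1"], [6.0, 9.0])
        assert np.allclose(out.counts["s2"], [6.0, 9.0])
        assert np.allclose(out.counts.sum(axis=0), 15.0)

    def test_uniform_totals_identity(self, tiny_matrix):
        equalized = tiny_matrix.counts * (
            tiny_matrix.counts.sum().mean() / tiny_matrix.counts.sum()
        )
        m = CountMatrix(equalized, tiny_matrix.design)
        out = normalize_total_signal(m)
        assert np.allclose(out.counts.to_numpy(), equalized.to_numpy())

    def test_column_totals_equal_and_order_preserved(self, tiny_matrix):
        out = normalize_total_signal(tiny_matrix)
        totals = out.counts.sum(axis=0).to_numpy()
        assert np.allclose(totals, totals[0], rtol=1e-9)
        assert list(out.counts.index) == list(tiny_matrix.counts.index)
        assert list(out.counts.columns) == list(tiny_matrix.counts.columns)
        assert out.normalized

    def test_all_zero_sample_errors_with_name(self, tiny_matrix):
        counts = tiny_matrix.counts.copy()
        counts["B_r3"] = 0
        with pytest.raises(ValueError, match="B_r3"):
            normalize_total_signal(CountMatrix(counts, tiny_matrix.design))

    def test_double_normalization_rejected(self, tiny_matrix):
        out = normalize_total_signal(tiny_matrix)
        with pytest.raises(ValueError, match="already normalized"):
            normalize_total_signal(out)


class TestScaleTo0100:
    @pytest.mark.parametrize(
        "values,expected",
        [
            ([2, 4, 8, 0], [25, 50, 100, 0]),
            ([7], [100]),
            ([3, 3, 3], [100, 100, 100]),
            ([0, 0], [0, 0]),
        ],
    )
    def test_examples(self, values, expected):
        assert np.allclose(scale_to_0_100(values), expected)


class TestTwoGroupF:
    def test_worked_example(self):
        f, p = two_group_f([1, 2, 3], [4, 5, 6])
        assert f == pytest.approx(13.5, abs=1e-12)
        # two-sided pooled t-test oracle at df (1, 4)
        t_p = st.ttest_ind([1, 2, 3], [4, 5, 6]).pvalue
        assert p == pytest.approx(t_p, abs=1e-12)
        assert p == pytest.approx(0.021, abs=5e-4)

    def test_identical_groups(self):
        f, p = two_group_f([2.0, 3.0, 4.0], [2.0, 3.0, 4.0])
        assert f == 0.0

    def test_zero_variance_equal_means(self):
        assert two_group_f([2, 2], [2, 2]) == (0.0, 1.0)

    def test_perfect_separation_sentinel(self):
        f, p = two_group_f([1, 1], [2, 2])
        assert np.isinf(f) and p == 0.0

    def test_equals_t_squared_on_random_inputs(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            a = rng.normal(size=rng.integers(2, 12))
            b = rng.normal(size=rng.integers(2, 12))
            f, p = two_group_f(a, b)
            t = st.ttest_ind(a, b)
            assert f == pytest.approx(t.statistic**2, rel=1e-10)
            assert p == pytest.approx(t.pvalue, rel=1e-10)

    @given(hst.floats(min_value=1e-3, max_value=1e3))
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, c):
        a, b = np.array([1.0, 2.0, 5.0]), np.array([3.0, 7.0, 8.0])
        f0, p0 = two_group_f(a, b)
        f1, p1 = two_group_f(c * a, c * b)
        assert f1 == pytest.approx(f0, rel=1e-9)
        assert p1 == pytest.approx(p0, rel=1e-9)


class TestFoldChange:
    def test_natural_log(self):
        assert fold_change(np.e, 1.0) == pytest.approx(1.0)

    def test_exclusive_caps(self):
        assert fold_change(3.2, 0.0) == 5.0
        assert fold_change(0.0, 3.2) == -5.0

    def test_equal_values_zero(self):
        assert fold_change(7.7, 7.7) == 0.0

    def test_both_zero_errors(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 0.0)

    def test_clipped_to_cap(self):
        assert fold_change(1e6, 1e-6) == 5.0

    @given(
        hst.floats(min_value=0, max_value=1e4),
        hst.floats(min_value=0, max_value=1e4),
    )
    @settings(deadline=None, max_examples=200)
    def test_antisymmetry(self, a, b):
        if a == 0 and b == 0:
            return
        assert fold_change(a, b) == pytest.approx(-fold_change(b, a), abs=1e-12)


class TestDifferentialAbundance:
    def test_requires_normalized(self, tiny_matrix):
        with pytest.raises(ValueError, match="normalize"):
            differential_abundance(tiny_matrix, ("A", "B"))

    def test_unknown_condition(self, tiny_matrix):
        with pytest.raises(ValueError, match="condition"):
            differential_abundance(normalize_total_signal(tiny_matrix), ("A", "Z"))

    def test_exclusive_flag_and_cap(self, tiny_matrix):
        recs = {r.protein_id: r for r in
                differential_abundance(normalize_total_signal(tiny_matrix), ("A", "B"))}
        # p3 has zero counts in condition A only
        assert recs["p3"].exclusive == "b_only"
        assert recs["p3"].ln_fc == -5.0
        swapped = {r.protein_id: r for r in
                   differential_abundance(normalize_total_signal(tiny_matrix), ("B", "A"))}
        assert swapped["p3"].exclusive == "a_only"
        assert swapped["p3"].ln_fc == 5.0

    def test_lnfc_antisymmetric_across_swap(self, tiny_matrix):
        norm = normalize_total_signal(tiny_matrix)
        ab = {r.protein_id: r.ln_fc for r in differential_abundance(norm, ("A", "B"))}
        ba = {r.protein_id: r.ln_fc for r in differential_abundance(norm, ("B", "A"))}
        for pid in ab:
            assert ab[pid] == pytest.approx(-ba[pid], abs=1e-12)

    def test_all_zero_proteins_dropped(self, tiny_matrix):
        counts = tiny_matrix.counts.copy()
        counts.loc["p_zero"] = 0
        norm = normalize_total_signal(CountMatrix(counts, tiny_matrix.design))
        ids = {r.protein_id for r in differential_abundance(norm, ("A", "B"))}
        assert "p_zero" not in ids


class TestSelectDaps:
    def test_thresholds(self):
        from protnet import DifferentialRecord

        recs = [
            DifferentialRecord("a", ("A", "B"), 1, 2, 4.9, 0.001, 0.5),
            DifferentialRecord("b", ("A", "B"), 1, 2, 13.5, 0.021, 0.5),
            DifferentialRecord("c", ("A", "B"), 1, 2, 20.0, 0.005, 0.5),
        ]
        out = select_daps(recs)
        assert list(out["protein"]) == ["c"]  # a fails F, b fails p
        strict = select_daps(recs, p_max=0.001)
        assert strict.empty

    def test_empty_input(self):
        assert select_daps([]).empty


class TestClusterProfiles:
    def test_two_blocks_merge_last(self):
        counts = pd.DataFrame(
            [[10, 10, 10, 0, 0, 0], [11, 10, 10, 0, 0, 0],
             [0, 0, 0, 9, 9, 9], [0, 0, 0, 9, 10, 9]],
            index=["a1", "a2", "b1", "b2"],
            columns=[f"s{i}" for i in range(6)],
        )
        design = pd.DataFrame(
            {"condition": ["A"] * 6, "batch": [1] * 6, "replicate": range(1, 7)},
            index=counts.columns,
        )
        dend = cluster_profiles(CountMatrix(counts, design))
        # final merge joins the two 2-leaf blocks: its children are internal nodes
        last = dend.linkage[-1]
        assert last[0] >= 4 and last[1] >= 4
        assert np.all(np.diff(dend.heights) >= 0)

    def test_duplicate_rows_merge_at_zero(self):
        counts = pd.DataFrame(
            [[1, 2, 3], [1, 2, 3], [9, 9, 9]],
            index=["a", "b", "c"], columns=["s1", "s2", "s3"],
        )
        design = pd.DataFrame(
            {"condition": ["A"] * 3, "batch": [1] * 3, "replicate": [1, 2, 3]},
            index=counts.columns,
        )
        dend = cluster_profiles(CountMatrix(counts, design))
        assert dend.heights[0] == 0.0

    def test_single_leaf(self):
        counts = pd.DataFrame([[1, 2]], index=["a"], columns=["s1", "s2"])
        design = pd.DataFrame(
            {"condition": ["A", "A"], "batch": [1, 1], "replicate": [1, 2]},
            index=counts.columns,
        )
        dend = cluster_profiles(CountMatrix(counts, design))
        assert dend.linkage is None
        assert dend.to_newick() == "a;"

    def test_newick_roundtrip_leaf_names(self, tiny_matrix):
        dend = cluster_profiles(tiny_matrix)
        nwk = dend.to_newick()
        for pid in tiny_matrix.protein_ids:
            assert pid in nwk
        assert nwk.endswith(";")


class TestDetectionOverlap:
    def test_two_set_regions(self, tiny_matrix):
        ov = detection_overlap(
            tiny_matrix, groups={"S1": {"A", "B"}, "S2": {"B", "C"}}
        )
        assert ov.region("S1") == 1
        assert ov.region("S2") == 1
        assert ov.region("S1", "S2") == 1

    def test_identical_sets_full_intersection(self, tiny_matrix):
        ov = detection_overlap(tiny_matrix, groups={"X": {"A", "B"}, "Y": {"A", "B"}})
        assert ov.region("X") == 0 and ov.region("Y") == 0
        assert ov.region("X", "Y") == 2

    def test_core_excludes_any_zero(self, tiny_matrix):
        ov = detection_overlap(tiny_matrix)
        # p3 is zero in all A samples, so out of the core; p1/p2/p4 always > 0
        assert ov.core == {"p1", "p2", "p4"}

    def test_condition_sets(self, tiny_matrix):
        ov = detection_overlap(tiny_matrix)
        assert ov.region("A", "B") == 3  # p1, p2, p4 detected in both
        assert ov.region("B") == 1  # p3 only in B


class TestCountMatrixContracts:
    def test_duplicate_protein_rejected(self, tiny_matrix):
        counts = pd.concat([tiny_matrix.counts, tiny_matrix.counts.iloc[[0]]])
        with pytest.raises(ValueError, match="duplicate protein"):
            CountMatrix(counts, tiny_matrix.design)

    def test_design_mismatch_rejected(self, tiny_matrix):
        with pytest.raises(ValueError, match="mismatch"):
            CountMatrix(tiny_matrix.counts, tiny_matrix.design.iloc[:-1])

    def test_negative_counts_rejected(self, tiny_matrix):
        counts = tiny_matrix.counts.copy()
        counts.iloc[0, 0] = -1
        with pytest.raises(ValueError, match="negative"):
            CountMatrix(counts, tiny_matrix.design)
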