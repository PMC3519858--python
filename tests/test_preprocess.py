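"""Fold-change computation, probe collapse, cross-study quantile
normalization and matrix combination."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ranetkit.errors import ConfigurationError, EmptySelectionError
from ranetkit.preprocess import (
    ExpressionStudy,
    FoldChangeMatrix,
    collapse_probes_to_genes,
    combine_matrices,
    compute_fold_changes,
    cross_study_quantile_normalize,
    _quantile_normalize_vectors,
)


def fc_matrix(study_id, data, condition="disease_primary", level="gene"):
    return FoldChangeMatrix(
        study_id=study_id, values=pd.DataFrame(data), condition=condition, level=level
    )


class TestComputeFoldChanges:
    def test_subtracts_normal_median_per_probe(self, tiny_study):
        fc = compute_fold_changes(tiny_study, "disease_primary")
        # probe p1: normals [5,6,7] median 6 -> d1=8 gives 2, d2=6 gives 0
        assert fc.values.loc["p1", "d1"] == pytest.approx(2.0)
        assert fc.values.loc["p1", "d2"] == pytest.approx(0.0)
        # probe p2: normals [10,11,12] median 11
        assert fc.values.loc["p2", "d2"] == pytest.approx(2.0)

    def test_conditions_give_separate_matrices(self, tiny_study):
        ra = compute_fold_changes(tiny_study, "disease_primary")
        oa = compute_fold_changes(tiny_study, "disease_comparator")
        assert ra.sample_ids == ["d1", "d2"]
        assert oa.sample_ids == ["o1"]
        assert oa.values.loc["p1", "o1"] == pytest.approx(3.0)

    def test_no_normals_is_configuration_error(self, tiny_study):
        conds = {s: ("disease_primary" if c == "normal" else c) for s, c in tiny_study.conditions.items()}
        study = ExpressionStudy("S1", tiny_study.values, conds)
        with pytest.raises(ConfigurationError):
            compute_fold_changes(study, "disease_primary")

    def test_empty_target_selection_raises(self, tiny_study):
        with pytest.raises(EmptySelectionError):
            compute_fold_changes(tiny_study, "treated")


class TestCollapseProbes:
    def make(self, rows, samples=("s1", "s2")):
        vals = pd.DataFrame(rows, columns=list(samples)).T
        vals = pd.DataFrame(dict(zip([f"pr{i}" for i in range(len(rows))], rows))).T
        vals.columns = list(samples)
        return FoldChangeMatrix("S", vals, "disease_primary", level="probe")

    def test_single_probe_row_unchanged(self):
        fc = self.make([[1.0, -0.5]])
        out, report = collapse_probes_to_genes(fc, {"pr0": "GA"})
        assert list(out.values.loc["GA"]) == [1.0, -0.5]
        assert report["n_unmapped_dropped"] == 0

    def test_keeps_probe_with_largest_absolute_fold_change(self):
        # pr0 peaks at |1.5|, pr1 at |-2.5|; the 2.5-magnitude row wins whole
        fc = self.make([[1.5, 0.2], [0.1, -2.5]])
        out, _ = collapse_probes_to_genes(fc, {"pr0": "GA", "pr1": "GA"})
        assert list(out.values.loc["GA"]) == [0.1, -2.5]

    def test_tie_breaks_to_smallest_probe_id(self):
        fc = self.make([[2.0, 0.0], [0.0, 2.0]])
        out, _ = collapse_probes_to_genes(fc, {"pr1": "GA", "pr0": "GA"})
        assert list(out.values.loc["GA"]) == [2.0, 0.0]  # pr0 wins the tie

    def test_disjoint_genes_ordered_by_gene_id(self):
        fc = self.make([[1.0, 0.0], [0.0, 1.0]])
        out, _ = collapse_probes_to_genes(fc, {"pr0": "GB", "pr1": "GA"})
        assert list(out.values.index) == ["GA", "GB"]

    def test_unmapped_probes_dropped_and_counted(self):
        fc = self.make([[1.0, 0.0], [0.0, 1.0], [3.0, 3.0]])
        out, report = collapse_probes_to_genes(fc, {"pr0": "GA"})
        assert report["n_unmapped_dropped"] == 2
        assert list(out.values.index) == ["GA"]

    def test_empty_map_and_all_unmapped_raise(self):
        fc = self.make([[1.0, 0.0]])
        with pytest.raises(ValueError):
            collapse_probes_to_genes(fc, {})
        with pytest.raises(EmptySelectionError):
            collapse_probes_to_genes(fc, {"nope": "GA"})

    @given(
        st.lists(
            st.lists(st.floats(-5, 5, allow_nan=False, width=32), min_size=3, max_size=3),
            min_size=1,
            max_size=8,
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_collapse_never_increases_rows_and_preserves_columns(self, rows):
        fc = self.make(rows, samples=("a", "b", "c"))
        pmap = {f"pr{i}": f"G{i % 3}" for i in range(len(rows))}
        out, _ = collapse_probes_to_genes(fc, pmap)
        assert len(out.values) <= len(rows)
        assert list(out.values.columns) == ["a", "b", "c"]


class TestQuantileNormalize:
    def test_two_vectors_mean_of_order_statistics(self):
        m1 = fc_matrix("A", {"x": [1.0], "y": [2.0], "z": [3.0]})
        m2 = fc_matrix("B", {"x": [4.0], "y": [5.0], "z": [6.0]})
        out = cross_study_quantile_normalize([m1, m2])
        assert list(out[0].values.iloc[0]) == pytest.approx([2.5, 3.5, 4.5])
        assert list(out[1].values.iloc[0]) == pytest.approx([2.5, 3.5, 4.5])

    def test_identical_matrices_unchanged(self):
        mats = [fc_matrix(f"S{i}", {"x": [0.5, 1.5], "y": [-1.0, 2.0]}) for i in range(5)]
        out = cross_study_quantile_normalize(mats)
        for m in out:
            assert np.allclose(m.values.to_numpy(), mats[0].values.to_numpy())

    def test_equal_length_outputs_share_sorted_values(self):
        rng = np.random.default_rng(0)
        mats = [
            fc_matrix(f"S{i}", pd.DataFrame(rng.normal(i, 1 + i, size=(4, 3))))
            for i in range(3)
        ]
        out = cross_study_quantile_normalize(mats)
        sorted_vals = [np.sort(m.values.to_numpy().ravel()) for m in out]
        for sv in sorted_vals[1:]:
            assert np.allclose(sv, sorted_vals[0])

    def test_idempotent_for_equal_lengths(self):
        rng = np.random.default_rng(1)
        mats = [fc_matrix(f"S{i}", pd.DataFrame(rng.normal(size=(5, 4)))) for i in range(3)]
        once = cross_study_quantile_normalize(mats)
        twice = cross_study_quantile_normalize(once)
        for a, b in zip(once, twice):
            assert np.allclose(a.values.to_numpy(), b.values.to_numpy(), atol=1e-9)

    def test_unequal_lengths_interpolate_onto_common_grid(self):
        v1 = np.array([0.0, 1.0, 2.0, 3.0])
        v2 = np.array([10.0, 20.0])
        n1, n2 = _quantile_normalize_vectors([v1, v2])
        # both normalized vectors are monotone in the original ranks
        assert np.all(np.diff(n1) > 0) and np.all(np.diff(n2) > 0)
        assert len(n1) == 4 and len(n2) == 2
        # extremes map to the averaged extremes
        assert n1[0] == pytest.approx((0.0 + 10.0) / 2)
        assert n1[-1] == pytest.approx((3.0 + 20.0) / 2)

    def test_too_few_matrices_or_entries_raise(self):
        m = fc_matrix("A", {"x": [1.0, 2.0]})
        with pytest.raises(ValueError):
            cross_study_quantile_normalize([m])
        tiny = fc_matrix("B", {"x": [1.0]})
        with pytest.raises(ValueError):
            cross_study_quantile_normalize([m, tiny])


class TestCombineMatrices:
    def g(self, study, genes, n_samples, condition="disease_primary"):
        vals = pd.DataFrame(
            np.arange(len(genes) * n_samples, dtype=float).reshape(len(genes), n_samples),
            index=genes,
            columns=[f"{study.lower()}s{j}" for j in range(n_samples)],
        )
        return FoldChangeMatrix(study, vals, condition, level="gene")

    def test_column_concatenation_over_shared_genes(self):
        combined = combine_matrices([self.g("A", ["gA", "gB"], 2), self.g("B", ["gA", "gB"], 3)])
        assert combined.values.shape == (2, 5)
        assert combined.studies() == ["A", "A", "B", "B", "B"]

    def test_intersection_policy(self):
        combined = combine_matrices([self.g("A", ["gA", "gB"], 1), self.g("B", ["gB", "gC"], 1)])
        assert combined.gene_ids == ["gB"]

    def test_union_policy_flags_missing(self):
        combined = combine_matrices(
            [self.g("A", ["gA", "gB"], 1), self.g("B", ["gB", "gC"], 1)], match="union"
        )
        assert combined.gene_ids == ["gA", "gB", "gC"]
        assert combined.values.isna().sum().sum() == 2

    def test_duplicate_study_sample_pair_raises(self):
        m1 = self.g("A", ["gA"], 2)
        m2 = self.g("A", ["gA"], 2, condition="disease_comparator")
        with pytest.raises(ValueError, match="duplicate"):
            combine_matrices([m1, m2])

    def test_five_matrices_from_three_studies_combine(self):
        mats = [
            self.g("A", ["gA", "gB"], 2),
            self.g("A2", ["gA", "gB"], 1, condition="disease_comparator"),
            self.g("B", ["gA", "gB"], 2),
            self.g("C", ["gA", "gB"], 1),
            self.g("C2", ["gA", "gB"], 1, condition="disease_comparator"),
        ]
        combined = combine_matrices(mats)
        assert combined.values.shape == (2, 7)
        assert len(set(combined.sample_keys)) == 7
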