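"""Attribution model: correction, multiplication, normalization, edge weights."""

import logging

import numpy as np
import pytest

from taxafunc import (
    GenomeAnnotationTable,
    InputFormatError,
    MatrixTable,
    align_comparison,
    compute_attributions,
    correct_copy_number,
    edge_weights,
    function_abundance,
    tensor_from_long,
    tensor_to_long,
    to_relative,
)
from taxafunc.attribution import AttributionTensor

from conftest import attribution_loop_oracle, random_instance


class TestCopyNumberCorrection:
    def test_toy_division(self, toy_taxa, toy_annot):
        c = correct_copy_number(toy_taxa, toy_annot)
        assert np.array_equal(c.values.ravel(), [5.0, 5.0])

    def test_unit_copies_identity(self, toy_taxa):
        annot = GenomeAnnotationTable(
            ["T1", "T2"], ["K1"], [[1.0], [1.0]], [1.0, 1.0]
        )
        assert correct_copy_number(toy_taxa, annot) == toy_taxa

    def test_drop_policy_logs_summed_abundance(self, toy_annot, caplog):
        taxa = MatrixTable(["T1", "T2", "TX"], ["S1"], [[10], [5], [7]])
        with caplog.at_level(logging.WARNING, logger="taxafunc"):
            c = correct_copy_number(taxa, toy_annot, policy="drop")
        assert c.row_ids == ["T1", "T2"]
        assert any("TX" in r.message and "7" in r.message for r in caplog.records)

    def test_error_policy_lists_taxa(self, toy_annot):
        taxa = MatrixTable(["T1", "TX"], ["S1"], [[10], [7]])
        with pytest.raises(InputFormatError, match="TX"):
            correct_copy_number(taxa, toy_annot, policy="error")


class TestComputeAttributions:
    def test_toy_values(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        idx = {
            (t, f): A.values[0, A.taxon_ids.index(t), A.function_ids.index(f)]
            for t in A.taxon_ids
            for f in A.function_ids
        }
        assert idx[("T1", "K1")] == 10.0
        assert idx[("T2", "K2")] == 15.0
        assert idx[("T2", "K1")] == 5.0
        assert idx[("T1", "K2")] == 0.0  # zero gene copy multiplier

    def test_matches_triple_loop_oracle(self):
        taxa, annot = random_instance(seed=7, n_taxa=20, n_functions=15, n_samples=6)
        corrected = correct_copy_number(taxa, annot)
        A = compute_attributions(corrected, annot)
        oracle = attribution_loop_oracle(corrected, annot)
        # the oracle keeps all functions; restrict to the tensor's axis
        cols = [annot.function_ids.index(f) for f in A.function_ids]
        assert np.max(np.abs(A.values - oracle[:, :, cols])) <= 1e-12

    def test_empty_taxon_intersection_rejected(self, toy_annot):
        taxa = MatrixTable(["TX"], ["S1"], [[1.0]])
        with pytest.raises(InputFormatError):
            compute_attributions(taxa, toy_annot, policy="drop")

    def test_linearity_over_samples(self):
        taxa, annot = random_instance(seed=3, n_samples=2)
        summed = MatrixTable(
            list(taxa.row_ids), ["Ssum"], taxa.values.sum(axis=1, keepdims=True)
        )
        A = compute_attributions(taxa, annot)
        A_sum = compute_attributions(summed, annot)
        assert np.allclose(
            A.values.sum(axis=0), A_sum.values[0], rtol=0, atol=1e-9
        )

    def test_scale_equivariance_and_relative_invariance(self):
        taxa, annot = random_instance(seed=11, n_samples=3)
        scaled_vals = taxa.values.copy()
        scaled_vals[:, 1] *= 4.0
        scaled = MatrixTable(list(taxa.row_ids), list(taxa.col_ids), scaled_vals)
        A = compute_attributions(taxa, annot)
        A2 = compute_attributions(scaled, annot)
        assert np.allclose(A2.values[1], 4.0 * A.values[1], rtol=1e-12, atol=0)
        assert np.allclose(
            to_relative(A2).values[1], to_relative(A).values[1], rtol=0, atol=1e-12
        )


class TestLongFormRoundTrip:
    def test_mode_consistency(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        back = tensor_from_long(tensor_to_long(A))
        assert back.equivalent(A, atol=0.0)

    def test_record_order_invariance(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        rec = tensor_to_long(A)
        perm = np.array([2, 0, 1])
        from taxafunc import AttributionLongTable

        shuffled = AttributionLongTable(
            [rec.taxa[i] for i in perm],
            [rec.functions[i] for i in perm],
            [rec.samples[i] for i in perm],
            rec.abundances[perm],
        )
        assert tensor_from_long(shuffled).equivalent(tensor_from_long(rec))

    def test_explicit_axes_give_zero_slices(self):
        from taxafunc import AttributionLongTable

        rec = AttributionLongTable(["T1"], ["K1"], ["S1"], [2.0])
        t = tensor_from_long(rec, sample_ids=["S1", "S2"])
        assert t.values[t.sample_ids.index("S2")].sum() == 0.0


class TestFunctionAbundance:
    def test_toy_sums(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        F = function_abundance(A)
        assert F.axis_kind == "function"
        vals = dict(zip(F.row_ids, F.values[:, 0]))
        assert vals == {"K1": 15.0, "K2": 15.0}

    def test_matches_loop_oracle_exactly(self):
        taxa, annot = random_instance(seed=19)
        A = compute_attributions(taxa, annot)
        F = function_abundance(A)
        for k, f in enumerate(A.function_ids):
            for i, s in enumerate(A.sample_ids):
                acc = 0.0
                for j in range(len(A.taxon_ids)):
                    acc += A.values[i, j, k]
                assert F.values[k, i] == acc  # identical summation order

    def test_all_zero_tensor(self):
        A = AttributionTensor(["S1"], ["T1"], ["K1"], np.zeros((1, 1, 1)))
        assert function_abundance(A).values.sum() == 0.0


class TestToRelative:
    def test_counts_to_proportions(self, toy_taxa):
        r = to_relative(toy_taxa)
        assert np.allclose(r.values.ravel(), [2 / 3, 1 / 3], rtol=0, atol=1e-15)

    def test_idempotent(self, toy_taxa):
        r = to_relative(toy_taxa)
        assert np.max(np.abs(to_relative(r).values - r.values)) <= 1e-12

    def test_tensor_sums_to_one(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        rel = to_relative(A)
        assert abs(rel.values[0].sum() - 1.0) <= 1e-9

    def test_zero_total_sample_named(self):
        t = MatrixTable(["T1"], ["S1", "S2"], [[1.0, 0.0]])
        with pytest.raises(InputFormatError, match="S2"):
            to_relative(t)


class TestEdgeWeights:
    def test_toy_single_sample(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        w = edge_weights(A).weights
        assert w[("T1", "K1")] == pytest.approx(2 / 3, abs=1e-12)
        assert w[("T2", "K1")] == pytest.approx(1 / 3, abs=1e-12)
        assert w[("T2", "K2")] == 1.0
        assert ("T1", "K2") not in w

    def test_single_contributor_is_one(self):
        A = AttributionTensor(
            ["S1", "S2"], ["T1"], ["K1"], np.array([[[3.0]], [[7.0]]])
        )
        assert edge_weights(A).weights[("T1", "K1")] == 1.0

    def test_mean_over_present_samples_only(self):
        # shares 0.2 and 0.6 in two samples; third sample lacks the function
        vals = np.array(
            [[[2.0], [8.0]], [[6.0], [4.0]], [[0.0], [0.0]]]
        )  # samples x taxa x functions
        A = AttributionTensor(["S1", "S2", "S3"], ["T1", "T2"], ["K1"], vals)
        assert edge_weights(A).weights[("T1", "K1")] == pytest.approx(0.4, abs=1e-12)

    def test_weights_sum_to_one_per_function(self):
        taxa, annot = random_instance(seed=5)
        A = compute_attributions(taxa, annot)
        ew = edge_weights(A)
        for f in A.function_ids:
            s = sum(ew.for_function(f).values())
            assert s == pytest.approx(1.0, abs=1e-9)


class TestAlignComparison:
    def test_self_comparison(self, toy_taxa, toy_annot):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        F = function_abundance(A)
        al = align_comparison(F, F)
        assert al.taxa_based == al.measured

    def test_union_expansion_with_zeros(self):
        pred = MatrixTable(["K1", "K2"], ["S1"], [[3.0], [1.0]], "function")
        meas = MatrixTable(["K1"], ["S1"], [[5.0]], "function")
        al = align_comparison(pred, meas)
        assert al.measured.row_ids == ["K1", "K2"]
        assert al.measured.values[1, 0] == 0.0
        assert al.measured.values[0, 0] == 1.0  # renormalized

    def test_extra_sample_dropped_and_reported(self, caplog):
        pred = MatrixTable(["K1"], ["S1"], [[3.0]], "function")
        meas = MatrixTable(["K1"], ["S1", "S9"], [[5.0, 2.0]], "function")
        with caplog.at_level(logging.WARNING, logger="taxafunc"):
            al = align_comparison(pred, meas)
        assert al.dropped_measured == ["S9"]
        assert al.measured.col_ids == ["S1"]
        assert any("S9" in r.message for r in caplog.records)

    def test_disjoint_samples_rejected(self):
        pred = MatrixTable(["K1"], ["S1"], [[3.0]], "function")
        meas = MatrixTable(["K1"], ["S2"], [[5.0]], "function")
        with pytest.raises(InputFormatError):
            align_comparison(pred, meas)
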