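"""Level trees, frontiers, and aggregation laws."""

import numpy as np
import pytest

from taxafunc import (
    HierarchyMap,
    InputFormatError,
    MatrixTable,
    build_tree,
    collapse,
    collapse_annotation,
    compute_attributions,
    correct_copy_number,
    default_frontier,
    leaf_order,
    node_mean_abundance,
    root_frontier,
    to_relative,
    validate_frontier,
)
from taxafunc.hierarchy import Frontier

from conftest import random_hierarchy, random_instance


class TestBuildTree:
    def test_full_depth(self, toy_hmap):
        tree = build_tree(toy_hmap, min_level=2)
        assert sorted(tree.leaf_ids()) == ["T1", "T2"]
        assert tree.nodes["T1"].parent == "Firmicutes"
        assert tree.nodes["Firmicutes"].parent == "Bacteria"

    def test_truncation_preaggregates_leaves(self, toy_hmap):
        tree = build_tree(toy_hmap, min_level=1)
        assert sorted(tree.leaf_ids()) == ["Bacteroidetes", "Firmicutes"]
        assert tree.nodes["Firmicutes"].base_leaves == ("T1",)

    def test_single_leaf_path_tree(self):
        hmap = HierarchyMap({"T1": (("A", "B"),)}, ("l1", "l2"))
        tree = build_tree(hmap)
        assert tree.leaf_ids() == ["T1"]
        assert tree.ancestors("T1") == ["B", "A", "root"]

    def test_min_level_beyond_depth_rejected(self, toy_hmap):
        with pytest.raises(InputFormatError, match="min_level"):
            build_tree(toy_hmap, min_level=3)


class TestFrontiers:
    def test_default_at_phylum_level(self, toy_tree):
        fr = default_frontier(toy_tree, 1)
        assert set(fr.node_ids) == {"Firmicutes", "Bacteroidetes"}

    def test_root_frontier_is_coarsest(self, toy_tree):
        fr = root_frontier(toy_tree)
        assert fr.node_ids == ("root",)

    def test_antichain_violation_named(self, toy_tree):
        with pytest.raises(InputFormatError, match="antichain"):
            validate_frontier(toy_tree, ["Firmicutes", "T2", "Bacteroidetes"])

    def test_non_covering_rejected(self, toy_tree):
        with pytest.raises(InputFormatError, match="cover"):
            validate_frontier(toy_tree, ["Firmicutes"])


class TestCollapse:
    def test_matrix_to_phyla(self, toy_tree, toy_taxa):
        fr = default_frontier(toy_tree, 1)
        c = collapse(toy_taxa, toy_tree, fr)
        assert c.row_ids == ["Bacteroidetes", "Firmicutes"]
        assert np.array_equal(c.values.ravel(), [5.0, 10.0])

    def test_leaf_frontier_is_identity_up_to_order(self, toy_tree, toy_taxa):
        fr = default_frontier(toy_tree, 2)
        c = collapse(toy_taxa, toy_tree, fr)
        assert sorted(c.row_ids) == ["T1", "T2"]
        got = dict(zip(c.row_ids, c.values[:, 0]))
        assert got == {"T1": 10.0, "T2": 5.0}

    def test_tensor_collapsed_to_root_on_both_axes(self, toy_taxa, toy_annot, toy_tree):
        A = compute_attributions(correct_copy_number(toy_taxa, toy_annot), toy_annot)
        from taxafunc import trivial_hierarchy

        fn_tree = trivial_hierarchy(list(A.function_ids))
        t1 = collapse(A, toy_tree, root_frontier(toy_tree), axis="taxon")
        t2 = collapse(t1, fn_tree, root_frontier(fn_tree), axis="function")
        assert t2.values.shape == (1, 1, 1)
        assert t2.values[0, 0, 0] == 30.0

    def test_missing_leaf_policies(self, toy_tree):
        t = MatrixTable(["T1", "T2", "TX"], ["S1"], [[1.0], [2.0], [4.0]])
        fr = default_frontier(toy_tree, 1)
        with pytest.raises(InputFormatError, match="TX"):
            collapse(t, toy_tree, fr)
        c = collapse(t, toy_tree, fr, missing="unclassified")
        assert c.row_ids[-1] == "Unclassified"
        assert c.values[-1, 0] == 4.0


class TestNodeMeans:
    def test_toy_single_sample(self, toy_tree, toy_taxa):
        means = node_mean_abundance(to_relative(toy_taxa), toy_tree)
        assert means["Firmicutes"] == pytest.approx(2 / 3, abs=1e-12)
        assert means["root"] == pytest.approx(1.0, abs=1e-12)

    def test_two_sample_arithmetic_mean(self, toy_tree):
        t = MatrixTable(["T1", "T2"], ["S1", "S2"], [[0.2, 0.4], [0.8, 0.6]])
        means = node_mean_abundance(t, toy_tree)
        assert means["Firmicutes"] == pytest.approx(0.3, abs=1e-12)
        assert means["Bacteroidetes"] == pytest.approx(0.7, abs=1e-12)

    def test_concentrated_leaf_saturates_ancestors(self, toy_tree):
        t = MatrixTable(["T1", "T2"], ["S1"], [[1.0], [0.0]])
        means = node_mean_abundance(t, toy_tree)
        assert means["Firmicutes"] == 1.0
        assert means["Bacteria"] == 1.0

    def test_non_relative_rejected(self, toy_tree, toy_taxa):
        with pytest.raises(InputFormatError, match="relative"):
            node_mean_abundance(toy_taxa, toy_tree)


class TestLeafOrder:
    def test_lexicographic(self, toy_tree):
        fr = default_frontier(toy_tree, 1)
        assert leaf_order(toy_tree, fr) == ["Bacteroidetes", "Firmicutes"]

    def test_deterministic_across_calls(self, toy_tree):
        fr = default_frontier(toy_tree, 2)
        assert leaf_order(toy_tree, fr) == leaf_order(toy_tree, fr)


class TestAggregationLaws:
    @pytest.mark.parametrize("seed", range(6))
    def test_collapse_commutes_with_attribution_on_function_axis(self, seed):
        # A(s,t,f) is linear in g, so summing attributions over a pathway's
        # member functions equals attributing against the pathway-summed
        # gene content.
        taxa, annot = random_instance(seed, n_taxa=15, n_functions=10, n_samples=4)
        fn_tree = build_tree(random_hierarchy(seed + 100, annot.function_ids))
        fr = default_frontier(fn_tree, 1)
        A = compute_attributions(taxa, annot)
        left = collapse(A, fn_tree, fr, axis="function")
        order = leaf_order(fn_tree, fr)
        f_idx = {f: k for k, f in enumerate(annot.function_ids)}
        g_coarse = np.stack(
            [
                annot.copy_numbers[
                    :, sorted(f_idx[b] for b in set(fn_tree.nodes[n].base_leaves))
                ].sum(axis=1)
                for n in order
            ],
            axis=1,
        )
        from taxafunc import GenomeAnnotationTable

        right = compute_attributions(
            taxa, GenomeAnnotationTable(list(annot.taxon_ids), order, g_coarse)
        )
        aligned = right.aligned_values(
            left.sample_ids, left.taxon_ids, left.function_ids
        )
        assert np.max(np.abs(left.values - aligned)) <= 1e-12

    @pytest.mark.parametrize("seed", range(6))
    def test_taxon_collapse_conserves_attribution_slices(self, seed):
        # Summing a clade's attributions preserves every (sample, function)
        # marginal exactly: the taxon-axis counterpart of linearity.
        taxa, annot = random_instance(seed, n_taxa=15, n_functions=10, n_samples=4)
        tree = build_tree(random_hierarchy(seed + 100, taxa.row_ids))
        fr = default_frontier(tree, 1)
        A = compute_attributions(taxa, annot)
        left = collapse(A, tree, fr, axis="taxon")
        assert np.allclose(
            A.values.sum(axis=1), left.values.sum(axis=1), rtol=0, atol=1e-9
        )

    @pytest.mark.parametrize("seed", range(6))
    def test_refinement_composition(self, seed):
        taxa, annot = random_instance(seed, n_taxa=15, n_functions=5, n_samples=3)
        tree = build_tree(random_hierarchy(seed + 7, taxa.row_ids))
        fine = default_frontier(tree, 1)
        coarse = default_frontier(tree, 0)
        direct = collapse(taxa, tree, coarse)
        fine_tab = collapse(taxa, tree, fine)
        # re-collapse the mid-level result through a one-level tree whose
        # leaves are the mid labels
        hmap = random_hierarchy(seed + 7, taxa.row_ids)
        mid_top = {lin[1]: lin[0] for lins in hmap.lineages.values() for lin in lins}
        retree = build_tree(
            HierarchyMap(
                {m: ((mid_top[m],),) for m in fine_tab.row_ids}, ("top",)
            )
        )
        again = collapse(fine_tab, retree, default_frontier(retree, 0))
        assert direct.row_ids == again.row_ids
        assert np.allclose(direct.values, again.values, rtol=0, atol=1e-9)

    @pytest.mark.parametrize("seed", range(4))
    def test_totals_invariant_under_any_frontier(self, seed):
        taxa, _ = random_instance(seed, n_taxa=12, n_functions=3, n_samples=3)
        tree = build_tree(random_hierarchy(seed + 55, taxa.row_ids))
        for level in (0, 1, 2):
            fr = default_frontier(tree, level)
            c = collapse(taxa, tree, fr)
            assert np.allclose(
                c.values.sum(axis=0), taxa.values.sum(axis=0), rtol=0, atol=1e-9
            )


class TestMultiParentLeaves:
    def test_replicated_leaf_double_counts_at_parents(self):
        hmap = HierarchyMap(
            {"K1": (("PathA",), ("PathB",)), "K2": (("PathA",),)}, ("pathway",)
        )
        tree = build_tree(hmap, min_level=0)
        t = MatrixTable(["K1", "K2"], ["S1"], [[3.0], [4.0]], "function")
        fr = default_frontier(tree, 0)
        c = collapse(t, tree, fr)
        got = dict(zip(c.row_ids, c.values[:, 0]))
        assert got == {"PathA": 7.0, "PathB": 3.0}
        # replication: collapsed total exceeds the leaf total
        assert c.values.sum() == 10.0 > t.values.sum()
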