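import numpy as np
import pytest

from taxafunc import (
    GenomeAnnotationTable,
    HierarchyMap,
    MatrixTable,
    build_tree,
)


@pytest.fixture
def toy_taxa():
    """a(T1,S1)=10, a(T2,S1)=5."""
    return MatrixTable(["T1", "T2"], ["S1"], [[10.0], [5.0]], "taxon")


@pytest.fixture
def toy_annot():
    """g = [[2,0],[1,3]], c16S = (2,1), NSTI = (0.03, 0.15)."""
    return GenomeAnnotationTable(
        ["T1", "T2"],
        ["K1", "K2"],
        [[2.0, 0.0], [1.0, 3.0]],
        [2.0, 1.0],
        [0.03, 0.15],
    )


@pytest.fixture
def toy_hmap():
    return HierarchyMap(
        {
            "T1": (("Bacteria", "Firmicutes"),),
            "T2": (("Bacteria", "Bacteroidetes"),),
        },
        ("kingdom", "phylum"),
    )


@pytest.fixture
def toy_tree(toy_hmap):
    return build_tree(toy_hmap)


def random_instance(seed, n_taxa=20, n_functions=15, n_samples=6):
    """A random (taxa table, annotation) pair for oracle comparisons."""
    rng = np.random.default_rng(seed)
    taxa_ids = [f"T{i}" for i in range(n_taxa)]
    func_ids = [f"K{k}" for k in range(n_functions)]
    sample_ids = [f"S{j}" for j in range(n_samples)]
    abund = rng.gamma(2.0, 50.0, size=(n_taxa, n_samples))
    g = np.where(rng.random((n_taxa, n_functions)) < 0.6,
                 rng.integers(1, 6, size=(n_taxa, n_functions)), 0).astype(float)
    g[:, 0] = np.maximum(g[:, 0], 1.0)  # keep at least one ubiquitous function
    rrna = rng.integers(1, 8, size=n_taxa).astype(float)
    nsti = rng.uniform(0, 0.3, size=n_taxa)
    taxa = MatrixTable(taxa_ids, sample_ids, abund, "taxon")
    annot = GenomeAnnotationTable(taxa_ids, func_ids, g, rrna, nsti)
    return taxa, annot


def random_hierarchy(seed, leaf_ids, n_top=3, n_mid=6):
    """A random two-named-level hierarchy over the given leaves."""
    rng = np.random.default_rng(seed)
    mids = [f"M{m}" for m in range(n_mid)]
    mid_top = {m: f"P{rng.integers(0, n_top)}" for m in mids}
    lineages = {}
    for leaf in leaf_ids:
        m = mids[int(rng.integers(0, n_mid))]
        lineages[leaf] = ((mid_top[m], m),)
    return HierarchyMap(lineages, ("top", "mid"))


def attribution_loop_oracle(corrected, annot):
    """Naive triple-loop reference for A(s,t,f) = a_hat(t,s) * g(t,f)."""
    t_idx = annot.taxon_index()
    f_ids = annot.function_ids
    out = np.zeros((len(corrected.col_ids), len(corrected.row_ids), len(f_ids)))
    for i, s in enumerate(corrected.col_ids):
        for j, t in enumerate(corrected.row_ids):
            for k, f in enumerate(f_ids):
                out[i, j, k] = (
                    corrected.values[j, i] * annot.copy_numbers[t_idx[t], k]
                )
    return out
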