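"""Attribution of functional abundance to taxa of origin.

The functional profile of a community is a linear combination of its
taxonomic composition and the genomic content of each member: after
correcting taxon abundances for 16S rRNA copy number, the abundance of
function *f* attributed to taxon *t* in sample *s* is

    A(s, t, f) = a_hat(t, s) * g(t, f)

where ``a_hat`` is the corrected taxon abundance and ``g`` the per-genome
gene copy number.  Summing A over taxa yields the predicted functional
profile F(s, f); normalizing A(s, t, f) by F(s, f) yields per-sample
attribution shares, whose across-sample mean is the edge weight drawn in
the bipartite taxa-function panel.

Because the model is linear, it accepts taxon tables in absolute read
counts or relative abundances interchangeably: scaling a sample's column
scales that sample's attribution slice, and relative views are unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import InputFormatError, InvariantError
from .io_formats import (
    AttributionLongTable,
    GenomeAnnotationTable,
    MatrixTable,
)

logger = logging.getLogger("taxafunc")

RELATIVE_TOL = 1e-9


@dataclass
class AttributionTensor:
    """Dense A(s, t, f) attribution values.

    Axes keep insertion order and are deduplicated; values are finite
    and nonnegative.  The function-abundance matrix F(s, f) is always
    derived by summation, never stored.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    function_ids: list[str]
    values: np.ndarray  # shape (samples, taxa, functions)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        self.function_ids = [str(f) for f in self.function_ids]
        self.values = np.asarray(self.values, dtype=float)
        for ids, name in (
            (self.sample_ids, "sample"),
            (self.taxon_ids, "taxon"),
            (self.function_ids, "function"),
        ):
            if len(set(ids)) != len(ids):
                raise InputFormatError(f"duplicate {name} ids in AttributionTensor")
        expected = (len(self.sample_ids), len(self.taxon_ids), len(self.function_ids))
        if self.values.shape != expected:
            raise InputFormatError(
                f"tensor shape {self.values.shape} does not match axes {expected}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise InputFormatError("attribution values must be finite and >= 0")

    def copy(self) -> "AttributionTensor":
        return AttributionTensor(
            list(self.sample_ids),
            list(self.taxon_ids),
            list(self.function_ids),
            self.values.copy(),
        )

    def aligned_values(
        self, sample_ids, taxon_ids, function_ids
    ) -> np.ndarray:
        """Values re-indexed onto the given axis orders (missing ids -> 0)."""
        out = np.zeros((len(sample_ids), len(taxon_ids), len(function_ids)))
        s_idx = {s: i for i, s in enumerate(self.sample_ids)}
        t_idx = {t: i for i, t in enumerate(self.taxon_ids)}
        f_idx = {f: i for i, f in enumerate(self.function_ids)}
        for i, s in enumerate(sample_ids):
            if s not in s_idx:
                continue
            for j, t in enumerate(taxon_ids):
                if t not in t_idx:
                    continue
                for k, f in enumerate(function_ids):
                    if f in f_idx:
                        out[i, j, k] = self.values[s_idx[s], t_idx[t], f_idx[f]]
        return out

    def equivalent(self, other: "AttributionTensor", atol: float = 0.0) -> bool:
        """Axis-order-insensitive comparison of two tensors."""
        samples = sorted(set(self.sample_ids) | set(other.sample_ids))
        taxa = sorted(set(self.taxon_ids) | set(other.taxon_ids))
        funcs = sorted(set(self.function_ids) | set(other.function_ids))
        a = self.aligned_values(samples, taxa, funcs)
        b = other.aligned_values(samples, taxa, funcs)
        return bool(np.allclose(a, b, rtol=0.0, atol=atol))


@dataclass
class EdgeWeightTable:
    """Mean attributed share w(t, f) per (taxon, function) pair.

    ``weights`` holds only pairs with w > 0.  For every function with
    nonzero abundance in at least one sample, the weights over taxa sum
    to 1.  Functions absent from every sample carry no edges.
    """

    weights: dict[tuple[str, str], float]
    taxon_ids: list[str]
    function_ids: list[str]

    def __post_init__(self) -> None:
        for (t, f), w in self.weights.items():
            if not (0.0 <= w <= 1.0 + RELATIVE_TOL):
                raise InvariantError(f"edge weight w({t},{f})={w} outside [0, 1]")

    def for_function(self, f: str) -> dict[str, float]:
        return {t: w for (t, ff), w in self.weights.items() if ff == f}


@dataclass
class AlignedComparison:
    """Predicted and measured function tables on a common (sample, function) grid."""

    taxa_based: MatrixTable
    measured: MatrixTable
    dropped_taxa_based: list[str]
    dropped_measured: list[str]


# ---------------------------------------------------------------------------
# Core operations
# ---------------------------------------------------------------------------


def _resolve_unknown_taxa(
    taxa: MatrixTable,
    known: set[str],
    policy: str,
    reason: str,
) -> MatrixTable:
    """Apply the unknown-taxon policy, returning the retained subset."""
    missing = [t for t in taxa.row_ids if t not in known]
    if not missing:
        return taxa
    if policy == "error":
        raise InputFormatError(
            f"taxa {reason}: {', '.join(missing)} (unknown-taxon policy is 'error')"
        )
    if policy != "drop":
        raise InputFormatError(f"unknown-taxon policy {policy!r}; use 'drop' or 'error'")
    idx = taxa.row_index()
    for t in missing:
        logger.warning(
            "dropping taxon %s (%s; summed abundance %g)",
            t,
            reason,
            float(taxa.values[idx[t]].sum()),
        )
    keep = [t for t in taxa.row_ids if t in known]
    if not keep:
        raise InputFormatError(f"no taxa remain after dropping those {reason}")
    rows = [idx[t] for t in keep]
    return MatrixTable(keep, list(taxa.col_ids), taxa.values[rows], taxa.axis_kind)


def correct_copy_number(
    taxa: MatrixTable,
    annot: GenomeAnnotationTable,
    policy: str = "drop",
) -> MatrixTable:
    """Divide each taxon's abundance by its 16S rRNA copy number.

    Marker-gene read counts over-represent taxa with many rRNA operons;
    dividing by c16S(t) makes abundances approximate cell counts.  Taxa
    without a copy-number estimate are dropped with a logged warning
    (default) or raise, per ``policy``.
    """
    if taxa.axis_kind != "taxon":
        raise InputFormatError("copy-number correction applies to taxon tables")
    if annot.rrna_copies is None:
        known: set[str] = set()
    else:
        known = set(annot.taxon_ids)
    kept = _resolve_unknown_taxa(taxa, known, policy, "without a 16S copy number")
    t_idx = annot.taxon_index()
    c = np.array([annot.rrna_copies[t_idx[t]] for t in kept.row_ids])
    return MatrixTable(
        list(kept.row_ids),
        list(kept.col_ids),
        kept.values / c[:, None],
        "taxon",
    )


def compute_attributions(
    corrected: MatrixTable,
    annot: GenomeAnnotationTable,
    policy: str = "drop",
) -> AttributionTensor:
    """Multiply corrected taxon abundances by per-genome gene copy numbers.

    Returns the dense tensor A(s, t, f) = a_hat(t, s) * g(t, f).  The
    function axis contains every annotated gene family with a nonzero
    copy number in at least one retained taxon, in annotation order.
    """
    if corrected.axis_kind != "taxon":
        raise InputFormatError("attribution needs a taxon x sample table")
    kept = _resolve_unknown_taxa(
        corrected, set(annot.taxon_ids), policy, "absent from the genomic content table"
    )
    t_idx = annot.taxon_index()
    rows = [t_idx[t] for t in kept.row_ids]
    g = annot.copy_numbers[rows]  # taxa x functions
    func_mask = (g > 0).any(axis=0)
    function_ids = [f for j, f in enumerate(annot.function_ids) if func_mask[j]]
    if not function_ids:
        raise InputFormatError("no function has a nonzero copy number in retained taxa")
    g = g[:, func_mask]
    # A(s, t, f) = a_hat(t, s) * g(t, f)
    a_hat = kept.values  # taxa x samples
    values = a_hat.T[:, :, None] * g[None, :, :]
    return AttributionTensor(
        list(kept.col_ids), list(kept.row_ids), function_ids, values
    )


def tensor_from_long(
    records: AttributionLongTable,
    sample_ids: list[str] | None = None,
    taxon_ids: list[str] | None = None,
    function_ids: list[str] | None = None,
) -> AttributionTensor:
    """Densify long-form attribution records; absent triples are 0.

    Axis orders default to sorted unique ids from the records; explicit
    axes may add ids not present in any record (all-zero slices).
    """

    def _axis(given: list[str] | None, present: list[str], name: str) -> list[str]:
        if given is None:
            return sorted(set(present))
        extra = set(present) - set(given)
        if extra:
            raise InputFormatError(
                f"records contain {name} ids missing from the requested axis: "
                f"{', '.join(sorted(extra))}"
            )
        return list(given)

    samples = _axis(sample_ids, records.samples, "sample")
    taxa = _axis(taxon_ids, records.taxa, "taxon")
    funcs = _axis(function_ids, records.functions, "function")
    values = np.zeros((len(samples), len(taxa), len(funcs)))
    s_idx = {s: i for i, s in enumerate(samples)}
    t_idx = {t: i for i, t in enumerate(taxa)}
    f_idx = {f: i for i, f in enumerate(funcs)}
    for t, f, s, v in records.records():
        values[s_idx[s], t_idx[t], f_idx[f]] = v
    return AttributionTensor(samples, taxa, funcs, values)


def tensor_to_long(attr: AttributionTensor) -> AttributionLongTable:
    """Flatten a tensor to long records, omitting zero cells."""
    taxa, funcs, samples, ab = [], [], [], []
    for j, t in enumerate(attr.taxon_ids):
        for k, f in enumerate(attr.function_ids):
            for i, s in enumerate(attr.sample_ids):
                v = attr.values[i, j, k]
                if v != 0:
                    taxa.append(t)
                    funcs.append(f)
                    samples.append(s)
                    ab.append(v)
    return AttributionLongTable(taxa, funcs, samples, np.array(ab))


def function_abundance(attr: AttributionTensor) -> MatrixTable:
    """Predicted function x sample profile: F(s, f) = sum over taxa of A(s, t, f).

    Summation runs in ascending taxon-index order so repeated runs are
    bit-identical.
    """
    values = np.add.reduce(attr.values, axis=1)  # ascending taxon index
    return MatrixTable(
        list(attr.function_ids), list(attr.sample_ids), values.T, "function"
    )


def to_relative(obj):
    """Normalize each sample to relative abundance (per-sample sum = 1).

    For matrices the total is the column sum; for tensors it is the sum
    over all (taxon, function) pairs of the sample's slice.  Idempotent
    on already-relative input.
    """
    if isinstance(obj, MatrixTable):
        totals = obj.values.sum(axis=0)
        zero = [c for c, tot in zip(obj.col_ids, totals) if tot <= 0]
        if zero:
            raise InputFormatError(f"zero-total sample(s): {', '.join(zero)}")
        return MatrixTable(
            list(obj.row_ids), list(obj.col_ids), obj.values / totals, obj.axis_kind
        )
    if isinstance(obj, AttributionTensor):
        totals = obj.values.sum(axis=(1, 2))
        zero = [s for s, tot in zip(obj.sample_ids, totals) if tot <= 0]
        if zero:
            raise InputFormatError(f"zero-total sample(s): {', '.join(zero)}")
        return AttributionTensor(
            list(obj.sample_ids),
            list(obj.taxon_ids),
            list(obj.function_ids),
            obj.values / totals[:, None, None],
        )
    raise InputFormatError(f"cannot normalize object of type {type(obj).__name__}")


def edge_weights(attr: AttributionTensor) -> EdgeWeightTable:
    """Mean attributed share of each function per taxon, across samples.

    share(s, t, f) = A(s, t, f) / F(s, f) is defined only for samples
    where the function is present (F > 0); the mean is taken over
    exactly those samples.  Functions absent everywhere yield no edges.
    """
    F = attr.values.sum(axis=1)  # samples x functions
    present = F > 0
    weights: dict[tuple[str, str], float] = {}
    for k, f in enumerate(attr.function_ids):
        mask = present[:, k]
        n = int(mask.sum())
        if n == 0:
            continue
        shares = attr.values[mask, :, k] / F[mask, k][:, None]  # samples x taxa
        w = shares.mean(axis=0)
        for j, t in enumerate(attr.taxon_ids):
            if w[j] > 0:
                weights[(t, f)] = float(w[j])
    return EdgeWeightTable(weights, list(attr.taxon_ids), list(attr.function_ids))


def align_comparison(
    taxa_based: MatrixTable, measured: MatrixTable
) -> AlignedComparison:
    """Pair a predicted function profile with an independently measured one.

    Both tables are restricted to the shared samples, expanded to the
    union of function ids (missing functions -> 0), and renormalized to
    per-sample relative abundance, since predicted and measured profiles
    live on incommensurate scales.  Samples present on one side only are
    logged and dropped.
    """
    shared = [s for s in taxa_based.col_ids if s in set(measured.col_ids)]
    if not shared:
        raise InputFormatError("no samples shared between predicted and measured tables")
    dropped_t = [s for s in taxa_based.col_ids if s not in set(shared)]
    dropped_m = [s for s in measured.col_ids if s not in set(shared)]
    for s in dropped_t:
        logger.warning("sample %s only in the taxa-based table; dropped", s)
    for s in dropped_m:
        logger.warning("sample %s only in the measured table; dropped", s)

    functions = list(taxa_based.row_ids)
    functions += [f for f in measured.row_ids if f not in set(functions)]

    def _expand(tab: MatrixTable) -> MatrixTable:
        r_idx = tab.row_index()
        c_idx = tab.col_index()
        vals = np.zeros((len(functions), len(shared)))
        for i, f in enumerate(functions):
            if f not in r_idx:
                continue
            for j, s in enumerate(shared):
                vals[i, j] = tab.values[r_idx[f], c_idx[s]]
        return MatrixTable(list(functions), list(shared), vals, "function")

    return AlignedComparison(
        to_relative(_expand(taxa_based)),
        to_relative(_expand(measured)),
        dropped_t,
        dropped_m,
    )


def is_relative(table: MatrixTable, tol: float = 1e-6) -> bool:
    """True when every sample column sums to 1 within ``tol``."""
    return bool(np.all(np.abs(table.values.sum(axis=0) - 1.0) <= tol))
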