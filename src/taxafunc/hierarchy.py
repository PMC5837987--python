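"""Level trees over taxa and functions, and aggregation to a display frontier.

Taxonomic ranks and function categories (e.g. a KEGG-style three-level
pathway hierarchy) are represented as rooted trees whose leaves all sit
at the same depth.  A *frontier* is an antichain of nodes whose
descendant leaves partition all leaves — the batch analogue of
interactively expanding and collapsing tree branches.  Collapsing an
abundance matrix or attribution tensor to a frontier sums each frontier
node's descendant leaves, and orders the output axis depth-first with
children sorted by label, so taxa and functions keep the same vertical
order across every figure and table.

Multi-parent leaves (a gene family listed under several pathways) are
supported for programmatically built hierarchies: the leaf is duplicated
under each parent and its abundance replicated, matching common KEGG
roll-up practice.  Collapsed totals can then exceed leaf-level totals;
per-sample conservation holds only for single-parent hierarchies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .attribution import AttributionTensor
from .errors import InputFormatError
from .io_formats import GenomeAnnotationTable, HierarchyMap, MatrixTable

ROOT = "root"
UNCLASSIFIED = "Unclassified"


@dataclass
class TreeNode:
    id: str
    label: str
    level: int  # internal: root = 0, named levels 1.., leaves deepest
    parent: str | None
    children: list[str] = field(default_factory=list)
    base_leaves: tuple[str, ...] = ()  # original leaf ids, with multiplicity


@dataclass
class HierarchyTree:
    """A rooted, uniform-depth level tree (see module docstring)."""

    nodes: dict[str, TreeNode]
    root_id: str
    depth: int  # internal level at which the tree's leaves sit
    level_names: tuple[str, ...]
    min_level: int  # public numbering: 0-based into (level_names..., base)

    def leaf_ids(self) -> list[str]:
        return [n.id for n in self.nodes.values() if not n.children]

    def base_leaf_ids(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for n in self.nodes.values():
            if not n.children:
                for b in n.base_leaves:
                    if b not in seen:
                        seen.add(b)
                        out.append(b)
        return out

    def ancestors(self, node_id: str) -> list[str]:
        out = []
        cur = self.nodes[node_id].parent
        while cur is not None:
            out.append(cur)
            cur = self.nodes[cur].parent
        return out

    def sorted_children(self, node_id: str) -> list[str]:
        kids = self.nodes[node_id].children
        return sorted(kids, key=lambda c: (self.nodes[c].label, self.nodes[c].id))

    def top_ancestor(self, node_id: str) -> str:
        """The ancestor at the first named level (or the node itself)."""
        node = self.nodes[node_id]
        if node.level <= 1:
            return node_id
        cur = node_id
        while self.nodes[cur].level > 1:
            cur = self.nodes[cur].parent  # type: ignore[assignment]
        return cur


@dataclass(frozen=True)
class Frontier:
    """An antichain of tree nodes partitioning all leaves, in display order."""

    node_ids: tuple[str, ...]

    def __iter__(self):
        return iter(self.node_ids)

    def __len__(self) -> int:
        return len(self.node_ids)


# ---------------------------------------------------------------------------
# Construction
# ---------------------------------------------------------------------------


def build_tree(hmap: HierarchyMap, min_level: int | None = None) -> HierarchyTree:
    """Build a level tree, optionally truncated to a minimum resolution.

    ``min_level`` is a 0-based index into ``(level_names..., leaf)``:
    ``min_level == len(level_names)`` (the default) keeps the original
    leaves; smaller values truncate the tree so its leaves are the
    ancestor labels at that level, each carrying the original leaves
    beneath it (so collapsed abundances are pre-aggregated sums).
    """
    L = hmap.depth
    if min_level is None:
        min_level = L
    if not (0 <= min_level <= L):
        raise InputFormatError(
            f"min_level {min_level} exceeds map depth {L} (valid: 0..{L})"
        )

    # paths keyed by label tuple from the root; base-leaf chains end in the leaf id
    paths: dict[tuple[str, ...], dict] = {
        (): {"label": ROOT, "level": 0, "bases": []}
    }
    for leaf, lineages in hmap.lineages.items():
        for lin in lineages:
            if min_level < L:
                chain = lin[: min_level + 1]
            else:
                chain = tuple(lin) + (leaf,)
            for d in range(1, len(chain) + 1):
                p = tuple(chain[:d])
                node = paths.setdefault(p, {"label": chain[d - 1], "level": d, "bases": []})
                node["bases"].append(leaf)

    depth = (min_level + 1) if min_level < L else (L + 1)

    # public ids: bare label (or leaf id) when unambiguous, else the full path
    candidates: dict[str, list[tuple[str, ...]]] = {}
    for p, info in paths.items():
        cand = info["label"] if p != () else ROOT
        candidates.setdefault(cand, []).append(p)
    ids: dict[tuple[str, ...], str] = {}
    for cand, plist in candidates.items():
        for p in plist:
            ids[p] = cand if len(plist) == 1 else "/".join(p) or ROOT

    nodes: dict[str, TreeNode] = {}
    for p in sorted(paths, key=len):
        info = paths[p]
        nid = ids[p]
        parent = ids[p[:-1]] if p else None
        nodes[nid] = TreeNode(
            id=nid,
            label=info["label"],
            level=info["level"],
            parent=parent,
            base_leaves=tuple(info["bases"]) if p else tuple(
                b for q, i in paths.items() if len(q) == 1 for b in i["bases"]
            ),
        )
    # root base leaves = concatenation over its children (set above); wire children
    for p, info in paths.items():
        if p:
            nodes[ids[p[:-1]]].children.append(ids[p])
    for n in nodes.values():
        # deterministic child order for reproducible traversal
        n.children = sorted(set(n.children), key=lambda c: (nodes[c].label, nodes[c].id))

    tree = HierarchyTree(nodes, ids[()], depth, hmap.level_names, min_level)
    leaf_levels = {nodes[l].level for l in tree.leaf_ids()}
    if leaf_levels != {depth}:
        raise InputFormatError(
            f"hierarchy leaves are not at uniform depth {depth}: levels {sorted(leaf_levels)}"
        )
    return tree


def trivial_hierarchy(leaf_ids: list[str], level_name: str = "all") -> HierarchyTree:
    """A one-level tree placing every leaf under a single category."""
    hmap = HierarchyMap({l: (("All",),) for l in leaf_ids}, (level_name,))
    return build_tree(hmap)


# ---------------------------------------------------------------------------
# Frontiers
# ---------------------------------------------------------------------------


def _descendant_leaves(tree: HierarchyTree, node_id: str) -> set[str]:
    node = tree.nodes[node_id]
    if not node.children:
        return {node_id}
    out: set[str] = set()
    stack = [node_id]
    while stack:
        cur = tree.nodes[stack.pop()]
        if not cur.children:
            out.add(cur.id)
        else:
            stack.extend(cur.children)
    return out


def validate_frontier(tree: HierarchyTree, node_ids) -> Frontier:
    """Check antichain + leaf-partition properties and return an ordered Frontier."""
    node_ids = list(node_ids)
    for n in node_ids:
        if n not in tree.nodes:
            raise InputFormatError(f"frontier node {n!r} is not in the tree")
    if len(set(node_ids)) != len(node_ids):
        raise InputFormatError("frontier contains duplicate nodes")
    id_set = set(node_ids)
    for n in node_ids:
        bad = [a for a in tree.ancestors(n) if a in id_set]
        if bad:
            raise InputFormatError(
                f"frontier is not an antichain: {bad[0]!r} is an ancestor of {n!r}"
            )
    covered: set[str] = set()
    for n in node_ids:
        leaves = _descendant_leaves(tree, n)
        overlap = covered & leaves
        if overlap:
            raise InputFormatError(
                f"frontier nodes overlap on leaves: {sorted(overlap)[:5]}"
            )
        covered |= leaves
    all_leaves = set(tree.leaf_ids())
    missing = all_leaves - covered
    if missing:
        raise InputFormatError(
            f"frontier does not cover leaves: {sorted(missing)[:5]}"
        )
    return Frontier(tuple(leaf_order(tree, Frontier(tuple(node_ids)))))


def default_frontier(tree: HierarchyTree, level: int) -> Frontier:
    """All nodes at public ``level`` (0-based into named levels, deepest = leaves).

    Shallower tree leaves are included too, so truncated or ragged
    branches stay covered.
    """
    internal = level + 1
    if not (1 <= internal <= tree.depth):
        raise InputFormatError(
            f"frontier level {level} outside 0..{tree.depth - 1}"
        )
    picks = [
        n.id
        for n in tree.nodes.values()
        if n.level == internal or (not n.children and n.level < internal)
    ]
    return validate_frontier(tree, picks)


def root_frontier(tree: HierarchyTree) -> Frontier:
    """The coarsest valid frontier: the root alone."""
    return validate_frontier(tree, [tree.root_id])


def leaf_order(tree: HierarchyTree, frontier: Frontier) -> list[str]:
    """Depth-first frontier order, children sorted by (label, id)."""
    f_set = set(frontier.node_ids)
    out: list[str] = []

    def visit(node_id: str) -> None:
        if node_id in f_set:
            out.append(node_id)
            return
        for c in tree.sorted_children(node_id):
            visit(c)

    visit(tree.root_id)
    return out


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------


def _frontier_row_sums(
    values: np.ndarray,
    ids: list[str],
    tree: HierarchyTree,
    frontier: Frontier,
    missing: str,
    axis: int,
):
    """Sum ``values`` along ``axis`` onto frontier nodes.

    Base leaves are summed in sorted-id order regardless of input row
    order, so equal inputs give bit-identical sums.
    """
    order = leaf_order(tree, frontier)
    idx = {r: i for i, r in enumerate(ids)}
    known = set()
    for n in order:
        known |= set(tree.nodes[n].base_leaves)
    unmapped = [r for r in ids if r not in known]
    if unmapped and missing == "error":
        raise InputFormatError(
            f"ids not found in the hierarchy: {', '.join(unmapped[:10])}"
            + ("..." if len(unmapped) > 10 else "")
        )

    out_ids = list(order)
    slabs = []
    for n in order:
        bases = sorted(b for b in tree.nodes[n].base_leaves)
        rows = [idx[b] for b in bases if b in idx]
        if rows:
            slab = np.add.reduce(np.take(values, rows, axis=axis), axis=axis)
        else:
            slab = np.zeros(values.shape[:axis] + values.shape[axis + 1 :])
        slabs.append(slab)
    if unmapped and missing == "unclassified":
        rows = [idx[r] for r in sorted(unmapped)]
        slabs.append(np.add.reduce(np.take(values, rows, axis=axis), axis=axis))
        out_ids.append(UNCLASSIFIED)
    return out_ids, np.stack(slabs, axis=axis)


def collapse(
    obj,
    tree: HierarchyTree,
    frontier: Frontier,
    axis: str | None = None,
    missing: str = "error",
):
    """Aggregate a matrix or tensor to the given frontier.

    Each frontier node's value is the sum over its descendant base
    leaves; the output axis follows depth-first tree order.  Ids absent
    from the tree raise by default, or are pooled into an
    ``Unclassified`` bucket when ``missing='unclassified'``.
    """
    frontier = validate_frontier(tree, list(frontier.node_ids))
    if missing not in ("error", "unclassified"):
        raise InputFormatError(f"unknown missing-leaf policy {missing!r}")
    if isinstance(obj, MatrixTable):
        out_ids, vals = _frontier_row_sums(
            obj.values, obj.row_ids, tree, frontier, missing, axis=0
        )
        return MatrixTable(out_ids, list(obj.col_ids), vals, obj.axis_kind)
    if isinstance(obj, AttributionTensor):
        if axis not in ("taxon", "function"):
            raise InputFormatError("tensor collapse needs axis='taxon' or 'function'")
        ax = 1 if axis == "taxon" else 2
        ids = obj.taxon_ids if axis == "taxon" else obj.function_ids
        out_ids, vals = _frontier_row_sums(obj.values, ids, tree, frontier, missing, ax)
        if axis == "taxon":
            return AttributionTensor(
                list(obj.sample_ids), out_ids, list(obj.function_ids), vals
            )
        return AttributionTensor(
            list(obj.sample_ids), list(obj.taxon_ids), out_ids, vals
        )
    raise InputFormatError(f"cannot collapse object of type {type(obj).__name__}")


def collapse_annotation(
    annot: GenomeAnnotationTable, tree: HierarchyTree, frontier: Frontier
) -> GenomeAnnotationTable:
    """Sum gene copy numbers over each frontier node's member taxa.

    16S copy numbers and NSTI values do not aggregate additively and are
    dropped from the result.
    """
    frontier = validate_frontier(tree, list(frontier.node_ids))
    out_ids, vals = _frontier_row_sums(
        annot.copy_numbers, annot.taxon_ids, tree, frontier, "error", axis=0
    )
    return GenomeAnnotationTable(out_ids, list(annot.function_ids), vals)


def node_mean_abundance(table: MatrixTable, tree: HierarchyTree) -> dict[str, float]:
    """Across-sample mean of the summed relative abundance under every node.

    The input must be a relative table (per-sample sums 1); the root's
    mean is 1 whenever the table covers all tree leaves.  Used to size
    nodes in the bipartite panel and tree diagrams.
    """
    sums = table.values.sum(axis=0)
    if not np.all(np.abs(sums - 1.0) <= 1e-6):
        raise InputFormatError(
            "node_mean_abundance requires a relative table (per-sample sums 1)"
        )
    idx = table.row_index()
    out: dict[str, float] = {}

    def visit(node_id: str) -> None:
        node = tree.nodes[node_id]
        bases = sorted(set(node.base_leaves))
        rows = [idx[b] for b in bases if b in idx]
        counts = {b: node.base_leaves.count(b) for b in bases}
        total = 0.0
        if rows:
            acc = np.zeros(len(table.col_ids))
            for b in bases:
                if b in idx:
                    acc = acc + counts[b] * table.values[idx[b]]
            total = float(acc.mean())
        out[node_id] = total
        for c in tree.sorted_children(node_id):
            visit(c)

    visit(tree.root_id)
    return out
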