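"""End-to-end orchestration of the three input modes, plus fixture generation.

Input modes:

``reference``
    taxon table + genomic content with 16S copy numbers: abundances are
    copy-number corrected, then multiplied by gene copy numbers.
``custom_content``
    taxon table + user genomic content; abundances are assumed to be
    already normalized by 16S copy number, so correction is skipped.
``precomputed``
    taxon table + a long-form attribution table; no content table needed.

Every run writes the function-abundance table, the attribution long
table (both on the raw scale, at the configured minimum resolutions),
per-sample NSTI when available, differential abundance statistics when a
binary grouping is given, three SVG figures (taxon bars, function bars,
bipartite panel; plus a comparison figure when a measured shotgun
profile is provided), and a run log.  Partial outputs are removed if any
step fails.

The fixture generator emulates a small reference pack (toy taxa with
three-level lineages, toy gene families with a three-level pathway
hierarchy, integer copy numbers, 16S counts, NSTI values) together with
sample tables, group labels and a noisy "measured" functional profile,
so the full pipeline can run without any external database.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import attribution as attr_mod
from . import hierarchy as hier_mod
from . import io_formats as io_mod
from . import stats as stats_mod
from . import viz as viz_mod
from .errors import InputFormatError
from .io_formats import (
    GenomeAnnotationTable,
    HierarchyMap,
    MatrixTable,
    SampleGroupMap,
)

logger = logging.getLogger("taxafunc")

MODES = ("reference", "custom_content", "precomputed")


@dataclass
class RunConfig:
    """All knobs of a pipeline run; mirrors the CLI flags 1:1."""

    mode: str
    taxa_path: str
    out_dir: str
    content_path: str | None = None
    attribution_path: str | None = None
    taxonomy_path: str | None = None
    function_hierarchy_path: str | None = None
    groups_path: str | None = None
    comparison_path: str | None = None
    min_taxon_level: int | None = None
    min_function_level: int | None = None
    color_scheme: str = "hierarchical"
    color_seed: int = 0
    unknown_taxa: str = "drop"
    stats_method: str = "mannwhitney"
    edge_min: float = 0.01

    def validate(self) -> None:
        if self.mode not in MODES:
            raise InputFormatError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode in ("reference", "custom_content") and not self.content_path:
            raise InputFormatError(f"mode {self.mode!r} requires a genomic content table")
        if self.mode == "precomputed" and not self.attribution_path:
            raise InputFormatError("mode 'precomputed' requires an attribution table")


@dataclass
class RunResult:
    """Paths of the files a pipeline run produced."""

    out_dir: Path
    outputs: dict[str, Path]


@dataclass
class FixturePack:
    """An internally consistent synthetic input set (see module docstring)."""

    taxa: MatrixTable
    annot: GenomeAnnotationTable
    taxonomy_map: HierarchyMap
    function_map: HierarchyMap
    groups: SampleGroupMap
    measured: MatrixTable
    planted_class: str
    planted_taxa: list[str]
    seed: int
    paths: dict[str, Path] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Fixture generation
# ---------------------------------------------------------------------------

_PHYLA = ("Firmicutes", "Bacteroidetes", "Proteobacteria")
_SUPERPATHWAYS = ("Metabolism", "GeneticInformation", "Signaling")


def generate_fixtures(
    seed: int,
    n_taxa: int = 20,
    n_functions: int = 15,
    n_samples: int = 12,
    out_dir: str | Path | None = None,
    noise_sigma: float = 0.25,
    planted_fold: float = 3.0,
) -> FixturePack:
    """Generate a deterministic synthetic reference pack.

    Taxon abundances are heavy-tailed lognormal draws; gene copy numbers
    are small integers with ~40% zeros; 16S copy numbers lie in 1..7 and
    NSTI values in [0, 0.3].  Samples split into two balanced groups
    with one class-level clade scaled ``planted_fold``-fold in the first
    group, so differential testing has real signal.  The measured
    function table is the pipeline's own inferred profile under
    multiplicative lognormal noise (``noise_sigma = 0`` makes it exact).
    Identical seeds yield byte-identical packs.
    """
    if min(n_taxa, n_functions, n_samples) < 2:
        raise InputFormatError("fixture sizes must be >= 2")
    rng = np.random.default_rng(seed)

    taxon_ids = [f"T{i + 1:03d}" for i in range(n_taxa)]
    sample_ids = [f"S{j + 1:02d}" for j in range(n_samples)]
    function_ids = [f"K{k + 1:04d}" for k in range(n_functions)]

    # three-level taxonomy: phylum -> class (2 per phylum) -> order (2 per class)
    tax_lineages: dict[str, tuple[tuple[str, ...], ...]] = {}
    for i, t in enumerate(taxon_ids):
        p = _PHYLA[i % len(_PHYLA)]
        c = f"{p}_c{(i // len(_PHYLA)) % 2 + 1}"
        o = f"{c}_o{(i // (len(_PHYLA) * 2)) % 2 + 1}"
        tax_lineages[t] = ((p, c, o),)
    taxonomy_map = HierarchyMap(tax_lineages, ("phylum", "class", "order"))

    fn_lineages: dict[str, tuple[tuple[str, ...], ...]] = {}
    for k, f in enumerate(function_ids):
        sp = _SUPERPATHWAYS[k % len(_SUPERPATHWAYS)]
        pw = f"{sp}_p{(k // len(_SUPERPATHWAYS)) % 2 + 1}"
        sub = f"{pw}_s{(k // (len(_SUPERPATHWAYS) * 2)) % 2 + 1}"
        fn_lineages[f] = ((sp, pw, sub),)
    function_map = HierarchyMap(fn_lineages, ("superpathway", "pathway", "subpathway"))

    # genomic content: ~40% zeros, integer copies 1..5
    present = rng.random((n_taxa, n_functions)) < 0.6
    g = np.where(present, rng.integers(1, 6, size=(n_taxa, n_functions)), 0).astype(float)
    for k in range(n_functions):  # every function encoded somewhere
        if not g[:, k].any():
            g[int(rng.integers(0, n_taxa)), k] = 1.0
    for i in range(n_taxa):  # every taxon encodes something
        if not g[i].any():
            g[i, int(rng.integers(0, n_functions))] = 1.0
    rrna = rng.integers(1, 8, size=n_taxa).astype(float)
    nsti = rng.uniform(0.0, 0.3, size=n_taxa)
    annot = GenomeAnnotationTable(taxon_ids, function_ids, g, rrna, nsti)

    # abundances: lognormal baseline, planted clade x fold in group A
    abund = rng.lognormal(mean=math.log(50.0), sigma=1.0, size=(n_taxa, n_samples))
    half = n_samples // 2
    group_labels = {
        s: ("case" if j < half else "control") for j, s in enumerate(sample_ids)
    }
    planted_class = f"{_PHYLA[0]}_c1"
    planted_taxa = [
        t for t in taxon_ids if tax_lineages[t][0][1] == planted_class
    ]
    rows = [taxon_ids.index(t) for t in planted_taxa]
    abund[np.ix_(rows, range(half))] *= planted_fold
    taxa = MatrixTable(taxon_ids, sample_ids, abund, "taxon")
    groups = SampleGroupMap(group_labels)

    # measured profile = inferred profile under multiplicative noise
    corrected = attr_mod.correct_copy_number(taxa, annot)
    inferred = attr_mod.function_abundance(
        attr_mod.compute_attributions(corrected, annot)
    )
    noise = np.exp(rng.normal(0.0, noise_sigma, size=inferred.values.shape)) if noise_sigma > 0 else 1.0
    measured = MatrixTable(
        list(inferred.row_ids),
        list(inferred.col_ids),
        inferred.values * noise,
        "function",
    )

    pack = FixturePack(
        taxa=taxa,
        annot=annot,
        taxonomy_map=taxonomy_map,
        function_map=function_map,
        groups=groups,
        measured=measured,
        planted_class=planted_class,
        planted_taxa=planted_taxa,
        seed=seed,
    )
    if out_dir is not None:
        pack.paths = write_fixture_pack(pack, out_dir)
    return pack


def write_fixture_pack(pack: FixturePack, out_dir: str | Path) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "taxa": io_mod.write_table(pack.taxa, out / "taxa.tsv"),
        "content": io_mod.write_genomic_content(pack.annot, out / "genomic_content.tsv"),
        "taxonomy": io_mod.write_hierarchy_map(pack.taxonomy_map, out / "taxonomy.tsv"),
        "functions": io_mod.write_hierarchy_map(pack.function_map, out / "functions.tsv"),
        "groups": io_mod.write_sample_groups(pack.groups, out / "groups.tsv"),
        "measured": io_mod.write_table(pack.measured, out / "measured_functions.tsv"),
    }
    return paths


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _load_tree(
    path: str | None, leaf_ids: list[str], min_level: int | None
) -> hier_mod.HierarchyTree:
    if path is None:
        return hier_mod.trivial_hierarchy(leaf_ids)
    return hier_mod.build_tree(io_mod.read_hierarchy_map(path), min_level)


def run_pipeline(config: RunConfig) -> RunResult:
    """Execute one full run; see the module docstring for the output set."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    log_path = out_dir / "run_log.txt"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        result = _run(config, out_dir, written)
        result.outputs["run_log"] = log_path
        return result
    except Exception:
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: RunConfig, out_dir: Path, written: list[Path]) -> RunResult:
    outputs: dict[str, Path] = {}
    logger.info("pipeline start: mode=%s taxa=%s", config.mode, config.taxa_path)

    def emit(name: str, path: Path) -> None:
        written.append(path)
        outputs[name] = path

    taxa = io_mod.read_matrix_table(config.taxa_path, "taxon")
    annot = None
    nsti_basis: MatrixTable | None = None

    if config.mode == "reference":
        annot = io_mod.read_genomic_content(config.content_path, layout="wide")
        corrected = attr_mod.correct_copy_number(taxa, annot, config.unknown_taxa)
        tensor = attr_mod.compute_attributions(corrected, annot, config.unknown_taxa)
        nsti_basis = corrected
    elif config.mode == "custom_content":
        # abundances are assumed to be pre-normalized by 16S copy number
        annot = io_mod.read_genomic_content(config.content_path, layout="wide")
        tensor = attr_mod.compute_attributions(taxa, annot, config.unknown_taxa)
        nsti_basis = attr_mod._resolve_unknown_taxa(
            taxa, set(annot.taxon_ids), config.unknown_taxa, "absent from the genomic content table"
        )
    else:  # precomputed
        records = io_mod.read_attribution_long(config.attribution_path)
        tensor = attr_mod.tensor_from_long(records)
        logger.info("mode precomputed: %d attribution records", len(records))

    tax_tree = _load_tree(
        config.taxonomy_path, list(taxa.row_ids), config.min_taxon_level
    )
    fn_tree = _load_tree(
        config.function_hierarchy_path,
        list(tensor.function_ids),
        config.min_function_level,
    )
    tax_frontier = hier_mod.default_frontier(tax_tree, tax_tree.depth - 1)
    fn_frontier = hier_mod.default_frontier(fn_tree, fn_tree.depth - 1)

    # collapse to the display resolution on both axes
    tensor_c = _collapse_tensor_axis(tensor, tax_tree, tax_frontier, "taxon")
    tensor_c = _collapse_tensor_axis(tensor_c, fn_tree, fn_frontier, "function")
    func_tab = attr_mod.function_abundance(tensor_c)
    taxa_c = hier_mod.collapse(taxa, tax_tree, tax_frontier)

    emit("function_abundance", io_mod.write_table(func_tab, out_dir / "function_abundance.tsv"))
    emit(
        "attribution",
        io_mod.write_table(attr_mod.tensor_to_long(tensor_c), out_dir / "attribution.tsv"),
    )

    if annot is not None and annot.nsti is not None and nsti_basis is not None:
        nsti = stats_mod.sample_nsti(nsti_basis, annot)
        emit("nsti", io_mod.write_table(nsti.to_frame(), out_dir / "sample_nsti.tsv"))

    groups = None
    if config.groups_path:
        groups = io_mod.read_sample_groups(config.groups_path)
        labels = sorted(
            {groups.groups[s] for s in taxa.col_ids if s in groups.groups}
        )
        if len(labels) == 2:
            frames = [
                stats_mod.results_frame(
                    stats_mod.differential_abundance(
                        attr_mod.to_relative(taxa_c), groups, config.stats_method
                    ),
                    "taxon",
                ),
                stats_mod.results_frame(
                    stats_mod.differential_abundance(
                        attr_mod.to_relative(func_tab), groups, config.stats_method
                    ),
                    "function",
                ),
            ]
            import pandas as pd

            emit(
                "stats",
                io_mod.write_table(
                    pd.concat(frames, ignore_index=True),
                    out_dir / "differential_abundance.tsv",
                ),
            )
        else:
            logger.info(
                "differential abundance skipped: %d group labels (need exactly 2)",
                len(labels),
            )

    # figures
    cfg = viz_mod.RenderConfig(edge_min=config.edge_min)
    taxa_rel = attr_mod.to_relative(taxa_c)
    func_rel = attr_mod.to_relative(func_tab)
    tax_colors = viz_mod.assign_colors(
        tax_tree, tax_frontier, config.color_scheme, config.color_seed
    )
    fn_colors = viz_mod.assign_colors(
        fn_tree, fn_frontier, config.color_scheme, config.color_seed
    )
    fig_t = viz_mod.render_stacked_bars(taxa_rel, tax_colors, groups, cfg)
    fig_f = viz_mod.render_stacked_bars(func_rel, fn_colors, groups, cfg)
    ew = attr_mod.edge_weights(tensor_c)
    t_means = hier_mod.node_mean_abundance(taxa_rel, tax_tree)
    f_means = hier_mod.node_mean_abundance(func_rel, fn_tree)
    panel = viz_mod.render_bipartite_panel(
        ew,
        {n: t_means[n] for n in hier_mod.leaf_order(tax_tree, tax_frontier)},
        {n: f_means[n] for n in hier_mod.leaf_order(fn_tree, fn_frontier)},
        viz_mod.ColorAssignment(
            {**tax_colors.colors, **fn_colors.colors}, config.color_scheme, config.color_seed
        ),
        cfg,
    )
    for name, fig in (("taxa_bars", fig_t), ("function_bars", fig_f), ("bipartite_panel", panel)):
        p = out_dir / f"{name}.svg"
        fig.write(p)
        emit(name, p)

    if config.comparison_path:
        measured = io_mod.read_matrix_table(config.comparison_path, "function")
        aligned = attr_mod.align_comparison(func_tab, measured)
        comp_colors = _extend_colors(fn_colors, aligned.taxa_based.row_ids)
        fig_c = viz_mod.render_stacked_bars(
            aligned.taxa_based, comp_colors, groups, cfg, companion=aligned.measured
        )
        p = out_dir / "comparison_bars.svg"
        fig_c.write(p)
        emit("comparison", p)

    logger.info("pipeline complete: %d outputs in %s", len(outputs), out_dir)
    return RunResult(out_dir, outputs)


def _collapse_tensor_axis(tensor, tree, frontier, axis):
    """Collapse one tensor axis, tolerating ids already at frontier resolution."""
    ids = tensor.taxon_ids if axis == "taxon" else tensor.function_ids
    base = set()
    for n in frontier.node_ids:
        base |= set(tree.nodes[n].base_leaves)
    if set(ids) <= base:
        return hier_mod.collapse(tensor, tree, frontier, axis=axis)
    if set(ids) <= set(frontier.node_ids):
        # already collapsed (e.g. a precomputed attribution table exported
        # at this resolution): align to display order, missing nodes -> 0
        order = hier_mod.leaf_order(tree, frontier)
        if axis == "taxon":
            vals = _align_axis(tensor.values, ids, order, 1)
            return attr_mod.AttributionTensor(
                list(tensor.sample_ids), order, list(tensor.function_ids), vals
            )
        vals = _align_axis(tensor.values, ids, order, 2)
        return attr_mod.AttributionTensor(
            list(tensor.sample_ids), list(tensor.taxon_ids), order, vals
        )
    raise InputFormatError(
        f"{axis} ids match neither the hierarchy's leaves nor its display frontier"
    )


def _align_axis(values, ids, order, axis):
    idx = {r: i for i, r in enumerate(ids)}
    shape = list(values.shape)
    shape[axis] = len(order)
    out = np.zeros(shape)
    for j, nid in enumerate(order):
        if nid in idx:
            src = np.take(values, idx[nid], axis=axis)
            sl = [slice(None)] * values.ndim
            sl[axis] = j
            out[tuple(sl)] = src
    return out


def _extend_colors(colors: viz_mod.ColorAssignment, row_ids) -> viz_mod.ColorAssignment:
    """Give deterministic fallback colors to rows a palette does not cover."""
    merged = dict(colors.colors)
    extra = [r for r in row_ids if r not in merged]
    for i, r in enumerate(sorted(extra)):
        merged[r] = viz_mod._hls_hex(0.08 + 0.61803398875 * i, 0.5, 0.25)
    return viz_mod.ColorAssignment(merged, colors.scheme, colors.seed)
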