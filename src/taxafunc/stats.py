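"""Downloadable analytics: two-group differential abundance and per-sample NSTI.

Differential abundance uses the two-sided Mann-Whitney U test on
relative abundances (the standard nonparametric two-group comparison for
compositional microbiome features), with an exact null when both groups
have at most 8 samples and the pooled values contain no ties, and the
normal approximation with tie correction otherwise.  P-values are
adjusted across all tested features with the Benjamini-Hochberg step-up
FDR procedure.  A Welch t-test is available behind the same interface
for users who prefer a parametric comparison.

The Nearest Sequenced Taxon Index (NSTI) summarizes prediction
confidence: each taxon's phylogenetic distance to its closest sequenced
genome, averaged per sample with copy-number-corrected relative
abundances as weights.  Low values mean the community is well covered
by reference genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .attribution import to_relative
from .errors import InputFormatError
from .io_formats import GenomeAnnotationTable, MatrixTable, SampleGroupMap

EXACT_MAX_N = 8


@dataclass
class DiffAbundanceResult:
    """One feature's two-group comparison."""

    feature_id: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    statistic: float
    p_value: float
    q_value: float


@dataclass
class SampleNSTI:
    """Per-sample abundance-weighted mean NSTI."""

    values: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sample_id": list(self.values), "weighted_nsti": list(self.values.values())}
        )


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (same order as input)."""
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise InputFormatError("bh_adjust expects a non-empty 1-D p-value vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise InputFormatError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _mannwhitney(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([x, y])) == 0:
        # identical constant values in both groups: no separation
        return float(len(x) * len(y) / 2.0), 1.0
    pooled = np.concatenate([x, y])
    no_ties = len(np.unique(pooled)) == len(pooled)
    if len(x) <= EXACT_MAX_N and len(y) <= EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _welch(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.ptp(np.concatenate([x, y])) == 0:
        return 0.0, 1.0
    res = sps.ttest_ind(x, y, equal_var=False)
    p = float(res.pvalue)
    return float(res.statistic), 1.0 if np.isnan(p) else p


def differential_abundance(
    table: MatrixTable,
    groups: SampleGroupMap,
    method: str = "mannwhitney",
) -> list[DiffAbundanceResult]:
    """Per-feature two-group test with BH correction across all features.

    ``table`` must be relative (per-sample sums 1) and its mapped
    samples must carry exactly two group labels, each with at least two
    samples; unmapped samples are ignored.  Group A/B are the two labels
    in sorted order.
    """
    sums = table.values.sum(axis=0)
    if not np.all(np.abs(sums - 1.0) <= 1e-6):
        raise InputFormatError("differential abundance requires a relative table")
    tests = {"mannwhitney": _mannwhitney, "welch": _welch}
    if method not in tests:
        raise InputFormatError(f"unknown test method {method!r}")
    mapped = [(j, groups.groups[s]) for j, s in enumerate(table.col_ids) if s in groups.groups]
    labels = sorted({g for _, g in mapped})
    if len(labels) != 2:
        raise InputFormatError(
            f"differential abundance needs exactly 2 group labels among the "
            f"table's samples; found {len(labels)}: {labels}"
        )
    ga, gb = labels
    a_cols = [j for j, g in mapped if g == ga]
    b_cols = [j for j, g in mapped if g == gb]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise InputFormatError("each group needs at least 2 samples")
    stats_p = [
        tests[method](table.values[i, a_cols], table.values[i, b_cols])
        for i in range(len(table.row_ids))
    ]
    q = bh_adjust([p for _, p in stats_p])
    return [
        DiffAbundanceResult(
            feature_id=fid,
            group_a=ga,
            group_b=gb,
            n_a=len(a_cols),
            n_b=len(b_cols),
            statistic=u,
            p_value=p,
            q_value=float(qv),
        )
        for fid, (u, p), qv in zip(table.row_ids, stats_p, q)
    ]


def results_frame(results: list[DiffAbundanceResult], axis: str) -> pd.DataFrame:
    """Stack results into the exported TSV schema."""
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "axis": [axis] * len(results),
            "group_a_n": [r.n_a for r in results],
            "group_b_n": [r.n_b for r in results],
            "statistic": [r.statistic for r in results],
            "p_value": [r.p_value for r in results],
            "q_value": [r.q_value for r in results],
        }
    )


def sample_nsti(
    corrected_taxa: MatrixTable, annot: GenomeAnnotationTable
) -> SampleNSTI:
    """Abundance-weighted mean NSTI per sample.

    N(s) = sum_t r(t, s) * n(t), where r is the per-sample relative
    abundance of the copy-number-corrected taxon table, so weights sum
    to 1 and N(s) is invariant to rescaling any sample's column.
    """
    if annot.nsti is None:
        raise InputFormatError("genomic content table carries no NSTI values")
    t_idx = annot.taxon_index()
    missing = [t for t in corrected_taxa.row_ids if t not in t_idx]
    if missing:
        raise InputFormatError(f"NSTI missing for taxa: {', '.join(missing)}")
    rel = to_relative(corrected_taxa)
    n = np.array([annot.nsti[t_idx[t]] for t in rel.row_ids])
    weighted = n @ rel.values  # per-sample weighted mean
    return SampleNSTI({s: float(v) for s, v in zip(rel.col_ids, weighted)})
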