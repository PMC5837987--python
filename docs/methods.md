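# Methods

## Model

A microbiome sample's functional profile is modeled as a linear
combination of its taxonomic composition and the genomic content of each
member taxon.  Writing `a(t,s)` for the abundance of taxon `t` in sample
`s`, `c16S(t)` for the taxon's 16S rRNA operon count and `g(t,f)` for
the number of copies of gene family `f` per genome of `t`:

    a_hat(t,s) = a(t,s) / c16S(t)                (copy-number correction)
    A(s,t,f)   = a_hat(t,s) * g(t,f)             (attribution)
    F(s,f)     = sum_t A(s,t,f)                  (predicted function profile)

`A` deconvolves every function's abundance into taxon-specific shares:
`A(s,t,f) / F(s,f)` is the share of function `f` in sample `s`
attributed to taxon `t`.  The *edge weight* drawn in the bipartite
taxa–function panel is the across-sample mean of that share,

    w(t,f) = mean over { s : F(s,f) > 0 } of A(s,t,f) / F(s,f),

restricted to samples where the function is present, since 0/0 is
undefined; a function absent from every sample carries no edges.
Whether samples with zero function abundance should enter this average
is a genuinely open choice — including them would shrink all weights of
rarely observed functions toward zero — and the exclusion rule used here
is deliberate and documented rather than implied.

Because the model is linear in `a`, taxon tables may be given as
absolute read counts or relative abundances interchangeably: scaling a
sample's column scales its attribution slice, and all relative views
(stacked bars, shares, edge weights) are unchanged.

### Input modes

1. **reference** — taxon table + annotated genomic content with 16S
   copy numbers: correction and attribution as above.
2. **custom_content** — taxon table + user content table; abundances
   are assumed to be already copy-number normalized, so the correction
   step is skipped.
3. **precomputed** — a long-form `(taxon, function, sample, abundance)`
   attribution table replaces the computation entirely.

Taxa present in the abundance table but absent from the content table
are dropped with a logged warning by default (reference packs never
cover every OTU); a strict `error` policy is available.

## Hierarchical aggregation

Taxonomic ranks and function categories are uniform-depth level trees.
A *frontier* is an antichain of nodes whose descendant leaves partition
all leaves; collapsing a matrix or tensor to a frontier sums each node's
descendant leaves.  Two exact laws follow from linearity and are tested
to 1e-12 on seeded random instances:

* **Function axis** — collapsing attributions over a pathway's member
  functions equals attributing against the pathway-summed gene content
  (`A` is linear in `g`).
* **Taxon axis** — collapsing attributions over a clade preserves every
  `(sample, function)` marginal, hence `F` and all per-sample totals.

Note that attributing a clade's *summed* abundance against its *summed*
gene content is **not** equivalent to summing the clade's attributions
(sum of products versus product of sums); aggregation in this package
is therefore always performed by summing leaf-level attributions, which
is also what the interactive expand/collapse semantics require.

Determinism: collapse sums base leaves in sorted-id order regardless of
input row order, and output axes follow depth-first tree order with
children sorted by label.  This makes collapsed tables byte-identical
across input modes and repeated runs.

Leaves listed under several parents (a gene family in several pathways)
are supported for programmatically built hierarchies: the leaf is
duplicated under each parent and its abundance replicated, matching
common KEGG roll-up practice.  Collapsed function totals can then exceed
leaf totals, and per-sample conservation holds only for single-parent
hierarchies; the file reader rejects duplicate leaves, so this behavior
never occurs by accident.

`min_level` truncates a tree before display: it is a 0-based index into
`(level_names..., leaf)`, so `min_level = len(level_names)` keeps the
original leaves and `min_level = 0` truncates to the root-most named
level.

## Statistics

* **Differential abundance** — two-sided Mann-Whitney U per feature on
  relative abundances, exact null when both groups have ≤ 8 samples and
  the pooled values are tie-free, normal approximation with tie and
  continuity correction otherwise; Benjamini-Hochberg step-up FDR across
  all features of one axis (one family for taxa, one for functions).
  Testing is restricted to binary groupings; richer designs are out of
  scope.  A Welch t-test is selectable behind the same flag for users
  preferring a parametric test.  The nonparametric default was chosen
  because relative abundances are bounded, skewed and zero-inflated.
* **NSTI** — per-sample prediction confidence:
  `N(s) = sum_t r(t,s) * n(t)` with `r` the relative abundance of the
  copy-number-corrected taxon table, so `N` is a weighted mean bounded
  by the NSTI range of the taxa present and invariant to rescaling a
  sample's column.

## Rendering

SVG output is a pure function of data, configuration and seed:
repeated runs are byte-identical.  Geometry defaults (bar width 24 px,
gap 6 px, group gap 18 px, bar height 300 px) are fixed in
`RenderConfig`.  Segment heights are proportional to relative
abundances (printed at 3 decimals, well within half-pixel rounding);
zero-valued cells emit no rectangle.  Bipartite edge stroke width is
linear in `w(t,f)` with a configurable maximum (8 px); edges with mean
share ≤ `edge_min` (default 0.01) are suppressed to avoid hairline
clutter.  Color schemes are `hierarchical` (one hue band per top-level
ancestor, lightness varied within the band in leaf order) or `random`
(seeded shuffle of an evenly spaced palette); distinct frontier nodes
always receive distinct colors, and frontiers beyond 256 nodes are
rejected with a suggestion to coarsen.  PNG export is best-effort
rasterization and requires an external SVG rasterizer; SVG is the
contract format.

## Synthetic reference pack

`generate_fixtures` emulates the external reference databases and
sample tables needed to exercise the full pipeline:

* taxon abundances ~ lognormal(log 50, σ = 1) — heavy-tailed positive
  draws resembling OTU count spreads;
* integer gene copy numbers 1–5 with ~40 % structural zeros, patched so
  every taxon encodes ≥ 1 function and every function has ≥ 1 encoder;
* 16S copy numbers uniform on {1..7}; NSTI ~ U(0, 0.3);
* a three-level taxonomy (phylum/class/order) and a three-level
  function hierarchy (superpathway/pathway/subpathway);
* two balanced sample groups with one class-level clade scaled ×3 in
  the first group, giving differential testing a planted signal;
* a "measured" function table equal to the inferred profile under
  multiplicative lognormal noise (σ = 0.25 by default; 0 makes it
  exact), standing in for shotgun-derived profiles.

The pack is byte-identically regenerable from its seed.  It does *not*
emulate sequencing depth variation, sparsity patterns of real OTU
tables, phylogenetic correlation of gene content, or compositional
correlation structure beyond closure; passing tests demonstrate the
correctness of the computations, not predictive accuracy on real
communities.  At the default sizes (20 taxa × 15 functions × 12–20
samples) every test and the full verification script run in seconds.

Detection of the planted clade (smallest class-level q-value, counting
exact BH ties at the minimum) occurs in ≥ 90 % of generator seeds on
average; individual 20-seed batches fluctuate binomially around that
rate, which the verification script reports rather than hides.

## Numerical choices

* Summation over taxa uses ascending taxon-index order; collapse sums
  sorted leaf ids — both fixed so results are bit-reproducible.
* Relative-abundance checks use 1e-6; conservation assertions 1e-9
  absolute (or 1e-12 relative where magnitudes are large); oracle
  comparisons 1e-12.
* Written floats use `repr` (shortest round-trip), so
  read ∘ write is the identity bit for bit.
* Zero-total samples are a hard error in normalization; all-constant
  features short-circuit to p = 1.

## Known limitations

* No inference of genomic content from marker-gene placement; content
  tables are inputs.
* No compositional transforms (CLR/ALR) before testing.
* No >2-group statistics; the pipeline logs and skips the stats step
  for non-binary groupings.
* HDF5 BIOM is not read (the optional BIOM reader handles JSON only);
  TSV is the contract format.
* No interactive display; hover/click semantics exist only as their
  batch equivalents (frontiers, exports).
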