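# taxafunc

Attribute microbiome functional abundance to the taxa it comes from.

Marker-gene surveys give a taxon × sample abundance table; annotated
genomes give each taxon's gene-family copy numbers.  Because a
community's gene content is a linear combination of its members'
genomes, the functional profile of each sample can be predicted from
its taxonomic profile — and, more usefully, *deconvolved*: every
function's abundance splits into taxon-specific shares.  `taxafunc`
implements that attribution engine for people analyzing paired
taxonomic/functional microbiome data: it performs 16S copy-number
correction, computes the attribution tensor, aggregates both axes along
taxonomic and pathway hierarchies, runs two-group differential
abundance tests with FDR correction, summarizes prediction confidence
(NSTI), compares predictions against shotgun-measured profiles, and
exports deterministic SVG figures (stacked bars and a bipartite
taxa–function panel).

## The model

For taxon `t`, sample `s`, gene family `f`:

    a_hat(t,s) = a(t,s) / c16S(t)          # correct for rRNA operon count
    A(s,t,f)   = a_hat(t,s) * g(t,f)       # attribution tensor
    F(s,f)     = Σ_t A(s,t,f)              # predicted functional profile
    w(t,f)     = mean_s A(s,t,f) / F(s,f)  # mean attributed share (edge weight)

`N(s) = Σ_t r(t,s) · n(t)` (abundance-weighted NSTI) summarizes how well
the community is covered by sequenced genomes.  See `docs/methods.md`
for assumptions, aggregation laws and numerical conventions.

## Worked example

```python
import taxafunc as tf

taxa  = tf.MatrixTable(["T1", "T2"], ["S1"], [[10], [5]], "taxon")
annot = tf.GenomeAnnotationTable(
    ["T1", "T2"], ["K1", "K2"],
    [[2, 0], [1, 3]],          # gene copies g(t,f)
    [2, 1],                    # 16S copies c16S(t)
    [0.03, 0.15],              # NSTI n(t)
)

corrected = tf.correct_copy_number(taxa, annot)   # (10/2, 5/1) -> (5, 5)
A = tf.compute_attributions(corrected, annot)
F = tf.function_abundance(A)
w = tf.edge_weights(A).weights
n = tf.sample_nsti(corrected, annot)

print(A.values[0])
# [[10.  0.]
#  [ 5. 15.]]
print(dict(zip(F.row_ids, F.values[:, 0])))
# {'K1': np.float64(15.0), 'K2': np.float64(15.0)}
print(w)
# {('T1', 'K1'): 0.6666666666666666, ('T2', 'K1'): 0.3333333333333333, ('T2', 'K2'): 1.0}
print(n.values)
# {'S1': 0.09}
```

Both taxa encode K1, so its 15 units split 2:1 between T1 and T2; K2 is
encoded only by T2, which therefore carries 100 % of it.  The sample's
NSTI of 0.09 is the abundance-weighted mean of (0.03, 0.15) at equal
corrected abundances.

## Command line

```sh
taxafunc fixtures --seed 42 --out-dir pack/          # synthetic reference pack
taxafunc run --mode reference \
    --taxa pack/taxa.tsv --content pack/genomic_content.tsv \
    --taxonomy pack/taxonomy.tsv --function-hierarchy pack/functions.tsv \
    --groups pack/groups.tsv --comparison pack/measured_functions.tsv \
    --out-dir out/
```

A run writes `function_abundance.tsv`, `attribution.tsv`,
`sample_nsti.tsv`, `differential_abundance.tsv`, three (plus an
optional comparison) SVG figures, and a run log.  Subcommands
`attribute`, `collapse`, `stats` and `render` expose the individual
steps.

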