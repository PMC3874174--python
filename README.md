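# eqtldomains

Tools for relating **expression quantitative trait loci (eQTLs)** to the
three-dimensional organisation of chromatin measured by **Hi-C**.  The
package asks two questions about distal eQTL–gene associations (SNPs at
least 50 kb from their target gene):

1. **Spatial proximity** — are eQTL SNPs in unusually frequent Hi-C
   contact with their target genes, beyond what their genomic distance,
   gene length and coverage would predict?
2. **Domain structure** — how do eQTL–gene pairs sit relative to
   topological domains (TADs): do they concentrate near domain
   boundaries, and do they cross domains more often than chance?

It is aimed at regulatory-genomics analysts who have a binned Hi-C
contact matrix, a set of domain calls (BED), and a table of eQTL–gene
pairs, and want calibrated resampling statistics rather than ad-hoc
overlap counts.

## Model and statistics

A chromosome is partitioned into fixed 40-kb bins; the Hi-C data become
a symmetric contact graph with frequencies *f(u, v)* and per-bin totals
*t(v) = Σ_u f(u, v)*.  eQTL–gene pairs that share a SNP bin and a target
gene are collapsed into **equivalence classes**, each described by five
properties:

| symbol | meaning |
|---|---|
| *d* | SNP–gene distance (bin midpoints) |
| *g* | gene length (first to last gene-bin midpoint) |
| *m* | max *t(v)* over gene bins |
| *t̂* | *t* of the SNP bin |
| *p* | spatial proximity: max *f*(SNP bin, gene bin) |

**Matched-control proximity test.** A large space of random eQTL
classes is sampled by resampling the observed gene-length and distance
distributions and placing SNPs uniformly.  Each observed class is paired
with its optimal match (minimum total Euclidean distance on
(*d*, *g*, *t̂*, *m*), solved as a global min-cost bipartite assignment),
and the paired proximities are compared with the Wilcoxon signed-rank
test.  Matching makes the comparison robust to the confounders in the
feature vector.

**Conditioned domain-crossing test.** The observed count *n* of classes
whose SNP–gene interval crosses a domain is compared with the same count
*N* over domain sequences shuffled so that domain lengths, gap lengths
and the domain/gap pattern are preserved.  The empirical p-value is
conditioned on the number of crossing genes (*N_G*) and crossing SNP
fragments (*N_S*) lying in ranges derived from the *k* shuffles best
matching the observed values; the observed sequence is always a member,
so *p* > 0.  Crossing p-values are Benjamini–Hochberg corrected across
chromosomes.

Boundary-window enrichment (fraction of SNP bins within 250 kb of a
boundary, empirical p over shuffles), size-stratified chi-squared
boundary tests, total-frequency rank sums and a regulatory-element
subset test complete the analysis.

A fully-featured synthetic-data generator produces chromosomes with
distance-decay + domain-block contact matrices and eQTLs with plantable
proximity, boundary and crossing preferences, so every statistic can be
validated for calibration and power without any external download.

## Worked example

```python
from eqtldomains import *
from eqtldomains.synthetic_data import SyntheticConfig, generate_dataset
from eqtldomains.eqtl_mapping import (attach_properties, build_classes,
                                      filter_pairs, classify_many)
from eqtldomains.hic_graph import total_frequencies
from eqtldomains.proximity_stats import proximity_matched_test
from eqtldomains.crossing_stats import conditioned_pvalue

# one synthetic 20-Mb chromosome with planted SNP-gene contact enrichment
ds = generate_dataset(SyntheticConfig(proximity_planting=3.0), seed=11)
totals = total_frequencies(ds.graph)
pairs = filter_pairs(ds.pairs)                      # distal (>= 50 kb) pairs
classes = attach_properties(build_classes(pairs, ds.graph), ds.graph, totals)
labels = classify_many(classes, ds.domains)

space = sample_random_eqtls(classes, pairs, ds.graph.chrom_length,
                            ds.graph, n_p=20, seed=12)
t = proximity_matched_test(classes, space)
shuffles = build_shuffle_set(ds.domains, n_d=200, seed=13)
cs = conditioned_pvalue(classes, ds.domains, shuffles, k_cond=100)
```

Output of the session above:

```
200 pairs -> 200 distal -> 151 classes
crossing: 7, within-domain: 143, gap: 1
matched-pair signed-rank: W=2920, p=2.67e-06, direction=observed
match quality rho: [1.0, 1.0, 0.958, 0.954]
crossing: n=7, N_G=4, N_S=7, space=115, p=1.000
```

Reading the numbers: the planted contact preference pulls SNPs into
high-frequency bins near their genes, so nearly all classes are
within-domain; the matched-pair test detects the proximity enrichment
decisively (p ≈ 3e-6 with the observed side larger) while the four
matching features stay almost perfectly balanced (ρ ≥ 0.95); and the
crossing count is entirely unremarkable against shuffled domains
(p = 1.0), as it should be when no crossing preference was planted.

The same pipeline runs from the shell on files
(`eqtl-domain-prox run --config run.yaml`), and
`eqtl-domain-prox simulate` writes synthetic inputs in the accepted
dialects (dense matrix text, BED3 domains, eQTL TSV).

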