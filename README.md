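# foldspec

Fold-change-specific enrichment analysis for differential expression.

Classical over-representation analysis asks *which* functional gene groups
respond in a treatment; it is blind to *how strongly* they respond.
`foldspec` asks the sharper question: are the member genes of a GO term (or
the genes sharing a promoter hexamer) concentrated in a specific window of
fold-change magnitude? A term like "translation" may be enriched among all
up-regulated genes, yet its members may respond almost exclusively with
*weak* fold changes — a fold-change-specific regulation signature that the
standard analysis averages away.

The package is aimed at transcriptomics analysts with a differential
expression table (any tool's output: a signed log2FC table or separate
up/down lists), a gene-set annotation (two-column TSV or GAF, optionally
with an OBO ontology for ancestor propagation), and — for the motif arm —
a genome FASTA + GFF3 or a pre-extracted promoter FASTA.

## Method

For each direction separately, the n DEGs are ranked by linear fold-change
magnitude and cut into q equal-size quantiles (default q = 6, labelled
very weak `vw` … very strong `vs`; quantile k covers ranks
⌈(k−1)n/q⌉…⌈kn/q⌉−1). A *fold-change interval* is any contiguous run of
quantiles: q(q+1)/2 = 21 intervals for q = 6 including the full list, 20
*component* intervals excluding it. Enrichment is tested in two steps, each
with a one-sided Fisher exact test and Bonferroni family-wise control:

1. **Interval enrichment.** For every term t and interval I, the 2×2 table
   {gene ∈ I vs rest of genome background} × {gene ∈ t vs not}; p-values
   multiplied by (terms tested) × (intervals tested); terms with adjusted
   p < 0.001 anywhere are selected.
2. **Fold-change specificity.** For each selected term and each of the 20
   component intervals, the table {DEG ∈ I vs remaining DEGs} × {DEG ∈ t
   vs not} — the universe is now the directional DEG list itself; p-values
   multiplied by (selected terms) × 20. A term with min adjusted p < 0.05
   is *fold-change-specific*, assigned to the interval attaining the
   minimum (ties: shortest, then weakest interval).

The promoter-motif arm mirrors this exactly for the 2080 canonical hexamers
(4096 6-mers with complementary pairs collapsed, 64 palindromes), using
per-gene presence in the [−1500 bp; 5′UTR] region: step 1 against all
genome promoters (Bonferroni 2080 × 21), step 2 against the directional DEG
promoters (survivors × 20).

A synthetic-data module generates DEG tables, annotations and promoters
with *planted* fold-change-specific structure (a term concentrated in a
target interval at concentration π; a hexamer inserted at different rates
inside/outside an interval), so the whole pipeline is validated by
parameter recovery and null false-positive simulations.

## Worked example

```python
from foldspec import ContingencyTable, fisher_one_sided

# a 108-gene term among 789 up-regulated genes, 96 members inside the
# 263-gene weakest-two-quantile interval
t = ContingencyTable(96, 12, 167, 514)
print(f"{100*t.a/t.focal_total:.1f}% vs {100*t.interval_total/t.universe:.1f}%")
print(f"{fisher_one_sided(t):.3e}")
```

prints

```
88.9% vs 33.3%
1.487e-38
```

— 88.9% of the term's genes fall in the weak-response window that holds
only 33.3% of all up-regulated genes, and the one-sided Fisher p of
1.5 × 10⁻³⁸ (before Bonferroni) marks the term as sharply
fold-change-specific. `examples/` contains runnable scripts for every
capability: quantile partitioning, the two-step GO test, promoter
extraction, hexamer scanning, and end-to-end recovery of planted structure.

A thin CLI wraps the pipeline:

```sh
foldspec go --deg deg.tsv --annotation ann.tsv --out out/
foldspec motif --deg deg.tsv --promoters promoters.fa --out out/
foldspec simulate --config cfg.yaml --out sim/
foldspec benchmark --out bench/
```

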