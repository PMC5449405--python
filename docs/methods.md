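# Methods

## Model and procedure

`foldspec` treats a differential-expression experiment as two directional
gene lists (up- and down-regulated, analysed separately throughout). Each
list is ranked by the linear fold-change magnitude |FC| (equivalently
|log2FC|; signed input tables are converted on read, FC = 2^|log2FC|) and
partitioned into q equal-size quantiles. Quantile k spans ranks
⌈(k−1)n/q⌉ … ⌈kn/q⌉−1 of the ascending ranking; sizes therefore differ by
at most one, with the extra genes placed so that a 789-gene list at q = 6
puts 263 genes in the two weakest quantiles. Ties in fold change are broken
lexicographically by gene id, making the partition invariant under input
permutation. Fold-change windows are *intervals* [a..b] of contiguous
quantiles — q(q+1)/2 in total including the full list, one fewer
("component" intervals) excluding it.

Both enrichment steps use the one-sided (over-representation) Fisher exact
test, computed as the exact hypergeometric tail P(X ≥ a) given the table's
margins, and Bonferroni correction sized to the family actually tested:

* **Step 1** tests every (term, interval) pair against a genome-scale
  background universe. The multiplier is (terms with ≥ `min_genes` members
  in some interval) × (number of intervals, full included). Terms passing
  adjusted p < α₁ = 0.001 anywhere are selected.
* **Step 2** tests each selected term against the directional DEG list
  itself over the component intervals only — the full interval is excluded
  because with every gene inside it the one-sided p is identically 1.
  Multiplier: (selected terms) × (component intervals). A term with minimum
  adjusted p < α₂ = 0.05 is fold-change-specific; its *best interval* is
  the argmin, ties resolved toward the shortest then weakest interval so
  the tightest specificity claim wins.

The hexamer arm is the same design over the 2080 canonical hexamers
(complementary pairs collapsed to the lexicographically smaller member; 64
palindromes are self-representative). The statistic is gene-level
*presence* (≥ 1 occurrence in the promoter region), not occurrence counts:
presence is the natural reading of a gene-level 2×2 design, and scanning a
single strand with canonicalisation is mathematically equivalent to
scanning both. Occurrence windows containing non-ACGT characters are
skipped rather than failing the gene. The step-1 Bonferroni multiplier uses
the full 2080-hexamer vocabulary (every hexamer is always tested); step 2
uses the count of step-1 survivors.

## Promoter regions

Promoters are the strand-aware regions [−`upstream_len` (default 1500 bp);
end of 5′UTR] around the representative transcript of each gene, extracted
from a genome FASTA + GFF3. The representative transcript is the mRNA with
the lowest-sorting identifier. Genes lacking an annotated 5′UTR fall back
to the pure upstream window [−upstream_len, TSS). Regions are clipped at
contig edges (logged) and are *not* truncated when they overlap a
neighbouring gene; provenance (contig, strand, 0-based half-open interval)
is recorded per gene. GFF3 1-based closed coordinates are converted to
0-based half-open on read.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `q` | 6 | quantile count; 3, 4 and 8 supported for robustness re-runs |
| `alpha1` | 0.001 | step-1 adjusted-p selection threshold |
| `alpha2` | 0.05 | step-2 fold-change-specificity threshold |
| `min_genes` | 2 | minimum term members in an interval to enter step 1 |
| `upstream_len` | 1500 bp | promoter length upstream of the TSS |
| `padj_threshold` | 0.05 | DEG inclusion cutoff on the adjusted p column |
| `background_mode` | annotation | step-1 universe: all annotated genes (+DEGs), or an explicit gene list |

The q = 6 labels vw/w/m/i/s/vs follow the field's very-weak…very-strong
naming; other q values use generic q1..qk labels since no canonical naming
exists there. The step-1 background is configurable because the exact
universe used by web enrichment services is generally unrecoverable; the
default is every gene appearing in the annotation plus all DEGs.

## Synthetic data

The generator emulates the shape of a hormone-response root transcriptome:
789 up- and 659 down-regulated genes by default, with linear fold changes
drawn from a log-normal (ln FC ~ Normal(1, 1)) clipped to 1.5–88 (up) and
1.4–143 (down) — a heavy-tailed magnitude distribution matching those
observed ranges. Any strictly positive distribution would serve; the
log-normal is a documented default, not a claim about the data-generating
process. Planted terms are defined on *rank* intervals (quantiles), exactly
how the pipeline stratifies, not on raw fold-change thresholds: a term of
size s at concentration π places round(π·s) members uniformly inside the
target interval and the rest among the same direction's DEGs outside it;
background terms draw uniformly from the whole gene universe (non-DEG
filler genes receive annotations and promoters too, so step-1 backgrounds
are realistic). Promoters are i.i.d. uniform ACGT (configurable GC);
planted hexamers overwrite one uniform random window per selected gene with
probability `presence_in` inside the target interval and `presence_out`
elsewhere. Every output is a pure function of the seed.

What passing recovery tests shows — and does not: the generator reproduces
ranked heavy-tailed fold changes, independent gene-set memberships and
independent promoter composition. It does not model correlated gene sets,
overlapping term hierarchies (unless an ontology is supplied), positional
motif preferences, dinucleotide promoter structure, or fold-change
estimation noise; recovery on synthetic data therefore demonstrates the
statistical machinery, not performance on any particular organism's data.

## Numerical choices

* Fisher p-values come from the exact hypergeometric survival function
  (scipy), never a normal approximation; the test suite checks agreement
  with an exact-rational enumeration oracle to 1e-12 on a thousand random
  tables with universe ≤ 200.
* Bonferroni-adjusted p = min(1, m·p) with m logged at each stage so the
  multiple-testing design of every run is auditable.
* Degenerate inputs: empty background and mixed-direction lists are
  errors; DEGs missing from the background are added with a warning; terms
  with no DEG members are skipped in step 2 with a warning; promoters
  shorter than 6 bp contribute no windows.
* Determinism: sorting with explicit tie-breaks everywhere (gene id,
  interval width then position), integer-seeded NumPy generators, no
  locale- or hash-order-dependent behaviour.

## Problem sizes used in validation

The recovery experiments run at a deliberately modest scale chosen to make
the statistical behaviour visible: planted-term runs use 1200 up-regulated
genes in a 5000-gene universe with 50 background terms (term size 100,
π = 0.85 or 0.9); null runs use 300 DEGs in a 2000-gene universe, 500
replicates; hexamer runs use a 3000-gene genome with 1500-bp promoters and
a 60%-vs-10% insertion contrast. These sizes give step-2 signals many
orders of magnitude below the thresholds when structure is present, and
family-wise false-positive rates indistinguishable from zero when it is
absent.

## Known limitations

Step 1 treats the background as a flat gene universe (no conditioning on
gene length, expression level or annotation breadth). Bonferroni control is
conservative given the strong overlap between nested intervals; an
FDR-based alternative would trade the family-wise guarantee for power and
is deliberately not part of the default procedure. The motif arm reports
presence-based enrichment only — occurrence counts and positional
preferences are out of scope.
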