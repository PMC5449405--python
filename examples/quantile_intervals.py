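"""Partition a directional DEG list into fold-change quantiles.

Builds a 789-gene up-regulated list (the scale of a typical root
transcriptome response), ranks it by linear fold change, cuts it into six
equal-size quantiles labelled very weak .. very strong, and enumerates the
21 contiguous fold-change intervals tested downstream.
"""

from foldspec import GeneRecord, Interval, enumerate_intervals, interval_gene_set, rank_and_partition

genes = [GeneRecord(f"U{i:04d}", "up", 1.5 + 0.11 * i) for i in range(789)]
part = rank_and_partition(genes, q=6)

print("quantile sizes:", part.sizes)
print("fold-change boundaries:", [round(b, 2) for b in part.boundaries])
intervals = enumerate_intervals(6, include_full=True)
print(f"{len(intervals)} intervals:", ", ".join(iv.label(6) for iv in intervals))
weak = interval_gene_set(part, Interval(1, 2))
print(f"genes in the very-weak-to-weak interval: {len(weak)} of {part.n}")

# The sizes differ by at most one; 263/789 genes sit in the two weakest
# quantiles, the denominator of the specificity test's background fraction.
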