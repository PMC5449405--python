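"""Quantile partitioning of ranked DEG lists and fold-change interval enumeration.

Each directional gene list (up- or down-regulated) is ranked by linear
fold-change magnitude and split into ``q`` equal-size quantiles (1 = weakest
response). A *fold-change interval* is a single quantile or a union of
neighbouring quantiles; intervals name the fold-change windows tested for
enrichment downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from .records import GeneRecord

#: Quantile labels for the canonical q=6 scheme, weakest to strongest.
Q6_LABELS = ("vw", "w", "m", "i", "s", "vs")


@dataclass(frozen=True, order=True)
class Interval:
    """A contiguous run of quantiles [lo..hi], 1-based inclusive."""

    lo: int
    hi: int

    def __post_init__(self) -> None:
        if not 1 <= self.lo <= self.hi:
            raise ValueError(f"invalid interval ({self.lo},{self.hi})")

    @property
    def width(self) -> int:
        return self.hi - self.lo + 1

    def label(self, q: int) -> str:
        """Human-readable label; vw..vs for q=6, q1..qk otherwise."""
        names = Q6_LABELS if q == 6 else tuple(f"q{i}" for i in range(1, q + 1))
        if self.hi > q:
            raise ValueError(f"interval {self} exceeds q={q}")
        if self.lo == self.hi:
            return names[self.lo - 1]
        return f"{names[self.lo - 1]}-{names[self.hi - 1]}"

    def overlaps(self, other: "Interval") -> bool:
        return self.lo <= other.hi and other.lo <= self.hi


@dataclass
class QuantilePartition:
    """A directional gene list ranked by fold change and cut into q quantiles.

    Attributes
    ----------
    direction : 'up' or 'down'
    q : number of quantiles
    ordered_genes : gene ids sorted by ascending fold change (ties by id)
    quantile_of : gene id -> quantile index in 1..q (1 = weakest)
    boundaries : fold-change values at the q+1 quantile edges
        (min, edge values between consecutive quantiles, max)
    sizes : genes per quantile
    fold_change : gene id -> linear fold-change magnitude
    """

    direction: str
    q: int
    ordered_genes: list[str]
    quantile_of: dict[str, int]
    boundaries: list[float]
    sizes: list[int]
    fold_change: dict[str, float]
    _offsets: list[int] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        if not self._offsets:
            off = [0]
            for s in self.sizes:
                off.append(off[-1] + s)
            self._offsets = off

    @property
    def n(self) -> int:
        return len(self.ordered_genes)

    def genes(self) -> set[str]:
        return set(self.ordered_genes)


def _quantile_sizes(n: int, q: int) -> list[int]:
    # quantile k spans ranks [ceil((k-1)n/q), ceil(kn/q)); reproduces the
    # 263-of-789 weakest-two-quantiles count for the q=6 reference split
    cum = [math.ceil(k * n / q) for k in range(q + 1)]
    return [cum[k + 1] - cum[k] for k in range(q)]


def rank_and_partition(genes: Sequence[GeneRecord], q: int) -> QuantilePartition:
    """Rank one directional gene list by fold change and cut into q quantiles.

    Genes are sorted ascending by fold-change magnitude with ties broken by
    gene id, so the partition is deterministic under input permutation.
    Quantile sizes differ by at most one.

    Raises
    ------
    ValueError
        If the list mixes directions, is smaller than q, or q < 2.
    """
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    records = list(genes)
    if len(records) < q:
        raise ValueError(f"need at least q={q} genes, got {len(records)}")
    directions = {g.direction for g in records}
    if len(directions) != 1:
        raise ValueError(f"mixed directions in one partition: {sorted(directions)}")
    direction = directions.pop()
    ids = {g.gene_id for g in records}
    if len(ids) != len(records):
        raise ValueError("duplicate gene ids within one direction")

    records.sort(key=lambda g: (g.fold_change, g.gene_id))
    n = len(records)
    sizes = _quantile_sizes(n, q)

    ordered = [g.gene_id for g in records]
    fc = {g.gene_id: g.fold_change for g in records}
    quantile_of: dict[str, int] = {}
    boundaries = [records[0].fold_change]
    pos = 0
    for k, size in enumerate(sizes, start=1):
        for g in records[pos : pos + size]:
            quantile_of[g.gene_id] = k
        pos += size
        boundaries.append(records[pos - 1].fold_change)
    return QuantilePartition(
        direction=direction,
        q=q,
        ordered_genes=ordered,
        quantile_of=quantile_of,
        boundaries=boundaries,
        sizes=sizes,
        fold_change=fc,
    )


def enumerate_intervals(q: int, include_full: bool = True) -> list[Interval]:
    """All contiguous quantile intervals, sorted by (width, lo).

    With the full interval (1,q) included there are q(q+1)/2 intervals
    (21 for q=6); excluding it leaves the q(q+1)/2 - 1 *component* intervals
    (20 for q=6).
    """
    if q < 2:
        raise ValueError(f"q must be >= 2, got {q}")
    ivs = [
        Interval(lo, hi)
        for hi in range(1, q + 1)
        for lo in range(1, hi + 1)
        if include_full or not (lo == 1 and hi == q)
    ]
    ivs.sort(key=lambda iv: (iv.width, iv.lo))
    return ivs


def interval_gene_set(p: QuantilePartition, iv: Interval) -> set[str]:
    """Genes whose quantile falls inside the interval (union of quantiles lo..hi)."""
    return set(interval_gene_list(p, iv))


def interval_gene_list(p: QuantilePartition, iv: Interval) -> list[str]:
    """Like :func:`interval_gene_set` but preserving the fold-change ranking."""
    if iv.hi > p.q:
        raise ValueError(f"interval {iv} exceeds partition q={p.q}")
    return p.ordered_genes[p._offsets[iv.lo - 1] : p._offsets[iv.hi]]


def interval_mask(p: QuantilePartition, iv: Interval, gene_index: dict[str, int], size: int):
    """Boolean membership vector of the interval over an indexed gene universe."""
    import numpy as np

    mask = np.zeros(size, dtype=bool)
    for g in interval_gene_list(p, iv):
        idx = gene_index.get(g)
        if idx is not None:
            mask[idx] = True
    return mask
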