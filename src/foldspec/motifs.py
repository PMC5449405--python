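"""Canonical hexamer enumeration, promoter scanning, and two-step motif enrichment.

A hexamer and its reverse complement read the same double-stranded site, so
complementary pairs are collapsed to one *canonical* representative (the
lexicographically smaller of the pair). Of the 4^6 = 4096 raw hexamers, 64
are palindromic (self-complementary), giving (4096 - 64)/2 + 64 = 2080
canonical classes. Presence (>= 1 occurrence anywhere in a gene's promoter
region) feeds gene-level 2x2 tables; scanning one strand with
canonicalisation covers both strands.

The two-step test mirrors the GO procedure: step 1 compares each interval's
genes against the whole-genome promoter set (Bonferroni over 2080 x
intervals); step 2 tests survivors for fold-change-specificity against the
directional DEG promoters (Bonferroni over survivors x component intervals).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .enrichment import ContingencyTable, _fisher_sf_vec, bonferroni
from .intervals import Interval, QuantilePartition, enumerate_intervals, interval_gene_list
from .records import PromoterSet

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_BASES = "ACGT"
K = 6
N_CANONICAL = 2080


def revcomp(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; an involution."""
    s = seq.upper()
    if set(s) - set("ACGTN"):
        raise ValueError(f"non-DNA characters in {seq!r}")
    return s.translate(_COMPLEMENT)[::-1]


def canonical(hexamer: str) -> str:
    """Lexicographically smaller of {h, revcomp(h)}; idempotent."""
    h = hexamer.upper()
    if len(h) != K:
        raise ValueError(f"expected a hexamer, got {hexamer!r}")
    return min(h, revcomp(h))


@dataclass(frozen=True)
class CanonicalHexamer:
    sequence: str
    palindromic: bool

    @property
    def pair(self) -> str:
        """Display form 'h/revcomp(h)'."""
        return f"{self.sequence}/{revcomp(self.sequence)}"


def _all_kmers() -> list[str]:
    out = [""]
    for _ in range(K):
        out = [s + b for s in out for b in _BASES]
    return out


def enumerate_canonical_hexamers() -> list[CanonicalHexamer]:
    """All 2080 canonical hexamers, lexicographically sorted."""
    seen: dict[str, bool] = {}
    for h in _all_kmers():
        rc = revcomp(h)
        c = min(h, rc)
        seen.setdefault(c, h == rc)
    return [CanonicalHexamer(s, pal) for s, pal in sorted(seen.items())]


def _build_tables() -> tuple[np.ndarray, list[str]]:
    """Lookup from raw hexamer code (base-4 big-endian) to canonical class index."""
    canon = enumerate_canonical_hexamers()
    seqs = [c.sequence for c in canon]
    idx_of = {s: i for i, s in enumerate(seqs)}
    lut = np.empty(4 ** K, dtype=np.int32)
    base_of = {b: i for i, b in enumerate(_BASES)}
    for h in _all_kmers():
        code = 0
        for ch in h:
            code = code * 4 + base_of[ch]
        lut[code] = idx_of[canonical(h)]
    return lut, seqs


_CANON_LUT: np.ndarray | None = None
_CANON_SEQS: list[str] | None = None


def _canon_tables() -> tuple[np.ndarray, list[str]]:
    global _CANON_LUT, _CANON_SEQS
    if _CANON_LUT is None:
        _CANON_LUT, _CANON_SEQS = _build_tables()
    return _CANON_LUT, _CANON_SEQS


_CHAR_LUT = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _CHAR_LUT[ord(_b)] = _i
    _CHAR_LUT[ord(_b.lower())] = _i


class MotifPresence:
    """Binary presence of each canonical hexamer per gene.

    Backed by a genes x 2080 boolean matrix for vectorised testing; the
    mapping interface yields per-gene sets of canonical hexamer strings.
    """

    def __init__(self, gene_ids: list[str], matrix: np.ndarray):
        self.gene_ids = gene_ids
        self.matrix = matrix
        self._index = {g: i for i, g in enumerate(gene_ids)}
        _, self.hexamers = _canon_tables()

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    def __len__(self) -> int:
        return len(self.gene_ids)

    def hexamers_in(self, gene_id: str) -> set[str]:
        row = self.matrix[self._index[gene_id]]
        return {self.hexamers[j] for j in np.flatnonzero(row)}

    def presence_of(self, hexamer: str) -> np.ndarray:
        """Boolean vector over gene_ids for one hexamer (canonicalised)."""
        j = self.hexamers.index(canonical(hexamer))
        return self.matrix[:, j]


def scan_presence(promoters: PromoterSet | dict[str, str]) -> MotifPresence:
    """Slide a 6-bp window over each promoter and record canonical presence.

    Windows containing non-ACGT characters contribute nothing; sequences
    shorter than 6 bp yield an empty presence set.
    """
    seqs = promoters.sequences if isinstance(promoters, PromoterSet) else promoters
    gene_ids = sorted(seqs)
    lut, _ = _canon_tables()
    matrix = np.zeros((len(gene_ids), N_CANONICAL), dtype=bool)

    # concatenate with N spacers so windows never straddle two genes
    spacer = "N" * K
    blob = spacer.join(seqs[g] for g in gene_ids)
    arr = _CHAR_LUT[np.frombuffer(blob.encode("ascii"), dtype=np.uint8)]
    if arr.size >= K:
        win = np.lib.stride_tricks.sliding_window_view(arr, K)
        valid = (win < 4).all(axis=1)
        codes = np.zeros(win.shape[0], dtype=np.int64)
        for k in range(K):
            codes = codes * 4 + np.where(valid, win[:, k], 0)
        offset = 0
        for i, g in enumerate(gene_ids):
            length = len(seqs[g])
            if length < K:
                logger.warning("promoter of %s shorter than %d bp; no windows", g, K)
            else:
                lo, hi = offset, offset + length - K + 1
                v = valid[lo:hi]
                if v.any():
                    matrix[i, lut[np.unique(codes[lo:hi][v])]] = True
            offset += length + K
    return MotifPresence(gene_ids, matrix)


@dataclass
class HexamerResult:
    hexamer: CanonicalHexamer
    direction: str
    interval: Interval
    counts: ContingencyTable
    step1_raw_p: float
    step1_adj_p: float
    step2_raw_p: float
    step2_adj_p: float
    fold_change_specific: bool


def hexamer_two_step(
    presence: MotifPresence,
    partition: QuantilePartition,
    genome_genes: set[str] | list[str],
    alpha1: float = 0.001,
    alpha2: float = 0.05,
    include_full: bool = True,
) -> list[HexamerResult]:
    """Two-step hexamer enrichment for one direction.

    Step 1: per interval (full included), {genes in interval vs rest of
    genome} x {has hexamer vs not}, Bonferroni over 2080 x intervals.
    Step 2: for hexamers passing step 1, {DEGs in interval vs remaining
    DEGs} x {has hexamer vs not}, Bonferroni over survivors x component
    intervals. Returns one result per surviving hexamer at its best step-2
    interval. Genes without promoters are excluded from both margins.
    """
    genome = set(genome_genes) | partition.genes()
    with_prom = {g for g in genome if g in presence}
    dropped = genome - with_prom
    if dropped:
        logger.warning("%d genes lack promoters and are excluded (e.g. %s)",
                       len(dropped), sorted(dropped)[:3])

    bg_list = sorted(with_prom)
    rows = np.array([presence._index[g] for g in bg_list])
    mat = presence.matrix[rows]  # genes x 2080
    gene_index = {g: i for i, g in enumerate(bg_list)}
    universe = len(bg_list)
    hex_tot = mat.sum(axis=0).astype(np.int64)  # genome-wide presence per hexamer

    intervals1 = enumerate_intervals(partition.q, include_full=include_full)
    mult1 = N_CANONICAL * len(intervals1)
    logger.info("hexamers tested: %d", N_CANONICAL)
    logger.info("motif step 1 (%s): Bonferroni multiplier %d x %d = %d",
                partition.direction, N_CANONICAL, len(intervals1), mult1)

    step1_raw = np.ones((N_CANONICAL, len(intervals1)))
    step1_a = np.zeros((N_CANONICAL, len(intervals1)), dtype=np.int64)
    iv_sizes = []
    for k, iv in enumerate(intervals1):
        idx = [gene_index[g] for g in interval_gene_list(partition, iv) if g in gene_index]
        iv_sizes.append(len(idx))
        a = mat[idx].sum(axis=0).astype(np.int64)
        step1_a[:, k] = a
        step1_raw[:, k] = _fisher_sf_vec(a, hex_tot, len(idx), universe)
    step1_adj = np.minimum(1.0, step1_raw * mult1)
    surviving = np.flatnonzero(step1_adj.min(axis=1) < alpha1)
    logger.info("motif step 1 (%s): %d hexamers pass adj p < %g",
                partition.direction, len(surviving), alpha1)
    if len(surviving) == 0:
        return []

    # step 2: universe is the directional DEG set (with promoters)
    deg_list = [g for g in partition.ordered_genes if g in gene_index]
    deg_rows = np.array([gene_index[g] for g in deg_list])
    deg_mat = mat[np.ix_(deg_rows, surviving)]  # DEGs x survivors
    deg_index = {g: i for i, g in enumerate(deg_list)}
    n_deg = len(deg_list)
    deg_tot = deg_mat.sum(axis=0).astype(np.int64)

    intervals2 = enumerate_intervals(partition.q, include_full=False)
    mult2 = len(surviving) * len(intervals2)
    logger.info("motif step 2 (%s): Bonferroni multiplier %d x %d = %d",
                partition.direction, len(surviving), len(intervals2), mult2)

    step2_raw = np.ones((len(surviving), len(intervals2)))
    step2_a = np.zeros((len(surviving), len(intervals2)), dtype=np.int64)
    iv2_sizes = []
    for k, iv in enumerate(intervals2):
        idx = [deg_index[g] for g in interval_gene_list(partition, iv) if g in deg_index]
        iv2_sizes.append(len(idx))
        a = deg_mat[idx].sum(axis=0).astype(np.int64)
        step2_a[:, k] = a
        step2_raw[:, k] = _fisher_sf_vec(a, deg_tot, len(idx), universe=n_deg)
    step2_adj = np.minimum(1.0, step2_raw * mult2)

    _, canon_seqs = _canon_tables()
    canon = enumerate_canonical_hexamers()
    results: list[HexamerResult] = []
    for si, hi in enumerate(surviving):
        order = sorted(
            range(len(intervals2)),
            key=lambda k: (step2_adj[si, k], intervals2[k].width, intervals2[k].lo),
        )
        kbest = order[0]
        iv = intervals2[kbest]
        a = int(step2_a[si, kbest])
        t = ContingencyTable(
            a=a,
            b=int(deg_tot[si]) - a,
            c=iv2_sizes[kbest] - a,
            d=n_deg - int(deg_tot[si]) - iv2_sizes[kbest] + a,
        )
        results.append(
            HexamerResult(
                hexamer=canon[hi],
                direction=partition.direction,
                interval=iv,
                counts=t,
                step1_raw_p=float(step1_raw[hi].min()),
                step1_adj_p=float(step1_adj[hi].min()),
                step2_raw_p=float(step2_raw[si, kbest]),
                step2_adj_p=float(step2_adj[si, kbest]),
                fold_change_specific=bool(step2_adj[si, kbest] < alpha2),
            )
        )
    results.sort(key=lambda r: (r.step2_adj_p, r.hexamer.sequence))
    return results
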