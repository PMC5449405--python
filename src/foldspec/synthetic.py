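"""Synthetic DEG tables, annotations and promoters with planted structure.

The generator emulates the shape of an auxin-style root transcriptome
experiment: two directional DEG lists (defaults 789 up, 659 down) whose
linear fold changes follow a clipped log-normal spanning roughly 1.5-88
(up) and 1.4-143 (down); gene-set annotations in which chosen terms
concentrate their members inside a chosen quantile interval at a chosen
concentration pi; and random promoters into which a chosen hexamer is
inserted preferentially for genes of a chosen interval. Ground truth is
recorded alongside so recovery can be scored without re-derivation. A seed
fully determines every output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .intervals import Interval, interval_gene_set, rank_and_partition
from .records import GeneRecord, GeneSetAnnotation, PromoterSet


@dataclass(frozen=True)
class PlantedTerm:
    term_id: str
    size: int
    direction: str
    interval: tuple[int, int]
    concentration: float  # pi: fraction of members inside the target interval


@dataclass(frozen=True)
class MotifPlant:
    hexamer: str
    direction: str
    interval: tuple[int, int]
    presence_in: float  # insertion probability for target-interval genes
    presence_out: float  # insertion probability for every other gene


@dataclass
class SyntheticConfig:
    n_up: int = 789
    n_down: int = 659
    q: int = 6
    fc_log_mean: float = 1.0  # mean of ln(fold change)
    fc_log_sd: float = 1.0
    fc_range_up: tuple[float, float] = (1.5, 88.0)
    fc_range_down: tuple[float, float] = (1.4, 143.0)
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    n_background_terms: int = 50
    background_term_size_range: tuple[int, int] = (10, 200)
    promoter_length: int = 1500
    gc_content: float = 0.5
    motif_plants: list[MotifPlant] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.fc_range_up, self.fc_range_down):
            if lo >= hi:
                raise ValueError(f"degenerate fold-change range ({lo}, {hi})")
        for p in self.planted_terms:
            width = p.interval[1] - p.interval[0] + 1
            if p.concentration < width / self.q:
                raise ValueError(
                    f"planting {p.term_id}: concentration {p.concentration} below the "
                    f"interval's background share {width}/{self.q} would be depletion"
                )


@dataclass
class GroundTruth:
    planted_terms: list[PlantedTerm] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    quantile_of: dict[str, dict[str, int]] = field(default_factory=dict)  # direction -> gene -> q

    def to_dict(self) -> dict:
        return {
            "planted_terms": [asdict(p) for p in self.planted_terms],
            "motif_plants": [asdict(m) for m in self.motif_plants],
            "quantile_of": self.quantile_of,
        }


def _gen_direction(
    rng: np.random.Generator, n: int, prefix: str, direction: str,
    cfg: SyntheticConfig, fc_range: tuple[float, float],
) -> list[GeneRecord]:
    fc = np.exp(rng.normal(cfg.fc_log_mean, cfg.fc_log_sd, size=n))
    fc = np.clip(fc, *fc_range)
    padj = rng.uniform(0.0, 0.049, size=n)
    return [
        GeneRecord(f"{prefix}{i:05d}", direction, float(fc[i]), float(padj[i]))
        for i in range(n)
    ]


def gen_deg_table(cfg: SyntheticConfig) -> tuple[list[GeneRecord], GroundTruth]:
    """Two directional DEG lists with clipped log-normal fold changes."""
    if cfg.n_up < cfg.q or cfg.n_down < cfg.q:
        raise ValueError("n_up and n_down must each be >= q")
    rng = np.random.default_rng(cfg.seed)
    ups = _gen_direction(rng, cfg.n_up, "UP", "up", cfg, cfg.fc_range_up)
    downs = _gen_direction(rng, cfg.n_down, "DN", "down", cfg, cfg.fc_range_down)
    records = ups + downs
    truth = GroundTruth()
    for direction, recs in (("up", ups), ("down", downs)):
        part = rank_and_partition(recs, cfg.q)
        truth.quantile_of[direction] = dict(part.quantile_of)
    return records, truth


def genome_gene_ids(genome_size: int, degs: list[GeneRecord]) -> list[str]:
    """DEG ids plus enough non-DEG filler ids to reach genome_size, sorted."""
    deg_ids = [g.gene_id for g in degs]
    n_extra = genome_size - len(deg_ids)
    if n_extra < 0:
        raise ValueError(f"genome_size {genome_size} smaller than DEG count {len(deg_ids)}")
    return sorted(deg_ids + [f"BG{i:06d}" for i in range(n_extra)])


def gen_annotation(
    cfg: SyntheticConfig, degs: list[GeneRecord], genome_size: int
) -> tuple[GeneSetAnnotation, GroundTruth]:
    """Background terms drawn uniformly from the gene universe, plus planted
    terms concentrated in their target quantile intervals.

    A planted term of size s places round(pi*s) members inside the target
    interval of its direction's partition (without replacement) and the rest
    among the same direction's DEGs outside the interval.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    universe = genome_gene_ids(genome_size, degs)
    ann = GeneSetAnnotation()
    lo, hi = cfg.background_term_size_range
    for i in range(cfg.n_background_terms):
        size = int(rng.integers(lo, hi + 1))
        for g in rng.choice(universe, size=size, replace=False):
            ann.add(f"BGTERM{i:04d}", str(g))
        ann.set_meta(f"BGTERM{i:04d}", name=f"background term {i}")

    parts = {
        d: rank_and_partition([g for g in degs if g.direction == d], cfg.q)
        for d in ("up", "down")
    }
    truth = GroundTruth(planted_terms=list(cfg.planted_terms))
    for p in cfg.planted_terms:
        part = parts[p.direction]
        inside = sorted(interval_gene_set(part, Interval(*p.interval)))
        outside = sorted(part.genes() - set(inside))
        n_in = round(p.concentration * p.size)
        n_out = p.size - n_in
        if n_in > len(inside):
            raise ValueError(
                f"planting {p.term_id}: {n_in} members exceed interval capacity {len(inside)}"
            )
        if n_out > len(outside):
            raise ValueError(f"planting {p.term_id}: {n_out} members exceed outside capacity")
        for g in rng.choice(inside, size=n_in, replace=False):
            ann.add(p.term_id, str(g))
        if n_out:
            for g in rng.choice(outside, size=n_out, replace=False):
                ann.add(p.term_id, str(g))
        ann.set_meta(p.term_id, name=f"planted {p.term_id}")
    for d, part in parts.items():
        truth.quantile_of[d] = dict(part.quantile_of)
    return ann, truth


def gen_promoters(
    cfg: SyntheticConfig, degs: list[GeneRecord], genome_genes: list[str]
) -> tuple[PromoterSet, GroundTruth]:
    """I.i.d. background promoters with hexamers planted by interval.

    Each gene gets a promoter of ``promoter_length`` drawn i.i.d. with the
    configured GC content. For each motif plant, the hexamer overwrites a
    uniform random window with probability presence_in for genes inside the
    plant's target interval and presence_out for every other gene.
    """
    if cfg.promoter_length < 6:
        raise ValueError("promoter_length must be >= 6")
    rng = np.random.default_rng(cfg.seed + 2)
    gc = cfg.gc_content
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    base_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)

    target_sets: list[set[str]] = []
    for m in cfg.motif_plants:
        part = rank_and_partition([g for g in degs if g.direction == m.direction], cfg.q)
        target_sets.append(interval_gene_set(part, Interval(*m.interval)))

    genes = sorted(genome_genes)
    L = cfg.promoter_length
    codes = rng.choice(4, size=(len(genes), L), p=probs).astype(np.uint8)
    ps = PromoterSet()
    for i, gene in enumerate(genes):
        row = base_bytes[codes[i]]
        for m, targets in zip(cfg.motif_plants, target_sets):
            p_insert = m.presence_in if gene in targets else m.presence_out
            if rng.random() < p_insert:
                pos = int(rng.integers(0, L - 6 + 1))
                row[pos : pos + 6] = np.frombuffer(m.hexamer.upper().encode(), dtype=np.uint8)
        ps.add(gene, row.tobytes().decode("ascii"))
    truth = GroundTruth(motif_plants=list(cfg.motif_plants))
    return ps, truth
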