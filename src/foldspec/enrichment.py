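"""Two-step fold-change-specific enrichment testing.

Step 1 asks the classic over-representation question: is a gene set (GO
term) enriched among the genes of one fold-change interval, against a
genome-wide background? It is run for every interval including the full
directional DEG list, with a Bonferroni multiplier of (terms tested) x
(intervals tested), and terms passing an adjusted-p cutoff (default 0.001)
are carried forward.

Step 2 asks the *specificity* question: within the directional DEG list
itself, are the term's member genes concentrated in one component interval?
The 2x2 table is {term genes in/out of interval} x {remaining DEGs in/out},
one-sided Fisher, Bonferroni over (selected terms) x (component intervals).
A term whose minimum adjusted p falls below 0.05 is *fold-change-specific*,
and the interval attaining that minimum is its best interval. The full
interval is excluded in step 2: with every gene inside, its one-sided p is
identically 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom

from .intervals import Interval, QuantilePartition, enumerate_intervals, interval_gene_list
from .records import GeneSetAnnotation

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 counts: focal genes in/out of the interval vs the rest.

    a = focal genes inside the interval, b = focal genes outside,
    c = non-focal genes inside, d = non-focal genes outside.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError(f"negative count in {self}")

    @property
    def focal_total(self) -> int:
        return self.a + self.b

    @property
    def interval_total(self) -> int:
        return self.a + self.c

    @property
    def universe(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    term_id: str
    interval: Interval
    direction: str
    counts: ContingencyTable
    raw_p: float
    adj_p: float
    significant: bool


@dataclass
class SpecificityResult:
    term_id: str
    direction: str
    per_interval: list[tuple[Interval, float, float]]
    best_interval: Interval | None
    fold_change_specific: bool
    best_counts: ContingencyTable | None = None

    @property
    def min_adj_p(self) -> float:
        return min(adj for _, _, adj in self.per_interval) if self.per_interval else 1.0

    @property
    def min_raw_p(self) -> float:
        return min(raw for _, raw, _ in self.per_interval) if self.per_interval else 1.0


def fisher_one_sided(t: ContingencyTable) -> float:
    """One-sided (enrichment) Fisher exact p: P(X >= a) under the hypergeometric
    distribution with the table's margins."""
    return float(hypergeom.sf(t.a - 1, t.universe, t.focal_total, t.interval_total))


def bonferroni(raw_p: float, m: int) -> float:
    """Bonferroni-adjusted p: min(1, raw_p * m)."""
    if m < 1:
        raise ValueError(f"Bonferroni multiplier must be >= 1, got {m}")
    return min(1.0, raw_p * m)


def _fisher_sf_vec(a: np.ndarray, focal_tot: np.ndarray, interval_tot, universe: int) -> np.ndarray:
    # vectorised P(X >= a) over many tables sharing the universe size
    return hypergeom.sf(a - 1, universe, focal_tot, interval_tot)


def _membership_matrix(
    term_ids: list[str], ann: GeneSetAnnotation, gene_index: dict[str, int]
) -> np.ndarray:
    m = np.zeros((len(term_ids), len(gene_index)), dtype=bool)
    for i, t in enumerate(term_ids):
        for g in ann.genes_for(t):
            j = gene_index.get(g)
            if j is not None:
                m[i, j] = True
    return m


def step1_enrichment(
    partition: QuantilePartition,
    ann: GeneSetAnnotation,
    background: set[str] | list[str],
    alpha1: float = 0.001,
    min_genes: int = 2,
    include_full: bool = True,
) -> list[EnrichmentResult]:
    """Per-interval over-representation of every gene set vs the background.

    Every DEG in the partition must be part of the background universe;
    missing DEGs are added with a warning. Only terms with at least
    ``min_genes`` members in at least one tested interval enter the family,
    and the Bonferroni multiplier is (terms tested) x (intervals tested).
    """
    bg = set(background)
    if not bg:
        raise ValueError("empty background universe")
    missing = partition.genes() - bg
    if missing:
        logger.warning(
            "%d DEGs absent from background; adding them (e.g. %s)",
            len(missing),
            sorted(missing)[:3],
        )
        bg |= missing

    bg_list = sorted(bg)
    gene_index = {g: i for i, g in enumerate(bg_list)}
    universe = len(bg_list)

    intervals = enumerate_intervals(partition.q, include_full=include_full)
    iv_masks = np.zeros((len(intervals), universe), dtype=bool)
    for k, iv in enumerate(intervals):
        for g in interval_gene_list(partition, iv):
            iv_masks[k, gene_index[g]] = True

    term_ids = sorted(ann.terms)
    memb = _membership_matrix(term_ids, ann, gene_index)

    # counts of term members inside each interval: terms x intervals
    a_mat = memb.astype(np.int64) @ iv_masks.T.astype(np.int64)
    tested = (a_mat >= min_genes).any(axis=1)
    if not tested.any():
        logger.warning("no terms with >= %d genes in any interval", min_genes)
        return []
    term_ids = [t for t, keep in zip(term_ids, tested) if keep]
    memb = memb[tested]
    a_mat = a_mat[tested]

    focal_tot = memb.sum(axis=1)  # term size within background
    iv_tot = iv_masks.sum(axis=1)  # interval sizes
    multiplier = len(term_ids) * len(intervals)
    logger.info(
        "step 1 (%s): %d terms x %d intervals, Bonferroni multiplier %d, universe %d",
        partition.direction,
        len(term_ids),
        len(intervals),
        multiplier,
        universe,
    )

    results: list[EnrichmentResult] = []
    for k, iv in enumerate(intervals):
        raw = _fisher_sf_vec(a_mat[:, k], focal_tot, int(iv_tot[k]), universe)
        for i, term in enumerate(term_ids):
            a = int(a_mat[i, k])
            t = ContingencyTable(
                a=a,
                b=int(focal_tot[i]) - a,
                c=int(iv_tot[k]) - a,
                d=universe - int(focal_tot[i]) - int(iv_tot[k]) + a,
            )
            p = float(raw[i])
            adj = bonferroni(p, multiplier)
            results.append(
                EnrichmentResult(
                    term_id=term,
                    interval=iv,
                    direction=partition.direction,
                    counts=t,
                    raw_p=p,
                    adj_p=adj,
                    significant=adj < alpha1,
                )
            )
    return results


def select_terms(results: list[EnrichmentResult]) -> list[str]:
    """Terms significant in at least one step-1 interval, sorted."""
    return sorted({r.term_id for r in results if r.significant})


def step2_specificity(
    selected_terms: list[str],
    partition: QuantilePartition,
    ann: GeneSetAnnotation,
    alpha2: float = 0.05,
) -> list[SpecificityResult]:
    """Fold-change-specificity of selected terms within the directional DEG set.

    The universe is the directional DEG list itself; the 2x2 table for a term
    and a component interval counts term genes in/out of the interval against
    the remaining DEGs in/out. Bonferroni multiplier = (selected terms) x
    (component intervals); a term is fold-change-specific when its minimum
    adjusted p is below ``alpha2``, and its best interval is the argmin.
    """
    deg_genes = partition.genes()
    universe = partition.n
    intervals = enumerate_intervals(partition.q, include_full=False)

    usable: list[tuple[str, set[str]]] = []
    for term in selected_terms:
        members = ann.genes_for(term) & deg_genes
        if not members:
            logger.warning("term %s has no genes in the %s set; skipped", term, partition.direction)
            continue
        usable.append((term, members))
    if not usable:
        return []

    multiplier = len(usable) * len(intervals)
    logger.info(
        "step 2 (%s): %d terms x %d component intervals, Bonferroni multiplier %d",
        partition.direction,
        len(usable),
        len(intervals),
        multiplier,
    )

    iv_sets = [set(interval_gene_list(partition, iv)) for iv in intervals]
    results: list[SpecificityResult] = []
    for term, members in usable:
        focal = len(members)
        per_interval: list[tuple[Interval, float, float]] = []
        tables: list[ContingencyTable] = []
        for iv, iv_genes in zip(intervals, iv_sets):
            a = len(members & iv_genes)
            t = ContingencyTable(
                a=a, b=focal - a, c=len(iv_genes) - a, d=universe - focal - len(iv_genes) + a
            )
            raw = fisher_one_sided(t)
            per_interval.append((iv, raw, bonferroni(raw, multiplier)))
            tables.append(t)
        res = SpecificityResult(
            term_id=term,
            direction=partition.direction,
            per_interval=per_interval,
            best_interval=None,
            fold_change_specific=min(adj for _, _, adj in per_interval) < alpha2,
        )
        if res.fold_change_specific:
            best = assign_best_interval(res)
            res.best_interval = best
            res.best_counts = tables[intervals.index(best)]
        results.append(res)
    return results


def assign_best_interval(res: SpecificityResult) -> Interval:
    """Interval with minimal adjusted p; ties broken by (width, lo) so the
    shortest, weakest-fold interval wins — the tightest specificity claim."""
    if not res.per_interval:
        raise ValueError("no tested intervals")
    return min(res.per_interval, key=lambda x: (x[2], x[0].width, x[0].lo))[0]
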