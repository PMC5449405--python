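"""Core domain records shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """One differentially expressed gene.

    ``fold_change`` is the linear-scale magnitude of the response (>= 1 by
    convention for both directions); ``direction`` is 'up' or 'down'.
    """

    gene_id: str
    direction: str
    fold_change: float
    adj_p: float | None = None

    def __post_init__(self) -> None:
        if self.direction not in ("up", "down"):
            raise ValueError(f"direction must be 'up' or 'down', got {self.direction!r}")
        if not self.fold_change > 0:
            raise ValueError(f"fold_change must be positive, got {self.fold_change}")
        if self.adj_p is not None and not 0.0 <= self.adj_p <= 1.0:
            raise ValueError(f"adj_p outside [0,1]: {self.adj_p}")


@dataclass
class TermMeta:
    name: str = ""
    namespace: str = ""


class GeneSetAnnotation:
    """term id -> set of gene ids, with optional term metadata."""

    def __init__(self) -> None:
        self.terms: dict[str, set[str]] = {}
        self.meta: dict[str, TermMeta] = {}

    def add(self, term_id: str, gene_id: str) -> None:
        self.terms.setdefault(term_id, set()).add(gene_id)

    def genes_for(self, term_id: str) -> set[str]:
        return self.terms.get(term_id, set())

    def set_meta(self, term_id: str, name: str = "", namespace: str = "") -> None:
        self.meta[term_id] = TermMeta(name=name, namespace=namespace)

    def term_name(self, term_id: str) -> str:
        return self.meta.get(term_id, TermMeta()).name

    def term_namespace(self, term_id: str) -> str:
        return self.meta.get(term_id, TermMeta()).namespace

    def gene_universe(self) -> set[str]:
        out: set[str] = set()
        for genes in self.terms.values():
            out |= genes
        return out

    def n_memberships(self) -> int:
        return sum(len(g) for g in self.terms.values())

    def __len__(self) -> int:
        return len(self.terms)

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __iter__(self):
        return iter(self.terms)

    def copy(self) -> "GeneSetAnnotation":
        new = GeneSetAnnotation()
        new.terms = {t: set(g) for t, g in self.terms.items()}
        new.meta = {t: TermMeta(m.name, m.namespace) for t, m in self.meta.items()}
        return new


@dataclass
class PromoterProvenance:
    chrom: str
    strand: str
    start: int  # 0-based half-open genomic interval actually extracted
    end: int
    clipped: bool = False


@dataclass
class PromoterSet:
    """gene id -> upper-case promoter sequence, with extraction provenance."""

    sequences: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, PromoterProvenance] = field(default_factory=dict)

    def add(self, gene_id: str, seq: str, prov: PromoterProvenance | None = None) -> None:
        self.sequences[gene_id] = seq.upper()
        if prov is not None:
            self.provenance[gene_id] = prov

    def __len__(self) -> int:
        return len(self.sequences)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.sequences

    def __getitem__(self, gene_id: str) -> str:
        return self.sequences[gene_id]

    def gene_ids(self) -> list[str]:
        return sorted(self.sequences)
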