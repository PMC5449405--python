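"""Readers and writers for every external format the pipeline touches.

DEG tables (TSV, signed log2 or direction + linear fold change), gene-set
annotations (two-column TSV or GAF 2.x), OBO ontologies (via obonet) with
is_a/part_of ancestor propagation, genome FASTA + GFF3 promoter extraction,
promoter FASTA, and the result TSVs. All coordinates are handled internally
as 0-based half-open; GFF3's 1-based closed intervals are converted on read.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .intervals import Interval
from .records import GeneRecord, GeneSetAnnotation, PromoterProvenance, PromoterSet

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """A file does not match its declared format."""


# ---------------------------------------------------------------- DEG tables


@dataclass
class DegTableSchema:
    """Column mapping for a DEG table.

    Either ``log2fc`` (signed) or both ``direction`` and ``fold_change``
    (linear magnitude) must be present in the file. ``padj_threshold`` rows
    above the adjusted-p cutoff are excluded when the column exists.
    """

    gene_id: str = "gene_id"
    log2fc: str = "log2FoldChange"
    direction: str = "direction"
    fold_change: str = "fold_change"
    padj: str = "padj"
    padj_threshold: float = 0.05


def read_deg_table(
    path: str | Path,
    schema: DegTableSchema | None = None,
    direction: str | None = None,
) -> list[GeneRecord]:
    """Read a DEG table into GeneRecords.

    Signed log2 fold changes are converted to direction + linear magnitude
    (fold_change = 2^|log2FC|). With ``direction`` given, the file may carry
    only gene ids and linear fold changes (the two-list form: one file per
    direction).
    """
    schema = schema or DegTableSchema()
    df = pd.read_csv(path, sep="\t", dtype=str)
    if schema.gene_id not in df.columns:
        raise FormatError(f"missing column {schema.gene_id!r} in {path}")

    signed = schema.log2fc in df.columns
    if not signed:
        if schema.fold_change not in df.columns:
            raise FormatError(
                f"need column {schema.log2fc!r} or {schema.fold_change!r} in {path}"
            )
        if direction is None and schema.direction not in df.columns:
            raise FormatError(
                f"missing column {schema.direction!r} in {path} (or pass direction=)"
            )

    has_padj = schema.padj in df.columns
    records: list[GeneRecord] = []
    for line_no, row in enumerate(df.itertuples(index=False), start=2):
        row = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        adj_p = None
        if has_padj:
            try:
                adj_p = float(row[schema.padj])
            except (TypeError, ValueError):
                raise FormatError(f"{path}:{line_no}: non-numeric adjusted p {row[schema.padj]!r}")
            if not adj_p < schema.padj_threshold:
                continue
        if signed:
            try:
                l2 = float(row[schema.log2fc])
            except (TypeError, ValueError):
                raise FormatError(f"{path}:{line_no}: non-numeric fold change {row[schema.log2fc]!r}")
            if l2 == 0.0:
                logger.warning("%s:%d: log2FC of 0; row skipped", path, line_no)
                continue
            d = "up" if l2 > 0 else "down"
            fc = 2.0 ** abs(l2)
        else:
            d = direction if direction is not None else str(row[schema.direction]).strip().lower()
            try:
                fc = float(row[schema.fold_change])
            except (TypeError, ValueError):
                raise FormatError(
                    f"{path}:{line_no}: non-numeric fold change {row[schema.fold_change]!r}"
                )
        records.append(GeneRecord(str(row[schema.gene_id]), d, fc, adj_p))
    return records


def write_deg_table(records: list[GeneRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in records],
            "direction": [r.direction for r in records],
            "fold_change": [r.fold_change for r in records],
            "padj": [r.adj_p if r.adj_p is not None else math.nan for r in records],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------- gene annotations


def read_gene_sets(path: str | Path, format: str = "two_column_tsv") -> GeneSetAnnotation:
    """Read a gene->term annotation: two-column TSV (gene, term) or GAF 2.x.

    GAF columns 2 (object id) and 5 (term id) are used; rows with a NOT
    qualifier are skipped; malformed lines are skipped with a warning.
    """
    ann = GeneSetAnnotation()
    n_lines = 0
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("!") or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if format == "two_column_tsv":
                if len(fields) < 2:
                    logger.warning("%s:%d: fewer than 2 columns; skipped", path, line_no)
                    continue
                if line_no == 1 and fields[0].lower() in ("gene_id", "gene"):
                    continue  # tolerate a header row
                ann.add(fields[1], fields[0])
            elif format == "gaf":
                if len(fields) < 5:
                    logger.warning("%s:%d: malformed GAF line; skipped", path, line_no)
                    continue
                qualifier = fields[3]
                if "NOT" in qualifier.split("|"):
                    continue
                ann.add(fields[4], fields[1])
            else:
                raise ValueError(f"unknown annotation format {format!r}")
    if n_lines == 0:
        raise FormatError(f"empty annotation file {path}")
    return ann


def write_gene_sets(ann: GeneSetAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tterm_id\n")
        for term in sorted(ann.terms):
            for gene in sorted(ann.terms[term]):
                fh.write(f"{gene}\t{term}\n")


def read_obo(path: str | Path) -> nx.MultiDiGraph:
    """Parse an OBO ontology into a child->parent MultiDiGraph (obonet)."""
    import obonet

    return obonet.read_obo(path)


_PROPAGATE_RELS = ("is_a", "part_of")


def _parent_map(ontology) -> dict[str, set[str]]:
    """child -> direct parents over is_a/part_of, from an obonet graph or a
    plain {child: parents} mapping."""
    if isinstance(ontology, nx.MultiDiGraph):
        parents: dict[str, set[str]] = {}
        for child, parent, key in ontology.edges(keys=True):
            if key in _PROPAGATE_RELS:
                parents.setdefault(child, set()).add(parent)
        return parents
    return {c: set(ps) for c, ps in dict(ontology).items()}


def propagate_annotations(ann: GeneSetAnnotation, ontology) -> GeneSetAnnotation:
    """Annotate every gene to all ancestors of its terms (is_a/part_of closure).

    Idempotent; raises on a cyclic ontology, listing one cycle.
    """
    parents = _parent_map(ontology)
    dag = nx.DiGraph((c, p) for c, ps in parents.items() for p in ps)
    try:
        cycle = nx.find_cycle(dag)
    except nx.NetworkXNoCycle:
        cycle = None
    if cycle:
        raise ValueError(f"ontology contains a cycle: {cycle}")

    ancestors: dict[str, set[str]] = {}

    def anc(term: str) -> set[str]:
        if term not in ancestors:
            out: set[str] = set()
            for p in parents.get(term, ()):  # DFS with memoisation
                out.add(p)
                out |= anc(p)
            ancestors[term] = out
        return ancestors[term]

    new = ann.copy()
    for term in list(ann.terms):
        for parent in anc(term):
            for gene in ann.terms[term]:
                new.add(parent, gene)
            if parent not in new.meta and isinstance(ontology, nx.MultiDiGraph):
                data = ontology.nodes.get(parent, {})
                new.set_meta(parent, data.get("name", ""), data.get("namespace", ""))
    return new


# ------------------------------------------------------- promoter extraction


def extract_promoters(
    genome_fasta: str | Path,
    gff3: str | Path,
    upstream_len: int = 1500,
) -> PromoterSet:
    """Extract [-upstream_len; end of 5'UTR] regions per gene, strand-aware.

    The representative transcript is the mRNA with the lowest-sorting ID.
    Genes without an annotated 5'UTR get the pure upstream window
    [-upstream_len, TSS). Regions are clipped at contig edges (logged);
    minus-strand regions are reverse-complemented so the returned sequence
    reads 5'->3' on the transcribed strand. Promoters are not truncated at
    neighbouring genes; provenance records the genomic interval used.
    """
    import gffutils
    from pyfaidx import Fasta

    db = gffutils.create_db(
        str(gff3), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    fasta = Fasta(str(genome_fasta), as_raw=True, sequence_always_upper=True)

    promoters = PromoterSet()
    for gene in db.features_of_type("gene"):
        transcripts = sorted(
            db.children(gene, featuretype=("mRNA", "transcript")), key=lambda t: t.id
        )
        if not transcripts:
            logger.warning("gene %s has no transcript; skipped", gene.id)
            continue
        tx = transcripts[0]
        utrs = list(db.children(tx, featuretype="five_prime_UTR"))
        if gene.seqid not in fasta:
            raise FormatError(f"contig {gene.seqid!r} absent from {genome_fasta}")
        contig_len = len(fasta[gene.seqid])

        if gene.strand == "-":
            tss0 = tx.end - 1
            start0 = min(u.start for u in utrs) - 1 if utrs else tss0 + 1
            end0 = tss0 + 1 + upstream_len
        else:
            tss0 = tx.start - 1
            start0 = tss0 - upstream_len
            end0 = max(u.end for u in utrs) if utrs else tss0

        clipped = start0 < 0 or end0 > contig_len
        if clipped:
            logger.warning(
                "promoter of %s clipped to contig bounds [%d, %d)",
                gene.id, max(0, start0), min(contig_len, end0),
            )
        start0, end0 = max(0, start0), min(contig_len, end0)
        seq = str(fasta[gene.seqid][start0:end0])
        if gene.strand == "-":
            from .motifs import revcomp

            seq = revcomp(seq)
        promoters.add(
            gene.id,
            seq,
            PromoterProvenance(gene.seqid, gene.strand, start0, end0, clipped),
        )
    return promoters


def read_promoter_fasta(path: str | Path) -> PromoterSet:
    """Promoter FASTA with gene ids as headers."""
    from Bio import SeqIO

    ps = PromoterSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        ps.add(rec.id, str(rec.seq))
    return ps


def write_promoter_fasta(promoters: PromoterSet, path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for gene_id in promoters.gene_ids():
            prov = promoters.provenance.get(gene_id)
            desc = (
                f" {prov.chrom}:{prov.start}-{prov.end}({prov.strand})" if prov else ""
            )
            fh.write(f">{gene_id}{desc}\n")
            seq = promoters.sequences[gene_id]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# --------------------------------------------------------------- result TSVs


def write_partition_tsv(partition, path: str | Path) -> None:
    rows = [
        {
            "gene_id": g,
            "direction": partition.direction,
            "fold_change": partition.fold_change[g],
            "quantile": partition.quantile_of[g],
            "quantile_label": Interval(
                partition.quantile_of[g], partition.quantile_of[g]
            ).label(partition.q),
        }
        for g in partition.ordered_genes
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_step1_tsv(results, ann: GeneSetAnnotation, q: int, path: str | Path) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": ann.term_name(r.term_id),
            "namespace": ann.term_namespace(r.term_id),
            "direction": r.direction,
            "interval_label": r.interval.label(q),
            "a": r.counts.a,
            "b": r.counts.b,
            "c": r.counts.c,
            "d": r.counts.d,
            "raw_p": r.raw_p,
            "adj_p": r.adj_p,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_step2_tsv(results, ann: GeneSetAnnotation, q: int, path: str | Path) -> None:
    rows = []
    for r in results:
        for iv, raw, adj in r.per_interval:
            rows.append(
                {
                    "term_id": r.term_id,
                    "term_name": ann.term_name(r.term_id),
                    "namespace": ann.term_namespace(r.term_id),
                    "direction": r.direction,
                    "interval_label": iv.label(q),
                    "raw_p": raw,
                    "adj_p": adj,
                    "fold_change_specific": r.fold_change_specific,
                    "best_interval": r.best_interval.label(q) if r.best_interval else "",
                }
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_summary_tsv(results, ann: GeneSetAnnotation, q: int, path: str | Path) -> None:
    rows = [
        {
            "term_id": r.term_id,
            "term_name": ann.term_name(r.term_id),
            "direction": r.direction,
            "best_interval": r.best_interval.label(q) if r.best_interval else "",
            "min_adj_p": r.min_adj_p,
            "fold_change_specific": r.fold_change_specific,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_hexamer_tsv(results, q: int, path: str | Path) -> None:
    rows = [
        {
            "hexamer": r.hexamer.sequence,
            "pair": r.hexamer.pair,
            "direction": r.direction,
            "interval_label": r.interval.label(q),
            "a": r.counts.a,
            "b": r.counts.b,
            "c": r.counts.c,
            "d": r.counts.d,
            "step1_raw_p": r.step1_raw_p,
            "step1_adj_p": r.step1_adj_p,
            "step2_raw_p": r.step2_raw_p,
            "step2_adj_p": r.step2_adj_p,
            "fold_change_specific": r.fold_change_specific,
        }
        for r in results
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
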