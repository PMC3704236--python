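"""Gene models: extraction from genome + annotation, CDS validation, filters.

A :class:`GeneRecord` carries everything downstream analyses need for one
gene: the spliced CDS, intron sequences, up/downstream flanks, a per-stage
expression vector and any validation flags.  Extraction consumes FASTA +
GFF3 (1-based closed intervals, per the format); internally all coordinates
are 0-based half-open.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import STOP_CODONS, reverse_complement

logger = logging.getLogger(__name__)

#: validation-failure labels emitted by :func:`validate_cds`
QC_BAD_START = "bad_start"
QC_PARTIAL = "partial_last_codon"
QC_UNTRANSLATABLE = "untranslatable_codon"
QC_INTERNAL_STOP = "internal_stop"
QC_OUT_OF_BOUNDS = "out_of_bounds_exon"
QC_NO_EXPRESSION = "missing_expression"

DEFAULT_START_CODONS = ("ATG",)


@dataclass
class GeneRecord:
    """One gene's sequences, expression and QC status."""

    gene_id: str
    cds: str
    introns: list[str] = field(default_factory=list)
    flank_up: str = ""
    flank_down: str = ""
    expression: np.ndarray = field(default_factory=lambda: np.zeros(0))
    qc_flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        self.expression = np.asarray(self.expression, dtype=float)

    @property
    def max_expression(self) -> float:
        return float(self.expression.max()) if self.expression.size else 0.0


@dataclass(frozen=True)
class ExpressionSummary:
    """Maximum expression across stages and the high-expression call.

    Genes are called highly expressed above 25,000 AU of maximum observed
    expression across the developmental stages.
    """

    gene_id: str
    max_expression: float
    is_high: bool


def expression_summary(
    gene_id: str, expression: Sequence[float], high_threshold: float = 25000.0
) -> ExpressionSummary:
    m = float(np.max(expression)) if len(expression) else 0.0
    return ExpressionSummary(gene_id, m, m > high_threshold)


def validate_cds(
    cds: str, start_codons: Sequence[str] = DEFAULT_START_CODONS
) -> set[str]:
    """Validate a coding sequence; return the set of applicable QC flags.

    An empty set means the CDS starts with a recognized start codon, has a
    length that is a multiple of three, contains only unambiguous A/C/G/T
    codons, and has no stop codon before the final position.
    """
    flags: set[str] = set()
    s = cds.upper().replace("U", "T")
    if s[:3] not in start_codons:
        flags.add(QC_BAD_START)
    if len(s) % 3 != 0:
        flags.add(QC_PARTIAL)
    n_full = len(s) // 3
    full = [s[3 * i : 3 * i + 3] for i in range(n_full)]
    if any(any(b not in "ACGT" for b in codon) for codon in full):
        flags.add(QC_UNTRANSLATABLE)
    # a stop is "internal" unless it is the final complete codon of an
    # in-frame sequence
    internal = full[:-1] if len(s) % 3 == 0 else full
    if any(codon in STOP_CODONS for codon in internal):
        flags.add(QC_INTERNAL_STOP)
    return flags


def _load_genome(genome) -> dict[str, str]:
    if isinstance(genome, Mapping):
        return {k: str(v).upper() for k, v in genome.items()}
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(genome), "fasta")
    }


def _cds_segments(db: gffutils.FeatureDB, gene) -> list[tuple[int, int]]:
    """0-based half-open CDS intervals of a gene, ascending."""
    segs = {
        (f.start - 1, f.end)
        for f in db.children(gene, featuretype="CDS", order_by="start")
    }
    return sorted(segs)


def extract_gene_records(
    genome,
    gff,
    flank_width: int = 1000,
    expression: pd.DataFrame | None = None,
    start_codons: Sequence[str] = DEFAULT_START_CODONS,
) -> list[GeneRecord]:
    """Extract spliced CDS, introns and flanks for every gene in a GFF3.

    Parameters
    ----------
    genome
        FASTA path or mapping of contig name to sequence.
    gff
        GFF3 path or string of GFF3 text.
    flank_width
        Nucleotides of genomic context taken upstream and downstream of the
        coding span (truncated at contig edges).
    expression
        Optional table indexed by gene id, one column per stage; genes
        missing from it are flagged.

    A feature referencing an absent contig is a hard error; an exon running
    off its contig flags the gene and leaves its sequences empty.
    """
    contigs = _load_genome(genome)
    gff_text = gff if "\t" in str(gff)[:200] else Path(gff).read_text()
    db = gffutils.create_db(
        gff_text,
        ":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )
    records: list[GeneRecord] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        gid = gene.id
        if gene.seqid not in contigs:
            raise KeyError(
                f"gene {gid!r} references contig {gene.seqid!r} absent from the genome"
            )
        contig = contigs[gene.seqid]
        segs = _cds_segments(db, gene)
        expr = np.zeros(0)
        qc: set[str] = set()
        if expression is not None:
            if gid in expression.index:
                expr = expression.loc[gid].to_numpy(dtype=float)
            else:
                qc.add(QC_NO_EXPRESSION)
        if any(s < 0 or e > len(contig) for s, e in segs) or not segs:
            qc.add(QC_OUT_OF_BOUNDS)
            records.append(GeneRecord(gid, "", [], "", "", expr, qc))
            continue
        exons = [contig[s:e] for s, e in segs]
        gaps = [contig[segs[i][1] : segs[i + 1][0]] for i in range(len(segs) - 1)]
        span_start, span_end = segs[0][0], segs[-1][1]
        up = contig[max(0, span_start - flank_width) : span_start]
        down = contig[span_end : span_end + flank_width]
        cds = "".join(exons)
        if gene.strand == "-":
            cds = reverse_complement(cds)
            gaps = [reverse_complement(g) for g in reversed(gaps)]
            up, down = reverse_complement(down), reverse_complement(up)
        qc |= validate_cds(cds, start_codons=start_codons)
        records.append(GeneRecord(gid, cds, gaps, up, down, expr, qc))
    return records


def apply_study_filters(
    genes: Iterable[GeneRecord],
    expression: pd.DataFrame,
    nc_scores: Mapping[str, float],
    min_expression: float = 200.0,
) -> list[str]:
    """Apply the study's gene filters; return retained gene ids in input order.

    Drops genes carrying any QC flag, genes absent from the expression
    table, and genes whose maximum expression over stages is below
    ``min_expression`` AU.  Groups of genes with identical expression
    vectors across all stages are treated as unhandled duplicates: only the
    member with the smallest Nc (strongest bias) is kept.
    """
    candidates: list[GeneRecord] = []
    n_missing = 0
    for g in genes:
        if g.qc_flags:
            continue
        if g.gene_id not in expression.index:
            n_missing += 1
            continue
        candidates.append(g)
    if n_missing:
        logger.warning("%d genes missing from the expression table; removed", n_missing)

    kept: list[GeneRecord] = []
    for g in candidates:
        vec = expression.loc[g.gene_id].to_numpy(dtype=float)
        if float(vec.max()) >= min_expression:
            kept.append(g)

    groups: dict[tuple[float, ...], list[str]] = {}
    for g in kept:
        key = tuple(expression.loc[g.gene_id].to_numpy(dtype=float))
        groups.setdefault(key, []).append(g.gene_id)

    winners: set[str] = set()
    for members in groups.values():
        if len(members) == 1:
            winners.add(members[0])
        else:
            winners.add(min(members, key=lambda gid: (nc_scores[gid], members.index(gid))))
    return [g.gene_id for g in kept if g.gene_id in winners]


# ---------------------------------------------------------------------------
# JSON round-trip for gene records (the pipeline's on-disk gene format)

def write_gene_records(genes: Iterable[GeneRecord], path) -> None:
    payload = []
    for g in genes:
        d = asdict(g)
        d["expression"] = [float(x) for x in g.expression]
        d["qc_flags"] = sorted(g.qc_flags)
        payload.append(d)
    Path(path).write_text(json.dumps(payload))


def read_gene_records(path) -> list[GeneRecord]:
    payload = json.loads(Path(path).read_text())
    return [
        GeneRecord(
            d["gene_id"],
            d["cds"],
            list(d["introns"]),
            d["flank_up"],
            d["flank_down"],
            np.asarray(d["expression"], dtype=float),
            set(d["qc_flags"]),
        )
        for d in payload
    ]
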