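"""Synthetic study generator with planted, recoverable structure.

Emulates the statistical shape of a genome-wide codon-bias study in an
AT-rich genome: genes drawn from S planted codon-usage clusters, AT-rich
introns and flanks (GC 0.36 by default against elevated GC3 in biased
clusters), lognormal developmental expression with one high-expression
cluster (~4x the others), pairwise ortholog "alignments" with a planted
preferred-codon conservation odds ratio, secondary structures with a
planted N3 stem-pairing odds ratio, and tRNA gene counts proportional to
recognized-codon usage.

Every consumer-facing artifact can be written in the same plain-text
formats the pipeline reads (FASTA/GFF3/TSV/aligned FASTA/dot-bracket), and
truth labels are returned for recovery tests.  All randomness flows from
the mandatory seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .conservation_tests import CodonAlignment
from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    FAMILIES,
    SENSE_CODONS,
    reverse_complement,
)
from .preferred_codons import PreferredCodonSet
from .seq_models import GeneRecord
from .structure_tests import StructureAnnotation


@dataclass
class SimConfig:
    """Knobs of the synthetic study (defaults mimic the study's shape)."""

    seed: int
    n_genes: int = 500
    S: int = 5
    separation: float = 0.45  # excess frequency of each cluster's preferred codon
    mean_len: int = 500  # codons per gene (before start/stop)
    bg_gc: float = 0.36  # intron/flank GC fraction
    bias_gradient: tuple[float, float] | None = None  # per-gene bias multiplier range
    flank_width: int = 1000
    mean_introns: float = 3.0
    intron_len: tuple[int, int] = (60, 300)
    expr_base_median: float = 3100.0  # AU, clusters other than the high one
    expr_high_median: float = 12400.0  # AU, high-expression cluster (cluster 0)
    expr_sigma: float = 0.8
    expr_stage_sigma: float = 0.3
    n_stages: int = 5
    conservation_or: float = 1.3
    base_conservation: float = 0.7  # synonymous-state probability, unpreferred codons
    stem_or: float = 1.5
    base_stem_p: float = 0.5  # stem probability for unpreferred N3
    trna_scale: float = 2000.0
    trna_noise: float = 1.0  # 0 = deterministic counts

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")


@dataclass
class SimulatedStudy:
    """Generated genes plus every planted truth needed for recovery tests."""

    config: SimConfig
    genes: list[GeneRecord]
    expression: pd.DataFrame
    contigs: dict[str, str]
    gff: str
    truth: dict = field(default_factory=dict)

    def cluster_preferred(self, s: int) -> PreferredCodonSet:
        return PreferredCodonSet(
            choice=dict(self.truth["cluster_preferred"][s]), scope=f"CUG{s}"
        )

    def genomewide_preferred(self) -> PreferredCodonSet:
        return PreferredCodonSet(
            choice=dict(self.truth["cluster_preferred"][0]), scope="genome"
        )


# amino-acid composition used for every gene: degenerate amino acids
# dominate so all 18 families are well sampled at a few hundred codons
_AA_POOL = tuple(DEGENERATE_AAS) + ("M", "W")
_AA_WEIGHTS = np.array([1.0] * len(DEGENERATE_AAS) + [0.4, 0.4])
_AA_WEIGHTS = _AA_WEIGHTS / _AA_WEIGHTS.sum()


def cluster_preferred_choice(s: int) -> dict[str, str]:
    """Planted preferred codon of cluster s: rotate within each family."""
    return {aa: FAMILIES[aa][s % DEGENERACY[aa]] for aa in DEGENERATE_AAS}


def _cluster_family_probs(s: int, separation: float) -> dict[str, np.ndarray]:
    probs = {}
    for aa in DEGENERATE_AAS:
        d = DEGENERACY[aa]
        p = np.full(d, (1.0 - (1.0 / d + separation * (1 - 1.0 / d))) / (d - 1))
        p[s % d] = 1.0 / d + separation * (1 - 1.0 / d)
        probs[aa] = p
    return probs


def _random_background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def generate_genome(config: SimConfig) -> SimulatedStudy:
    """Draw genes, assemble one contig per gene, and tabulate expression.

    Each gene: cluster from uniform weights; amino-acid sequence from a
    fixed composition; codons from the cluster's family distributions
    (optionally damped by a per-gene bias multiplier); start codon and
    terminal stop added; introns inserted at random positions and AT-rich
    flanks appended.  Genes alternate between the two strands.
    """
    rng = np.random.default_rng(config.seed)
    theta = {
        s: _cluster_family_probs(s, config.separation) for s in range(config.S)
    }
    genes: list[GeneRecord] = []
    contigs: dict[str, str] = {}
    gff_lines = ["##gff-version 3"]
    labels: dict[str, int] = {}
    bias: dict[str, float] = {}
    expr_rows = []

    for i in range(config.n_genes):
        gid = f"g{i:05d}"
        s = int(rng.integers(config.S))
        labels[gid] = s
        mult = (
            float(rng.uniform(*config.bias_gradient))
            if config.bias_gradient is not None
            else 1.0
        )
        bias[gid] = mult
        n_codons = max(60, int(rng.normal(config.mean_len, config.mean_len / 4)))
        aas = rng.choice(len(_AA_POOL), size=n_codons, p=_AA_WEIGHTS)
        codons = []
        for ai in aas:
            aa = _AA_POOL[ai]
            if aa in ("M", "W"):
                codons.append(FAMILIES[aa][0])
                continue
            d = DEGENERACY[aa]
            p = mult * theta[s][aa] + (1 - mult) * np.full(d, 1.0 / d)
            codons.append(FAMILIES[aa][rng.choice(d, p=p / p.sum())])
        cds = "ATG" + "".join(codons) + "TAA"

        # split the CDS into exons at arbitrary nucleotide positions
        n_introns = int(rng.poisson(config.mean_introns))
        cuts = sorted(rng.choice(np.arange(1, len(cds)), size=n_introns, replace=False)) if n_introns else []
        exons = []
        prev = 0
        for cut in cuts:
            exons.append(cds[prev:cut])
            prev = cut
        exons.append(cds[prev:])
        introns = [
            _random_background(rng, int(rng.integers(*config.intron_len)), config.bg_gc)
            for _ in range(len(exons) - 1)
        ]
        flank_up = _random_background(rng, config.flank_width, config.bg_gc)
        flank_down = _random_background(rng, config.flank_width, config.bg_gc)

        body = exons[0]
        for intron, exon in zip(introns, exons[1:]):
            body += intron + exon
        contig = flank_up + body + flank_down
        strand = "+" if i % 2 == 0 else "-"
        # exon coordinates on the sense-oriented contig (0-based half-open)
        sense_coords = []
        pos = len(flank_up)
        for k, exon in enumerate(exons):
            sense_coords.append((pos, pos + len(exon)))
            pos += len(exon) + (len(introns[k]) if k < len(introns) else 0)
        if strand == "-":
            contig = reverse_complement(contig)
            L = len(contig)
            sense_coords = [(L - e, L - s0) for s0, e in reversed(sense_coords)]
        contig_name = f"contig_{gid}"
        contigs[contig_name] = contig
        gstart = min(s0 for s0, _ in sense_coords) + 1
        gend = max(e for _, e in sense_coords)
        gff_lines.append(
            f"{contig_name}\tsim\tgene\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}"
        )
        gff_lines.append(
            f"{contig_name}\tsim\tmRNA\t{gstart}\t{gend}\t.\t{strand}\t.\tID={gid}.t1;Parent={gid}"
        )
        for s0, e in sense_coords:
            gff_lines.append(
                f"{contig_name}\tsim\tCDS\t{s0 + 1}\t{e}\t.\t{strand}\t0\tParent={gid}.t1"
            )

        median = config.expr_high_median if s == 0 else config.expr_base_median
        level = float(np.exp(rng.normal(np.log(median), config.expr_sigma)))
        stages = level * np.exp(
            rng.normal(0.0, config.expr_stage_sigma, size=config.n_stages)
        )
        expr_rows.append({"gene_id": gid, **{f"stage_{t}": stages[t] for t in range(config.n_stages)}})

        genes.append(
            GeneRecord(gid, cds, introns, flank_up, flank_down, stages, set())
        )

    expression = pd.DataFrame(expr_rows).set_index("gene_id")
    truth = {
        "labels": labels,
        "bias": bias,
        "S": config.S,
        "cluster_preferred": {s: cluster_preferred_choice(s) for s in range(config.S)},
        "theta": {
            s: {aa: theta[s][aa].tolist() for aa in DEGENERATE_AAS}
            for s in range(config.S)
        },
    }
    return SimulatedStudy(config, genes, expression, contigs, "\n".join(gff_lines) + "\n", truth)


def generate_ortholog_alignments(
    sim: SimulatedStudy, rng: np.random.Generator | None = None
) -> list[CodonAlignment]:
    """Pairwise ortholog codons with a planted conservation odds ratio.

    For each focal codon the ortholog state is synonymous with probability
    q (odds multiplied by ``conservation_or`` when the codon is its
    cluster's preferred codon): synonymous draws a random codon from the
    same family, nonsynonymous a random sense codon of another amino acid.
    """
    cfg = sim.config
    rng = rng if rng is not None else np.random.default_rng((cfg.seed, 101))
    q_u = cfg.base_conservation
    odds_u = q_u / (1 - q_u) if q_u < 1 else np.inf
    q_p = 1.0 if not np.isfinite(odds_u) else (
        cfg.conservation_or * odds_u / (1 + cfg.conservation_or * odds_u)
    )
    by_aa_other = {
        aa: [c for c in SENSE_CODONS if CODON_TO_AA[c] != aa] for aa in set(CODON_TO_AA.values())
    }
    out = []
    for g in sim.genes:
        pref = sim.truth["cluster_preferred"][sim.truth["labels"][g.gene_id]]
        cods = [g.cds[i : i + 3] for i in range(0, len(g.cds) - 3, 3)]  # stop excluded
        other = []
        for c in cods:
            aa = CODON_TO_AA.get(c)
            if aa is None:
                other.append(c)
                continue
            preferred = pref.get(aa) == c
            q = q_p if preferred else q_u
            if rng.random() < q:
                fam = FAMILIES[aa]
                other.append(fam[rng.integers(len(fam))])
            else:
                pool = by_aa_other[aa]
                other.append(pool[rng.integers(len(pool))])
        out.append(CodonAlignment(g.gene_id, cods, other))
    return out


def generate_structures(
    sim: SimulatedStudy, rng: np.random.Generator | None = None
) -> dict[str, tuple[str, StructureAnnotation]]:
    """Dot-bracket structures with a planted N3 stem-pairing odds ratio.

    The third position of each degenerate codon is paired with probability
    whose odds are ``stem_or`` times the baseline when the codon is its
    cluster's preferred codon; other positions pair at the baseline rate.
    Paired positions are matched into a nested bracket layout so the
    emitted string is always balanced.
    """
    cfg = sim.config
    rng = rng if rng is not None else np.random.default_rng((cfg.seed, 202))
    odds_u = cfg.base_stem_p / (1 - cfg.base_stem_p)
    p_pref = cfg.stem_or * odds_u / (1 + cfg.stem_or * odds_u)
    out: dict[str, tuple[str, StructureAnnotation]] = {}
    for g in sim.genes:
        pref = sim.truth["cluster_preferred"][sim.truth["labels"][g.gene_id]]
        L = len(g.cds)
        paired = rng.random(L) < cfg.base_stem_p
        n3_idx = []
        for i in range(0, L - L % 3, 3):
            codon = g.cds[i : i + 3]
            aa = CODON_TO_AA.get(codon)
            if aa is None or DEGENERACY[aa] < 2:
                continue
            n3_idx.append(i + 2)
            p = p_pref if pref.get(aa) == codon else cfg.base_stem_p
            paired[i + 2] = rng.random() < p
        idx = np.flatnonzero(paired)
        if len(idx) % 2 == 1:
            non_n3 = [j for j in idx if j not in set(n3_idx)]
            drop = non_n3[-1] if non_n3 else idx[-1]
            paired[drop] = False
            idx = np.flatnonzero(paired)
        chars = np.array(["."] * L)
        half = len(idx) // 2
        chars[idx[:half]] = "("
        chars[idx[half:]] = ")"
        db = "".join(chars)
        out[g.gene_id] = (db, StructureAnnotation(g.gene_id, paired.copy()))
    return out


def generate_trna_counts(
    config: SimConfig,
    usage: Mapping[str, float],
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """tRNA gene counts proportional to recognized-codon usage.

    One species per Watson-Crick anticodon of each sense codon (species
    whose wobble-decoded set would span several amino acids are dropped);
    expected count = trna_scale x summed usage of recognized codons, with
    Poisson noise unless ``trna_noise`` is 0.
    """
    from .trna_correspondence import wobble_decoding

    rng = rng if rng is not None else np.random.default_rng((config.seed, 303))
    rows = []
    seen = set()
    for codon in SENSE_CODONS:
        ac = reverse_complement(codon)
        if ac in seen:
            continue
        seen.add(ac)
        decoded = wobble_decoding(ac)
        aas = {CODON_TO_AA[c.replace("U", "T")] for c in decoded}
        if len(aas) != 1:
            continue
        usage_sum = sum(usage.get(c.replace("U", "T"), 0.0) for c in decoded)
        expected = config.trna_scale * usage_sum
        count = (
            int(round(expected))
            if config.trna_noise == 0
            else int(rng.poisson(expected))
        )
        rows.append(
            {"anticodon": ac, "amino_acid": aas.pop(), "gene_count": count}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# on-disk round trip: write the same formats the pipeline reads

def write_study(sim: SimulatedStudy, outdir) -> None:
    """Write genome FASTA, GFF3, expression TSV and truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "genome.fa", "w") as fh:
        for name, seq in sim.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    (out / "models.gff3").write_text(sim.gff)
    sim.expression.to_csv(out / "expression.tsv", sep="\t")
    truth = dict(sim.truth)
    (out / "truth.json").write_text(json.dumps(truth, default=str))


def write_alignments(alignments: list[CodonAlignment], outdir) -> None:
    """One aligned FASTA per gene: focal record then ortholog record."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for aln in alignments:
        with open(out / f"{aln.gene_id}.afa", "w") as fh:
            fh.write(f">{aln.gene_id}|focal\n{''.join(aln.focal_codons)}\n")
            fh.write(f">{aln.gene_id}|ortholog\n{''.join(aln.other_codons)}\n")


def read_alignment_fasta(path) -> CodonAlignment:
    """Read a two-record aligned FASTA into codon columns, dropping pairs
    where either sequence has a gap in any base of the codon."""
    from Bio import SeqIO

    recs = list(SeqIO.parse(str(path), "fasta"))
    if len(recs) != 2:
        raise ValueError(f"{path}: expected exactly two aligned records")
    gid = recs[0].id.split("|")[0]
    s1, s2 = str(recs[0].seq).upper(), str(recs[1].seq).upper()
    if len(s1) != len(s2):
        raise ValueError(f"{path}: aligned sequences differ in length")
    focal, other = [], []
    for i in range(0, len(s1) - len(s1) % 3, 3):
        c1, c2 = s1[i : i + 3], s2[i : i + 3]
        if "-" in c1 or "-" in c2:
            continue
        focal.append(c1)
        other.append(c2)
    return CodonAlignment(gid, focal, other)


def write_structures(structures: Mapping[str, tuple[str, StructureAnnotation]], genes, outdir) -> None:
    """RNAfold-style text files: sequence line then dot-bracket line."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    cds_by_id = {g.gene_id: g.cds for g in genes}
    for gid, (db, _) in structures.items():
        (out / f"{gid}.fold").write_text(
            f">{gid}\n{cds_by_id[gid].replace('T', 'U')}\n{db}\n"
        )


def read_fold_file(path) -> tuple[str, str, StructureAnnotation]:
    """(gene_id, sequence, annotation) from an RNAfold-style text file."""
    from .structure_tests import parse_dot_bracket

    lines = Path(path).read_text().splitlines()
    gid = lines[0][1:].strip() if lines[0].startswith(">") else Path(path).stem
    seq = lines[1].strip() if lines[0].startswith(">") else lines[0].strip()
    db = lines[2].strip() if lines[0].startswith(">") else lines[1].strip()
    return gid, seq, StructureAnnotation(gid, parse_dot_bracket(db))
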