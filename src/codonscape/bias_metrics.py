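"""Codon-usage-bias metrics: Nc, background-corrected Nc', GC partitions,
per-amino-acid sENC-X, and degeneracy-centered usage.

Wright's effective number of codons Nc summarizes how far a gene's
synonymous codon usage departs from uniformity: 61 means every synonymous
codon is used equally, 20 means a single codon per amino acid.  It is the
codon analogue of the effective number of alleles: per synonymous family
the codon "homozygosity" F is estimated, class means are taken over
families of equal degeneracy, and

    Nc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

with the sixfold families (Leu, Ser, Arg) kept whole so the minimum is
exactly 2 + 9 + 1 + 5 + 3 = 20.

Nc' replaces Wright's homozygosity with a chi-square deviation of observed
within-family frequencies from expectations derived from a background
nucleotide composition, so that compositional (mutational) bias alone does
not register as codon bias.  Under a uniform background Nc' reduces
algebraically to Nc.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .genetic_code import (
    CLASS_COUNTS,
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    FAMILIES,
    STOP_CODONS,
    codons_of,
)
from .seq_models import GeneRecord

NC_MIN, NC_MAX = 20.0, 61.0


@dataclass
class CodonCounts:
    """Per-gene counts of the 61 sense codons."""

    gene_id: str
    counts: dict[str, int] = field(default_factory=dict)

    @classmethod
    def from_cds(cls, gene_id: str, cds: str, drop_terminal_stop: bool = True):
        """Count sense codons of a CDS.

        A terminal stop codon, if present, is excluded: stops carry no
        synonymous-choice information.  Codons with ambiguous bases are
        skipped.
        """
        cods = codons_of(cds)
        if drop_terminal_stop and cods and cods[-1] in STOP_CODONS:
            cods = cods[:-1]
        counts: dict[str, int] = {}
        for c in cods:
            if c in CODON_TO_AA:
                counts[c] = counts.get(c, 0) + 1
        return cls(gene_id, counts)

    def family_counts(self, aa: str) -> np.ndarray:
        return np.array([self.counts.get(c, 0) for c in FAMILIES[aa]], dtype=float)

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass(frozen=True)
class BiasProfile:
    """Per-gene bias metrics (NaN where a metric is undefined)."""

    gene_id: str
    nc: float
    nc_prime: float
    gc3: float
    gc_cds: float
    gc_i: float
    gc_f: float
    senc: dict[str, float]


def family_homozygosity(counts_in_family: Sequence[float]) -> float | None:
    """Wright's small-sample codon homozygosity F-hat for one family.

    F = (n * sum(p_i^2) - 1) / (n - 1); families with fewer than two codons
    observed are unusable and return None.
    """
    c = np.asarray(counts_in_family, dtype=float)
    n = c.sum()
    if n < 2:
        return None
    p = c / n
    return float((n * (p @ p) - 1.0) / (n - 1.0))


def _family_f_prime(
    counts_in_family: np.ndarray, expected: np.ndarray
) -> float | None:
    """Composition-corrected homozygosity for one family of m codons."""
    n = counts_in_family.sum()
    m = len(counts_in_family)
    if n < 2:
        return None
    p = counts_in_family / n
    chi2 = n * float(((p - expected) ** 2 / expected).sum())
    return (chi2 + n - m) / (m * (n - 1.0))


def _assemble_nc(class_fbar: dict[int, float | None]) -> float:
    """Combine class-mean homozygosities into Nc, imputing missing classes.

    If the threefold class (Ile only) is unusable its mean is imputed as the
    average of the two- and fourfold means; any other missing class takes
    the mean of the available class means.  This mirrors the behaviour of
    the classic Nc implementations.
    """
    fbar = dict(class_fbar)
    present = [v for v in fbar.values() if v is not None]
    if not present:
        return math.nan
    if fbar.get(3) is None and fbar.get(2) is not None and fbar.get(4) is not None:
        fbar[3] = (fbar[2] + fbar[4]) / 2.0
    for d in (2, 3, 4, 6):
        if fbar.get(d) is None:
            fbar[d] = float(np.mean(present))
    nc = 2.0 + sum(CLASS_COUNTS[d] / fbar[d] for d in (2, 3, 4, 6))
    return float(min(NC_MAX, max(NC_MIN, nc)))


def _class_means(per_family: dict[str, float | None]) -> dict[int, float | None]:
    out: dict[int, float | None] = {}
    for d in (2, 3, 4, 6):
        vals = [
            f
            for aa, f in per_family.items()
            if DEGENERACY[aa] == d and f is not None and f > 0
        ]
        out[d] = float(np.mean(vals)) if vals else None
    return out


def nc_wright(counts: CodonCounts) -> float:
    """Wright's effective number of codons, clamped to [20, 61].

    Families with n < 2 observations, or with non-positive estimated
    homozygosity, are excluded from their class average.
    """
    per_family = {
        aa: family_homozygosity(counts.family_counts(aa)) for aa in DEGENERATE_AAS
    }
    return _assemble_nc(_class_means(per_family))


def background_composition(
    seqs: Iterable[str], floor: float = 1e-9
) -> dict[str, float]:
    """Pooled mononucleotide composition of background sequences.

    Typically fed the 1000-nt flanks of all genes.  A small floor keeps all
    four frequencies positive on degenerate inputs.
    """
    tally = {b: 0 for b in "ACGT"}
    for s in seqs:
        for b in s.upper().replace("U", "T"):
            if b in tally:
                tally[b] += 1
    total = sum(tally.values())
    if total == 0:
        return {b: 0.25 for b in "ACGT"}
    freq = {b: max(tally[b] / total, floor) for b in "ACGT"}
    z = sum(freq.values())
    return {b: v / z for b, v in freq.items()}


def expected_family_frequencies(bg: Mapping[str, float]) -> dict[str, np.ndarray]:
    """Per-family expected codon frequencies under a background composition.

    The expectation for a codon is the product of the background
    frequencies of its three bases, renormalized within the family.
    """
    out: dict[str, np.ndarray] = {}
    for aa in DEGENERATE_AAS:
        raw = np.array(
            [bg[c[0]] * bg[c[1]] * bg[c[2]] for c in FAMILIES[aa]], dtype=float
        )
        out[aa] = raw / raw.sum()
    return out


def nc_prime(counts: CodonCounts, bg: Mapping[str, float]) -> float:
    """Background-corrected effective number of codons (Nc')."""
    expected = expected_family_frequencies(bg)
    per_family = {
        aa: _family_f_prime(counts.family_counts(aa), expected[aa])
        for aa in DEGENERATE_AAS
    }
    return _assemble_nc(_class_means(per_family))


def _gc_fraction(seq: str) -> float:
    s = seq.upper().replace("U", "T")
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        return math.nan
    return (s.count("G") + s.count("C")) / acgt


def gc_metrics(gene: GeneRecord) -> tuple[float, float, float, float]:
    """(GC3, GC_cds, GC_i, GC_f) for one gene.

    GC3 is taken over third positions of sense codons (terminal stop
    excluded); GC_i is NaN for intronless genes.
    """
    cods = codons_of(gene.cds)
    if cods and cods[-1] in STOP_CODONS:
        cods = cods[:-1]
    third = "".join(c[2] for c in cods if c in CODON_TO_AA)
    gc3 = _gc_fraction(third) if third else math.nan
    gc_cds = _gc_fraction(gene.cds) if gene.cds else math.nan
    gc_i = _gc_fraction("".join(gene.introns)) if gene.introns else math.nan
    flanks = gene.flank_up + gene.flank_down
    gc_f = _gc_fraction(flanks) if flanks else math.nan
    return gc3, gc_cds, gc_i, gc_f


def senc_x(counts_in_family: Sequence[float], degeneracy: int) -> float:
    """Scaled per-amino-acid bias in [0, 1] (0 = no bias, 1 = maximum bias).

    Uses plain frequency homozygosity (ENC-X = 1 / sum p^2) rather than the
    small-sample estimator, so the endpoints are exact at any sample size.
    """
    if degeneracy < 2:
        raise ValueError("sENC-X is undefined for nondegenerate amino acids")
    c = np.asarray(counts_in_family, dtype=float)
    n = c.sum()
    if n < 1:
        return math.nan
    p = c / n
    enc_x = 1.0 / float(p @ p)
    return float(min(1.0, max(0.0, (degeneracy - enc_x) / (degeneracy - 1.0))))


def centered_usage(p: float, degeneracy: int) -> float:
    """Center a within-family frequency on its equal-usage expectation.

    v = (p - 1/d) / (1 - 1/d): 0 at equal usage, 1 at exclusive usage,
    -1/(d-1) at complete avoidance.
    """
    e = 1.0 / degeneracy
    return (p - e) / (1.0 - e)


def bias_profile(
    gene: GeneRecord, bg: Mapping[str, float], counts: CodonCounts | None = None
) -> BiasProfile:
    counts = counts or CodonCounts.from_cds(gene.gene_id, gene.cds)
    gc3, gc_cds, gc_i, gc_f = gc_metrics(gene)
    senc = {}
    for aa in DEGENERATE_AAS:
        fam = counts.family_counts(aa)
        senc[aa] = senc_x(fam, DEGENERACY[aa]) if fam.sum() >= 1 else math.nan
    return BiasProfile(
        gene.gene_id,
        nc_wright(counts),
        nc_prime(counts, bg),
        gc3,
        gc_cds,
        gc_i,
        gc_f,
        senc,
    )


def profiles_table(profiles: Iterable[BiasProfile]) -> pd.DataFrame:
    """Flatten profiles to a table (one row per gene, sENC in columns)."""
    rows = []
    for p in profiles:
        row = {
            "gene_id": p.gene_id,
            "Nc": p.nc,
            "Ncp": p.nc_prime,
            "GC3": p.gc3,
            "GCcds": p.gc_cds,
            "GCi": p.gc_i,
            "GCf": p.gc_f,
        }
        row.update({f"sENC_{aa}": v for aa, v in p.senc.items()})
        rows.append(row)
    return pd.DataFrame(rows).set_index("gene_id")
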