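"""Akashi's test for preferred-codon conservation.

Each aligned gene contributes one 2x2 stratum crossing codon preference
(preferred vs unpreferred, scored on the focal species) with evolutionary
conservation (synonymous vs nonsynonymous state of the aligned ortholog
codon).  Strata are combined with the Mantel-Haenszel common odds ratio and
the Cochran-Mantel-Haenszel chi-square; the Woolf test checks homogeneity
of the per-gene odds ratios; and the strength of the observed association
is referenced against odds ratios recomputed for randomly chosen
synonymous-codon sets.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    FAMILIES,
)
from .preferred_codons import PreferredCodonSet

logger = logging.getLogger(__name__)

_AA_INDEX = {aa: i for i, aa in enumerate(DEGENERATE_AAS)}
_DEG_CODONS = sorted(c for c in CODON_TO_AA if DEGENERACY[CODON_TO_AA[c]] >= 2)
_DEG_CODON_INDEX = {c: i for i, c in enumerate(_DEG_CODONS)}


@dataclass
class CodonAlignment:
    """One gene's pairwise codon alignment (gap columns already removed)."""

    gene_id: str
    focal_codons: list[str]
    other_codons: list[str]

    def __post_init__(self) -> None:
        if len(self.focal_codons) != len(self.other_codons):
            raise ValueError(
                f"alignment {self.gene_id!r}: focal and other codon lists differ in length"
            )


@dataclass
class StratumTable:
    """Per-gene 2x2 table: (preferred, unpreferred) x (conserved/stem, not)."""

    gene_id: str
    a: int  # preferred & conserved (or stem)
    b: int  # preferred & nonconserved (or loop)
    c: int  # unpreferred & conserved (or stem)
    d: int  # unpreferred & nonconserved (or loop)

    @property
    def usable(self) -> bool:
        """All four marginals positive — the stratum informs the OR."""
        return (
            self.a + self.b > 0
            and self.c + self.d > 0
            and self.a + self.c > 0
            and self.b + self.d > 0
        )

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class _EncodedAlignments:
    """Vectorized view of a set of alignments for fast table rebuilding."""

    gene_ids: list[str]
    gene_idx: np.ndarray  # per scored codon
    aa_idx: np.ndarray  # degenerate amino-acid index per codon
    codon_idx: np.ndarray  # index into _DEG_CODONS
    conserved: np.ndarray  # bool


def _encode_alignments(alignments: Iterable[CodonAlignment]) -> _EncodedAlignments:
    gene_ids, gene_idx, aa_idx, codon_idx, conserved = [], [], [], [], []
    for gi, aln in enumerate(alignments):
        gene_ids.append(aln.gene_id)
        for focal, other in zip(aln.focal_codons, aln.other_codons):
            focal = focal.upper().replace("U", "T")
            other = other.upper().replace("U", "T")
            aa = CODON_TO_AA.get(focal)
            other_aa = CODON_TO_AA.get(other)
            # skip gaps, stops, ambiguity, and nondegenerate focal codons
            if aa is None or other_aa is None or DEGENERACY[aa] < 2:
                continue
            gene_idx.append(gi)
            aa_idx.append(_AA_INDEX[aa])
            codon_idx.append(_DEG_CODON_INDEX[focal])
            conserved.append(aa == other_aa)
    return _EncodedAlignments(
        gene_ids,
        np.asarray(gene_idx, dtype=np.intp),
        np.asarray(aa_idx, dtype=np.intp),
        np.asarray(codon_idx, dtype=np.intp),
        np.asarray(conserved, dtype=bool),
    )


def _preferred_vector(pref: PreferredCodonSet) -> np.ndarray:
    """Per degenerate amino acid the preferred codon's index, or -1."""
    vec = np.full(len(DEGENERATE_AAS), -1, dtype=np.intp)
    for aa, codon in pref.choice.items():
        vec[_AA_INDEX[aa]] = _DEG_CODON_INDEX[codon]
    return vec


def _tables_from_encoding(
    enc: _EncodedAlignments, pref_vec: np.ndarray
) -> np.ndarray:
    """(n_genes x 4) a,b,c,d counts; codons of unassigned families skipped."""
    assigned = pref_vec[enc.aa_idx] >= 0
    preferred = assigned & (enc.codon_idx == pref_vec[enc.aa_idx])
    G = len(enc.gene_ids)
    cell = 2 * (~preferred[assigned]).astype(np.intp) + (
        ~enc.conserved[assigned]
    ).astype(np.intp)
    flat = np.bincount(enc.gene_idx[assigned] * 4 + cell, minlength=G * 4)
    return flat.reshape(G, 4)


def build_akashi_tables(
    alignments: Iterable[CodonAlignment], preferred: PreferredCodonSet
) -> list[StratumTable]:
    """Score each alignment into a preferred x conserved 2x2 stratum.

    A focal codon is preferred iff it matches its family's preferred codon;
    conserved iff the aligned ortholog codon encodes the same amino acid.
    Codons aligned to gaps, stops or ambiguous codons are skipped, as are
    families with no assigned preferred codon.  Strata with an empty margin
    are dropped (their odds ratio is uninformative).
    """
    enc = _encode_alignments(alignments)
    abcd = _tables_from_encoding(enc, _preferred_vector(preferred))
    tables = [
        StratumTable(gid, *row) for gid, row in zip(enc.gene_ids, abcd.tolist())
    ]
    usable = [t for t in tables if t.usable]
    if len(usable) < len(tables):
        logger.info(
            "dropped %d/%d strata with insufficient data", len(tables) - len(usable), len(tables)
        )
    return usable


def _abcd(tables: Sequence[StratumTable]) -> np.ndarray:
    return np.array([[t.a, t.b, t.c, t.d] for t in tables], dtype=float)


def mh_common_odds_ratio(tables: Sequence[StratumTable]) -> float:
    """Mantel-Haenszel common odds ratio sum(ad/n) / sum(bc/n)."""
    if not tables:
        raise ValueError("no usable strata")
    m = _abcd(tables)
    n = m.sum(axis=1)
    num = float((m[:, 0] * m[:, 3] / n).sum())
    den = float((m[:, 1] * m[:, 2] / n).sum())
    if den == 0.0:
        logger.warning("MH odds ratio denominator is zero; reporting +inf")
        return math.inf
    return num / den


def cmh_test(
    tables: Sequence[StratumTable],
    alternative: str = "two_sided",
    continuity: bool = True,
) -> tuple[float, float]:
    """Cochran-Mantel-Haenszel chi-square over per-gene 2x2 strata.

    chi2 = (|sum(a_k - E_k)| - 1/2)^2 / sum(V_k) with the hypergeometric
    mean and variance per stratum; p from chi-square(1).  With
    ``alternative="greater"`` the one-sided p tests OR > 1, halving the
    two-sided p when the deviation is in that direction.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    m = _abcd(tables)
    n = m.sum(axis=1)
    a = m[:, 0]
    r1 = m[:, 0] + m[:, 1]
    r2 = m[:, 2] + m[:, 3]
    c1 = m[:, 0] + m[:, 2]
    c2 = m[:, 1] + m[:, 3]
    E = r1 * c1 / n
    with np.errstate(invalid="ignore", divide="ignore"):
        V = r1 * r2 * c1 * c2 / (n**2 * (n - 1.0))
    V = np.where(n > 1, V, 0.0)
    sv = float(V.sum())
    if sv == 0.0:
        logger.warning("CMH variance is zero; test undefined")
        return math.nan, math.nan
    dev = float((a - E).sum())
    # no clamping at zero when |dev| < 1/2: matches the classical R and
    # statsmodels conventions for the corrected statistic
    num = abs(dev) - (0.5 if continuity else 0.0)
    chi2 = num**2 / sv
    p_two = float(stats.chi2.sf(chi2, 1))
    if alternative == "two_sided":
        return chi2, p_two
    p_one = p_two / 2.0 if dev > 0 else 1.0 - p_two / 2.0
    return chi2, p_one


def woolf_test(tables: Sequence[StratumTable]) -> tuple[float, int, float]:
    """Woolf chi-square for homogeneity of odds ratios across strata.

    Haldane-corrected (+0.5 per cell) log odds ratios, inverse-variance
    weights, statistic = sum w_k (lnOR_k - pooled)^2 on K-1 df.
    """
    if len(tables) < 2:
        raise ValueError("Woolf test needs at least two usable strata")
    m = _abcd(tables) + 0.5
    ln_or = np.log(m[:, 0] * m[:, 3] / (m[:, 1] * m[:, 2]))
    w = 1.0 / (1.0 / m).sum(axis=1)
    pooled = float((w * ln_or).sum() / w.sum())
    statistic = float((w * (ln_or - pooled) ** 2).sum())
    df = len(tables) - 1
    return statistic, df, float(stats.chi2.sf(statistic, df))


def _or_from_abcd(abcd: np.ndarray) -> float:
    """MH common OR from an (K x 4) array restricted to usable strata."""
    usable = (
        ((abcd[:, 0] + abcd[:, 1]) > 0)
        & ((abcd[:, 2] + abcd[:, 3]) > 0)
        & ((abcd[:, 0] + abcd[:, 2]) > 0)
        & ((abcd[:, 1] + abcd[:, 3]) > 0)
    )
    m = abcd[usable].astype(float)
    if m.shape[0] == 0:
        return math.nan
    n = m.sum(axis=1)
    den = float((m[:, 1] * m[:, 2] / n).sum())
    if den == 0:
        return math.inf
    return float((m[:, 0] * m[:, 3] / n).sum()) / den


def randomized_codon_set_reference(
    alignments: Iterable[CodonAlignment],
    observed_preferred: PreferredCodonSet,
    n_sets: int = 1000,
    seed: int = 0,
) -> float:
    """Fraction of random synonymous-codon sets beating the observed set.

    Each random set picks one codon uniformly per degenerate family (for
    families the observed set leaves unassigned the random set is also
    unassigned, so the comparison is like for like); Akashi tables are
    rebuilt and the MH common odds ratio recomputed.  Returns the
    proportion of sets with a strictly greater OR than the observed one —
    the P(Better Codon Set) reference.
    """
    enc = _encode_alignments(list(alignments))
    obs_vec = _preferred_vector(observed_preferred)
    observed_or = _or_from_abcd(_tables_from_encoding(enc, obs_vec))
    rng = np.random.default_rng(seed)
    better = 0
    valid = 0
    for _ in range(n_sets):
        vec = np.array(
            [
                -1
                if obs_vec[_AA_INDEX[aa]] < 0
                else _DEG_CODON_INDEX[FAMILIES[aa][rng.integers(DEGENERACY[aa])]]
                for aa in DEGENERATE_AAS
            ],
            dtype=np.intp,
        )
        r = _or_from_abcd(_tables_from_encoding(enc, vec))
        if math.isnan(r):
            logger.info("random codon set produced no usable strata; skipped")
            continue
        valid += 1
        if r > observed_or:
            better += 1
    if valid == 0:
        return math.nan
    return better / valid
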