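"""Preferred-codon identification.

Genome scope: a family's preferred codon is the synonymous codon whose
within-family usage rises most significantly as gene-level bias increases
(most significant negative Spearman correlation with Nc'), at a per-family
Bonferroni threshold of 0.05/d where d is the family's degeneracy.

Group scope: within a codon-usage group the preferred codon is simply the
codon with the greatest pooled usage frequency across the group's genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bias_metrics import CodonCounts
from .genetic_code import (
    CODON_TO_AA,
    DEGENERACY,
    DEGENERATE_AAS,
    DEGENERATE_CODONS,
    FAMILIES,
)

logger = logging.getLogger(__name__)


@dataclass
class PreferredCodonSet:
    """One preferred codon per degenerate amino acid (where assignable)."""

    choice: dict[str, str] = field(default_factory=dict)
    evidence: dict[str, tuple[float, float]] = field(default_factory=dict)
    scope: str = "genome"

    def preferred(self, codon: str) -> bool:
        aa = CODON_TO_AA.get(codon)
        return aa is not None and self.choice.get(aa) == codon


def family_frequency_matrix(genes: Iterable[CodonCounts]) -> pd.DataFrame:
    """Per-gene within-family codon frequencies (genes x 59 degenerate codons).

    Genes with no occurrence of a family get NaN for that family's codons
    and are dropped pairwise from downstream correlations.
    """
    gene_list = list(genes)
    mat = np.full((len(gene_list), len(DEGENERATE_CODONS)), np.nan)
    col = {c: j for j, c in enumerate(DEGENERATE_CODONS)}
    for i, g in enumerate(gene_list):
        for aa in DEGENERATE_AAS:
            fam = FAMILIES[aa]
            counts = g.family_counts(aa)
            n = counts.sum()
            if n > 0:
                for c, k in zip(fam, counts / n):
                    mat[i, col[c]] = k
    return pd.DataFrame(
        mat, index=[g.gene_id for g in gene_list], columns=list(DEGENERATE_CODONS)
    )


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and two-sided p.

    Pairs with a NaN in either vector are dropped; fewer than three complete
    pairs, or a constant vector, yields (nan, nan).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return (float("nan"), float("nan"))
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def identify_preferred_genomewide(
    freqs: pd.DataFrame, nc_prime: pd.Series, alpha: float = 0.05
) -> PreferredCodonSet:
    """Preferred codons from the correlation of usage with gene-level bias.

    For each degenerate family, each codon's within-family frequency is
    correlated with Nc' across genes; the codon with the smallest p-value
    among those with negative rho is preferred iff p < alpha/d.  Families
    with no qualifying codon are left unassigned.
    """
    ncp = nc_prime.reindex(freqs.index).to_numpy(dtype=float)
    out = PreferredCodonSet(scope="genome")
    for aa in DEGENERATE_AAS:
        d = DEGENERACY[aa]
        best: tuple[float, str] | None = None
        for codon in FAMILIES[aa]:
            if codon not in freqs.columns:
                continue
            rho, p = spearman_correlation(freqs[codon].to_numpy(), ncp)
            out.evidence[codon] = (rho, p)
            if not np.isnan(rho) and rho < 0 and (best is None or p < best[0]):
                best = (p, codon)
        if best is not None and best[0] < alpha / d:
            out.choice[aa] = best[1]
    return out


def identify_preferred_by_majority(
    genes: Iterable[CodonCounts], scope: str = "group"
) -> PreferredCodonSet:
    """Preferred codon per family = greatest pooled usage across the group.

    Pooled counts (not per-gene majority votes) decide; exact ties are
    broken toward the lexicographically first codon with a warning.
    """
    gene_list = list(genes)
    if not gene_list:
        raise ValueError("empty group")
    out = PreferredCodonSet(scope=scope)
    for aa in DEGENERATE_AAS:
        pooled = np.sum([g.family_counts(aa) for g in gene_list], axis=0)
        total = pooled.sum()
        if total == 0:
            continue
        fam = FAMILIES[aa]
        best = int(np.argmax(pooled))
        if int((pooled == pooled[best]).sum()) > 1:
            logger.warning(
                "tie for preferred codon of %s in group %s; choosing %s",
                aa,
                scope,
                fam[best],
            )
        out.choice[aa] = fam[best]
        for c, k in zip(fam, pooled / total):
            out.evidence[c] = (float(k), float("nan"))
    return out


def evidence_table(pref: PreferredCodonSet) -> pd.DataFrame:
    """Per-codon rho/p table with the chosen codon marked."""
    rows = []
    for codon, (rho, p) in sorted(pref.evidence.items()):
        aa = CODON_TO_AA[codon]
        rows.append(
            {
                "codon": codon,
                "amino_acid": aa,
                "rho": rho,
                "p": p,
                "preferred": pref.choice.get(aa) == codon,
            }
        )
    return pd.DataFrame(rows)
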