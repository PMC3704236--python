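"""tRNA gene copy number vs codon usage.

tRNA gene counts serve as proxies for cellular tRNA abundance.  Each
anticodon is mapped to the codons it decodes under general wobble rules
(first anticodon position = codon position 3): G34 reads C/U, U34 reads
A/G, C34 reads G only, and A34 is treated as inosine-like, reading U/C/A.
A species' usage frequency is the summed observed frequency of its
recognized codons; both gene-count and usage vectors are normalized to a
maximum of 1 before correlation.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .genetic_code import CODON_TO_AA, translate_codon
from .preferred_codons import spearman_correlation

logger = logging.getLogger(__name__)

_WC = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: anticodon position 34 -> codon third-position bases it decodes
DEFAULT_WOBBLE_34: dict[str, tuple[str, ...]] = {
    "G": ("C", "T"),
    "T": ("A", "G"),
    "C": ("G",),
    "A": ("T", "C", "A"),
}


def wobble_decoding(
    anticodon: str, rules: Mapping[str, tuple[str, ...]] | None = None
) -> list[str]:
    """Sense codons decoded by an anticodon under general wobble rules.

    Codon positions 1-2 pair Watson-Crick with anticodon positions 3-2;
    the third codon position is set by the wobble rules for anticodon
    position 1 (position 34).  Stop codons are discarded; if the decoded
    set spans more than one amino acid, only codons matching the amino
    acid of the full Watson-Crick codon are kept, with a warning.

    Codons are returned in the alphabet of the input (U for RNA input).
    """
    rules = dict(DEFAULT_WOBBLE_34) if rules is None else dict(rules)
    ac = anticodon.upper().replace("U", "T")
    if len(ac) != 3 or any(b not in "ACGT" for b in ac):
        raise ValueError(f"invalid anticodon {anticodon!r}")
    stem = _WC[ac[2]] + _WC[ac[1]]
    codons = [stem + b for b in rules[ac[0]]]
    codons = [c for c in codons if c in CODON_TO_AA]
    aas = {CODON_TO_AA[c] for c in codons}
    if len(aas) > 1:
        wc_codon = stem + _WC[ac[0]]
        wc_aa = translate_codon(wc_codon)
        logger.warning(
            "anticodon %s decodes several amino acids (%s); keeping %s",
            anticodon,
            ",".join(sorted(aas)),
            wc_aa,
        )
        codons = [c for c in codons if CODON_TO_AA[c] == wc_aa]
    if "U" in anticodon.upper():
        codons = [c.replace("T", "U") for c in codons]
    return codons


def trna_usage_frequencies(
    trna: pd.DataFrame,
    usage: Mapping[str, float],
    rules: Mapping[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """Normalized tRNA gene-count and codon-usage frequencies per species.

    ``trna`` has columns anticodon, amino_acid, gene_count; ``usage`` maps
    codons to observed genome frequencies.  Amino acids represented by a
    single tRNA gene copy are excluded.  Both resulting vectors are divided
    by their own maxima so the largest value is exactly 1.
    """
    df = trna.copy()
    df["anticodon"] = df["anticodon"].str.upper().str.replace("U", "T")
    per_aa = df.groupby("amino_acid")["gene_count"].sum()
    keep_aas = set(per_aa[per_aa > 1].index)
    df = df[df["amino_acid"].isin(keep_aas)].reset_index(drop=True)
    if df.empty:
        logger.warning("all tRNA species excluded; empty correspondence table")
        return pd.DataFrame(
            columns=["anticodon", "amino_acid", "gene_count", "trna_freq", "usage_freq"]
        )
    usage = {k.upper().replace("U", "T"): v for k, v in usage.items()}
    sums = []
    for ac in df["anticodon"]:
        codons = wobble_decoding(ac, rules=rules)
        sums.append(sum(usage.get(c.replace("U", "T"), 0.0) for c in codons))
    df["usage_sum"] = sums
    df["trna_freq"] = df["gene_count"] / df["gene_count"].max()
    mx = max(max(sums), 1e-300)
    df["usage_freq"] = df["usage_sum"] / mx
    return df[["anticodon", "amino_acid", "gene_count", "usage_sum", "trna_freq", "usage_freq"]]


def trna_codon_correlation(
    table: pd.DataFrame, level: str = "codon"
) -> tuple[float, float]:
    """Spearman correlation of tRNA frequencies with usage frequencies.

    ``level="codon"`` correlates per tRNA species; ``level="amino_acid"``
    first sums gene counts and usage within each amino acid.
    """
    if level == "codon":
        x = table["trna_freq"].to_numpy()
        y = table["usage_freq"].to_numpy()
    elif level == "amino_acid":
        agg = table.groupby("amino_acid")[["gene_count", "usage_sum"]].sum()
        x = (agg["gene_count"] / agg["gene_count"].max()).to_numpy()
        y = (agg["usage_sum"] / agg["usage_sum"].max()).to_numpy()
    else:
        raise ValueError(f"unknown level {level!r}")
    return spearman_correlation(x, y)


def pooled_codon_usage(counts_list) -> dict[str, float]:
    """Observed frequency of each sense codon pooled over genes."""
    tally: dict[str, float] = {}
    for cc in counts_list:
        for c, k in cc.counts.items():
            tally[c] = tally.get(c, 0.0) + k
    total = sum(tally.values())
    return {c: v / total for c, v in tally.items()}
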