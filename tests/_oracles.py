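"""Independent reference implementations used only as test oracles.

Each oracle is coded from first principles, separately from the package
(own genetic-code tables, own formulas), so that agreement is evidence and
not tautology.
"""

from __future__ import annotations

import numpy as np

# Hand-written family table for the Nc oracle (not imported from the package).
ORACLE_FAMILIES = {
    2: [
        ("TTT", "TTC"),  # Phe
        ("TAT", "TAC"),  # Tyr
        ("CAT", "CAC"),  # His
        ("CAA", "CAG"),  # Gln
        ("AAT", "AAC"),  # Asn
        ("AAA", "AAG"),  # Lys
        ("GAT", "GAC"),  # Asp
        ("GAA", "GAG"),  # Glu
        ("TGT", "TGC"),  # Cys
    ],
    3: [("ATT", "ATC", "ATA")],  # Ile
    4: [
        ("GTT", "GTC", "GTA", "GTG"),  # Val
        ("CCT", "CCC", "CCA", "CCG"),  # Pro
        ("ACT", "ACC", "ACA", "ACG"),  # Thr
        ("GCT", "GCC", "GCA", "GCG"),  # Ala
        ("GGT", "GGC", "GGA", "GGG"),  # Gly
    ],
    6: [
        ("TTA", "TTG", "CTT", "CTC", "CTA", "CTG"),  # Leu
        ("TCT", "TCC", "TCA", "TCG", "AGT", "AGC"),  # Ser
        ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG"),  # Arg
    ],
}


def nc_brute_force(counts: dict[str, int]) -> float:
    """Wright's Nc by explicit family enumeration."""
    class_f = {}
    for d, families in ORACLE_FAMILIES.items():
        fs = []
        for fam in families:
            c = np.array([counts.get(codon, 0) for codon in fam], dtype=float)
            n = c.sum()
            if n < 2:
                continue
            p = c / n
            f = (n * (p**2).sum() - 1) / (n - 1)
            if f > 0:
                fs.append(f)
        if fs:
            class_f[d] = float(np.mean(fs))
    if not class_f:
        return float("nan")
    if 3 not in class_f and 2 in class_f and 4 in class_f:
        class_f[3] = (class_f[2] + class_f[4]) / 2
    available = list(class_f.values())
    for d in (2, 3, 4, 6):
        class_f.setdefault(d, float(np.mean(available)))
    nc = 2 + 9 / class_f[2] + 1 / class_f[3] + 5 / class_f[4] + 3 / class_f[6]
    return min(61.0, max(20.0, nc))


def mh_or_statsmodels(abcd: np.ndarray) -> float:
    """Mantel-Haenszel pooled OR via statsmodels StratifiedTable."""
    from statsmodels.stats.contingency_tables import StratifiedTable

    tables = np.stack(
        [[[abcd[:, 0], abcd[:, 1]], [abcd[:, 2], abcd[:, 3]]]], axis=0
    )[0].astype(float)
    return float(StratifiedTable(tables).oddsratio_pooled)


def cmh_statsmodels(abcd: np.ndarray, correction: bool = True) -> tuple[float, float]:
    """CMH chi-square and two-sided p via statsmodels StratifiedTable."""
    from statsmodels.stats.contingency_tables import StratifiedTable

    tables = np.stack(
        [[[abcd[:, 0], abcd[:, 1]], [abcd[:, 2], abcd[:, 3]]]], axis=0
    )[0].astype(float)
    res = StratifiedTable(tables).test_null_odds(correction=correction)
    return float(res.statistic), float(res.pvalue)


def woolf_reference(abcd: np.ndarray) -> tuple[float, int, float]:
    """Woolf homogeneity statistic via the weighted-variance identity.

    T = sum w y^2 - (sum w y)^2 / sum w with y the Haldane-corrected log
    odds ratios — algebraically the weighted sum of squared deviations,
    computed along a different route than the implementation.
    """
    from scipy.stats import chi2

    m = abcd.astype(float) + 0.5
    y = np.log(m[:, 0]) + np.log(m[:, 3]) - np.log(m[:, 1]) - np.log(m[:, 2])
    w = 1.0 / (1 / m[:, 0] + 1 / m[:, 1] + 1 / m[:, 2] + 1 / m[:, 3])
    t = float((w * y**2).sum() - (w * y).sum() ** 2 / w.sum())
    df = len(m) - 1
    return t, df, float(chi2.sf(t, df))


_ORACLE_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def max_pairs_enumeration(seq: str, min_loop: int = 3) -> int:
    """Maximum base pairs by exhaustive recursion (small strings only)."""
    s = seq.upper().replace("T", "U")

    def rec(i: int, j: int) -> int:
        if j - i <= min_loop:
            return 0
        best = rec(i + 1, j)
        for k in range(i + min_loop + 1, j + 1):
            if (s[i], s[k]) in _ORACLE_PAIRS:
                best = max(best, 1 + rec(i + 1, k - 1) + rec(k + 1, j))
        return best

    return rec(0, len(s) - 1)


def random_stratified_tables(rng, n_tables: int, max_cell: int = 30) -> np.ndarray:
    """Random usable 2x2 strata (all marginals positive) as an (K,4) array."""
    out = []
    while len(out) < n_tables:
        t = rng.integers(0, max_cell, size=4)
        if (
            t[0] + t[1] > 0
            and t[2] + t[3] > 0
            and t[0] + t[2] > 0
            and t[1] + t[3] > 0
            and t.sum() > 1
        ):
            out.append(t)
    return np.array(out)
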