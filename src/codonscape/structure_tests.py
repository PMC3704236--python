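"""Stem/loop preference of preferred-codon third positions.

Given a secondary-structure prediction for each mRNA (dot-bracket), the
third position (N3) of every degenerate codon is classified as paired
(stem) or unpaired (loop) and as belonging to a preferred or unpreferred
codon.  Per-gene 2x2 strata are combined with the one-sided CMH procedure
to ask whether preferred-codon N3 sites pair in stems more often than
unpreferred ones, overall (N3) and restricted to each third-position base
(A3/C3/G3/U3).

A small base-pair-maximization folder (`toy_fold`) is included so the test
machinery can be exercised end to end without an external structure
predictor; it is not a thermodynamic model.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .genetic_code import CODON_TO_AA, DEGENERACY, STOP_CODONS, codons_of
from .conservation_tests import StratumTable
from .preferred_codons import PreferredCodonSet

BASE_FILTERS = ("A3", "C3", "G3", "U3", "N3")


@dataclass
class StructureAnnotation:
    """Per-nucleotide paired/unpaired states of one folded sequence."""

    gene_id: str
    pairing: np.ndarray  # bool, True = paired (stem)


def parse_dot_bracket(structure: str) -> np.ndarray:
    """Pairing vector from a dot-bracket string (True = paired).

    Raises ValueError naming the offending position on unbalanced input.
    """
    pairing = np.zeros(len(structure), dtype=bool)
    stack: list[int] = []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairing[i] = pairing[j] = True
        elif ch != ".":
            raise ValueError(f"unexpected character {ch!r} at position {i}")
    if stack:
        raise ValueError(f"unbalanced '(' at position {stack[-1]}")
    return pairing


_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}


def toy_fold(seq: str, min_loop: int = 3) -> str:
    """Base-pair-maximization folding (Watson-Crick + GU wobble pairs).

    Dynamic program over the number of pairs with hairpin loops of at
    least ``min_loop`` unpaired bases; deterministic traceback that pairs
    the leftmost available partner.  Returns a dot-bracket string.
    """
    s = seq.upper().replace("T", "U")
    n = len(s)

    def can_pair(i: int, j: int) -> bool:
        return (s[i], s[j]) in _PAIRS and j - i > min_loop

    dp = np.zeros((n + 1, n + 1), dtype=int)
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = dp[i + 1][j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    best = max(best, dp[i + 1][k - 1] + dp[k + 1][j] + 1)
            dp[i][j] = best

    out = ["."] * n

    def trace(i: int, j: int) -> None:
        while i < j:
            if dp[i][j] == dp[i + 1][j]:
                i += 1
                continue
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k) and dp[i][j] == dp[i + 1][k - 1] + dp[k + 1][j] + 1:
                    out[i], out[k] = "(", ")"
                    trace(i + 1, k - 1)
                    i, j = k + 1, j
                    break

    trace(0, n - 1)
    return "".join(out)


@lru_cache(maxsize=None)
def _filter_base(base_filter: str) -> str | None:
    if base_filter not in BASE_FILTERS:
        raise ValueError(f"unknown base filter {base_filter!r}")
    return None if base_filter == "N3" else base_filter[0].replace("U", "T")


def build_structure_tables(
    cds: str,
    structure: StructureAnnotation,
    preferred: PreferredCodonSet,
    base_filter: str = "N3",
) -> StratumTable:
    """Cross codon preference with the stem/loop state of N3 for one gene.

    Rows: preferred vs unpreferred codon (per the group's preferred set);
    columns: N3 paired in a stem vs unpaired in a loop.  Only degenerate
    sense codons whose family has an assigned preferred codon are scored;
    ``base_filter`` restricts to codons with that third base (N3 = all).
    """
    cods = codons_of(cds)
    if len(structure.pairing) != len(cds):
        raise ValueError(
            f"structure length {len(structure.pairing)} != CDS length {len(cds)} "
            f"for {structure.gene_id!r}"
        )
    want = _filter_base(base_filter)
    a = b = c = d = 0
    for i, codon in enumerate(cods):
        if codon in STOP_CODONS or codon not in CODON_TO_AA:
            continue
        aa = CODON_TO_AA[codon]
        if DEGENERACY[aa] < 2 or aa not in preferred.choice:
            continue
        if want is not None and codon[2] != want:
            continue
        stem = bool(structure.pairing[3 * i + 2])
        if preferred.choice[aa] == codon:
            a, b = (a + 1, b) if stem else (a, b + 1)
        else:
            c, d = (c + 1, d) if stem else (c, d + 1)
    return StratumTable(structure.gene_id, a, b, c, d)


def structure_cmh(
    genes: dict[str, str],
    structures: dict[str, StructureAnnotation],
    preferred: PreferredCodonSet,
    base_filter: str = "N3",
    continuity: bool = True,
) -> dict[str, float]:
    """One-sided CMH (stem > loop for preferred codons) over a gene group.

    ``genes`` maps gene id to CDS.  Returns chi2, one-sided p, the MH
    common odds ratio and the number of usable strata.
    """
    from .conservation_tests import cmh_test, mh_common_odds_ratio

    tables = [
        build_structure_tables(cds, structures[gid], preferred, base_filter)
        for gid, cds in genes.items()
        if gid in structures
    ]
    usable = [t for t in tables if t.usable]
    if not usable:
        return {"chi2": float("nan"), "p": float("nan"), "or": float("nan"), "n_genes": 0}
    chi2, p = cmh_test(usable, alternative="greater", continuity=continuity)
    return {
        "chi2": chi2,
        "p": p,
        "or": mh_common_odds_ratio(usable),
        "n_genes": len(usable),
    }
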