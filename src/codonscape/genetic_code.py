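"""Standard genetic code tables and synonymous-family structure.

Everything downstream (Nc, sENC-X, clustering, Akashi tables) works on the
61 sense codons of the standard nuclear code, grouped into synonymous
families.  Degeneracy classes follow the convention in which the three
sixfold amino acids (Leu, Ser, Arg) are kept as single 6-codon families, so
the class weights of Wright's Nc are 9 twofold + 1 threefold (Ile) +
5 fourfold + 3 sixfold, and Nc spans [20, 61].
"""

from __future__ import annotations

from Bio.Data.CodonTable import unambiguous_dna_by_id

_TABLE = unambiguous_dna_by_id[1]

#: codon (DNA alphabet) -> one-letter amino acid, sense codons only
CODON_TO_AA: dict[str, str] = {
    codon: aa for codon, aa in _TABLE.forward_table.items() if len(codon) == 3
}

STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

#: the 61 sense codons in lexicographic order
SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))

#: amino acid -> sorted tuple of its synonymous codons
FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in CODON_TO_AA.items():
    FAMILIES.setdefault(_aa, ())
FAMILIES = {
    aa: tuple(sorted(c for c, a in CODON_TO_AA.items() if a == aa))
    for aa in FAMILIES
}

#: amino acid -> degeneracy (number of synonymous codons)
DEGENERACY: dict[str, int] = {aa: len(cods) for aa, cods in FAMILIES.items()}

#: the 18 amino acids with two or more synonymous codons
DEGENERATE_AAS: tuple[str, ...] = tuple(
    sorted(aa for aa, d in DEGENERACY.items() if d >= 2)
)

#: the 59 sense codons belonging to degenerate families
DEGENERATE_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if DEGENERACY[CODON_TO_AA[c]] >= 2
)

#: degeneracy class -> number of families (9/1/5/3), used as Nc weights
CLASS_COUNTS: dict[int, int] = {}
for _aa in DEGENERATE_AAS:
    CLASS_COUNTS[DEGENERACY[_aa]] = CLASS_COUNTS.get(DEGENERACY[_aa], 0) + 1

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA/RNA string (returned in DNA alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


def codons_of(cds: str) -> list[str]:
    """Split a CDS into complete codons (uppercased, T alphabet)."""
    s = cds.upper().replace("U", "T")
    return [s[i : i + 3] for i in range(0, len(s) - len(s) % 3, 3)]


def translate_codon(codon: str) -> str | None:
    """One-letter amino acid for a sense codon, '*' for stops, None otherwise."""
    c = codon.upper().replace("U", "T")
    if c in CODON_TO_AA:
        return CODON_TO_AA[c]
    if c in STOP_CODONS:
        return "*"
    return None
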