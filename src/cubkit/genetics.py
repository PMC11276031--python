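"""Genetic-code tables and synonymous-family schemes.

Codons are RNA triplets (``U`` not ``T``) throughout the package; FASTA
input in the DNA alphabet is converted on read.  The standard (nuclear)
genetic code is assumed everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product

RNA_BASES = "UCAG"

#: All 64 RNA codons in a fixed, reproducible order.
CODONS: tuple[str, ...] = tuple("".join(p) for p in product(RNA_BASES, repeat=3))

STOP_CODONS: frozenset[str] = frozenset({"UAA", "UAG", "UGA"})
START_CODON = "AUG"

#: Standard genetic code, RNA codon -> one-letter amino acid ('*' = stop).
GENETIC_CODE: dict[str, str] = {
    "UUU": "F", "UUC": "F", "UUA": "L", "UUG": "L",
    "UCU": "S", "UCC": "S", "UCA": "S", "UCG": "S",
    "UAU": "Y", "UAC": "Y", "UAA": "*", "UAG": "*",
    "UGU": "C", "UGC": "C", "UGA": "*", "UGG": "W",
    "CUU": "L", "CUC": "L", "CUA": "L", "CUG": "L",
    "CCU": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAU": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "CGU": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AUU": "I", "AUC": "I", "AUA": "I", "AUG": "M",
    "ACU": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "AAU": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "AGU": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GUU": "V", "GUC": "V", "GUA": "V", "GUG": "V",
    "GCU": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "GAU": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGU": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

SENSE_CODONS: tuple[str, ...] = tuple(c for c in CODONS if c not in STOP_CODONS)

#: Codons of the two single-codon amino acids (Met, Trp).
SINGLE_CODONS: frozenset[str] = frozenset({"AUG", "UGG"})

#: The 59 codons of degenerate (synonymous) families.
SYNONYMOUS_CODONS: tuple[str, ...] = tuple(
    c for c in SENSE_CODONS if c not in SINGLE_CODONS
)

#: Amino acid -> tuple of its codons (standard code, stops excluded).
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon in CODONS:
    _aa = GENETIC_CODE[_codon]
    if _aa != "*":
        AA_TO_CODONS.setdefault(_aa, ())
        AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)


@dataclass(frozen=True)
class FamilyScheme:
    """A partition of the 61 sense codons into synonymous families.

    ``STANDARD`` keeps Leu/Ser/Arg as six-fold families (the grouping
    Wright's ENC classes use).  ``SPLIT`` divides each six-fold family
    into its four-fold and two-fold codon boxes (Leu -> CUN + UUR,
    Ser -> UCN + AGY, Arg -> CGN + AGR), the convention under which
    published genome RSCU tables for these species are reproduced.
    """

    name: str
    families: tuple[tuple[str, ...], ...]
    codon_to_family: dict[str, tuple[str, ...]] = field(
        init=False, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        seen: set[str] = set()
        lookup: dict[str, tuple[str, ...]] = {}
        for fam in self.families:
            for codon in fam:
                if codon in lookup:
                    raise ValueError(f"codon {codon} in two families")
                lookup[codon] = fam
                seen.add(codon)
        if seen != set(SENSE_CODONS):
            missing = set(SENSE_CODONS) - seen
            raise ValueError(f"scheme does not cover sense codons: {sorted(missing)}")
        object.__setattr__(self, "codon_to_family", lookup)

    def degeneracy(self, codon: str) -> int:
        return len(self.codon_to_family[codon])


def _standard_families() -> tuple[tuple[str, ...], ...]:
    return tuple(sorted(AA_TO_CODONS[aa]) for aa in sorted(AA_TO_CODONS))


def _split_families() -> tuple[tuple[str, ...], ...]:
    sixfold_split = {
        "L": (("CUA", "CUC", "CUG", "CUU"), ("UUA", "UUG")),
        "S": (("UCA", "UCC", "UCG", "UCU"), ("AGC", "AGU")),
        "R": (("CGA", "CGC", "CGG", "CGU"), ("AGA", "AGG")),
    }
    fams: list[tuple[str, ...]] = []
    for aa in sorted(AA_TO_CODONS):
        if aa in sixfold_split:
            fams.extend(sixfold_split[aa])
        else:
            fams.append(tuple(sorted(AA_TO_CODONS[aa])))
    return tuple(fams)


STANDARD = FamilyScheme("standard", _standard_families())
SPLIT = FamilyScheme("split", _split_families())

SCHEMES: dict[str, FamilyScheme] = {"standard": STANDARD, "split": SPLIT}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for an RNA codon ('*' for a stop)."""
    return GENETIC_CODE[codon]
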