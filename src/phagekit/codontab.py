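"""Codon usage tables.

A :class:`CodonTable` maps each amino acid (one-letter code, ``*`` for stop)
to its synonymous codons together with within-amino-acid usage fractions.
Usage drives deterministic codon choice during back-translation: the
highest-usage codon wins, and codons whose fraction falls below
``rare_threshold`` are avoided unless a sequence constraint forces them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data import CodonTable as _bio_tables
from Bio.Seq import Seq

STANDARD_CODE = _bio_tables.unambiguous_dna_by_id[1]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
STOP_SYMBOL = "*"
STOP_CODONS = tuple(sorted(STANDARD_CODE.stop_codons))  # ('TAA', 'TAG', 'TGA')
AMBER_CODON = "TAG"


def synonymous_codons() -> dict[str, tuple[str, ...]]:
    """Amino acid -> synonymous codons under the standard genetic code."""
    by_aa: dict[str, list[str]] = {}
    for codon, aa in STANDARD_CODE.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    by_aa[STOP_SYMBOL] = list(STOP_CODONS)
    return {aa: tuple(sorted(codons)) for aa, codons in by_aa.items()}


SYNONYMS = synonymous_codons()


def translate(dna: str) -> str:
    """Translate a DNA string (length divisible by 3) with the standard code."""
    if len(dna) % 3:
        raise ValueError(f"length {len(dna)} is not a multiple of 3")
    return str(Seq(dna).translate())


# E. coli K-12 codon usage, expressed as within-amino-acid fractions.
# Values are the conventional whole-genome figures rounded to two decimals
# and renormalised so each amino acid sums to exactly 1.
ECOLI_K12_USAGE: dict[str, list[tuple[str, float]]] = {
    "A": [("GCG", 0.36), ("GCC", 0.27), ("GCA", 0.21), ("GCT", 0.16)],
    "R": [("CGC", 0.40), ("CGT", 0.38), ("CGG", 0.10), ("CGA", 0.06),
          ("AGA", 0.04), ("AGG", 0.02)],
    "N": [("AAC", 0.55), ("AAT", 0.45)],
    "D": [("GAT", 0.63), ("GAC", 0.37)],
    "C": [("TGC", 0.55), ("TGT", 0.45)],
    "Q": [("CAG", 0.65), ("CAA", 0.35)],
    "E": [("GAA", 0.68), ("GAG", 0.32)],
    "G": [("GGC", 0.40), ("GGT", 0.34), ("GGG", 0.15), ("GGA", 0.11)],
    "H": [("CAT", 0.57), ("CAC", 0.43)],
    "I": [("ATT", 0.51), ("ATC", 0.42), ("ATA", 0.07)],
    "L": [("CTG", 0.50), ("TTA", 0.13), ("TTG", 0.13), ("CTT", 0.10),
          ("CTC", 0.10), ("CTA", 0.04)],
    "K": [("AAA", 0.77), ("AAG", 0.23)],
    "M": [("ATG", 1.00)],
    "F": [("TTT", 0.57), ("TTC", 0.43)],
    "P": [("CCG", 0.52), ("CCA", 0.19), ("CCT", 0.16), ("CCC", 0.13)],
    "S": [("AGC", 0.28), ("TCT", 0.15), ("TCC", 0.15), ("TCG", 0.15),
          ("AGT", 0.15), ("TCA", 0.12)],
    "T": [("ACC", 0.44), ("ACG", 0.26), ("ACT", 0.17), ("ACA", 0.13)],
    "W": [("TGG", 1.00)],
    "Y": [("TAT", 0.57), ("TAC", 0.43)],
    "V": [("GTG", 0.37), ("GTT", 0.28), ("GTC", 0.20), ("GTA", 0.15)],
    "*": [("TAA", 0.64), ("TGA", 0.29), ("TAG", 0.07)],
}


@dataclass(frozen=True)
class CodonTable:
    """Per-amino-acid codon usage with a rareness cut-off.

    Parameters
    ----------
    usage
        Map amino acid -> list of ``(codon, fraction)``; fractions within
        each amino acid must sum to 1 (tolerance 1e-9) and every codon must
        translate to its key under the standard genetic code.
    rare_threshold
        Within-amino-acid usage fraction below which a codon is considered
        rare (strict ``<``). Default 0.10.
    """

    usage: dict[str, tuple[tuple[str, float], ...]] = field(default_factory=dict)
    rare_threshold: float = 0.10

    def __post_init__(self) -> None:
        frozen = {aa: tuple(entries) for aa, entries in self.usage.items()}
        object.__setattr__(self, "usage", frozen)
        for aa, entries in frozen.items():
            total = 0.0
            for codon, weight in entries:
                codon = codon.upper()
                expected = (STOP_SYMBOL if codon in STOP_CODONS
                            else STANDARD_CODE.forward_table[codon])
                if expected != aa:
                    raise ValueError(f"codon {codon} does not encode {aa}")
                if not 0.0 <= weight <= 1.0:
                    raise ValueError(f"usage weight {weight} for {codon} not in [0,1]")
                total += weight
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"usage for {aa} sums to {total}, expected 1")

    @classmethod
    def ecoli(cls, rare_threshold: float = 0.10) -> "CodonTable":
        return cls({aa: tuple(v) for aa, v in ECOLI_K12_USAGE.items()},
                   rare_threshold=rare_threshold)

    def codons_for(self, aa: str, include_rare: bool = True) -> list[str]:
        """Codons for ``aa``, highest usage first (codon string breaks ties)."""
        entries = sorted(self.usage[aa], key=lambda cw: (-cw[1], cw[0]))
        if include_rare:
            return [c for c, _ in entries]
        return [c for c, w in entries if w >= self.rare_threshold]

    def preferred_codon(self, aa: str) -> str:
        """Highest-usage codon for ``aa`` (ignores rareness: it is the max)."""
        return self.codons_for(aa)[0]

    def weight(self, aa: str, codon: str) -> float:
        for c, w in self.usage[aa]:
            if c == codon.upper():
                return w
        raise KeyError(f"{codon} not listed for {aa}")

    def is_rare(self, aa: str, codon: str) -> bool:
        return self.weight(aa, codon) < self.rare_threshold
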