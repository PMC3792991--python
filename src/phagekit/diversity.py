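"""CDR diversity design for trinucleotide (trimer) randomization.

A :class:`CdrDesign` holds ordered per-position amino-acid frequency
tables for the randomized positions of a CDR cassette, plus the fixed
flanking residues. Trimer synthesis realises the frequencies exactly by
mixing whole-codon building blocks, so the library contains no stop
codons and exactly one codon per amino acid.

The compositional rules the designs are validated against:

* hydrophobicity cap — the summed frequency of {V, I, L, M, F} at any
  randomized position must not exceed 0.25 (aggregation control);
* CDR2 cassettes randomize exactly 4 positions and omit positively
  charged residues (K, R, H);
* CDR3 cassettes randomize exactly 7 positions of a 10-residue loop
  ending in the fixed F, D, Y tail, and exclude C, I, M and K outright.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

from .codontab import CodonTable, AMINO_ACIDS, STOP_CODONS, STOP_SYMBOL

HYDROPHOBIC = frozenset("VILMF")
POSITIVE = frozenset("KRH")

FREQ_TOL = 1e-9


@dataclass(frozen=True)
class PositionFrequency:
    """Amino-acid frequency table for one randomized position."""

    position_label: str
    freq: dict[str, float]

    def __post_init__(self) -> None:
        clean = {}
        for aa, p in self.freq.items():
            aa = aa.upper()
            if aa == STOP_SYMBOL:
                raise ValueError(f"{self.position_label}: stop symbol not allowed")
            if aa not in AMINO_ACIDS:
                raise ValueError(f"{self.position_label}: unknown residue {aa!r}")
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{self.position_label}: frequency {p} outside [0,1]")
            clean[aa] = float(p)
        total = math.fsum(clean.values())
        if abs(total - 1.0) > FREQ_TOL:
            raise ValueError(
                f"{self.position_label}: frequencies sum to {total!r}, expected 1"
            )
        object.__setattr__(self, "freq", clean)

    @property
    def support(self) -> tuple[str, ...]:
        """Residues with nonzero frequency, alphabetical."""
        return tuple(sorted(aa for aa, p in self.freq.items() if p > 0.0))

    def p(self, aa: str) -> float:
        return self.freq.get(aa.upper(), 0.0)

    def hydrophobic_mass(self) -> float:
        return math.fsum(p for aa, p in self.freq.items() if aa in HYDROPHOBIC)


@dataclass(frozen=True)
class CdrDesign:
    """Frequency design for one CDR cassette.

    ``constraint_profile`` names the rule set used by :func:`validate_design`
    ("cdr2", "cdr3", or "generic" for frequency-only checks).
    """

    name: str
    positions: tuple[PositionFrequency, ...]
    fixed_flanks: tuple[str, str] = ("", "")
    constraint_profile: str = "generic"

    def __post_init__(self) -> None:
        object.__setattr__(self, "positions", tuple(self.positions))
        left, right = self.fixed_flanks
        object.__setattr__(self, "fixed_flanks", (left.upper(), right.upper()))

    @property
    def n_randomized(self) -> int:
        return len(self.positions)

    @property
    def loop_length(self) -> int:
        left, right = self.fixed_flanks
        return len(left) + self.n_randomized + len(right)


@dataclass(frozen=True)
class Violation:
    rule: str
    position: str
    value: float
    message: str


def validate_design(design: CdrDesign) -> list[Violation]:
    """Check a design against its constraint profile; never raises.

    Returns an empty list iff the design is valid. Frequency-sum and
    stop-exclusion rules are enforced at construction time by
    :class:`PositionFrequency`, so validation covers the compositional
    rules only.
    """
    out: list[Violation] = []

    def add(rule: str, pos: str, value: float, msg: str) -> None:
        out.append(Violation(rule, pos, value, msg))

    for pf in design.positions:
        mass = pf.hydrophobic_mass()
        if mass > 0.25 + FREQ_TOL:
            add("hydrophobic_cap", pf.position_label, mass,
                f"{pf.position_label}: hydrophobic frequency {mass:.3f} exceeds 0.25")

    profile = design.constraint_profile
    if profile == "cdr2":
        if design.n_randomized != 4:
            add("cdr2_randomized_positions", design.name, design.n_randomized,
                f"CDR2 must randomize exactly 4 positions, found {design.n_randomized}")
        for pf in design.positions:
            for aa in sorted(POSITIVE):
                if pf.p(aa) > 0.0:
                    add("cdr2_no_positive", pf.position_label, pf.p(aa),
                        f"{pf.position_label}: positively charged {aa} present "
                        f"at {pf.p(aa):.3f}")
    elif profile == "cdr3":
        if design.n_randomized != 7:
            add("cdr3_randomized_positions", design.name, design.n_randomized,
                f"CDR3 must randomize exactly 7 positions, found {design.n_randomized}")
        if design.loop_length != 10:
            add("cdr3_loop_length", design.name, design.loop_length,
                f"CDR3 loop must span 10 residues, found {design.loop_length}")
        if not design.fixed_flanks[1].endswith("FDY"):
            add("cdr3_fdy_tail", design.name, 0.0,
                f"CDR3 must end with the fixed FDY tail, "
                f"found {design.fixed_flanks[1]!r}")
        for pf in design.positions:
            for aa in "CIMK":
                if pf.p(aa) > 0.0:
                    add("cdr3_excluded_residue", pf.position_label, pf.p(aa),
                        f"{pf.position_label}: excluded residue {aa} present "
                        f"at {pf.p(aa):.3f}")
    elif profile != "generic":
        add("unknown_profile", design.name, 0.0,
            f"unknown constraint profile {profile!r}")
    return out


def clone_probability(design: CdrDesign, sequence: str) -> float:
    """Probability that random assembly draws ``sequence`` at the
    randomized positions: the product of per-position frequencies."""
    sequence = sequence.upper()
    if len(sequence) != design.n_randomized:
        raise ValueError(
            f"sequence length {len(sequence)} != {design.n_randomized} "
            f"randomized positions"
        )
    prob = 1.0
    for pf, aa in zip(design.positions, sequence):
        prob *= pf.p(aa)
        if prob == 0.0:
            return 0.0
    return prob


def theoretical_diversity(design: CdrDesign) -> int:
    """Number of distinct sequences with nonzero probability."""
    n = 1
    for pf in design.positions:
        n *= len(pf.support)
    return n


def extreme_probability(design: CdrDesign, mode: str = "most_common") -> float:
    """Probability of the most common (or rarest nonzero) clone."""
    if mode not in ("most_common", "rarest"):
        raise ValueError("mode must be 'most_common' or 'rarest'")
    prob = 1.0
    for pf in design.positions:
        nonzero = [p for p in pf.freq.values() if p > 0.0]
        if not nonzero:
            raise ValueError(f"{pf.position_label}: empty support")
        prob *= max(nonzero) if mode == "most_common" else min(nonzero)
    return prob


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures."""
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def clones_per_occurrence(design: CdrDesign, mode: str = "most_common") -> float:
    """'1 in N' rarity of the extreme clone, N to 3 significant figures."""
    return round_sig(1.0 / extreme_probability(design, mode), 3)


def combined_rarity(n2: float, n3: float) -> float:
    """Clones-per-occurrence of a joint CDR2+CDR3 combination.

    Assumes the two cassettes assort independently (they are ligated in
    separate steps), so the joint rarity is the product, reported to
    3 significant figures.
    """
    if n2 < 1 or n3 < 1:
        raise ValueError("clones-per-occurrence must be >= 1")
    return round_sig(n2 * n3, 3)


@dataclass(frozen=True)
class TrimerOligoSpec:
    """Synthesis sheet for a trimer-randomized cassette oligo.

    One codon per allowed amino acid at each randomized position, with
    mixing fractions mirroring the design frequencies; constant flanking
    DNA carries the cassette restriction sites verbatim.
    """

    design_name: str
    positions: tuple[tuple[str, tuple[tuple[str, float], ...]], ...]
    left_flank_dna: str
    right_flank_dna: str
    codon_by_aa: dict[str, str] = field(default_factory=dict)

    def realizable_codons(self, index: int) -> tuple[str, ...]:
        return tuple(codon for codon, _ in self.positions[index][1])

    def to_json(self) -> str:
        payload = {
            "design": self.design_name,
            "left_flank_dna": self.left_flank_dna,
            "right_flank_dna": self.right_flank_dna,
            "positions": [
                {"label": label, "trimers": [
                    {"codon": codon, "fraction": frac} for codon, frac in trimers
                ]}
                for label, trimers in self.positions
            ],
        }
        return json.dumps(payload, indent=2)

    def synthesis_sheet(self) -> str:
        lines = [f"# trimer synthesis sheet for {self.design_name}",
                 f"5' constant: {self.left_flank_dna}"]
        for label, trimers in self.positions:
            mix = ", ".join(f"{codon} {frac:.3f}" for codon, frac in trimers)
            lines.append(f"{label}: {mix}")
        lines.append(f"3' constant: {self.right_flank_dna}")
        return "\n".join(lines)


def compile_oligo_spec(
    design: CdrDesign,
    codon_choice: CodonTable | None = None,
    left_flank_dna: str = "",
    right_flank_dna: str = "",
    required_sites: tuple[str, ...] = (),
) -> TrimerOligoSpec:
    """Compile a design into a trimer oligo specification.

    The codon for each amino acid is the table's highest-usage codon
    (deterministic single-codon design). Stop codons can never appear:
    trimers are sense codons and the fixed flanks are validated. Each
    ``required_sites`` recognition string must occur verbatim in a flank.
    """
    problems = validate_design(design)
    if problems:
        raise ValueError(
            "design is invalid: " + "; ".join(v.message for v in problems)
        )
    table = codon_choice or CodonTable.ecoli()
    codon_by_aa = {aa: table.preferred_codon(aa) for aa in AMINO_ACIDS}
    for aa, codon in codon_by_aa.items():
        if codon in STOP_CODONS:
            raise ValueError(f"codon table maps {aa} to stop codon {codon}")
    left, right = left_flank_dna.upper(), right_flank_dna.upper()
    for name, flank in (("left", left), ("right", right)):
        if len(flank) % 3:
            raise ValueError(f"{name} flank length must be a codon multiple")
        for i in range(0, len(flank), 3):
            if flank[i: i + 3] in STOP_CODONS:
                raise ValueError(
                    f"{name} flank carries stop codon {flank[i:i+3]} "
                    f"at nt {i + 1}"
                )
    for site in required_sites:
        if site.upper() not in left and site.upper() not in right:
            raise ValueError(f"required site {site} missing from flanks")
    positions = tuple(
        (pf.position_label,
         tuple((codon_by_aa[aa], pf.freq[aa]) for aa in pf.support))
        for pf in design.positions
    )
    return TrimerOligoSpec(design.name, positions, left, right, codon_by_aa)


def _pf(label: str, freq: dict[str, float]) -> PositionFrequency:
    return PositionFrequency(label, freq)


def default_cdr2_design() -> CdrDesign:
    """Illustrative CDR2 frequency table (4 randomized positions).

    Tyrosine/serine/glycine dominate (favourable binding contributions),
    hydrophobics stay at or under the 0.25 cap, and positively charged
    residues are absent. These numbers are an illustrative default, not a
    published table; supply your own via the io module to reproduce a
    specific design.
    """
    a = _pf("CDR2.1", {"Y": 0.20, "S": 0.20, "G": 0.15, "T": 0.10, "N": 0.10,
                       "D": 0.10, "V": 0.05, "L": 0.05, "F": 0.05})
    b = _pf("CDR2.2", {"S": 0.25, "G": 0.20, "Y": 0.15, "T": 0.10, "D": 0.10,
                       "E": 0.05, "W": 0.05, "V": 0.10})
    c = _pf("CDR2.3", {"Y": 0.25, "S": 0.15, "G": 0.15, "N": 0.10, "T": 0.10,
                       "Q": 0.05, "A": 0.05, "L": 0.10, "F": 0.05})
    d = _pf("CDR2.4", {"G": 0.25, "S": 0.20, "Y": 0.20, "D": 0.15, "T": 0.10,
                       "V": 0.05, "A": 0.05})
    return CdrDesign("CDR2", (a, b, c, d), fixed_flanks=("AIS", "STY"),
                     constraint_profile="cdr2")


def default_cdr3_design() -> CdrDesign:
    """Illustrative CDR3 frequency table (7 randomized of a 10-residue loop).

    Mimics functional-repertoire composition: Y/S/G-rich, no C/I/M/K,
    positives rare, alanine omitted at most positions, fixed FDY tail.
    Illustrative default, not a published table.
    """
    a = _pf("CDR3.1", {"Y": 0.18, "S": 0.16, "G": 0.16, "D": 0.12, "N": 0.08,
                       "T": 0.08, "E": 0.06, "Q": 0.04, "W": 0.03, "P": 0.04,
                       "V": 0.02, "L": 0.01, "F": 0.02})
    b = _pf("CDR3.2", {"G": 0.20, "S": 0.18, "Y": 0.14, "D": 0.10, "N": 0.08,
                       "T": 0.08, "E": 0.05, "Q": 0.04, "R": 0.02, "H": 0.02,
                       "P": 0.03, "W": 0.02, "V": 0.02, "L": 0.01, "F": 0.01})
    c = _pf("CDR3.3", {"Y": 0.18, "S": 0.16, "G": 0.14, "D": 0.12, "N": 0.08,
                       "T": 0.08, "E": 0.06, "Q": 0.04, "W": 0.03, "P": 0.04,
                       "A": 0.02, "V": 0.02, "L": 0.01, "F": 0.02})
    positions = (a, b, c,
                 _pf("CDR3.4", dict(a.freq)),
                 _pf("CDR3.5", dict(b.freq)),
                 _pf("CDR3.6", dict(a.freq)),
                 _pf("CDR3.7", dict(c.freq)))
    return CdrDesign("CDR3", positions, fixed_flanks=("", "FDY"),
                     constraint_profile="cdr3")
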