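"""Scaffold gene engineering.

Back-translation with codon-usage preferences, silent (synonymous)
insertion of restriction sites around CDR cassettes, and IUPAC-aware
site counting for vector-wide uniqueness audits.

Coordinates are 0-based half-open internally; human-readable reports are
1-based inclusive.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

from Bio.Data.IUPACData import ambiguous_dna_values
from Bio.Seq import Seq

from .codontab import CodonTable, SYNONYMS, STOP_SYMBOL, translate


class DesignError(ValueError):
    """Raised when a sequence-design request cannot be satisfied."""


def reverse_complement(dna: str) -> str:
    """Reverse complement, IUPAC-aware."""
    return str(Seq(dna).reverse_complement())


def iupac_regex(pattern: str) -> re.Pattern[str]:
    """Compile an IUPAC ambiguity pattern into a case-insensitive regex."""
    parts = []
    for ch in pattern.upper():
        try:
            values = ambiguous_dna_values[ch]
        except KeyError:
            raise ValueError(f"{ch!r} is not an IUPAC DNA code") from None
        parts.append(values if len(values) == 1 else f"[{values}]")
    return re.compile("".join(parts), re.IGNORECASE)


@dataclass(frozen=True)
class RestrictionSite:
    """A restriction enzyme's recognition sequence (IUPAC alphabet)."""

    enzyme_name: str
    recognition: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "recognition", self.recognition.upper())
        iupac_regex(self.recognition)  # validates alphabet

    @property
    def length(self) -> int:
        return len(self.recognition)

    @property
    def is_palindromic(self) -> bool:
        return reverse_complement(self.recognition) == self.recognition


# Recognition sequences for the enzymes used in the shipped scaffold plus a
# few common cloning enzymes; cross-checked against Bio.Restriction in tests.
BUILTIN_ENZYMES: dict[str, RestrictionSite] = {
    name: RestrictionSite(name, site)
    for name, site in [
        ("SacI", "GAGCTC"),
        ("XhoI", "CTCGAG"),
        ("PstI", "CTGCAG"),
        ("KpnI", "GGTACC"),
        ("SapI", "GCTCTTC"),
        ("Mva1269I", "GAATGC"),
        ("EcoRI", "GAATTC"),
        ("NcoI", "CCATGG"),
        ("NotI", "GCGGCCGC"),
        ("BamHI", "GGATCC"),
        ("HindIII", "AAGCTT"),
        ("XbaI", "TCTAGA"),
    ]
}


def get_enzyme(name: str) -> RestrictionSite:
    try:
        return BUILTIN_ENZYMES[name]
    except KeyError:
        raise KeyError(
            f"unknown enzyme {name!r}; known: {', '.join(sorted(BUILTIN_ENZYMES))}"
        ) from None


@dataclass(frozen=True)
class SitePlacement:
    """A synonymous edit that realises a recognition site at ``offset``."""

    offset: int
    substitutions: tuple[tuple[int, str, str], ...]  # (position, from, to)
    enzyme_name: str
    strand: str = "+"  # strand whose 5'->3' sequence matches the recognition

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    def describe(self) -> str:
        """1-based human-readable summary."""
        subs = ", ".join(f"{f}{p + 1}{t}" for p, f, t in self.substitutions) or "none"
        return (f"{self.enzyme_name} at {self.offset + 1} ({self.strand}); "
                f"substitutions: {subs}")


@dataclass(frozen=True)
class ScaffoldSpec:
    """Protein scaffold with framework/CDR tiling and cassette boundaries.

    ``regions`` are (label, start, end) half-open amino-acid intervals that
    must tile the protein exactly; ``cassette_boundaries`` pin each cassette
    enzyme to a nucleotide window (start, end) of any derived coding DNA.
    """

    protein_sequence: str
    regions: tuple[tuple[str, int, int], ...]
    cassette_boundaries: tuple[tuple[str, tuple[int, int]], ...] = ()

    def __post_init__(self) -> None:
        pos = 0
        for label, start, end in self.regions:
            if start != pos or end <= start:
                raise ValueError(
                    f"region {label} [{start},{end}) does not tile the protein"
                )
            pos = end
        if pos != len(self.protein_sequence):
            raise ValueError("regions do not cover the full protein")

    def region(self, label: str) -> tuple[int, int]:
        for lab, start, end in self.regions:
            if lab == label:
                return start, end
        raise KeyError(label)


def _motif_patterns(motifs: list[str]) -> list[re.Pattern[str]]:
    patterns = []
    for motif in motifs:
        patterns.append(iupac_regex(motif))
        rc = reverse_complement(motif)
        if rc != motif.upper():
            patterns.append(iupac_regex(rc))
    return patterns


def back_translate(
    protein: str,
    table: CodonTable | None = None,
    forbidden_motifs: list[str] | tuple[str, ...] = (),
) -> str:
    """Back-translate a protein deterministically, avoiding rare codons.

    Chooses the highest-usage non-rare codon at every residue; rare codons
    are considered only when every non-rare choice would create one of the
    ``forbidden_motifs`` (checked on both strands, IUPAC-aware). Depth-first
    search with backtracking keeps the choice deterministic.

    Raises
    ------
    DesignError
        If no codon assignment avoids the forbidden motifs; the message
        names the residue window where the search got stuck.
    """
    if not protein:
        raise ValueError("protein must be non-empty")
    protein = protein.upper()
    table = table or CodonTable.ecoli()
    for aa in protein:
        if aa == STOP_SYMBOL or aa not in SYNONYMS:
            raise ValueError(f"unexpected residue {aa!r}")
    patterns = _motif_patterns(list(forbidden_motifs))
    max_motif = max((len(m) for m in forbidden_motifs), default=0)

    def clean(prefix: str) -> bool:
        # A motif completed by the newest codon lies within the last
        # (max_motif + 2) characters; older completions were already vetoed.
        tail = prefix[max(0, len(prefix) - 2 - max_motif):]
        return not any(pat.search(tail) for pat in patterns)

    choices: list[list[str]] = []
    for aa in protein:
        ranked = table.codons_for(aa, include_rare=False)
        rare = [c for c in table.codons_for(aa) if c not in ranked]
        choices.append(ranked + rare)  # rare codons only as a last resort

    deepest_fail = 0

    def search(i: int, prefix: str) -> str | None:
        nonlocal deepest_fail
        if i == len(protein):
            return prefix
        for codon in choices[i]:
            candidate = prefix + codon
            if not patterns or clean(candidate):
                result = search(i + 1, candidate)
                if result is not None:
                    return result
        deepest_fail = max(deepest_fail, i)
        return None

    dna = search(0, "")
    if dna is None:
        lo = max(0, deepest_fail - 2)
        hi = min(len(protein), deepest_fail + 3)
        raise DesignError(
            "cannot satisfy motif constraints; blocked around residues "
            f"{lo + 1}-{hi} ({protein[lo:hi]})"
        )
    return dna


def count_site_occurrences(
    vector_dna: str, site: RestrictionSite, circular: bool = False
) -> int:
    """Count recognition-site matches on both strands (IUPAC-aware).

    A match on the reverse strand is reported at its forward-strand offset;
    palindromic sites therefore count once per offset. In circular mode the
    origin-spanning junction of length ``site.length - 1`` is also scanned.
    """
    if not vector_dna:
        raise ValueError("vector_dna must be non-empty")
    seq = vector_dna.upper()
    n, length = len(seq), site.length
    scan = seq + seq[: length - 1] if circular else seq
    limit = n if circular else n - length + 1
    fwd = iupac_regex(site.recognition)
    rc = iupac_regex(reverse_complement(site.recognition))
    hits = set()
    for off in range(max(0, limit)):
        window = scan[off: off + length]
        if len(window) < length:
            continue
        if fwd.fullmatch(window) or rc.fullmatch(window):
            hits.add(off)
    return len(hits)


def _codon_span(offset: int, length: int, frame: int, n: int) -> tuple[int, int]:
    """Indices [first, last) of codons overlapping [offset, offset+length)."""
    first = max(0, (offset - frame) // 3)
    last = min((n - frame) // 3, -(-(offset + length - frame) // 3))
    return first, last


def find_silent_site_placements(
    dna: str,
    protein_frame: int,
    site: RestrictionSite,
    window: tuple[int, int],
) -> list[SitePlacement]:
    """Enumerate synonymous edits creating ``site`` inside ``window``.

    For every candidate offset, all synonymous re-codings of the codons
    overlapping the recognition footprint are enumerated and those whose
    edited window matches the recognition pattern (either strand) are
    returned, sorted by (number of substitutions, offset). Bases outside
    the reading frame (before ``protein_frame`` or past the last complete
    codon) are immutable. Returns an empty list when no silent placement
    exists.
    """
    dna = dna.upper()
    start, end = window
    if not 0 <= start <= end <= len(dna):
        raise ValueError(f"window {window} outside sequence of length {len(dna)}")
    if end - start < site.length:
        raise DesignError(
            f"window {window} shorter than {site.enzyme_name} site ({site.length} nt)"
        )
    n_codons = (len(dna) - protein_frame) // 3
    coding = dna[protein_frame: protein_frame + 3 * n_codons]
    protein = translate(coding)
    if STOP_SYMBOL in protein:
        raise ValueError("dna contains an internal stop codon in the given frame")

    fwd = iupac_regex(site.recognition)
    rc_pattern = reverse_complement(site.recognition)
    rc = None if rc_pattern == site.recognition else iupac_regex(rc_pattern)

    found: dict[tuple[int, tuple[tuple[int, str, str], ...]], str] = {}
    for offset in range(start, end - site.length + 1):
        first, last = _codon_span(offset, site.length, protein_frame, len(dna))
        spans = [(protein_frame + 3 * c, SYNONYMS[protein[c]])
                 for c in range(first, last)]
        for combo in itertools.product(*(syns for _, syns in spans)):
            edited = list(dna)
            for (pos, _), codon in zip(spans, combo):
                edited[pos: pos + 3] = codon
            window_seq = "".join(edited[offset: offset + site.length])
            strand = None
            if fwd.fullmatch(window_seq):
                strand = "+"
            elif rc is not None and rc.fullmatch(window_seq):
                strand = "-"
            if strand is None:
                continue
            subs = tuple(
                (i, dna[i], b)
                for i, b in zip(range(len(dna)), edited)
                if dna[i] != b
            )
            key = (offset, subs)
            if key not in found:
                found[key] = strand
    placements = [
        SitePlacement(offset, subs, site.enzyme_name, strand)
        for (offset, subs), strand in found.items()
    ]
    placements.sort(key=lambda p: (p.n_substitutions, p.offset, p.substitutions))
    return placements


def apply_placement(dna: str, placement: SitePlacement) -> str:
    """Apply a placement's substitutions, verifying the from-bases."""
    dna = dna.upper()
    chars = list(dna)
    for pos, from_base, to_base in placement.substitutions:
        if chars[pos] != from_base.upper():
            raise DesignError(
                f"substitution at position {pos + 1} expects {from_base}, "
                f"sequence has {chars[pos]}"
            )
        chars[pos] = to_base.upper()
    return "".join(chars)
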