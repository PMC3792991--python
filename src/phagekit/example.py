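"""Shipped example scaffold and its cassette engineering.

The protein below is a SYNTHETIC, illustrative VH3-family-style domain
antibody: framework regions follow the common germline idiom with a few
residues chosen so that each cassette restriction site admits a silent
placement (E-L for SacI, L-E for XhoI, L-Q for PstI, G-T for KpnI), the
CDR1 carries the solubility-associated D/E/D acidic patch, and the CDR3
ends in the fixed F-D-Y tail. It is not any published antibody sequence.

``engineer_scaffold`` produces the full synthetic construct: a pelB
leader and SapI site upstream, the engineered coding sequence with four
silent cassette sites, and a myc tag plus Mva1269I site downstream —
then audits that all six enzymes are unique on the construct.
"""

from __future__ import annotations

from dataclasses import dataclass

from .codontab import CodonTable, translate
from .seqdesign import (
    DesignError,
    ScaffoldSpec,
    SitePlacement,
    apply_placement,
    back_translate,
    count_site_occurrences,
    find_silent_site_placements,
    get_enzyme,
)

FR1 = "EVQLLESGGGLVQPGGSLRLSCAAS"
CDR1 = "GFTFSDEDMS"
FR2 = "WVRQAPGKELEWVS"
CDR2 = "AISGSGGSTY"
FR3 = "LEDSVKGRFTISRDNSKNTLYLQMNSLRAEDTAVYYCAK"
CDR3 = "GSSYGSSFDY"
FR4 = "WGQGTLVTVSS"

EXAMPLE_PROTEIN = FR1 + CDR1 + FR2 + CDR2 + FR3 + CDR3 + FR4

PELB_LEADER = "MKYLLPTAAAGLLLLAAQPAMA"
MYC_TAG = "EQKLISEEDL"

#: The six enzymes engineered into / flanking the construct.
CASSETTE_ENZYMES = ("SapI", "SacI", "XhoI", "PstI", "KpnI", "Mva1269I")

#: Enzymes placed silently inside the coding sequence, with the
#: nucleotide window (codon-aligned, CDS coordinates) each may occupy.
SILENT_SITE_WINDOWS: tuple[tuple[str, tuple[int, int]], ...] = ()


def _regions() -> tuple[tuple[str, int, int], ...]:
    regions = []
    pos = 0
    for label, seq in (("FR1", FR1), ("CDR1", CDR1), ("FR2", FR2),
                       ("CDR2", CDR2), ("FR3", FR3), ("CDR3", CDR3),
                       ("FR4", FR4)):
        regions.append((label, pos, pos + len(seq)))
        pos += len(seq)
    return tuple(regions)


def _silent_windows() -> tuple[tuple[str, tuple[int, int]], ...]:
    spec_regions = dict((label, (start, end)) for label, start, end in _regions())

    def nt(aa_span: tuple[int, int]) -> tuple[int, int]:
        return (3 * aa_span[0], 3 * aa_span[1])

    fr2 = spec_regions["FR2"]
    fr3 = spec_regions["FR3"]
    fr4 = spec_regions["FR4"]
    return (
        ("SacI", nt(fr2)),                               # 5' of CDR2
        ("XhoI", nt((fr3[0], fr3[0] + 12))),             # 3' of CDR2
        ("PstI", nt((fr3[0] + 12, fr3[1]))),             # 5' of CDR3
        ("KpnI", nt(fr4)),                               # 3' of CDR3
    )


SILENT_SITE_WINDOWS = _silent_windows()


def example_scaffold_spec() -> ScaffoldSpec:
    return ScaffoldSpec(
        protein_sequence=EXAMPLE_PROTEIN,
        regions=_regions(),
        cassette_boundaries=SILENT_SITE_WINDOWS,
    )


@dataclass(frozen=True)
class EngineeredScaffold:
    """Result of cassette engineering on the example scaffold."""

    cds: str                               # engineered coding sequence
    construct: str                         # flank5 + cds + flank3
    placements: tuple[SitePlacement, ...]  # silent placements applied
    cds_offset: int                        # position of the CDS in construct

    def site_counts(self, circular: bool = False) -> dict[str, int]:
        return {
            name: count_site_occurrences(self.construct, get_enzyme(name),
                                         circular=circular)
            for name in CASSETTE_ENZYMES
        }


def engineer_scaffold(table: CodonTable | None = None) -> EngineeredScaffold:
    """Back-translate the example scaffold and place the cassette sites.

    The baseline back-translation forbids all six recognition sequences
    (both strands), so each site exists exactly once afterwards: four are
    introduced by minimal silent substitution inside their framework
    windows, two sit in the constant vector flanks.
    """
    table = table or CodonTable.ecoli()
    forbidden = [get_enzyme(name).recognition for name in CASSETTE_ENZYMES]

    cds = back_translate(EXAMPLE_PROTEIN, table, forbidden_motifs=forbidden)
    placements = []
    for enzyme_name, window in SILENT_SITE_WINDOWS:
        site = get_enzyme(enzyme_name)
        options = find_silent_site_placements(cds, 0, site, window)
        if not options:
            raise DesignError(
                f"no silent placement for {enzyme_name} in window {window}"
            )
        placement = options[0]  # fewest substitutions, lowest offset
        cds = apply_placement(cds, placement)
        placements.append(placement)
    if translate(cds) != EXAMPLE_PROTEIN:
        raise DesignError("engineering changed the protein sequence")

    pelb = back_translate(PELB_LEADER, table, forbidden_motifs=forbidden)
    myc = back_translate(MYC_TAG, table, forbidden_motifs=forbidden)
    flank5 = "AATT" + get_enzyme("SapI").recognition + "A" + pelb
    flank3 = myc + "T" + get_enzyme("Mva1269I").recognition + "ATTAA"
    construct = flank5 + cds + flank3

    engineered = EngineeredScaffold(
        cds=cds, construct=construct, placements=tuple(placements),
        cds_offset=len(flank5),
    )
    bad = {name: n for name, n in engineered.site_counts().items() if n != 1}
    if bad:
        raise DesignError(f"uniqueness audit failed: {bad}")
    return engineered
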