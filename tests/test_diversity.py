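"""Diversity-design tests: constraint validation, clone probabilities
against enumeration oracles, rarity arithmetic, and oligo compilation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phagekit.codontab import STOP_CODONS
from phagekit.diversity import (
    CdrDesign,
    PositionFrequency,
    clone_probability,
    clones_per_occurrence,
    combined_rarity,
    compile_oligo_spec,
    extreme_probability,
    round_sig,
    theoretical_diversity,
    validate_design,
)


def two_pos_design():
    return CdrDesign("toy", (
        PositionFrequency("P1", {"A": 0.5, "G": 0.5}),
        PositionFrequency("P2", {"Y": 0.9, "S": 0.1}),
    ))


def enumerate_support(design):
    supports = [pf.support for pf in design.positions]
    return ["".join(s) for s in itertools.product(*supports)]


@st.composite
def random_designs(draw, max_positions=3, max_support=5):
    n_pos = draw(st.integers(1, max_positions))
    positions = []
    for i in range(n_pos):
        k = draw(st.integers(1, max_support))
        residues = draw(st.permutations(list("ACDEFGHIKLMNPQRSTVWY")))[:k]
        raw = [draw(st.integers(1, 10)) for _ in range(k)]
        total = sum(raw)
        freq = {aa: r / total for aa, r in zip(residues, raw)}
        # repair float dust so the sum is exactly 1.0
        freq[residues[0]] += 1.0 - math.fsum(freq.values())
        positions.append(PositionFrequency(f"P{i}", freq))
    return CdrDesign("rand", tuple(positions))


class TestValidation:
    def test_shipped_defaults_are_valid(self, cdr2_design, cdr3_design):
        assert validate_design(cdr2_design) == []
        assert validate_design(cdr3_design) == []
        assert cdr2_design.loop_length == 10
        assert cdr3_design.loop_length == 10

    def test_cysteine_in_cdr3_is_flagged_with_position(self, cdr3_design):
        positions = list(cdr3_design.positions)
        bad = dict(positions[2].freq)
        top = max(bad, key=bad.get)
        bad[top] -= 0.05
        bad["C"] = 0.05
        positions[2] = PositionFrequency("CDR3.3", bad)
        design = CdrDesign("CDR3", tuple(positions),
                          cdr3_design.fixed_flanks, "cdr3")
        violations = validate_design(design)
        assert len(violations) == 1
        assert violations[0].rule == "cdr3_excluded_residue"
        assert violations[0].position == "CDR3.3"
        assert violations[0].value == pytest.approx(0.05)

    def test_hydrophobic_cap_violation_reports_value(self):
        design = CdrDesign("toy", (
            PositionFrequency("P1", {"V": 0.15, "L": 0.15, "Y": 0.70}),
        ))
        violations = validate_design(design)
        assert [v.rule for v in violations] == ["hydrophobic_cap"]
        assert violations[0].value == pytest.approx(0.30)

    def test_cdr2_profile_counts_positions_and_positives(self):
        design = CdrDesign("CDR2", (
            PositionFrequency("P1", {"K": 0.5, "S": 0.5}),
        ), constraint_profile="cdr2")
        rules = {v.rule for v in validate_design(design)}
        assert rules == {"cdr2_randomized_positions", "cdr2_no_positive"}

    def test_cdr3_profile_checks_loop_and_tail(self):
        design = CdrDesign("CDR3", tuple(
            PositionFrequency(f"P{i}", {"S": 1.0}) for i in range(7)
        ), fixed_flanks=("", "GDY"), constraint_profile="cdr3")
        rules = {v.rule for v in validate_design(design)}
        assert "cdr3_fdy_tail" in rules

    def test_stop_symbol_rejected_at_construction(self):
        with pytest.raises(ValueError, match="stop"):
            PositionFrequency("P1", {"*": 1.0})

    def test_unnormalized_frequencies_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            PositionFrequency("P1", {"A": 0.5, "G": 0.4})


class TestCloneProbability:
    def test_hand_product(self):
        design = two_pos_design()
        assert clone_probability(design, "AY") == pytest.approx(0.45)
        total = math.fsum(clone_probability(design, s)
                          for s in enumerate_support(design))
        assert total == pytest.approx(1.0, abs=1e-12)

    def test_excluded_residue_gives_zero(self, cdr3_design):
        assert clone_probability(cdr3_design, "CSSSSSS") == 0.0

    def test_single_certain_position(self):
        design = CdrDesign("w", (PositionFrequency("P1", {"W": 1.0}),))
        assert clone_probability(design, "W") == 1.0

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError, match="length"):
            clone_probability(two_pos_design(), "AYG")

    @given(design=random_designs())
    def test_normalization_over_support(self, design):
        total = math.fsum(clone_probability(design, s)
                          for s in enumerate_support(design))
        assert total == pytest.approx(1.0, abs=1e-9)


class TestDiversityCounts:
    def test_degenerate_and_product_rule(self):
        single = CdrDesign("s", (PositionFrequency("P1", {"W": 1.0}),))
        assert theoretical_diversity(single) == 1
        five = {aa: 0.2 for aa in "ASDFG"}
        design = CdrDesign("f", tuple(
            PositionFrequency(f"P{i}", dict(five)) for i in range(4)))
        assert theoretical_diversity(design) == 625

    @given(design=random_designs())
    def test_matches_enumeration_of_nonzero_sequences(self, design):
        support = [s for s in enumerate_support(design)
                   if clone_probability(design, s) > 0]
        assert theoretical_diversity(design) == len(support)


class TestExtremes:
    def test_enumeration_example(self):
        design = two_pos_design()
        probs = [clone_probability(design, s)
                 for s in enumerate_support(design)]
        assert extreme_probability(design, "most_common") == pytest.approx(max(probs))
        assert extreme_probability(design, "rarest") == pytest.approx(min(probs))
        assert extreme_probability(design, "most_common") == pytest.approx(0.45)
        assert extreme_probability(design, "rarest") == pytest.approx(0.05)

    def test_certain_position_both_modes(self):
        design = CdrDesign("w", (PositionFrequency("P1", {"W": 1.0}),))
        assert extreme_probability(design, "most_common") == 1.0
        assert extreme_probability(design, "rarest") == 1.0

    @given(design=random_designs())
    def test_order_and_coverage_bounds(self, design):
        hi = extreme_probability(design, "most_common")
        lo = extreme_probability(design, "rarest")
        assert hi >= lo > 0
        n = theoretical_diversity(design)
        assert hi * n >= 1.0 - 1e-12
        assert lo * n <= 1.0 + 1e-12

    def test_invalid_mode(self):
        with pytest.raises(ValueError):
            extreme_probability(two_pos_design(), "median")


class TestRarity:
    def test_combined_rarity_product(self):
        assert combined_rarity(1, 1) == 1
        assert combined_rarity(2, 3) == 6
        assert combined_rarity(334, 727_000) == pytest.approx(2.43e8)

    def test_rejects_sub_unit_rarity(self):
        with pytest.raises(ValueError):
            combined_rarity(0.5, 10)

    def test_clones_per_occurrence_rounding(self):
        design = two_pos_design()
        assert clones_per_occurrence(design, "most_common") == pytest.approx(
            round_sig(1 / 0.45, 3))

    def test_round_sig(self):
        assert round_sig(2.42814e8, 3) == 2.43e8
        assert round_sig(0.0, 3) == 0.0
        assert round_sig(6.17e7, 2) == 6.2e7


class TestOligoSpec:
    def test_single_residue_position_uses_top_codon(self, ecoli_table):
        design = CdrDesign("g", (PositionFrequency("P1", {"G": 1.0}),))
        spec = compile_oligo_spec(design, ecoli_table)
        assert spec.realizable_codons(0) == ("GGC",)

    def test_fractions_mirror_design(self, cdr3_design, ecoli_table):
        spec = compile_oligo_spec(cdr3_design, ecoli_table)
        for pf, (label, trimers) in zip(cdr3_design.positions, spec.positions):
            assert label == pf.position_label
            fractions = {codon: frac for codon, frac in trimers}
            assert math.fsum(fractions.values()) == pytest.approx(1.0)
            for aa in pf.support:
                assert fractions[spec.codon_by_aa[aa]] == pf.freq[aa]

    def test_no_stop_codons_realizable(self, cdr2_design, cdr3_design):
        for design in (cdr2_design, cdr3_design):
            spec = compile_oligo_spec(design)
            for i in range(len(spec.positions)):
                assert not set(spec.realizable_codons(i)) & set(STOP_CODONS)

    def test_flanks_must_carry_required_sites(self, cdr2_design):
        with pytest.raises(ValueError, match="required site"):
            compile_oligo_spec(cdr2_design, left_flank_dna="GAGCTC",
                               required_sites=("GGTACC",))
        spec = compile_oligo_spec(cdr2_design, left_flank_dna="GAGCTC",
                                  required_sites=("GAGCTC",))
        assert "GAGCTC" in spec.left_flank_dna

    def test_stop_codon_in_flank_rejected(self, cdr2_design):
        with pytest.raises(ValueError, match="stop"):
            compile_oligo_spec(cdr2_design, left_flank_dna="TAAGCA")

    def test_invalid_design_rejected(self):
        design = CdrDesign("bad", (
            PositionFrequency("P1", {"V": 0.3, "Y": 0.7}),
        ))
        with pytest.raises(ValueError, match="invalid"):
            compile_oligo_spec(design)

    def test_json_and_sheet_render(self, cdr2_design):
        spec = compile_oligo_spec(cdr2_design, left_flank_dna="GAGCTC",
                                  right_flank_dna="CTCGAG")
        assert "GAGCTC" in spec.to_json()
        assert "trimer synthesis sheet" in spec.synthesis_sheet()
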