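# phagekit

A toolkit for designing and quality-controlling synthetic single-domain
antibody (dAb) phage-display libraries. It is aimed at protein engineers
building trimer-randomized CDR libraries on a fixed framework, and at
anyone who wants to sanity-check the numbers such a project produces:
what the rarest designed clone costs in transformants, how sequencing QC
corrects a library-size estimate, what a trypsin-protection titer says
about display level, and whether a melt curve or an ITC isotherm
supports the stability and affinity being claimed.

The toolkit covers five stages:

1. **Scaffold gene engineering** (`phagekit.seqdesign`) — deterministic
   back-translation with codon-usage preferences (rare codons avoided),
   insertion of unique restriction sites by synonymous substitution
   around the CDR cassettes, and IUPAC-aware, both-strand,
   circular-aware site counting for vector-wide uniqueness audits.
2. **CDR diversity design** (`phagekit.diversity`) — per-position
   amino-acid frequency tables for trinucleotide ("trimer")
   randomization, validated against compositional rules (hydrophobic
   frequency ≤ 25% per position; 4 randomized CDR2 positions with no
   K/R/H; 7 of 10 CDR3 positions with fixed FDY tail and no C/I/M/K),
   compiled into stop-free oligo specifications with one codon per
   amino acid.
3. **Library statistics** (`phagekit.libstats`) — clone probabilities
   p(s) = Π_i p_i(s_i), theoretical diversity Π_i |support_i|, expected
   coverage Σ_c count_c (1 − (1 − p_c)^n), the QC-corrected functional
   size N·(n_good + n_double)/n_sampled, display level from
   trypsin-protected titers, and absorbance-based phage titer.
4. **Construction simulation** (`phagekit.simlib`) — a seeded stand-in
   for the wet lab: multinomial clone sampling, frameshift errors
   confined to a hotspot, double-transformation events, QC sequencing,
   trypsin filtering, and one-round panning enrichment
   f_i → f_i w_i / Σ_j f_j w_j.
5. **Biophysical fits** (`phagekit.biophys`) — four-parameter logistic
   melts (Tm at the inflection; refolding from amplitude ratios) and the
   1:1 ITC isotherm (K_D, ΔH, and the stoichiometry×active-fraction
   product) with multi-start bounded least squares, plus synthetic-data
   generators for parameter-recovery testing.

See `docs/methods.md` for the models, defaults and their rationale.

## Worked example

```python
from phagekit.diversity import (default_cdr2_design, default_cdr3_design,
                                clones_per_occurrence, combined_rarity,
                                theoretical_diversity)
from phagekit.libstats import QcSummary, functional_size
from phagekit.example import engineer_scaffold
from phagekit.biophys import synthetic_itc_series, fit_itc

d2, d3 = default_cdr2_design(), default_cdr3_design()
print(clones_per_occurrence(d2), clones_per_occurrence(d3),
      combined_rarity(clones_per_occurrence(d2), clones_per_occurrence(d3)))
# 320.0 132000.0 42200000.0
```

With the shipped illustrative frequency tables, the most common CDR2
combination appears once per 320 clones and the most common CDR3
combination once per 132,000; assuming the two cassettes assort
independently, their most common joint combination appears once per
4.22×10⁷ clones. (These numbers are properties of the shipped default
tables; load your own tables with `phagekit.io.load_frequency_csv` to
audit a real design — the published numbers for any given library
follow from its own table.)

```python
print(functional_size(7.8e7, QcSummary(24, 14, 5, 8, 2)))
# 62000000.0
```

A library titered at 7.8×10⁷ transformants, with 24 colonies sequenced
of which 14 read correctly (5 of them double reads, i.e. colonies
carrying two correct plasmids), 8 frameshifted and 2 failed, has a
functional size of 6.2×10⁷.

```python
eng = engineer_scaffold()
print(eng.placements[0].describe())
# SacI at 130 (+); substitutions: A132G, G135C
print(eng.site_counts())
# {'SapI': 1, 'SacI': 1, 'XhoI': 1, 'PstI': 1, 'KpnI': 1, 'Mva1269I': 1}
```

Cassette engineering on the example scaffold places SacI by two silent
substitutions in FR2 (positions are 1-based), and the uniqueness audit
confirms each of the six enzymes cuts the full construct exactly once.

```python
fit = fit_itc(synthetic_itc_series(kd=5e-6, n_active=0.77, seed=11))
print(f"KD = {fit.kd*1e6:.2f} uM, n_active = {fit.n_active:.3f}")
# KD = 5.77 uM, n_active = 0.737
```

Fitting a synthetic 19-injection isotherm generated at K_D = 5 µM with
77% active binder recovers both parameters within the precision a c ≈ 5
titration supports.

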