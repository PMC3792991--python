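# Methods

`phagekit` models the computational side of building a synthetic
single-domain-antibody (dAb) phage-display library: engineering the
scaffold gene, designing the CDR randomization, predicting library-scale
statistics, simulating the construction and QC, and fitting the two
standard characterization experiments (CD thermal melts, ITC binding
isotherms). This note records the models, the defaults and why they were
chosen, and what the synthetic data do and do not establish.

## Scaffold gene engineering (`seqdesign`)

**Back-translation.** Codon choice is deterministic: the highest-usage
codon of the target expression host (built-in *E. coli* K-12 table,
within-amino-acid fractions; user tables via TSV). Codons whose fraction
falls below `rare_threshold` (default 0.10, strict `<`) are avoided; a
depth-first search with backtracking admits them only when every
non-rare choice would create a forbidden motif. Forbidden motifs are
IUPAC-aware and checked on both strands. An unsatisfiable constraint set
raises with the residue window where the search got stuck, rather than
silently emitting a motif.

**Silent restriction sites.** A placement search scans every offset of a
window, enumerates all synonymous re-codings of the codons overlapping
the recognition footprint (at most ~6^4 combinations for a 6–8 nt
site), and keeps those whose edited window matches the recognition
pattern on either strand. Placements are returned sorted by
(substitution count, offset); ties therefore resolve to the lowest
offset, which keeps designs reproducible. Because only footprint-
overlapping codons are re-coded, returned placements never carry
gratuitous edits. The same enumeration run globally over a whole window
serves as the independent oracle in the test suite.

**Counting and uniqueness.** Site counting is IUPAC-aware on both
strands, reports reverse-strand hits at their forward offset (so
palindromes count once per offset), and in circular mode also scans the
origin-spanning junction of length `len(site) − 1`.

**The shipped example scaffold** is a synthetic, illustrative VH3-style
dAb sequence (119 aa; FR1–CDR1–FR2–CDR2–FR3–CDR3–FR4). It is not a
published antibody. Framework residues were chosen so each cassette
enzyme has a dipeptide that admits a silent site (E-L → SacI GAGCTC,
L-E → XhoI CTCGAG, L-Q → PstI CTGCAG, G-T → KpnI GGTACC); the CDR3 ends
in the fixed F-D-Y tail. `engineer_scaffold` first back-translates with
all six recognition sequences forbidden, then introduces the four
cassette sites by minimal silent substitution, and finally places SapI
and Mva1269I as constant sites in the synthetic vector flanks (pelB
leader upstream, myc tag downstream) — mirroring the common practice of
cloning the whole gene between two terminal sites. The audit that every
enzyme occurs exactly once on the full construct is re-run on every
call and in the acceptance suite.

## CDR diversity (`diversity`)

A cassette design is an ordered list of per-position amino-acid
frequency tables plus fixed flanking residues. Validation enforces the
compositional rules of the library concept: summed frequency of
{V, I, L, M, F} ≤ 0.25 at every randomized position; CDR2 cassettes
randomize exactly 4 positions with no K/R/H; CDR3 cassettes randomize 7
positions of a 10-residue loop ending in F-D-Y, with C, I, M and K
excluded. Frequencies must sum to 1 (±1e-9) and stops are rejected at
construction.

The numeric content of any particular published frequency table is
treated as user input (CSV/JSON). The shipped defaults are illustrative
tables that satisfy every rule — Y/S/G-rich, positives absent (CDR2) or
at 2% (CDR3), alanine omitted at most CDR3 positions — and exist so the
pipeline runs end to end; they are not a transcription of any published
design.

Clone statistics follow from per-position independence (that is what
trimer synthesis buys): a clone's probability is the product of its
per-position frequencies; theoretical diversity is the product of
support sizes; the most-common/rarest clone probability is the product
of per-position maxima/nonzero minima. "1 in N" rarities are reported
to 3 significant figures, and the joint CDR2×CDR3 rarity multiplies the
two cassette rarities under the assumption that the two ligation steps
assort independently.

**Trimer oligo compilation** assigns one codon per amino acid (the
table's top codon — single-codon design minimizes DNA-level differences
between clones), mirrors the design frequencies as mixing fractions,
and embeds the cassette restriction sites in the constant flanks. Since
every trimer is a sense codon and flanks are screened, no realizable
insert can contain a stop codon (including amber TAG); the acceptance
suite verifies this on 10^5 sampled clones.

## Library statistics (`libstats`)

* **Coverage.** For clone classes (p_c, count_c) with Σ p_c·count_c = 1,
  the expected number of distinct clones among n draws is
  Σ count_c (1 − (1 − p_c)^n); the Poisson form Σ count_c (1 − e^{−n p_c})
  is reported alongside (they agree within 1% when max n·p_c ≤ 0.01).
  Computed with `log1p`/`expm1` to stay accurate in the sparse regime.
* **Functional size.** QC sequencing of n_sampled colonies yields n_good
  correct clones of which n_double show two superimposed clean reads
  (double-transformed colonies carrying two distinct correct plasmids);
  frameshifted and failed reads are non-functional. The corrected size
  is `estimated_size × (n_good + n_double) / n_sampled`, reported to 2
  significant figures: each double colony contributes two functional
  clones but was counted as one transformant. Sequencing failures are
  not discounted separately; with 24 sampled, 14 good and 5 doubles this
  reproduces the 7.8×10⁷ → 6.2×10⁷ correction.
* **Display level** is the trypsin-resistant fraction of the infective
  titer, cfu_trypsin / cfu_untreated: with KM13 helper packaging, only
  helper-derived pIII is trypsin-cleavable, so trypsin-surviving
  infectivity marks antibody-displaying particles.
* **Titer from absorbance**: (A269 − A320) × 6×10¹⁶ / genome_length
  virions/mL, the standard spectrophotometric constant (configurable).

## Construction simulator (`simlib`)

The simulator stands in for all wet-lab steps. Clones are drawn
per-position multinomially from the designs. Each clone founds a colony
that is frameshifted with probability f (a single-nucleotide indel
placed uniformly inside a declared hotspot window, emulating error
clustering near the reverse-primer annealing site), else
double-transformed with probability d (a second plasmid drawn uniformly
from the pool), else clean. QC picks uniformly without replacement and
applies an independent sequencing-failure rate; doubles are reported as
good-with-double-read, matching how trace data are read. Trypsin
filtering removes frameshifted colonies (no functional pIII fusion) and
keeps the rest. One panning round multiplies each clone frequency by
its capture weight (plus an optional nonspecific background) and
renormalizes; the stochastic version draws the eluted pool
multinomially. Rates default to the observed QC proportions (f = 8/24;
d = 5/19 among correct clones) but are configuration, since a single
24-colony sample only loosely constrains them. All randomness flows
from one root seed through `numpy.random.SeedSequence` spawning, so
whole-pipeline runs are bit-reproducible across platforms.

A deliberate simplification: frameshift indels are placed uniformly in
the hotspot and do not otherwise alter the clone sequence; real error
spectra (repeat slippage at TATTAT-like motifs) are not modelled beyond
the window confinement.

## Thermal melts (`biophys`)

Unfolding monitored by CD at 235 nm is fitted with a four-parameter
logistic, s(T) = post + (pre − post)/(1 + exp((T − Tm)/b)); Tm is the
inflection point. Sloped baselines are deliberately omitted from the
default model (the simplest sigmoid family consistent with the data the
generator produces); the fit is seeded from data quantiles and refuses
curves whose apparent amplitude is within ~3× the point-to-point noise
("no transition"). Because the 4PL family is closed under affine signal
maps, Tm is invariant to signal rescaling (asserted to 1e-6 °C).
Refolding is quantified as the ratio of second-ramp to first-ramp
transition amplitude; 1.0 means the two heating curves overlap.

The synthetic generator produces 25–85 °C ramps at 0.5 °C spacing with
Gaussian noise of 1% of the transition amplitude. Under these
conditions the fitted Tm lands within 0.5 °C of truth on every one of
100 seeds (the acceptance suite uses truth 45.9 °C, the least stable
clone regime of interest). Real melts add irreversible aggregation,
drifting baselines and ramp-rate effects that these synthetic curves do
not contain, so recovery here demonstrates the estimator, not the
instrument.

## ITC 1:1 isotherm (`biophys`)

Totals in the cell follow a perfusion model: an injection of volume v
into the fixed cell volume V₀ scales existing totals by (1 − v/V₀) and
adds titrant at syringe_conc·v/V₀. Bound complex solves 1:1 mass action,
B² − (M + X + K_D)B + MX = 0, taken as the smaller root in the
cancellation-free quotient form; a bracketed root search on the
mass-action residual serves as the independent oracle (agreement to
1e-10 relative everywhere tested). The heat of injection k is
ΔH·V₀·(B_k − B_{k−1}(1 − v_k/V₀)): complex displaced by the injection
leaves the cell before re-equilibration.

Stoichiometry n and active fraction are not separately identifiable
from one isotherm — both scale the binding-competent cell
concentration — so the fit estimates their product `n_active` (with 1:1
stoichiometry it reads directly as the active fraction). Fitting is
bounded least squares over (log₁₀ K_D, n_active, ΔH) with 5 log-spaced
K_D starts, tolerances 1e-12; a K_D pinned at a bound raises, and a
schedule whose total titrant cannot reach the cell's binding capacity
only flags `low_information`. Standard errors come from the Jacobian at
the optimum.

The generator's default schedule is a micro-calorimeter run matched to
a weak (~5 µM) dAb/antigen pair: 24.6 µM binder in a 200 µL cell, 19 ×
4 µL injections of 350 µM titrant (c ≈ 5). Published descriptions of
such experiments sometimes transpose the two concentrations; with the
roles as stated here the titration saturates and the fit is
well-posed, and the fitting code itself is role-agnostic. Two noise
models are available: "peak" (default; sd = 2% of the largest heat,
emulating baseline-integration scatter) and "relative" (2% per-peak
proportional error). At c ≈ 5 and 2% peak noise the median recovery
error over 100 seeds is ~10% on K_D and ~4% on n_active; individual
seeds can exceed 15% on K_D, which is inherent to the information
content of a c ≈ 5 isotherm, so recovery guarantees are stated as
medians. Across the design space (K_D 0.5–50 µM, c 1–500) the median
|log(K_D ratio)| stays below 0.15 under the proportional model; under
peak noise the extreme-c corners are harder because the few transition
injections carry all the K_D information.

## Problem sizes

Default test and acceptance runs use: 10⁵ sampled clones for marginal-
frequency and stop-codon checks, 10⁴ Monte-Carlo replicates for
coverage, 100 seeds for each parameter-recovery suite, and exhaustive
enumeration oracles on ≤4-codon windows and ≤6-position designs. These
sizes make every Monte-Carlo bound a ≥3σ comparison while keeping a
full run in the tens of seconds.

## Known limitations

* The silent-site search edits only codons overlapping the recognition
  footprint; it will not find placements that require re-coding a
  neighbouring codon merely to license a different synonymous choice
  (no such case exists for the shipped enzymes).
* Coverage statistics assume independent draws from a fixed clone
  distribution; ligation bias and growth competition are out of scope.
* The panning model is a single multiplicative capture weight per
  clone; avidity, washing kinetics and elution efficiency are not
  modelled, and no claim is made about reproducing any particular
  selection outcome.
* The ITC model assumes a single site class and instantaneous mixing;
  titrant dimerization or active-fraction drift during the run are not
  represented.
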