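"""Library-scale statistics.

Coverage of clone classes at a given transformant count, correction of
the library size for non-functional clones found in QC sequencing,
display-level estimation from trypsin-protection titers, and the
absorbance-based phage titer.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .diversity import round_sig


@dataclass(frozen=True)
class QcSummary:
    """Counts of sequenced clones by category.

    ``n_double`` counts the subset of good clones whose trace shows two
    superimposed clean reads (a colony co-transformed with two plasmids);
    it is not a separate category, so ``n_good + n_frameshift + n_failed``
    must equal ``n_sampled``.
    """

    n_sampled: int
    n_good: int
    n_double: int
    n_frameshift: int
    n_failed: int

    def __post_init__(self) -> None:
        counts = (self.n_sampled, self.n_good, self.n_double,
                  self.n_frameshift, self.n_failed)
        if any(c < 0 for c in counts):
            raise ValueError("counts must be non-negative")
        if self.n_good + self.n_frameshift + self.n_failed != self.n_sampled:
            raise ValueError(
                f"good ({self.n_good}) + frameshift ({self.n_frameshift}) + "
                f"failed ({self.n_failed}) != sampled ({self.n_sampled})"
            )
        if self.n_double > self.n_good:
            raise ValueError("double reads cannot exceed good clones")


@dataclass(frozen=True)
class TiterPair:
    """Matched CFU counts (same dilution) with and without trypsin."""

    cfu_untreated: float
    cfu_trypsin: float

    def __post_init__(self) -> None:
        if self.cfu_untreated < 0 or self.cfu_trypsin < 0:
            raise ValueError("CFU counts must be non-negative")
        if self.cfu_trypsin > self.cfu_untreated:
            warnings.warn(
                "trypsin-treated CFU exceeds untreated CFU; check the dilutions",
                stacklevel=2,
            )


def expected_copies(p: float, n_transformants: float) -> float:
    """Expected copies of a clone with probability ``p`` among ``n`` draws."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if n_transformants < 0:
        raise ValueError("n_transformants must be >= 0")
    return p * n_transformants


@dataclass(frozen=True)
class CoverageEstimate:
    """Expected number of distinct clones among ``n_draws`` transformants."""

    exact: float      # sum count_c * (1 - (1 - p_c)^n)
    poisson: float    # sum count_c * (1 - exp(-n p_c))
    n_draws: int
    total_clones: float


def expected_distinct(
    prob_classes: list[tuple[float, float]], n_draws: int
) -> CoverageEstimate:
    """Expected distinct clones after ``n_draws`` independent draws.

    ``prob_classes`` lists ``(probability, clone_count)`` pairs: each of
    ``clone_count`` clones is drawn with the given per-draw probability.
    The class probabilities must account for the whole distribution
    (sum of p * count = 1, tolerance 1e-6). Both the exact binomial form
    and the Poisson approximation are reported.
    """
    if n_draws < 0:
        raise ValueError("n_draws must be >= 0")
    p = np.asarray([pc[0] for pc in prob_classes], dtype=float)
    counts = np.asarray([pc[1] for pc in prob_classes], dtype=float)
    if np.any(p < 0) or np.any(p > 1) or np.any(counts < 0):
        raise ValueError("probabilities must be in [0,1], counts >= 0")
    total_mass = float(np.sum(p * counts))
    if abs(total_mass - 1.0) > 1e-6:
        raise ValueError(
            f"class probabilities sum to {total_mass!r}, expected 1 +/- 1e-6"
        )
    if n_draws == 0:
        return CoverageEstimate(0.0, 0.0, 0, float(np.sum(counts)))
    # expm1/log1p keep precision in the n*p << 1 regime
    with np.errstate(divide="ignore"):
        log_miss = n_draws * np.log1p(-p)  # -inf when p == 1
    exact = float(np.sum(counts * -np.expm1(log_miss)))
    poisson = float(np.sum(counts * -np.expm1(-n_draws * p)))
    return CoverageEstimate(exact, poisson, n_draws, float(np.sum(counts)))


def functional_size(estimated_size: float, qc: QcSummary) -> float:
    """Library size corrected for non-functional clones seen in QC.

    Each double-read colony is counted as two distinct correct plasmids
    (one colony on the plate, two functional clones in the library), while
    frameshifted and failed clones drop out of the functional count:

        functional = estimated_size * (n_good + n_double) / n_sampled

    reported to 2 significant figures.
    """
    if estimated_size <= 0:
        raise ValueError("estimated_size must be positive")
    if qc.n_sampled == 0:
        raise ValueError("QC sample is empty")
    return round_sig(estimated_size * (qc.n_good + qc.n_double) / qc.n_sampled, 2)


def display_level(t: TiterPair) -> float:
    """Fraction of phage particles displaying antibody.

    With KM13 packaging, helper-derived pIII is trypsin-cleavable while the
    antibody-pIII fusion is not, so the trypsin-resistant fraction of the
    infective titer estimates the displaying fraction.
    """
    if t.cfu_untreated <= 0:
        raise ValueError("untreated CFU must be positive")
    return t.cfu_trypsin / t.cfu_untreated


#: Virions/mL per absorbance unit and per nucleotide of genome, from the
#: standard spectrophotometric phage-quantification protocol.
TITER_CONSTANT = 6.0e16


def titer_from_absorbance(
    a269: float, a320: float, genome_length: float,
    constant: float = TITER_CONSTANT,
) -> float:
    """Phage particles per mL from A269/A320 and the ssDNA genome length.

    titer = (A269 - A320) * constant / genome_length. A negative
    difference (scatter exceeding signal) warns and floors at zero.
    """
    if genome_length <= 0:
        raise ValueError("genome_length must be positive")
    diff = a269 - a320
    if diff < 0:
        warnings.warn("A269 < A320; flooring titer at zero", stacklevel=2)
        return 0.0
    return diff * constant / genome_length
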