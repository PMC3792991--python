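"""Seeded stochastic simulator of library construction and selection.

Synthetic stand-in for the wet-lab pipeline: clone sampling from CDR
frequency designs, colony formation with frameshift errors confined to a
declared hotspot and occasional double-transformation events, QC
sequencing of a picked subset, trypsin filtering of non-displaying
(frameshifted) clones, and one-round panning enrichment.

Every operation takes an explicit seed (or Generator); a root seed is
expanded into independent per-stage streams with ``numpy``'s
``SeedSequence`` spawning, so whole-pipeline runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .diversity import CdrDesign
from .libstats import QcSummary

GOOD, FRAMESHIFT, DOUBLE = "good", "frameshift", "double"


def rng_from(seed: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def spawn_streams(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one root seed."""
    return [np.random.default_rng(child)
            for child in np.random.SeedSequence(seed).spawn(n)]


@dataclass(frozen=True)
class CloneSequence:
    """Residues drawn at the randomized positions of both cassettes."""

    cdr2: str
    cdr3: str

    def key(self) -> str:
        return f"{self.cdr2}|{self.cdr3}"


@dataclass(frozen=True)
class SyntheticColony:
    """One transformant colony from a simulated construction run."""

    plasmids: tuple[CloneSequence, ...]  # 1, or 2 when category == double
    category: str
    frameshift_position: int | None = None

    def __post_init__(self) -> None:
        if self.category not in (GOOD, FRAMESHIFT, DOUBLE):
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == DOUBLE) != (len(self.plasmids) == 2):
            raise ValueError("double colonies carry exactly two plasmids")
        if (self.category == FRAMESHIFT) != (self.frameshift_position is not None):
            raise ValueError("frameshift_position set iff category is frameshift")

    def propagated_plasmid(self, rng: np.random.Generator) -> CloneSequence:
        """Plasmid surviving single-colony propagation (uniform for doubles)."""
        if self.category == DOUBLE:
            return self.plasmids[int(rng.integers(2))]
        return self.plasmids[0]


def _sample_positions(design: CdrDesign, n: int,
                      rng: np.random.Generator) -> list[str]:
    cols = []
    for pf in design.positions:
        support = list(pf.support)
        probs = np.asarray([pf.freq[aa] for aa in support])
        probs = probs / probs.sum()  # remove float dust; sums to 1 by design
        cols.append(rng.choice(support, size=n, p=probs))
    return ["".join(row) for row in zip(*cols)]


def sample_library(
    design2: CdrDesign, design3: CdrDesign, n: int,
    seed: int | np.random.Generator | None,
) -> list[CloneSequence]:
    """Draw ``n`` clones, each position independently multinomial."""
    rng = rng_from(seed)
    cdr2 = _sample_positions(design2, n, rng)
    cdr3 = _sample_positions(design3, n, rng)
    return [CloneSequence(a, b) for a, b in zip(cdr2, cdr3)]


def simulate_construction(
    clones: Sequence[CloneSequence],
    double_rate: float,
    frameshift_rate: float,
    hotspot: tuple[int, int],
    seed: int | np.random.Generator | None,
) -> list[SyntheticColony]:
    """Turn sampled clones into colonies with construction errors.

    Each clone founds one colony: with probability ``frameshift_rate`` the
    insert carries a single-nucleotide indel placed uniformly inside the
    ``hotspot`` window (the error-prone stretch near the reverse-primer
    annealing site); otherwise, with probability ``double_rate``, the
    colony was co-transformed and carries a second, independently chosen
    plasmid from the pool.
    """
    for name, rate in (("double_rate", double_rate),
                       ("frameshift_rate", frameshift_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    lo, hi = hotspot
    if frameshift_rate > 0 and hi <= lo:
        raise ValueError("empty hotspot with nonzero frameshift_rate")
    rng = rng_from(seed)
    colonies = []
    n = len(clones)
    for i, clone in enumerate(clones):
        u = rng.random()
        if u < frameshift_rate:
            pos = int(rng.integers(lo, hi))
            colonies.append(SyntheticColony((clone,), FRAMESHIFT, pos))
        elif u < frameshift_rate + (1 - frameshift_rate) * double_rate:
            partner = clones[int(rng.integers(n))]
            colonies.append(SyntheticColony((clone, partner), DOUBLE))
        else:
            colonies.append(SyntheticColony((clone,), GOOD))
    return colonies


def simulate_qc(
    colonies: Sequence[SyntheticColony],
    n_picked: int,
    fail_rate: float,
    seed: int | np.random.Generator | None,
) -> QcSummary:
    """Sequence a uniform without-replacement pick of colonies.

    Sequencing fails independently with ``fail_rate``; surviving reads
    report frameshifted colonies as frameshifts and double colonies as
    good clones with a double read.
    """
    if n_picked > len(colonies):
        raise ValueError("cannot pick more colonies than exist")
    if not 0.0 <= fail_rate <= 1.0:
        raise ValueError("fail_rate must be in [0, 1]")
    rng = rng_from(seed)
    picked = rng.choice(len(colonies), size=n_picked, replace=False)
    n_good = n_double = n_frameshift = n_failed = 0
    for idx in picked:
        if rng.random() < fail_rate:
            n_failed += 1
            continue
        colony = colonies[int(idx)]
        if colony.category == FRAMESHIFT:
            n_frameshift += 1
        else:
            n_good += 1
            if colony.category == DOUBLE:
                n_double += 1
    return QcSummary(n_picked, n_good, n_double, n_frameshift, n_failed)


def trypsin_filter(
    colonies: Sequence[SyntheticColony],
) -> list[SyntheticColony]:
    """Remove frameshifted colonies (no functional pIII fusion survives
    trypsin elution with KM13 packaging); good and double colonies pass."""
    return [c for c in colonies if c.category != FRAMESHIFT]


@dataclass(frozen=True)
class PanningModel:
    """Per-clone capture weights for panning rounds.

    ``background`` is an elution background added to every weight
    (nonspecifically carried-over phage); at least one effective weight
    must be positive.
    """

    capture_weights: tuple[float, ...]
    rounds: int = 1
    background: float = 0.0

    def __post_init__(self) -> None:
        w = np.asarray(self.capture_weights, dtype=float)
        if np.any(w < 0) or self.background < 0:
            raise ValueError("weights must be non-negative")
        if not np.any(w + self.background > 0):
            raise ValueError("at least one effective weight must be positive")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")

    def effective(self) -> np.ndarray:
        return np.asarray(self.capture_weights) + self.background


def expected_panning(frequencies: Sequence[float],
                     model: PanningModel) -> np.ndarray:
    """Deterministic expectation: each round multiplies frequency i by
    w_i and renormalises, so enrichment of clone i is w_i / sum_j f_j w_j."""
    f = np.asarray(frequencies, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be normalized")
    w = model.effective()
    if len(w) != len(f):
        raise ValueError("weights and frequencies differ in length")
    for _ in range(model.rounds):
        mass = float(np.sum(f * w))
        if mass <= 0:
            raise ValueError("all clones with nonzero frequency have zero weight")
        f = f * w / mass
    return f


def simulate_panning(
    frequencies: Sequence[float],
    model: PanningModel,
    seed: int | np.random.Generator | None,
    pool_size: int = 10_000,
) -> np.ndarray:
    """Stochastic panning: per round, the eluted pool of ``pool_size``
    phage is drawn multinomially from the expected post-selection
    distribution; returns the final empirical frequencies."""
    rng = rng_from(seed)
    f = np.asarray(frequencies, dtype=float)
    if abs(f.sum() - 1.0) > 1e-6:
        raise ValueError("frequencies must be normalized")
    w = model.effective()
    if len(w) != len(f):
        raise ValueError("weights and frequencies differ in length")
    for _ in range(model.rounds):
        mass = float(np.sum(f * w))
        if mass <= 0:
            raise ValueError("all clones with nonzero frequency have zero weight")
        post = f * w / mass
        counts = rng.multinomial(pool_size, post)
        f = counts / pool_size
    return f
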