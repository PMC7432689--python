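"""Fickett TESTCODE statistic.

Eight statistics are computed from the transcript: for each base B in
A, C, G, T a *position value* MAX(B1,B2,B3)/(MIN(B1,B2,B3)+1) — where
B1/B2/B3 count B at positions congruent to 0/1/2 mod 3 — and a
*composition fraction* (count of B over all non-N bases).  Each statistic
is mapped through a published interval lookup to a coding probability and
the eight probabilities are combined as a weighted sum.

The lookup content (interval boundaries, probabilities, weights) follows
Fickett's original TESTCODE tables and is shipped here as data.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

from ..sequence_io import Transcript

BASES = "ACGT"

# Coding probabilities for the position statistic, listed for ascending
# value intervals: (-inf,1.1), [1.1,1.2), ..., [1.8,1.9), [1.9,inf).
_POSITION_BOUNDARIES = [1.1, 1.2, 1.3, 1.4, 1.5, 1.6, 1.7, 1.8, 1.9]
_POSITION_PROB = {
    "A": [0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94],
    "C": [0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80],
    "G": [0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90],
    "T": [0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97],
}
_POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}

# Composition statistic intervals: (-inf,0.17), [0.17,0.19), ..., [0.33,inf).
_CONTENT_BOUNDARIES = [0.17, 0.19, 0.21, 0.23, 0.25, 0.27, 0.29, 0.31, 0.33]
_CONTENT_PROB = {
    "A": [0.21, 0.81, 0.65, 0.67, 0.49, 0.62, 0.55, 0.44, 0.49, 0.28],
    "C": [0.31, 0.39, 0.44, 0.43, 0.59, 0.59, 0.64, 0.51, 0.64, 0.82],
    "G": [0.29, 0.33, 0.41, 0.41, 0.73, 0.61, 0.64, 0.47, 0.54, 0.40],
    "T": [0.58, 0.51, 0.69, 0.56, 0.75, 0.55, 0.40, 0.39, 0.24, 0.28],
}
_CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}


@dataclass(frozen=True)
class IntervalLookup:
    """Step-function mapping a statistic value to a coding probability."""

    boundaries: tuple[float, ...]
    probabilities: tuple[float, ...]
    weight: float

    def __post_init__(self) -> None:
        if len(self.probabilities) != len(self.boundaries) + 1:
            raise ValueError("need len(boundaries)+1 probabilities")
        if list(self.boundaries) != sorted(set(self.boundaries)):
            raise ValueError("boundaries must be strictly increasing")
        if not all(0.0 <= p <= 1.0 for p in self.probabilities):
            raise ValueError("probabilities must lie in [0,1]")
        if self.weight <= 0:
            raise ValueError("weight must be positive")

    def __call__(self, value: float) -> float:
        return self.probabilities[bisect_right(self.boundaries, value)]


@dataclass(frozen=True)
class FickettLookup:
    """The eight TESTCODE lookups: position and composition per base."""

    position: dict[str, IntervalLookup]
    composition: dict[str, IntervalLookup]

    def __post_init__(self) -> None:
        for table in (self.position, self.composition):
            if set(table) != set(BASES):
                raise ValueError("lookups required for exactly A, C, G, T")


def default_fickett_lookup() -> FickettLookup:
    """The published TESTCODE tables."""
    position = {
        b: IntervalLookup(tuple(_POSITION_BOUNDARIES), tuple(_POSITION_PROB[b]),
                          _POSITION_WEIGHT[b])
        for b in BASES
    }
    composition = {
        b: IntervalLookup(tuple(_CONTENT_BOUNDARIES), tuple(_CONTENT_PROB[b]),
                          _CONTENT_WEIGHT[b])
        for b in BASES
    }
    return FickettLookup(position=position, composition=composition)


def fickett_position_values(t: Transcript | str) -> dict[str, float]:
    """Per-base MAX(B1,B2,B3)/(MIN(B1,B2,B3)+1) over codon positions.

    Positions are anchored at the transcript 5' end (position i has codon
    phase i mod 3); N contributes to no base count.
    """
    seq = t.seq if isinstance(t, Transcript) else t
    if len(seq) < 3:
        raise ValueError(f"sequence too short for codon-position statistics: {len(seq)} nt")
    counts = {b: [0, 0, 0] for b in BASES}
    for i, c in enumerate(seq):
        if c in counts:
            counts[c][i % 3] += 1
    return {b: max(v) / (min(v) + 1.0) for b, v in counts.items()}


def fickett_composition(t: Transcript | str) -> dict[str, float]:
    """Base fraction among non-N positions (all zero if sequence is all N)."""
    seq = t.seq if isinstance(t, Transcript) else t
    total = sum(seq.count(b) for b in BASES)
    if total == 0:
        return {b: 0.0 for b in BASES}
    return {b: seq.count(b) / total for b in BASES}


def fickett_score(t: Transcript | str,
                  lookup: FickettLookup | None = None) -> float:
    """TESTCODE score: weighted sum of the eight looked-up probabilities."""
    if lookup is None:
        lookup = default_fickett_lookup()
    pos = fickett_position_values(t)
    comp = fickett_composition(t)
    score = 0.0
    for b in BASES:
        score += lookup.position[b](pos[b]) * lookup.position[b].weight
        score += lookup.composition[b](comp[b]) * lookup.composition[b].weight
    return score
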