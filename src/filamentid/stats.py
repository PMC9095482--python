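"""Match-specificity statistics for gapped patterns.

How surprising is it that a pattern hits exactly one protein in a
proteome?  Under an order-0 (i.i.d.) background model the probability that
a single window satisfies the pattern is the product, over its
residue-class elements, of the class probabilities; wildcard positions
contribute a factor of 1.  The expected number of hits in a proteome is
that probability times the number of scannable windows, and the chance of
seeing the observed hit count is read off a Poisson tail.

Two approximations are made deliberately and are validated by simulation
tests rather than corrected for: residues are treated as i.i.d. (no
dipeptide structure), and the dependence between overlapping windows is
ignored in the Poisson tail.  The expected hit count itself is exact under
the i.i.d. model by linearity of expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats as sps

from .motif import CANONICAL_RESIDUES, MotifPattern
from .scanner import SequenceRecord

__all__ = [
    "BackgroundModel",
    "SpecificityReport",
    "window_match_probability",
    "information_bits",
    "expected_hits",
    "estimate_background",
]

_TOL = 1e-9


@dataclass(frozen=True)
class BackgroundModel:
    """Residue frequencies over the 20 canonical amino acids."""

    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        freqs = dict(self.frequencies)
        missing = CANONICAL_RESIDUES - freqs.keys()
        if missing:
            raise ValueError(f"background is missing residues {sorted(missing)}")
        extra = freqs.keys() - CANONICAL_RESIDUES
        if extra:
            raise ValueError(f"background has non-canonical residues {sorted(extra)}")
        if any(v < 0 for v in freqs.values()):
            raise ValueError("background frequencies must be non-negative")
        total = sum(freqs.values())
        if abs(total - 1.0) > _TOL:
            raise ValueError(f"background frequencies sum to {total}, not 1")
        object.__setattr__(self, "frequencies", freqs)

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        return cls({r: 1.0 / 20.0 for r in CANONICAL_RESIDUES})

    def __getitem__(self, residue: str) -> float:
        return self.frequencies[residue]

    def class_probability(self, residues: Iterable[str]) -> float:
        return sum(self.frequencies[r] for r in residues)

    def as_arrays(self) -> tuple[list[str], list[float]]:
        """Residues and frequencies in fixed (alphabetical) order."""
        letters = sorted(CANONICAL_RESIDUES)
        return letters, [self.frequencies[r] for r in letters]


@dataclass(frozen=True)
class SpecificityReport:
    """Per-window probability, expected hits and Poisson tail for a scan."""

    p_window: float
    n_windows: int
    expected_hits: float
    observed_hits: int
    poisson_tail: float
    information_bits: float

    def summary(self) -> dict:
        return {
            "p_window": self.p_window,
            "n_windows": self.n_windows,
            "expected_hits": self.expected_hits,
            "observed_hits": self.observed_hits,
            "poisson_tail": self.poisson_tail,
            "information_bits": self.information_bits,
        }


def window_match_probability(pattern: MotifPattern, background: BackgroundModel) -> float:
    """Probability that one i.i.d. window satisfies every class element."""
    p = 1.0
    for e in pattern.elements:
        if e.is_class:
            p *= background.class_probability(e.residues)
    return p


def information_bits(pattern: MotifPattern, background: BackgroundModel) -> float:
    """Total information content of the class positions, in bits.

    Each residue-class element contributes ``log2(1/p_element)``; wildcards
    contribute nothing.  Under a uniform background a single-residue anchor
    is worth log2(20) ~ 4.32 bits and [ST] is worth log2(10) ~ 3.32 bits.
    """
    bits = 0.0
    for e in pattern.elements:
        if e.is_class:
            p = background.class_probability(e.residues)
            if p <= 0:
                return math.inf
            bits += math.log2(1.0 / p)
    return bits


def n_windows(lengths: Iterable[int], span: int) -> int:
    return sum(max(0, length - span + 1) for length in lengths)


def expected_hits(
    pattern: MotifPattern,
    lengths: Sequence[int],
    background: BackgroundModel,
    observed_hits: int = 0,
) -> SpecificityReport:
    """Specificity of a pattern against a proteome of given sequence lengths.

    ``poisson_tail`` is P[K >= observed_hits] for K ~ Poisson(expected);
    with ``observed_hits=0`` the tail is 1 by construction.
    """
    if any(length < 0 for length in lengths):
        raise ValueError("sequence lengths must be non-negative")
    if observed_hits < 0:
        raise ValueError("observed hit count must be non-negative")
    p = window_match_probability(pattern, background)
    windows = n_windows(lengths, pattern.span)
    lam = p * windows
    # P[K >= k] = sf(k - 1); sf(-1) = 1
    tail = float(sps.poisson.sf(observed_hits - 1, lam))
    return SpecificityReport(
        p_window=p,
        n_windows=windows,
        expected_hits=lam,
        observed_hits=observed_hits,
        poisson_tail=tail,
        information_bits=information_bits(pattern, background),
    )


def estimate_background(records: Iterable[SequenceRecord]) -> BackgroundModel:
    """Maximum-likelihood residue frequencies with add-one smoothing.

    Unknown residues (X) are excluded from the counts.  Smoothing keeps
    every canonical residue at non-zero probability, so information content
    and window probabilities stay finite on small fixtures.
    """
    counts = {r: 0 for r in CANONICAL_RESIDUES}
    total = 0
    for record in records:
        for ch in record.residues:
            if ch in counts:
                counts[ch] += 1
                total += 1
    if total == 0:
        raise ValueError("no canonical residues in input; cannot estimate background")
    denom = total + 20
    return BackgroundModel({r: (c + 1) / denom for r, c in counts.items()})
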