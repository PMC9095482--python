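"""Decoy proteomes and the packaged TMEM106B reference sequence.

Decoy proteomes are i.i.d. sequence collections drawn from a configurable
background composition, optionally with implanted full or deliberately
degraded motif instances.  They stand in for a real proteome when
calibrating match-specificity statistics: every claim of the form "this
pattern is expected to hit lambda windows by chance" can be checked by
scanning seeded decoys.  Decoys carry no homology, repeat or domain
structure — they emulate composition only.

Generation is deterministic: the RNG algorithm (NumPy PCG64) is fixed and
recorded, with the seed, in every FASTA header, so decoy fixtures are
byte-stable across runs and releases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Literal, Optional, Sequence

import numpy as np

from .motif import CANONICAL_RESIDUES, MotifPattern
from .scanner import SequenceRecord, read_fasta
from .stats import BackgroundModel

__all__ = [
    "LengthDistribution",
    "ImplantSpec",
    "DecoySpec",
    "DecoyProteome",
    "generate_proteome",
    "tmem106b_record",
    "ORDERED_CORE",
    "GLYCOSYLATION_SITES",
    "DISULFIDE_PAIR",
    "VARIANT_POSITION",
]

_RNG_TAG = "pcg64"

# Structure-derived annotations of the packaged TMEM106B sequence:
# ordered filament core span, glycosylated asparagines, disulfide pair and
# the T185S (rs3173615) variant position.
ORDERED_CORE = (120, 254)
GLYCOSYLATION_SITES = (145, 151, 164, 183, 256)
DISULFIDE_PAIR = (214, 253)
VARIANT_POSITION = 185


@dataclass(frozen=True)
class LengthDistribution:
    """Fixed length, or log-normal(mu, sigma) truncated to [minimum, maximum]."""

    kind: Literal["fixed", "lognormal"] = "fixed"
    length: int = 300
    mu: float = 5.8
    sigma: float = 0.6
    minimum: int = 50
    maximum: int = 5000

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "fixed":
            if self.length < 1:
                raise ValueError("fixed length must be positive")
            return np.full(n, self.length, dtype=int)
        if self.kind != "lognormal":
            raise ValueError(f"unknown length distribution {self.kind!r}")
        lengths = np.empty(n, dtype=int)
        filled = 0
        while filled < n:  # rejection sampling keeps the truncated shape
            draw = rng.lognormal(self.mu, self.sigma, size=2 * (n - filled))
            keep = draw[(draw >= self.minimum) & (draw <= self.maximum)][: n - filled]
            lengths[filled : filled + keep.size] = keep.astype(int)
            filled += keep.size
        return lengths


@dataclass(frozen=True)
class ImplantSpec:
    """Motif instances to implant: full copies are guaranteed scanner hits;
    partial copies degrade the listed elements (a class residue is replaced
    by a residue outside the class) and are guaranteed misses of those
    elements."""

    pattern: MotifPattern
    n_copies: int = 1
    mode: Literal["full", "partial"] = "full"
    degrade_elements: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if self.n_copies < 0:
            raise ValueError("implant copy count must be non-negative")
        if self.mode == "partial":
            if not self.degrade_elements:
                raise ValueError("partial implants must name the degraded elements")
            for i in self.degrade_elements:
                if not 0 <= i < len(self.pattern.elements):
                    raise ValueError(f"degrade index {i} out of range")
                if not self.pattern.elements[i].is_class:
                    raise ValueError("only residue-class elements can be degraded")


@dataclass(frozen=True)
class DecoySpec:
    """Recipe for a reproducible decoy proteome."""

    seed: int
    n_sequences: int = 2000
    lengths: LengthDistribution = field(default_factory=LengthDistribution)
    background: Optional[BackgroundModel] = None
    implants: tuple[ImplantSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.n_sequences < 0:
            raise ValueError("n_sequences must be non-negative")


@dataclass(frozen=True)
class ImplantSite:
    sequence_id: str
    start: int  # 1-based inclusive
    end: int
    pattern: MotifPattern
    mode: str


@dataclass
class DecoyProteome:
    records: list[SequenceRecord]
    implant_sites: list[ImplantSite]
    spec: DecoySpec


_MAX_PLACEMENT_ATTEMPTS = 1000


def _realize(
    implant: ImplantSpec, rng: np.random.Generator, letters: list[str], freqs: np.ndarray
) -> str:
    chars: list[str] = []
    for i, e in enumerate(implant.pattern.elements):
        if e.is_class:
            choices = sorted(e.residues)
            if implant.mode == "partial" and i in implant.degrade_elements:
                choices = sorted(CANONICAL_RESIDUES - e.residues)
            chars.append(choices[rng.integers(len(choices))])
        else:
            idx = rng.choice(len(letters), size=e.run_length, p=freqs)
            chars.extend(letters[j] for j in idx)
    return "".join(chars)


def generate_proteome(spec: DecoySpec) -> DecoyProteome:
    """Generate a decoy proteome; equal seeds give byte-identical output.

    Implants are placed uniformly among feasible windows and never overlap
    one another (rejection sampling, capped at 1000 attempts per copy).
    """
    rng = np.random.Generator(np.random.PCG64(spec.seed))
    background = spec.background or BackgroundModel.uniform()
    letters, freq_list = background.as_arrays()
    freqs = np.asarray(freq_list)
    freqs = freqs / freqs.sum()  # remove float round-off for rng.choice
    lengths = spec.lengths.sample(spec.n_sequences, rng)
    letter_arr = np.array(letters)
    width = max(5, len(str(max(spec.n_sequences, 1))))
    sequences: list[list[str]] = []
    for i, L in enumerate(lengths):
        idx = rng.choice(len(letters), size=int(L), p=freqs)
        sequences.append(list(letter_arr[idx]))

    occupied: dict[int, list[tuple[int, int]]] = {}
    sites: list[ImplantSite] = []
    for implant in spec.implants:
        span = implant.pattern.span
        feasible = [i for i, L in enumerate(lengths) if L >= span]
        if not feasible and implant.n_copies > 0:
            raise ValueError(
                f"implant span {span} exceeds every sequence length; cannot place"
            )
        # uniform over feasible windows: weight sequences by window count
        window_counts = np.array([lengths[i] - span + 1 for i in feasible], dtype=float)
        window_p = window_counts / window_counts.sum() if feasible else None
        for _ in range(implant.n_copies):
            for attempt in range(_MAX_PLACEMENT_ATTEMPTS):
                seq_idx = feasible[rng.choice(len(feasible), p=window_p)]
                start0 = int(rng.integers(lengths[seq_idx] - span + 1))
                window = (start0, start0 + span - 1)
                taken = occupied.setdefault(seq_idx, [])
                if all(window[1] < lo or window[0] > hi for lo, hi in taken):
                    taken.append(window)
                    text = _realize(implant, rng, letters, freqs)
                    sequences[seq_idx][start0 : start0 + span] = list(text)
                    sites.append(
                        ImplantSite(
                            sequence_id=_decoy_id(seq_idx, width),
                            start=start0 + 1,
                            end=start0 + span,
                            pattern=implant.pattern,
                            mode=implant.mode,
                        )
                    )
                    break
            else:
                raise ValueError(
                    f"could not place implant without overlap after "
                    f"{_MAX_PLACEMENT_ATTEMPTS} attempts"
                )

    records = [
        SequenceRecord(
            id=_decoy_id(i, width),
            residues="".join(seq),
            description=(
                f"{_decoy_id(i, width)} decoy len={len(seq)} "
                f"seed={spec.seed} rng={_RNG_TAG}"
            ),
        )
        for i, seq in enumerate(sequences)
    ]
    return DecoyProteome(records=records, implant_sites=sites, spec=spec)


def _decoy_id(index: int, width: int) -> str:
    return f"decoy_{index + 1:0{width}d}"


def tmem106b_record() -> SequenceRecord:
    """The packaged 274-residue human TMEM106B sequence (UniProt Q9NUM4).

    The description annotates the ordered filament core (S120-G254), the
    five N-glycosylation sequon asparagines and the C214-C253 disulfide
    pair; the annotations are asserted against the sequence at load time.
    """
    path = resources.files("filamentid.data") / "tmem106b.fasta"
    record = read_fasta(str(path))[0]
    if len(record) != 274:
        raise AssertionError("packaged TMEM106B sequence is not 274 residues")
    lo, hi = ORDERED_CORE
    if record[lo] != "S" or record[hi] != "G":
        raise AssertionError("ordered-core endpoints are not S120/G254")
    for n in GLYCOSYLATION_SITES:
        if record[n] != "N" or record[n + 2] not in "ST":
            raise AssertionError(f"position {n} is not a glycosylation sequon")
    for c in DISULFIDE_PAIR:
        if record[c] != "C":
            raise AssertionError(f"position {c} is not a cysteine")
    return record
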