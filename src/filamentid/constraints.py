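"""From density-map features to candidate scanning patterns.

Before the protein behind a filament density is known, a map provides
relative information only: rung offsets between recognisable side-chain
features.  Glycan densities mark asparagines of N-glycosylation sequons
(N-x-[ST], three positions); a disulfide bridge marks a cysteine pair.
This module turns an ordered list of such observations into concrete
gapped patterns, enumerating integer spacer uncertainty where the rung
assignment is ambiguous, so the candidates can be scanned and ranked
against a proteome.

Feature offsets are expressed relative to the first feature (first = 0),
because that is what a map gives; absolute residue numbers only appear
once a pattern matches a known sequence.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

from .motif import MotifPattern, PatternElement, residue_class, wildcard
from .scanner import SequenceRecord, scan_fasta
from .stats import BackgroundModel, information_bits, window_match_probability

__all__ = [
    "DensityFeature",
    "ConstraintSet",
    "NoFeasiblePatternError",
    "build_patterns",
    "rank_patterns",
    "RankedPattern",
    "load_constraints",
]

FEATURE_CLASSES = ("glycosylated-asn", "disulfide-cys", "generic-residue")

# strict biological sequon forbids proline at the middle position
_NON_PROLINE = frozenset("ACDEFGHIKLMNQRSTVWY")

DEFAULT_EXPANSION_BOUND = 10_000


class NoFeasiblePatternError(ValueError):
    """All offset combinations were infeasible (negative implied spacers)."""


@dataclass(frozen=True)
class DensityFeature:
    """One map-derived observation: a feature class at a rung offset.

    ``rung_offset`` counts residues relative to the first feature of the
    set; ``offset_uncertainty`` widens it to ``offset ± u`` during pattern
    enumeration.  ``residue_class`` is the allowed residue set at the
    anchor position ({N} for a glycosylated asparagine, {C} for a
    disulfide cysteine, caller-supplied for generic features).
    """

    rung_offset: int
    feature_class: str = "glycosylated-asn"
    residue_class: frozenset[str] = frozenset()
    offset_uncertainty: int = 0

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise ValueError(f"unknown feature class {self.feature_class!r}")
        if self.rung_offset < 0:
            raise ValueError("rung offsets are relative to the first feature and non-negative")
        if self.offset_uncertainty < 0:
            raise ValueError("offset uncertainty must be non-negative")
        if not self.residue_class:
            default = {"glycosylated-asn": "N", "disulfide-cys": "C"}.get(self.feature_class)
            if default is None:
                raise ValueError("generic-residue features need an explicit residue class")
            object.__setattr__(self, "residue_class", frozenset(default))
        else:
            object.__setattr__(self, "residue_class", frozenset(self.residue_class))

    @property
    def footprint(self) -> int:
        """Sequence positions the feature occupies (sequon = 3, else 1)."""
        return 3 if self.feature_class == "glycosylated-asn" else 1

    def elements(self, strict_sequon: bool = False) -> list[PatternElement]:
        """Pattern elements for this feature; anchor element first."""
        anchor = residue_class(self.residue_class)
        if self.feature_class == "glycosylated-asn":
            middle = (
                PatternElement("class", _NON_PROLINE) if strict_sequon else wildcard(1)
            )
            return [anchor, middle, residue_class("ST")]
        return [anchor]


@dataclass(frozen=True)
class ConstraintSet:
    """An ordered collection of density features defining one fingerprint."""

    features: tuple[DensityFeature, ...]
    name: str = "constraints"

    def __post_init__(self) -> None:
        features = tuple(self.features)
        if len(features) < 2:
            raise ValueError("a single feature is uninformative; need at least 2")
        offsets = [f.rung_offset for f in features]
        if offsets[0] != 0:
            raise ValueError("the first feature defines the origin (offset 0)")
        if any(b <= a for a, b in zip(offsets, offsets[1:])):
            raise ValueError("feature offsets must be strictly increasing")
        object.__setattr__(self, "features", features)

    @property
    def expansion_count(self) -> int:
        count = 1
        for f in self.features:
            count *= 2 * f.offset_uncertainty + 1
        return count


def build_patterns(
    constraint_set: ConstraintSet,
    strict_sequon: bool = False,
    max_patterns: int = DEFAULT_EXPANSION_BOUND,
) -> list[MotifPattern]:
    """Enumerate candidate patterns over the feature offset uncertainties.

    With zero uncertainty exactly one pattern results.  Offset combinations
    whose implied spacer between consecutive features is negative (the
    previous feature's footprint would overlap the next anchor) are
    dropped; if every combination is dropped a
    :class:`NoFeasiblePatternError` is raised.  Duplicate patterns arising
    from different combinations are merged.
    """
    if constraint_set.expansion_count > max_patterns:
        raise ValueError(
            f"offset enumeration would produce {constraint_set.expansion_count} "
            f"combinations, above the bound of {max_patterns}"
        )
    ranges = [
        range(f.rung_offset - f.offset_uncertainty, f.rung_offset + f.offset_uncertainty + 1)
        for f in constraint_set.features
    ]
    patterns: dict[str, MotifPattern] = {}
    for combo in itertools.product(*ranges):
        if any(b <= a for a, b in zip(combo, combo[1:])):
            continue
        elements: list[PatternElement] = []
        anchor_indices: list[int] = []
        feasible = True
        for i, (feature, offset) in enumerate(zip(constraint_set.features, combo)):
            if i > 0:
                prev = constraint_set.features[i - 1]
                spacer = offset - combo[i - 1] - prev.footprint
                if spacer < 0:
                    feasible = False
                    break
                if spacer > 0:
                    elements.append(wildcard(spacer))
            anchor_indices.append(len(elements))
            elements.extend(feature.elements(strict_sequon=strict_sequon))
        if not feasible:
            continue
        pattern = MotifPattern(tuple(elements), anchor_indices=tuple(anchor_indices))
        patterns.setdefault(pattern.canonical(), pattern)
    if not patterns:
        raise NoFeasiblePatternError(
            f"no feasible pattern for constraint set {constraint_set.name!r}"
        )
    return list(patterns.values())


@dataclass(frozen=True)
class RankedPattern:
    """A candidate pattern with its specificity ranking keys."""

    pattern: MotifPattern
    expected_hits: float
    observed_hits: int
    information_bits: float

    @property
    def sort_key(self):
        return (
            self.expected_hits,
            self.observed_hits,
            -self.information_bits,
            self.pattern.canonical(),
        )


def rank_patterns(
    patterns: Sequence[MotifPattern],
    proteome: Iterable[SequenceRecord],
    background: BackgroundModel,
) -> list[RankedPattern]:
    """Order candidates by specificity: fewest expected background hits
    first, then fewest observed hits, then highest information content;
    remaining ties break on the canonical pattern string."""
    if not patterns:
        raise ValueError("no patterns to rank")
    records = list(proteome)
    ranked = []
    for p in patterns:
        report = scan_fasta(p, records)
        lam = window_match_probability(p, background) * report.n_windows
        ranked.append(
            RankedPattern(
                pattern=p,
                expected_hits=lam,
                observed_hits=len(report.hits),
                information_bits=information_bits(p, background),
            )
        )
    return sorted(ranked, key=lambda r: r.sort_key)


def load_constraints(path) -> ConstraintSet:
    """Read a constraint set from a YAML config.

    Schema::

        name: tmem106b-glycans
        features:
          - {offset: 0, class: glycosylated-asn, uncertainty: 0}
          - {offset: 6, class: glycosylated-asn}
          ...

    ``residues`` may be given for generic-residue features.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "features" not in doc:
        raise ValueError(f"constraint config {path} must define a 'features' list")
    features = []
    for entry in doc["features"]:
        features.append(
            DensityFeature(
                rung_offset=int(entry["offset"]),
                feature_class=entry.get("class", "glycosylated-asn"),
                residue_class=frozenset(entry.get("residues", "")),
                offset_uncertainty=int(entry.get("uncertainty", 0)),
            )
        )
    return ConstraintSet(tuple(features), name=str(doc.get("name", "constraints")))
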