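"""Gapped scanning patterns in a PROSITE-like dialect.

A pattern is a dash-separated list of elements::

    N-x-[ST]-x(3)-N-x-[ST]

where a bare letter is a single-residue class, ``[ST]`` is a multi-residue
class, ``x`` is a one-position wildcard and ``x(n)`` a wildcard run of
length *n*.  Patterns of this form describe sequence fingerprints deduced
from cryo-EM density maps (glycan-bearing asparagines with exact spacers,
disulfide cysteine pairs) and are scanned exactly against proteomes.

Canonical form: adjacent wildcard runs are merged (``x-x(2)`` becomes
``x(3)``), residue classes are written in alphabetical order and
single-residue classes are written as the bare letter.  ``parse_pattern``
and ``serialize_pattern`` round-trip through this canonical form.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

CANONICAL_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

__all__ = [
    "CANONICAL_RESIDUES",
    "PatternElement",
    "MotifPattern",
    "PatternParseError",
    "parse_pattern",
    "serialize_pattern",
    "read_patterns",
    "write_patterns",
]


class PatternParseError(ValueError):
    """Raised for malformed pattern text; the message names the bad token."""


@dataclass(frozen=True)
class PatternElement:
    """One element of a gapped pattern.

    ``kind`` is ``"class"`` (a set of allowed residues at one position) or
    ``"wildcard"`` (a run of ``run_length`` unconstrained positions).
    """

    kind: str
    residues: frozenset[str] = frozenset()
    run_length: int = 1

    def __post_init__(self) -> None:
        if self.kind == "class":
            if not self.residues:
                raise ValueError("residue-class element needs a non-empty residue set")
            bad = set(self.residues) - CANONICAL_RESIDUES
            if bad:
                raise ValueError(f"non-canonical residue(s) in class: {sorted(bad)}")
            if self.run_length != 1:
                raise ValueError("residue-class elements have run_length 1")
        elif self.kind == "wildcard":
            if self.residues:
                raise ValueError("wildcard elements carry no residue set")
            if self.run_length < 1:
                raise ValueError("wildcard run length must be >= 1")
        else:
            raise ValueError(f"unknown element kind: {self.kind!r}")

    @property
    def is_class(self) -> bool:
        return self.kind == "class"

    def token(self) -> str:
        """Canonical text token for this element."""
        if self.is_class:
            letters = "".join(sorted(self.residues))
            return letters if len(letters) == 1 else f"[{letters}]"
        return "x" if self.run_length == 1 else f"x({self.run_length})"


def wildcard(run_length: int = 1) -> PatternElement:
    return PatternElement("wildcard", frozenset(), run_length)


def residue_class(residues: Iterable[str]) -> PatternElement:
    return PatternElement("class", frozenset(residues), 1)


@dataclass(frozen=True)
class MotifPattern:
    """An ordered gapped pattern with anchor elements.

    Anchors are the residue-class elements that correspond to map-derived
    features (e.g. the sequon asparagines, the disulfide cysteines).  By
    default every single-residue class is an anchor; multi-residue classes
    such as ``[ST]`` are constraint positions but not anchors.
    ``anchor_indices`` index into ``elements``.
    """

    elements: tuple[PatternElement, ...]
    anchor_indices: tuple[int, ...] = ()
    source_text: str = ""

    def __post_init__(self) -> None:
        elements = tuple(self.elements)
        if not elements:
            raise ValueError("pattern must have at least one element")
        elements = _merge_wildcards(elements)
        anchors = self.anchor_indices
        if not anchors:
            anchors = tuple(
                i for i, e in enumerate(elements) if e.is_class and len(e.residues) == 1
            )
        for i in anchors:
            if not (0 <= i < len(elements)) or not elements[i].is_class:
                raise ValueError(f"anchor index {i} does not point at a residue-class element")
        object.__setattr__(self, "elements", elements)
        object.__setattr__(self, "anchor_indices", tuple(anchors))
        if not self.source_text:
            object.__setattr__(self, "source_text", serialize_pattern(self))

    @property
    def span(self) -> int:
        """Total number of sequence positions the pattern covers."""
        return sum(e.run_length for e in self.elements)

    @property
    def element_offsets(self) -> tuple[int, ...]:
        """0-based sequence offset (within a match) of each element."""
        offsets = []
        pos = 0
        for e in self.elements:
            offsets.append(pos)
            pos += e.run_length
        return tuple(offsets)

    @property
    def anchor_offsets(self) -> tuple[int, ...]:
        """0-based offsets of the anchor positions within a match."""
        offs = self.element_offsets
        return tuple(offs[i] for i in self.anchor_indices)

    @property
    def n_class_positions(self) -> int:
        return sum(1 for e in self.elements if e.is_class)

    def canonical(self) -> str:
        return serialize_pattern(self)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MotifPattern):
            return NotImplemented
        return (
            self.elements == other.elements
            and self.anchor_indices == other.anchor_indices
        )

    def __hash__(self) -> int:
        return hash((self.elements, self.anchor_indices))

    def __str__(self) -> str:
        return self.canonical()


def _merge_wildcards(elements: Sequence[PatternElement]) -> tuple[PatternElement, ...]:
    merged: list[PatternElement] = []
    for e in elements:
        if merged and not e.is_class and not merged[-1].is_class:
            merged[-1] = wildcard(merged[-1].run_length + e.run_length)
        else:
            merged.append(e)
    return tuple(merged)


_TOKEN_CLASS = re.compile(r"^\[([A-Z]+)\]$")
_TOKEN_RUN = re.compile(r"^X\((-?\d+)\)$")


def _split_tokens(text: str) -> list[str]:
    # split on dashes, but not inside () or [] so that e.g. a negative run
    # length stays one token and is reported whole
    tokens, buf, depth = [], [], 0
    for ch in text:
        if ch == "-" and depth == 0:
            tokens.append("".join(buf))
            buf = []
        else:
            if ch in "([":
                depth += 1
            elif ch in ")]":
                depth = max(0, depth - 1)
            buf.append(ch)
    tokens.append("".join(buf))
    return tokens


def parse_pattern(text: str) -> MotifPattern:
    """Parse pattern text into a :class:`MotifPattern`.

    Lowercase letters are uppercased; adjacent wildcard runs are merged.
    Raises :class:`PatternParseError` for malformed tokens.
    """
    if not text or not text.strip():
        raise PatternParseError("empty pattern string")
    elements: list[PatternElement] = []
    for raw in _split_tokens(text.strip()):
        token = raw.strip().upper()
        if not token:
            raise PatternParseError(f"empty token in pattern {text!r}")
        if token == "X":
            elements.append(wildcard(1))
            continue
        run = _TOKEN_RUN.match(token)
        if run:
            n = int(run.group(1))
            if n < 1:
                raise PatternParseError(f"non-positive run length in token {raw!r}")
            elements.append(wildcard(n))
            continue
        cls = _TOKEN_CLASS.match(token)
        if cls:
            letters = cls.group(1)
            bad = set(letters) - CANONICAL_RESIDUES
            if bad:
                raise PatternParseError(
                    f"unknown residue letter(s) {sorted(bad)} in token {raw!r}"
                )
            elements.append(residue_class(letters))
            continue
        if "[" in token or "]" in token or "(" in token or ")" in token:
            raise PatternParseError(f"malformed token {raw!r}")
        if len(token) == 1 and token in CANONICAL_RESIDUES:
            elements.append(residue_class(token))
            continue
        raise PatternParseError(f"unknown residue letter in token {raw!r}")
    return MotifPattern(tuple(elements), source_text=text.strip())


def serialize_pattern(pattern: MotifPattern) -> str:
    """Canonical text for a pattern; ``parse_pattern`` inverts it."""
    return "-".join(e.token() for e in _merge_wildcards(pattern.elements))


def read_patterns(path) -> list[MotifPattern]:
    """Read patterns from plain text, one per line; ``#`` starts a comment."""
    patterns = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                patterns.append(parse_pattern(line))
    return patterns


def write_patterns(patterns: Iterable[MotifPattern], path, comments: Iterable[str] = ()) -> None:
    """Write patterns one per line, preceded by optional ``#`` comment lines."""
    with open(path, "w") as fh:
        for c in comments:
            fh.write(f"# {c}\n")
        for p in patterns:
            fh.write(serialize_pattern(p) + "\n")
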