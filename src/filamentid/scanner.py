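"""Exact scanning of protein sequences for gapped-pattern occurrences.

The scanner reports every window of a sequence that satisfies every
residue-class element of a pattern.  Overlapping matches are all reported;
uniqueness claims ("a hit in only one protein") are made at sequence level
in :class:`ScanReport`.  All coordinates are 1-based with inclusive spans,
matching conventional protein residue numbering.

An unknown residue ``X`` in a sequence satisfies wildcard positions only,
never a residue class: a low-quality proteome entry can therefore never
produce a spurious unique hit.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .motif import CANONICAL_RESIDUES, MotifPattern

__all__ = [
    "SequenceRecord",
    "MatchHit",
    "ScanReport",
    "scan_sequence",
    "scan_fasta",
    "read_fasta",
    "write_fasta",
    "report_to_tsv",
]

_ALLOWED = CANONICAL_RESIDUES | {"X"}
# ambiguity / rare codes seen in public proteomes, conservatively mapped to X
_TO_X = str.maketrans({c: "X" for c in "BZJUO*"})


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence; residues are the 20 canonical codes plus X.

    Residue indexing is 1-based throughout: ``record[145]`` is the residue
    a biologist would call residue 145.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        residues = self.residues.upper().translate(_TO_X)
        bad = set(residues) - _ALLOWED
        if bad:
            raise ValueError(f"sequence {self.id!r} has invalid characters {sorted(bad)}")
        object.__setattr__(self, "residues", residues)

    def __len__(self) -> int:
        return len(self.residues)

    def __getitem__(self, position: int) -> str:
        """1-based residue access."""
        if not 1 <= position <= len(self.residues):
            raise IndexError(f"residue index {position} out of range 1..{len(self)}")
        return self.residues[position - 1]


@dataclass(frozen=True)
class MatchHit:
    """One pattern occurrence: 1-based inclusive span plus anchor positions."""

    sequence_id: str
    start: int
    end: int
    anchor_positions: tuple[int, ...]
    matched_text: str

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.matched_text):
            raise ValueError("span and matched text length disagree")
        if any(not self.start <= a <= self.end for a in self.anchor_positions):
            raise ValueError("anchor positions must lie within the match span")
        if list(self.anchor_positions) != sorted(set(self.anchor_positions)):
            raise ValueError("anchor positions must be strictly increasing")


@dataclass
class ScanReport:
    """Aggregate result of scanning a sequence collection with one pattern."""

    pattern: MotifPattern
    n_sequences: int
    n_windows: int
    hits: list[MatchHit] = field(default_factory=list)

    @property
    def unique_hit(self) -> bool:
        """True iff exactly one sequence carries at least one hit."""
        return len({h.sequence_id for h in self.hits}) == 1

    @property
    def hit_sequence_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for h in self.hits:
            seen.setdefault(h.sequence_id)
        return list(seen)

    def summary(self) -> dict:
        return {
            "pattern": self.pattern.canonical(),
            "span": self.pattern.span,
            "n_sequences": self.n_sequences,
            "n_windows": self.n_windows,
            "n_hits": len(self.hits),
            "n_hit_sequences": len(self.hit_sequence_ids),
            "unique_hit": self.unique_hit,
        }


@lru_cache(maxsize=256)
def _compile(canonical: str) -> re.Pattern:
    # Overlapping matches via a look-ahead capture.  X must not satisfy a
    # residue class, so classes are written out explicitly while wildcards
    # use ``.`` (the scanned alphabet is the 20 canonical residues plus X).
    from .motif import parse_pattern

    pattern = parse_pattern(canonical)
    parts = []
    for e in pattern.elements:
        if e.is_class:
            letters = "".join(sorted(e.residues))
            parts.append(letters if len(letters) == 1 else f"[{letters}]")
        else:
            parts.append("." if e.run_length == 1 else f".{{{e.run_length}}}")
    return re.compile("(?=(" + "".join(parts) + "))")


def scan_sequence(
    pattern: MotifPattern,
    record: SequenceRecord,
    region: tuple[int, int] | None = None,
) -> list[MatchHit]:
    """All pattern occurrences in one sequence, sorted by start position.

    ``region`` restricts the scan to an inclusive 1-based residue window
    (e.g. an ordered core); reported coordinates stay in full-sequence
    numbering.  A pattern longer than the sequence yields an empty list.
    """
    residues = record.residues
    base = 0
    if region is not None:
        lo, hi = region
        if not 1 <= lo <= hi <= len(residues):
            raise ValueError(f"region {region} outside sequence 1..{len(residues)}")
        residues = residues[lo - 1 : hi]
        base = lo - 1
    rx = _compile(pattern.canonical())
    offsets = pattern.anchor_offsets
    hits = []
    for m in rx.finditer(residues):
        start = base + m.start() + 1
        text = m.group(1)
        hits.append(
            MatchHit(
                sequence_id=record.id,
                start=start,
                end=start + pattern.span - 1,
                anchor_positions=tuple(start + o for o in offsets),
                matched_text=text,
            )
        )
    return hits


def scan_fasta(
    pattern: MotifPattern,
    proteome: Union[str, Path, Iterable[SequenceRecord]],
) -> ScanReport:
    """Scan every record of a multi-FASTA file (or record iterable)."""
    if isinstance(proteome, (str, Path)):
        records = read_fasta(proteome)
    else:
        records = list(proteome)
    seen = set()
    for r in records:
        if r.id in seen:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)
    span = pattern.span
    n_windows = sum(max(0, len(r) - span + 1) for r in records)
    hits: list[MatchHit] = []
    for r in records:
        hits.extend(scan_sequence(pattern, r))
    return ScanReport(pattern=pattern, n_sequences=len(records), n_windows=n_windows, hits=hits)


def read_fasta(path: Union[str, Path]) -> list[SequenceRecord]:
    """Read a multi-FASTA file; record id is the first header token."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not str(rec.seq):
            raise ValueError(f"record {rec.id!r} has an empty sequence")
        records.append(
            SequenceRecord(id=rec.id, residues=str(rec.seq), description=rec.description)
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[SequenceRecord], path: Union[str, Path]) -> None:
    """Write records as FASTA, wrapped at 60 columns."""
    seqrecords = []
    for r in records:
        desc = r.description
        if desc.startswith(r.id):
            desc = desc[len(r.id) :].strip()
        seqrecords.append(SeqRecord(Seq(r.residues), id=r.id, description=desc))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=60)
        writer.write_file(seqrecords)


def report_to_tsv(report: ScanReport, path: Union[str, Path]) -> None:
    """Write hits as TSV with a ``#``-commented summary footer."""
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tend\tanchors\tmatched_text\n")
        for h in report.hits:
            anchors = ";".join(str(a) for a in h.anchor_positions)
            fh.write(f"{h.sequence_id}\t{h.start}\t{h.end}\t{anchors}\t{h.matched_text}\n")
        for key, value in report.summary().items():
            fh.write(f"# {key}: {value}\n")
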