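"""Case-table analysis: filament folds versus TMEM106B genotype.

The packaged table transcribes the 25 brain donors whose filament
structures were solved: diagnosis, age at death, rs3173615 genotype
(T185S; threonine or serine at residue 185) and the filament types
observed, labelled by protofilament fold (I, IIa/IIb, III) and by whether
a filament comprises one (``-s``) or two (``-d``) protofilaments.

The module reproduces the fold/genotype tabulations (fold III is strongly
enriched for S/S homozygotes) and quantifies them with Fisher's exact
test, implemented as an exact hypergeometric enumeration in integer
arithmetic.

Filament-type percentages reflect picked cryo-EM segments, not brain
content; they are carried as annotation and excluded from all statistics.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Sequence, Union

__all__ = [
    "CaseRecord",
    "FilamentType",
    "CrossTab",
    "FoldCensus",
    "load_case_table",
    "crosstab",
    "fisher_exact",
    "summarize_folds",
]

GENOTYPES = ("T/T", "T/S", "S/S")
FOLD_LABELS = ("I", "II", "IIa", "IIb", "III")


@dataclass(frozen=True)
class FilamentType:
    """One observed filament type, e.g. ``I-s`` at 21% of picked segments.

    ``percent`` is numeric ( ``<1`` in the source is stored as 0.5 with the
    raw token preserved); it annotates segment abundance only.
    """

    label: str
    percent: float
    raw_percent: str

    def __post_init__(self) -> None:
        fold, _, form = self.label.partition("-")
        if fold not in FOLD_LABELS or form not in ("s", "d"):
            raise ValueError(f"malformed filament type label {self.label!r}")
        if not 0.0 <= self.percent <= 100.0:
            raise ValueError(f"percentage {self.percent} outside [0, 100]")

    @property
    def fold(self) -> str:
        """Protofilament fold with IIa/IIb collapsed to II."""
        fold = self.label.partition("-")[0]
        return "II" if fold in ("IIa", "IIb") else fold

    @property
    def subtype(self) -> str:
        return self.label.partition("-")[0]

    @property
    def n_protofilaments(self) -> int:
        return 1 if self.label.endswith("-s") else 2


@dataclass(frozen=True)
class CaseRecord:
    """One donor: diagnosis, age, T185S genotype, observed filament types."""

    case_id: int
    disease: str
    age: int
    genotype: str
    filament_types: tuple[FilamentType, ...]
    other_filaments: str = ""

    def __post_init__(self) -> None:
        if not 1 <= self.case_id <= 25:
            raise ValueError(f"case id {self.case_id} outside 1..25")
        if self.genotype not in GENOTYPES:
            raise ValueError(f"unknown genotype {self.genotype!r}")
        if not self.filament_types:
            raise ValueError(f"case {self.case_id} lists no filament types")

    @property
    def is_control(self) -> bool:
        return self.disease.lower() == "control"

    def folds(self, collapse_subtypes: bool = True) -> frozenset[str]:
        """Distinct protofilament folds this case shows (once per case)."""
        if collapse_subtypes:
            return frozenset(ft.fold for ft in self.filament_types)
        return frozenset(ft.subtype for ft in self.filament_types)


def _parse_percent(token: str) -> tuple[float, str]:
    token = token.strip().rstrip("%")
    if token.startswith("<"):
        bound = float(token[1:])
        return bound / 2.0, token
    value = float(token)
    return value, token


def _normalize_genotype(token: str) -> str:
    token = token.strip().upper().replace("/", "")
    if sorted(token) == sorted("TS"):
        return "T/S"  # heterozygote order fixed
    if token == "TT":
        return "T/T"
    if token == "SS":
        return "S/S"
    raise ValueError(f"unknown genotype token {token!r}")


def _packaged_table() -> Path:
    return resources.files("filamentid.data") / "table1.tsv"


def load_case_table(path: Union[str, Path, None] = None) -> list[CaseRecord]:
    """Load a case table TSV (the packaged transcription by default).

    Columns: case_id, disease, age, genotype, filament_types
    (semicolon-separated ``label:percent``), other_filaments.
    """
    source = _packaged_table() if path is None else Path(path)
    with open(source) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise ValueError(f"case table {source} is empty")
        required = {"case_id", "disease", "age", "genotype", "filament_types"}
        missing = required - set(reader.fieldnames)
        if missing:
            raise ValueError(f"case table is missing columns {sorted(missing)}")
        records: list[CaseRecord] = []
        seen_ids: set[int] = set()
        for row in reader:
            case_id = int(row["case_id"])
            if case_id in seen_ids:
                raise ValueError(f"duplicate case id {case_id}")
            seen_ids.add(case_id)
            types = []
            for part in row["filament_types"].split(";"):
                label, _, pct = part.strip().partition(":")
                value, raw = _parse_percent(pct)
                types.append(FilamentType(label=label.strip(), percent=value, raw_percent=raw))
            records.append(
                CaseRecord(
                    case_id=case_id,
                    disease=row["disease"].strip(),
                    age=int(row["age"]),
                    genotype=_normalize_genotype(row["genotype"]),
                    filament_types=tuple(types),
                    other_filaments=(row.get("other_filaments") or "").strip(),
                )
            )
    if not records:
        raise ValueError(f"case table {source} has no data rows")
    return records


@dataclass(frozen=True)
class CrossTab:
    """A labelled 2x2 contingency table with margins."""

    row_factor: str
    col_factor: str
    counts: tuple[tuple[int, int], tuple[int, int]]

    @property
    def row_margins(self) -> tuple[int, int]:
        (a, b), (c, d) = self.counts
        return (a + b, c + d)

    @property
    def col_margins(self) -> tuple[int, int]:
        (a, b), (c, d) = self.counts
        return (a + c, b + d)

    @property
    def total(self) -> int:
        return sum(self.row_margins)


def crosstab(
    records: Sequence[CaseRecord],
    fold: str,
    predicate: Union[str, Callable[[CaseRecord], bool]],
    collapse_subtypes: bool = True,
) -> CrossTab:
    """2x2 table of (shows fold, does not) x (predicate true, false).

    ``predicate`` may be a genotype string (e.g. ``"S/S"``) or any callable
    on a :class:`CaseRecord`.  A case counts once per fold no matter how
    many filament types of that fold it shows.
    """
    if not records:
        raise ValueError("no case records")
    if isinstance(predicate, str):
        genotype = _normalize_genotype(predicate)
        col_name = f"genotype == {genotype}"
        test = lambda r: r.genotype == genotype  # noqa: E731
    else:
        col_name = getattr(predicate, "__name__", "predicate")
        test = predicate
    a = b = c = d = 0
    for r in records:
        has_fold = fold in r.folds(collapse_subtypes=collapse_subtypes)
        if has_fold and test(r):
            a += 1
        elif has_fold:
            b += 1
        elif test(r):
            c += 1
        else:
            d += 1
    return CrossTab(row_factor=f"fold {fold}", col_factor=col_name, counts=((a, b), (c, d)))


def _table_cells(table) -> tuple[int, int, int, int]:
    if isinstance(table, CrossTab):
        (a, b), (c, d) = table.counts
    else:
        (a, b), (c, d) = table
    cells = (a, b, c, d)
    for x in cells:
        if isinstance(x, float) and not x.is_integer():
            raise ValueError(f"non-integer cell {x}")
    cells = tuple(int(x) for x in cells)
    if any(x < 0 for x in cells):
        raise ValueError("negative cell count")
    return cells


def fisher_exact(table, alternative: str = "two-sided") -> float:
    """Fisher's exact test for a 2x2 table, by full hypergeometric enumeration.

    Conditional on the margins, the top-left cell A follows a
    hypergeometric distribution.  ``greater``/``less`` sum the upper/lower
    tail in A; ``two-sided`` sums the probability of every table whose
    point probability does not exceed the observed one.  All arithmetic is
    exact (integer binomial coefficients), so ties in the two-sided rule
    are resolved without floating-point slack.
    """
    a, b, c, d = _table_cells(table)
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    # integer weights proportional to the hypergeometric pmf
    weights = {k: math.comb(r1, k) * math.comb(r2, c1 - k) for k in range(lo, hi + 1)}
    total = math.comb(n, c1)
    observed = weights[a]
    if alternative == "two-sided":
        numer = sum(w for w in weights.values() if w <= observed)
    elif alternative == "greater":
        numer = sum(w for k, w in weights.items() if k >= a)
    elif alternative == "less":
        numer = sum(w for k, w in weights.items() if k <= a)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return numer / total


@dataclass(frozen=True)
class FoldCensus:
    """Summary of fold occurrence across cases."""

    n_cases: int
    n_disease: int
    n_controls: int
    fold_case_counts: dict
    fold_genotype_counts: dict
    fold_protofilament_counts: dict

    @property
    def n_folds(self) -> int:
        return len(self.fold_case_counts)

    def summary(self) -> dict:
        return {
            "n_cases": self.n_cases,
            "n_disease": self.n_disease,
            "n_controls": self.n_controls,
            "n_folds": self.n_folds,
            "fold_case_counts": dict(self.fold_case_counts),
            "fold_genotype_counts": {k: dict(v) for k, v in self.fold_genotype_counts.items()},
            "fold_protofilament_counts": {
                k: dict(v) for k, v in self.fold_protofilament_counts.items()
            },
        }


def summarize_folds(
    records: Sequence[CaseRecord], collapse_subtypes: bool = True
) -> FoldCensus:
    """Census of folds: case counts, genotype breakdown and single- versus
    double-protofilament occurrence per fold."""
    if not records:
        raise ValueError("no case records")
    fold_cases: dict[str, int] = {}
    fold_genotypes: dict[str, dict[str, int]] = {}
    fold_protos: dict[str, dict[str, int]] = {}
    for r in records:
        for fold in sorted(r.folds(collapse_subtypes=collapse_subtypes)):
            fold_cases[fold] = fold_cases.get(fold, 0) + 1
            geno = fold_genotypes.setdefault(fold, {g: 0 for g in GENOTYPES})
            geno[r.genotype] += 1
        for ft in r.filament_types:
            key = ft.fold if collapse_subtypes else ft.subtype
            proto = fold_protos.setdefault(key, {"single": 0, "double": 0})
            proto["single" if ft.n_protofilaments == 1 else "double"] += 1
    return FoldCensus(
        n_cases=len(records),
        n_disease=sum(1 for r in records if not r.is_control),
        n_controls=sum(1 for r in records if r.is_control),
        fold_case_counts=dict(sorted(fold_cases.items())),
        fold_genotype_counts=dict(sorted(fold_genotypes.items())),
        fold_protofilament_counts=dict(sorted(fold_protos.items())),
    )
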