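"""Domain types and file I/O for family rosters and sibship tables.

A *roster* is one row per surveyed relative of a proband family: the family
identifier, the study arm (``case``/``control``), the relative class
(parent, sibling, ... maternal cousin), and a binary affection status
(diagnosed in hospital before the survey).  A *sibship table* aggregates
sibling households by size: total siblings ``T``, affected siblings ``R``,
households with exactly one affected sibling ``J`` and with exactly two
``Q`` — the quantities the modified-Weinberg segregation estimator consumes.

Rosters are CSV (comma-delimited, header mandatory, ``affected`` encoded
0/1); sibship tables are TSV with five integer columns.  Both are UTF-8 and
newline-terminated.
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Iterable, Sequence

__all__ = [
    "Group",
    "RelativeClass",
    "RelativeRecord",
    "PrevalenceCell",
    "SibshipRecord",
    "SibshipTable",
    "RosterFormatError",
    "SibshipConsistencyError",
    "read_roster",
    "write_roster",
    "read_sibship_table",
    "write_sibship_table",
]


class RosterFormatError(ValueError):
    """Malformed roster or sibship file (missing column, bad value...)."""


class SibshipConsistencyError(ValueError):
    """Aggregated sibship counts violate J <= R <= T or a per-row bound."""


class Group(str, enum.Enum):
    """Study arm of a proband family in the matched design."""

    case = "case"
    control = "control"


class RelativeClass(enum.Enum):
    """Closed vocabulary of relative classes with degree and relatedness.

    ``degree`` is the classical degree of relationship and ``relatedness_r``
    the genetic similarity coefficient (expected fraction of alleles shared
    identical by descent): 1/2, 1/4 and 1/8 for first-, second- and
    third-degree relatives.  The vocabulary is closed on purpose — an
    unknown label would otherwise be silently mis-weighted in the
    heritability formula.
    """

    parent = ("parent", 1, Fraction(1, 2))
    sibling = ("sibling", 1, Fraction(1, 2))
    offspring = ("offspring", 1, Fraction(1, 2))
    paternal_sibling = ("paternal_sibling", 2, Fraction(1, 4))
    maternal_sibling = ("maternal_sibling", 2, Fraction(1, 4))
    paternal_cousin = ("paternal_cousin", 3, Fraction(1, 8))
    maternal_cousin = ("maternal_cousin", 3, Fraction(1, 8))

    def __init__(self, label: str, degree: int, relatedness_r: Fraction):
        self.label = label
        self.degree = degree
        self.relatedness_r = relatedness_r

    @classmethod
    def from_label(cls, label: str) -> "RelativeClass":
        try:
            return cls[label.strip()]
        except KeyError:
            known = ", ".join(m.name for m in cls)
            raise RosterFormatError(
                f"unknown relative class {label!r}; known classes: {known}"
            ) from None


#: relatedness coefficient per degree, for degree-level estimation
RELATEDNESS_BY_DEGREE = {1: Fraction(1, 2), 2: Fraction(1, 4), 3: Fraction(1, 8)}


@dataclass(frozen=True)
class RelativeRecord:
    """One surveyed relative of one proband family."""

    family_id: str
    group: Group
    relative_class: RelativeClass
    affected: bool

    def __post_init__(self):
        if not isinstance(self.affected, bool):
            raise RosterFormatError(
                f"affected must be strictly binary, got {self.affected!r}"
            )


@dataclass(frozen=True)
class PrevalenceCell:
    """Counts and exact prevalence for one group x stratum cell.

    ``q`` is kept as an exact rational of the two counts; rounding happens
    only at presentation.  An empty stratum (``n_total == 0``) carries
    ``q is None`` and is never reported as a silent 0/0.
    """

    n_total: int
    n_affected: int

    def __post_init__(self):
        if not (0 <= self.n_affected <= self.n_total):
            raise ValueError(
                f"need 0 <= n_affected <= n_total, got {self.n_affected}/{self.n_total}"
            )

    @property
    def q(self) -> Fraction | None:
        if self.n_total == 0:
            return None
        return Fraction(self.n_affected, self.n_total)

    @property
    def empty(self) -> bool:
        return self.n_total == 0

    def __add__(self, other: "PrevalenceCell") -> "PrevalenceCell":
        return PrevalenceCell(
            self.n_total + other.n_total, self.n_affected + other.n_affected
        )


@dataclass(frozen=True)
class SibshipRecord:
    """Aggregated counts for all sibling households of one size.

    ``size`` is siblings per household (proband included), ``households``
    how many such households were surveyed, ``cases_among_siblings`` the
    total affected siblings across them, and the last two fields the counts
    of households with exactly one and exactly two affected siblings.
    """

    size: int
    households: int
    cases_among_siblings: int
    households_single_case: int
    households_two_cases: int

    def __post_init__(self):
        if self.size < 1:
            raise SibshipConsistencyError(f"sibship size must be >= 1, got {self.size}")
        for name in ("households", "cases_among_siblings",
                     "households_single_case", "households_two_cases"):
            if getattr(self, name) < 0:
                raise SibshipConsistencyError(f"{name} must be non-negative")
        if self.cases_among_siblings > self.size * self.households:
            raise SibshipConsistencyError(
                f"size {self.size}: {self.cases_among_siblings} cases exceed "
                f"{self.size} x {self.households} sibling slots"
            )
        if self.households_single_case + self.households_two_cases > self.households:
            raise SibshipConsistencyError(
                f"size {self.size}: single-case + two-case households exceed "
                f"household count {self.households}"
            )
        if self.households_single_case > self.cases_among_siblings:
            raise SibshipConsistencyError(
                f"size {self.size}: more single-case households than cases"
            )

    @property
    def total_siblings(self) -> int:
        return self.size * self.households


@dataclass(frozen=True)
class SibshipTable:
    """Aggregate T, R, J, Q for the segregation estimator, plus the rows.

    ``T`` is the total number of siblings, ``R`` the affected siblings,
    ``J`` the households with exactly one affected sibling and ``Q`` those
    with exactly two.  Build via :meth:`from_rows` (totals summed from the
    per-size rows) or :meth:`from_totals` (published aggregate only; rows
    empty).  Published tables often print only a global two-case count — or
    none — so ``from_rows`` accepts a ``q_override`` that replaces the
    per-row sum as the table-level Q.
    """

    T: int
    R: int
    J: int
    Q: int
    rows: tuple[SibshipRecord, ...] = ()
    households: int | None = None

    def __post_init__(self):
        if not (0 <= self.J <= self.R <= self.T):
            raise SibshipConsistencyError(
                f"need 0 <= J <= R <= T, got T={self.T}, R={self.R}, J={self.J}"
            )
        if self.Q < 0:
            raise SibshipConsistencyError(f"Q must be non-negative, got {self.Q}")

    @classmethod
    def from_rows(cls, rows: Iterable[SibshipRecord],
                  q_override: int | None = None) -> "SibshipTable":
        rows = tuple(rows)
        q_sum = sum(r.households_two_cases for r in rows)
        return cls(
            T=sum(r.total_siblings for r in rows),
            R=sum(r.cases_among_siblings for r in rows),
            J=sum(r.households_single_case for r in rows),
            Q=q_sum if q_override is None else q_override,
            rows=rows,
            households=sum(r.households for r in rows),
        )

    @classmethod
    def from_totals(cls, T: int, R: int, J: int, Q: int = 0,
                    households: int | None = None) -> "SibshipTable":
        """Carry published aggregate counts without a per-size breakdown."""
        return cls(T=T, R=R, J=J, Q=Q, rows=(), households=households)


# ---------------------------------------------------------------------------
# roster I/O

ROSTER_COLUMNS = ("family_id", "group", "relative_class", "affected")


def read_roster(path: str | Path, delimiter: str = ",") -> list[RelativeRecord]:
    """Read a roster CSV into validated :class:`RelativeRecord` rows.

    The header must name the four columns ``family_id, group,
    relative_class, affected`` (extra columns are ignored); ``affected`` is
    0/1.  Errors carry the line number of the offending row.
    """
    path = Path(path)
    records: list[RelativeRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            raise RosterFormatError(f"{path}: empty file, expected a header row")
        missing = [c for c in ROSTER_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise RosterFormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            raw = row["affected"].strip()
            if raw not in ("0", "1"):
                raise RosterFormatError(
                    f"{path}:{lineno}: affected must be 0 or 1, got {raw!r}"
                )
            try:
                group = Group(row["group"].strip())
            except ValueError:
                raise RosterFormatError(
                    f"{path}:{lineno}: group must be 'case' or 'control', "
                    f"got {row['group']!r}"
                ) from None
            try:
                rel = RelativeClass.from_label(row["relative_class"])
            except RosterFormatError as exc:
                raise RosterFormatError(f"{path}:{lineno}: {exc}") from None
            records.append(
                RelativeRecord(
                    family_id=row["family_id"].strip(),
                    group=group,
                    relative_class=rel,
                    affected=raw == "1",
                )
            )
    return records


def write_roster(records: Sequence[RelativeRecord], path: str | Path) -> None:
    """Write records as roster CSV; ``read_roster`` round-trips exactly."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(ROSTER_COLUMNS)
        for rec in records:
            writer.writerow(
                [rec.family_id, rec.group.value, rec.relative_class.name,
                 int(rec.affected)]
            )


# ---------------------------------------------------------------------------
# sibship I/O

SIBSHIP_COLUMNS = (
    "size",
    "households",
    "cases_among_siblings",
    "households_single_case",
    "households_two_cases",
)


def read_sibship_table(
    path: str | Path,
    q_absent: bool = False,
    q_total: int | None = None,
) -> SibshipTable:
    """Read a five-column TSV of sibship rows and aggregate T, R, J, Q.

    With ``q_absent`` the fifth column may be omitted from the file; per-row
    two-case counts are set to zero and ``q_total`` must then supply the
    table-level Q explicitly.
    """
    path = Path(path)
    if q_absent and q_total is None:
        raise RosterFormatError(
            "q_absent requires the table-level Q via q_total "
            "(households_two_cases column is absent from the file)"
        )
    rows: list[SibshipRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise RosterFormatError(f"{path}: empty file, expected a header row")
        required = SIBSHIP_COLUMNS[:4] if q_absent else SIBSHIP_COLUMNS
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise RosterFormatError(
                f"{path}: missing required column(s): {', '.join(missing)}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                values = {c: int(row[c]) for c in required}
            except ValueError:
                raise RosterFormatError(
                    f"{path}:{lineno}: all sibship fields must be integers"
                ) from None
            if q_absent:
                values["households_two_cases"] = 0
            try:
                rows.append(SibshipRecord(**values))
            except SibshipConsistencyError as exc:
                raise SibshipConsistencyError(f"{path}:{lineno}: {exc}") from None
    return SibshipTable.from_rows(rows, q_override=q_total)


def write_sibship_table(table: SibshipTable, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(SIBSHIP_COLUMNS)
        for row in table.rows:
            writer.writerow(
                [row.size, row.households, row.cases_among_siblings,
                 row.households_single_case, row.households_two_cases]
            )
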