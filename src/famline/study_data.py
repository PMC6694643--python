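"""Bundled aggregate counts from a published matched case-control family
study of essential hypertension (342 case and 342 control probands, Han
population, Shanghai; 8599 surveyed relatives).

These constants let the full pipeline run — and its published headline
numbers be recomputed — without any external data:

* ``PREVALENCE_COUNTS`` — surveyed relatives and affected counts per study
  arm and relative class, as published.
* ``SIBSHIP_TOTALS`` / ``SIBSHIP_Q`` — the aggregate sibship counts behind
  the segregation analysis: T = 2013 siblings, R = 891 affected, J = 580
  single-case households over 684 households, with the published two-case
  count Q = 163 (printed only as an aggregate, never per row; note
  J + Q exceeds the household count, so Q is carried as a table-level
  override exactly as published rather than re-derived).
* ``SIBSHIP_ROWS`` — a per-size breakdown whose first two rows are the
  published ones; the remaining rows are SYNTHETIC fillers chosen only to
  satisfy the per-row invariants and reproduce the published totals (the
  source's middle rows are not unambiguously legible).  Every estimator in
  this package consumes the totals only.
* ``DEVIATE_TABLE`` — the (x, a) threshold/mean deviates the original
  analysis looked up per prevalence from a simplified Falconer table.
  Several entries differ from exact normal-theory deviates at the same
  prevalence by more than rounding; the table reproduces the published
  arithmetic verbatim, while exact mode recomputes from theory.
"""

from __future__ import annotations

from .roster_model import (
    Group,
    RelativeClass,
    RelativeRecord,
    SibshipRecord,
    SibshipTable,
)

__all__ = [
    "N_PROBANDS_PER_ARM",
    "PREVALENCE_COUNTS",
    "SIBSHIP_TOTALS",
    "SIBSHIP_Q",
    "SIBSHIP_ROWS",
    "DEVIATE_TABLE",
    "DEGREE_PREVALENCES",
    "reference_roster",
    "reference_sibships",
]

N_PROBANDS_PER_ARM = 342

#: (n_total, n_affected) per (group, relative class)
PREVALENCE_COUNTS: dict[tuple[Group, RelativeClass], tuple[int, int]] = {
    (Group.control, RelativeClass.parent): (570, 203),
    (Group.control, RelativeClass.sibling): (704, 217),
    (Group.control, RelativeClass.offspring): (440, 33),
    (Group.control, RelativeClass.paternal_sibling): (791, 123),
    (Group.control, RelativeClass.maternal_sibling): (740, 107),
    (Group.control, RelativeClass.paternal_cousin): (176, 14),
    (Group.control, RelativeClass.maternal_cousin): (825, 97),
    (Group.case, RelativeClass.parent): (583, 314),
    (Group.case, RelativeClass.sibling): (670, 332),
    (Group.case, RelativeClass.offspring): (419, 67),
    (Group.case, RelativeClass.paternal_sibling): (802, 168),
    (Group.case, RelativeClass.maternal_sibling): (770, 148),
    (Group.case, RelativeClass.paternal_cousin): (175, 32),
    (Group.case, RelativeClass.maternal_cousin): (934, 142),
}

SIBSHIP_TOTALS = {"T": 2013, "R": 891, "J": 580, "households": 684}
SIBSHIP_Q = 163

#: per-size sibship rows: (size, households, cases, single-case, two-case).
#: Rows for sizes 1 and 2 are as published; the rest are SYNTHETIC fillers
#: preserving the published totals.  Per-row two-case counts are zero
#: because the source prints Q only as an aggregate (see SIBSHIP_Q).
SIBSHIP_ROWS: tuple[tuple[int, int, int, int, int], ...] = (
    (1, 167, 167, 167, 0),
    (2, 163, 154, 129, 0),
    (3, 119, 150, 110, 0),      # synthetic
    (4, 106, 170, 100, 0),      # synthetic
    (5, 75, 130, 44, 0),        # synthetic
    (6, 44, 90, 24, 0),         # synthetic
    (10, 10, 30, 6, 0),         # synthetic
)

#: published (x, a) lookups per prevalence, keyed by prevalence fraction
DEVIATE_TABLE: dict[float, tuple[float, float]] = {
    0.2643: (0.681, 1.278),   # control, first degree
    0.4264: (0.251, 0.962),   # case, first degree
    0.1502: (1.062, 1.575),   # control, second degree
    0.2010: (0.845, 1.406),   # case, second degree
    0.1109: (1.301, 1.761),   # control, third degree
    0.1569: (1.089, 1.623),   # case, third degree
}

#: published relative prevalences (fractions) per (group, degree)
DEGREE_PREVALENCES: dict[tuple[Group, int], float] = {
    (Group.control, 1): 0.2643,
    (Group.case, 1): 0.4264,
    (Group.control, 2): 0.1502,
    (Group.case, 2): 0.2010,
    (Group.control, 3): 0.1109,
    (Group.case, 3): 0.1569,
}


def reference_roster() -> list[RelativeRecord]:
    """Expand the published class-level counts into one row per relative.

    Family identifiers are assigned round-robin over the 342 probands per
    arm; within each class the affected relatives come first.  Aggregation
    is invariant to both choices, and the round-robin reproduces the
    published mean family sizes (8599/684 overall, 4353/342 case arm).
    """
    records: list[RelativeRecord] = []
    counters = {Group.case: 0, Group.control: 0}
    for (group, cls), (n_total, n_affected) in PREVALENCE_COUNTS.items():
        for i in range(n_total):
            fam = counters[group] % N_PROBANDS_PER_ARM
            counters[group] += 1
            records.append(
                RelativeRecord(
                    family_id=f"{group.value}_{fam:03d}",
                    group=group,
                    relative_class=cls,
                    affected=i < n_affected,
                )
            )
    return records


def reference_sibships(with_rows: bool = False) -> SibshipTable:
    """The published sibship aggregate, with Q carried as published.

    With ``with_rows`` the partially synthetic per-size breakdown is
    attached; by default only the published totals are carried.
    """
    if with_rows:
        return SibshipTable.from_rows(
            (SibshipRecord(*row) for row in SIBSHIP_ROWS),
            q_override=SIBSHIP_Q,
        )
    return SibshipTable.from_totals(
        T=SIBSHIP_TOTALS["T"],
        R=SIBSHIP_TOTALS["R"],
        J=SIBSHIP_TOTALS["J"],
        Q=SIBSHIP_Q,
        households=SIBSHIP_TOTALS["households"],
    )
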