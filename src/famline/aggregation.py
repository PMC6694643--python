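"""Collapse a roster into prevalence tables and run association tests.

The central object is the :class:`PrevalenceTable`: counts and exact
prevalences per (group, stratum) cell, where a stratum is a relative class,
a degree of relationship, or ``all`` relatives pooled.  Class cells sum to
degree cells sum to the pooled cell, for totals and affected counts alike.

The shipped association test for a case-vs-control 2x2 is the standard
Pearson chi-square with one degree of freedom (optionally Yates-corrected).
A McNemar test on discordant pair counts is available for designs where the
matched-pair structure survives into the table, but is off by default: the
usual published family tables discard pair identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Sequence

from scipy.stats import chi2 as _chi2_dist

from .roster_model import Group, PrevalenceCell, RelativeClass, RelativeRecord

__all__ = [
    "PrevalenceTable",
    "prevalence_by_stratum",
    "pearson_chi2_2x2",
    "mcnemar_chi2",
    "mean_family_size",
]

StratumLevel = Literal["class", "degree", "all"]


@dataclass(frozen=True)
class PrevalenceTable:
    """Per-(group, stratum) prevalence cells with optional test results.

    Keys of ``cells`` are ``(Group, stratum)`` where stratum is a
    :class:`RelativeClass`, an int degree, or the string ``"all"``.
    ``tests`` maps a stratum to ``(chi2, p_value)`` for the case-vs-control
    comparison within that stratum.
    """

    level: StratumLevel
    cells: dict[tuple[Group, object], PrevalenceCell]
    tests: dict[object, tuple[float, float]] = field(default_factory=dict)

    def cell(self, group: Group | str, stratum: object) -> PrevalenceCell:
        return self.cells[(Group(group), stratum)]

    def strata(self) -> list[object]:
        return sorted({s for (_, s) in self.cells}, key=_stratum_sort_key)

    def pooled(self, stratum: object) -> PrevalenceCell:
        """Case + control cell for one stratum."""
        return self.cell(Group.case, stratum) + self.cell(Group.control, stratum)

    def to_records(self) -> list[dict]:
        out = []
        for stratum in self.strata():
            for group in (Group.control, Group.case):
                c = self.cell(group, stratum)
                out.append({
                    "stratum": _stratum_name(stratum),
                    "group": group.value,
                    "n_total": c.n_total,
                    "n_affected": c.n_affected,
                    "prevalence_pct": None if c.empty else round(float(c.q) * 100, 2),
                })
            if stratum in self.tests:
                stat, p = self.tests[stratum]
                out[-1]["chi2"] = round(stat, 3)
                out[-1]["p_value"] = p
        return out


def _stratum_sort_key(s):
    if isinstance(s, RelativeClass):
        return (0, s.degree, list(RelativeClass).index(s))
    if isinstance(s, int):
        return (1, s, 0)
    return (2, 0, 0)


def _stratum_name(s) -> str:
    if isinstance(s, RelativeClass):
        return s.name
    if isinstance(s, int):
        return f"degree_{s}"
    return str(s)


def _stratum_of(rec: RelativeRecord, level: StratumLevel):
    if level == "class":
        return rec.relative_class
    if level == "degree":
        return rec.relative_class.degree
    return "all"


def prevalence_by_stratum(
    records: Sequence[RelativeRecord],
    level: StratumLevel = "class",
    with_tests: bool = True,
    yates: bool = False,
) -> PrevalenceTable:
    """Aggregate a roster into a group x stratum prevalence table.

    Every stratum observed in the roster appears for both groups; a group
    with no relatives in a stratum gets an explicit empty cell (``q`` is
    None) rather than a silent 0/0.  With ``with_tests`` a Pearson 2x2 test
    of case vs control affection is attached per stratum wherever both
    margins are positive.
    """
    if not records:
        raise ValueError("empty roster: no relatives to aggregate")
    counts: dict[tuple[Group, object], list[int]] = {}
    for rec in records:
        key = (rec.group, _stratum_of(rec, level))
        tot_aff = counts.setdefault(key, [0, 0])
        tot_aff[0] += 1
        tot_aff[1] += int(rec.affected)
    strata = {s for (_, s) in counts}
    cells = {
        (g, s): PrevalenceCell(*counts.get((g, s), [0, 0]))
        for g in Group for s in strata
    }
    table = PrevalenceTable(level=level, cells=cells)
    if with_tests:
        for s in strata:
            ctrl = table.cell(Group.control, s)
            case = table.cell(Group.case, s)
            a, b = ctrl.n_affected, ctrl.n_total - ctrl.n_affected
            c, d = case.n_affected, case.n_total - case.n_affected
            if min(a + b, c + d, a + c, b + d) > 0:
                table.tests[s] = pearson_chi2_2x2(a, b, c, d, yates=yates)
    return table


def pearson_chi2_2x2(
    a: int, b: int, c: int, d: int, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square for a 2x2 table [[a, b], [c, d]], 1 df.

    Without correction the statistic is N (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)];
    Yates' continuity correction replaces |ad - bc| by
    max(0, |ad - bc| - N/2).  Returns ``(statistic, p_value)``.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("cell counts must be non-negative")
    n = a + b + c + d
    margins = ((a + b), (c + d), (a + c), (b + d))
    if min(margins) == 0:
        raise ZeroDivisionError(
            "chi-square undefined: a table margin is zero"
        )
    cross = abs(a * d - b * c)
    if yates:
        cross = max(0.0, cross - n / 2)
    stat = n * cross**2 / (margins[0] * margins[1] * margins[2] * margins[3])
    return float(stat), float(_chi2_dist.sf(stat, df=1))


def mcnemar_chi2(discordant_case_only: int, discordant_control_only: int,
                 yates: bool = True) -> tuple[float, float]:
    """McNemar test on matched-pair discordant counts, 1 df.

    Applicable only when pair identifiers survive aggregation; most
    published family prevalence tables pool relatives and lose them.
    """
    b, c = discordant_case_only, discordant_control_only
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be non-negative")
    if b + c == 0:
        raise ZeroDivisionError("McNemar undefined with no discordant pairs")
    num = abs(b - c) - 1 if yates else abs(b - c)
    num = max(0.0, num)
    stat = num**2 / (b + c)
    return float(stat), float(_chi2_dist.sf(stat, df=1))


def mean_family_size(
    records: Sequence[RelativeRecord], by_group: bool = False
) -> float | dict[str, float]:
    """Mean surveyed relatives per family (proband excluded).

    With ``by_group`` returns ``{"case": ..., "control": ...}``.
    """
    if not records:
        raise ValueError("empty roster")
    if by_group:
        return {
            g.value: mean_family_size([r for r in records if r.group == g])
            for g in Group
            if any(r.group == g for r in records)
        }
    families = {r.family_id for r in records}
    return len(records) / len(families)
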