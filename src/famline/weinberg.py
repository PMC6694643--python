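"""Modified-Weinberg segregation-ratio estimation from sibship tables.

With T total siblings, R affected siblings, J households containing exactly
one affected sibling and Q households containing exactly two, the
ascertainment-corrected segregation ratio is

    p = (R - J) / (T - J)

i.e. single-case households (which enter the sample only through their
proband) are removed from both numerator and denominator.  Two standard
error conventions are carried, because the classical formula circulates in
two forms that differ in the exponent of (T - J) in the first term:

* ``as_computed`` (default):  SE^2 = (R-J)(T-R)/(T-J)^3 + 2Q(T-R)^2/(T-J)^4
* ``as_printed_formula``:     SE^2 = (R-J)(T-R)/(T-J)^2 + 2Q(T-R)^2/(T-J)^4

``as_computed`` is the binomial-variance-style form that published analyses
actually evaluate; the other reproduces the formula as it is usually
printed.  The 95% CI is the symmetric normal interval p +/- 1.96 SE.

The point estimate is compared with the classical single-gene expectations
(0.5 for dominant, 0.25 for recessive inheritance): a CI entirely below
0.25 is the signature of multigene (polygenic) inheritance.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from fractions import Fraction
from math import sqrt

from .roster_model import SibshipTable

__all__ = [
    "SeMode",
    "InheritanceCall",
    "SegregationResult",
    "segregation_ratio",
    "segregation_se",
    "segregation_ci",
    "classify_inheritance",
    "analyze_sibships",
]

_Z95 = 1.96


class SeMode(str, enum.Enum):
    as_computed = "as_computed"
    as_printed_formula = "as_printed_formula"


class InheritanceCall(str, enum.Enum):
    consistent_dominant = "consistent_dominant"
    consistent_recessive = "consistent_recessive"
    below_recessive_multigene = "below_recessive_multigene"
    inconclusive = "inconclusive"


@dataclass(frozen=True)
class SegregationResult:
    p: Fraction
    se: float
    ci95: tuple[float, float]
    se_mode: SeMode
    classification: InheritanceCall

    def to_dict(self) -> dict:
        return {
            "p": float(self.p),
            "se": self.se,
            "ci95": list(self.ci95),
            "se_mode": self.se_mode.value,
            "classification": self.classification.value,
        }


def segregation_ratio(table: SibshipTable) -> Fraction:
    """Exact rational (R - J) / (T - J); requires T > J."""
    if table.T <= table.J:
        raise ZeroDivisionError(
            f"segregation ratio undefined: no siblings beyond single-case "
            f"households (T={table.T}, J={table.J})"
        )
    return Fraction(table.R - table.J, table.T - table.J)


def segregation_se(table: SibshipTable, se_mode: SeMode = SeMode.as_computed) -> float:
    """Standard error of the segregation ratio under the chosen convention."""
    T, R, J, Q = table.T, table.R, table.J, table.Q
    if T <= J:
        raise ZeroDivisionError(f"SE undefined for T <= J (T={T}, J={J})")
    d = T - J
    first_exponent = 3 if se_mode == SeMode.as_computed else 2
    first = (R - J) * (T - R) / d**first_exponent
    second = 2 * Q * (T - R) ** 2 / d**4
    return sqrt(first + second)


def segregation_ci(p: float | Fraction, se: float) -> tuple[float, float]:
    """Symmetric normal 95% interval p +/- 1.96 SE."""
    if se < 0:
        raise ValueError(f"se must be non-negative, got {se}")
    p = float(p)
    return (p - _Z95 * se, p + _Z95 * se)


def classify_inheritance(
    p: float | Fraction, ci95: tuple[float, float]
) -> InheritanceCall:
    """Compare the estimate with single-gene expectations.

    ``consistent_dominant`` if 0.50 lies in the CI, ``consistent_recessive``
    if 0.25 does, ``below_recessive_multigene`` if the CI sits entirely
    below 0.25 — each returned only when exactly one of the three matches;
    otherwise ``inconclusive``.
    """
    lo, hi = ci95
    if lo > hi:
        raise ValueError(f"invalid interval {ci95}")
    matches = []
    if lo <= 0.50 <= hi:
        matches.append(InheritanceCall.consistent_dominant)
    if lo <= 0.25 <= hi:
        matches.append(InheritanceCall.consistent_recessive)
    if hi < 0.25:
        matches.append(InheritanceCall.below_recessive_multigene)
    if len(matches) == 1:
        return matches[0]
    return InheritanceCall.inconclusive


def analyze_sibships(
    table: SibshipTable, se_mode: SeMode = SeMode.as_computed
) -> SegregationResult:
    """Point estimate, SE, CI and inheritance classification in one call."""
    p = segregation_ratio(table)
    se = segregation_se(table, se_mode)
    ci = segregation_ci(p, se)
    return SegregationResult(
        p=p, se=se, ci95=ci, se_mode=se_mode,
        classification=classify_inheritance(p, ci),
    )
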