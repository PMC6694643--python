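"""Falconer heritability of liability from relative prevalences.

Falconer's method estimates the heritability of liability of a threshold
trait from the difference in prevalence between relatives of cases and
relatives of controls.  With q0 the prevalence among control-group
relatives, q1 among case-group relatives, (x, a) the threshold and mean
deviates at those prevalences, and r the genetic similarity coefficient of
the relative class, the regression of relative liability on proband
liability is

    b = p0 * (x0 - x1) / a0,        p0 = 1 - q0

and heritability is h^2 = b / r.  A second multiplier convention,
``paper_fixed_2``, applies h^2 = 2 b at every degree; some published
analyses use the fixed doubling for second- and third-degree relatives
where 1/r would give 4 b and 8 b.  Both conventions coincide at r = 1/2.

The standard error follows the classical approximation

    SE(h^2) = (1/r) * sqrt( p1 / (A * a1^2) * (p0 / a0)^2 )

where A is the number of case probands and (p1, a1) belong to the
case-relative prevalence q1.  The 95% CI is the symmetric normal interval
h^2 +/- 1.96 SE.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from fractions import Fraction
from math import sqrt
from typing import Mapping

from .liability import ThresholdDeviates, deviates_from_table, threshold_deviates

__all__ = [
    "DeviatesMode",
    "MultiplierMode",
    "FalconerInput",
    "HeritabilityResult",
    "estimate_h2",
    "h2_standard_error",
    "h2_confidence_interval",
]

_Z95 = 1.96

_VALID_R = (Fraction(1, 2), Fraction(1, 4), Fraction(1, 8))


class DeviatesMode(str, enum.Enum):
    """How (x, a) are resolved from a prevalence."""

    exact = "exact"      # normal-theory computation
    table = "table"      # verbatim lookup in a supplied table


class MultiplierMode(str, enum.Enum):
    """Scaling from the liability regression b to h^2."""

    one_over_r = "one_over_r"        # h2 = b / r  (the formula as stated)
    paper_fixed_2 = "paper_fixed_2"  # h2 = 2 b    (fixed doubling at all degrees)


@dataclass(frozen=True)
class FalconerInput:
    """Inputs for one heritability estimate.

    ``A`` (number of case probands) is only needed when a standard error is
    requested.  ``deviate_table`` must be supplied in table mode.
    """

    q0: float
    q1: float
    r: Fraction | float
    A: int | None = None
    deviates_mode: DeviatesMode = DeviatesMode.exact
    multiplier_mode: MultiplierMode = MultiplierMode.one_over_r
    deviate_table: Mapping[float, tuple[float, float]] | None = None

    def __post_init__(self):
        for name, q in (("q0", self.q0), ("q1", self.q1)):
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must lie strictly in (0, 1), got {q}")
        r = Fraction(self.r).limit_denominator(1000)
        if r not in _VALID_R:
            raise ValueError(
                f"r must be one of 1/2, 1/4, 1/8 (got {self.r}); "
                "only first/second/third-degree relatives are supported"
            )
        object.__setattr__(self, "r", r)
        if self.deviates_mode == DeviatesMode.table and self.deviate_table is None:
            raise ValueError("table mode requires a deviate_table")

    def resolve_deviates(self, q: float) -> ThresholdDeviates:
        if self.deviates_mode == DeviatesMode.table:
            return deviates_from_table(q, self.deviate_table)
        return threshold_deviates(q)


@dataclass(frozen=True)
class HeritabilityResult:
    """Point estimate with SE, CI and the conventions that produced it.

    ``h2`` is a fraction (0.4951, not 49.51).  Estimates outside [0, 1] are
    never clamped; ``flags`` records ``out_of_range`` (and ``negative`` when
    q1 < q0) so that model misfit stays visible.
    """

    h2: float
    se: float | None
    ci95: tuple[float, float] | None
    deviates_mode: DeviatesMode
    multiplier_mode: MultiplierMode
    deviates_control: ThresholdDeviates
    deviates_case: ThresholdDeviates
    flags: tuple[str, ...] = field(default_factory=tuple)

    def to_dict(self) -> dict:
        return {
            "h2": self.h2,
            "se": self.se,
            "ci95": list(self.ci95) if self.ci95 is not None else None,
            "deviates_mode": self.deviates_mode.value,
            "multiplier_mode": self.multiplier_mode.value,
            "flags": list(self.flags),
        }


def estimate_h2(inp: FalconerInput) -> HeritabilityResult:
    """Falconer heritability for one relative class, with SE and CI.

    The SE (and hence the CI) is computed only when ``inp.A`` is given.
    """
    d0 = inp.resolve_deviates(inp.q0)
    d1 = inp.resolve_deviates(inp.q1)
    p0 = 1.0 - inp.q0
    b = p0 * (d0.x - d1.x) / d0.a
    if inp.multiplier_mode == MultiplierMode.paper_fixed_2:
        h2 = 2.0 * b
    else:
        h2 = b / float(inp.r)

    flags: list[str] = []
    if h2 < 0.0:
        flags += ["negative"]
    if not 0.0 <= h2 <= 1.0:
        flags += ["out_of_range"]

    se = ci = None
    if inp.A is not None:
        se = h2_standard_error(inp, d0, d1)
        ci = h2_confidence_interval(h2, se)
    return HeritabilityResult(
        h2=h2, se=se, ci95=ci,
        deviates_mode=inp.deviates_mode, multiplier_mode=inp.multiplier_mode,
        deviates_control=d0, deviates_case=d1, flags=tuple(flags),
    )


def h2_standard_error(
    inp: FalconerInput,
    deviates_control: ThresholdDeviates,
    deviates_case: ThresholdDeviates,
) -> float:
    """Classical SE approximation, evaluated as printed in Falconer tables.

    SE = (1/r) * sqrt( p1 / (A a1^2) * (p0 / a0)^2 ), decreasing as
    1 / sqrt(A) in the number of case probands A.
    """
    if inp.A is None or inp.A <= 0:
        raise ValueError(f"A (number of case probands) must be >= 1, got {inp.A}")
    p0 = 1.0 - inp.q0
    p1 = 1.0 - inp.q1
    a0 = deviates_control.a
    a1 = deviates_case.a
    inner = p1 / (inp.A * a1 * a1) * (p0 / a0) ** 2
    return sqrt(inner) / float(inp.r)


def h2_confidence_interval(h2: float, se: float) -> tuple[float, float]:
    """Symmetric normal 95% interval h2 +/- 1.96 SE."""
    if se < 0:
        raise ValueError(f"se must be non-negative, got {se}")
    return (h2 - _Z95 * se, h2 + _Z95 * se)
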