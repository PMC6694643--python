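"""Threshold deviates of the liability-threshold model.

Under the liability-threshold model a binary trait is expressed when an
unobserved standard-normal liability exceeds a threshold.  For a group with
trait prevalence ``q`` the two quantities classical heritability tables
("simplified Falconer tables") report are

* ``x`` — the threshold deviate, the upper-tail standard-normal quantile at
  ``q``: the distance of the threshold from the population mean in SD units,
  Phi(x) = 1 - q;
* ``a`` — the mean deviate of affected individuals, the mean of the standard
  normal truncated to the upper tail: a = phi(x) / q.

Two paths are provided: exact normal-theory computation, and verbatim lookup
in a user-supplied table.  Historical printed tables were coarse — their
entries can differ from the exact deviates at the same prevalence by more
than rounding — so the lookup path exists to reproduce published arithmetic
bit-for-bit, and deliberately refuses to interpolate: silent interpolation
would mask exactly the lookup discrepancies the dual path exists to expose.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

from scipy.stats import norm

__all__ = [
    "ThresholdDeviates",
    "threshold_deviates",
    "deviates_from_table",
    "read_deviate_table",
]

#: rounding applied to prevalences when used as lookup keys
_KEY_DP = 9


@dataclass(frozen=True)
class ThresholdDeviates:
    """Prevalence ``q`` with its threshold deviate ``x`` and mean deviate ``a``."""

    q: float
    x: float
    a: float


def threshold_deviates(q: float) -> ThresholdDeviates:
    """Exact (x, a) for prevalence ``q`` from standard-normal theory.

    Parameters
    ----------
    q : float
        Trait prevalence, strictly between 0 and 1.

    Returns
    -------
    ThresholdDeviates
        x = Phi^-1(1 - q) computed as the upper-tail quantile, and
        a = phi(x) / q, the mean of the upper truncated standard normal.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {q}")
    x = float(norm.isf(q))
    a = float(norm.pdf(x)) / q
    return ThresholdDeviates(q=q, x=x, a=a)


def deviates_from_table(
    q: float, table: Mapping[float, tuple[float, float]]
) -> ThresholdDeviates:
    """Verbatim (x, a) lookup for ``q`` in an explicit prevalence table.

    ``table`` maps prevalence to an ``(x, a)`` pair, e.g. values transcribed
    from a published simplified Falconer table.  The match is exact (keys
    compared after rounding to 9 dp); a missing prevalence raises rather
    than interpolating.
    """
    if not 0.0 < q < 1.0:
        raise ValueError(f"prevalence must lie strictly in (0, 1), got {q}")
    keyed = {round(k, _KEY_DP): v for k, v in table.items()}
    try:
        x, a = keyed[round(q, _KEY_DP)]
    except KeyError:
        raise KeyError(
            f"prevalence {q} not in the supplied deviate table "
            f"(no interpolation; available: {sorted(keyed)})"
        ) from None
    return ThresholdDeviates(q=q, x=float(x), a=float(a))


def read_deviate_table(path: str | Path) -> dict[float, tuple[float, float]]:
    """Read a three-column TSV (q, x, a) into a lookup table."""
    table: dict[float, tuple[float, float]] = {}
    path = Path(path)
    with path.open(encoding="utf-8") as fh:
        header = fh.readline().split()
        if [h.strip().lower() for h in header[:3]] != ["q", "x", "a"]:
            raise ValueError(f"{path}: expected header columns 'q\\tx\\ta'")
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected three columns")
            q, x, a = (float(p) for p in parts[:3])
            table[q] = (x, a)
    return table
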