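"""Liability-threshold simulation of matched case-control family studies.

The generator emulates the sampling design the estimators in this package
assume: an unobserved standard-normal liability per person, a threshold
``t`` fixed by the population prevalence ``K`` (affected iff liability
exceeds ``t``), case probands drawn from the upper truncated liability
distribution and control probands from the lower one (controls are
*screened unaffected*, not population-random), and relatives whose
liabilities correlate with the proband's through ``rho = r * h2`` where
``r`` is the genetic similarity coefficient of the relative class.

Two dependence models are available:

* ``conditional_on_proband`` (default) — each relative's liability is drawn
  as Normal(rho * L_proband, 1 - rho^2), relatives mutually independent
  given the proband.  This is exactly the model under which the Falconer
  regression is unbiased, so parameter-recovery tests are sharp.
* ``full_mvn`` — one joint multivariate-normal draw per family with
  pairwise liability correlation r_ij * h2, where r_ij comes from a
  pedigree built to match the family structure (latent founders included),
  with kinship computed recursively.  Siblings are then correlated with
  each other, not just with the proband.

One root seed derives an independent substream per family, so changing the
family structure or the number of families never shifts another family's
draws.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal

import numpy as np
from scipy.integrate import quad
from scipy.stats import norm

from .roster_model import (
    Group,
    RelativeClass,
    RelativeRecord,
    SibshipRecord,
    SibshipTable,
)

__all__ = [
    "RelativeModel",
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_study",
    "expected_relative_prevalence",
    "simulate_sibships",
    "family_relatedness_matrix",
]

#: family structure matching surveyed mean family sizes of ~12.6 relatives:
#: 5 first-degree, 4 second-degree, 3 third-degree
DEFAULT_STRUCTURE: dict[RelativeClass, int] = {
    RelativeClass.parent: 2,
    RelativeClass.sibling: 2,
    RelativeClass.offspring: 1,
    RelativeClass.paternal_sibling: 2,
    RelativeClass.maternal_sibling: 2,
    RelativeClass.paternal_cousin: 1,
    RelativeClass.maternal_cousin: 2,
}


class RelativeModel(str, enum.Enum):
    conditional_on_proband = "conditional_on_proband"
    full_mvn = "full_mvn"


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated matched case-control family study.

    Defaults mirror a surveyed urban hypertension study population: overall
    relative prevalence K = 0.2322, 342 families per arm, and a family of
    twelve surveyed relatives spanning all three degrees.
    """

    K: float = 0.2322
    h2_true: float = 0.5
    n_case_families: int = 342
    n_control_families: int = 342
    structure: dict[RelativeClass, int] = field(
        default_factory=lambda: dict(DEFAULT_STRUCTURE)
    )
    seed: int = 0
    relative_model: RelativeModel = RelativeModel.conditional_on_proband

    def __post_init__(self):
        if not 0.0 < self.K < 1.0:
            raise ValueError(f"K must lie in (0, 1), got {self.K}")
        if not 0.0 <= self.h2_true <= 1.0:
            raise ValueError(f"h2_true must lie in [0, 1], got {self.h2_true}")
        if self.n_case_families < 0 or self.n_control_families < 0:
            raise ValueError("family counts must be non-negative")
        if any(v < 0 for v in self.structure.values()):
            raise ValueError("structure counts must be non-negative")

    @property
    def threshold(self) -> float:
        return float(norm.isf(self.K))


@dataclass(frozen=True)
class SimulatedStudy:
    """Roster plus sibship table, with the generating config echoed back."""

    roster: list[RelativeRecord]
    sibships: SibshipTable
    truth: SimulationConfig


# ---------------------------------------------------------------------------
# pedigree and kinship for the full-MVN model


def _build_pedigree(structure: dict[RelativeClass, int]):
    """Expand a class-count structure into a pedigree with latent founders.

    Returns ``(parents, observed)``: ``parents`` maps each member index to
    its parent pair (``None`` for founders); ``observed`` lists
    ``(index, RelativeClass)`` for the relatives the roster reports.  Index
    0 is always the proband.  Grandparents, spouses and the parents of
    cousins are latent — present for kinship only.  Each cousin descends
    from its own latent aunt/uncle, so same-side cousins are first cousins
    of each other as well as of the proband.
    """
    parents: list[tuple[int, int] | None] = []
    observed: list[tuple[int, RelativeClass]] = []

    def add(parent_pair=None) -> int:
        parents.append(parent_pair)
        return len(parents) - 1

    pgf, pgm = add(), add()        # paternal grandparents (latent founders)
    mgf, mgm = add(), add()        # maternal grandparents
    father = add((pgf, pgm))
    mother = add((mgf, mgm))
    proband = add((father, mother))
    assert proband == 6
    spouse = add()                 # proband's mate, latent founder

    n = dict(structure)
    for i in range(n.get(RelativeClass.parent, 0)):
        observed.append((father if i == 0 else mother, RelativeClass.parent))
    for _ in range(n.get(RelativeClass.sibling, 0)):
        observed.append((add((father, mother)), RelativeClass.sibling))
    for _ in range(n.get(RelativeClass.offspring, 0)):
        observed.append((add((proband, spouse)), RelativeClass.offspring))
    for side, grands, cls in (
        ("paternal", (pgf, pgm), RelativeClass.paternal_sibling),
        ("maternal", (mgf, mgm), RelativeClass.maternal_sibling),
    ):
        for _ in range(n.get(cls, 0)):
            observed.append((add(grands), cls))
    for grands, cls in (
        ((pgf, pgm), RelativeClass.paternal_cousin),
        ((mgf, mgm), RelativeClass.maternal_cousin),
    ):
        for _ in range(n.get(cls, 0)):
            aunt = add(grands)          # latent, distinct per cousin
            mate = add()                # latent founder
            observed.append((add((aunt, mate)), cls))

    # members move proband to front of the observed-liability ordering
    return parents, observed


def _kinship(parents: list[tuple[int, int] | None]) -> np.ndarray:
    """Kinship matrix by the standard recursion (founders unrelated, F=0)."""
    m = len(parents)
    phi = np.zeros((m, m))
    for i in range(m):               # parents always precede children
        pi = parents[i]
        phi[i, i] = 0.5 if pi is None else 0.5 + 0.5 * phi[pi[0], pi[1]]
        for j in range(i):
            phi[i, j] = phi[j, i] = (
                0.0 if pi is None else 0.5 * (phi[pi[0], j] + phi[pi[1], j])
            )
    return phi


def family_relatedness_matrix(
    structure: dict[RelativeClass, int],
) -> tuple[np.ndarray, list[RelativeClass]]:
    """Pairwise relatedness (2 * kinship) for proband + observed relatives.

    Row/column 0 is the proband; the remaining order matches the returned
    class list.  Used by the ``full_mvn`` model to build the liability
    correlation matrix r_ij * h2.
    """
    parents, observed = _build_pedigree(structure)
    phi = _kinship(parents)
    idx = [6] + [i for i, _ in observed]
    r = 2.0 * phi[np.ix_(idx, idx)]
    np.fill_diagonal(r, 1.0)
    return r, [cls for _, cls in observed]


# ---------------------------------------------------------------------------
# study simulation


def _proband_liability(rng: np.random.Generator, K: float, t: float,
                       affected: bool) -> float:
    """Inverse-CDF draw from the standard normal truncated at t."""
    u = rng.random()
    if affected:
        return float(norm.isf(u * K))          # upper tail (t, inf)
    return float(norm.ppf(u * (1.0 - K)))      # lower tail (-inf, t)


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Simulate a matched case-control family study under the liability model.

    Case probands are affected, control probands unaffected; every relative
    is assigned an affection flag by thresholding its liability at the
    population threshold.  The returned sibship table aggregates the
    case-arm sibling households (proband included), i.e. the sibships a
    segregation analysis of the case arm would tabulate.

    Deterministic given ``config.seed``: repeated calls with an equal config
    yield byte-identical rosters.
    """
    t = config.threshold
    # canonical enum order, matching the pedigree builder's member order
    classes = [c for c in RelativeClass for _ in range(config.structure.get(c, 0))]
    rho = np.array([float(c.relatedness_r) * config.h2_true for c in classes])

    if config.relative_model == RelativeModel.full_mvn:
        r_mat, mvn_classes = family_relatedness_matrix(config.structure)
        assert mvn_classes == classes
        sigma = r_mat * config.h2_true
        np.fill_diagonal(sigma, 1.0)
        # relatives | proband: mean sigma_rp * L_p, cov sigma_rr - sigma_rp sigma_pr
        s_rp = sigma[1:, 0]
        cond_cov = sigma[1:, 1:] - np.outer(s_rp, s_rp)
        try:
            chol = np.linalg.cholesky(
                cond_cov + 1e-12 * np.eye(len(cond_cov))
            )
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "family relatedness matrix does not yield a positive "
                f"semi-definite liability correlation: {exc}"
            ) from exc

    root = np.random.SeedSequence(config.seed)
    arms = [(Group.case, config.n_case_families),
            (Group.control, config.n_control_families)]
    streams = iter(root.spawn(sum(n for _, n in arms)))

    roster: list[RelativeRecord] = []
    sib_rows: list[SibshipRecord] = []
    n_sibs = config.structure.get(RelativeClass.sibling, 0)

    for group, n_fam in arms:
        for i in range(n_fam):
            rng = np.random.default_rng(next(streams))
            fam = f"{group.value}_{i:05d}"
            lp = _proband_liability(rng, config.K, t, group == Group.case)
            if config.relative_model == RelativeModel.full_mvn:
                liab = s_rp * lp + chol @ rng.standard_normal(len(classes))
            else:
                liab = rho * lp + np.sqrt(1.0 - rho**2) * rng.standard_normal(
                    len(classes)
                )
            affected = liab > t
            roster.extend(
                RelativeRecord(family_id=fam, group=group, relative_class=cls,
                               affected=bool(a))
                for cls, a in zip(classes, affected)
            )
            if group == Group.case:
                sib_affected = 1 + sum(
                    int(a) for cls, a in zip(classes, affected)
                    if cls == RelativeClass.sibling
                )  # proband counts as an affected sibling
                sib_rows.append(SibshipRecord(
                    size=n_sibs + 1,
                    households=1,
                    cases_among_siblings=sib_affected,
                    households_single_case=int(sib_affected == 1),
                    households_two_cases=int(sib_affected == 2),
                ))

    return SimulatedStudy(
        roster=roster,
        sibships=SibshipTable.from_rows(_merge_sibship_rows(sib_rows)),
        truth=replace(config, structure=dict(config.structure)),
    )


def _merge_sibship_rows(rows: Iterable[SibshipRecord]) -> list[SibshipRecord]:
    """Collapse per-household rows into one row per sibship size."""
    by_size: dict[int, list[int]] = {}
    for r in rows:
        acc = by_size.setdefault(r.size, [0, 0, 0, 0])
        acc[0] += r.households
        acc[1] += r.cases_among_siblings
        acc[2] += r.households_single_case
        acc[3] += r.households_two_cases
    return [
        SibshipRecord(size=s, households=a[0], cases_among_siblings=a[1],
                      households_single_case=a[2], households_two_cases=a[3])
        for s, a in sorted(by_size.items())
    ]


# ---------------------------------------------------------------------------
# closed-form companion


def expected_relative_prevalence(
    K: float, h2: float, r: float, arm: Literal["case", "control"]
) -> float:
    """Expected relative prevalence under the conditional liability model.

    Integrates P(relative affected | proband liability l)
    = Phi((rho l - t) / sqrt(1 - rho^2)), rho = r h2, against the density of
    the proband liability: standard normal truncated above the threshold for
    the case arm, below it for the control arm.  With h2 = 0 both arms
    return K exactly.
    """
    if not 0.0 < K < 1.0:
        raise ValueError(f"K must lie in (0, 1), got {K}")
    arm = Group(arm)
    rho = r * h2
    if rho == 0.0:
        return K
    if rho >= 1.0:        # degenerate: relative shares the proband's liability
        return 1.0 if arm == Group.case else 0.0
    t = float(norm.isf(K))
    s = np.sqrt(1.0 - rho**2)

    def integrand(l):
        return norm.cdf((rho * l - t) / s) * norm.pdf(l)

    if arm == Group.case:
        val, _ = quad(integrand, t, np.inf)
        return float(val / K)
    val, _ = quad(integrand, -np.inf, t)
    return float(val / (1.0 - K))


# ---------------------------------------------------------------------------
# sibship-only simulation for the segregation estimator


def simulate_sibships(
    config: SimulationConfig,
    ascertainment: Literal["single", "complete"] = "single",
    pi: float = 1.0,
    n_sibships: int | None = None,
    sibship_size: int | None = None,
) -> SibshipTable:
    """Simulate ascertained sibships and aggregate them into T, R, J, Q.

    ``n_sibships`` population sibships (default: the config's case-family
    count) of ``sibship_size`` siblings (default: the structure's sibling
    count + 1, counting the proband slot) are drawn with exchangeable
    liability correlation 0.5 * h2_true.  Ascertainment then decides which
    enter the table:

    * ``complete`` — each affected sibling is independently detected with
      probability ``pi``; the sibship enters iff at least one is detected
      (``pi = 1``: every sibship with an affected member enters).
    * ``single`` — the limit ``pi -> 0``: a sibship enters with probability
      proportional to its number of affected siblings (at most one proband
      per household).
    """
    if not 0.0 < pi <= 1.0:
        raise ValueError(f"pi must lie in (0, 1], got {pi}")
    if ascertainment not in ("single", "complete"):
        raise ValueError(f"unknown ascertainment mode {ascertainment!r}")
    n = config.n_case_families if n_sibships is None else n_sibships
    size = (
        config.structure.get(RelativeClass.sibling, 0) + 1
        if sibship_size is None else sibship_size
    )
    if size < 1:
        raise ValueError(f"sibship size must be >= 1, got {size}")

    t = config.threshold
    rho = 0.5 * config.h2_true
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    # exchangeable correlation via a shared family factor
    shared = np.sqrt(rho) if rho > 0 else 0.0
    unique = np.sqrt(1.0 - rho)
    fam_factor = rng.standard_normal((n, 1))
    liab = shared * fam_factor + unique * rng.standard_normal((n, size))
    affected = (liab > t).sum(axis=1)

    if ascertainment == "single":
        keep = rng.random(n) < affected / size      # acceptance prob ∝ k
    else:
        keep = rng.binomial(affected, pi) >= 1
    k = affected[keep]
    rows = [
        SibshipRecord(
            size=size,
            households=int(len(k)),
            cases_among_siblings=int(k.sum()),
            households_single_case=int((k == 1).sum()),
            households_two_cases=int((k == 2).sum()),
        )
    ] if len(k) else []
    return SibshipTable.from_rows(rows)
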