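"""End-to-end driver: roster -> prevalence -> heritability -> segregation.

``run_pipeline`` chains the stages on user files and returns a
:class:`ReplicationReport`; ``replicate_reference_study`` runs the same
chain on the bundled published counts in fidelity modes (table-lookup
deviates, fixed doubling for the h2 multiplier, the as-computed SE
convention) and so reproduces the published headline numbers end to end.

Reports are deterministic: rerunning on identical inputs yields an
identical report.  Numbers are carried at full precision and rounded only
in the presentation helpers (prevalences to 2 dp, ratios to 3 dp).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Mapping

from . import __version__
from .aggregation import PrevalenceTable, mean_family_size, prevalence_by_stratum
from .falconer import (
    DeviatesMode,
    FalconerInput,
    HeritabilityResult,
    MultiplierMode,
    estimate_h2,
)
from .roster_model import (
    RELATEDNESS_BY_DEGREE,
    Group,
    SibshipTable,
    read_roster,
    read_sibship_table,
)
from .weinberg import SegregationResult, SeMode, analyze_sibships

__all__ = ["RunConfig", "ReplicationReport", "PipelineError",
           "run_pipeline", "replicate_reference_study"]

log = logging.getLogger("famline.pipeline")


class PipelineError(RuntimeError):
    """Stage failure, carrying the stage name and input locus."""

    def __init__(self, stage: str, locus: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed on {locus}: {cause}")
        self.stage = stage
        self.locus = locus
        self.__cause__ = cause


@dataclass(frozen=True)
class RunConfig:
    """Conventions and inputs shared across pipeline stages."""

    deviates_mode: DeviatesMode = DeviatesMode.exact
    multiplier_mode: MultiplierMode = MultiplierMode.one_over_r
    se_mode: SeMode = SeMode.as_computed
    n_case_probands: int | None = None
    deviate_table: Mapping[float, tuple[float, float]] | None = None
    yates: bool = False
    sibship_q_total: int | None = None
    seed: int | None = None


@dataclass(frozen=True)
class ReplicationReport:
    """Joint result of the three analyses plus provenance."""

    prevalence_by_class: PrevalenceTable
    prevalence_by_degree: PrevalenceTable
    prevalence_all: PrevalenceTable
    mean_family_size: float
    mean_family_size_by_group: dict[str, float]
    heritability_by_degree: dict[int, HeritabilityResult]
    segregation: SegregationResult
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "prevalence": {
                "by_class": self.prevalence_by_class.to_records(),
                "by_degree": self.prevalence_by_degree.to_records(),
                "all": self.prevalence_all.to_records(),
                "mean_family_size": round(self.mean_family_size, 2),
                "mean_family_size_by_group": {
                    k: round(v, 2) for k, v in self.mean_family_size_by_group.items()
                },
            },
            "heritability_by_degree": {
                str(d): r.to_dict() for d, r in self.heritability_by_degree.items()
            },
            "segregation": self.segregation.to_dict(),
            "provenance": self.provenance,
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent)


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _heritability_by_degree(
    table: PrevalenceTable, cfg: RunConfig
) -> dict[int, HeritabilityResult]:
    out: dict[int, HeritabilityResult] = {}
    for degree in table.strata():
        q0 = table.cell(Group.control, degree).q
        q1 = table.cell(Group.case, degree).q
        if q0 is None or q1 is None:
            continue
        q0, q1 = float(q0), float(q1)
        if cfg.deviates_mode == DeviatesMode.table:
            # published lookup tables are keyed by rounded prevalence; use
            # the same rounded value throughout to reproduce their arithmetic
            q0, q1 = round(q0, 4), round(q1, 4)
        out[degree] = estimate_h2(FalconerInput(
            q0=q0, q1=q1,
            r=RELATEDNESS_BY_DEGREE[degree],
            A=cfg.n_case_probands,
            deviates_mode=cfg.deviates_mode,
            multiplier_mode=cfg.multiplier_mode,
            deviate_table=cfg.deviate_table,
        ))
    return out


def _assemble(roster, sibships: SibshipTable, cfg: RunConfig,
              provenance: dict) -> ReplicationReport:
    try:
        by_class = prevalence_by_stratum(roster, "class", yates=cfg.yates)
        by_degree = prevalence_by_stratum(roster, "degree", yates=cfg.yates)
        overall = prevalence_by_stratum(roster, "all", yates=cfg.yates)
        mfs = mean_family_size(roster)
        mfs_by_group = mean_family_size(roster, by_group=True)
    except (ValueError, ZeroDivisionError) as exc:
        raise PipelineError("aggregation", provenance.get("roster", "roster"), exc)
    log.info("aggregation: %d relatives, %d strata", len(roster),
             len(by_class.strata()))
    try:
        herit = _heritability_by_degree(by_degree, cfg)
    except (ValueError, KeyError) as exc:
        raise PipelineError("falconer", "degree-level prevalences", exc)
    log.info("falconer: degrees %s", sorted(herit))
    try:
        seg = analyze_sibships(sibships, cfg.se_mode)
    except (ValueError, ZeroDivisionError) as exc:
        raise PipelineError("weinberg", provenance.get("sibships", "sibships"), exc)
    log.info("weinberg: p=%.3f (%s)", float(seg.p), seg.classification.value)
    return ReplicationReport(
        prevalence_by_class=by_class,
        prevalence_by_degree=by_degree,
        prevalence_all=overall,
        mean_family_size=mfs,
        mean_family_size_by_group=mfs_by_group,
        heritability_by_degree=herit,
        segregation=seg,
        provenance=provenance,
    )


def run_pipeline(
    roster_path: str | Path,
    sibship_path: str | Path,
    config: RunConfig = RunConfig(),
) -> ReplicationReport:
    """Run all three analyses on roster and sibship files."""
    roster_path, sibship_path = Path(roster_path), Path(sibship_path)
    try:
        roster = read_roster(roster_path)
    except Exception as exc:
        raise PipelineError("read_roster", str(roster_path), exc)
    try:
        sibships = read_sibship_table(sibship_path, q_total=config.sibship_q_total)
    except Exception as exc:
        raise PipelineError("read_sibship_table", str(sibship_path), exc)
    provenance = {
        "famline_version": __version__,
        "roster": str(roster_path),
        "roster_sha256": _checksum(roster_path),
        "sibships": str(sibship_path),
        "sibships_sha256": _checksum(sibship_path),
        "deviates_mode": config.deviates_mode.value,
        "multiplier_mode": config.multiplier_mode.value,
        "se_mode": config.se_mode.value,
        "seed": config.seed,
    }
    return _assemble(roster, sibships, config, provenance)


def replicate_reference_study() -> ReplicationReport:
    """Re-run the full analysis on the bundled published counts.

    Uses the fidelity conventions under which the published arithmetic is
    reproduced: table-lookup deviates, the fixed doubling multiplier at
    every degree, and the as-computed SE convention for the segregation
    ratio.
    """
    from . import study_data

    cfg = RunConfig(
        deviates_mode=DeviatesMode.table,
        multiplier_mode=MultiplierMode.paper_fixed_2,
        se_mode=SeMode.as_computed,
        n_case_probands=study_data.N_PROBANDS_PER_ARM,
        deviate_table=study_data.DEVIATE_TABLE,
    )
    provenance = {
        "famline_version": __version__,
        "roster": "bundled reference study counts",
        "sibships": "bundled reference study totals",
        "deviates_mode": cfg.deviates_mode.value,
        "multiplier_mode": cfg.multiplier_mode.value,
        "se_mode": cfg.se_mode.value,
    }
    return _assemble(
        study_data.reference_roster(),
        study_data.reference_sibships(),
        cfg,
        provenance,
    )
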