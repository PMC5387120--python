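"""Stratified (subgroup) pooling and leave-one-out sensitivity analysis.

Studies are stratified on one of five study-level covariates — ethnicity,
genotyping method, control source, quality (Newcastle-Ottawa score >= 7 vs
< 7) and publication language — and each stratum is pooled with the same
model as the overall analysis.  Leave-one-out sensitivity re-pools the
comparison n times, omitting one study at a time, to show whether any single
study drives the pooled odds ratio.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .pooling import EffectEstimate, PooledResult, pool, woolf_effect
from .tables import Comparison, StudyRecord, comparison_table

__all__ = [
    "Stratifier",
    "SensitivityReport",
    "stratum_of",
    "study_effects",
    "subgroup_analysis",
    "leave_one_out",
]

NOS_HIGH_QUALITY = 7  # quality stratum boundary: higher = NOS >= 7


class Stratifier(str, Enum):
    ETHNICITY = "ethnicity"
    GENOTYPING_METHOD = "genotyping_method"
    CONTROL_SOURCE = "control_source"
    QUALITY = "quality"
    LANGUAGE = "language"


def stratum_of(study: StudyRecord, stratifier: Stratifier) -> str:
    """The stratum label a study falls in; every study maps to exactly one."""
    stratifier = Stratifier(stratifier)
    if stratifier is Stratifier.QUALITY:
        return "higher" if study.nos_score >= NOS_HIGH_QUALITY else "lower"
    value = getattr(study, stratifier.value)
    if value is None:
        raise ValueError(f"study {study.study_id}: missing {stratifier.value}")
    return value.value


def study_effects(studies: Sequence[StudyRecord], comparison: Comparison,
                  correction: float = 0.5) -> list[EffectEstimate]:
    """Woolf effects for every study that reports the comparison's count block."""
    effects = []
    for s in studies:
        table = comparison_table(s, comparison)
        if table is not None:
            effects.append(woolf_effect(table, correction=correction, study_id=s.study_id))
    return effects


def subgroup_analysis(studies: Sequence[StudyRecord], comparison: Comparison,
                      stratifier: Stratifier, model: str = "dl_default",
                      ) -> dict[str, PooledResult]:
    """Pool the comparison within each stratum of one covariate.

    Strata with no study reporting the comparison are omitted; a stratum of
    size one returns the single-study estimate (its heterogeneity is flagged
    undefined in the result).
    """
    strata: dict[str, list[StudyRecord]] = {}
    for s in studies:
        strata.setdefault(stratum_of(s, stratifier), []).append(s)
    out: dict[str, PooledResult] = {}
    for label, members in sorted(strata.items()):
        effects = study_effects(members, comparison)
        if effects:
            out[label] = pool(effects, model=model)
    return out


@dataclass(frozen=True)
class SensitivityReport:
    """Leave-one-out re-poolings keyed by the omitted study."""

    results: tuple[tuple[str, PooledResult], ...]  # (omitted study_id, re-pooled)
    min_or: float
    max_or: float
    stable: bool  # all omissions keep the pooled OR on one side of 1, CIs overlapping

    def __len__(self) -> int:
        return len(self.results)


def leave_one_out(studies: Sequence[StudyRecord], comparison: Comparison,
                  model: str = "dl_default") -> SensitivityReport:
    """Re-pool the comparison once per study, omitting that study.

    Stability requires every re-pooled OR to sit on the same side of 1 and
    all the re-pooled confidence intervals to share a common overlap.
    """
    reporting = [s for s in studies
                 if comparison_table(s, comparison) is not None]
    if len(reporting) < 2:
        raise ValueError("leave_one_out needs >= 2 studies reporting the comparison")
    results = []
    for omit in reporting:
        subset = [s for s in reporting if s.study_id != omit.study_id]
        results.append((omit.study_id, pool(study_effects(subset, comparison), model=model)))
    ors = [r.pooled_or for _, r in results]
    same_side = all(o > 1 for o in ors) or all(o < 1 for o in ors) or all(o == 1 for o in ors)
    ci_overlap = max(r.ci_low for _, r in results) <= min(r.ci_high for _, r in results)
    return SensitivityReport(results=tuple(results), min_or=min(ors), max_or=max(ors),
                             stable=bool(same_side and ci_overlap))
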