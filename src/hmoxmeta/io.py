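"""CSV readers/writers, the packaged study table, and report assembly.

The on-disk interchange format is one UTF-8 CSV row per primary study:
metadata covariates followed by allele, genotype and severity count blocks.
A blank cell means "not reported" (never zero); a block is present only when
every one of its cells is filled.  The packaged fixture encodes the seven
published case-control studies of the HMOX1 promoter (GT)n polymorphism and
COPD verbatim; the severity counts of the four severity studies were only
published as supplementary material and are therefore not included — the
severity comparison is exercised on simulated data.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from . import __version__
from .bias import BiasTestResult, FunnelPoint, bias_tests, funnel_data
from .pooling import EffectEstimate, PooledResult
from .subgroups import (SensitivityReport, Stratifier, leave_one_out,
                        study_effects, subgroup_analysis)
from .tables import (AlleleBlock, Comparison, ControlSource, Ethnicity,
                     GenotypeBlock, GenotypingMethod, InvalidCountsError,
                     Language, SeverityBlock, StudyRecord)

__all__ = [
    "STUDY_COLUMNS",
    "ComparisonSpec",
    "Report",
    "NoDataError",
    "read_studies",
    "write_studies",
    "run_analysis",
    "write_report",
    "fixture_path",
    "load_fixture",
]

log = logging.getLogger("hmoxmeta")

_META_COLUMNS = ["study_id", "year", "ethnicity", "genotyping_method",
                 "control_source", "nos_score", "language"]
_ALLELE_COLUMNS = ["case_S", "case_M", "case_L", "ctrl_S", "ctrl_M", "ctrl_L"]
_GENOTYPE_COLUMNS = ["case_typeI", "case_typeII", "ctrl_typeI", "ctrl_typeII"]
_SEVERITY_COLUMNS = ["less_typeI", "less_typeII", "more_typeI", "more_typeII"]
_SIZE_COLUMNS = ["n_cases", "n_controls"]
STUDY_COLUMNS = (_META_COLUMNS + _ALLELE_COLUMNS + _GENOTYPE_COLUMNS
                 + _SEVERITY_COLUMNS + _SIZE_COLUMNS)


class NoDataError(ValueError):
    """No study in the input reports the requested comparison's counts."""


def fixture_path() -> Path:
    """Path of the packaged table of the seven published studies."""
    return Path(resources.files("hmoxmeta") / "data" / "studies.csv")


def load_fixture() -> list[StudyRecord]:
    return read_studies(fixture_path())


def _cell(row: pd.Series, col: str):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    s = str(v).strip()
    return s if s else None


def _int_cell(row: pd.Series, col: str, rownum: int):
    v = _cell(row, col)
    if v is None:
        return None
    try:
        f = float(v)
        if f != int(f):
            raise ValueError
        return int(f)
    except ValueError:
        raise InvalidCountsError(f"row {rownum}: column {col!r} must be an integer, got {v!r}")


def _block(row: pd.Series, cols: list[str], cls, rownum: int):
    values = {c: _int_cell(row, c, rownum) for c in cols}
    present = [v for v in values.values() if v is not None]
    if not present:
        return None
    if len(present) != len(cols):
        missing = [c for c in cols if values[c] is None]
        raise InvalidCountsError(
            f"row {rownum}: partially reported block — missing {missing}")
    return cls(**values)


def read_studies(path: Union[str, Path]) -> list[StudyRecord]:
    """Read and validate the study CSV; every error names its row number.

    Row numbers in messages count the header as row 1, so the first data row
    is row 2 — matching what a spreadsheet shows.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise NoDataError(f"{path}: empty input file")
    if df.empty:
        raise NoDataError(f"{path}: no study rows")
    missing = [c for c in _META_COLUMNS if c not in df.columns]
    if missing:
        raise InvalidCountsError(f"{path}: missing required columns {missing}")

    records: list[StudyRecord] = []
    for i, row in df.iterrows():
        rownum = i + 2
        try:
            record = StudyRecord(
                study_id=str(_cell(row, "study_id")),
                year=_int_cell(row, "year", rownum),
                ethnicity=Ethnicity(_cell(row, "ethnicity")),
                genotyping_method=GenotypingMethod(_cell(row, "genotyping_method")),
                control_source=ControlSource(_cell(row, "control_source")),
                nos_score=_int_cell(row, "nos_score", rownum),
                language=Language(_cell(row, "language")),
                allele_counts=_block(row, _ALLELE_COLUMNS, AlleleBlock, rownum),
                genotype_counts=_block(row, _GENOTYPE_COLUMNS, GenotypeBlock, rownum),
                severity_counts=_block(row, _SEVERITY_COLUMNS, SeverityBlock, rownum),
                n_cases=_int_cell(row, "n_cases", rownum),
                n_controls=_int_cell(row, "n_controls", rownum),
            )
        except (ValueError, InvalidCountsError) as exc:
            raise InvalidCountsError(f"{path} row {rownum}: {exc}") from exc
        records.append(record)
    return records


def write_studies(studies: Sequence[StudyRecord], path: Union[str, Path]) -> Path:
    """Write studies in the same CSV schema :func:`read_studies` consumes."""
    rows = []
    for s in studies:
        row = {c: "" for c in STUDY_COLUMNS}
        row.update(study_id=s.study_id, year=s.year, ethnicity=s.ethnicity.value,
                   genotyping_method=s.genotyping_method.value,
                   control_source=s.control_source.value, nos_score=s.nos_score,
                   language=s.language.value)
        if s.allele_counts:
            for c in _ALLELE_COLUMNS:
                row[c] = getattr(s.allele_counts, c)
        if s.genotype_counts:
            for c in _GENOTYPE_COLUMNS:
                row[c] = getattr(s.genotype_counts, c)
        if s.severity_counts:
            for c in _SEVERITY_COLUMNS:
                row[c] = getattr(s.severity_counts, c)
        if s.n_cases is not None:
            row["n_cases"] = s.n_cases
        if s.n_controls is not None:
            row["n_controls"] = s.n_controls
        rows.append(row)
    path = Path(path)
    pd.DataFrame(rows, columns=STUDY_COLUMNS).to_csv(path, index=False)
    return path


@dataclass(frozen=True)
class ComparisonSpec:
    """What to analyse: contrast, model mode and optional extras."""

    comparison: Comparison
    model: str = "dl_default"            # or "rule_based"
    subgroups: tuple[Stratifier, ...] = ()
    sensitivity: bool = False
    bias: bool = False
    funnel: bool = False


@dataclass
class Report:
    """All outputs of one comparison, with provenance."""

    comparison: Comparison
    overall: PooledResult
    effects: list[EffectEstimate]
    subgroups: dict[str, dict[str, PooledResult]]
    sensitivity: Optional[SensitivityReport]
    bias: Optional[BiasTestResult]
    funnel: Optional[tuple[list[FunnelPoint], Optional[float]]]
    provenance: dict


def _input_hash(studies: Sequence[StudyRecord]) -> str:
    payload = repr([(s.study_id, s.year, s.ethnicity.value, s.genotyping_method.value,
                     s.control_source.value, s.nos_score, s.language.value,
                     s.allele_counts, s.genotype_counts, s.severity_counts,
                     s.n_cases, s.n_controls) for s in studies])
    return hashlib.sha256(payload.encode()).hexdigest()


def run_analysis(studies: Sequence[StudyRecord], spec: ComparisonSpec,
                 seed: Optional[int] = None) -> Report:
    """Run one comparison end to end: pool, stratify, sensitivity, bias."""
    t0 = time.perf_counter()
    from .pooling import pool  # local import avoids a cycle in type checkers
    effects = study_effects(studies, spec.comparison)
    if not effects:
        raise NoDataError(
            f"no study reports counts for comparison {spec.comparison.value!r}")
    overall = pool(effects, model=spec.model)
    log.info("pooled %d studies for %s in %.1f ms", len(effects),
             spec.comparison.value, 1e3 * (time.perf_counter() - t0))

    subgroups: dict[str, dict[str, PooledResult]] = {}
    for strat in spec.subgroups:
        subgroups[Stratifier(strat).value] = subgroup_analysis(
            studies, spec.comparison, strat, model=spec.model)

    sensitivity = None
    if spec.sensitivity and len(effects) >= 2:
        sensitivity = leave_one_out(studies, spec.comparison, model=spec.model)

    bias = bias_tests(effects) if spec.bias else None
    funnel = funnel_data(effects) if spec.funnel else None

    provenance = {
        "package_version": __version__,
        "input_sha256": _input_hash(studies),
        "model_mode": spec.model,
        "comparison": spec.comparison.value,
        "seed": seed,
    }
    return Report(comparison=spec.comparison, overall=overall, effects=effects,
                  subgroups=subgroups, sensitivity=sensitivity, bias=bias,
                  funnel=funnel, provenance=provenance)


def _fmt(x: float) -> float:
    """2-decimal 'printed' view, matching publication precision."""
    return round(float(x), 2)


def _pooled_dict(r: PooledResult) -> dict:
    return {
        "model": r.model.value,
        "n_studies": r.n_studies,
        "pooled_log_or": r.pooled_log_or,
        "pooled_se": r.pooled_se,
        "pooled_or": r.pooled_or,
        "ci_low": r.ci_low,
        "ci_high": r.ci_high,
        "z": r.z,
        "p_value": r.p_value,
        "q": r.q,
        "df": r.df,
        "p_q": r.p_q,
        "i_squared": r.i_squared,
        "tau_squared": r.tau_squared,
        "weights": {sid: w for sid, w in r.weights},
        "printed": {"or": _fmt(r.pooled_or), "ci_low": _fmt(r.ci_low),
                    "ci_high": _fmt(r.ci_high)},
    }


def report_to_dict(report: Report) -> dict:
    out: dict = {
        "comparison": report.comparison.value,
        "provenance": report.provenance,
        "overall": _pooled_dict(report.overall),
        "effects": [
            {"study_id": e.study_id, "log_or": e.log_or, "var": e.var,
             "or": e.or_point, "ci_low": e.ci_low, "ci_high": e.ci_high,
             "corrected": e.corrected}
            for e in report.effects
        ],
    }
    if report.subgroups:
        out["subgroups"] = {strat: {label: _pooled_dict(r) for label, r in strata.items()}
                            for strat, strata in report.subgroups.items()}
    if report.sensitivity is not None:
        out["sensitivity"] = {
            "results": {sid: _pooled_dict(r) for sid, r in report.sensitivity.results},
            "min_or": report.sensitivity.min_or,
            "max_or": report.sensitivity.max_or,
            "stable": report.sensitivity.stable,
        }
    if report.bias is not None:
        out["bias"] = {
            "egger": None if report.bias.egger is None else {
                "intercept": report.bias.egger.intercept, "se": report.bias.egger.se,
                "t": report.bias.egger.t, "df": report.bias.egger.df,
                "p_value": report.bias.egger.p_value},
            "begg": None if report.bias.begg is None else {
                "s": report.bias.begg.s, "var_s": report.bias.begg.var_s,
                "z": report.bias.begg.z, "p_value": report.bias.begg.p_value,
                "n_ties": report.bias.begg.n_ties},
        }
    if report.funnel is not None:
        points, ref = report.funnel
        out["funnel"] = {
            "points": [{"study_id": p.study_id, "or": p.or_point,
                        "log_or": p.log_or, "se": p.se} for p in points],
            "pooled_reference_or": ref,
        }
    return out


def write_report(report: Report, out_dir: Union[str, Path],
                 formats: Sequence[str] = ("json", "tsv")) -> list[Path]:
    """Write report.json plus forest (and funnel) TSVs; deterministic bytes.

    Floats are serialized at full precision alongside a 2-decimal "printed"
    view; the forest table carries per-study OR, CI and weight percentages
    ready for plotting.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stem = report.comparison.value
    if "json" in formats:
        p = out_dir / f"{stem}_report.json"
        p.write_text(json.dumps(report_to_dict(report), indent=2, sort_keys=False) + "\n")
        written.append(p)
    if "tsv" in formats:
        weights = dict(report.overall.weights)
        forest = pd.DataFrame(
            [{"study_id": e.study_id, "or": e.or_point, "ci_low": e.ci_low,
              "ci_high": e.ci_high, "weight_pct": 100.0 * weights.get(e.study_id, 0.0)}
             for e in report.effects])
        p = out_dir / f"{stem}_forest.tsv"
        forest.to_csv(p, sep="\t", index=False)
        written.append(p)
        if report.funnel is not None:
            points, _ = report.funnel
            fp = out_dir / f"{stem}_funnel.tsv"
            pd.DataFrame([{"study_id": q.study_id, "log_or": q.log_or, "se": q.se}
                          for q in points]).to_csv(fp, sep="\t", index=False)
            written.append(fp)
    return written
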