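"""Synthetic case-control study generator with known ground truth.

The generator emulates the data-generating process the meta-analysis assumes:
control genotypes at a tri-allelic (S/M/L) locus drawn from Hardy-Weinberg
proportions; a dominant (carrier) effect of the L allele on case status, so
the exposure is the type I genotype (>= 1 L allele); between-study
heterogeneity as a normal distribution of the study-level carrier log odds
ratio around a grand mean; study-level covariates for the five stratifiers;
and an optional selective-publication rule that suppresses non-significant
studies.

The carrier-level model is primary: allele-level odds ratios *emerge* from
it (case L-allele counts are split between heterozygous and homozygous
carriers using the control HWE conditional) rather than being imposed, so
allele-comparison recovery tests must use the simulator-computed induced
truth, not the carrier log OR itself.

Randomness uses a single root seed with one independent substream per study
(numpy SeedSequence spawning); the seed is a required configuration field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .pooling import woolf_effect
from .tables import (AlleleBlock, Comparison, ControlSource, Ethnicity,
                     GenotypeBlock, GenotypingMethod, Language, SeverityBlock,
                     StudyRecord, comparison_table)

__all__ = [
    "SimulationConfig",
    "PublicationSelection",
    "SimulationTruth",
    "AllStudiesSuppressedError",
    "simulate_study",
    "simulate_meta",
]

SizeSpec = Union[int, tuple[int, int]]


class AllStudiesSuppressedError(RuntimeError):
    """The selective-publication rule removed every generated study."""


@dataclass(frozen=True)
class PublicationSelection:
    """Suppress a study with probability ``suppress_prob`` when its
    genotype-comparison p-value exceeds ``alpha`` (and, if ``max_cases`` is
    set, only when the study is small: n_cases <= max_cases)."""

    suppress_prob: float = 1.0
    alpha: float = 0.05
    max_cases: Optional[int] = None


@dataclass(frozen=True)
class SimulationConfig:
    """Study-generation parameters.

    Defaults mirror the conditions of the real study pool: seven studies,
    case sizes 48-256 and control sizes 30-266 (the published ranges),
    control allele frequencies (0.45, 0.44, 0.11) close to the pooled
    controls, a carrier log odds ratio of ln 1.8 and moderate between-study
    variance.  ``seed`` has no default: reproducibility is mandatory.
    """

    seed: int
    n_studies: int = 7
    n_cases: SizeSpec = (48, 256)
    n_controls: SizeSpec = (30, 266)
    freq_s: float = 0.45
    freq_m: float = 0.44
    freq_l: float = 0.11
    mu: float = math.log(1.8)           # true carrier (type I vs II) log OR
    tau_squared: float = 0.05           # between-study variance of the log OR
    severity_log_or: float = 0.0        # carrier effect on severe vs less-severe, among cases
    simulate_severity: bool = False
    prob_asian: float = 6 / 7
    prob_automated_sequencing: float = 5 / 7
    prob_general_population: float = 4 / 7
    prob_chinese_given_asian: float = 0.5  # Caucasian-population studies publish in English
    nos_range: tuple[int, int] = (5, 7)
    selection: Optional[PublicationSelection] = None

    def __post_init__(self) -> None:
        freqs = (self.freq_s, self.freq_m, self.freq_l)
        if any(f < 0 for f in freqs) or abs(sum(freqs) - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies must lie in the simplex, got {freqs}")
        if self.freq_l <= 0:
            raise ValueError("freq_l must be > 0: the carrier model needs L alleles")
        if self.tau_squared < 0:
            raise ValueError("tau_squared must be >= 0")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth returned alongside simulated data for recovery tests."""

    mu: float
    tau_squared: float
    thetas: tuple[float, ...]            # per-study carrier log OR, suppressed included
    induced_allele_log_or: dict          # population-level allele log ORs at theta = mu
    suppressed: tuple[str, ...]


def _draw_size(spec: SizeSpec, rng: np.random.Generator) -> int:
    if isinstance(spec, int):
        return spec
    lo, hi = spec
    return int(rng.integers(lo, hi + 1))


def _hwe_genotype_probs(p_s: float, p_m: float, p_l: float) -> np.ndarray:
    """HWE probabilities in the (SS, SM, SL, MM, ML, LL) order."""
    return np.array([p_s * p_s, 2 * p_s * p_m, 2 * p_s * p_l,
                     p_m * p_m, 2 * p_m * p_l, p_l * p_l])


def _case_counts(n: int, q1: float, cfg: SimulationConfig,
                 rng: np.random.Generator) -> tuple[int, int, np.ndarray]:
    """Case carrier split and allele counts under the dominant-L model.

    Carriers are split into LL homozygotes vs L heterozygotes with the
    control-HWE conditional P(LL | carrier) = p_L^2 / (1 - (1 - p_L)^2); the
    non-L allele of a heterozygous carrier, and both alleles of a
    non-carrier, follow the control S/M conditional.  This keeps allele and
    genotype blocks mutually consistent by construction.
    """
    p_s, p_m, p_l = cfg.freq_s, cfg.freq_m, cfg.freq_l
    q0 = 1.0 - (1.0 - p_l) ** 2
    type_i = int(rng.binomial(n, q1))
    type_ii = n - type_i
    ll = int(rng.binomial(type_i, p_l * p_l / q0))
    het = type_i - ll
    # heterozygous carriers: the non-L chromosome is S or M
    het_s = int(rng.binomial(het, p_s / (p_s + p_m))) if het else 0
    het_m = het - het_s
    # non-carriers: genotype among SS/SM/MM with conditional HWE proportions
    denom = (p_s + p_m) ** 2
    probs = np.array([p_s * p_s, 2 * p_s * p_m, p_m * p_m]) / denom
    n_ss, n_sm, n_mm = rng.multinomial(type_ii, probs)
    alleles = np.array([2 * n_ss + n_sm + het_s,
                        2 * n_mm + n_sm + het_m,
                        2 * ll + het])
    return type_i, type_ii, alleles


def _simulate_one(cfg: SimulationConfig, rng: np.random.Generator,
                  study_id: str) -> tuple[StudyRecord, float]:
    n_cases = _draw_size(cfg.n_cases, rng)
    n_controls = _draw_size(cfg.n_controls, rng)

    # controls: tri-allelic HWE genotypes
    geno = rng.multinomial(n_controls, _hwe_genotype_probs(cfg.freq_s, cfg.freq_m, cfg.freq_l))
    ss, sm, sl, mm, ml, ll = (int(x) for x in geno)
    ctrl_alleles = (2 * ss + sm + sl, 2 * mm + sm + ml, 2 * ll + sl + ml)
    ctrl_type_i = sl + ml + ll
    ctrl_type_ii = ss + sm + mm

    # cases: dominant carrier model with study-level log OR
    theta = float(rng.normal(cfg.mu, math.sqrt(cfg.tau_squared)))
    q0 = 1.0 - (1.0 - cfg.freq_l) ** 2
    odds1 = q0 / (1.0 - q0) * math.exp(theta)
    q1 = odds1 / (1.0 + odds1)
    case_type_i, case_type_ii, case_alleles = _case_counts(n_cases, q1, cfg, rng)

    severity = None
    if cfg.simulate_severity:
        # severity assigned within cases; type I carriers shift by severity_log_or
        p0 = 0.5
        p1 = 1.0 / (1.0 + math.exp(-(math.log(p0 / (1 - p0)) + cfg.severity_log_or)))
        more_i = int(rng.binomial(case_type_i, p1))
        more_ii = int(rng.binomial(case_type_ii, p0))
        severity = SeverityBlock(less_typeI=case_type_i - more_i,
                                 less_typeII=case_type_ii - more_ii,
                                 more_typeI=more_i, more_typeII=more_ii)

    ethnicity = Ethnicity.ASIAN if rng.random() < cfg.prob_asian else Ethnicity.CAUCASIAN
    if ethnicity is Ethnicity.ASIAN and rng.random() < cfg.prob_chinese_given_asian:
        language = Language.CHINESE
    else:
        language = Language.ENGLISH
    method = (GenotypingMethod.AUTOMATED_SEQUENCING
              if rng.random() < cfg.prob_automated_sequencing else GenotypingMethod.PCR_PAGE)
    source = (ControlSource.GENERAL_POPULATION
              if rng.random() < cfg.prob_general_population else ControlSource.HOSPITAL)
    nos = int(rng.integers(cfg.nos_range[0], cfg.nos_range[1] + 1))
    year = int(rng.integers(2000, 2016))

    record = StudyRecord(
        study_id=study_id, year=year, ethnicity=ethnicity,
        genotyping_method=method, control_source=source, nos_score=nos,
        language=language,
        allele_counts=AlleleBlock(case_S=int(case_alleles[0]), case_M=int(case_alleles[1]),
                                  case_L=int(case_alleles[2]), ctrl_S=ctrl_alleles[0],
                                  ctrl_M=ctrl_alleles[1], ctrl_L=ctrl_alleles[2]),
        genotype_counts=GenotypeBlock(case_typeI=case_type_i, case_typeII=case_type_ii,
                                      ctrl_typeI=ctrl_type_i, ctrl_typeII=ctrl_type_ii),
        severity_counts=severity,
        n_cases=n_cases, n_controls=n_controls,
    )
    return record, theta


def simulate_study(config: SimulationConfig, rng: np.random.Generator,
                   study_id: str = "sim01") -> StudyRecord:
    """Generate one study from an explicit random generator (deterministic
    for a fixed generator state)."""
    record, _ = _simulate_one(config, rng, study_id)
    return record


def _induced_allele_log_or(cfg: SimulationConfig) -> dict:
    """Population allele-level log ORs implied by the carrier model at theta = mu.

    Computed from expected allele frequencies in cases vs controls; used as
    the recovery target for allele comparisons.
    """
    p = np.array([cfg.freq_s, cfg.freq_m, cfg.freq_l])
    q0 = 1.0 - (1.0 - cfg.freq_l) ** 2
    odds1 = q0 / (1.0 - q0) * math.exp(cfg.mu)
    q1 = odds1 / (1.0 + odds1)
    # expected case allele frequencies: carriers contribute L and a conditional
    # non-L mix; non-carriers contribute the S/M conditional mix
    p_ll_given_carrier = cfg.freq_l ** 2 / q0
    # chromosomes per carrier: 2; expected L chromosomes per carrier = 1 + P(LL|carrier)
    e_l = q1 * (1 + p_ll_given_carrier) / 2
    s_share = cfg.freq_s / (cfg.freq_s + cfg.freq_m)
    e_nonl = 1 - e_l
    case_freqs = np.array([e_nonl * s_share, e_nonl * (1 - s_share), e_l])
    out = {}
    for idx, name in enumerate("SML"):
        ca, co = case_freqs[idx], p[idx]
        out[name] = math.log(ca / (1 - ca)) - math.log(co / (1 - co))
    return out


def simulate_meta(config: SimulationConfig) -> tuple[list[StudyRecord], SimulationTruth]:
    """Generate a full study pool plus its ground truth.

    One substream per study is spawned from the root seed, so adding studies
    never perturbs earlier ones.  When a selective-publication rule is
    configured it is applied after generation; suppressing every study is an
    explicit error.
    """
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(config.n_studies + 1)
    records: list[StudyRecord] = []
    thetas: list[float] = []
    for i in range(config.n_studies):
        rng = np.random.default_rng(streams[i])
        rec, theta = _simulate_one(config, rng, study_id=f"sim{i + 1:02d}")
        records.append(rec)
        thetas.append(theta)

    suppressed: list[str] = []
    if config.selection is not None:
        sel = config.selection
        sel_rng = np.random.default_rng(streams[-1])
        kept = []
        for rec in records:
            eff = woolf_effect(comparison_table(rec, Comparison.GENOTYPE),
                               study_id=rec.study_id)
            p = 2.0 * float(stats.norm.sf(abs(eff.log_or / eff.se)))
            small = sel.max_cases is None or (rec.n_cases or 0) <= sel.max_cases
            if p > sel.alpha and small and sel_rng.random() < sel.suppress_prob:
                suppressed.append(rec.study_id)
            else:
                kept.append(rec)
        if not kept:
            raise AllStudiesSuppressedError(
                "selective-publication rule suppressed every generated study")
        records = kept

    truth = SimulationTruth(mu=config.mu, tau_squared=config.tau_squared,
                            thetas=tuple(thetas),
                            induced_allele_log_or=_induced_allele_log_or(config),
                            suppressed=tuple(suppressed))
    return records, truth
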