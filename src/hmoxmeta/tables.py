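"""Study records, 2x2 table construction and Hardy-Weinberg testing.

The HMOX1 promoter carries a (GT)n microsatellite whose repeat-count classes
are conventionally binned into three alleles: S (short), M (medium) and
L (long).  Genotypes are dominance-coded on L: *type I* carries at least one
L allele, *type II* carries none.  Each primary study reports case-control
allele counts and/or type I / type II genotype counts; this module turns
those multi-allele count blocks into the fourfold (2x2) tables that the
meta-analysis pools, and tests Hardy-Weinberg equilibrium (HWE) in controls.

Allele-level tables treat each of the 2N chromosomes as one observation
(the standard allele-counting model).  This ignores within-subject
correlation between the two chromosomes of a genotype; it is the
construction under which published allele odds ratios are defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "Ethnicity",
    "GenotypingMethod",
    "ControlSource",
    "Language",
    "Comparison",
    "AlleleBlock",
    "GenotypeBlock",
    "SeverityBlock",
    "StudyRecord",
    "FourfoldTable",
    "TriallelicGenotypeTable",
    "HWEResult",
    "InvalidCountsError",
    "InconsistentMarginalsError",
    "allele_table",
    "genotype_table",
    "severity_table",
    "comparison_table",
    "collapse_to_biallelic",
    "hwe_biallelic",
    "hwe_multiallelic",
]


class InvalidCountsError(ValueError):
    """A count block violates its invariants (negative, non-integer, ...)."""


class InconsistentMarginalsError(ValueError):
    """Printed marginal counts imply a negative genotype count."""


class Ethnicity(str, Enum):
    ASIAN = "Asian"
    CAUCASIAN = "Caucasian"


class GenotypingMethod(str, Enum):
    AUTOMATED_SEQUENCING = "automated_sequencing"
    PCR_PAGE = "pcr_page"


class ControlSource(str, Enum):
    GENERAL_POPULATION = "general_population"
    HOSPITAL = "hospital"


class Language(str, Enum):
    CHINESE = "Chinese"
    ENGLISH = "English"


class Comparison(str, Enum):
    """The pooled contrasts: one allele vs the other two, or genotype/severity."""

    ALLELE_S = "allele_S"
    ALLELE_M = "allele_M"
    ALLELE_L = "allele_L"
    GENOTYPE = "genotype"
    SEVERITY = "severity"


def _check_counts(name: str, *values: int) -> None:
    for v in values:
        if v is None or int(v) != v or v < 0:
            raise InvalidCountsError(f"{name}: counts must be non-negative integers, got {v!r}")


@dataclass(frozen=True)
class AlleleBlock:
    """Per-group chromosome counts of the S/M/L alleles (2 per subject)."""

    case_S: int
    case_M: int
    case_L: int
    ctrl_S: int
    ctrl_M: int
    ctrl_L: int

    def __post_init__(self) -> None:
        _check_counts("AlleleBlock", self.case_S, self.case_M, self.case_L,
                      self.ctrl_S, self.ctrl_M, self.ctrl_L)

    @property
    def case_total(self) -> int:
        return self.case_S + self.case_M + self.case_L

    @property
    def ctrl_total(self) -> int:
        return self.ctrl_S + self.ctrl_M + self.ctrl_L


@dataclass(frozen=True)
class GenotypeBlock:
    """Subject counts of L-carrier (type I) vs non-carrier (type II) genotypes."""

    case_typeI: int
    case_typeII: int
    ctrl_typeI: int
    ctrl_typeII: int

    def __post_init__(self) -> None:
        _check_counts("GenotypeBlock", self.case_typeI, self.case_typeII,
                      self.ctrl_typeI, self.ctrl_typeII)


@dataclass(frozen=True)
class SeverityBlock:
    """Type I / type II counts in less-severe vs more-severe COPD strata."""

    less_typeI: int
    less_typeII: int
    more_typeI: int
    more_typeII: int

    def __post_init__(self) -> None:
        _check_counts("SeverityBlock", self.less_typeI, self.less_typeII,
                      self.more_typeI, self.more_typeII)


@dataclass
class StudyRecord:
    """One primary case-control study: covariates plus count blocks.

    At least one of ``allele_counts`` / ``genotype_counts`` /
    ``severity_counts`` must be present.  ``n_cases`` / ``n_controls``, when
    supplied, are cross-checked against the blocks (allele totals are
    chromosome counts, twice the subject count).
    """

    study_id: str
    year: int
    ethnicity: Ethnicity
    genotyping_method: GenotypingMethod
    control_source: ControlSource
    nos_score: int
    language: Language
    allele_counts: Optional[AlleleBlock] = None
    genotype_counts: Optional[GenotypeBlock] = None
    severity_counts: Optional[SeverityBlock] = None
    n_cases: Optional[int] = None
    n_controls: Optional[int] = None

    def __post_init__(self) -> None:
        if not (0 <= self.nos_score <= 9):
            raise InvalidCountsError(
                f"{self.study_id}: NOS score must be in [0, 9], got {self.nos_score}")
        if (self.allele_counts is None and self.genotype_counts is None
                and self.severity_counts is None):
            raise InvalidCountsError(
                f"{self.study_id}: at least one count block must be present")
        if self.n_cases is not None:
            if self.allele_counts and self.allele_counts.case_total != 2 * self.n_cases:
                raise InvalidCountsError(
                    f"{self.study_id}: case allele total "
                    f"{self.allele_counts.case_total} != 2 x n_cases ({self.n_cases})")
            g = self.genotype_counts
            if g and g.case_typeI + g.case_typeII != self.n_cases:
                raise InvalidCountsError(
                    f"{self.study_id}: case typeI+typeII "
                    f"{g.case_typeI + g.case_typeII} != n_cases ({self.n_cases})")
        if self.n_controls is not None:
            if self.allele_counts and self.allele_counts.ctrl_total != 2 * self.n_controls:
                raise InvalidCountsError(
                    f"{self.study_id}: control allele total "
                    f"{self.allele_counts.ctrl_total} != 2 x n_controls ({self.n_controls})")
            g = self.genotype_counts
            if g and g.ctrl_typeI + g.ctrl_typeII != self.n_controls:
                raise InvalidCountsError(
                    f"{self.study_id}: control typeI+typeII "
                    f"{g.ctrl_typeI + g.ctrl_typeII} != n_controls ({self.n_controls})")


@dataclass(frozen=True)
class FourfoldTable:
    """2x2 exposure-by-status table: a,b exposed/unexposed cases; c,d controls."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        _check_counts("FourfoldTable", self.a, self.b, self.c, self.d)

    @property
    def degenerate(self) -> bool:
        """True when every cell is zero (no information)."""
        return self.a == self.b == self.c == self.d == 0

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


_ALLELES = ("S", "M", "L")


def allele_table(block: AlleleBlock, target: str) -> FourfoldTable:
    """2x2 table of the target allele vs the other two, chromosomes as units.

    For ``target="L"`` this is the L vs S+M contrast; each of the 2N
    chromosomes in a group is one observation.
    """
    if target not in _ALLELES:
        raise ValueError(f"unknown target allele {target!r}; expected one of {_ALLELES}")
    case = {"S": block.case_S, "M": block.case_M, "L": block.case_L}
    ctrl = {"S": block.ctrl_S, "M": block.ctrl_M, "L": block.ctrl_L}
    a = case[target]
    c = ctrl[target]
    return FourfoldTable(a=a, b=block.case_total - a, c=c, d=block.ctrl_total - c)


def genotype_table(block: GenotypeBlock) -> FourfoldTable:
    """2x2 table of type I (L-carrier) vs type II genotypes, subjects as units."""
    return FourfoldTable(a=block.case_typeI, b=block.case_typeII,
                         c=block.ctrl_typeI, d=block.ctrl_typeII)


def severity_table(block: SeverityBlock) -> FourfoldTable:
    """2x2 severity table; the more-severe stratum plays the 'case' role.

    OR > 1 downstream therefore means type I is enriched in severe disease.
    """
    return FourfoldTable(a=block.more_typeI, b=block.more_typeII,
                         c=block.less_typeI, d=block.less_typeII)


def comparison_table(study: StudyRecord, comparison: Comparison) -> Optional[FourfoldTable]:
    """The study's 2x2 table for a comparison, or None if the block is absent."""
    comparison = Comparison(comparison)
    if comparison in (Comparison.ALLELE_S, Comparison.ALLELE_M, Comparison.ALLELE_L):
        if study.allele_counts is None:
            return None
        return allele_table(study.allele_counts, comparison.value[-1])
    if comparison is Comparison.GENOTYPE:
        if study.genotype_counts is None:
            return None
        return genotype_table(study.genotype_counts)
    if study.severity_counts is None:
        return None
    return severity_table(study.severity_counts)


def collapse_to_biallelic(l_alleles: int, type_i: int, type_ii: int,
                          study_id: str = "") -> tuple[int, int, int]:
    """Derive the (LL, L-heterozygote, non-L homozygote) split from marginals.

    Primary studies typically print only the L-allele count and the carrier
    (type I) / non-carrier (type II) subject counts.  The identities
    ``LL = L - typeI`` and ``het = 2*typeI - L`` recover the dominant-coded
    genotype triple exactly; a negative derived count means the printed
    marginals are mutually inconsistent.
    """
    _check_counts("collapse_to_biallelic", l_alleles, type_i, type_ii)
    ll = l_alleles - type_i
    het = 2 * type_i - l_alleles
    if ll < 0 or het < 0:
        who = f" for study {study_id}" if study_id else ""
        raise InconsistentMarginalsError(
            f"inconsistent marginals{who}: L={l_alleles}, typeI={type_i} "
            f"imply LL={ll}, het={het}")
    return ll, het, type_ii


@dataclass(frozen=True)
class HWEResult:
    """Pearson chi-square goodness-of-fit test against HWE proportions."""

    chi_square: float
    df: int
    p_value: float
    observed: tuple[float, ...]
    expected: tuple[float, ...]
    derived: bool = False  # True when computed from collapsed marginals, not a primary table

    @property
    def n(self) -> float:
        return float(sum(self.observed))


def hwe_biallelic(hom1: int, het: int, hom2: int, *, derived: bool = False) -> HWEResult:
    """HWE chi-square for a bi-allelic genotype triple (df = 1).

    Allele frequency is estimated from the genotype counts themselves;
    expected counts are (Np^2, 2Npq, Nq^2).
    """
    _check_counts("hwe_biallelic", hom1, het, hom2)
    n = hom1 + het + hom2
    if n == 0:
        raise InvalidCountsError("hwe_biallelic: empty sample (N = 0)")
    p = (2 * hom1 + het) / (2 * n)
    q = 1.0 - p
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([hom1, het, hom2], dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi = float(terms.sum())
    return HWEResult(chi_square=chi, df=1, p_value=float(stats.chi2.sf(chi, 1)),
                     observed=tuple(observed), expected=tuple(expected), derived=derived)


@dataclass(frozen=True)
class TriallelicGenotypeTable:
    """Counts of the six genotypes of a tri-allelic locus in one group.

    Fields are ordered as the upper triangle of the genotype matrix for
    alleles (S, M, L): SS, SM, SL, MM, ML, LL.
    """

    ss: int
    sm: int
    sl: int
    mm: int
    ml: int
    ll: int

    def __post_init__(self) -> None:
        _check_counts("TriallelicGenotypeTable", self.ss, self.sm, self.sl,
                      self.mm, self.ml, self.ll)

    @property
    def n(self) -> int:
        return self.ss + self.sm + self.sl + self.mm + self.ml + self.ll

    def allele_counts(self) -> tuple[int, int, int]:
        """Implied chromosome counts (S, M, L)."""
        return (2 * self.ss + self.sm + self.sl,
                2 * self.mm + self.sm + self.ml,
                2 * self.ll + self.sl + self.ml)


def hwe_multiallelic(table: TriallelicGenotypeTable) -> HWEResult:
    """HWE chi-square for a tri-allelic genotype table, df = k(k-1)/2 = 3.

    Expected homozygote counts are N p_i^2 and heterozygotes 2 N p_i p_j,
    with allele frequencies estimated from the table.
    """
    n = table.n
    if n == 0:
        raise InvalidCountsError("hwe_multiallelic: empty sample (N = 0)")
    counts = np.array(table.allele_counts(), dtype=float)
    freqs = counts / (2 * n)
    # observed in the (SS, SM, SL, MM, ML, LL) order
    observed = np.array([table.ss, table.sm, table.sl, table.mm, table.ml, table.ll],
                        dtype=float)
    pS, pM, pL = freqs
    expected = n * np.array([pS * pS, 2 * pS * pM, 2 * pS * pL,
                             pM * pM, 2 * pM * pL, pL * pL])
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (observed - expected) ** 2 / expected, 0.0)
    chi = float(terms.sum())
    df = 3  # k(k-1)/2 for k = 3 alleles
    return HWEResult(chi_square=chi, df=df, p_value=float(stats.chi2.sf(chi, df)),
                     observed=tuple(observed), expected=tuple(expected))
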