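# Methods

## Data model

One row per primary study: covariates (ethnicity, genotyping method,
control source, Newcastle–Ottawa quality score 0–9, publication language,
year) plus up to three count blocks — allele counts (S/M/L chromosomes per
group; group total = 2 × subjects), genotype counts (type I = L-carrier /
type II subjects) and severity counts (type I/II within less- vs
more-severe COPD strata). A blank CSV cell means *not reported*, never
zero; a block must be complete to be used. The packaged table encodes the
seven published case–control studies; two of them (Budhi, Putra) report
genotype but not allele counts, so allele contrasts pool five studies and
genotype contrasts seven. Budhi and Putra report identical control counts
(140/32), which suggests a shared control cohort; they are pooled as
printed, as in the source analysis.

## Effect sizes and pooling

Allele contrasts (S vs M+L, M vs S+L, L vs S+M) treat each chromosome as an
independent observation. This allele-counting model ignores the
within-subject correlation of the two chromosomes of a genotype; it is the
construction under which the published allele odds ratios are defined, and
its standard errors are mildly anti-conservative when genotypes deviate
from HWE. The genotype contrast (type I vs II) and the severity contrast
(more-severe stratum in the "case" role, so OR > 1 means L-carriage
enriched in severe disease) use subjects.

Woolf log odds ratios carry variance 1/a+1/b+1/c+1/d; when any cell is
zero, 0.5 is added to all four cells and the estimate is flagged
`corrected` (no zero cells occur in the packaged table — the policy exists
for synthetic and user data). Fixed-effect pooling is inverse variance;
random effects is DerSimonian–Laird method-of-moments with τ² truncated at
zero. Q, its chi-square p-value and I² are always computed from the
fixed-effect weights. 95% CIs use z = 1.959964; p-values are two-sided and
stored at full precision ("<0.001" appears only in formatted output).

**Default model.** DL random effects is applied to every comparison. The
conventional rule — fixed effect when the Q test's p > 0.10 — is exposed as
`model="rule_based"` but is not the default, because the published overall
genotype result (p_Q = 0.14) matches the random-effects numbers: the source
analysis evidently used random effects there despite its stated rule. With
τ² truncated at zero the DL fit equals the fixed-effect fit in every
homogeneous subgroup (e.g. the Asian allele subsets), so the single default
reproduces all printed values. One printed inconsistency is noted: the
abstract gives the L-allele CI as 1.32–3.11 while the results table gives
1.31–3.11; the computation yields 1.309 → 1.31, reproducing the table.

Fixed-effect inverse variance was chosen over Mantel–Haenszel because it
exactly reproduces the printed subgroup values; MH is not implemented.
Peto ORs, REML/Paule–Mandel τ² and Hartung–Knapp adjustment are out of
scope.

## Hardy–Weinberg testing

Controls are tested by Pearson chi-square against HWE proportions with
allele frequencies estimated from the same data: bi-allelic (df = 1) on the
dominance-collapsed triple, tri-allelic (df = 3) on a full six-genotype
table. Because the published table prints only marginals (L-allele count,
type I/II counts), the collapsed triple is derived via LL = L − typeI,
het = 2·typeI − L and the result is flagged `derived`: it does **not**
reproduce the published per-study HWE p-values, which were computed on full
tri-allelic genotype tables available only in the primary reports (e.g. the
largest study's collapsed triple gives p ≈ 0.20 where the published value
is <0.001). Derived HWE results should be read as a consistency check on
the printed marginals, not as the primary studies' HWE tests.

## Subgroups and sensitivity

Five stratifiers: ethnicity, genotyping method, control source, quality
(Newcastle–Ottawa ≥ 7 vs < 7) and language. Language labels are data
columns in the packaged table ({Du, Fu, Ma} Chinese; the rest English) —
the only assignment consistent with the published Chinese-subgroup OR.
Each stratum is pooled with the same model as the overall analysis; strata
of size one return the single-study estimate with heterogeneity flagged
undefined; no between-subgroup Q-difference test is computed (none was
published). Leave-one-out sensitivity re-pools n times, omitting one study
each; the report is flagged stable when every re-pooled OR stays on one
side of 1 and the re-pooled CIs share a common overlap.

## Publication bias

Egger's test is *unweighted* OLS of the standardized effect on precision —
this variant reproduces the published p = 0.79 for the L-allele comparison
(the weighted variant does not and is not implemented). Begg's test uses
the normal approximation z = S/√(n(n−1)(2n+5)/18) with *no* continuity
correction, reproducing the published p = 0.327 (the corrected variant
gives ≈ 0.46). Tied pairs contribute 0 to S, the variance is left
unadjusted, and a warning is emitted; when some variance does not exceed
1/Σw the standardizing denominator is clamped at a small positive value
with a warning. An exact-fit Egger regression (zero residual scatter) is
treated as a limiting case: intercept 0 → p = 1. Funnel output is
plot-ready (study, OR, SE, pooled reference line) — no rendering.

## Simulator

`SimulationConfig` defines the generating process the analysis assumes:
control genotypes multinomial under tri-allelic HWE; a dominant L-carrier
effect on case status with study-level log OR θᵢ ~ N(μ, τ²); case carrier
counts binomial with odds q₀/(1−q₀)·eᶿ, where q₀ = 1−(1−p_L)²; case allele
counts split among carrier/non-carrier genotypes using the control HWE
conditionals (a modelling choice that keeps allele and genotype blocks
mutually consistent); covariates assigned independently per study; optional
selective publication (suppress with probability π when the study's
genotype p-value exceeds α, optionally only for small studies). Severity
strata, when enabled, are assigned within cases with a logistic shift of
`severity_log_or` for carriers (0 = no association).

Defaults mirror the real study pool: 7 studies, case sizes 48–256, control
sizes 30–266 (the published ranges), control allele frequencies
(0.45, 0.44, 0.11) close to the pooled published controls, μ = ln 1.8
(near the published genotype OR), τ² = 0.05 (moderate heterogeneity,
I² ≈ 30–50% at these sizes). The carrier effect is primary; allele-level
odds ratios *emerge* from it, so allele-contrast recovery tests use the
simulator-computed induced truth, not μ itself. Randomness derives from a
single mandatory root seed with one spawned substream per study, so
extending a pool never perturbs earlier studies.

What the simulator does not emulate: raw (GT)n repeat lengths and
genotyping error, repeat-class cutoff differences between laboratories,
shared control cohorts, covariate–effect confounding (covariates are
independent of θᵢ unless the user constructs them otherwise), and
non-normal between-study effect distributions. Passing recovery tests
therefore demonstrate correctness of the estimators under the assumed
model, not robustness to those real-data features.

## Verification scale

The published-table checks are exact desk-scale computations (well under a
second). Stochastic calibration checks use: Q-test type-I error at
threshold 0.10 over 5,000 replicates of 5 homogeneous studies (n = 500 per
arm, tolerance ±0.02); DL recovery of μ = ln 2 over 200 replicate
meta-analyses of 20 studies × n = 500 (tolerance 10% on the mean pooled
OR); HWE rejection rate over 5,000 HWE-true tables of N = 500 (±0.015);
Egger selective-publication inflation over 200 replicate pools of 15
studies with all non-significant studies suppressed (directional check
against the matched unselected worlds). These sizes give Monte-Carlo
standard errors several times smaller than the stated tolerances.

## Known limitations

- The severity comparison is schema + simulation only; the published
  severity counts are supplementary-only and not redistributed, so the
  published severity OR (0.97 [0.49–1.92]) is not reproduced numerically.
- Published per-study HWE p-values are not reproducible from printed
  marginals (see above).
- No meta-regression on continuous covariates, no trim-and-fill or Peters'
  test, no literature-screening workflow.
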