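# Methods

## Problem and model

CYP2D6 poor metabolizers (PMs) carry two lack-of-function alleles and
have no CYP2D6 activity; they are at risk of overexposure on standard
doses of CYP2D6-metabolized drugs. Solanidine, a dietary steroidal
alkaloid from potatoes, is metabolized by CYP2D6, so the ratio of a
solanidine metabolite's chromatographic peak area to the solanidine
peak area in the same serum sample (the metabolic ratio, MR) reflects
in-vivo enzyme activity. This package implements the full analysis that
turns per-patient peak areas of solanidine and seven metabolites
(M402–M444, labelled by nominal mass; M444 is
3,4-seco-solanidine-3,4-dioic acid) into a validated PM classifier, and
a synthetic-cohort generator that makes the whole pipeline testable
without patient data.

## Genotype translation

The supported panel is eight star alleles: lack-of-function ("Def")
\*3, \*4, \*5, \*6; reduced-function ("Red") \*9, \*10, \*41; and the
wild type \*1, plus copy-number duplication calls ("xN"). Diplotypes
map to phenotypes as PM = Def/def, IM = {Def/red, Red/red, \*1/def},
NM = {\*1/red, \*1/\*1}, UM = \*1/\*1 xN. This grouping places \*1/red
in NM, which differs from the current CPIC activity-score convention
(where an activity score of 1.25–2.25 is NM and \*1/\*41 scores 1.5 —
also NM — but \*1/\*10 would score 1.25 at the NM/IM boundary); the
historical DPWG/CPIC consensus grouping is implemented deliberately so
results remain comparable to the clinical dataset the models were
estimated on. Because the duplication assay does not resolve *which*
allele is duplicated, any duplication co-occurring with a Red or Def
allele is INCONCLUSIVE and excluded from threshold derivation and
regression (such patients are still split into cohorts). The group enum
carries two members (Red/red xN, Def/def xN) beyond the groups observed
in the source cohort so that every supported diplotype maps to exactly
one group; both are inconclusive by the same rule.

## Synthetic cohort generator

The generator's defaults are the study conditions, not free dials:

- **Genotype mix**: the combined test+validation counts over n = 839
  (e.g. Def/def 58/839 ≈ 6.9%), including the three inconclusive
  duplication groups (8/8/6 of 839) so exclusion logic is exercised.
- **Covariates**: female with probability 341/839; age normal
  (mean 41.3 y, SD 11.0 y) truncated to the study's 18–65 y range; sex,
  age and genotype drawn independently.
- **Outcomes**: each of the seven ln metabolic ratios and the ln
  solanidine concentration (nmol/L) follows the published multiple
  linear regression — intercept (female, mean-age, \*1/\*1 reference) +
  sex effect + centered-age effect + genotype effect + homoscedastic
  normal residual on the ln scale. Outcomes are drawn independently
  given the covariates; the source models report no residual
  cross-metabolite correlation, so none is imposed by default.
- **Residual noise**: the published tables give coefficients and model
  R² but not residual variance. The generator calibrates it
  deterministically as σ² = Var(Xβ)·(1 − R²)/R², with Var(Xβ) computed
  under the conclusive-genotype mixture (the population the regressions
  were fitted on). For the M414 ratio this gives σ ≈ 1.90; an OLS refit
  on a large generated cohort then recovers both the coefficients and
  R² = 0.688, which is the package's parameter-recovery test.
- **Inconclusive-group effects**: no published estimates exist (those
  patients were excluded from the regressions), so the generator
  borrows the content-matched conclusive effect (\*1/red xN → \*1/red,
  \*1/def xN → \*1/def, Red/def xN → Def/red).
- **Peak areas**: solanidine area = concentration × 1000 area units per
  nmol/L (an arbitrary instrument response chosen once); metabolite
  area = solanidine area × exp(lnMR).
- **Missingness**: per-analyte limits of detection were calibrated once
  by simulation (seed 20230220, n = 200 000) so detected fractions match
  the published 76/71/42/91/87/98/61/71% for
  SOLA/M402/M412/M414/M416/M432/M440/M444, then frozen as documented
  constants. A `clean()` preset disables missingness for model-level
  checks.
- **Inhibitor users**: default fraction 0. No published effect sizes
  exist for CYP2D6-inhibitor use (only significance markers), so
  enabling inhibitor simulation requires explicit user-specified
  ln-scale shifts.

What the generator does *not* emulate: potato-intake behaviour (diet
enters only through the ln-concentration model), pharmacokinetic
time-courses, genotype-specific residual variance, per-genotype
detection rates, and analytical batch effects. Passing tests therefore
demonstrate that the statistical machinery is correct under the stated
model, not that the biomarker performs identically in new populations.

## Truncation and ratios

Undetected areas are truncated to half the minimum detected area of the
same analyte (derived from the data by default; the published constants
— solanidine 1278, M402 970, M412 798, M414 782, M416 1117, M432 844,
M440 963, M444 629 area units — can be pinned for worked examples).
Truncation constants are derived after the subject-level exclusions, on
the analysis population. lnMR = ln(metabolite area / solanidine area).
A patient is excluded from metabolite m's analyses only when solanidine
and m are *both* undetected, so the included n differs per metabolite.
The concentration analysis keeps a patient unless every analyte is
undetected; undetected solanidine concentrations use the truncated area
pushed through the calibration scale.

## Splitting and balance

Randomization is 4:1 into test and validation cohorts, stratified on
PM and UM phenotypes (all other patients pool into one stratum).
The validation share of a stratum of n is the round-half-up nearest
integer to n/5 — the rule that sends exactly 12 of 58 PMs to validation
(floor would give 11). Balance is checked with equal-variance Student
t-tests (age, solanidine concentration) and two-sided Fisher's exact
tests (sex, each genotype group, per-analyte undetected proportions);
the two-sided Fisher p is the tail-sum of table probabilities ≤ the
observed one, a convention stated explicitly because software differs.

## Classification

ROC curves place candidate thresholds at midpoints between adjacent
distinct scores plus ±∞ sentinels (rather than at observed values, a
choice some packages make differently); the trapezoidal AUC then equals
the Mann–Whitney statistic exactly. "Highest sensitivity and
specificity" is operationalized as Youden's J = sens + spec − 1, with
ties broken toward higher specificity — a false PM call is the
clinically costly error — and then toward the lower threshold.
Metabolic ratios predict PM *below* the threshold; the solanidine
concentration predicts PM *above* it (the parent accumulates when it is
not metabolized). Threshold comparisons are inclusive (≤ / ≥).
AUC confidence intervals and the one-sided test against chance use
DeLong's placement-value variance with a normal approximation, clipped
to [0, 1]. Confusion metrics report sensitivity, specificity, PPV, NPV
and MCC; undefined rates are NaN with a flag, and a zero MCC
denominator yields 0 by convention, flagged.

## Regression

Each outcome is fitted by OLS with terms {male, centered age, six
genotype dummies}, reference female/mean-age/\*1/\*1; age is centered on
the per-analysis sample mean (the original centering constant is not
published). Genotype-contrast p-values are Bonferroni-multiplied by the
number of genotype terms (6), capped at 1; sex and age are unadjusted.
Both plain and adjusted R² are reported (at these sample sizes they
differ by < 0.5%). Empty genotype cells are dropped with a warning.
The Dunnett many-to-one adjustment for the genotype ANOVA is computed
by Monte Carlo on the exact null of the max-|t| statistic (group means
~ N(0, 1/nᵢ), pooled variance ~ χ²/df; 10⁵ draws, fixed seed) — chosen
over multivariate-t quadrature because it is directly verifiable
against a permutation oracle; the test suite also cross-checks it
against an independent quadrature implementation. Inhibitor-user
comparisons are equal-variance Student t-tests, as in the source
analysis.

## HRMS extraction

Analytes are located by the theoretical [M+H]⁺ m/z (computed from the
molecular formula where given; solanidine is C27H43NO) within an
inclusive ±5 ppm window; identity can be confirmed by the diagnostic
iminium fragment at m/z 98.0967 in MS2 scans whose precursor matches
within 10 ppm, using an absolute 0.005 Da fragment tolerance (at this
low mass a ppm window would be sub-millidalton). Peak integration uses
a median out-of-window baseline, a 3·MAD detection rule and trapezoidal
integration of the maximal contiguous above-baseline region in the
expected-RT window (default half-width 0.3 min; expected RTs are config
inputs). Solanidine is quantified through a free-intercept least-squares
line over external calibrators (routine: three, 2–60 nmol/L); negative
predictions clip to zero with a warning. mzML reading uses a
purpose-built streaming parser covering the centroided subset this
pipeline consumes; the fixture writer emits valid minimal mzML and the
two round-trip bit-exactly.

## Problem sizes and numerical choices

Model-level checks use 100 000-patient clean cohorts (Monte-Carlo SE of
the Def/def M414 coefficient ≈ 0.025 ln units, well inside the ±0.05
check band) and 50 000–200 000 draws where distribution tails matter;
the acceptance script simulates 100 000 patients in a few seconds. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`; equal-seed runs are bit-reproducible.
Degenerate inputs (single-class ROC labels, empty genotype cells,
all-undetected analytes, zero-variance t-tests) raise or flag rather
than silently produce numbers.

## Known limitations

The regression coefficients used as generator truth are point
estimates; their sampling error is inherited silently. Homoscedastic
residuals are an assumption, not a reported fact. The ±5 ppm window and
the integration baseline rule are idealizations of vendor software with
manual review. Published molecular formulas and retention times for the
metabolites are not bundled, so targeted extraction of M402–M444
requires user-supplied analyte definitions.
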