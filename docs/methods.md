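# Methods

## Surrogate indices and units

SPISE = 600 · HDL^0.185 / (TG^0.2 · BMI^1.338) with HDL and TG in mg/dL and
BMI in kg/m²; HOMA-IR = insulin [µU/mL] · glucose [mmol/L] / 22.5. Cohort
files carry lipids and glucose in mmol/L, so SPISE inputs are converted with
the standard molar-mass factors (cholesterol ×38.67, triglyceride ×88.57,
glucose ×18.016); the factors and exponents are exposed in `IndexConfig` for
sensitivity analyses but should not normally be touched. SPISE is strictly
increasing in HDL and decreasing in TG and BMI; both indices are undefined
(reported missing, never imputed) when an input is missing. Per-field
missingness propagates to per-index missingness and subjects are never
dropped at the scoring stage.

## MetS classification

The classifier implements the NCEP ≥3-of-5 rule with pediatric thresholds:
glucose ≥ 6.1 mmol/L; TG ≥ 1.24 mmol/L below exact age 16.0 and ≥ 1.7
mmol/L at or above it; HDL ≤ 1.03 mmol/L; waist and blood pressure at or
above the age- and sex-specific 90th percentile (BP is elevated if either
SBP or DBP crosses its percentile). All comparisons are inclusive.

Because no external waist/BP percentile table is bundled, the reference is
**cohort-empirical** by default: within each (sex, completed age year) cell
the 90th percentile is computed by linear interpolation between order
statistics (NumPy's default quantile definition; stated because percentile
conventions differ across software). Cells with fewer than 10 subjects are
pooled with adjacent age years, widening the window one year at a time until
the cell fills. An external reference CSV (columns sex, age_year, waist_p90,
sbp_p90, dbp_p90) can be supplied instead. A consequence of the empirical
default is that roughly 10% of each sex–age cell is flagged for waist by
construction; a study using a national reference table may flag more or
fewer.

Subjects missing any required field are marked unclassifiable, counted, and
excluded from downstream MetS tables — never imputed.

## ROC analysis and the Youden cut-off

SPISE is a "lower is worse" marker, so candidate rules are "score ≤ c
positive" with c ranging over the unique observed values (plus a sentinel
for the empty rule); between-group ties at c count on the positive side.
AUC is the tie-corrected Mann–Whitney statistic (concordant pairs + half the
tied pairs over n_pos·n_neg), which equals the trapezoidal area under the
empirical curve; the implementation checks this identity to 1e−12 in tests.

The Youden cut-off maximizes J = sensitivity + specificity − 1 over the
observed thresholds. Ties in J are broken by (1) higher sensitivity, then
(2) the rule admitting more subjects as positive (screening convention:
prefer not to miss cases). The reported cut-off is an observed score value,
not a midpoint between observations, matching the reporting style of the
clinical literature. No binormal smoothing is applied to the headline
curves; the binormal closed form Φ(Δμ/√(σ₁²+σ₂²)) serves only as a test
oracle for the published group moments (boys MetS 5.53 ± 2.5 vs non-MetS
9.41 ± 3.2 gives ≈0.830).

## Odds ratios, logistic regression, group tests

Unadjusted ORs are the cross-product (a·d)/(b·c) with the Woolf interval
exp(ln OR ± z₁₋α/₂ √(1/a+1/b+1/c+1/d)); this combination reproduces the
validation cohort's printed interval (16.5, 72.3) for the boys
elevated-waist row, which is why it is the default. A zero cell yields an
undefined estimate; the Haldane–Anscombe +0.5 correction is available by
flag but never applied silently.

Age-adjusted ORs come from logistic regression fitted by IRLS (Newton
scoring), converged when the score falls below 1e−8 in max-norm, capped at
100 iterations. Separation is detected two ways — diverging coefficients
during iteration, or a "converged" score at |β| > 15 (probabilities
saturated before the gradient vanished) — and reported as non-converged with
a diagnostic; no penalization is applied silently. For a single binary
predictor the exponentiated coefficient agrees with the cross-product OR to
1e−6 (tested on 200 random tables, and against statsmodels on continuous
designs). Age enters as a single linear covariate in years.

Group comparisons follow the reporting conventions of the field: gaussian
variables as mean ± SD with a pooled-variance t test (Welch by flag),
skewed variables as median (Q1–Q3) with the asymptotic tie-corrected
rank-sum test, categorical variables with chi-square without continuity
correction. The correlation panel natural-log transforms a configurable
skewed set (TG, insulin, adipokines, CRP, APAI-1, 25(OH)D, HOMA-IR,
adiponectin/leptin — the variables reported as medians) before Pearson
correlation; no automatic normality testing is performed and no
multiple-testing correction is applied, matching the analysis being
reproduced.

## Synthetic cohort generator

The generator exists because the validation cohort's raw data are available
only on request; it emulates that cohort's *published summary structure* so
the pipeline can be exercised and property-tested end to end.

Construction, per sex (503/951 boys by default):

1. a latent standard-normal cardiometabolic risk factor Z; the intended
   MetS group is Z above the (1 − prevalence) quantile, with prevalence
   targets 10.7% (boys) and 6.3% (girls) from the published counts;
2. each variable's normal score is λ·Z + √(1−λ²)·ε — a one-factor Gaussian
   copula. Residual correlations among the ε capture relationships not
   mediated by overall risk (BMI–waist 0.55, BMI–hip and waist–hip 0.50,
   SBP–DBP 0.65, BMI–leptin 0.45, glucose–insulin 0.25, TG–HDL −0.25,
   chol–HDL 0.30, adiponectin–leptin −0.15); the matrix is projected to the
   nearest positive-definite correlation matrix if needed;
3. normal scores map to sex-specific marginals by inverse-CDF: truncated
   normals for mean±SD variables (physiological floors, e.g. BMI ≥ 10,
   HDL ≥ 0.25; age truncated to the 10–17 inclusion range), lognormals
   matched to the printed median (Q1–Q3) via μ = ln(median),
   σ = ln(Q3/Q1)/(2·0.67449) for the skewed ones.

Loadings λ are computed at run time from the published MetS/non-MetS group
contrasts: λ = Δlocation / (scale · ΔE[Z]), where ΔE[Z] = φ(z₀)/(p(1−p)) is
the separation of the latent group means implied by thresholding. For the
six variables that define the components (waist, SBP, DBP, glucose, TG,
HDL) no published contrast exists — those rows are omitted from the source
tables precisely because they define the groups — so their loadings
(0.65, 0.40, 0.35, 0.30, 0.50, −0.50) were fixed once by calibrating the
classified prevalence and ROC separation against the published targets and
are not meant to be re-tuned. SPISE and HOMA-IR are always computed from
the generated inputs, never sampled.

The single-factor design is the simplest structure that makes the five
components co-occur; without co-occurrence, realistic per-component
prevalences would almost never stack to ≥3 in one subject.

What the generator does **not** emulate, and what passing tests therefore do
not show about real data:

* individually asymmetric quartiles: the two-parameter lognormal reproduces
  the median and the Q3/Q1 ratio exactly but centers the quartiles
  geometrically, so log-asymmetric printed quartiles (leptin especially) are
  not individually matched; the calibration report checks the median and the
  quartile ratio;
* the classified prevalence: with the published means/SDs driving normal
  marginals, the implied component margins (e.g. ~16–20% of glucose values
  over 6.1 mmol/L) put the classified ≥3-of-5 prevalence near 11–12%, above
  the published 8.6% but inside the stated [5%, 13%] calibration band — the
  real data are presumably right-skewed-but-tighter in ways mean±SD cannot
  encode;
* latent-group recovery at the boundary: subjects just above the latent
  threshold are borderline by construction, so agreement between classified
  and intended MetS is ~50% for intended cases while classified MetS remains
  ~6× enriched in the intended group; the calibration check is that
  enrichment, not majority agreement;
* pubertal stage, measurement error, cluster (school) structure, and any
  within-sex joint distribution beyond the one-factor-plus-pairs copula —
  the joint structure is an assumption, not an estimate.

Exact reproduction of the published AUCs and cut-offs is out of reach
without the raw data; the corresponding checks are property-based: cut-offs
in [4.5, 7.5] per sex, AUC > 0.75, correlation signs matching the published
panel, and mean SPISE decreasing across the 0/1/2/≥3 component groups.

## Problem sizes and numerical conventions

Calibration and acceptance checks run at n = 10,000 (marginal locations,
correlation signs, prevalence band, cut-off ranges) and n = 100,000 for the
binormal AUC simulation, sizes at which the sampling error of every checked
quantity is well below its tolerance; the worked example and the analysis
scripts use the published cohort size (951). All randomness flows through
`numpy.random.default_rng` seeds; the same seed gives byte-identical
cohorts. Display rounding (2 decimals for ORs, 1 for percentages) lives
exclusively in the report formatters; tests and computations carry full
precision.

## Known limitations

* The empirical percentile reference cannot reproduce component assignments
  made with an unavailable national reference table.
* The published boys low-HDL odds ratio is internally inconsistent with its
  own printed cell counts (cross-product 7.20 vs printed 2.51); the
  reconstruction table carries the counts and flags the row rather than
  checking against the printed value.
* Woolf intervals and Wald logistic CIs are asymptotic; no exact (Fisher)
  or profile-likelihood alternatives are provided.
* The generator's truncated-normal marginals shift means slightly above
  their targets for variables with low floors relative to their SD (≤ ~2%
  for BMI); tolerances account for this.
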