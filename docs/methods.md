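# Methods

## The analysis in one paragraph

Children aged 8–12 run the 20-m shuttle run test; their performance is
expressed as laps, the speed of the last completed stage, and predicted
V̇O2peak.  Obesity is defined from BMI and waist-circumference z-scores
exceeding +2 SD (and their conjunction).  For every
sex × age × obesity-definition × metric stratum the package builds the
empirical ROC of "score ≤ c ⇒ screen positive", estimates the AUC with
DeLong inference, selects an optimal cut-point, tabulates its
diagnostic properties, compares the two V̇O2peak equations with a
paired DeLong test, and quantifies the obesity–fitness association as
crude and adjusted logistic odds ratios for children below the fitted
cut-points.

## Shuttle scoring

The stage schedule starts at 8.5 km/h and adds 0.5 km/h per one-minute
stage.  Laps per stage are `round_half_up(60 s × speed / 3.6 /
course_length)`; with the 20-m course this gives 7, 8, 8, … laps and
cumulative counts 7, 15, 23, …, so 15 completed laps correspond to the
9.0 km/h stage.  The rounding rule is a design choice: half-up
reproduces the published pairing of the 15-lap and 9.0 km/h cut-points,
and an explicit laps-per-stage table can override the derivation for
protocols that publish their own lap structure.  Children completing no
full stage receive the sentinel speed 8.0 km/h (one increment below the
scale) so the speed variable stays ordinal for ROC analysis.  15-m
course records are mapped to the 20-m scale through an external
monotone conversion table before any scoring.

V̇O2peak equations are data, not code.  The shipped registry holds a
Léger speed-and-age set (intercept 31.025, +3.238 per km/h, −3.248 per
year, +0.1536 per km/h·year; validated ages 8–19) and a
FitnessGram-style laps-and-age set (intercept 45.619, +0.353 per lap,
−1.121 per year).  Both transcriptions carry provenance notes and
should be re-verified against their primary sources before scientific
use; alternative coefficient sets load from YAML.  Ages are whole
years; outside an equation's validated range the default is a warning,
configurable to a hard error.  METs are V̇O2peak / 3.5 exactly, rounded
only at the reporting layer.

## Obesity measures

Duplicate anthropometric readings follow the field protocol: the mean
of two readings within tolerance (0.5 cm / 0.5 kg), otherwise the mean
of the closest two of three.  A closest-pair tie resolves to the pair
containing the median reading — deterministic, and identical in value
to any other choice when the gaps are symmetric.  Two discordant
readings without a third raise an explicit error so the record can be
excluded with a logged reason.

BMI z-scores use the LMS transform `((x/M)^L − 1)/(L·S)` with the log
limit at L = 0, against any reference table supplied as CSV (sex, age,
L, M, S); completed years enter a monthly grid at `age×12 + 6` months,
otherwise the nearest grid point.  A WHO-style restricted application
of the reference beyond ±3 SD is available behind a flag, default off,
because the motivating analysis does not state it was used.  Waist
circumference has no reference cut-points at these ages, so waist
z-scores default to internal empirical standardisation within
(sex, whole-year age) groups using the sample SD; the LMS route is also
available.  Obesity is z > +2 (strict inequality; the threshold and
strictness are configurable since published wording and table labels
disagree between ">" and "≥"), and the combined label requires BMI and
waist obesity simultaneously, which guarantees combined prevalence
≤ min(BMI, waist prevalence).

## ROC machinery

Candidate cut-points are the observed score values only — laps, stage
speeds and equation outputs at integer ages are discrete, and
interpolating between them would manufacture unobservable thresholds.
The AUC is the trapezoid area over the empirical curve and equals the
Mann–Whitney statistic (pairs scored 1 if the obese child scores lower,
½ on ties); this identity is enforced by test on random tied instances.
Standard errors use the DeLong placement decomposition in its midrank
formulation, and the paired-equation comparison uses the placement
covariance with a two-sided normal p-value.  Scores that are strictly
monotone transforms of each other have identical placements, so their
AUC difference is exactly zero — the mechanism by which lap, speed and
V̇O2peak cut-points select the same children within a stratum.

Two optimality criteria are implemented because published wording
supports both: Youden's J = sens + spec − 1 (default, the convention of
the software behind most published cut-point tables) and the raw
minimum of false positives plus false negatives.  Ties break toward
higher sensitivity, then toward the lower threshold — screening
prefers catching affected children.  Sensitivity and specificity carry
exact Clopper–Pearson 95% intervals (the CI method behind published
tables is unstated; an exact method never under-covers).  PPV and NPV
come from the observed 2×2 or from a supplied prevalence via the Bayes
identities; LR+ is reported as +∞ at specificity 1 and LR− as undefined
at specificity 0.  AUC discrimination bands on the 2-dp reporting
scale: 0.55–0.62 small, 0.63–0.71 medium, above 0.71 large.

## Association models

Logistic fits go through maximum likelihood (Newton scoring) with a
1e−8 convergence tolerance and at most 100 iterations; perfect
separation raises an error rather than returning silent estimates.
Odds ratios are exp(β) with Wald intervals exp(β ± 1.96·SE), matching
the reporting style of published OR tables.  Adjusted models code age
in whole years (continuous), study site as reference-coded indicators,
and screen time and weekly physical activity as continuous — codings
the source material leaves unstated, fixed here as the package's
convention.  Cohen's d uses the unweighted root-mean of the two group
variances (group sizes in this design are near-equal; the n-weighted
form is available), and Cramér's V uses the uncorrected chi-square.

## Synthetic cohorts

No raw cohort from the motivating study is public, so the generator
emulates its statistical structure: the 8–12 age mix
(11.2/19.7/25.4/32.6/11.1%), a 50/50 sex split, sex-specific lap
distributions (boys mean 26 SD 16, girls 21/11), screen time and
physical activity drawn per sex from the published summaries, and 11
study sites.  Each child gets a trivariate Gaussian latent: one fitness
factor and two adiposity factors (BMI- and waist-scale) correlating 0.8
with each other and −0.40 with fitness — a value that places the
resulting AUCs in the mid-0.6 to 0.7 range typical of this literature.
Laps are the fitness factor rescaled to the sex's lap moments,
truncated at zero and rounded; the truncation's small upward bias on
the calibrated moments is documented, not corrected.  BMI and waist
z-scores are the adiposity factors shifted by
`threshold − Φ⁻¹(1 − prevalence)` so their +2 SD tails hit 15.1% and
5.0%.  The combined-obesity rate is emergent — the bivariate-normal
orthant probability implied by the 0.8 correlation (≈3.9%), not an
independently calibrated target.

All draws come from one fixed-width block of Philox counter-based
uniforms per child, so a child's record is invariant to enlarging the
cohort.  An optional inverse-LMS route emits raw height, mass and waist
consistent with the drawn z-scores, against a clearly-labelled
synthetic LMS table, so the anthropometry chain can be tested
end-to-end against known z.

What the generator does **not** emulate: site-level clustering,
measurement error beyond the duplicate-reading mechanism,
covariate–fitness confounding, non-Gaussian tails in adiposity, or any
higher moments of the real score distributions (only means, SDs and
tail prevalences are constrained).  Passing recovery tests therefore
shows the machinery is correct under the assumed structure, not that
the published empirical cut-points are right.

## Numerical and testing choices

* Trapezoid–Mann–Whitney equality is asserted to 1e−12 (floating
  arithmetic, not symbolic).
* DeLong SEs are validated against 2,000-replicate stratified
  bootstraps (25% relative band) and the paired test against a
  within-subject score-swap permutation reference.
* Clopper–Pearson coverage is checked empirically at n = 50,
  p ∈ {0.1, 0.5, 0.9}, 5,000 replicates.
* Parameter-recovery tests run at n = 50,000, where binomial 3-SE bands
  and the ±0.01 AUC band are informative yet the whole suite stays
  under ten seconds; pipeline-level tests use 2,000–3,000 children.
* The empirical Youden arg-max over discrete laps has cube-root
  asymptotics on a locally flat objective and fluctuates a few laps
  around the population optimum even at n = 50,000; cut-point recovery
  is therefore asserted at two stable levels — the true-law population
  optimum (computed from the bivariate-normal orthant CDF) lies within
  one lap of the binormal density-crossing oracle, and the empirical
  cut-point's achieved J is within 0.02 of the analytic optimum.
* Degenerate strata (a single outcome class, or fewer than two cases
  for DeLong) are skipped with a structured warning, never silently.

## Known limitations

* The two shipped equation transcriptions are conventions of this
  package until verified against their primary sources; results change
  with the registry.
* Internal waist standardisation makes waist z-scores cohort-relative:
  the same child can change label when the cohort changes.
* Wald intervals for odds ratios and normal-theory DeLong p-values are
  large-sample approximations; very sparse strata raise errors instead
  of producing them.
* The 15-m conversion chart shipped for tests is synthetic; analyses of
  real 15-m protocol data need the published chart.
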