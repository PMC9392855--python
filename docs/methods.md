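# Methods

## Physiologic model

A T-piece spontaneous breathing trial loads a ventilated patient with the
full work of breathing. In a patient with adequate cardiopulmonary
reserve, oxygen uptake and CO2 removal rise together; in one without,
anaerobic metabolism sets in, CO2 production outruns oxygen uptake, and
the pair of blood draws bracketing the trial records it. Mod-RER adapts
the exercise-testing respiratory exchange ratio VCO2/VO2 to what two
syringes can measure: the central-venous CO2 tension PcvCO2 is taken as
proportional to CO2 production, and the arterial-to-central-venous O2
tension difference PaO2 − PcvO2 as proportional to oxygen uptake, giving
Mod-RER = PcvCO2/(PaO2 − PcvO2). The assumptions — venous CO2 tension
tracking VCO2, the a-v PO2 gradient tracking muscle O2 extraction up to
the capillary diffusion limit, central-venous values substituting for
mixed-venous ones — are exercise-physiology approximations, crudest
exactly where the index is most useful (early anaerobic transition); the
index is an empirical predictor, not a measurement of either quantity.

Comparator indices computable from the same draws: arterial pH, PaCO2,
ScvO2 and lactate changes; the cv-arterial CO2 gap PcvCO2 − PaCO2 (a
perfusion marker) and the gap-based Mod-RER variant
(PcvCO2 − PaCO2)/(PaO2 − PcvO2); the simplified O2 extraction ratio
(SaO2 − ScvO2)/SaO2; the a-v O2 difference; and P(cv−a)CO2/C(a−cv)O2,
with O2 content C = 1.34·Hb·Sat + 0.0031·pO2 (mL/dL). Each index carries
a polarity: Mod-RER and PaCO2 changes predict failure when positive,
ScvO2 change when negative.

Conventions. Saturations are fractions in (0, 1] internally; CSV input
above 1 is treated as percent and normalised, the only unit
auto-detection performed. Percent change is 100·(post − pre)/pre on the
raw scale, including pH (matching how such tables are reported, not a
hydrogen-ion transformation). Hemoglobin is optional: content-based
indices degrade to missing rather than failing the record, as do indices
with a degenerate denominator (PaO2 ≤ PcvO2 raises in direct calls, and
becomes a missing value with a warning in whole-record derivation). ScvO2
above SaO2 is representable (mislabelled syringes, shunt) but warned
about. The a-v O2 difference defaults to content form (mL/L); the
pressure form (mmHg) is kept because the Mod-RER derivation argues in
partial pressures. Published values for this row (~340) match neither
convention and are not reproduced.

## Statistical procedures

All tests are written from first principles with scipy supplying only
reference distributions; each is pinned to an independent oracle in the
test suite (scipy/statsmodels/pingouin/pROC cross-checks, exact-rational
enumeration, brute-force search).

* Pooled-variance two-sample t and paired t; two-sided p. Zero pooled
  variance degenerates to p = 1 (equal means) or 0.
* Mann-Whitney with midranks and tie-corrected normal approximation, no
  continuity correction. The reported U is U1 = #{pairs with group1
  larger} + half-ties, so U1/(n1·n2) is exactly the empirical AUC — an
  identity asserted to 1e-12 including ties.
* Pearson chi-square on 2×2 tables without Yates correction (the
  uncorrected statistic reproduces the published group comparisons;
  a corrected one would not).
* Fisher's exact test, two-sided by the probability-mass rule: sum of
  hypergeometric probabilities ≤ the observed table's (1+1e-7 rounding
  guard). Verified against exact-rational enumeration for all N ≤ 30.
* Repeated-measurements ANOVA (2 groups × 2 times) via the exact
  two-stratum decomposition: subject means carry the group effect,
  change scores carry time and group × time. Effects are unweighted
  (Type III) contrasts, exact for unbalanced groups; with two time
  points the interaction F is identically the squared two-sample t on
  change scores (asserted to 1e-10), and the per-group time effects are
  paired t-tests.
* Empirical ROC over all distinct observed thresholds plus +∞, ties
  contributing half. AUC inference by the DeLong placement-value
  estimator (digit-identical to R pROC), Wald 95% CI clipped to [0, 1].
  AUC equality across k markers on the same trials: Wald chi-square on
  contrasts against the first marker with the DeLong covariance, k−1 df,
  rank-aware inverse so duplicated markers give p = 1 rather than a
  crash.
* Youden cutoff: maximise sens + spec − 1 over observed score values,
  ties broken toward the smallest oriented threshold (most sensitive
  rule); reported on the original scale with PPV/NPV from the observed
  2×2. The event is predicted at or beyond the cutoff in the
  event-predicting direction.
* Logistic regression by Newton-Raphson; convergence when the relative
  log-likelihood change is below 1e-8, at most 50 iterations;
  non-convergence names the separation-suspect variable. OR CIs are
  exp(coef ± 1.96·se). Stepwise selection uses Wald p-values (entry
  0.05, removal 0.10, both configurable), forward entry of the smallest
  qualifying p followed by worst-first backward elimination, with a step
  bound against cycling and per-candidate skip (not abort) on fit
  failure.

Pipeline routing rules make the published reporting conventions explicit:
continuous covariates use t when both groups have |skewness| ≤ 1
(bias-corrected sample skewness — a stand-in for the by-eye symmetry
judgment) and Mann-Whitney otherwise; categorical covariates use
chi-square unless some expected cell is below 5, which routes to Fisher.
On the reference cohort's printed counts these rules reproduce the
published test assignments row for row. Trials are treated as independent
even when a patient contributes several, mirroring the reference
analysis; this understates the variance of patient-level effects and is
the main inferential caveat.

## Synthetic cohort generator

No patient-level data were published, so the generator emulates the
cohort's *summary* structure: outcome ~ Bernoulli(32/71); per-group
truncated normals for age, days intubated, trial duration and APACHE II
(normal stand-ins are used even where medians/IQRs were printed, with
IQR/1.349 as the SD); per-group Bernoulli prevalences for the seven
comorbidity flags; and for each calibrated index (pH, PaCO2, ScvO2,
lactate, Mod-RER) pre ~ truncated Normal(group mean, SD) and percent
change ~ Normal(group mean, SD), post = pre·(1 + change/100). The first
51 trials get distinct patients; the remaining 20 reuse patients whose
first trial failed, reproducing repeat trials in difficult-to-wean
patients.

Truncation and its costs. A positive index whose printed SD is large
relative to its mean cannot be an untruncated normal, so truncation is
unavoidable and has visible consequences, stated here rather than hidden:
(i) pre draws keep one-sided physiologic floors, so realised pre means
sit slightly above the printed ones (Mod-RER fail group 1.35 vs 1.25,
analytically, and the tests assert the analytic truncated-normal mean);
(ii) change draws are truncated *symmetrically about the group mean*, at
the tighter of the two distances to the feasible interval implied by the
post bounds — one-sided resampling would shift the realised group change
means (an implicit −100% floor biased the success-group Mod-RER change
from 3.3% to ~12% in development), while the symmetric rule preserves
the calibrated means exactly at the cost of shrinking the change SD
where a bound binds (realised success-group Mod-RER change SD ~46 vs
printed 63.7).

Gas back-solve. Downstream code consumes gas panels, not index values, so
panels are reconstructed to reproduce the drawn indices exactly: PaO2 ~
N(78, 12) on [55, 300] and PcvO2 ~ N(42, 6) on [25, 60] with the
difference floored at 5 mmHg; PcvCO2 := Mod-RER·(PaO2 − PcvO2); PaCO2,
ScvO2, pH and lactate are their own calibrated draws; SaO2 follows a
fixed Hill curve pO2^2.7/(pO2^2.7 + 26.6^2.7) of PaO2 (≈0.95 at 78 mmHg,
matching the trial's oxygenation target), resampled jointly with the
tensions so SaO2 > ScvO2. The PaO2 level is chosen so the implied PcvCO2
(~45 mmHg) and cv-a CO2 gap (~6 mmHg) sit on the physiologic scale.
Hemoglobin (not published) defaults to N(10.5, 1.5) g/dL on [7, 17],
constant within a trial, and can be omitted. Because only the calibrated
indices are constrained, *uncalibrated* combinations can stray (a low
drawn Mod-RER can imply a PcvCO2 of ~15 mmHg); the generator reproduces
index distributions, not the joint physiology of real gas panels.

What passing tests therefore show: that the estimators are correct and
the pipeline behaves as specified under the published group-level
distributions with independent indices and multiplicative pre/post
dependence. They cannot show how the indices co-vary in real patients,
the empirical AUCs of the original data (see below), or per-patient
correlation effects. The `pre_post_rho` parameter is reserved for a
bivariate-normal dependence mode and unused by the default multiplicative
model.

## Reproducibility properties and known limits

Every random procedure takes an explicit seed; the same (spec, seed)
yields a byte-identical cohort CSV and an identical analysis report.
Default problem sizes in the tests and acceptance script — 200 cohorts
for ranking frequencies, 10000 binormal replicates for CI coverage, 2000
null cohorts for type-I error, 50 cohorts of n = 500 for stepwise
recovery — keep the full suite in the tens of seconds while holding
Monte-Carlo error well below the tolerances asserted.

Two honest gaps. First, the DeLong Wald CI at the study's group sizes
(32/39, AUC ≈ 0.76) has true coverage ≈ 93.7%, the known small-sample
behaviour of the asymptotic interval (the implementation is
digit-identical to pROC); the coverage check measures this with <0.3% MC
error. Second, the published empirical AUC ordering 0.80 > 0.68 > 0.66 is
only weakly reproducible from the published summaries: the binormal AUC
implied by the published change means/SDs is ≈0.72–0.75 for Mod-RER vs
≈0.66 for both comparators, and with AUC-difference SE ≈ 0.085 at n = 71
the Mod-RER change ranks strictly above both comparators in only ~75–78%
of synthetic cohorts. The corresponding acceptance test asserts the ≥80%
frequency and is expected to fail; the gap is a property of what the
published summaries determine, not of the estimators, and recalibrating
the generator to force a pass would misstate the study conditions.
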