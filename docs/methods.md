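# Methods

## The score

The continuous fall risk score (cFRs) is a composite of ten fall-risk
components measured on community-dwelling adults aged 65+: eight intrinsic
factors — chronic-disease count, physical-impairment count, cognition
(MMSE, 0–30), physical function (CPF, 0–24), multidimensional balance
(FAB, 0–40), fear of falling (FES-I, 16–64), stepping-forward
affordance-perception absolute error (cm), gait (Tinetti gait section,
0–12) — and two exposure factors — habitual physical activity (IPAQ
MET-min/week) and environmental-hazard count (0–34).

Each component x_k is regressed on age and sex by ordinary least squares
over the cohort being scored,

    x_ik = b0 + b1 * age_i + b2 * 1[female_i] + e_ik ,

and the standardized residual z_ik = e_ik / SD(e_k) is the component
Z-score (SD with the n−1 denominator; the residual mean is zero by
construction, so z has mean 0 and SD 1 over the fitting sample). Six
components are protective — higher cognition, physical function, balance,
affordance accuracy, gait quality and physical activity mean *lower* risk
— so their Z-scores are multiplied by −1. The score is the signed sum

    cFRs_i = sum_k s_k * z_ik ,   s_k = −1 for protective components,

which has mean exactly 0 over the fitting sample. The score is
sample-specific: standardization is relative to the cohort in hand. To
compare new individuals against a reference cohort, the fitted
coefficients and residual SDs can be frozen (`save_model` / `apply_model`);
applied to a different population the mean is no longer 0, which is the
point — it is measured on the reference scale.

Participants are *occasional* fallers with ≤ 1 self-reported fall in the
previous 12 months and *recurrent* fallers with ≥ 2. Discrimination of
recurrent fallers is summarised by the ROC curve of the cFRs under the rule
"positive if score ≥ threshold", its AUC (trapezoid over the empirical
curve, identical to the Mann–Whitney probability that a random recurrent
faller outscores a random occasional faller, ties counted half), and the
Youden-optimal cutoff argmax_t (sensitivity + specificity − 1).

### Interface choices

* **Sex adjustment.** The default is one pooled regression with a female
  indicator. An alternative reading of "sex-specific" — separate per-sex
  regressions on age with within-sex standardization — is available via
  `stratify_by_sex=True`. The two agree closely when age slopes are similar
  across sexes; the pooled form is the default because it matches the
  covariate-adjustment description of the derivation and keeps a single
  frozen model applicable to both sexes.
* **Degenerate components.** A component that is an exact linear function
  of age and sex (including a constant) has zero residual SD and cannot be
  standardized; scoring raises an error naming the component rather than
  producing infinities. The guard is relative: residual SD ≤ 1e-10 × the
  component's scale.
* **Youden ties.** When several thresholds attain the maximal J, the
  lowest is returned (favouring sensitivity); with all scores tied this is
  the −inf sentinel, with J = 0.
* **AUC bands.** 0.5 noninformative, (0.5, 0.7] less accurate, (0.7, 0.9]
  moderately accurate, (0.9, 1.0) highly accurate, 1.0 perfect. AUCs below
  0.5 (worse than chance, possible for a mis-oriented component) are
  reported as noninformative.
* **Magnitude bands for Cohen's d** (|d|): < 0.2 trivial, < 0.6 small,
  < 1.2 moderate, < 2.0 large, else very large. The published band edges
  leave |d| = 2.0 unallocated; it is assigned to very large.

## Confidence intervals

* Cohen's d (default 90% level) uses the normal-approximation standard
  error sqrt((n1+n2)/(n1 n2) + d²/(2(n1+n2))); this reproduces published
  two-decimal intervals for group contrasts of this size. A noncentral-t
  interval was considered and rejected as the default because the printed
  intervals match the normal approximation.
* AUC: Hanley–McNeil standard error by default; percentile bootstrap
  (participant-level resampling) as an option. Resamples that lose a class
  are redrawn.
* Sensitivity/specificity: Wilson score intervals without continuity
  correction (the convention of the clinical calculators used for such
  tables).
* PPV/NPV: percentile bootstrap (default 2000 resamples) at the fixed
  cutoff; resamples with an empty predicted class contribute nothing to the
  affected interval.

## Missing data

Missing component cells are handled by fully conditional specification
(FCS): for each of m = 8 completions, missing cells are initialised by
random draws from the variable's observed values, then 10 cycles visit
each incomplete variable (least-missing first), regress it on all other
components plus age and sex over the currently completed data, and redraw
its missing cells as predicted mean + N(0, residual SD) — stochastic
normal-linear regression within FCS, the simplest fully specifiable
variant (predictive mean matching would be the main alternative). Imputed
values are clipped into the variable's valid range; observed cells are
never touched. A per-iteration trace of imputed-cell means is exposed for
convergence checking; with components this weakly coupled the trace is
flat after 2–3 cycles, and 10 is a comfortable default.

Only one score per person is reported despite the 8 completions. The
default policy averages the 8 completed tables cell-wise before scoring
(`ImputationResult.pooled()`); scoring each completion and averaging the
scores (`pool_scores`) is exposed as the documented alternative. The two
differ only through the nonlinearity of the residual-SD normalisation and
agree to well under 0.1 score units on default-size cohorts. Rubin's-rules
pooling of variances is out of scope: no inferential quantity here is
reported per-imputation.

Demographics (age, sex, falls) must be complete; body-composition fields
are passed through without imputation.

## The synthetic generator

Real cohort data for this analysis are not publicly deposited, so the
package ships a generator that emulates the *assumed* structure: group
membership Bernoulli(0.294); sex Bernoulli(0.776 female) independent of
group; age normal per group (73.1 ± 6.4 occasional, 73.8 ± 6.5 recurrent,
floored at 65); the ten components multivariate normal within group with
the published group means/SDs and an exchangeable correlation (default
ρ = 0.2) on the raw component scale; integer-valued scales rounded; all
components clipped into their valid ranges. Falls counts are assigned
consistently with group: occasional → 1 with probability 0.3 else 0 (the
0/1 split is not published; this is an explicit knob), recurrent →
2 + Poisson(1). Missingness is applied per variable at the published
marginal rates (cognition 1.3%, physical function 2.8%, balance 1.1%,
fear 1.7%, affordance 8.5%, gait 4.3%, physical activity 4.6%), missing
at random keyed to age: the oldest tertile is missing at 1.5× the rate of
the younger tertiles, renormalised to the marginal target.

Randomness is split into named sub-streams (group, sex, age, joint
component draw, falls, one per missing variable) seeded as
SeedSequence([seed, stream_index]), so changing missingness settings never
perturbs the component values — which is what makes exact
mask-and-recover experiments possible — and adding a variable leaves
existing columns untouched. The joint component draw is a single stream
because the correlated normals are mixed through one matrix factor.

What the generator does **not** emulate, and what that implies for tests:

* Marginals are normal. The real MMSE distribution is strongly
  left-skewed with a ceiling; under normal marginals the cognitive
  component alone discriminates at AUC ≈ 0.81, higher than any published
  single component. Passing tests therefore show pipeline correctness
  under the stated mixture model, not that real cognition screens this
  well.
* The correlation is a single exchangeable knob on the raw scale; the
  real inter-factor correlation matrix is unpublished. ρ drives how close
  the synthetic composite AUC sits to the published value, and 0.2 places
  the full-pipeline median at ≈ 0.90 (moderately accurate band).
* Rounding and clipping shift means of variables near their floors or
  ceilings (physical activity sits ~1 SD above its zero floor, so
  clipping inflates its mean by ≈ 140 MET-min/week; gait and MMSE press
  their ceilings). Group means reproduce the configured targets exactly
  only where clipping is immaterial, and the tests distinguish these two
  regimes.
* Within the occasional group, the 0-vs-1-fall split is independent of
  the components, so the synthetic zero-fall and one-fall groups share a
  score distribution; the graded three-group trend seen in real data is
  not emulated, only the binary contrast.

## Group statistics and planning

Between-group comparisons use Student's pooled-variance t-test by default
(Welch by flag), Pearson χ² without continuity correction for proportions
(Yates by flag), and one-way ANOVA with Tukey HSD (studentized-range
adjusted p) across the three fall-count groups. The planning formula is
the finite-population-corrected sample size for a proportion,
ceil(N z² p(1−p) / (d²(N−1) + z² p(1−p))) capped at N; with N = 182,988,
z = 1.96, d = 0.05, p = 0.5 it gives 384.

## Problem sizes and tolerances

The test suite works at the study scale (n = 504) or below; the
composite-vs-components property is evaluated over 200 seeded replicates
of the full generate → impute (m = 8) → pool → score → ROC pipeline,
which completes in well under a minute. Exact identities (trapezoid vs.
pairwise AUC, Youden vs. exhaustive scan) are asserted at 1e-12; score
normalisation invariants at 1e-8; stochastic recovery checks at 3 standard
errors.

## Known limitations

* The score is sample-specific by design; cross-cohort comparability
  requires a frozen reference model and stable measurement protocols.
* Equal component weighting is assumed; no principal-component or fitted
  weighting is provided.
* DeLong AUC comparison tests, partial AUC and cost-weighted cutoffs are
  out of scope; the Hanley–McNeil interval is mildly conservative for
  highly discriminative scores.
* The FCS variant is normal-linear; for heavily skewed components
  (physical activity) imputed values rely on clipping rather than a
  distributional transform.
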