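# Methods

This note documents the models, calibrations and numerical choices behind
`dispatchtrial`: what the synthetic generator emulates, how the trial
protocol and analyses are defined, and what passing tests do and do not
demonstrate about real dispatch data.

## The estimand and outcome definitions

Each resource-constrained situation (RCS) contributes one binary primary
outcome: whether the patient given the immediate ambulance response (the
*prioritized* patient — operationally, the first RCS member assigned an
ambulance after randomization in the dispatch log) belongs to the set of
members with the maximal NEWS 2 total. Ties therefore count as correct for
any prioritization strategy, which also fixes the random-choice baseline
at E[|winner set| / |RCS|] > 1/2. The primary contrast is the
intervention-vs-control odds ratio from logistic regression on this
outcome, pooled over imputations; secondaries are the same construction on
an observed composite outcome score (4:2:1:1-weighted mean of the four
binary proxy outcomes, restricted to site 1) and the prioritized-minus-
delayed NEWS difference tested by pooled Wilcoxon rank-sum. For RCS with
more than two members the NEWS difference uses the mean of the delayed
members' scores (a `news_diff_rule="max"` variant is available); the same
winner-set tie rule is applied to the composite outcome as to NEWS. All
arm contrasts are intention-to-treat on the resolved, post-exclusion
events.

## Synthetic cohort model

**Latent acuity.** Each patient carries one scalar a ~ N(0, `acuity_sd`);
it drives the vital signs, the four proxy outcomes
(P(yₖ=1) = expit(αₖ + a), baseline prevalences 0.35 / 0.07 / 0.25 / 0.40),
the model's predictions and (most of) the nurses' perception. A
one-dimensional severity axis is the minimal structure under which model
accuracy, nurse accuracy and NEWS are mutually coherent and tunable.

**Vitals by ordinal band sampling.** For every NEWS component the chart's
scoring bands are ordered by severity and sampled from a proportional-odds
model, P(level ≥ j | a) = expit(θⱼ + β·a) with shared slope
β = `band_slope` (default 0.8); a concrete reading is then drawn uniformly
inside the sampled band (integer grids for counts/pressures, 0.1 °C for
temperature). This gives direct control of the NEWS distribution rather
than indirect control through a physiologic simulator. The global
intercept shift is solved at run time (bisection on a Gauss–Hermite
quadrature of the analytic mean) so that the population mean NEWS equals
`baseline_news` (default 3.0); with a symmetric acuity distribution the
conditional mean at a = 0 is necessarily somewhat below that population
mean (≈2.3 at the defaults). Where the chart has two bands worth the same
points (e.g. brady- vs tachycardia) the generator emits one clinically
typical direction; the scorer accepts the whole chart.

**Nurse perception.** The dispatch nurses' preferred patient is the argmax
of a + w·r̃ + ε, where r̃ is the patient's standardized realized NEWS
residual (NEWS minus its analytic conditional mean, over its conditional
SD), w = `nurse_vitals_weight` and ε ~ N(0, `nurse_noise_sd`). The
residual term represents genuine physiologic information obtained in the
call that the dispatch-data model cannot see. It is structurally
necessary: if nurse and model rankings were both noisy functions of the
*same* scalar, any pair of accuracies near 0.63/0.70 against NEWS would
force their mutual agreement far above the ~0.50–0.54 observed in control
comparisons (a bivariate-normal sign-agreement bound, confirmed
numerically). Letting the nurse see part of the NEWS realization itself
decouples nurse accuracy from nurse–model agreement.

**Model predictions.** Each of the four predicted probabilities is
expit(αₖ + a + ηₖ) with ηₖ ~ N(0, `model_noise_sd`) independent across
outcomes; the composite score is their 4:2:1:1-weighted mean (weights
normalized; only ranks matter downstream, so any strictly monotone
combination is equivalent — the linear mean is documented as an
assumption). Model confidence is the top-two composite gap within a
comparison; the cutoff is the median gap of the calibration set, which by
construction splits it 50/50 within one element. The confidence statistic
is comparison-level; a patient-level variant would need a reference
population the synthetic setting does not define.

**Calibrated defaults.** With `band_slope=0.8`, `model_noise_sd=1.7`,
`nurse_noise_sd=5.0`, `nurse_vitals_weight=0.8` the generator produces:
pairwise NEWS tie mass ≈ 0.13, model pairwise accuracy ≈ 0.70, nurse
pairwise accuracy ≈ 0.645, trial-level control-arm nurse–model agreement
≈ 0.50, cohort mean NEWS ≈ 3.0, median age 77, 45 % female. The exact
triple (nurse 0.63, model 0.70, agreement 0.54) lies slightly outside the
model's feasible frontier; the chosen point keeps the model operating
point and the control-agreement band at the expense of ~1.5 points of
nurse accuracy. `compliance_prob` (the probability that an
intervention-arm dispatcher defers to the displayed recommendation) is
0.615, obtained from the calibration identity c = (t − q)/(1 − q) with
target observed agreement t = 0.809 and chance agreement q ≈ 0.504
(`risk.calibrate_compliance`); observed agreement and the behavioral
deferral parameter are deliberately distinct quantities.

**Missingness.** Documentation gaps are two-stage: ambulance-stage
per-component rates of 11.0–14.2 % (the two extremes anchored at pulse and
temperature, the rest interpolated), then hospital supplementation
restores entries to final rates of 3.7–4.8 %. By default the per-patient
log-odds of missingness are tilted by −0.3·a (sicker patients are more
completely documented, a mild MAR mechanism that exercises the imputation
machinery nontrivially); `mcar=True` switches it off. Missingness applies
to the *observed* outcome data only; the decision process sees the true
state of the patient.

**Protocol behavior.** Base RCS sizes are drawn from P(2)=.82, P(3)=.14,
P(4)=.04 (mean ≈ 2.22; the source flow tables print only totals, so this
is a calibration choice). After a control assignment dispatchers re-roll
with probability 0.20 (0.15 after intervention); a re-roll repeats the
identical set (the randomizer's memory returns the same arm; only the last
event is analyzed) or, with probability 0.40, adds a late-arriving patient
and re-randomizes the grown set, which draws a fresh arm and creates the
protocol-violation asymmetry (most violations begin as control
assignments). With 1,570 base RCS this yields ≈1,845 randomization events,
≈19 % violation exclusions and, with a 0.08 per-patient opt-out
probability, ≈1,250 analyzable RCS of ≈2,800 patients. Dispatch delays are
lognormal dressing on the assignment order (median ≈30 min for the
prioritized patient); only the order enters any hypothesis test.

## Imputation

Chained equations on the component measurement scale; NEWS totals are
computed only after completion, never imputed directly. Both engines
impute by donor draws, so imputed values always lie in the observed
support (valid ACVPU levels, booleans, physiologic ranges); consciousness
is carried as an ordinal A<C<V<P<U code. The default engine fits a small
random forest (10 trees, depth ≤ 12, ≥5 samples/leaf) per component per
iteration and draws each missing entry from a random tree's leaf donors;
the `pmm` engine uses bootstrap-OLS predictive mean matching with k = 5
donors and is roughly an order of magnitude faster — the heavy Monte-Carlo
tests use it. Defaults: m = 10 chains, 10 iterations, all demographic and
vitals columns as predictors (which auxiliaries entered the original
analysis is unrecorded; this is documented as an assumption). Mixing is
summarized per component by a PSRF-style between/within ratio on the
second-half chain-mean trajectories, clamped below at 1.0 so identical
chains score exactly 1.0, flagged above 1.2. With few chains or iterations
this statistic is noisy by construction; treat single flags at small m as
advisory. Rubin pooling rather than median-of-m is the only inference
path; a median-of-m variant exists solely for sensitivity analysis.

## Pooled inference

Logistic models are fitted per imputation by maximum likelihood
(statsmodels), falling back to Jeffreys-prior (Firth) penalized likelihood
on separation or non-convergence, flagged in the output. Coefficients are
pooled on the log-odds scale with T = W + (1+1/m)B and Barnard–Rubin
degrees of freedom (complete-data df = n − p − 1). Rank-sum tests use the
tie-corrected normal approximation without continuity correction and are
pooled on the z scale with unit within variance. P-values are reported
continuously everywhere; no output table dichotomizes significance.

## Counterfactuals and ancillaries

The 100 %-compliance counterfactual substitutes the model's top pick for
the prioritized patient in intervention-arm events only, recomputes
correctness per imputation and reruns the pooled logistic against the
untouched control arm; the blended strategy substitutes only in
high-confidence intervention events. Both coincide exactly with the
observed analysis in their degenerate limits (compliance = 1; all
comparisons low-confidence). Drift surveillance computes monthly
Spearman correlations between composite score and NEWS (months with <10
patients excluded) and regresses them on months-since-last-model-update,
with the update months (defaults 10 and 40) resetting the clock. The
calibration check regresses NEWS on the composite score plus age, sex and
call-type indicators by OLS, dropping aliased columns, and reports which
demographic terms retain residual significance. The power utility
implements the standard unpooled two-sample normal-approximation formula
and explicitly flags that, at 65.3 % vs 70.3 % with α = 0.05 and power
0.8, it requires ≈1,367 per group — planning documents citing ≈1,500
*total* for that effect are not reproducible by this (or any standard)
formula.

## Problem sizes in the test suite

The type-I-error check runs 1,000 replicate null trials (intervention
display disabled so both arms share the decision process) of 200 analyzed
comparisons with m = 5 PMM imputations each and asserts the pooled primary
test rejects in 3.5–6.5 % of them. Two structural effects push the true
rate below nominal at this scale, and the check measures them honestly
rather than hiding them: per-RCS correctness probabilities are
heterogeneous (tied comparisons are always "correct"), so the binomial
Wald variance Σ-bound is conservative; and with the *outcome* itself
multiply imputed, the pooled estimate averages conditional expectations of
the missing members' correctness (a Rao–Blackwellization), so its true
sampling variance falls below the complete-data variance W estimates and
T = W + (1+1/m)B over-covers. The pooled test is therefore conservative —
never anticonservative — in small trials with imputed outcomes; the effect
shrinks as the number of comparisons grows. Parameter recovery runs one 10,000-RCS trial for the observed
intervention-arm agreement (±2 points of the 80.9 % calibration target)
and 200 replicate 600-RCS trials whose mean pooled log-odds ratio is
compared, within Monte-Carlo error, to the effect measured on a single
120,000-RCS complete-data run. The replicate-recovery comparison is run at
zero missingness so that it isolates the decision process; imputation
behavior is covered separately by the type-I check (which imputes every
replicate) and by an MCAR oracle test comparing the pooled mean NEWS to
the complete-data mean.

## What the synthetic data do and do not show

The generator reproduces the *structure* the analyses rely on — a severity
signal observable three different ways with controlled fidelities, banded
vitals with realistic tie mass, MAR documentation gaps, protocol
violations with the observed arm asymmetry — but real dispatch data differ
in ways no passing test here addresses: call-type-specific vital
signatures, multi-dimensional acuity, temporally clustered RCS and shared
ambulances across overlapping comparisons, non-ignorable missingness for
patients never transported, and drifting case mix. Conclusions supported
by this package are about the correctness and calibration of the
*machinery* (scoring, protocol rules, imputation, pooling,
counterfactuals), not about the clinical effect size, which is an emergent
property of the calibrated behavioral rates.

## Known limitations

- SpO2 Scale 2 (hypercapnic target ranges) is unsupported; no data field
  carries the flag that would select it.
- The confidence indicator is comparison-level; a patient-level population
  split is not defined in the synthetic setting.
- Opt-out exclusions are independent per patient; the generator does not
  model household or repeat-caller correlation.
- The mixing diagnostic is a scalar summary; with m ≤ 5 chains it has
  appreciable sampling noise and the 1.2 threshold should be read as a
  screen, not a test.
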