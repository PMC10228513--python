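# Methods

## Setting and estimand

A randomized trial with a continuous final outcome `Y`, baseline covariates
`L0`, randomized arm `A0 ∈ {0,1}`, and an intercurrent event (ICE) that can
occur at one or two post-baseline timepoints.  The ICE indicators `A1`, `A2`
are cumulative and absorbing: `A_k = 1` means the ICE has occurred by
timepoint k, so `A1 = 1` forces `A2 = 1` and non-absorbing patterns are
rejected at validation rather than reinterpreted.  Post-baseline covariates
`L1` (and `L2`) are measured before the corresponding ICE opportunity; the
package assumes `L1` precedes `A1` and is always observed (the causal
ordering `L1 → A1` requires it).

The estimand is the hypothetical no-ICE mean `E(Y^{a0, 0[, 0]})` per arm and
their difference.  Only the all-zeros ICE regime is supported —
`EstimandSpec` rejects anything else — because that is the regime for which
the missing-data/causal-inference correspondence is exact.

Identification rests on three assumptions, which the simulator satisfies by
construction and the estimators presuppose on real data:

* **Consistency** — a patient whose history matches the regime has
  `Y = Y^{a0,0,…}`.
* **Sequential exchangeability** — the ICE at each timepoint is independent
  of the hypothetical outcome given arm and measured covariate history.
  Operationally: `L0, L1(, L2)` must contain *all* common causes of ICE
  occurrence and outcome, not merely repeated outcome measurements.
* **Positivity** — every attainable history has positive probability of
  remaining ICE-free at each timepoint.  Protocol-mandated ICEs
  (deterministic threshold rules) violate this; see "Deterministic ICEs".

## Estimators

**G-formula.**  `gformula_single` fits an outcome mean model by OLS and
averages its no-ICE predictions over the arm's patients, standardizing over
the empirical `(L0, L1)` distribution rather than a parametric covariate
model.  Model scope and arm pooling are orthogonal switches:
`ice_free_only` fits among patients with no ICE at the modeled stage (no
post-ICE data enter anywhere; deleting or corrupting post-ICE values cannot
change the estimate — a tested invariant), `all_data` fits on every row with
observed outcome and includes the ICE indicators as covariates (more
precise when correct, more assumptions; rows with missing post-ICE outcome
are dropped from the fit with a warning, never from the standardization
population).  `pooled` replaces per-arm fits with a single model carrying
`A0` as a covariate.  At two timepoints, `gformula_two_timepoint` fits
`E(L2 | A0, A1=0, L0, L1)` and substitutes its prediction into
`E(Y | A0, A1=0, A2=0, L0, L1, L2)` — an exact coefficient composition for
models linear in `L2`.  For the all-data scope the L2 model mirrors the
ICE-free covariate set plus `A1` (the covariate set for that variant is a
package choice; nothing forces it).  `gformula_monte_carlo` instead draws
L2 from the fitted Gaussian residual law `n_mc` times per patient; it
converges to the plug-in composition for linear outcome models and remains
valid for nonlinear ones.  Default mean structures are main effects;
richer structure (interactions, saturated models, basis expansions) is
available through patsy right-hand-side formulas over the covariate
columns, with treatment/ICE indicators appended as main effects.

**IPW.**  Unstabilized weights
`W_i = P(A0=a0_i)^{-1} ∏_k P(A_k=a_{k,i}|history)^{-1}` with the
randomization probability treated as known (it is, in an RCT; 1:1 makes the
first factor exactly 2).  ICE probabilities are logistic regressions on the
history, pooled or per arm; the timepoint-2 model is fitted only among
patients ICE-free at timepoint 1, so no model for post-ICE dynamics is ever
specified, and the timepoint-2 factor for patients with an earlier ICE is 1
(absorbing pattern).  The estimate is the Hajek (normalized) weighted mean
over regime-compatible patients — there is deliberately no Horvitz–Thompson
option, since the normalized form is what the identity with the
missing-data weighting estimator concerns.  Because "hypothetical outcome
observed" and "ICE-free" are the same event, the
inverse-probability-of-missingness estimator is the identical computation;
`ipw_missingness_estimate` simply calls `ipw_estimate`, and a test pins the
bit-level equality.  Weight truncation is available as an explicitly
labeled diagnostic option only — it changes the estimand and is off by
default.  An estimated no-ICE probability of exactly 1 for an ICE-free
patient contributes a finite factor of 1 (reported through diagnostics); a
probability of exactly 0 for a required history is an error naming the
patients.

**Factored MLE.**  Treating `Y^{no ICE}` (and `L2^{no ICE}` at K=2) as
partially observed with a monotone missingness pattern, the joint-normal
likelihood factorizes, so the MLEs are stagewise OLS fits: the L1 model on
all (arm) patients, the L2 model among `A1=0`, the outcome model among the
fully ICE-free.  The arm mean composes those coefficients at the arm sample
mean of `L0` (its nonparametric MLE).  This route is implemented
independently of the G-formula route — prediction at covariate means versus
the mean of per-patient predictions — and their equality is exactly the
property OLS guarantees (fitted values average to the fitted value at the
mean, and residuals are mean-zero within any group spanned by the design).
The identity therefore holds on *every* dataset; `certify_equivalence`
checks it at tolerance `1e-8`, a comfortable ceiling for two OLS solves in
double precision whose observed gaps are ~1e-15.  The identity is certified
for matched arm pooling only (per-arm against per-arm, pooled against
pooled); a mismatched pairing is either refused or, on request, reported
with a `theorem_covered = False` flag as a negative control.  The pooled
pairing at two timepoints is verified numerically on the same footing as
the rest — the package treats it as an empirical certificate, not a
re-derivation.

**Multiple imputation.**  Proper MI with the same mean structures: residual
variance drawn as `SSE/χ²(df)`, coefficients from
`N(β̂, σ²(XᵀX)^{-1})`, missing hypothetical values imputed from the
conditional normal (L2 first at K=2, then Y given completed L2), and the
completed-data arm means pooled by Rubin's rules with the Barnard–Rubin
small-sample t reference.  Because the imputation model matches the MLE fit,
the M→∞ limit is the MLE (hence G-formula) value; the Monte-Carlo SE
reported in the diagnostics (`between-imputation SD / √M`) quantifies the
remaining gap and the test suite checks it at M = 10⁴.

**Naive comparator.**  The unadjusted mean difference among ICE-free
patients — the analysis one gets by deleting post-ICE data and adjusting
for nothing.  It is included in the estimator menu as the foil: the study
conditions are designed so its bias is clearly detectable while the
adjusted estimators' is not.

## Simulator

Structural models are drawn in topological order
`L0 → A0 → L1 → A1 (→ L2 → A2) → Y`, all linear with Gaussian noise; the
ICE mechanism is logistic in the history or a deterministic threshold rule
(`A1 = 1` iff the marker strictly exceeds the threshold; ties go to
no-ICE).  The two counterfactual worlds (each arm, ICE forced off) reuse
every exogenous draw of the factual world.  This single-world coupling is
stronger than the estimand requires — only the marginal law of the
counterfactual is needed — but it makes consistency testable patient by
patient: ICE-free patients in the matching arm have `Y` equal to the
counterfactual *exactly*, and the test suite asserts that equality, not an
approximation.  Counterfactual columns exist only on simulated data, are
stripped by `TrialDataset.analysis_frame()` (the only view estimators
read), are not written to CSV unless requested, and a property test
confirms estimates are unchanged when they are deleted outright.

`true_estimand` propagates means through the structural equations with the
regime substituted — exact, no simulation.  Every scenario expressible in
`ScenarioConfig` is linear-Gaussian, so the closed form always applies; the
Monte-Carlo cross-check (mean of the counterfactual columns at n = 10⁵
within 3 standard errors) is a test, not a fallback.

The packaged default scenarios are calibrated to a glycemic-control trial
with rescue medication as the ICE: baseline HbA1c ~ N(8.0, 1.0) %, an
interim HbA1c lowered by ~0.5 points under active treatment, rescue uptake
logistic in the interim value with per-arm rates around 25–40% (typical of
add-on rescue designs), and a final HbA1c responding to both the marker
and treatment.  The interim marker drives both rescue and outcome strongly
— that is deliberate: these are the conditions under which the naive
analysis fails visibly and adjustment is worth testing.  The true
hypothetical effect in `rescue_k1` is −0.775 points.  `threshold_k1`
replaces the logistic mechanism with the protocol rule "rescue iff interim
HbA1c > 8.3".  `null_k1` removes all treatment effects.  The deterministic
rule conditions on a single marker; a vector-threshold protocol is not
expressible (use the logistic mechanism to approximate one).

What the generator does **not** emulate: non-Gaussian or binary outcomes,
dropout unrelated to the ICE, missed visits, measurement error, multiple
ICE types, more than two ICE timepoints, or treatment nonadherence distinct
from the ICE.  Passing tests therefore certify the estimators' algebra and
their behavior under correctly specified linear-Gaussian mechanisms — they
do not certify robustness to the model misspecification real trials face,
beyond the specific misspecifications the suite constructs on purpose.

## Deterministic ICEs

When the protocol mandates the ICE above a marker threshold, positivity
fails and the estimand is not nonparametrically identified.  The package's
behavior mirrors the two honest options.  IPW with the correctly specified
(known) mechanism produces weight 2 for every patient — each ICE factor is
the reciprocal of a probability equal to 1 — so the estimate collapses to
the unadjusted ICE-free mean, which is biased whenever the marker predicts
the outcome; the replicate tests measure that bias at hundreds of
Monte-Carlo SEs.  G-formula/MLE/MI recover the truth, but only because the
linear outcome model extrapolates correctly beyond the observed marker
range; the suite also fits a threshold-truncated outcome model (flat beyond
the protocol cut-off) to show the recovery is a property of the
extrapolation, not of the estimator.  Attempting to *estimate* the
deterministic mechanism by logistic regression is perfect separation and
surfaces as `SeparationError` — never as silently enormous coefficients —
with an opt-in "flag" mode (pseudo-inverse IRLS fallback) so the
positivity diagnostics can still describe the degenerate fit.

## Numerical choices

* OLS via `numpy.linalg.lstsq` preceded by a pivoted-QR rank check
  (relative tolerance 1e-9 on the R diagonal).  Rank deficiency raises
  `SingularDesignError` naming the collinear columns; there is no silent
  pseudo-inverse fallback, because the downstream coefficient compositions
  assume an identified fit.
* Logistic fits via `statsmodels.Logit` (Newton); statsmodels'
  perfect-separation warning, convergence failure, or a singular Hessian
  are promoted to `SeparationError` under the default policy.
* Patient order never matters (shuffle-invariance is property-tested), and
  CSV round trips are exact: floats are parsed with
  `float_precision="round_trip"`.
* Missing cells are empty strings in CSV; the literal `NA` is accepted as
  an opt-in synonym.
* All randomness flows through `numpy.random.default_rng` with mandatory
  seeds (no wall-clock fallback).  Study sub-streams derive per-cell seeds
  below 2³¹ from `SeedSequence([study_seed, scenario, (estimator,) rep])`,
  so any cell reproduces in isolation and all estimators of a scenario see
  identical datasets.
* Bootstrap: patient-level resampling of the whole trial (not stratified),
  percentile intervals, all nuisance models refitted per resample; failed
  resamples are dropped and counted, with >10% failures an error.

## Study sizes used by the test suite

The replicate-level checks run at sizes chosen to separate signal from
Monte-Carlo noise while keeping the default suite quick: 100-dataset sweeps
(n = 200) for the equivalence identities, 500 replicates at n = 1000 for
bias of G-formula/IPW/MLE versus the naive contrast and for the
deterministic-ICE pathology, 1000 replicates for the all-data precision
comparison, and M = 10⁴ imputations for the MI limit.  Bias conclusions use
the 3-Monte-Carlo-SE yardstick throughout, with the truth supplied by
`true_estimand`.

## Limitations

* Hajek IPW inherits heavy-tailed weights when fitted no-ICE probabilities
  approach 0; the two-timepoint default scenario already shows visibly
  slower convergence for IPW than for the outcome-model estimators.  The
  diagnostics (ESS, minimum probability, flags) are the intended first
  line of defense; stabilized weights and doubly robust augmentation are
  out of scope.
* Variance estimation is bootstrap-only; no sandwich estimators.
* Two ICE timepoints at most, one ICE type, wide single-outcome format; no
  survival or binary endpoints.
* The MLE/MI implementations fix the linear main-effect mean structure
  (that is what makes them the factored-normal MLE); formula descriptors
  are rejected there rather than silently changing the model family.
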