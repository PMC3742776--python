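# Methods

## Outcome and variable coding

The follow-up wall motion index score (WMIS) lives in [0, 4]; 1.0 denotes
fully preserved contractility and acts as a hard floor (a patient cannot
score better than "all segments normal" in practice, and the observed
distribution has a point mass there).  The binary endpoint is
`impaired = 1{WMIS > 1.2}`, strictly greater — 1.2 itself belongs to the
preserved group — and is always recomputed from the stored WMIS, never
trusted from a file.  Clinical flags are coded 1 = present / 0 = absent;
sex enters as a female indicator (male reference).  Nt-proBNP is used on
the log₁₀ scale, miRNA expression on the log₂ scale of the spike-in ratio
`2^(mean spike Ct − target Ct)`; both transforms are conventions of the
package and are recorded in the cohort metadata (raw scales can be supplied
instead).  The spike-in mean is the arithmetic mean of the three control
Ct values, which equals a geometric mean on the expression scale — standard
qPCR practice.  Age is modelled in raw years.

## Regression families

**Logistic** fits are Newton–Raphson/IRLS on the binomial log-likelihood
with step-halving; convergence requires a relative log-likelihood change
below 1e-10 (max 200 iterations).  The covariance is the inverse observed
information at the optimum.  Rank deficiency is detected from the QR
diagonal and reported with the offending column names.  Quasi-complete
separation is declared when any |β̂ⱼ|·sd(xⱼ) exceeds 15 — generous enough
never to fire on well-posed fits, tight enough to catch the runaway
estimates that small bootstrap resamples produce.

**Tobit** fits maximise the left-censored normal likelihood over
(β, log σ) — the log parameterisation keeps σ positive without constraints
— using BFGS with analytic gradients, started from OLS on all observations,
followed by damped Newton steps (finite-difference Hessian of the analytic
gradient) until the gradient sup-norm is below 1e-6.  Observations within
1e-12 of the floor are censored; values below the floor are rejected as
data errors.  With zero censored observations the likelihood reduces to the
uncensored normal and the closed-form Gaussian MLE (σ̂ with 1/n) is
returned directly.  The covariance is the inverse observed information,
delta-transformed from log σ to σ.

Parameter counting for AIC = 2k − 2·loglik includes the intercept and, for
tobit, σ; this keeps the AIC comparable across the base and extended rows
of one family's selection table.  All 95% intervals use z = 1.959964.
Per-term tests are Wald chi-squares (logistic) and Z tests (tobit); the
1-df p-values coincide between the two parameterisations.  The "global"
Wald test covers all non-intercept terms — whether such a test should
include only the added markers is genuinely ambiguous, so the choice is
recorded in the selection-table metadata.

## Panel selection

All 2^m − 1 non-empty subsets of the m-marker panel are enumerated — sizes
ascending, input order within a size — and each is added to the clinical
base model.  Rows carry the global Wald p, AIC, and the LRT p against the
base fit.  The AIC argmin (base row included, so "no miRNA" can win) is the
selected model; exact AIC ties break towards the smaller subset and then
enumeration order, purely for reproducibility.  A subset whose fit fails
(typically separation in a resample) is flagged and excluded from the
argmin rather than aborting the table.

## Reclassification

The continuous NRI counts risk movements: up if p_new > p_old, down if
smaller; exact ties (tie_eps = 0 by default, configurable) count in neither
direction while the denominators remain the full group sizes.  Its standard
error is the large-sample multinomial form
`sqrt[(p↑ₑ + p↓ₑ − (p↑ₑ − p↓ₑ)²)/nₑ + (p↑ₙ + p↓ₙ − (p↓ₙ − p↑ₙ)²)/nₙ]`.
The IDI is the difference in discrimination slopes; its SE combines the two
groups' standard errors of the mean paired risk difference in quadrature.
Both variance estimators admit variants in the literature; the chosen forms
are validated against bootstrap SEs on synthetic cohorts in the test suite.

These in-sample quantities are *apparent*: refitting even a pure-noise
marker inflates them (the measured nullity-test rejection rate for the NRI
of a refitted noise marker is ~3× nominal at n = 150), which is precisely
the optimism the validation stage removes.  The z-test does hold its level
when the two risk vectors are externally given rather than refitted.

For the tobit family, where reclassification needs a probability, the
package uses the model-implied exceedance probability
`P(WMIS* > 1.2 | x) = 1 − Φ((1.2 − xβ̂)/σ̂)` — the natural censored-model
analogue of the logistic fitted probability.

## Bootstrap internal validation

Each of B = 150 replicates draws n patients with replacement (unstratified
by default; a stratified option exists), reruns the entire subset search on
the resample, fits the selected and base models on the resample, and
computes the measure twice: on the resample (train) and, with the
resample-fitted coefficient vectors, on the original sample (test).  The
base comparator is the resample-refit base model in both evaluations —
symmetric refitting avoids mixing apparent and honest estimates.  Optimism
is mean(train − test); corrected = apparent − optimism.  Replicates with a
single-class outcome or any failed fit are redrawn (capped at 10·B
attempts, all counted and logged) so B stays fixed.  Replicates that select
"no miRNA" contribute zero to both train and test.  Selection frequencies
are reported over all successful replicates, including base-model
selections, rather than silently renormalising over marker-containing ones.

## Borderline patients

Borderline means 1 < WMIS < 1.4, strict at both ends.  Each borderline
patient is left out in turn; both logistic models are refitted on everyone
else (non-borderline patients always stay in the training set — the only
reading consistent with omitting *these* patients one by one); the held-out
patient classifies at probability ≥ 0.5 (ties to impaired).  Confusion
matrices accumulate over borderline patients only; folds whose fit fails
are skipped with a warning and reported.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes, not
any particular patient: independent covariates with realistic AMI-cohort
prevalences (male 0.77, smoker 0.40, family history 0.39, diabetes 0.16,
hypertension 0.35, hypercholesterolaemia 0.27, prior MI 0.08, STEMI 0.85,
anterior 0.39), age ~ TruncNormal(63, 12²; [24, 87]) in integer years,
log₁₀ Nt-proBNP ~ TruncNormal(2.8, 0.6²; [0.2, 4.0]), and per-miRNA normal
log₂ levels.  The latent outcome is

    WMIS* = α + Σⱼ γⱼ·zⱼ + ε,   ε ~ N(0, τ²),

with covariates standardized against their generating distributions so that
slope magnitudes are comparable; observed WMIS clips WMIS* to [1.0, 4.0]
(the upper clip binds < 0.1% of draws).  Effect directions are fixed —
positive for Nt-proBNP, miR-16, miR-27a, anterior, prior MI, STEMI;
negative for miR-101 and miR-150 — and magnitudes (0.20, 0.15, 0.18, 0.12,
0.08, 0.10, −0.12, −0.20) are a modelling choice giving model-2-style odds
ratios of the right order at n = 150, not ground truth.

Two marginal targets pin the remaining parameters analytically: a floor
point mass of 55/150 and an impaired fraction of 71/150 give the marginal
latent SD s = 0.2/(Φ⁻¹(79/150) − Φ⁻¹(55/150)) = 0.49069, hence
τ = sqrt(s² − Σγ²) = 0.24633 and α = 1 − s·Φ⁻¹(55/150) = 1.16718.
`calibrate_intercept` re-solves α for any floor target and is idempotent.
Discharge WMIS is generated as follow-up plus N(0.12, 0.15²), clipped — a
realism feature unused by the inference stages.  Each component (covariate
block, each marker, latent noise, discharge shift) draws from its own
fixed-offset RNG sub-stream, so extending the marker panel never perturbs
the other draws.

What the generator deliberately does *not* emulate: covariate correlation
(real risk factors cluster; only marginals are specified here), miRNA
co-expression, non-normal biomarker tails, and any missingness.  Passing
tests therefore demonstrate correctness of the *procedure* under the
model's own assumptions, not robustness to real-data pathologies.

A separate `borderline_scenario_config` (weak clinical slope 0.15 on
Nt-proBNP, one strong marker at 0.40, τ = 0.13, n = 300, recalibrated
intercept) constructs the regime where classification near the threshold is
driven by the marker alone; it exists to exercise the borderline LOOCV
comparison, not as a default.

## Problem sizes and numerical checks in the test suite

Simulation-based checks run at the sizes stated in their tests: generator
calibration over 200 cohorts of n = 150; tobit slope recovery at n = 5000;
Wald CI coverage over 200 default cohorts (observed ≈ 0.94, band
[0.92, 0.98]); LRT type-I error at n = 150 over 1000 replications per
family; bootstrap optimism over 50 outer cohorts × B = 150 replicates with
pure-noise markers; borderline LOOCV over 100 scenario cohorts.  The full
pipeline is run twice at B = 150 to assert byte-identical artifacts.
Independent oracles are used wherever one exists: statsmodels and a
gradient-free optimizer for the logistic likelihood, R's
`survival::survreg` for the left-censored gaussian fit, closed-form 2×2
odds ratios with Woolf intervals, and direct-count / discrimination-slope
recomputations for NRI and IDI.

## Known limitations

* The tobit observed information uses a finite-difference Hessian of the
  analytic gradient; for extremely ill-conditioned designs an analytic
  Hessian would be preferable.
* The NRI/IDI variance estimators are the standard large-sample forms; no
  small-sample or clustered variants are provided.
* No categorical NRI, no .632(+) bootstrap, no external-cohort validation,
  no penalised-likelihood fallback for separated logistic fits — separated
  candidate fits are excluded/redrawn instead.
* Generator covariates are mutually independent by construction.
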