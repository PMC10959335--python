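# Methods

## Estimands and outcome scale

Analyses contrast two treatment arms (reference T=0, comparator T=1) on a
restricted survival functional at a cut-off t₀, default 3.2 years — in the
motivating application the mean and median follow-up, and always
configurable:

* **RMST difference** (years): ∫₀^t₀ S₁ − ∫₀^t₀ S₀;
* **restricted hazard ratio** rHR = H₁(t₀)/H₀(t₀), H = −log S(t₀), on the
  *marginal* (population-averaged) survival of each counterfactual arm;
* **odds ratio** of event-by-t₀ for binary analyses, computed on the
  subsample whose status at t₀ is known (follow-up ≥ t₀ or an earlier
  event).

Censored follow-up is converted to complete-data pseudo-observations
Y_i = n·θ̂ − (n−1)·θ̂^(−i) of the chosen functional, computed **within each
arm** so each arm's pseudo mean equals its own Kaplan-Meier functional.
The leave-one-out values are obtained analytically from shared prefix
products of the product-limit factors (O(n) after sorting, exact to
floating precision against brute-force refits), so pseudo-observations are
cheap enough to recompute inside every bootstrap replicate.

Assumptions: independent right-censoring (given covariates for the
adjusted variant), no competing risks, no left truncation, consistency and
conditional exchangeability given the measured baseline covariates.

## Pseudo-observation variants

* `jackknife` (default): marginal Kaplan-Meier jackknife. Correct when
  censoring is covariate-independent — which holds in the default
  synthetic designs.
* `covariate_adjusted`: inverse-probability-of-censoring weighting with a
  proportional-hazards censoring model on the baseline covariates,
  Ŝ(t) = n⁻¹ Σ 1(T_i > t)/Ĝ_i(t), jackknifed with Ĝ held fixed (for
  mean-type functionals the jackknife of a sample mean returns the
  per-subject summand exactly). Ĝ is floored at 0.05 as a positivity
  guard; a failed censoring-model fit falls back to the jackknife with a
  warning. Under covariate-independent censoring the two variants agree
  (tested at n=2000 to within 2% of the functional).

Degenerate tails: when Ŝ(t₀)=0 the cumulative hazard is capped at −log ε
with ε = 1/(2 · risk-set size at that curve's last event), keeping
pseudo-values finite; the event subject that is alone in the final risk
set simply loses that event time in its leave-one-out curve.
Ties: events precede censorings at the same time (standard product-limit
convention).

## Strategy ensemble

Treatment models: plain logistic, forward-stepwise logistic
(likelihood-ratio entry/stay thresholds 0.05/0.05), elastic-net logistic
with internally cross-validated penalty (l1 ratio 0.5), random forest
(200 trees, min leaf 25), gradient boosting (100 trees, depth 2, learning
rate 0.1). Scores are clipped to [0.01, 0.99].

Adjustments: Hájek (normalised) IPW with ATE weights truncated at their
99th percentile; 1:1 nearest-neighbour matching on the logit score,
caliper 0.2·SD, without replacement, treated processed in seeded random
order; quantile stratification (5 strata) with stratum-size weights,
single-arm strata merged downward and logged.

Outcome models: Cox (Efron ties) with main effects or all two-way
interactions of the one-hot model matrix (treatment-by-covariate
interactions included by default, switchable), ridge-penalised Cox
(penaliser 0.1), Weibull parametric survival, and random-forest /
gradient-boosting regressions of the pseudo-observations on covariates
plus treatment — regressing the pseudo-outcome puts every strategy on one
prediction scale, which the CvMSPE comparison requires. `per_arm=True`
fits separate models per arm. An intercept-only `arm_means` outcome model
provides the unadjusted contrast.

Counterfactual predictions m̂(0,x), m̂(1,x) are produced for every patient
by toggling treatment; survival-model predictions are converted to the
functional scale (step integration of the fitted curve for RMST,
H₀(t₀)·exp(lp) for the cumulative hazard). For the rHR estimand the
counterfactual predictions are marginalised on the **survival** scale
(g-formula: S̄_t = mean_x exp(−m̂(t,x))) before taking −log, so outcome
models target the same marginal rHR as the Kaplan-Meier-based strategies;
for constant (weighting-based) predictions the two computations coincide.
Strategies that fail to converge are dropped from the average and logged,
never imputed.

## Scoring, weights, averaging

CvMSPE(S) = (N₀+N₁)⁻¹ Σ (Y_i − m̂_S^(−i)(T_i,x_i))², with the superscript
−i approximated by stratified K-fold cross-validation (default K=10; K=n
gives exact leave-one-out). All strategies in a roster are scored on a
**common fold partition** (the fold seed is separate from the model
seed): CvMSPE differences are then paired comparisons, not partition
noise.

The weight map is w_S ∝ exp(−N·(CvMSPE_S − min CvMSPE)/(2·σ̂²)) with
σ̂² = min CvMSPE — a scaled softmax chosen because it degenerates to
best-model selection as N → ∞ and to uniform weights under ties;
inverse-CvMSPE and top-1 rules are selectable and the rule in force is
recorded in result metadata. Ratio estimands are averaged (and
bootstrapped) on the log scale for symmetry and positivity. The
best-model estimate (minimum CvMSPE) is reported alongside the average.

Percentile-bootstrap CIs resample patients with replacement within each
arm (conditional on N₀, N₁) and re-run the entire pipeline — pseudo-
observations, strategy fits, cross-validation, weights — per replicate
(B default 500); a replicate failure rate above 20% aborts with
diagnostics. Multiple outcomes are reported without multiplicity
adjustment by design.

## Cohort builder

Rules run in prose order: index assignment (earliest qualifying DMT fill
in the index window; a same-day tie between different DMTs is a hard
error) → PDC ≥ 0.60 over the post-index year (union of supply intervals,
index day counted, both conventions config-exposed) → continuous
enrolment over [index−365, index+365) with every gap ≤ 30 days (a
total-gap-days mode is available) → ≥ 2 MS diagnoses pre-index → age ≥ 18
at index → exclusion of any pre-index outcome diagnosis or DMT fill.
Each step is recorded as (rule, n_before, n_removed, n_after) and the
report telescopes exactly to the final cohort size.

Two-record outcome definitions (e.g. two T2D diagnoses, or one diagnosis
plus a diabetes-medication fill) date the event at the *second*
qualifying record — the date the definition is first satisfied — with no
pairing window. Follow-up ends at the first of event, first day of an
enrolment gap > 90 days, study end, or (on-treatment mode) index-drug
discontinuation, defined as a supply gap > 60 days after exhaustion
(configurable; the source data never pin this down). Dates are integer
day offsets internally; spans inclusive of their end date; intervals
half-open. Missing region is imputed to the modal category,
lexicographic tie-break, logged.

## Synthetic data: what it emulates, what it does not

The generator draws baseline covariates from configurable marginals
(normal, Bernoulli, categorical, zero-inflated Poisson for count-like
scores such as the Charlson index — observed means ≈ 0.3–0.5 with SD ≈ 1
motivate the zero-inflated form), assigns treatment by multinomial logit
with intercepts set from the target arm sizes, draws event times from an
exponential or Weibull proportional-hazards model with a common
standard-exponential draw across arms (so counterfactual times are
consistent), and censors by independent (optionally covariate-dependent)
exponential dropout under an administrative horizon. Latent counterfactual
times live in an audit sidecar (`cohort.attrs["audit"]`) that estimation
code never reads. The raw-claims writer emits enrolment spans (carrying
demographics — claims enrolment files do), diagnosis records and fills
that rebuild the intended cohort through the attrition rules, with
configurable violation injection for attrition testing.

Ground truth: marginal survival S̄_a(t) = E_x exp(−H(t|x,a)) in closed
form without covariate effects, otherwise by Monte-Carlo marginalisation
over 10⁶ covariate draws with exact per-draw survival integrals (the
Weibull RMST uses the incomplete-gamma closed form); the method used is
recorded.

Benchmark designs (`benchmark_config`): the **confounded** design has
exponential hazards 0.10 vs 0.07 (conditional hazard ratio 0.70), one
binary confounder (prevalence 0.4, outcome log-hazard 0.7, assignment
log-odds 1.2 — raw standardised difference ≈ 0.6, ASAM ≈ 0.34), ~20%
independent dropout relative to the event hazard plus an 8-year horizon;
its true marginal rHR at 3.2 years is ≈ 0.706. The **null** design is the
randomised no-effect twin. These defaults are the package's study
conditions; the covariate–outcome effect sizes are chosen for
testability, since the motivating data report none.

What passing these benchmarks does *not* show about real claims data:
unmeasured confounding, informative censoring beyond the modelled
covariates, measurement error in diagnosis-code phenotypes, non-
proportional hazards, and calendar-time drift are all absent from the
generator by construction.

## Simulation scale and reproducibility

Every stochastic step is driven by explicit integer seeds (numpy
`default_rng` / `SeedSequence`; model seeds derived deterministically per
strategy), and a fixed configuration reproduces byte-identical result
JSON, including bootstrap draws and tree-based strategies. The test-suite
simulation studies use a reduced roster (unadjusted, IPW-logistic, Cox
main effects, gradient boosting) at n = 1000–4000 per arm with 5-fold
scoring, and the bootstrap-coverage study runs at n = 120 per arm with a
two-strategy roster, 2 folds and B = 200 over 50 outer replicates — sizes
chosen so the whole suite completes in minutes while leaving the
monitored properties (recovery within ±0.08, null within ±0.05, coverage
95% ± 7%) clearly resolvable. The null-recovery check averages three
seeded replicates because a single draw at n = 4000/arm has a log-SE near
0.04, the same order as its tolerance.

## Known limitations

* The FMA weight map is an implementation choice; the literature the
  method descends from does not print a canonical formula.
* Combining a propensity adjustment with a non-trivial outcome model
  (doubly-robust style) is out of scope and rejected at validation.
* The covariate-adjusted pseudo-observations hold the censoring model
  fixed across the jackknife; refitting per subject would change nothing
  at first order at the cost of n Cox fits.
* Weighted pseudo-observation means estimate arm functionals under
  covariate shift only approximately (the conditional-expectation property
  of pseudo-values is asymptotic); at the benchmark's event rates the
  residual gap is well inside the simulation tolerances.
* Matching estimates an effect on the matched population; with poor
  overlap its estimand drifts from the ATE. Unmatched patients are logged.
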