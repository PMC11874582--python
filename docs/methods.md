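# Methods

## Setting and estimand

`ipcwsim` studies a two-arm (1:1) randomised trial with discrete follow-up:
eight post-baseline visits at 12-week spacing, so visit 8 is week 96.  The
outcome is failure in an interval, modelled through the discrete-time hazard
λ_v = P(Y_v = 1 | survived to v).  A single intercurrent-event process —
*intervention deviation* (ID), e.g. stopping or switching the assigned
therapy — occurs in discrete time and is handled by the hypothetical
strategy: the estimand is the risk difference at the final visit had
deviation never occurred,

    RD(96) = P(Y₈^{ā₁} = 1) − P(Y₈^{ā₀} = 1),

where ā₁/ā₀ are the no-deviation regimens of the two arms.  Because the
estimand does not appear in the generator's parameters, its true value is
obtained by forward-simulating both no-deviation regimens at N = 2 × 10⁶
(common random numbers across the two arms, which reduces the Monte-Carlo
SE of the difference well below 0.001).

## Data-generating mechanism

Per individual, the sequential-conditional mechanism is:

1. **Baseline.** (B1 age, B3 severity score, L01..L05) ~ truncated
   multivariate normal, sampled by rejection with a capped number of
   rounds (the default bounds are mild, acceptance ≈ 1; an infeasible
   region raises instead of hanging).  Binary sex B2 follows a logistic
   model on B1, B3 and the baseline TVCs.
2. **Randomisation.** Z ~ Bernoulli(0.5).
3. **Visits v = 1..8**, in the within-visit causal order L_v → C_v → Y_v:
   - TVCs follow AR(1) updates with treatment, post-deviation and baseline
     shifts; the innovations of the two confounders (L1 log CD4, L2 log
     CD4/CD8) are jointly normal with a correlation held fixed over time,
     realised through a symmetric matrix square root (eigendecomposition,
     so a singular covariance is legal); L3 (viral load), L4, L5
     (lipids) have independent innovations.
   - Deviation is drawn only while no deviation has occurred
     (C is absorbing) and only in arms where the scenario allows it;
     its logistic hazard depends on visit, arm, baseline covariates and
     the *current* L1, L2, L4, L5 (never L3).  A deterministic variant
     replaces the draw by a threshold rule on L1 (positivity violation by
     construction).  C₀ := 0 — deviation can first occur at visit 1,
     matching the weight products which start at k = 1.
   - Failure is drawn from a logistic hazard on arm, time on the assigned
     regimen T_on = min(v, first-deviation visit), time off it
     T_off = max(v − first-deviation visit, 0), baseline covariates and
     the current L1, L2, L3 (never L4, L5).
4. Failure is absorbing; records stop after the first event.  Records
   *continue after deviation* — censoring at deviation is a decision made
   by the analysis methods, never by the generator.

Treatment actually received is deliberately not generated: every analysis
under study uses only randomised arm, deviation times, covariates and
outcomes.

## Parameter choices and calibration

All numeric parameters live in `src/ipcwsim/config/default.yaml`.  Covariate
scales emulate a paediatric HIV trial (log CD4 ≈ 6.0 ± 0.8, log CD4/CD8 ≈
−0.5 ± 0.6, log₁₀ viral load ≈ 4 ± 1, age 12 ± 3y).  AR coefficients are
0.7 with innovation SDs chosen so the stationary SDs match the baseline
SDs.  Worse prognosis (lower CD4, lower CD4/CD8 ratio) raises both the
deviation hazard (θ₄₁ = −0.6, θ₄₂ = −0.5 per unit, "medium"; halved /
doubled for the low/high confounding levels) and the failure hazard
(μ₇₁ = −0.5, μ₇₂ = −0.35), which is what makes censoring at deviation
informative.  In the default design, deviation means switching to a *more*
potent subsequent regimen: the post-deviation covariate shifts are
favourable and time off the assigned treatment lowers the hazard more than
time on it (μ₄ = −0.12 vs μ₂ = −0.04 per visit).

Five intercept-like quantities cannot be set a priori because they control
marginal data characteristics; they were calibrated once by root-finding
(`tune_intercept` and the same bisection applied to the outcome intercepts
and innovation correlation) and frozen into the YAML:

| quantity | target |
|---|---|
| θ₀ (low/medium/high deviation prevalence) | control-arm ever-deviation 0.210 / 0.387 / 0.601 |
| innovation + baseline corr(L1, L2) levels | realised corr 0.130 / 0.447 / 0.761 |
| μ₀ | control-arm 96-week incidence 0.188 |
| μ₁ levels | experimental-arm incidence 0.146 / 0.114 / 0.089 |
| deterministic threshold on L1 | ever-deviation 0.387 |

Under the resolved base case the counterfactual truth is RD(96) ≈ −0.090
— larger in magnitude than the naive observed difference (0.114 − 0.188 =
−0.074) because the no-deviation control arm loses the benefit its
deviators obtained from switching.

## Scenario grid

Eighteen scenarios, one factor at a time from the base case: correlation
level (2–3), deviation prevalence (4–5), confounder→deviation magnitude
(6–7), sign flip of the L2 effect (8), deterministic deviation (9), both-arm
deviation with arm effect 0/−/+ on the deviation hazard (10–12), arm→outcome
effect (13–14), confounder→outcome effect (15–16), and sample size 200/500
(17–18).  The arm configuration (which arms deviate, the arm coefficient in
the deviation hazard, between-arm post-deviation differences) is treated as
one composite factor, so every non-base scenario differs from scenario 1 in
exactly one factor.  Between-arm differences in the *effect* of deviation
(β_q3, μ₃, μ₅) are carried as parameters, default zero, for configurations
beyond the main grid.

## Analysis methods

Fourteen methods: ITT; per-protocol by censoring at the first deviation;
and {unstabilised, stabilised} × six censoring-model covariate sets —
{L1,L2} (correct), {L1}, {L2} (under-specified), {L1,L3,L4,L5}
(mis-specified), {L1,..,L5} (over-specified) and {L1*,L2*} where the star
marks a one-visit measurement delay (L*_v = L_{v−1}, baseline value reused
at v = 1).  All censoring models include the three baseline covariates, a
linear visit term f(v) = v (matching the generating hazard; per-visit
indicators are available by switch) and, when both arms have deviation
events, the arm.  The stabilising numerator keeps f(v) and arm — the
marginal-within-arm probability — with a switch for the arm-free version.
No covariate is ever dropped on significance grounds and weights are not
truncated by default (a percentile cap exists for diagnostics only).

When only one arm has deviation events (the single-arm scenarios), a pooled
fit with an arm term would be separated; the implementation then fits the
censoring models on the deviating arm's risk set only, drops the arm term
and assigns p̂ = 0 (unit weights) to the event-free arm.

The outcome analysis is one pooled logistic model for all methods,
logit λ_v = αZ + γ_v + ψZv with per-visit indicators γ_v (they nest the
generating hazard; a linear-in-v option exists) and a linear arm-by-visit
interaction, fitted unweighted (ITT, PP) or weighted by W or SW (IPCW).
Cumulative incidence is the product-limit transform
F(8) = 1 − Π(1 − λ_v(arm)); the risk difference is F₁(8) − F₀(8)
(experimental minus control).  Its SE comes from the delta method with the
analytic gradient dF/dβ = S(8) Σ_v λ_v x_{v,arm}; the coefficient
covariance is model-based for unweighted fits and a cluster-robust sandwich
(scores summed within individual, G/(G−1) correction) for weighted fits.
95% CIs are Normal-theory; a bootstrap over individuals — refitting the
weights inside every resample — is available as a cross-check (default
B = 1000 when used).

Model fitting is IRLS (statsmodels GLM) behind a wrapper that enforces the
framework's convergence contract: relative deviance tolerance 1e-8, capped
iterations, and *flags* for non-convergence, rank deficiency and separation
(|linear predictor| > 30 or extreme coefficients) instead of exceptions.
Flagged repetitions are excluded pairwise per method from performance
summaries, with exclusion counts reported.

## Study engine and seed policy

All randomness derives from one master seed through `SeedSequence` spawn
keys: repetition r uses key (0, r) — the same stream in every scenario, so
results are correlated within repetitions (common random numbers) — and the
truth computation for scenario s uses key (1, s), disjoint from every
repetition stream by construction.  Within a repetition all fourteen
methods are applied to the same panel.  Estimates are checkpointed to CSV;
an interrupted run can be resumed (configuration hash verified; n_reps is
excluded from the hash because completing an interrupted run is the point
of resuming) and yields byte-identical output to an uninterrupted run.

## Performance measures

Per (scenario, method): signed bias (an absolute-value column is derived
for ranking), empirical SE, model-based SE = √mean(SE²), RMSE and coverage
of the 95% CI, each with its Monte-Carlo SE (EmpSE/√n for bias,
EmpSE/√(2(n−1)) for EmpSE, √(Var(SE²)/(4n·ModSE²)) for ModSE, the MSE MCSE
divided by 2·RMSE for RMSE, √(c(100−c)/n) for coverage).  The definitional
identity RMSE² = bias² + EmpSE²(n−1)/n is enforced by test.
`compare_table` arranges the cells in nested-loop order (one block per
measure, scenarios in grid order, methods in catalogue order).

## Validation parameterisations

Two additional parameter sets back the end-to-end tests:

* **Null** (`null_params`): every treatment effect zero *and* deviation
  non-informative and outcome-inert (θ₃ = θ₄ = 0, no post-deviation
  covariate shifts, μ₄ = μ₂), with θ₀ = −3 keeping ever-deviation near the
  base case.  This is the only kind of null under which *all* methods are
  unbiased — zeroing treatment effects alone would leave per-protocol
  selection bias intact — and it checks the whole pipeline: truth ≈ 0,
  every estimator unbiased within 3 MCSE, coverage in the binomial band.
* **Discontinuation** (`discontinuation_params`): deviation means stopping
  effective therapy — post-deviation covariates deteriorate and time off
  treatment carries a higher hazard (μ₄ = μ₂ + 0.12).  Here the observed
  control arm does *worse* than its no-deviation counterfactual, giving
  the canonical bias ordering: ITT negative, per-protocol positive,
  correctly specified IPCW unbiased.  In the default (switch-to-better)
  base case ITT's bias is positive instead — toward the null — because the
  control deviators' benefit shrinks the observed arm contrast; both signs
  are mechanical consequences of where μ₄ sits relative to μ₂.

## Problem sizes used in the shipped checks

The test suite and `scripts/acceptance.py` run scaled-down versions of the
full experiment: 400–500 repetitions instead of 1000, truth at N = 4 × 10⁵
to 10⁶ instead of 2 × 10⁶, and method subsets where the check concerns
only specific methods.  These sizes keep every Monte-Carlo SE comfortably
below the margins being asserted (e.g. MCSE(bias) ≈ 0.0013 at 500 reps
against biases of |0.014|–|0.034|).  The full 18 × 1000 × 14 study runs
from the CLI in a few hours on one core.

## Known limitations

* The generator emulates structured trial follow-up only: no loss to
  follow-up or missing covariate measurements, a single combined deviation
  process, visits exactly on schedule.  Passing tests certify behaviour
  under this mechanism, not under real-trial messiness.
* Truncated-normal sampling is by rejection; pathologically narrow bounds
  fail explicitly rather than being handled by a specialised sampler.
* The delta-method CI is Normal-theory on the RD scale; near-boundary
  incidences could be handled better by transformation (the bootstrap
  cross-check exists for that purpose).
* Stata's generator streams cannot be reproduced bit-for-bit; only
  distributional equivalence of the mechanism is targeted.
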