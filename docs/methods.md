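# Methods

## Data model

Subjects are independent draws of the longitudinal sequence
{L₁, A, C₁, Y₁, L₂, C₂, Y₂, …, L_K, C_K, Y_K}: baseline covariates L₁, a
point exposure A ∈ {0, …, m−1}, and per-interval censoring and event
indicators with censoring preceding the event within an interval. Both
processes are absorbing, and Y is missing from the first censored interval
onward. `discretize_followup` maps continuous follow-up onto this layout
with half-open intervals (b_{j−1}, b_j], so an event or censoring time
exactly at a boundary belongs to the interval it closes. A subject whose
event-free follow-up reaches b_K is stored as complete (no censoring
record) by default; an `administrative_censor_at_end` flag instead codes
C_K = 1. The estimand at horizons t ≤ K is unaffected by that choice; the
flag exists because registry extracts differ in convention. Missing cells
are NaN, and every risk-set selection is defined on non-missing entries.

## Identification and estimator

Under conditional exchangeability given the measured history, consistency,
positivity, and missing-at-random censoring, S_a(t) = P(T_a > t) is
identified by the iterated-conditional-expectation form of the
g-computation formula. The estimator is the weighted-fluctuation TMLE for
survival described in the README: initial outcome fits, an intercept-only
logistic fluctuation per backward step with inverse-probability weights,
and the plug-in mean of the final updated predictions. The unweighted
"clever covariate" variant is deliberately not implemented; the weighted
regression form has better finite-sample behaviour and only one form keeps
the targeting code auditable.

The fluctuation is solved directly as a one-dimensional monotone root
problem (Brent's method, |ε| bracketed within ±40, xtol 1e−14) rather than
through a GLM, so the weighted score equation holds to ~1e−12 and the
influence curve is mean-zero to the same order. Initial predictions are
clamped to [1e−6, 1−1e−6] before the logit so the offset is finite. If a
risk set carries zero total weight, ε = 0 (no information to update).

Influence curve: the per-subject curve of Ŝ_a(t) is accumulated as
Σ_j H_a(j)(Q*_j − response_j) plus the centering term mean(Q*(1)) − Q*(1).
Its sample variance over n gives the Wald standard error; the ATE uses the
per-subject difference of the two arms' curves, which accounts for their
correlation. Estimates t ↦ Ŝ_a(t) are *not* isotonized; per-horizon
estimates may cross in finite samples and are reported as computed (the
hazard map clamps a resulting negative hazard to 0 with a warning).

Truncation: `gbound` (default 0.005) floors the exposure probability of
the followed regime and each per-interval probability of remaining
uncensored before the weight denominators are formed. Only a floor is
applied — the probabilities only ever appear in denominators, so a ceiling
would have no stabilising role. Floored counts are reported per target.

## Nuisance models

All event- and censoring-model fits are quasi-binomial IRLS (logit link)
with observation weights, because backward-step responses are fractional
probabilities. The parametric learner is a main-terms logistic regression,
optionally with pairwise interactions and squared terms (with binary
covariates the interaction design is saturated, which is what the
oracle-equivalence test exploits). Multilevel exposures always use an
unpenalised multinomial logistic model so per-level probabilities sum to
one; the stacking path is restricted to binary/fractional responses.

`SuperLearner` stacks a library (default: intercept-only mean, main-terms
logistic, logistic with two-way interactions and squares, additive
truncated-power cubic splines) using V-fold cross-validation and
squared-error loss; weights are non-negative least squares on the
out-of-fold prediction matrix, normalised to the simplex. Highly flexible
tree ensembles are excluded from the default library: without
sample-splitting they compromise the variance estimator. The adaptive fold
rule maps the fitting sample size to folds as <30 → error, 30–500 → 10,
501–5000 → 5, >5000 → 2; only the endpoints of this mapping are externally
anchored, the monotone interpolation is this package's documented choice.
A learner that fails on any fold is dropped with a warning; if all fail,
the ensemble degrades to the mean. Degenerate strata (an interval with no
censoring events, or an all-zero response) yield constant-probability
models with a logged warning rather than an error — sparse intervals are a
fact of discretized follow-up.

## Hazard MSM

Estimated hazards λ̂_a(t) = (Ŝ_a(t−1) − Ŝ_a(t))/Ŝ_a(t−1) (Ŝ_a(0) = 1) are
fitted by weighted quasi-binomial regression on the mK pseudo-observations
with weights Ŝ_a(t−1); the design is built from a small formula language
(`a`, `t`, `a:t`, `factor(t)`, default `a + factor(t)`). Hazards exactly at
0 or 1 are nudged by 1e−10 to keep the logit finite.

The covariance of γ̂ comes from the functional delta method. With
p_{a,t} = expit(X_{a,t}ᵀγ), the fit's estimating function is
U(γ, S) = Σ_{a,t} [S_a(t−1) − S_a(t) − S_a(t−1) p_{a,t}] X_{a,t}, so each
subject's γ-influence is B⁻¹ Σ_{a,t} [−X_{a,t} + X_{a,t+1}(1 − p_{a,t+1})]
IC_a(t), with bread B = Σ S_a(t−1) p(1−p) XXᵀ. At t = K there is no t+1
row and the second term vanishes — the boundary choice is validated by the
single-cell delta-method identity (exact to 1e−8) and by the coverage
simulation. `exp(γ)` is reported with the caveat that it is an odds ratio
unless the fitted hazards are small (≲0.1).

## Synthetic data generator

The generator emulates a pharmacoepidemiological point-exposure cohort:
one binary baseline confounder L ~ Bernoulli(0.5); a rare exposure
P(A=1|L) = expit(−3 + 0.6L) (≈6.5% exposed); counterfactual event hazards
expit(−2 − a + 0.25L) per interval, constant in time conditional on L;
light censoring expit(−5 + 0.2A + 0.2L) per interval (≈0.7%/interval); and
K = 4 intervals. Draws are consumed in the fixed order L, A, then per
interval censoring then event, with one shared event uniform driving both
counterfactual arms (a rank-preserving coupling), so consistency holds row
by row exactly and a seed is reproducible within this implementation (no
attempt is made to match any external RNG stream).

Ground truth is computed in closed form: with binary L,
S_a(t) = Σ_ℓ P(L=ℓ)(1 − expit(−2 − a + 0.25ℓ))^t, and the true working-MSM
coefficients solve the weighted logistic score on the exact hazards (IRLS
tolerance 1e−12): γ₀ = −1.8698, γ₁ = −0.9970, and time coefficients
−0.0017, −0.0034, −0.0050 — small and negative because only
depletion of the higher-risk L = 1 stratum moves the *marginal* hazard over
time. A Monte-Carlo path (counterfactual matrices from `generate`) is kept
as an independent cross-check of the closed forms.

What the generator does not emulate: continuous or high-dimensional
confounders, time-varying confounding of censoring, effect modification,
competing risks, or heavy censoring. Tests that pass on this generator
therefore demonstrate the estimator's algebra (score equations, double
robustness, coverage) under a clean point-exposure design, not robustness
to those real-data complications.

## Simulation sizes used in the test suite

Parameter-recovery checks run at n = 200 000 (3-SE bands from the fitted
information); the single-replicate comparisons at n = 5000, the cohort
size of the worked example; double robustness over 200 replicates at
n = 2000; interval coverage over 500 replicates at n = 5000, where the
binomial noise of the empirical coverage rate (±2 points at 2 SEs) is
small against the [0.90, 0.99] acceptance band. With ~325 exposed subjects
per replicate, Wald coverage for S₁(t) is ~93%: mildly below nominal, as
expected for a rare exposure at this size, and within the band.

## Known limitations

- Point exposures only; no time-varying treatment regimes, competing
  risks, or continuous exposures (dose-response estimands are not
  pathwise differentiable in this setting).
- Influence-curve variances assume the nuisance estimators converge fast
  enough and are not overly adaptive; no cross-fitting is provided.
- Near-positivity violations are handled only by `gbound` truncation.
- Long-format (person-interval) input, interval-censored event times, and
  left truncation are out of scope.
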