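# survtarget

Doubly robust estimation of the causal effect of a point exposure on a
time-to-event outcome, using targeted maximum likelihood estimation (TMLE)
on discretized follow-up with missing-at-random censoring.

`survtarget` is written for epidemiologists and biostatisticians who want
counterfactual (rather than merely covariate-adjusted) survival summaries
from observational cohorts: the counterfactual survival curve
S_a(t) = P(T_a > t), the average treatment effect
ATE(t) = S_1(t) − S_0(t), and the coefficients γ of a working marginal
structural model (MSM) for the discrete-time hazard,

    logit λ_a(t) = X_{a,t}ᵀ γ,   λ_a(t) = [S_a(t−1) − S_a(t)] / S_a(t−1).

## The estimator

Follow-up is divided into K intervals; within interval t the censoring
indicator C_t precedes the event indicator Y_t. For each target (a, t) the
estimator runs a backward recursion over j = t, …, 1:

1. fit an event / iterated-expectation model on the risk set
   {C_j = 0, Y_{j−1} = 0} — the response is the observed Y_t at j = t and
   the previous step's updated prediction at j < t;
2. predict under exposure A = a for everyone still uncensored at j − 1
   (predictions are pinned to 1 where Y_{j−1} = 1);
3. *target* the predictions: a weighted intercept-only logistic fluctuation
   with offset logit(Q) and inverse-probability weights
   H_a(j) = 1{A = a, C_j = 0} / [ĝ_A(a|L₁) ∏_{k≤j} P̂(C_k = 0 | ·)], each
   probability in the denominator floored at `gbound`;
4. accumulate the influence-curve component H_a(j)(Q* − response).

The final estimate is Ŝ_a(t) = 1 − mean(Q*(1)); because each fluctuation
solves its weighted score equation exactly, the estimator solves the
efficient-influence-curve estimating equation, is consistent if *either*
the outcome models *or* the exposure-plus-censoring models are correct, and
its variance is the sample variance of the influence curve over n. MSM
coefficients inherit delta-method variances from the survival influence
curves. Nuisance models can be main-terms logistic regressions or a
cross-validated stacking ensemble (`SuperLearner`).

## Worked example

```python
from survtarget import DGPParams, estimate_curves, fit_msm_from_curves, generate

data = generate(DGPParams(), n=5000, seed=1).data   # synthetic cohort, K = 4
curves = estimate_curves(data)                      # TMLE for every (a, t)
print(curves.table().round(4))
print(f"ATE(2) = {curves.ate(2).estimate:.4f}")
print(fit_msm_from_curves(curves).summary().round(3))
```

prints (abridged)

```
 a  t  estimate     se  ci_low  ci_high
 0  4    0.5608 0.0073  0.5464   0.5752
 1  1    0.9363 0.0141  0.9087   0.9639
 1  4    0.8083 0.0223  0.7647   0.8519
ATE(2) = 0.1446
coefficient  estimate    se  ci_low  ci_high
          a    -1.043 0.135  -1.309   -0.778
```

Ŝ₁(1) = 0.936 and Ŝ₀(4) = 0.561 sit within two standard errors of the
generator's exact values (0.946 and 0.564); the ATE at t = 2 estimates the
true risk difference 0.145; and the MSM exposure coefficient −1.04
(95% CI −1.31, −0.78) covers the true log-odds effect −1.00 — exp(−1.04) is
an odds ratio here because the unexposed hazards (~0.13) are too large for
a hazard-ratio reading.

The `examples/` scripts walk through each capability (simulation and truth
recovery, survival targeting, the hazard MSM, stacked nuisance models), and
a thin CLI (`survtarget simulate|validate|fit|plot`) wraps the same
pipeline for shell use.

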