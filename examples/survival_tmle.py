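"""Targeted estimation of counterfactual survival curves and treatment effects.

Simulates one cohort of n = 5000, fits the exposure, censoring, and event
models with main-terms logistic regressions, runs the targeting recursion
for every exposure level and horizon, and prints the survival table and the
per-interval average treatment effects with 95% Wald intervals.
"""

from survtarget import DGPParams, estimate_curves, generate, true_survival

params = DGPParams()
data = generate(params, n=5000, seed=1).data

curves = estimate_curves(data)  # parametric learners by default
table = curves.table()
table["truth"] = [true_survival(int(r.a), int(r.t), params) for r in table.itertuples()]
print(table.round(4).to_string(index=False))

print("\naverage treatment effects S_1(t) - S_0(t):")
for t in curves.times:
    r = curves.ate(t)
    print(f"  t={t}: {r.estimate:+.4f}  (95% CI {r.ci_low:+.4f}, {r.ci_high:+.4f})")

# Each estimate should sit within a couple of standard errors of the truth
# column; the ATE grows with t because the protective effect accumulates.
# The intervals for a = 1 are wider: only ~6.5% of subjects are exposed.
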