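"""The exactness claim, end to end: fitting across nine sites that only ever
exchange aggregate matrices reproduces the pooled fit.

Per Newton iteration each site sends M1 = X'WX (q x q) and M2 = X'Wz (q),
and the aggregator's solve on the sums IS the pooled solve.  We fit the same
model both ways and compare coefficients and per-subject predicted quantiles.
"""
import numpy as np

from fedgamlss import fit_distributed, fit_pooled, predict_quantile_of_observation
from fedgamlss.synthgen import default_spec, generate, scenario

real = generate(scenario("bmi_like", seed=7, n_total=5000))
y, covariates = real.pooled()
spec = default_spec(real.scenario, smooth_mode="fixed")

pooled_state, pooled_model = fit_pooled(y, covariates, spec)
dist_state, rounds, dist_model = fit_distributed(list(real.sites), spec)

coef_diff = max(
    float(np.max(np.abs(a - b)))
    for a, b in zip(pooled_state.coefficients, dist_state.coefficients)
)
qp = predict_quantile_of_observation(pooled_state, pooled_model, covariates, y)
qd = predict_quantile_of_observation(dist_state, dist_model, covariates, y)

print(f"sites: {len(real.sites)}   subjects: {len(y)}")
print(
    f"communication rounds: {rounds.n_rounds} "
    f"(basis setup {rounds.count('basis_setup')}, updates {rounds.count('update')})"
)
print(f"max |distributed - pooled| coefficient difference: {coef_diff:.2e}")
print(f"correlation of per-subject predicted quantiles:    {np.corrcoef(qp, qd)[0, 1]:.6f}")
print()
print(
    "The coefficient difference is at floating-point summation noise and the\n"
    "quantile correlation is 1 to six decimals: no site shared a single\n"
    "subject row, yet the federated model is the pooled model."
)
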