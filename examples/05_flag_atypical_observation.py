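"""Score new observations against a fitted reference model.

The predicted quantile of an observation is the CDF of its measured value
under the subject's own predicted distribution; values below 0.025 or above
0.975 fall outside the inner 95% reference range.
"""
import numpy as np
import pandas as pd

from fedgamlss import fit_pooled, predict_quantile_of_observation
from fedgamlss.synthgen import default_spec, generate, scenario

real = generate(scenario("bmi_like", seed=19, n_total=4000))
y, covariates = real.pooled()
state, model = fit_pooled(y, covariates, default_spec(real.scenario, smooth_mode="fixed"))

new = pd.DataFrame(
    {
        "age": [30.0, 30.0, 75.0],
        "sex": ["M", "M", "F"],
        "site": ["s01", "s01", "s01"],
        "bmi": [24.0, 41.0, 18.0],
    }
)
q = predict_quantile_of_observation(state, model, new, new["bmi"].to_numpy())
for row, qi in zip(new.itertuples(), q):
    flag = "within the reference range" if 0.025 <= qi <= 0.975 else "ATYPICAL"
    print(f"age {row.age:4.0f} sex {row.sex}  value {row.bmi:5.1f} -> centile {100 * qi:5.1f}  ({flag})")
print(
    "\nCentiles condition on each subject's age and sex: the same value can\n"
    "be unremarkable at one age and flagged at another."
)
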