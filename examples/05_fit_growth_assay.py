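"""Generate a synthetic spheroid growth assay and refit the model.

Emulates the standard design — counts on days 1, 3, 5, 7, untreated and
under a constant lethal drug bath from 72 h — with 10% multiplicative
noise, then estimates the growth and drug parameters by multistart
least squares (strategy and death rate treated as known).
"""

import numpy as np

from phenoswitch import AssayDesign, fit, generate
from phenoswitch.studies import STUDY_TRUTH

truth = STUDY_TRUTH
design = AssayDesign(cv=0.10, n_replicates=3)
data = generate(truth, design, seed=7)
print(f"{len(data)} datasets; untreated counts (replicate 1): "
      f"{np.round([d for d in data if d.condition == 'untreated'][0].counts)}")

res = fit(data, fixed={"strategy_B": truth.strategy_B, "d_A": truth.d_A},
          seed=8, n_starts=6)
print(f"best of {res.n_starts} starts: sse = {res.sse:.4g}")
true_values = {"r_A": truth.r_A, "r_B": truth.r_B,
               "d_A_max": truth.d_A_max, "lambda_A": truth.lambda_A}
for key, true in true_values.items():
    print(f"  {key:9s} = {res.estimates[key]:.4f}  (truth {true:.4f})")
print("lambda_A = r_A - d_A is the quantity the scheduler needs; at 10%")
print("count noise it is typically recovered within a few percent.")
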