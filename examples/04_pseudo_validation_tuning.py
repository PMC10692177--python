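"""Choose the compression hyperparameters (b, r) by pseudo-validation.

No held-out samples are needed: synthetic summary statistics are drawn
from the distribution the model implies given the LD itself, the
estimator is refit against each candidate compression, and the (b, r)
pair with the smallest mean absolute heritability bias wins.
"""

import warnings

import numpy as np

import heels as H

cfg = H.SimulationConfig(n=2000, p=100, h2=0.25, seed=9, ld_model="ar1", rho=0.9)
Xm = H.standardize(H.simulate_genotypes(cfg), "model_scale")
R = Xm.X.T @ Xm.X

with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    result = H.pseudo_validate(
        R, n=2000, b_grid=[1, 5, 20], r_grid=[0, 5], strategy="PSD_Band_LR",
        h2_grid=(0.1, 0.25, 0.5), reps=10, seed=0,
    )

print(f"{'b':>4} {'r':>4} {'mean |h2 bias|':>15}")
for row in result.table:
    bias = row["mean_abs_bias"]
    shown = f"{bias:.4f}" if np.isfinite(bias) else "failed"
    print(f"{row['b']:>4} {row['r']:>4} {shown:>15}")
print(f"\nselected (b*, r*) = ({result.best_b}, {result.best_r})")
# the bias drops sharply once the bandwidth covers the real LD range and
# flattens beyond it — the selected pair is the cheapest accurate setting
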