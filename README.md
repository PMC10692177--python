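# heels

Efficient SNP-heritability estimation from GWAS summary statistics and the
in-sample LD matrix, with banded-plus-low-rank LD compression.

## The problem

SNP-heritability — the proportion of phenotypic variance tagged by genotyped
variants — is most precisely estimated by restricted maximum likelihood
(REML) on individual-level genotypes and phenotypes, which are rarely
shareable. Estimators that use only published summary statistics (LD-score
regression and relatives) are widely applicable but pay a large price in
statistical efficiency: their standard errors can be several-fold larger
than REML's.

This package implements HEELS (Heritability Estimation with high Efficiency
using LD and association Summary Statistics): an iterative solver for the
REML score equations that needs only the variant-level statistics

- `S = Xᵀy` — marginal association statistics (or Z-scores),
- `R = XᵀX` — the LD matrix estimated **in the GWAS sample**,
- `yᵀy` — the phenotypic sum of squares (or the approximation `yᵀy/n = 1`
  when only Z-scores are available),

under the linear mixed model `y = Xβ + ε`, `β ~ N(0, σ²_g I_p)`,
`ε ~ N(0, σ²_e I_n)`, with `h²_SNP = σ²_g/(σ²_g + σ²_e)`. Because `(S, R,
yᵀy)` are sufficient for the variance components, the estimator attains
essentially the same precision as individual-level REML. It is aimed at
*local* heritability: one LD block (hundreds to a few thousand markers) at
a time.

The core iteration alternates a ridge-type BLUP solve with variance-component
updates until convergence:

```
β̂⁽ᵗ⁾   = (λ⁽ᵗ⁾ I_p + R)⁻¹ S,            λ⁽ᵗ⁾ = σ̂²_e/σ̂²_g
σ̂²_g   ← β̂ᵀβ̂ / tr[(λ I_p + R)⁻¹ R]
σ̂²_e   ← (yᵀy − Sᵀβ̂) / n
```

with an analytic standard error from the summary-statistics Fisher
information and the delta method.

Around the estimator the package provides:

- **LD compression** (`heels.ldapprox`): six representations of the form
  `R ≈ R_b + U_r Λ_r U_rᵀ` (banded plus low-rank; the diagonal special case
  is a spiked covariance model), fitted by Frobenius-norm optimization,
  with solve/trace/log-determinant contracts served through a banded
  Cholesky factorization and the Woodbury identity — never forming the
  dense matrix.
- **Hyperparameter tuning** (`heels.tuning`): pseudo-validation — synthetic
  summary statistics drawn from the model-implied distribution of `S`
  given `R` — selects the bandwidth/rank pair `(b, r)` without any held-out
  samples; plus incremental and randomized low-rank decompositions.
- **A synthetic-data simulator** (`heels.simulate`): latent-Gaussian
  threshold genotypes with AR(1)/block LD, additive phenotypes with
  configurable heritability and polygenicity.
- **An individual-level REML oracle** (`heels.reml`) used to certify that
  the summary-statistics fit lands on the same optimum.

## Worked example

```python
import heels as H

cfg = H.SimulationConfig(n=2000, p=200, h2=0.25, seed=1, ld_model="ar1", rho=0.8)
panel = H.simulate_genotypes(cfg)
Xu = H.standardize(panel, "unit_variance")
Xm = H.standardize(panel, "model_scale")
y, beta_true, causal = H.simulate_phenotype(Xu, cfg)

stats, R = H.compute_sumstats(Xm, y)      # S, y'y and the in-sample LD
fit = H.heels_fit(stats, H.DenseLD(R))
info = H.fisher_info(H.DenseLD(R), fit.vc, n=cfg.n)
se = H.h2_se(fit, info)
print(fit.h2, se)
```

Running `python examples/01_fit_heritability.py` (the same computation)
prints:

```
true h2        : 0.25
estimated h2   : 0.2779  (se 0.0297)
sigma_g2, sigma_e2 : 0.2974, 0.7726
iterations     : 13 (converged=True)
```

The estimate sits within one standard error of the generative value; the
SE is the analytic (Fisher/delta-method) uncertainty given this sample
size and LD. `examples/02_reml_equivalence.py` fits the same data from
individual-level data and from summary statistics and prints an absolute
difference of `1.17e-07` — the two routes maximize the same likelihood.
The other examples demonstrate LD compression and pseudo-validation
tuning.

A thin CLI mirrors the library (`heels simulate | fit | approx-ld | tune |
oracle`); run `heels --help` for the flags.

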