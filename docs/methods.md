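# Methods

## Model

We work with the single-component linear mixed model for one genomic locus:
`y = Xβ + ε` with `β ~ N(0, σ²_g I_p)` and `ε ~ N(0, σ²_e I_n)`, so that
`y ~ N(0, V)` with `V = σ²_g XXᵀ + σ²_e I_n`. Genotypes are standardized to
the *model scale*, `diag(XᵀX/n) = 1/p`, and the phenotype to unit variance;
then the genetic variance contributed by the locus equals `σ²_g` and
`h²_SNP = σ²_g/(σ²_g + σ²_e)`. Covariates are assumed projected out
(`project_covariates` does this residualization when needed; with fixed
effects removed, REML and ML of this model coincide).

Throughout, the summary statistics are kept unscaled: `S = Xᵀy` (no
`1/√n`), `R = XᵀX` (no `1/n`). All formulas are implemented in that
convention; the fit is equivariant to rescaling `y ↦ cy` (components scale
by `c²`, `h²` unchanged).

## The iterative solver

Writing `λ = σ²_e/σ²_g` and `W = λI_p + R`, the solver alternates

1. BLUP / ridge update: `β̂ = W⁻¹S`;
2. `σ²_g ← β̂ᵀβ̂ / tr(W⁻¹R)`, where `tr(W⁻¹R) = p − λ·tr(W⁻¹)`;
3. `σ²_e ← (yᵀy − Sᵀβ̂)/n`,

until the larger of the two component changes falls below `tol` (default
1e-6; `max_iter` 1000). The fixed points of this iteration are exactly the
stationary points of the marginal likelihood, which can be written in
summary statistics only:

```
ℓ(σ²_g, σ²_e) = −(n/2)·log σ²_e − ½·log|I_p + (σ²_g/σ²_e) R|
                − (yᵀy − SᵀW⁻¹S) / (2σ²_e).
```

The iteration has EM character: the likelihood trace recorded at each step
is non-decreasing (tests allow 1e-8 numerical slack), and iterates stay in
the parameter space. Components that fall below `1e-10 × (σ²_g + σ²_e)` are
floored there and the fit is flagged `boundary`; at a boundary the
delta-method SE degenerates and is reported as missing rather than
extrapolated.

Initialization is deterministic, `(σ²_g, σ²_e) = (½, ½)·(yᵀy/n)` — the
data-scale version of an equal split, identical to (0.5, 0.5) for a
standardized phenotype; a seeded uniform(0, 1) random start is available.
The likelihood is well behaved on every fixture we have examined and both
starts reach the same optimum.

**Z-score mode.** When only Z-scores are available, `yᵀy/n` is approximated
by 1. Z-scores and the model-scale statistics differ by a deterministic
factor (`S = √(n/p)·Z` for a standardized phenotype), so the fit rescales
the input accordingly, sets `yᵀy = n`, and renormalizes `(σ²_g, σ²_e)` to
sum to one after every iteration. With an exactly standardized phenotype
this reproduces the exact-mode `h²` to 1e-6; with an unstandardized one it
inherits the usual `yᵀy/n ≈ 1` approximation error.

## Standard errors

The expected information for `(σ²_e, σ²_g)` — in that order, fixed to avoid
transposition bugs — depends on the data only through `n`, `p`,
`tr(W⁻¹)` and `tr(W⁻²)`:

```
I = ½ [ (n−p)/σ⁴_e + tr(W⁻²)/σ⁴_g ,   tr(W⁻¹)/σ⁴_g − σ²_e·tr(W⁻²)/σ⁶_g
        (symmetric)               ,   p/σ⁴_g − 2σ²_e·tr(W⁻¹)/σ⁶_g + σ⁴_e·tr(W⁻²)/σ⁸_g ]
```

with `σ⁴ ≡ (σ²)²` etc. `Var(ĥ²)` follows by the delta method with gradient
`∇f = (−σ²_g/(σ²_g+σ²_e)², σ²_e/(σ²_g+σ²_e)²)`. When `p ≥ n` the `(n−p)`
term goes negative and the matrix may lose definiteness; a warning is
emitted and a numerically singular information matrix raises with its
condition number.

This is the *expected* information: the observed curvature of the
likelihood at a random data realization differs from it by a term of order
`n^(−1/2)`. To certify the formula itself we evaluate the likelihood on
*expectation-matched* statistics (`expected_sumstats`): a vector `S` built
in the eigenbasis of `R` with `S̃ᵢ² = σ²_g μᵢ² + σ²_e μᵢ` and
`yᵀy = σ²_g tr(R) + n σ²_e`, whose quadratic forms equal their model
expectations for every ridge shift simultaneously. On such statistics the
numerical Hessian reproduces the analytic matrix to the finite-difference
error (≈1e-5 relative), and the fit recovers the generative components
exactly. Calibration on random data is checked separately: over 500
simulated replicates at n=2000, p=200 the mean analytic SE tracks the
Monte-Carlo SD within 15% and 95% intervals cover at their nominal rate.

Relative efficiency of an estimator is reported as
`100 · var(reference)/var(estimator)` percent, with individual-level REML
as the reference.

## LD compression

The LD matrix is represented as `R ≈ R_b + U_r Λ_r U_rᵀ`: a central band of
half-bandwidth `b` (entries with `|i−j| < b`; `b = 1` is the diagonal,
giving a spiked covariance model) plus a rank-`r` correction. Six
strategies fit this form by minimizing `‖R − R̃‖²_F`:

- `Seq_Band_LR` keeps the band of `R` exactly and eigendecomposes the
  off-band residual (top-`r` eigenpairs by magnitude, signed; ties broken
  toward the earlier index). Exact when `R` is banded; not PSD in general.
- `PSD_Band_LR` first fits a lower-banded factor `L_b` to the banded slice
  (`min ‖R∘1_b − L_bL_bᵀ‖²_F`), then eigendecomposes the residual.
- `Joint_Band_LR` optimizes the banded and low-rank factors jointly
  (`min ‖R − L_bL_bᵀ − L_rL_rᵀ‖²_F`); the reconstruction is PSD by
  construction and the optimizer's objective trace is monotone.
- `Spike_LR` sets the diagonal to the smallest eigenvalue of a seeded
  random principal submatrix (size `min(p, 500)`) and takes top-`r`
  eigenpairs of the remainder; `Spike_PSD` / `Spike_PSD_hetero` optimize a
  homogeneous / heterogeneous non-negative diagonal jointly with a dense
  factor.

Constrained problems are solved in factor space (L-BFGS-B with analytic
gradients, `ftol` 1e-14), so positive semi-definiteness is automatic and no
projection steps are needed. Initialization: the eigenvalue-clipped
projection of the target slice (banded case; a tiny `1e-8` ridge makes the
Cholesky well defined) or the eigenvalue-space optimum of the spiked model
(mean of the trailing `p−r` eigenvalues). The joint strategy is
initialized at the two-step solution re-expressed in its parametrization,
so monotone descent guarantees it never does worse on the shared
objective. Non-convergence within the iteration cap returns the best
iterate with a warning.

Keeping *signed* residual eigenvalues is the accurate choice but means the
`Seq_Band_LR`/`PSD_Band_LR`/`Spike_LR` reconstructions can be slightly
indefinite even at small `r`; a `positive_only` flag truncates to positive
eigenpairs when a certified-PSD representation is required. A related
consequence: the Frobenius *ratio* `‖R̃‖_F/‖R‖_F` is not monotone in `r`
(a negative eigenpair lowers both the error and the norm); the error
`‖R − R̃‖_F` is the monotone quantity and is what the tests assert.

Solves and traces against a compressed `R̃ = B + FΦFᵀ` go through
`A = λI + B` (banded Cholesky in LAPACK band storage) and the Woodbury
identity with the `r×r` capacitance `C = Φ⁻¹ + FᵀA⁻¹F`:
`tr(M⁻¹)`, `tr(M⁻²)` reduce to traces of `C⁻¹(FᵀA⁻ᵏF)` products, and
`log|M|` uses the matrix determinant lemma, all deterministic (no
stochastic trace estimation at these problem sizes). One solve costs
`O(p·b² + p·r)` after factorization. The banded route requires
`λI + B ≻ 0`; for the signed banded slice of `Seq_Band_LR` this fails when
`λ` is below the magnitude of the slice's most negative eigenvalue, and the
operator raises advising a larger shift or a PSD strategy — the practical
reason the PSD variants are the recommended default.

## Pseudo-validation tuning

The model implies `S = Rβ + Xᵀε`, hence `S | R ~ N(0, σ²_g R² + σ²_e R)` on
the model scale with `σ²_g = h²`, `σ²_e = 1 − h²`. `simulate_pseudo_sumstats`
draws `S* = Rβ* + e*` with `β* ~ N(0, h² I_p)` and `e* ~ N(0, (1−h²) R)`
(via the eigendecomposition of `R`, floored at zero for tiny negative
eigenvalues), sets `yᵀy = n`, and is deterministic given its seed.
`pseudo_validate` evaluates each `(b, r)` candidate on a shared pool of
pseudo-replicates — default 30 per heritability in the grid
`{0.1, 0.25, 0.5}`, so a candidate cannot be tuned to a single
architecture — scores the mean absolute heritability bias, and picks the
minimizer with ties broken toward the cheaper representation (smaller `b`,
then `r`). Grid points whose approximation or fit fails (e.g. an
indefinite shifted system, or a degenerate variance update under a
too-aggressive truncation) are excluded and flagged in the result table.
The incremental rank search grows the factor set `step` eigenpairs at a
time and stops when a round improves the criterion by less than
`tol_improve` (default 1e-3); its factors at the chosen rank coincide with
a direct top-`r` decomposition. The randomized decomposition backend is a
seeded range-finder with oversampling 10 and 4 power iterations.

## REML oracle

`reml_direct` maximizes the individual-level likelihood
`−½log|V| − ½yᵀV⁻¹y` directly. The `grid_refine` route profiles the
likelihood through the thin SVD of `X` (making each evaluation O(p)),
scans a log-spaced grid over the variance ratio `σ²_g/σ²_e ∈ [1e-4, 1e4]`
crossed with total-variance multipliers, and polishes with Nelder–Mead in
log-parameters — deliberately sharing no code with the fixed-point
iteration it certifies. `direct_em` is the same Henderson iteration run
from `(X, y)`. The two agree to 1e-4, and the individual-level and
summary-statistics likelihoods agree identically (up to the common dropped
constant `−(n/2)log 2π`) at arbitrary parameter points. `henderson_blup`
solves the mixed-model equations and matches the summary-side ridge solve
to 1e-9 — the dual form the whole method rests on.

## Synthetic data

Genotypes: each marker gets a target allele frequency `f_j ~ U(0.05, 0.5)`
(the lower bound avoids near-monomorphic instability at small n; real-data
analyses typically filter at 1%, configurable via `maf_range`). Two
haplotype vectors per individual are drawn from a latent Gaussian with
independent / AR(1)(ρ) / block-equicorrelated structure across markers,
thresholded at `Φ⁻¹(f_j)`, and summed to a 0/1/2 genotype. This reproduces
the banded-dominant LD of real chromosomes — the regime the banded+low-rank
compression targets — and is deterministic given the seed (genotypes,
causal set, effects and noise use independent substreams). Columns that
come out monomorphic are redrawn independently (up to 10 rounds; the
salvage column loses its LD with neighbours) and failure raises.

Standardization applies the `(G − 2f)/√(2f(1−f))` transform and then
re-centers/re-scales to exact sample moments, which makes
`diag(XᵀX/n) = 1/p` hold exactly in finite samples, as the model assumes.
Phenotypes: a causal set of `round(polygenicity·p)` markers drawn
uniformly without replacement, `β_j ~ N(0, h²/p_causal)` on it,
`ε ~ N(0, (1−h²)I)`.

What the simulator does *not* emulate: relatedness and population
structure (environmental noise is independent across individuals),
MAF/LD-dependent per-SNP variance (the model weights all standardized
markers equally), imputation artifacts, and the MAF drift induced by
subsampling a larger cohort. Passing tests therefore certify the
estimator's behaviour under its own model assumptions — including
misspecified *sparsity* (polygenicity < 1), which the robustness sweep
covers — but not under MAF/LD-coupled architectures, where a bias is
expected for this model class.

## Problem sizes and numerical choices

The test and acceptance workloads use n = 2000, p = 200 with 100–500
replicates for the distributional checks, and p = 60–200 fixtures for the
algebraic ones — sizes at which every quantity is recomputable in seconds
while leaving the Monte-Carlo error well inside the asserted tolerances.
Convergence tolerance 1e-6 (components), boundary floor 1e-10 of the total
variance, eigenvalue clipping at 0 for PSD projections, banded-Cholesky
shift errors surfaced rather than regularized away. All randomness flows
from explicit seeds; there are no global RNG dependencies.

## Known limitations

- Single variance component only: no partitioned/annotation models.
- In-sample LD is assumed; mismatched (out-of-sample) LD gives biased
  estimates and is deliberately not supported beyond marker-count/ID
  checks.
- The analytic SE degenerates at the `h² = 0` boundary (reported missing).
- Genome-wide (as opposed to local) estimation is out of scope: cost
  scales with `p`, and concatenating local estimates is known to be
  biased by cross-block LD leakage.
- Liability-scale transformation for binary traits is not implemented.
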