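"""Synthetic GWAS data with controllable LD, polygenicity and heritability.

Genotypes are produced by a latent-Gaussian threshold model: each of the two
haplotypes of an individual is a correlated Gaussian vector across markers
(independent / AR(1) / block-equicorrelated), thresholded at the per-marker
allele-frequency quantile, and the two haplotype indicators are summed into
an additive 0/1/2 genotype.  This reproduces the banded-dominant LD of real
chromosomes while keeping every draw reproducible from a single seed.

Phenotypes follow the standard additive model on unit-variance genotypes:
``beta_j ~ N(0, sigma_g^2 / p_causal)`` on a causal set drawn uniformly
without replacement, with independent noise ``eps ~ N(0, (1 - sigma_g^2) I)``.
"""

from __future__ import annotations

from typing import Optional, Tuple

import numpy as np
from scipy import stats as sps

from .types import GenotypePanel, SimulationConfig, StandardizedGenotypes, SummaryStats

__all__ = [
    "simulate_genotypes",
    "standardize",
    "simulate_phenotype",
    "compute_sumstats",
    "expected_sumstats",
    "marginal_ols",
    "project_covariates",
]

_MAX_COLUMN_RETRIES = 10


def _latent_haplotypes(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Draw 2n latent Gaussian vectors of length p with the configured LD."""
    n2, p = 2 * config.n, config.p
    eps = rng.standard_normal((n2, p))
    if config.ld_model == "independent" or config.rho == 0.0:
        return eps
    if config.ld_model == "ar1":
        rho = config.rho
        z = np.empty_like(eps)
        z[:, 0] = eps[:, 0]
        scale = np.sqrt(1.0 - rho * rho)
        for j in range(1, p):
            z[:, j] = rho * z[:, j - 1] + scale * eps[:, j]
        return z
    # block-equicorrelated: z = sqrt(rho) * u_block + sqrt(1 - rho) * eps
    rho = config.rho
    n_blocks = -(-p // config.block_size)
    u = rng.standard_normal((n2, n_blocks))
    z = np.empty_like(eps)
    for b in range(n_blocks):
        lo, hi = b * config.block_size, min((b + 1) * config.block_size, p)
        z[:, lo:hi] = np.sqrt(rho) * u[:, [b]] + np.sqrt(1.0 - rho) * eps[:, lo:hi]
    return z


def simulate_genotypes(config: SimulationConfig) -> GenotypePanel:
    """Generate an n x p additive genotype panel with the configured LD.

    Deterministic given ``config.seed``.  Columns that come out monomorphic
    (possible at small n) are redrawn independently a bounded number of
    times; persistent failure raises.
    """
    ss = np.random.SeedSequence(entropy=(config.seed, 0x67656E6F))
    rng_f, rng_z, rng_retry = [np.random.default_rng(s) for s in ss.spawn(3)]
    lo, hi = config.maf_range
    f = rng_f.uniform(lo, hi, size=config.p)
    thresh = sps.norm.ppf(f)
    z = _latent_haplotypes(config, rng_z)
    hap = (z < thresh[None, :]).astype(np.int8)
    G = hap[: config.n] + hap[config.n :]

    for _ in range(_MAX_COLUMN_RETRIES):
        counts = G.sum(axis=0)
        mono = np.flatnonzero((counts == 0) | (counts == 2 * config.n))
        if mono.size == 0:
            break
        # redraw offending columns with independent latents; the (rare)
        # redrawn column loses its LD with neighbours, which is acceptable
        # for a salvage path at small n
        znew = rng_retry.standard_normal((2 * config.n, mono.size))
        hapnew = (znew < thresh[None, mono]).astype(np.int8)
        G[:, mono] = hapnew[: config.n] + hapnew[config.n :]
    else:
        raise RuntimeError(
            f"could not avoid monomorphic columns after {_MAX_COLUMN_RETRIES} retries"
        )

    maf = G.mean(axis=0) / 2.0
    ids = [f"snp{j}" for j in range(config.p)]
    return GenotypePanel(G=G, maf=maf, ids=ids)


def standardize(panel: GenotypePanel, convention: str = "unit_variance") -> StandardizedGenotypes:
    """Standardize a genotype panel.

    Columns are first scaled as ``(G_ij - 2 f_j) / sqrt(2 f_j (1 - f_j))``
    and then re-centered/re-scaled to exact sample moments (mean 0, variance
    1 with the 1/n convention), which makes ``diag(X^T X / n) = 1/p`` exact
    in finite samples under ``model_scale``.
    """
    G = np.asarray(panel.G, dtype=float)
    counts = G.sum(axis=0)
    mono = np.flatnonzero((counts == 0) | (counts == 2 * panel.n))
    if mono.size:
        raise ValueError(f"monomorphic marker at column {int(mono[0])}")
    f = panel.maf
    X = (G - 2.0 * f) / np.sqrt(2.0 * f * (1.0 - f))
    X = X - X.mean(axis=0)
    sd = np.sqrt((X**2).mean(axis=0))
    if np.any(sd == 0):
        raise ValueError(f"zero-variance marker at column {int(np.flatnonzero(sd == 0)[0])}")
    X = X / sd
    if convention == "model_scale":
        X = X / np.sqrt(panel.p)
    return StandardizedGenotypes(X=X, scale_convention=convention)


def simulate_phenotype(
    X: StandardizedGenotypes, config: SimulationConfig
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate one phenotype replicate; returns (y, beta_true, causal_set).

    Requires ``unit_variance`` genotypes.  The causal set (size
    ``round(polygenicity * p)``) and the effect/noise draws use independent
    substreams of ``config.seed``, so the same seed always reproduces the
    same phenotype.
    """
    if X.scale_convention != "unit_variance":
        raise ValueError("phenotype simulation expects unit_variance genotypes")
    if not (0.0 <= config.h2 < 1.0):
        raise ValueError("h2 must lie in [0, 1)")
    n, p = X.n, X.p
    ss = np.random.SeedSequence(entropy=(config.seed, 0x7068656E))
    rng_c, rng_b, rng_e = [np.random.default_rng(s) for s in ss.spawn(3)]
    beta = np.zeros(p)
    if config.h2 > 0:
        causal = np.sort(rng_c.choice(p, size=config.p_causal, replace=False))
        beta[causal] = rng_b.normal(0.0, np.sqrt(config.h2 / config.p_causal), size=causal.size)
    else:
        causal = np.array([], dtype=int)
    eps = rng_e.normal(0.0, np.sqrt(1.0 - config.h2), size=n)
    y = X.X @ beta + eps
    return y, beta, causal


def compute_sumstats(
    X: StandardizedGenotypes, y: np.ndarray
) -> Tuple[SummaryStats, np.ndarray]:
    """Form the sufficient statistics (S = X^T y, y^T y) and LD R = X^T X.

    Expects ``model_scale`` genotypes; S and R are kept unscaled by n.
    """
    if X.scale_convention != "model_scale":
        raise ValueError("summary statistics are defined on model_scale genotypes")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.n:
        raise ValueError(f"y has length {y.shape[0]}, expected {X.n}")
    S = X.X.T @ y
    R = X.X.T @ X.X
    R = (R + R.T) / 2.0
    stats = SummaryStats(S=S, n=X.n, yty=float(y @ y), z_mode=False)
    return stats, R


def expected_sumstats(R: np.ndarray, sigma_g2: float, sigma_e2: float, n: int) -> SummaryStats:
    """Noise-free summary statistics whose moments equal their expectations.

    Under the model, ``E[S S'] = sigma_g^2 R^2 + sigma_e^2 R`` and
    ``E[y'y] = sigma_g^2 tr(R) + n sigma_e^2``.  This constructs a single
    vector ``S`` (in the eigenbasis of R) whose quadratic forms
    ``S'(lam I + R)^{-1} S`` equal those expectations for *every* shift, so
    the summary likelihood evaluated on it is the exact expected
    log-likelihood.  Fitting on it recovers (sigma_g^2, sigma_e^2) exactly,
    and its curvature at the truth is the Fisher information — useful for
    certifying the analytic variance formulas.
    """
    R = np.asarray(R, dtype=float)
    w, U = np.linalg.eigh((R + R.T) / 2.0)
    s2 = np.clip(sigma_g2 * w**2 + sigma_e2 * w, 0.0, None)
    S = U @ np.sqrt(s2)
    yty = sigma_g2 * float(np.trace(R)) + n * sigma_e2
    return SummaryStats(S=S, n=n, yty=float(yty), z_mode=False)


def marginal_ols(X: StandardizedGenotypes, y: np.ndarray) -> np.ndarray:
    """Per-SNP marginal OLS slopes ``beta_hat_j = X_j^T y / n`` (unit-variance X)."""
    if X.scale_convention != "unit_variance":
        raise ValueError("marginal OLS slopes are defined on unit_variance genotypes")
    y = np.asarray(y, dtype=float).ravel()
    if y.shape[0] != X.n:
        raise ValueError(f"y has length {y.shape[0]}, expected {X.n}")
    return X.X.T @ y / X.n


def project_covariates(
    X: np.ndarray, y: np.ndarray, C: np.ndarray
) -> Tuple[np.ndarray, np.ndarray]:
    """Residualize genotypes and phenotype on a full-rank covariate matrix."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    C = np.asarray(C, dtype=float)
    if C.ndim == 1:
        C = C[:, None]
    Q, Rq = np.linalg.qr(C)
    if np.any(np.abs(np.diag(Rq)) < 1e-10 * max(1.0, np.abs(Rq).max())):
        raise ValueError("covariate matrix is rank-deficient")
    X_resid = X - Q @ (Q.T @ X)
    y_resid = y - Q @ (Q.T @ y)
    return X_resid, y_resid
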