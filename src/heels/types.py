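"""Shared data containers for the heritability-estimation pipeline.

Conventions
-----------
Two genotype scalings are used throughout:

``unit_variance``
    Each standardized genotype column has mean 0 and (population-style)
    sample variance 1.  Marginal OLS slopes and Z-scores live on this scale.
``model_scale``
    The unit-variance matrix divided by ``sqrt(p)``, so that
    ``diag(X^T X / n) = 1/p`` exactly.  The linear mixed model underlying the
    estimator is written on this scale, and the summary statistics
    ``S = X^T y`` and LD matrix ``R = X^T X`` are kept *unscaled* by n
    (no ``1/sqrt(n)`` on S, no ``1/n`` on R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "GenotypePanel",
    "StandardizedGenotypes",
    "SimulationConfig",
    "SummaryStats",
    "VarianceComponents",
]


@dataclass
class GenotypePanel:
    """Raw additive genotypes: n individuals x p markers with entries 0/1/2.

    ``maf`` holds the in-sample allele frequency ``f_j`` of the allele
    counted by ``G``; monomorphic columns (f_j in {0, 1}) are disallowed.
    """

    G: np.ndarray
    maf: np.ndarray
    ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.G = np.asarray(self.G)
        self.maf = np.asarray(self.maf, dtype=float)
        n, p = self.G.shape
        if n < 2 or p < 1:
            raise ValueError(f"panel needs n >= 2 and p >= 1, got {n} x {p}")
        if self.maf.shape != (p,):
            raise ValueError("maf length must equal number of markers")
        if np.any((self.maf <= 0.0) | (self.maf >= 1.0)):
            bad = int(np.flatnonzero((self.maf <= 0.0) | (self.maf >= 1.0))[0])
            raise ValueError(f"monomorphic marker at column {bad}")

    @property
    def n(self) -> int:
        return self.G.shape[0]

    @property
    def p(self) -> int:
        return self.G.shape[1]


@dataclass
class StandardizedGenotypes:
    """Standardized genotype matrix with its scale convention attached."""

    X: np.ndarray
    scale_convention: str  # "unit_variance" | "model_scale"

    def __post_init__(self) -> None:
        if self.scale_convention not in ("unit_variance", "model_scale"):
            raise ValueError(f"unknown scale convention {self.scale_convention!r}")
        self.X = np.asarray(self.X, dtype=float)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


@dataclass
class SimulationConfig:
    """Generative parameters for the synthetic GWAS simulator.

    Parameters
    ----------
    n, p
        Sample and marker counts.
    h2
        True SNP-heritability (the genetic variance sigma_g^2 on the
        standardized scale, since the phenotype has unit total variance).
    polygenicity
        Fraction of markers that are causal (p_causal / p).
    seed
        Master seed; all draws (genotypes, causal set, effects, noise) use
        independent substreams derived from it.
    ld_model
        "independent", "ar1" or "block" — correlation structure of the
        latent Gaussian used to generate linked genotypes.
    rho
        Adjacent-marker latent correlation (ar1) or within-block latent
        correlation (block).
    block_size
        Markers per block for ld_model="block".
    maf_range
        Range of the uniform in-sample allele-frequency targets.
    """

    n: int
    p: int
    h2: float = 0.25
    polygenicity: float = 1.0
    seed: int = 0
    ld_model: str = "ar1"
    rho: float = 0.0
    block_size: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 < 1.0):
            raise ValueError(f"h2 must lie in [0, 1), got {self.h2}")
        if not (0.0 < self.polygenicity <= 1.0):
            raise ValueError("polygenicity must lie in (0, 1]")
        if self.ld_model not in ("independent", "ar1", "block"):
            raise ValueError(f"unknown ld_model {self.ld_model!r}")
        if self.h2 > 0 and math.ceil(self.polygenicity * self.p) < 1:
            raise ValueError("no causal marker available at h2 > 0")

    @property
    def p_causal(self) -> int:
        return max(1, int(round(self.polygenicity * self.p)))


@dataclass
class SummaryStats:
    """Marginal association statistics for one locus.

    ``S`` is ``X^T y`` in model scale when ``z_mode`` is False; when
    ``z_mode`` is True, ``S`` holds Z-scores and ``yty`` is absent — the
    fitting routine then applies the per-iteration variance renormalization
    (equivalent to approximating ``y^T y / n`` by 1).
    """

    S: np.ndarray
    n: int
    yty: Optional[float] = None
    z_mode: bool = False
    ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float).ravel()
        if self.z_mode and self.yty is not None:
            raise ValueError("z_mode summary statistics carry no y^T y")

    @property
    def p(self) -> int:
        return self.S.shape[0]


@dataclass
class VarianceComponents:
    """The (sigma_g^2, sigma_e^2) pair of the single-component mixed model."""

    sigma_g2: float
    sigma_e2: float

    def __post_init__(self) -> None:
        if self.sigma_g2 < 0 or self.sigma_e2 < 0:
            raise ValueError("variance components must be non-negative")
        if self.sigma_g2 == 0 and self.sigma_e2 == 0:
            raise ValueError("variance components cannot both be zero")

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def shift(self) -> float:
        """The ridge shift lambda = sigma_e^2 / sigma_g^2."""
        return self.sigma_e2 / self.sigma_g2
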