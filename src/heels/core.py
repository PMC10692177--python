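"""Summary-statistics REML: the iterative variance-component solver.

Given marginal statistics ``S = X^T y``, the in-sample LD ``R = X^T X`` and
the phenotypic sum of squares ``y^T y``, the solver alternates

1. BLUP (ridge) update       ``beta = (lambda I + R)^{-1} S``, lambda = se2/sg2
2. genetic-variance update   ``sg2 = beta'beta / (p - lambda tr(W^{-1}))``
3. residual-variance update  ``se2 = (y'y - S'beta) / n``

whose fixed points solve the REML score equations of the individual-level
mixed model — hence the estimator matches direct REML on the same data.
The denominator in step 2 equals ``tr(W^{-1} R)`` with ``W = lambda I + R``,
i.e. ``p`` minus the trace-inverse of ``I + (sg2/se2) R``.

All LD access goes through :class:`LDOperator`, so the same iteration runs
against the exact dense matrix or a banded-plus-low-rank compression.
"""

from __future__ import annotations

import abc
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
import scipy.linalg

from .types import SummaryStats, VarianceComponents

__all__ = [
    "LDOperator",
    "DenseLD",
    "blup_update",
    "loglik_summary",
    "heels_fit",
    "HeelsFit",
]


class LDOperator(abc.ABC):
    """Contract for shifted solves and trace functionals of an LD matrix.

    Every method takes the ridge shift ``lam`` > 0 and refers to
    ``M = lam * I_p + R`` (or the approximation of R).
    """

    p: int
    mode: str

    @abc.abstractmethod
    def solve(self, lam: float, v: np.ndarray) -> np.ndarray:
        """Return ``(lam I + R)^{-1} v``."""

    @abc.abstractmethod
    def trace_inv(self, lam: float) -> float:
        """Return ``tr((lam I + R)^{-1})``."""

    @abc.abstractmethod
    def trace_inv_sq(self, lam: float) -> float:
        """Return ``tr((lam I + R)^{-2})``."""

    @abc.abstractmethod
    def logdet(self, lam: float) -> float:
        """Return ``log |lam I + R|``."""


class DenseLD(LDOperator):
    """Exact dense LD backed by a cached eigendecomposition.

    One O(p^3) factorization makes every subsequent solve / trace / logdet
    O(p^2) or O(p), which is what the per-iteration shift changes need.
    """

    mode = "exact_dense"

    def __init__(self, R: np.ndarray):
        R = np.asarray(R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("LD matrix must be square")
        self.R = (R + R.T) / 2.0
        self.p = R.shape[0]
        self._evals: Optional[np.ndarray] = None
        self._evecs: Optional[np.ndarray] = None

    def _eig(self) -> Tuple[np.ndarray, np.ndarray]:
        if self._evals is None:
            self._evals, self._evecs = np.linalg.eigh(self.R)
        return self._evals, self._evecs

    def _shifted(self, lam: float) -> np.ndarray:
        w, _ = self._eig()
        shifted = w + lam
        if np.any(shifted <= 0):
            raise np.linalg.LinAlgError(
                f"shifted LD matrix indefinite at lambda={lam:g} "
                f"(min eigenvalue {w.min():g})"
            )
        return shifted

    def solve(self, lam: float, v: np.ndarray) -> np.ndarray:
        shifted = self._shifted(lam)
        _, U = self._eig()
        return U @ ((U.T @ v) / shifted.reshape((-1,) + (1,) * (np.ndim(v) - 1)))

    def trace_inv(self, lam: float) -> float:
        return float(np.sum(1.0 / self._shifted(lam)))

    def trace_inv_sq(self, lam: float) -> float:
        return float(np.sum(1.0 / self._shifted(lam) ** 2))

    def logdet(self, lam: float) -> float:
        return float(np.sum(np.log(self._shifted(lam))))


def blup_update(S: np.ndarray, ld: LDOperator, vc: VarianceComponents) -> np.ndarray:
    """One BLUP update: ``(lambda I + R)^{-1} S`` with lambda = se2/sg2."""
    if vc.sigma_g2 <= 0:
        raise ValueError("BLUP update requires sigma_g2 > 0")
    lam = vc.shift
    try:
        return ld.solve(lam, np.asarray(S, dtype=float))
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"BLUP solve failed at lambda={lam:g}: {exc}"
        ) from exc


def loglik_summary(stats: SummaryStats, ld: LDOperator, vc: VarianceComponents) -> float:
    """Summary-statistics log-likelihood of the variance components.

    ``-n/2 log(se2) - 1/2 log|I_p + (sg2/se2) R| - (y'y - S'(lam I + R)^{-1}S)/(2 se2)``

    equals the individual-level marginal log-likelihood up to the constant
    ``-n/2 log(2 pi)`` dropped on both sides.
    """
    if vc.sigma_g2 <= 0 or vc.sigma_e2 <= 0:
        raise ValueError("log-likelihood requires strictly positive components")
    if stats.yty is None:
        raise ValueError("log-likelihood needs y^T y (not available in z_mode)")
    lam = vc.shift
    # log|I + (sg2/se2) R| = log|lam I + R| - p log lam
    ld_term = ld.logdet(lam) - ld.p * np.log(lam)
    quad = stats.yty - float(stats.S @ ld.solve(lam, stats.S))
    return float(
        -0.5 * stats.n * np.log(vc.sigma_e2) - 0.5 * ld_term - quad / (2.0 * vc.sigma_e2)
    )


@dataclass
class HeelsFit:
    """Result of the iterative summary-statistics REML fit."""

    vc: VarianceComponents
    h2: float
    blup: np.ndarray
    n_iter: int
    converged: bool
    boundary: bool
    loglik_trace: np.ndarray
    se_h2: Optional[float] = None  # filled by heels.uncertainty
    n: int = 0
    p: int = 0


_FLOOR_FRAC = 1e-10


def heels_fit(
    stats: SummaryStats,
    ld: LDOperator,
    init: Optional[Tuple[float, float]] = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
    random_init_seed: Optional[int] = None,
) -> HeelsFit:
    """Estimate (sigma_g^2, sigma_e^2) and h2 from summary statistics.

    Parameters
    ----------
    stats
        Marginal statistics.  In ``z_mode`` the entries of ``S`` are
        Z-scores; they are rescaled to the model-scale statistic
        ``S = sqrt(n/p) Z``, ``y^T y`` is approximated by ``n``, and the
        component pair is renormalized to sum to one after every iteration.
    ld
        Exact or approximated LD operator of matching dimension.
    init
        Starting ``(sigma_g2, sigma_e2)``; default (0.5, 0.5).  Pass
        ``random_init_seed`` instead for a uniform(0, 1) random start.
    tol
        Convergence threshold on the max absolute change of either
        component between consecutive iterations.
    """
    p = stats.p
    if p != ld.p:
        raise ValueError(f"dimension mismatch: stats p={p}, LD p={ld.p}")
    n = stats.n
    z_mode = stats.z_mode
    if z_mode:
        S = np.sqrt(n / p) * stats.S
        yty = float(n)
    else:
        S = stats.S.astype(float)
        if stats.yty is None:
            raise ValueError("y^T y is required unless z_mode is set")
        yty = float(stats.yty)

    if init is None:
        if random_init_seed is not None:
            rng = np.random.default_rng(random_init_seed)
            sg2, se2 = rng.uniform(0.05, 1.0, size=2)
        else:
            sg2, se2 = 0.5, 0.5
    else:
        sg2, se2 = float(init[0]), float(init[1])
    if sg2 <= 0 or se2 <= 0:
        raise ValueError("initial variance components must be positive")

    # scale-free default init: match the data scale so the first shift is O(1)
    if init is None and random_init_seed is None and not z_mode:
        total = max(yty / n, np.finfo(float).tiny)
        sg2, se2 = 0.5 * total, 0.5 * total

    track_loglik = yty is not None
    trace: List[float] = []
    beta = np.zeros(p)
    boundary = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        lam = se2 / sg2
        beta = ld.solve(lam, S)
        tr_winv = ld.trace_inv(lam)
        denom = p - lam * tr_winv  # = tr(W^{-1} R)
        if not np.isfinite(denom) or denom <= 0:
            raise FloatingPointError(
                f"degenerate genetic-variance update at iteration {it}: "
                f"p - lambda*tr(W^-1) = {denom:g} (lambda={lam:g})"
            )
        sg2_new = float(beta @ beta) / denom
        se2_new = (yty - float(S @ beta)) / n
        if not (np.isfinite(sg2_new) and np.isfinite(se2_new)):
            raise FloatingPointError(f"non-finite update at iteration {it}")

        total = sg2_new + se2_new
        floor = _FLOOR_FRAC * total
        if sg2_new < floor:
            sg2_new, boundary = floor, True
        if se2_new < floor:
            se2_new, boundary = floor, True
        if z_mode:
            s = sg2_new + se2_new
            sg2_new, se2_new = sg2_new / s, se2_new / s

        delta = max(abs(sg2_new - sg2), abs(se2_new - se2))
        sg2, se2 = sg2_new, se2_new
        if track_loglik:
            trace.append(loglik_summary(
                SummaryStats(S=S, n=n, yty=yty), ld, VarianceComponents(sg2, se2)
            ))
        if delta < tol:
            converged = True
            break

    vc = VarianceComponents(sg2, se2)
    beta = ld.solve(vc.shift, S)
    return HeelsFit(
        vc=vc,
        h2=vc.h2,
        blup=beta,
        n_iter=it,
        converged=converged,
        boundary=boundary,
        loglik_trace=np.asarray(trace),
        n=n,
        p=p,
    )
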