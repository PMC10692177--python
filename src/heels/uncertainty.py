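"""Analytic standard errors via the summary-statistics Fisher information.

The information matrix for (sigma_e^2, sigma_g^2) — in that order — can be
written entirely in terms of n, p and the traces tr(W^{-1}), tr(W^{-2})
with ``W = (sigma_e^2/sigma_g^2) I_p + R``:

    I = 1/2 [[ (n-p)/se^4 + tr(W^-2)/sg^4,
               tr(W^-1)/sg^4 - (se^2/sg^6) tr(W^-2) ],
             [ symmetric,
               p/sg^4 - 2 (se^2/sg^6) tr(W^-1) + (se^4/sg^8) tr(W^-2) ]]

The delta method then gives the variance of h2 = sg^2/(sg^2+se^2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .core import HeelsFit, LDOperator
from .types import VarianceComponents

__all__ = [
    "FisherInfo",
    "fisher_info",
    "h2_gradient",
    "h2_se",
    "relative_efficiency",
    "coverage_check",
]


@dataclass
class FisherInfo:
    """2x2 information matrix for (sigma_e^2, sigma_g^2), plus its traces."""

    matrix: np.ndarray
    tr_winv: float
    tr_winv2: float
    n: int
    p: int


def fisher_info(ld: LDOperator, vc: VarianceComponents, n: int) -> FisherInfo:
    """Expected information of the variance components at ``vc``.

    Valid for any n, p; when p >= n the (n-p) term goes negative and the
    matrix may lose definiteness, so a warning is emitted.
    """
    if vc.sigma_g2 <= 0 or vc.sigma_e2 <= 0:
        raise ValueError("Fisher information requires strictly positive components")
    p = ld.p
    if p >= n:
        warnings.warn(
            f"p={p} >= n={n}: the information matrix may lose definiteness",
            stacklevel=2,
        )
    se2, sg2 = vc.sigma_e2, vc.sigma_g2
    lam = vc.shift
    t1 = ld.trace_inv(lam)
    t2 = ld.trace_inv_sq(lam)
    i_ee = (n - p) / se2**2 + t2 / sg2**2
    i_eg = t1 / sg2**2 - se2 * t2 / sg2**3
    i_gg = p / sg2**2 - 2.0 * se2 * t1 / sg2**3 + se2**2 * t2 / sg2**4
    M = 0.5 * np.array([[i_ee, i_eg], [i_eg, i_gg]])
    return FisherInfo(matrix=M, tr_winv=t1, tr_winv2=t2, n=n, p=p)


def h2_gradient(vc: VarianceComponents) -> np.ndarray:
    """Gradient of f(se2, sg2) = sg2/(sg2+se2) in the (se2, sg2) order."""
    tot = vc.sigma_g2 + vc.sigma_e2
    return np.array([-vc.sigma_g2 / tot**2, vc.sigma_e2 / tot**2])


def h2_se(fit: HeelsFit, info: FisherInfo) -> Optional[float]:
    """Delta-method standard error of the heritability estimate.

    Returns None (and flags nothing else) when the fit sits on the
    parameter-space boundary, where the delta method degenerates.
    """
    if fit.boundary:
        return None
    grad = h2_gradient(fit.vc)
    M = info.matrix
    cond = np.linalg.cond(M)
    if not np.isfinite(cond) or cond > 1e14:
        raise np.linalg.LinAlgError(
            f"information matrix is numerically singular (condition number {cond:.3g})"
        )
    var = float(grad @ np.linalg.solve(M, grad))
    return float(np.sqrt(max(var, 0.0)))


def relative_efficiency(var_reference: float, var_estimator: float) -> float:
    """Efficiency of an estimator relative to a reference, in percent.

    ``100 * var_reference / var_estimator`` — the reference is the
    individual-level REML variance; values near 100% mean the estimator
    under test is (nearly) as precise as REML.
    """
    if var_reference <= 0 or var_estimator <= 0:
        raise ValueError("variances must be strictly positive")
    return 100.0 * var_reference / var_estimator


def coverage_check(
    fits: Sequence[Tuple[float, float]], h2_true: float, level: float = 0.95
) -> float:
    """Empirical coverage of normal-theory intervals ``h2_hat +- z * se``."""
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    fits = list(fits)
    if not fits:
        raise ValueError("empty list of fits")
    from scipy.stats import norm

    z = norm.ppf(0.5 + level / 2.0)
    hits = sum(
        1 for (h2_hat, se) in fits if abs(h2_hat - h2_true) <= z * se
    )
    return hits / len(fits)
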