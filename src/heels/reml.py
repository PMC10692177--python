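"""Individual-level REML reference implementations.

These fit the same single-component mixed model directly from (X, y) —
maximizing ``-1/2 log|V| - 1/2 y'V^{-1}y`` with
``V = sigma_g^2 X X' + sigma_e^2 I_n`` — and exist to certify that the
summary-statistics solver lands on the same optimum.  The ``grid_refine``
route goes through the thin SVD of X and a derivative-free search, so it
shares no code path with the fixed-point iteration it checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy import optimize

from .types import StandardizedGenotypes, VarianceComponents

__all__ = ["RemlFit", "reml_direct", "henderson_blup", "individual_loglik"]


@dataclass
class RemlFit:
    vc: VarianceComponents
    h2: float
    loglik: float
    method: str
    converged: bool


def _svd_profile(X: np.ndarray, y: np.ndarray):
    """Precompute the pieces that make the likelihood O(p) per evaluation.

    With thin SVD ``X = Q diag(s) V'``, the eigenvalues of XX' are s_i^2
    (and 0 with multiplicity n-p), and ``y'V^{-1}y`` splits into the top-p
    rotated coordinates plus the orthogonal remainder.
    """
    n, p = X.shape
    Q, s, _ = np.linalg.svd(X, full_matrices=False)
    d = s**2  # nonzero eigenvalues of XX^T (length min(n, p))
    qy = Q.T @ y
    resid2 = float(y @ y) - float(qy @ qy)  # ||y||^2 outside col(X)
    n_extra = n - d.shape[0]
    return d, qy, max(resid2, 0.0), n_extra


def individual_loglik(X: np.ndarray, y: np.ndarray, sg2: float, se2: float) -> float:
    """Marginal log-likelihood ``-1/2 log|V| - 1/2 y'V^{-1}y`` (constant dropped)."""
    d, qy, resid2, n_extra = _svd_profile(np.asarray(X, float), np.asarray(y, float).ravel())
    ev = sg2 * d + se2
    return float(
        -0.5 * (np.sum(np.log(ev)) + n_extra * np.log(se2))
        - 0.5 * (np.sum(qy**2 / ev) + resid2 / se2)
    )


def _loglik_from_profile(profile, sg2: float, se2: float) -> float:
    d, qy, resid2, n_extra = profile
    ev = sg2 * d + se2
    return float(
        -0.5 * (np.sum(np.log(ev)) + n_extra * np.log(se2))
        - 0.5 * (np.sum(qy**2 / ev) + resid2 / se2)
    )


def _grid_refine(profile, n: int) -> Tuple[float, float, float, bool]:
    d, qy, resid2, n_extra = profile
    yty = float(qy @ qy) + resid2
    total0 = yty / n
    ratios = np.logspace(-4, 4, 33)  # sigma_g2 / sigma_e2
    totals = total0 * np.logspace(-1, 1, 9)
    best, best_ll = None, -np.inf
    for t in totals:
        for r in ratios:
            sg2 = t * r / (1.0 + r)
            se2 = t / (1.0 + r)
            ll = _loglik_from_profile(profile, sg2, se2)
            if ll > best_ll:
                best_ll, best = ll, (sg2, se2)
    # local refinement in log-parameters, derivative-free
    x0 = np.log(best)
    res = optimize.minimize(
        lambda x: -_loglik_from_profile(profile, np.exp(x[0]), np.exp(x[1])),
        x0,
        method="Nelder-Mead",
        options={"xatol": 1e-9, "fatol": 1e-12, "maxiter": 2000},
    )
    sg2, se2 = np.exp(res.x)
    return float(sg2), float(se2), float(-res.fun), bool(res.success)


def _direct_em(X: np.ndarray, y: np.ndarray, tol: float = 1e-8, max_iter: int = 5000):
    """Henderson's individual-level iteration on (X, y)."""
    n, p = X.shape
    R = X.T @ X
    S = X.T @ y
    yty = float(y @ y)
    w, U = np.linalg.eigh((R + R.T) / 2.0)
    Sy = U.T @ S
    sg2 = se2 = 0.5 * yty / n
    converged = False
    for _ in range(max_iter):
        lam = se2 / sg2
        shifted = w + lam
        beta_rot = Sy / shifted
        denom = p - lam * np.sum(1.0 / shifted)
        sg2_new = float(beta_rot @ beta_rot) / denom
        se2_new = (yty - float(Sy @ beta_rot)) / n
        delta = max(abs(sg2_new - sg2), abs(se2_new - se2))
        sg2, se2 = sg2_new, se2_new
        if delta < tol:
            converged = True
            break
    return sg2, se2, converged


def reml_direct(X, y, method: str = "grid_refine") -> RemlFit:
    """Maximize the individual-level likelihood over (sigma_g^2, sigma_e^2).

    ``X`` may be a :class:`StandardizedGenotypes` (model scale) or a plain
    array already on the model scale.
    """
    if isinstance(X, StandardizedGenotypes):
        if X.scale_convention != "model_scale":
            raise ValueError("REML oracle expects model_scale genotypes")
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if method == "grid_refine":
        profile = _svd_profile(X, y)
        sg2, se2, ll, converged = _grid_refine(profile, X.shape[0])
    elif method == "direct_em":
        sg2, se2, converged = _direct_em(X, y)
        ll = individual_loglik(X, y, sg2, se2)
    else:
        raise ValueError(f"unknown method {method!r}")
    if not np.isfinite(ll):
        raise FloatingPointError("non-finite likelihood at the REML optimum")
    vc = VarianceComponents(sg2, se2)
    return RemlFit(vc=vc, h2=vc.h2, loglik=ll, method=method, converged=converged)


def henderson_blup(X, y, vc: VarianceComponents) -> Tuple[np.ndarray, np.ndarray]:
    """Solve the mixed model equations for the random-effect predictor.

    ``(X'X + lambda I) beta = X'y`` with ``lambda = sigma_e2/sigma_g2``;
    returns ``(beta_hat, X beta_hat)``.  Identical to the summary-side BLUP
    on ``(S, R) = (X'y, X'X)`` — the dual form the estimator exploits.
    """
    if isinstance(X, StandardizedGenotypes):
        X = X.X
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if vc.sigma_g2 <= 0 or vc.sigma_e2 < 0:
        raise ValueError("variance components must be positive")
    p = X.shape[1]
    A = X.T @ X + vc.shift * np.eye(p)
    try:
        beta = np.linalg.solve(A, X.T @ y)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(f"singular mixed-model equations: {exc}") from exc
    return beta, X @ beta
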