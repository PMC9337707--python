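"""Regularization of reference-panel LD matrices and likelihood-based
estimation of the regularization level.

A reference-panel LD estimate R0 inevitably differs from the in-sample
LD of the association study.  Shrinking it toward the identity,

    R_lambda = (1 - lambda) R0 + lambda I,    lambda in [0, 1],

improves consistency with the observed z-scores and makes the matrix
invertible.  The level lambda is chosen by maximizing the multivariate
normal log-density of the (PVE-adjusted) z-scores under the null
(zero-mean) model with covariance R_lambda.  When the z-scores and LD are
consistent the estimate lands near zero; gross misspecification drives it
toward one.
"""

from __future__ import annotations

import logging
from typing import Tuple

import numpy as np
from scipy.optimize import minimize_scalar

from ._exceptions import InputError, NumericalError
from .sufficient import LDMatrix

logger = logging.getLogger(__name__)

__all__ = ["regularize_ld", "estimate_lambda"]

_MIN_EIG = 1e-10


def regularize_ld(R0: LDMatrix, lam: float) -> LDMatrix:
    """Convex combination (1 - lam) R0 + lam I.

    The diagonal stays exactly 1 and symmetry is preserved; every
    eigenvalue is shifted to (1 - lam) e_i + lam.
    """
    if not 0.0 <= lam <= 1.0:
        raise InputError(f"lambda must lie in [0, 1], got {lam}")
    R = (1.0 - lam) * R0.R + lam * np.eye(R0.j)
    np.fill_diagonal(R, 1.0)
    return LDMatrix(R=R, lam=lam, source=R0.source)


def _null_loglik_terms(
    ztilde: np.ndarray, R0: LDMatrix
) -> Tuple[np.ndarray, np.ndarray]:
    """Eigendecompose R0 once; return (eigenvalues, squared rotated z)."""
    evals, evecs = np.linalg.eigh(R0.R)
    w2 = (evecs.T @ ztilde) ** 2
    return evals, w2


def _neg_null_loglik(lam: float, evals: np.ndarray, w2: np.ndarray) -> float:
    shifted = (1.0 - lam) * evals + lam
    if np.any(shifted <= 0):
        return np.inf
    return 0.5 * float(np.sum(np.log(shifted) + w2 / shifted))


def estimate_lambda(ztilde: np.ndarray, R0: LDMatrix) -> float:
    """Regularization level maximizing the null z-score log-density.

    Writing R0 = U diag(e) U' and w = U'z, the zero-mean normal
    log-density under R_lambda is, up to a constant,

        -1/2 sum_i [ log((1-lam) e_i + lam) + w_i^2 / ((1-lam) e_i + lam) ],

    maximized over lam in [0, 1] by a bounded 1-d search.  Negative
    eigenvalues of a non-PSD R0 are tolerated, but the search range is
    restricted so all shifted eigenvalues stay positive (an indefinite
    covariance has no density and can make the objective unbounded).
    Flat objectives (e.g. R0 = I) return the smallest maximizing value, 0.
    """
    ztilde = np.asarray(ztilde, dtype=float)
    if ztilde.shape != (R0.j,):
        raise InputError(
            f"z vector length {ztilde.shape[0]} does not match LD dimension {R0.j}"
        )
    evals, w2 = _null_loglik_terms(ztilde, R0)
    # smallest lam keeping all shifted eigenvalues > _MIN_EIG:
    # (1-lam) e_min + lam >= _MIN_EIG  =>  lam >= (_MIN_EIG - e_min)/(1 - e_min)
    e_min = float(evals.min())
    lo = 0.0
    if e_min <= _MIN_EIG:
        lo = (_MIN_EIG - e_min) / (1.0 - e_min)
        lo = min(max(lo, 0.0), 1.0)
    f_lo = _neg_null_loglik(lo, evals, w2)
    f_hi = _neg_null_loglik(1.0, evals, w2)
    if not (np.isfinite(f_lo) or np.isfinite(f_hi)):
        raise NumericalError("null log-likelihood is non-finite over [0, 1]")
    res = minimize_scalar(
        _neg_null_loglik, args=(evals, w2), bounds=(lo, 1.0),
        method="bounded", options={"xatol": 1e-8},
    )
    lam_hat = float(res.x)
    f_opt = float(res.fun)
    # prefer the smallest maximizer on flat or boundary-optimal objectives
    if f_lo <= f_opt + 1e-10:
        return lo
    if f_hi < f_opt - 1e-10:
        return 1.0
    return lam_hat


def null_loglik(ztilde: np.ndarray, R0: LDMatrix, lam: float) -> float:
    """Zero-mean multivariate normal log-density of z under R_lambda."""
    ztilde = np.asarray(ztilde, dtype=float)
    evals, w2 = _null_loglik_terms(ztilde, R0)
    neg = _neg_null_loglik(lam, evals, w2)
    j = R0.j
    return float(-neg - 0.5 * j * np.log(2.0 * np.pi))
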