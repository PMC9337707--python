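"""Diagnostics for inconsistencies between z-scores and the LD matrix.

Under the null z-score model z ~ N(0, R), the conditional distribution of
one z-score given all the others is, with Omega = R^{-1},

    z_j | z_{-j} ~ N( -Omega_{j,-j} z_{-j} / Omega_jj , 1 / Omega_jj ).

Large standardized deviations of the observed z_j from this conditional
mean flag SNPs whose summary statistics violate the model — mismatched
samples, data errors, or allele flips.  For allele flips specifically, a
likelihood ratio compares the conditional density under a sign-flipped
relationship to LD (conditional mean negated) against the unflipped one:

    LR_j = N(z_j; -mu_j, 1/Omega_jj) / N(z_j; mu_j, 1/Omega_jj)
         = exp(-2 z_j mu_j Omega_jj),

where mu_j is the conditional mean.  LR_j > 1 marks a candidate flip.

These computations require an invertible LD matrix; a reference-panel
estimate is first lambda-regularized (see :mod:`finemapss.ld`).  The
statistics are derived for PVE-adjusted z-scores but remain valid for
unadjusted z-scores when effects are small.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from ._exceptions import InputError, NumericalError
from .sufficient import LDMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "DiagnosticReport",
    "conditional_z",
    "z_discordance",
    "allele_flip_lr",
    "diagnostic_table",
]

_COND_TOL = 1e12        # condition-number threshold for "numerically singular"
_LARGE_J_WARN = 5000


@dataclass
class DiagnosticReport:
    """Per-SNP conditional moments, discordance statistics and flip LRs."""

    expected_z: np.ndarray    # conditional means given all other z-scores
    cond_var: np.ndarray      # conditional variances 1/Omega_jj
    t_stat: np.ndarray        # standardized observed-minus-expected
    flip_lr: np.ndarray       # allele-flip likelihood ratios
    lam_used: float           # regularization applied to invert R


def _precision(Rlam: LDMatrix) -> np.ndarray:
    R = Rlam.R
    if R.shape[0] > _LARGE_J_WARN:
        logger.warning(
            "inverting a %d x %d LD matrix; this may be expensive", *R.shape
        )
    evals = np.linalg.eigvalsh(R)
    if evals.min() <= 0 or evals.max() / evals.min() > _COND_TOL:
        raise NumericalError(
            "LD matrix is numerically singular; regularize it first "
            "(see regularize_ld / estimate_lambda)"
        )
    return np.linalg.inv(R)


def conditional_z(
    ztilde: np.ndarray, Rlam: LDMatrix
) -> Tuple[np.ndarray, np.ndarray]:
    """Conditional mean and variance of each z-score given the others.

    From a single matrix inverse Omega = R^{-1}:
    expected_z_j = -Omega_{j,-j} z_{-j} / Omega_jj, cond_var_j = 1/Omega_jj.
    (Using Omega z = Omega_jj z_j + Omega_{j,-j} z_{-j} row-wise avoids any
    per-SNP submatrix work.)
    """
    ztilde = np.asarray(ztilde, dtype=float)
    if ztilde.shape != (Rlam.j,):
        raise InputError(
            f"z vector length {ztilde.shape[0]} does not match LD dimension {Rlam.j}"
        )
    omega = _precision(Rlam)
    ojj = np.diag(omega)
    oz = omega @ ztilde
    expected = ztilde - oz / ojj
    cond_var = 1.0 / ojj
    return expected, cond_var


def z_discordance(ztilde: np.ndarray, Rlam: LDMatrix) -> np.ndarray:
    """Standardized discordance t_j = (z_j - expected_z_j) / sqrt(cond_var_j).

    Approximately standard normal for each SNP when the z-scores are
    consistent with the LD matrix; the largest |t_j| are the top
    candidates for data problems.
    """
    expected, cond_var = conditional_z(ztilde, Rlam)
    return (np.asarray(ztilde, dtype=float) - expected) / np.sqrt(cond_var)


def allele_flip_lr(ztilde: np.ndarray, Rlam: LDMatrix) -> np.ndarray:
    """Likelihood ratio for a flipped allele encoding at each SNP.

    LR_j = exp(-2 z_j expected_z_j Omega_jj); values above 1 favor the
    sign-flipped model.  Uninformative (LR = 1) when the conditional mean
    is zero.
    """
    ztilde = np.asarray(ztilde, dtype=float)
    expected, cond_var = conditional_z(ztilde, Rlam)
    log_lr = -2.0 * ztilde * expected / cond_var
    return np.exp(log_lr)


def diagnostic_table(
    ztilde: np.ndarray,
    Rlam: LDMatrix,
    z_threshold: float = 2.0,
    snp_ids: Optional[list] = None,
) -> Tuple[DiagnosticReport, pd.DataFrame]:
    """Full per-SNP report plus a ranked candidate table.

    SNPs are ranked by |t_j| descending; among SNPs with |z| above
    ``z_threshold``, those with LR > 1 are marked as allele-flip
    candidates.  The table carries observed and expected z-scores, ready
    for an observed-vs-expected scatter plot.
    """
    ztilde = np.asarray(ztilde, dtype=float)
    expected, cond_var = conditional_z(ztilde, Rlam)
    t = (ztilde - expected) / np.sqrt(cond_var)
    lr = np.exp(-2.0 * ztilde * expected / cond_var)
    report = DiagnosticReport(
        expected_z=expected, cond_var=cond_var, t_stat=t,
        flip_lr=lr, lam_used=Rlam.lam,
    )
    j = ztilde.shape[0]
    ids = snp_ids if snp_ids is not None else [f"snp{i + 1}" for i in range(j)]
    table = pd.DataFrame({
        "snp": ids,
        "z": ztilde,
        "expected_z": expected,
        "cond_var": cond_var,
        "t": t,
        "flip_lr": lr,
        "candidate": (np.abs(ztilde) > z_threshold) & (lr > 1.0),
    })
    table = table.reindex(
        np.argsort(-np.abs(t), kind="stable")
    ).reset_index(drop=True)
    return report, table
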