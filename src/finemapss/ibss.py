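"""IBSS-ss: coordinate ascent for the sum of single effects model from
sufficient statistics.

The model is y = X(b_1 + ... + b_L) + e with each b_l a single-effect
vector (exactly one nonzero entry) and e ~ N(0, sigma^2 I).  The fitting
algorithm iterates over effects l = 1..L, at each step computing the
residual inner products X'r_l = X'y - X'X bbar_{-l} from the sufficient
statistics alone (never touching X), and refitting effect l by the
closed-form SER update.  It maximizes the evidence lower bound (ELBO)

    ELBO = E_q[log p(y | b, sigma^2)] - sum_l KL(q_l || prior_l),

whose expected log-likelihood term is a quadratic in the posterior
moments and the sufficient statistics.  Per-iteration cost is O(J^2 L),
independent of sample size.

Residual-variance policy follows the data regime: with exact sufficient
statistics (individual data or in-sample LD) sigma^2 is estimated each
sweep by the expected residual sum of squares; with an approximate LD
matrix from a reference panel sigma^2 is held fixed at y'y/N, which is 1
when phenotypes are standardized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional

import numpy as np

from ._exceptions import InputError, NumericalError
from .ser import estimate_prior_variance, fit_ser, ser_lbf_model
from .sufficient import SufficientStats

logger = logging.getLogger(__name__)

__all__ = [
    "SusieFit",
    "fit_susie_ss",
    "fit_susie_rss",
    "elbo",
    "estimate_sigma2",
    "compute_pips",
]


@dataclass
class SusieFit:
    """State and results of a sum of single effects fit."""

    alpha: np.ndarray            # (L, J) posterior assignment probabilities
    mu1: np.ndarray              # (L, J) conditional posterior means
    mu2: np.ndarray              # (L, J) conditional posterior second moments
    prior_vars: np.ndarray       # (L,) prior effect variances sigma0_l^2
    sigma2: float                # residual variance (fixed or estimated)
    elbo_trace: List[float] = field(default_factory=list)
    niter: int = 0
    converged: bool = False
    pip: Optional[np.ndarray] = None
    lbf_per_effect: Optional[np.ndarray] = None
    prior_weights: Optional[np.ndarray] = None

    @property
    def L(self) -> int:
        return self.alpha.shape[0]

    @property
    def j(self) -> int:
        return self.alpha.shape[1]

    def posterior_mean_b(self) -> np.ndarray:
        """Posterior mean of the combined coefficient vector b."""
        return (self.alpha * self.mu1).sum(axis=0)

    def copy(self) -> "SusieFit":
        return SusieFit(
            alpha=self.alpha.copy(), mu1=self.mu1.copy(), mu2=self.mu2.copy(),
            prior_vars=self.prior_vars.copy(), sigma2=self.sigma2,
            elbo_trace=list(self.elbo_trace), niter=self.niter,
            converged=self.converged,
            pip=None if self.pip is None else self.pip.copy(),
            lbf_per_effect=(None if self.lbf_per_effect is None
                            else self.lbf_per_effect.copy()),
            prior_weights=(None if self.prior_weights is None
                           else self.prior_weights.copy()),
        )


def _expected_rss(state: SusieFit, ss: SufficientStats) -> float:
    """Posterior-expected residual sum of squares E||y - Xb||^2.

    With b = sum_l b_l and independent SER posteriors q_l,
        E||y - Xb||^2 = y'y - 2 B'X'y + B'X'X B
                        - sum_l bbar_l'X'X bbar_l + sum_l sum_j a_lj m2_lj d_j
    where bbar_l = alpha_l * mu1_l and B = sum_l bbar_l.
    """
    bbar = state.alpha * state.mu1            # (L, J)
    B = bbar.sum(axis=0)
    XtXB = ss.XtX @ B
    err = ss.yty - 2.0 * B @ ss.Xty + B @ XtXB
    # replace the squared-mean cross terms within each effect by second moments
    err -= np.einsum("lj,jk,lk->", bbar, ss.XtX, bbar)
    err += float(((state.alpha * state.mu2) @ ss.d).sum())
    return float(err)


def _kl_effect(
    alpha: np.ndarray,
    mu1: np.ndarray,
    mu2: np.ndarray,
    prior_var: float,
    prior_weights: np.ndarray,
    d: np.ndarray,
) -> float:
    """KL divergence of one SER posterior from its prior, in closed form.

    The posterior factors as a categorical over the assigned SNP times a
    normal conditional; the KL splits accordingly.  SNPs with d_j = 0 have
    a conditional equal to the prior slab (no data), contributing only the
    categorical term.  A pruned effect (prior_var = 0, alpha = prior) has
    KL exactly 0.
    """
    mask = alpha > 0
    kl = float(np.sum(alpha[mask] * (np.log(alpha[mask])
                                     - np.log(prior_weights[mask]))))
    if prior_var > 0:
        ok = mask & (d > 0)
        if ok.any():
            var = np.maximum(mu2[ok] - mu1[ok] ** 2, 1e-300)
            kl += float(np.sum(
                alpha[ok] * 0.5 * (mu2[ok] / prior_var - 1.0
                                   + np.log(prior_var) - np.log(var))
            ))
    return kl


def elbo(state: SusieFit, ss: SufficientStats) -> float:
    """Evidence lower bound of the fit at its current variational posterior.

    Expected Gaussian log-likelihood (a quadratic form in the sufficient
    statistics and posterior moments) minus the sum of per-effect KL
    divergences.  Matches the per-sweep trace stored during fitting.
    """
    if state.j != ss.j:
        raise InputError("fit and sufficient statistics have different J")
    sigma2 = state.sigma2
    eloglik = (
        -0.5 * ss.n * np.log(2.0 * np.pi * sigma2)
        - 0.5 * _expected_rss(state, ss) / sigma2
    )
    pw = state.prior_weights
    if pw is None:
        pw = np.full(state.j, 1.0 / state.j)
    kl = sum(
        _kl_effect(state.alpha[l], state.mu1[l], state.mu2[l],
                   state.prior_vars[l], pw, ss.d)
        for l in range(state.L)
    )
    return float(eloglik - kl)


def estimate_sigma2(state: SusieFit, ss: SufficientStats) -> float:
    """Residual-variance update: expected residual sum of squares over N.

    With inconsistent approximate X'X the expected RSS can go non-positive;
    it is then clamped to a small positive floor with a warning, since a
    non-positive variance would invalidate subsequent SER updates.
    """
    erss = _expected_rss(state, ss)
    floor = 1e-8 * ss.yty / ss.n if ss.yty > 0 else 1e-8
    if erss <= 0:
        logger.warning(
            "expected residual sum of squares is non-positive (%.3g); "
            "clamping residual variance to %.3g — the summary data may be "
            "inconsistent with the LD matrix", erss, floor
        )
        return floor
    return max(erss / ss.n, floor)


def compute_pips(
    alpha: np.ndarray,
    prior_vars: Optional[np.ndarray] = None,
    prune_null_effects: bool = True,
) -> np.ndarray:
    """Posterior inclusion probabilities PIP_j = 1 - prod_l (1 - alpha_lj).

    Effects whose fitted prior variance is zero carry no signal — their
    alpha rows are prior noise — and are excluded from the product when
    ``prune_null_effects`` is set (requires ``prior_vars``).
    """
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    keep = np.ones(alpha.shape[0], dtype=bool)
    if prune_null_effects and prior_vars is not None:
        keep = np.asarray(prior_vars) > 0
    if not keep.any():
        return np.zeros(alpha.shape[1])
    return 1.0 - np.prod(1.0 - alpha[keep], axis=0)


def fit_susie_ss(
    ss: SufficientStats,
    L: int = 10,
    fix_sigma2: bool = False,
    sigma2_init: Optional[float] = None,
    max_iter: int = 100,
    tol: float = 1e-3,
    prior_weights: Optional[np.ndarray] = None,
    estimate_prior_variance_flag: bool = True,
    init: Optional[SusieFit] = None,
) -> SusieFit:
    """Fit the sum of single effects model from sufficient statistics.

    Parameters
    ----------
    ss : sufficient statistics (X'X, X'y, y'y, N).
    L : maximum number of single effects (1 <= L <= J).
    fix_sigma2 : hold the residual variance at y'y/N (or ``sigma2_init``)
        throughout; the recommended setting when X'X is approximated from
        a reference-panel LD matrix.
    sigma2_init : starting (or fixed) residual variance; default y'y/N.
    max_iter, tol : stop when the ELBO increases by less than ``tol``
        between sweeps, or after ``max_iter`` sweeps.
    prior_weights : prior assignment probabilities shared by all effects;
        uniform by default.  Zero entries exclude SNPs (used by the
        refinement procedure).
    estimate_prior_variance_flag : re-estimate each effect's prior
        variance by empirical Bayes at every update; effects pruned to
        sigma0^2 = 0 stay inactive but are revisited each sweep.
    init : warm start from an existing fit (alpha, mu, prior variances).

    Returns a :class:`SusieFit` with a non-decreasing ELBO trace and PIPs.
    """
    j = ss.j
    if L < 1:
        raise InputError(f"L must be >= 1, got {L}")
    L = min(L, j)
    if tol <= 0:
        raise InputError(f"tol must be positive, got {tol}")
    if prior_weights is None:
        pw = np.full(j, 1.0 / j)
    else:
        pw = np.asarray(prior_weights, dtype=float)
        if pw.shape != (j,):
            raise InputError("prior_weights length must equal J")
        if pw.sum() <= 0:
            raise InputError("prior_weights must have positive mass")
        pw = pw / pw.sum()

    sigma2 = float(sigma2_init) if sigma2_init is not None else ss.yty / ss.n
    if sigma2 <= 0:
        sigma2 = 1e-8 if ss.yty == 0 else ss.yty / ss.n
    v0_default = 0.2 * ss.yty / ss.n  # starting prior variance before EB refit
    v_bounds = (1e-10 * max(ss.yty / ss.n, 1e-8), 1e3 * max(ss.yty / ss.n, 1e-8))

    if init is not None:
        if init.alpha.shape[1] != j:
            raise InputError("warm-start fit has wrong dimension J")
        state = init.copy()
        if state.L < L:  # pad with empty effects
            pad = L - state.L
            state.alpha = np.vstack([state.alpha, np.full((pad, j), 1.0 / j)])
            state.mu1 = np.vstack([state.mu1, np.zeros((pad, j))])
            state.mu2 = np.vstack([state.mu2, np.zeros((pad, j))])
            state.prior_vars = np.concatenate([state.prior_vars, np.zeros(pad)])
        state.sigma2 = sigma2
    else:
        state = SusieFit(
            alpha=np.full((L, j), 1.0 / j),
            mu1=np.zeros((L, j)),
            mu2=np.zeros((L, j)),
            prior_vars=np.full(L, v0_default),
            sigma2=sigma2,
        )
    state.prior_weights = pw
    state.elbo_trace = []
    state.converged = False
    L = state.L

    lbf_per_effect = np.zeros(L)
    bbar = state.alpha * state.mu1
    XtXB = ss.XtX @ bbar.sum(axis=0)

    for it in range(max_iter):
        for l in range(L):
            XtXB -= ss.XtX @ bbar[l]
            xtr = ss.Xty - XtXB
            if estimate_prior_variance_flag:
                v0 = estimate_prior_variance(
                    xtr, ss.d, state.sigma2, pw, bounds=v_bounds
                )
                # keep the previous prior variance if the 1-d search missed
                # a better value there (protects ELBO monotonicity)
                v_prev = state.prior_vars[l]
                if v_prev > 0 and v_prev != v0:
                    if (ser_lbf_model(xtr, ss.d, state.sigma2, v_prev, pw)
                            > ser_lbf_model(xtr, ss.d, state.sigma2, v0, pw)):
                        v0 = v_prev
            else:
                v0 = state.prior_vars[l] if state.prior_vars[l] > 0 else v0_default
            res = fit_ser(xtr, ss.d, state.sigma2, v0, pw)
            state.alpha[l] = res.alpha
            state.mu1[l] = res.mu1
            state.mu2[l] = res.mu2
            state.prior_vars[l] = res.prior_var
            lbf_per_effect[l] = res.lbf_model
            bbar[l] = res.alpha * res.mu1
            XtXB += ss.XtX @ bbar[l]
        if not fix_sigma2:
            state.sigma2 = estimate_sigma2(state, ss)
        current = elbo(state, ss)
        if not np.isfinite(current):
            raise NumericalError(
                f"non-finite ELBO at iteration {it + 1}: {current}"
            )
        state.elbo_trace.append(current)
        state.niter = it + 1
        if it > 0 and current - state.elbo_trace[-2] < tol:
            state.converged = True
            break

    state.lbf_per_effect = lbf_per_effect
    state.pip = compute_pips(state.alpha, state.prior_vars)
    return state


def fit_susie_rss(
    z: np.ndarray,
    R,
    n: Optional[int] = None,
    mode: str = "summary",
    L: int = 10,
    max_iter: int = 100,
    tol: float = 1e-3,
    prior_weights: Optional[np.ndarray] = None,
    estimate_prior_variance_flag: bool = True,
):
    """Fit the model from z-scores and an LD matrix.

    ``mode`` selects the residual-variance policy by data regime:
    ``"sufficient"`` means R is the in-sample LD matrix, so the implied
    statistics are exact and sigma^2 is estimated; ``"summary"`` means R
    comes from a reference panel, so sigma^2 is fixed at y'y/N (1 on the
    standardized scale).  The z-scores are PVE-adjusted when the sample
    size is known; without ``n`` the unadjusted z-scores are used (with a
    warning) and the fit runs on the noncentrality-parameter scale, where
    posteriors are invariant to the notional sample size.

    Returns ``(fit, ss)`` so downstream credible-set and ELBO work can
    reuse the implied sufficient statistics.
    """
    from .sufficient import LDMatrix, pve_adjusted_z, suff_from_standardized_summary

    if mode not in ("sufficient", "summary"):
        raise InputError(f"mode must be 'sufficient' or 'summary', got {mode!r}")
    if not isinstance(R, LDMatrix):
        R = LDMatrix(R=np.asarray(R, dtype=float), source=(
            "in_sample" if mode == "sufficient" else "reference_panel"))
    ztilde = pve_adjusted_z(np.asarray(z, dtype=float), n)
    n_eff = n if n is not None else 2
    ss = suff_from_standardized_summary(ztilde, R, n_eff)
    fit = fit_susie_ss(
        ss,
        L=L,
        fix_sigma2=(mode == "summary"),
        max_iter=max_iter,
        tol=tol,
        prior_weights=prior_weights,
        estimate_prior_variance_flag=estimate_prior_variance_flag,
    )
    return fit, ss
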