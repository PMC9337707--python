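"""Single effect regression (SER): the L = 1 building block.

The SER model assumes exactly one of J SNPs has a nonzero effect b ~
N(0, sigma0^2), with a categorical prior over which SNP carries it.  Its
posterior is available in closed form from per-SNP least-squares
quantities: given a residual-target inner product xtr_j = x_j'r and
d_j = x_j'x_j, the least-squares estimate is bhat_j = xtr_j / d_j with
sampling variance s_j^2 = sigma^2 / d_j, and the per-SNP log Bayes factor
is the normal-means ratio

    lbf_j = log N(bhat_j; 0, sigma0^2 + s_j^2) - log N(bhat_j; 0, s_j^2).

Posterior assignment probabilities are alpha_j proportional to
prior_weights_j * exp(lbf_j) (computed by max-shifted exponentials), and
the conditional posterior of the effect given assignment to SNP j is
normal with variance 1/(1/sigma0^2 + d_j/sigma^2).

The prior variance sigma0^2 can be estimated by empirical Bayes:
maximizing the SER marginal likelihood (equivalently the model log Bayes
factor) over sigma0^2, with an explicit boundary check at zero so that
effects with no support are pruned.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from ._exceptions import InputError

__all__ = ["SerResult", "fit_ser", "estimate_prior_variance", "ser_lbf_model"]


@dataclass
class SerResult:
    """Posterior summary of a fitted single effect regression."""

    alpha: np.ndarray       # posterior assignment probabilities, sums to 1
    mu1: np.ndarray         # conditional posterior mean of the effect
    mu2: np.ndarray         # conditional posterior second moment
    lbf: np.ndarray         # per-SNP log Bayes factors
    lbf_model: float        # log Bayes factor of the whole SER
    prior_var: float        # sigma0^2 used (possibly fitted)


def _check_inputs(
    xtr: np.ndarray, d: np.ndarray, sigma2: float, prior_weights: Optional[np.ndarray]
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    xtr = np.asarray(xtr, dtype=float)
    d = np.asarray(d, dtype=float)
    if xtr.shape != d.shape or xtr.ndim != 1:
        raise InputError(
            f"xtr and d must be 1-d vectors of equal length, "
            f"got {xtr.shape} and {d.shape}"
        )
    if np.any(d < 0):
        raise InputError("diag(X'X) entries must be non-negative")
    if not sigma2 > 0:
        raise InputError(f"residual variance must be positive, got {sigma2}")
    j = xtr.shape[0]
    if prior_weights is None:
        prior_weights = np.full(j, 1.0 / j)
    else:
        prior_weights = np.asarray(prior_weights, dtype=float)
        if prior_weights.shape != (j,):
            raise InputError("prior_weights length does not match xtr")
        if np.any(prior_weights < 0):
            raise InputError("prior_weights must be non-negative")
        total = prior_weights.sum()
        if not total > 0:
            raise InputError("prior_weights must not sum to zero")
        prior_weights = prior_weights / total
    return xtr, d, prior_weights


def _log_prior(pw: np.ndarray) -> np.ndarray:
    """log prior weights with zeros mapped to -inf (excluded SNPs)."""
    out = np.full_like(pw, -np.inf)
    pos = pw > 0
    out[pos] = np.log(pw[pos])
    return out


def _log_bf(xtr: np.ndarray, d: np.ndarray, sigma2: float, v0: float) -> np.ndarray:
    """Per-SNP log Bayes factors; zero where d_j = 0 (no data on SNP j)."""
    lbf = np.zeros_like(xtr)
    ok = d > 0
    if v0 > 0 and ok.any():
        s2 = sigma2 / d[ok]
        bhat = xtr[ok] / d[ok]
        # log N(bhat; 0, v0+s2) - log N(bhat; 0, s2)
        lbf[ok] = 0.5 * np.log(s2 / (v0 + s2)) + 0.5 * bhat**2 * v0 / (s2 * (v0 + s2))
    return lbf


def ser_lbf_model(
    xtr: np.ndarray,
    d: np.ndarray,
    sigma2: float,
    prior_var: float,
    prior_weights: Optional[np.ndarray] = None,
) -> float:
    """Model log Bayes factor of the SER at a given prior variance.

    This is the log marginal likelihood of the SER relative to the null
    (all effects zero); it is exactly 0 at prior_var = 0.
    """
    xtr, d, pw = _check_inputs(xtr, d, sigma2, prior_weights)
    lbf = _log_bf(xtr, d, sigma2, prior_var)
    logw = _log_prior(pw) + lbf
    return float(logsumexp(logw))


def fit_ser(
    xtr: np.ndarray,
    d: np.ndarray,
    sigma2: float,
    prior_var: float,
    prior_weights: Optional[np.ndarray] = None,
) -> SerResult:
    """Closed-form SER posterior for a fixed prior effect variance.

    Parameters
    ----------
    xtr : inner products x_j'r of each SNP with the residual target.
    d : diag(X'X).
    sigma2 : residual variance (> 0).
    prior_var : prior variance sigma0^2 of the single effect (>= 0).
    prior_weights : prior assignment probabilities; uniform by default.

    SNPs with d_j = 0 receive a unit Bayes factor and zero posterior
    moments, so they participate in the normalization only through the
    prior.  The posterior depends on the data only through (xtr_j, d_j) —
    never on off-diagonal LD.
    """
    xtr, d, pw = _check_inputs(xtr, d, sigma2, prior_weights)
    if prior_var < 0:
        raise InputError(f"prior variance must be non-negative, got {prior_var}")
    lbf = _log_bf(xtr, d, sigma2, prior_var)
    logw = _log_prior(pw) + lbf
    lbf_model = float(logsumexp(logw))
    shifted = logw - logw.max() if np.isfinite(logw.max()) else logw
    w = np.exp(shifted)
    alpha = w / w.sum()

    mu1 = np.zeros_like(xtr)
    mu2 = np.zeros_like(xtr)
    ok = d > 0
    if prior_var > 0 and ok.any():
        post_var = 1.0 / (1.0 / prior_var + d[ok] / sigma2)
        mu1[ok] = post_var * xtr[ok] / sigma2
        mu2[ok] = post_var + mu1[ok] ** 2
    return SerResult(
        alpha=alpha, mu1=mu1, mu2=mu2, lbf=lbf,
        lbf_model=lbf_model, prior_var=float(prior_var),
    )


def estimate_prior_variance(
    xtr: np.ndarray,
    d: np.ndarray,
    sigma2: float,
    prior_weights: Optional[np.ndarray] = None,
    method: str = "optimize",
    bounds: Optional[Tuple[float, float]] = None,
) -> float:
    """Empirical-Bayes estimate of the SER prior variance sigma0^2.

    Maximizes the SER model log Bayes factor over log(sigma0^2) within
    ``bounds`` (a bounded 1-d scalar search), then compares against the
    boundary sigma0^2 = 0 (lbf_model = 0): if the interior optimum does
    not beat the boundary, returns 0 and the effect is pruned.

    ``method="em"`` is accepted for interface compatibility but resolves
    to the same bounded optimization.
    """
    xtr, d, pw = _check_inputs(xtr, d, sigma2, prior_weights)
    if method not in ("optimize", "em"):
        raise InputError(f"unknown method {method!r}")
    if bounds is None:
        # scale-free default wide enough for standardized and raw data
        scale = max(float(np.max(np.abs(xtr / np.maximum(d, 1e-300)))) ** 2, 1.0)
        bounds = (1e-10, 1e3 * scale)
    lo, hi = bounds
    if not (0 < lo < hi):
        raise InputError(f"invalid bounds {bounds}")

    def neg_llik(log_v: float) -> float:
        lbf = _log_bf(xtr, d, sigma2, np.exp(log_v))
        logw = _log_prior(pw) + lbf
        return -float(logsumexp(logw))

    res = minimize_scalar(
        neg_llik, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-10},
    )
    v_hat = float(np.exp(res.x))
    # lbf_model at sigma0^2 = 0 is exactly log sum_j pw_j = 0
    if -res.fun <= 0.0:
        return 0.0
    return v_hat
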