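"""Independent reference implementations used only for cross-checking.

These deliberately take the individual-level-data route (explicit residual
vectors, per-SNP density arithmetic, dense linear solves) so that they
share no code path with the package's sufficient-statistic implementation.
"""

from __future__ import annotations

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import norm


def ser_alpha_bruteforce(xtr, d, sigma2, v0, pw=None):
    """SER assignment probabilities by direct per-assignment density arithmetic."""
    xtr = np.asarray(xtr, float)
    d = np.asarray(d, float)
    J = xtr.shape[0]
    pw = np.full(J, 1.0 / J) if pw is None else np.asarray(pw, float)
    log_bf = np.zeros(J)
    for j in range(J):
        if d[j] > 0 and v0 > 0:
            bhat = xtr[j] / d[j]
            s2 = sigma2 / d[j]
            log_bf[j] = (norm.logpdf(bhat, 0.0, np.sqrt(v0 + s2))
                         - norm.logpdf(bhat, 0.0, np.sqrt(s2)))
    w = pw * np.exp(log_bf - log_bf.max())
    return w / w.sum()


def standardize(X, y):
    """Center and scale to unit variance with denominator N."""
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    Xc = X - X.mean(axis=0)
    Xc = Xc / np.sqrt((Xc**2).mean(axis=0))
    yc = y - y.mean()
    yc = yc / np.sqrt((yc**2).mean())
    return Xc, yc


def ibss_individual(X, y, L=10, n_sweeps=60, estimate_sigma2=True):
    """Coordinate-ascent fit of the sum of single effects model from
    individual-level data, maintaining explicit N-vector residuals.

    Returns dict with alpha (L,J), mu (L,J), prior variances V (L,) and
    sigma2.  X and y are used as given (center/standardize beforehand).
    """
    X = np.asarray(X, float)
    y = np.asarray(y, float).ravel()
    n, J = X.shape
    d = (X**2).sum(axis=0)
    yty = float(y @ y)
    sigma2 = yty / n
    alpha = np.full((L, J), 1.0 / J)
    mu = np.zeros((L, J))
    mu2 = np.zeros((L, J))
    V = np.zeros(L)
    Bl = np.zeros((L, J))                      # per-effect posterior means
    vb = (1e-10 * yty / n, 1e3 * yty / n)

    def _log_bf_vec(xtr, v0, s2_scalar):
        s2 = s2_scalar / d
        bhat = xtr / d
        return (norm.logpdf(bhat, 0.0, np.sqrt(v0 + s2))
                - norm.logpdf(bhat, 0.0, np.sqrt(s2)))

    r_full = y - X @ Bl.sum(axis=0)
    for _ in range(n_sweeps):
        for l in range(L):
            r = r_full + X @ Bl[l]             # residual excluding effect l
            xtr = X.T @ r

            def neg(log_v):
                lb = _log_bf_vec(xtr, np.exp(log_v), sigma2)
                m = lb.max()
                return -(m + np.log(np.mean(np.exp(lb - m))))

            res = minimize_scalar(
                neg, bounds=(np.log(vb[0]), np.log(vb[1])),
                method="bounded", options={"xatol": 1e-10},
            )
            v0 = float(np.exp(res.x))
            if -res.fun <= 0.0:
                v0 = 0.0
            if v0 > 0:
                lb = _log_bf_vec(xtr, v0, sigma2)
                w = np.exp(lb - lb.max())
                a = w / w.sum()
                pv = 1.0 / (1.0 / v0 + d / sigma2)
                m1 = pv * xtr / sigma2
                m2 = pv + m1**2
            else:
                a = np.full(J, 1.0 / J)
                m1 = np.zeros(J)
                m2 = np.zeros(J)
            alpha[l], mu[l], mu2[l], V[l] = a, m1, m2, v0
            Bl[l] = a * m1
            r_full = r - X @ Bl[l]
        if estimate_sigma2:
            fitted = X @ Bl.sum(axis=0)
            rr = y - fitted
            erss = float(rr @ rr)
            for l in range(L):
                g = X @ Bl[l]
                erss += float((alpha[l] * mu2[l]) @ d) - float(g @ g)
            sigma2 = erss / n
    pip = 1.0 - np.prod(1.0 - alpha[V > 0], axis=0) if (V > 0).any() \
        else np.zeros(J)
    return {"alpha": alpha, "mu": mu, "V": V, "sigma2": sigma2, "pip": pip}


def conditional_z_deleteone(z, R):
    """Delete-one multivariate-normal conditionals via explicit solves."""
    z = np.asarray(z, float)
    R = np.asarray(R, float)
    J = z.shape[0]
    mean = np.zeros(J)
    var = np.zeros(J)
    for j in range(J):
        keep = [k for k in range(J) if k != j]
        Rjj = R[np.ix_(keep, keep)]
        rj = R[j, keep]
        sol = np.linalg.solve(Rjj, z[keep])
        mean[j] = rj @ sol
        var[j] = R[j, j] - rj @ np.linalg.solve(Rjj, rj)
    return mean, var


def lambda_grid_search(z, R0, n_grid=1001):
    """Maximize the null z-score log-density over a lambda grid.

    Evaluates the dense multivariate-normal log-density by solve/slogdet
    at each feasible grid point.
    """
    z = np.asarray(z, float)
    R0 = np.asarray(R0, float)
    J = z.shape[0]
    grid = np.linspace(0.0, 1.0, n_grid)
    best_lam, best_ll = None, -np.inf
    for lam in grid:
        S = (1.0 - lam) * R0 + lam * np.eye(J)
        sign, logdet = np.linalg.slogdet(S)
        if sign <= 0:
            continue
        try:
            quad = z @ np.linalg.solve(S, z)
        except np.linalg.LinAlgError:
            continue
        ll = -0.5 * (logdet + quad)
        if ll > best_ll + 1e-12:
            best_ll, best_lam = ll, lam
    return best_lam
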