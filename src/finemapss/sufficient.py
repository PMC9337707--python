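"""Sufficient statistics for the multiple-regression likelihood.

The Gaussian multiple-regression likelihood for y = Xb + e depends on the
data only through the quadruple (X'X, X'y, y'y, N).  This module builds
that quadruple from individual-level data, from standardized z-scores plus
an LD matrix, or from marginal effect estimates and standard errors, and
defines the PVE-adjusted z-scores that make the z-score route exact under
standardization.

Conventions
-----------
All centering and standardization uses denominator N (population-style
sample variance), so a standardized column x satisfies x'x = N exactly.
The marginal statistics for SNP j from a simple regression of y on x_j are

    bhat_j = x_j'y / x_j'x_j
    shat_j = sqrt( (y - x_j bhat_j)'(y - x_j bhat_j) / (N x_j'x_j) )

and z_j = bhat_j / shat_j.  The PVE-adjusted z-score is

    ztilde_j = z_j * sqrt(N / (N + z_j^2)),

which satisfies X'y = sqrt(N) ztilde when X and y are standardized.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from ._exceptions import InputError, ValidationError

logger = logging.getLogger(__name__)

_Z_CONSISTENCY_RTOL = 1e-6


@dataclass
class SummaryData:
    """Per-SNP marginal association statistics from single-SNP regressions.

    At least one of (``bhat`` and ``shat``) or ``zhat`` must be supplied;
    when both are given they must agree (z = bhat/shat elementwise).
    Allele labels are carried through untouched: harmonization mistakes are
    exactly what the diagnostics module is designed to detect.
    """

    snp_ids: Sequence[str]
    bhat: Optional[np.ndarray] = None
    shat: Optional[np.ndarray] = None
    zhat: Optional[np.ndarray] = None
    n: Optional[int] = None
    var_y: Optional[float] = None
    ref_allele: Optional[Sequence[str]] = None
    alt_allele: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        j = len(self.snp_ids)
        for name in ("bhat", "shat", "zhat"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=float)
                if v.ndim != 1 or v.shape[0] != j:
                    raise InputError(
                        f"{name} must be a length-{j} vector matching snp_ids, "
                        f"got shape {v.shape}"
                    )
                setattr(self, name, v)
        has_effects = self.bhat is not None and self.shat is not None
        if not has_effects and self.zhat is None:
            raise InputError(
                "summary data must provide either (bhat and shat) or zhat"
            )
        if self.shat is not None:
            bad = np.flatnonzero(~(self.shat > 0))
            if bad.size:
                raise ValidationError(
                    f"non-positive standard error for SNP "
                    f"{self.snp_ids[bad[0]]!r} (shat={self.shat[bad[0]]})"
                )
        if has_effects and self.zhat is not None:
            implied = self.bhat / self.shat
            if not np.allclose(self.zhat, implied, rtol=_Z_CONSISTENCY_RTOL,
                               atol=1e-8):
                raise ValidationError(
                    "zhat is inconsistent with bhat/shat"
                )
        if self.n is not None and self.n < 1:
            raise InputError(f"sample size must be >= 1, got {self.n}")
        for name in ("ref_allele", "alt_allele"):
            v = getattr(self, name)
            if v is not None and len(v) != j:
                raise InputError(f"{name} length {len(v)} != {j} SNPs")

    @property
    def j(self) -> int:
        return len(self.snp_ids)

    def zscores(self) -> np.ndarray:
        """z-scores, from zhat if present, otherwise bhat/shat."""
        if self.zhat is not None:
            return np.asarray(self.zhat, dtype=float)
        return zscores_from_effects(self)


@dataclass
class SufficientStats:
    """The quadruple (X'X, X'y, y'y, N) determining the regression likelihood."""

    XtX: np.ndarray
    Xty: np.ndarray
    yty: float
    n: int

    def __post_init__(self) -> None:
        self.XtX = np.asarray(self.XtX, dtype=float)
        self.Xty = np.asarray(self.Xty, dtype=float)
        self.yty = float(self.yty)
        self.n = int(self.n)
        if self.XtX.ndim != 2 or self.XtX.shape[0] != self.XtX.shape[1]:
            raise InputError(f"XtX must be square, got shape {self.XtX.shape}")
        j = self.XtX.shape[0]
        if self.Xty.shape != (j,):
            raise InputError(
                f"Xty shape {self.Xty.shape} does not match XtX dimension {j}"
            )
        if not np.allclose(self.XtX, self.XtX.T, atol=1e-8):
            raise ValidationError("XtX is not symmetric")
        if np.any(np.diag(self.XtX) < -1e-12):
            raise ValidationError("XtX has a negative diagonal entry")
        if self.yty < 0:
            raise ValidationError(f"yty must be non-negative, got {self.yty}")
        if self.n < 1:
            raise InputError(f"sample size must be >= 1, got {self.n}")

    @property
    def j(self) -> int:
        return self.XtX.shape[0]

    @property
    def d(self) -> np.ndarray:
        """diag(X'X), clipped at zero for numerical safety."""
        return np.maximum(np.diag(self.XtX), 0.0)


@dataclass
class LDMatrix:
    """J x J SNP correlation matrix, optionally lambda-regularized toward I."""

    R: np.ndarray
    lam: float = 0.0
    source: str = "in_sample"

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, dtype=float)
        if self.R.ndim != 2 or self.R.shape[0] != self.R.shape[1]:
            raise InputError(f"LD matrix must be square, got shape {self.R.shape}")
        if not np.allclose(self.R, self.R.T, atol=1e-8):
            raise ValidationError("LD matrix is not symmetric")
        if not np.allclose(np.diag(self.R), 1.0, atol=1e-6):
            raise ValidationError("LD matrix diagonal entries must all equal 1")
        if np.any(np.abs(self.R) > 1.0 + 1e-8):
            raise ValidationError("LD matrix entries must lie in [-1, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise InputError(f"lambda must lie in [0, 1], got {self.lam}")
        if self.source not in ("in_sample", "reference_panel"):
            raise InputError(f"unknown LD source {self.source!r}")

    @property
    def j(self) -> int:
        return self.R.shape[0]


def zscores_from_effects(sd: SummaryData) -> np.ndarray:
    """Per-SNP z-scores z_j = bhat_j / shat_j."""
    if sd.bhat is None or sd.shat is None:
        raise InputError("zscores_from_effects requires both bhat and shat")
    return sd.bhat / sd.shat


def pve_adjusted_z(z: np.ndarray, n: Optional[int]) -> np.ndarray:
    """PVE-adjusted z-scores: ztilde_j = z_j * sqrt(n / (n + z_j^2)).

    The adjustment factor is one minus the per-SNP estimated proportion of
    variance explained; it shrinks each z-score toward zero, negligibly so
    when effects are small.  When ``n`` is None the unadjusted z-scores are
    returned with a warning — an acceptable approximation when the sample
    size is genuinely unknown and effects are small.
    """
    z = np.asarray(z, dtype=float)
    if n is None:
        logger.warning(
            "sample size unknown; using unadjusted z-scores in place of "
            "PVE-adjusted z-scores"
        )
        return z.copy()
    if n < 1:
        raise InputError(f"sample size must be >= 1, got {n}")
    return z * np.sqrt(n / (n + z**2))


def suff_from_individual(
    X: np.ndarray, y: np.ndarray, standardize: bool = False
) -> SufficientStats:
    """Sufficient statistics from an N x J genotype matrix and phenotype.

    Both y and the columns of X are centered (and scaled to unit variance,
    denominator N, when ``standardize`` is set) before forming the products.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.ndim != 2:
        raise InputError(f"X must be 2-dimensional, got shape {X.shape}")
    n = X.shape[0]
    if y.shape[0] != n:
        raise InputError(
            f"X has {n} rows but y has {y.shape[0]} entries"
        )
    if n < 2:
        raise InputError("at least 2 samples are required")
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if standardize:
        sx = np.sqrt((Xc**2).mean(axis=0))
        bad = np.flatnonzero(sx == 0)
        if bad.size:
            raise ValidationError(
                f"column {bad[0]} has zero variance and cannot be standardized"
            )
        Xc = Xc / sx
        sy = np.sqrt((yc**2).mean())
        if sy > 0:
            yc = yc / sy
    return SufficientStats(XtX=Xc.T @ Xc, Xty=Xc.T @ yc, yty=float(yc @ yc), n=n)


def suff_from_standardized_summary(
    ztilde: np.ndarray, R: LDMatrix, n: int
) -> SufficientStats:
    """Sufficient statistics implied by standardized X, y.

    Under standardization X'X = N R, X'y = sqrt(N) ztilde, y'y = N; these
    are identities (not approximations) when R is the in-sample LD matrix.
    """
    ztilde = np.asarray(ztilde, dtype=float)
    if ztilde.shape != (R.j,):
        raise InputError(
            f"z vector length {ztilde.shape} does not match LD dimension {R.j}"
        )
    if n < 1:
        raise InputError(f"sample size must be >= 1, got {n}")
    return SufficientStats(
        XtX=n * R.R, Xty=np.sqrt(n) * ztilde, yty=float(n), n=n
    )


def suff_from_effect_summary(
    sd: SummaryData,
    R: LDMatrix,
    n: Optional[int] = None,
    var_y: Optional[float] = None,
) -> SufficientStats:
    """Sufficient statistics reconstructed from marginal effects and SEs.

    The simple-regression identities give, per SNP,

        x_j'x_j = y'y / (n shat_j^2 + bhat_j^2),

    (since n shat_j^2 x_j'x_j = y'y - bhat_j^2 x_j'x_j), after which
    X'X = D^{1/2} R D^{1/2} with D = diag(x_j'x_j), X'y_j = x_j'x_j bhat_j,
    and y'y = n var_y.  var_y defaults to 1 when absent.
    """
    if sd.bhat is None or sd.shat is None:
        raise InputError("effect-summary route requires both bhat and shat")
    if n is None:
        n = sd.n
    if n is None:
        raise InputError("sample size is required to reconstruct X'X from bhat/shat")
    if n < 1:
        raise InputError(f"sample size must be >= 1, got {n}")
    if var_y is None:
        var_y = sd.var_y if sd.var_y is not None else 1.0
    if sd.j != R.j:
        raise InputError(
            f"summary data has {sd.j} SNPs but LD matrix has dimension {R.j}"
        )
    yty = n * float(var_y)
    xtx_j = yty / (n * sd.shat**2 + sd.bhat**2)
    bad = np.flatnonzero(~(xtx_j > 0))
    if bad.size:
        raise ValidationError(
            f"implied x'x is non-positive for SNP {sd.snp_ids[bad[0]]!r}"
        )
    sqrt_d = np.sqrt(xtx_j)
    XtX = sqrt_d[:, None] * R.R * sqrt_d[None, :]
    Xty = xtx_j * sd.bhat
    return SufficientStats(XtX=XtX, Xty=Xty, yty=yty, n=n)
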