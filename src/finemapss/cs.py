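"""Credible sets: level-rho sets of candidate causal SNPs per effect.

A level-rho credible set for effect l is the smallest set of SNPs, taken
in decreasing order of posterior assignment probability, whose cumulative
probability reaches rho.  Sets are scored by "purity" — the smallest
absolute pairwise LD correlation among their SNPs — and low-purity sets
(which typically contain many weakly-linked SNPs and carry little
localization information) are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np

from ._exceptions import InputError
from .ibss import SusieFit
from .sufficient import LDMatrix

__all__ = [
    "CredibleSet",
    "credible_set_for_effect",
    "purity",
    "collect_credible_sets",
]

_PURITY_SUBSAMPLE_SEED = 20230301


@dataclass
class CredibleSet:
    """One level-rho credible set, traced back to its source effect."""

    snp_indices: List[int]       # 0-based positions, in decreasing alpha order
    effect_index: int            # which single effect produced this set
    coverage_attained: float     # cumulative alpha mass, >= requested rho
    purity: float                # min |r| over pairs; 1.0 for singletons

    def __len__(self) -> int:
        return len(self.snp_indices)


def credible_set_for_effect(alpha_row: np.ndarray, rho: float = 0.95) -> List[int]:
    """Smallest set of SNPs whose cumulative alpha mass reaches rho.

    SNPs enter in decreasing alpha order; exact ties are broken by SNP
    index ascending, making the result deterministic.
    """
    alpha_row = np.asarray(alpha_row, dtype=float)
    if not 0 < rho <= 1:
        raise InputError(f"coverage level must be in (0, 1], got {rho}")
    # stable sort on negated values: equal alphas keep ascending index order
    order = np.argsort(-alpha_row, kind="stable")
    cum = np.cumsum(alpha_row[order])
    # number of SNPs needed; guard against rho > attainable total mass
    k = int(np.searchsorted(cum, rho - 1e-12)) + 1
    k = min(k, alpha_row.shape[0])
    return [int(i) for i in order[:k]]


def purity(
    indices: Sequence[int],
    R: LDMatrix,
    max_subsample: int = 100,
    seed: int = _PURITY_SUBSAMPLE_SEED,
) -> float:
    """Smallest absolute pairwise correlation among the SNPs in a set.

    Singletons have purity 1.  Sets larger than ``max_subsample`` are
    scored on a seeded random subsample of SNPs to avoid a quadratic pair
    count on very large sets.
    """
    idx = np.asarray(list(indices), dtype=int)
    if idx.size == 0:
        raise InputError("purity of an empty set is undefined")
    if np.any(idx < 0) or np.any(idx >= R.j):
        raise InputError("credible set indices outside LD matrix range")
    if idx.size == 1:
        return 1.0
    if idx.size > max_subsample:
        rng = np.random.default_rng(seed)
        idx = rng.choice(idx, size=max_subsample, replace=False)
    sub = np.abs(R.R[np.ix_(idx, idx)])
    off = sub[np.triu_indices_from(sub, k=1)]
    return float(off.min())


def collect_credible_sets(
    fit: SusieFit,
    R: LDMatrix,
    rho: float = 0.95,
    min_purity: float = 0.5,
    dedupe: bool = True,
    max_subsample: int = 100,
) -> List[CredibleSet]:
    """Credible sets from all non-null effects, purity-filtered.

    Effects pruned to zero prior variance carry no signal and produce no
    set.  Candidates with purity below ``min_purity`` are discarded.  When
    ``dedupe`` is set, identical index sets from different effects are
    collapsed, keeping the lowest effect index.  Output is sorted by
    effect index.
    """
    if fit.j != R.j:
        raise InputError(
            f"fit has {fit.j} SNPs but LD matrix has dimension {R.j}"
        )
    out: List[CredibleSet] = []
    seen: set = set()
    for l in range(fit.L):
        if fit.prior_vars[l] <= 0:
            continue
        members = credible_set_for_effect(fit.alpha[l], rho)
        key = frozenset(members)
        if dedupe and key in seen:
            continue
        pur = purity(members, R, max_subsample=max_subsample)
        if pur < min_purity:
            continue
        seen.add(key)
        out.append(CredibleSet(
            snp_indices=members,
            effect_index=l,
            coverage_attained=float(np.sum(fit.alpha[l][members])),
            purity=pur,
        ))
    return out
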