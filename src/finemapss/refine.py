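"""ELBO-guided refinement: escaping poor local optima of the coordinate
ascent fitter.

Coordinate ascent on the sum of single effects model occasionally stalls
in a local optimum, typically when two causal SNPs in moderate LD have
partially cancelling effects and a non-causal SNP carries the strongest
marginal association.  The refinement procedure attacks each credible set
in turn: refit from scratch with that set's SNPs excluded (zero prior
weight), forcing the model to find alternative explanations for the
association, then warm-start a full-SNP fit from the alternative
solution.  A candidate is accepted only if it strictly improves the ELBO,
so the returned fit is never worse than the input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cs import collect_credible_sets
from .ibss import SusieFit, elbo, fit_susie_ss
from .sufficient import LDMatrix, SufficientStats

__all__ = ["RefineOptions", "refine_fit"]


@dataclass
class RefineOptions:
    """Knobs for the refinement loop."""

    max_passes: int = 100      # full passes over the current credible sets
    tol: float = 1e-3          # improvement threshold shared with the fitter
    rho: float = 0.95
    min_purity: float = 0.5
    L: Optional[int] = None    # effects in the refits; default: same as fit
    max_iter: int = 100


def refine_fit(
    fit: SusieFit,
    ss: SufficientStats,
    R: LDMatrix,
    options: Optional[RefineOptions] = None,
    fix_sigma2: bool = False,
    sigma2_init: Optional[float] = None,
) -> SusieFit:
    """Try to improve a fitted model by credible-set-masked restarts.

    For each current credible set (ascending effect index): (1) refit from
    scratch with the set's SNPs given zero prior weight; (2) continue that
    solution with a warm-started full-SNP fit; (3) accept if the ELBO
    strictly improves by more than ``options.tol`` relative rounding slack.
    The whole pass repeats until no set yields an improvement or
    ``max_passes`` is reached.  The residual-variance policy
    (``fix_sigma2``, ``sigma2_init``) should match the one used for the
    original fit so ELBOs are comparable.
    """
    opts = options or RefineOptions()
    best = fit
    base_pw = fit.prior_weights
    if base_pw is None:
        base_pw = np.full(fit.j, 1.0 / fit.j)
    L = opts.L or fit.L

    for _ in range(opts.max_passes):
        best_elbo = elbo(best, ss)
        sets = collect_credible_sets(
            best, R, rho=opts.rho, min_purity=opts.min_purity
        )
        improved = False
        for cs_ in sets:
            masked_pw = base_pw.copy()
            masked_pw[cs_.snp_indices] = 0.0
            if masked_pw.sum() <= 0:
                continue
            masked = fit_susie_ss(
                ss, L=L, fix_sigma2=fix_sigma2, sigma2_init=sigma2_init,
                max_iter=opts.max_iter, tol=opts.tol,
                prior_weights=masked_pw,
            )
            candidate = fit_susie_ss(
                ss, L=L, fix_sigma2=fix_sigma2, sigma2_init=sigma2_init,
                max_iter=opts.max_iter, tol=opts.tol,
                prior_weights=base_pw, init=masked,
            )
            if elbo(candidate, ss) > best_elbo:
                best = candidate
                best_elbo = elbo(candidate, ss)
                improved = True
        if not improved:
            break
    return best
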