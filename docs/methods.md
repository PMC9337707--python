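# Methods

## Model

The trait follows the multiple linear regression `y = Xb + e` with
`e ~ N(0, σ²I_N)`, `y` and the columns of `X` centered (an intercept is
therefore unnecessary).  The coefficient vector is a sum of `L` single
effects, `b = Σ_{l=1}^{L} b_l`, where each `b_l` has exactly one nonzero
entry: SNP assignment is categorical with prior weights `π` (uniform by
default) and the effect size is `N(0, σ₀ₗ²)`.  `L` bounds the number of
causal variants the model may use; the fit is robust to overstating it
because unneeded effects are pruned to `σ₀ₗ² = 0` by empirical Bayes.
Evidence for SNP `j` is summarized by its posterior inclusion
probability `PIP_j = 1 − Π_l (1 − α_{lj})`, the product over non-pruned
effects of the per-effect assignment probabilities.

All computations use the sufficient statistics `(X'X, X'y, y'y, N)`,
which fully determine the likelihood.  They are built from

- individual-level data (centered, optionally standardized with
  denominator-N variances, so a standardized column satisfies x'x = N);
- standardized summary data: `X'X = N R`, `X'y = √N z̃`, `y'y = N`, with
  `z̃_j = ẑ_j √(N/(N+ẑ_j²))` the PVE-adjusted z-scores (exact identities
  when `R` is the in-sample LD matrix; the adjustment factor is one
  minus the per-SNP estimated fraction of variance explained, so
  `z̃ ≈ ẑ` when effects are small);
- marginal effects and standard errors: per-SNP `x_j'x_j` is recovered
  from `y'y / (N ŝ_j² + b̂_j²)` and combined with `R` via
  `X'X = D^{1/2} R D^{1/2}`.

When `N` is unknown, `ẑ` replaces `z̃` with a logged warning and fitting
proceeds on the noncentrality-parameter scale (a notional `N` of 2 with
`y'y = N`); posteriors in the fixed-σ² regime are invariant to that
choice because the per-SNP Bayes factors depend on `(z_j, N·σ₀²)` only.

## Fitting

Coordinate ascent over effects `l = 1..L`.  Each update forms the
residual inner products `X'r_l = X'y − X'X b̄_{−l}` (posterior means of
the other effects), re-estimates `σ₀ₗ²` by maximizing the single effect
regression (SER) marginal likelihood, and sets the SER posterior in
closed form from the per-SNP quantities `b̂_j = (X'r)_j / d_j`,
`s_j² = σ²/d_j` with `d = diag(X'X)`:

    lbf_j = log N(b̂_j; 0, σ₀² + s_j²) − log N(b̂_j; 0, s_j²)
    α_j ∝ π_j exp(lbf_j)        (max-shifted exponentials; safe to |lbf| ~ 1e4)

The conditional posterior given assignment to `j` is normal with
variance `1/(1/σ₀² + d_j/σ²)`.  Monomorphic SNPs (`d_j = 0`) get unit
Bayes factors and zero moments.  The SER posterior depends only on the
pairs `(X'r_j, d_j)` — never on off-diagonal LD — which is why the
`L = 1` fit is identical across LD matrices sharing a diagonal,
including non-invertible ones.

**Objective.**  The evidence lower bound is computed as the expected
Gaussian log-likelihood (a quadratic form in the sufficient statistics
and the posterior moments) minus per-effect KL divergences evaluated in
closed form from `(α, μ₁, μ₂, σ₀², π)`.  Because each update sets the
exact SER posterior and the prior-variance step maximizes the same
per-effect marginal likelihood, the trace is non-decreasing; a safeguard
keeps the previous `σ₀ₗ²` whenever the 1-d search fails to beat it.
Convergence is declared when the ELBO gains less than `tol` (default
1e-3) between sweeps; effects are updated in fixed order `1..L` each
sweep for determinism.

**Residual variance.**  Policy follows the data regime (an explicit
`mode` flag, never guessed).  With exact statistics, σ² is updated each
sweep to `ERSS/N`, the posterior-expected residual sum of squares over
N.  With an approximate reference-panel `R̂`, σ² is fixed at `y'y/N`
(1 standardized): estimating it against inconsistent statistics can be
badly behaved, and ERSS can even go non-positive — in that case σ² is
clamped to `1e-8·y'y/N` with a warning rather than aborting the fit.

**Prior variance.**  `σ₀ₗ²` is optimized on the log scale over
`[1e-10·y'y/N, 1e3·y'y/N]` by bounded scalar minimization, with an
explicit boundary comparison against `σ₀² = 0` (model log Bayes factor
exactly 0); effects at the boundary are inactive but re-examined every
sweep.

## Credible sets, purity, refinement

A level-ρ (default 0.95) credible set per non-pruned effect: SNPs in
decreasing α order until cumulative mass ≥ ρ, ties broken by ascending
index.  Purity is the smallest absolute pairwise correlation within the
set (singletons: 1; sets above 100 SNPs: a seeded subsample caps the
quadratic pair count).  Sets with purity < 0.5 are discarded — large
low-purity sets carry no localization information — and identical sets
from different effects are deduplicated keeping the lowest effect index.

Refinement attacks each current credible set in ascending effect order:
refit from scratch with the set's SNPs at zero prior weight (masking by
weights rather than subsetting preserves indexing), then continue with a
warm-started full-SNP fit; accept only on strict ELBO improvement, and
repeat passes until stationary (pass budget 100).  By construction the
returned objective is never worse than the input.  Results can depend on
the order sets are tried within a pass; ascending effect index is the
fixed convention.

## LD regularization and diagnostics

`R̂_λ = (1−λ)R̂₀ + λI` with λ chosen to maximize the zero-mean normal
log-density of `z̃`.  A single eigendecomposition `R̂₀ = U diag(e) U'`
turns the objective into `−½ Σ_i [log((1−λ)e_i + λ) + w_i²/((1−λ)e_i + λ)]`
with `w = U'z̃`, minimized by bounded 1-d search; the feasible range is
restricted so all shifted eigenvalues exceed 1e-10 (an indefinite
matrix has no density), and flat objectives return the smallest
maximizer.  λ near zero signals consistency between z-scores and LD.
Note the null-model assumption: strong true signals inflate λ somewhat
even with a good panel.

Diagnostics invert `R̂_λ` (after regularization when needed; a
numerically singular matrix raises an error directing the user to
regularize) and compute, per SNP, the conditional mean
`−Ω_{j,−j}z̃_{−j}/Ω_{jj}` and variance `1/Ω_{jj}` of its z-score given
all others, the standardized discordance `t_j`, and the allele-flip
likelihood ratio `LR_j = exp(−2 z̃_j E[z̃_j|z̃_{−j}] Ω_{jj})`, the density
ratio between a sign-flipped and unflipped conditional mean.  `LR_j > 1`
among SNPs with `|z̃| > 2` flags flip candidates; negating `z̃_j` maps
`LR_j → 1/LR_j` exactly.  The derivation sets `b_j ≈ 0` in the
conditional, appropriate when individual effects are small or the SNP is
in strong LD with others.  These statistics use `z̃` by default and
remain valid for `ẑ` under small effects.  A warning is emitted above
J = 5000, where the J×J factorization dominates cost.

## Synthetic data

The generator emulates the statistical structure fine-mapping methods
are sensitive to, at desk scale.  Genotypes are Gaussian-copula dosages:
two haplotype-like latent draws per person with a block or AR(1) target
correlation, thresholded at MAF quantiles sampled from `maf_range`.
Thresholding attenuates correlation (latent 0.98 yields dosage |r|
around 0.87 for common variants), so near-complete latent LD is used
where dosage |r| > 0.9 is required.  Traits are `y = Xb + e` with
`σ² = 1` and i.i.d. normal causal effects rescaled so the realized
sample PVE equals its target exactly.  Marginal summaries use
denominator-N standard errors, matching the sufficient-statistic
conventions.  Reference panels are independent draws from the same
copula; allele flips recode panel dosages `g → 2−g`, exactly negating
that SNP's panel correlations while leaving study summaries untouched.

Default study conditions (n = 800, J = 200, blocks of 10 at latent
r = 0.9, 1–3 causal SNPs, total PVE 30%) are the large-effect/small-n
analogue of biobank-scale fine-mapping: small effects at very large N
and large effects at small N give comparable per-dataset power, and the
latter is tractable on a desktop.  What the generator does **not**
reproduce: real haplotype mosaics and recombination hotspots, allele
frequency spectra, imputation error, population structure, or
case-control ascertainment.  Passing tests demonstrate correctness of
the inference machinery under a well-specified model with realistic LD
block structure — not robustness to those real-data complications.

## Numerical choices and limitations

- Centering/standardization uses denominator N throughout, so all
  identities linking z-scores and sufficient statistics are exact.
- Assignment probabilities are normalized via max-shifted exponentials;
  prior-weight zeros are handled in log space (−∞), so masked SNPs can
  never re-enter an effect.
- Missing per-SNP statistics are rejected, not imputed; allele labels
  are carried through but never auto-harmonized — harmonization errors
  are precisely what the diagnostics detect.  SNPs present in the
  summary file but missing from the LD matrix are an error, never a
  silent subset.
- The refinement procedure is a heuristic for escaping local optima; it
  guarantees no degradation but not global optimality.
- Credible-set coverage guarantees are per-effect and approximate;
  with badly misspecified LD (small panels, flips) coverage degrades —
  which is the motivation for the λ estimate and the diagnostics.
- The residual-variance clamp (floor `1e-8·y'y/N`) and the fit under
  inconsistent `y'y`/`z̃`/`R̂` combinations surface as warnings; the fit
  is retained so the user can inspect it rather than losing the run.
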