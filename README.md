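# finemapss

Bayesian fine-mapping of genetic association signals from summary
statistics, using the sum of single effects (SuSiE) regression model.

## The problem

Fine-mapping asks which of the many correlated SNPs in an associated
genomic region actually affect a trait.  With individual-level genotypes
`X` (N×J) and phenotypes `y`, the standard approach fits the sparse
multiple regression `y = Xb + e`, `e ~ N(0, σ²I)`, and reports posterior
inclusion probabilities (PIPs) and credible sets (CSs).  In practice,
individual-level data are rarely shareable; what circulates are per-SNP
marginal statistics (effect estimates `b̂`, standard errors `ŝ`, or
z-scores `ẑ`) and an LD correlation matrix `R̂` estimated from a
reference panel.

`finemapss` fits the SuSiE model — `b = Σₗ bₗ` with each `bₗ` having
exactly one nonzero entry, `bₗⱼ ~ N(0, σ₀ₗ²)` — from any of three data
regimes:

| regime       | data                       | residual variance σ² |
|--------------|----------------------------|----------------------|
| individual   | `X, y`                     | estimated            |
| sufficient   | in-sample `R`, `ẑ`, `N`    | estimated            |
| summary      | reference-panel `R̂`, `ẑ`, `N` | fixed at `y'y/N` (1 standardized) |

The key identity: the Gaussian regression likelihood depends on the data
only through the sufficient statistics `(X'X, X'y, y'y, N)`, and under
standardization these are recovered from summary data as `X'X = N R`,
`X'y = √N z̃`, `y'y = N`, where `z̃ⱼ = ẑⱼ·√(N/(N+ẑⱼ²))` are the
PVE-adjusted z-scores.  Coordinate ascent on these statistics (cost
O(J²) per sweep, independent of N) therefore reproduces the
individual-data fit *exactly* when `R` is the in-sample LD matrix, and
approximates it otherwise — with no need for `R̂` to be invertible.

The package also provides:

- **credible sets** at level ρ with purity filtering (smallest absolute
  pairwise |r| within the set; default filter 0.5);
- an ELBO-guided **refinement** procedure that escapes local optima by
  refitting with each credible set's SNPs masked out, accepting a
  candidate only if the objective strictly improves;
- **LD regularization** `R̂_λ = (1−λ)R̂₀ + λI` with λ estimated by
  maximizing the null z-score likelihood `N_J(z̃; 0, R̂_λ)`;
- **diagnostics** for corrupted summary data: conditional expected
  z-scores `E[z̃ⱼ|z̃₋ⱼ] = −Ω_{j,−j}z̃₋ⱼ/Ω_{jj}` (Ω = R̂⁻¹), standardized
  discordance statistics, and a likelihood ratio for detecting **allele
  flips** (SNPs encoded differently in the study and the panel);
- a deterministic **simulator** (Gaussian-copula dosages with block/AR(1)
  LD, traits at exact target PVE, reference panels, injectable flips)
  used throughout the test suite.

## Worked example

Two SNPs with z-scores 6 and 7, and a reference panel claiming they are
in complete LD (an all-ones, non-invertible `R̂` — inconsistent with the
observed z-scores, since complete LD implies equal z):

```sh
printf 'snp\ta1\ta2\tz\nsnp1\tA\tG\t6.0\nsnp2\tA\tG\t7.0\n' > z.tsv
printf '1 1\n1 1\n' > R.txt
finemapss fit --mode summary --summary z.tsv --ld R.txt --out-prefix toy
```

```
$ cat toy.pip.tsv
snp	pip
snp1	0.00171387
snp2	0.998286
$ cat toy.cs.tsv
cs_id	effect	coverage	purity	n_snps	snps
1	1	0.998286	1	1	snp2
```

The likelihood-based fit keeps the more significant SNP as the better
candidate (PIP 0.998 vs 0.002) and reports a single 95% credible set
containing SNP 2 only — approaches that transform the data through
`R̂⁻¹` (or its pseudoinverse) would instead force both z-scores to 6.5
and lose the distinction.

The same workflow on simulated data, with the in-sample LD matrix:

```sh
finemapss simulate --n-study 800 --n-panel 500 --n-snps 100 \
    --n-causal 2 --pve 0.2 --seed 1 --out-prefix sim
finemapss fit --mode sufficient --summary sim.summary.tsv \
    --ld sim.ld_insample.txt --n 800 --out-prefix simfit
```

```
$ cat simfit.cs.tsv
cs_id	effect	coverage	purity	n_snps	snps
1	1	1	1	1	snp4
2	2	1	1	1	snp15
$ cat sim.truth.tsv
snp	b_true
snp4	-0.6769186480697
snp15	-0.5253492452883628
```

Both causal SNPs are recovered as singleton credible sets.  The library
API mirrors the CLI; see `finemapss.fit_susie_ss`,
`finemapss.ibss.fit_susie_rss`, `finemapss.collect_credible_sets`,
`finemapss.diagnostics` and `finemapss.simulate`.

## Layout

```
src/finemapss/
  sufficient.py    sufficient statistics from the three data routes
  ser.py           single effect regression (closed-form posterior, EB prior)
  ibss.py          coordinate ascent from sufficient statistics; ELBO
  cs.py            credible sets, purity, filtering
  refine.py        ELBO-guided refinement
  ld.py            LD regularization and lambda estimation
  diagnostics.py   conditional z-scores, discordance, allele-flip LR
  simulate.py      synthetic genotypes, traits, summaries, panels, flips
  io.py, cli.py    text formats and the command-line interface
```

`docs/methods.md` documents the model, algorithms, defaults and known
limitations.
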