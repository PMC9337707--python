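"""Coordinate-ascent fitting from sufficient statistics: equivalence with
the individual-data route, ELBO behavior, residual variance, PIPs."""

import numpy as np
import pytest

from finemapss import (
    LDMatrix,
    compute_pips,
    elbo,
    estimate_sigma2,
    fit_susie_ss,
    suff_from_individual,
)
from finemapss._exceptions import InputError
from finemapss.ibss import SusieFit, fit_susie_rss
from finemapss.sufficient import SufficientStats

from oracles import ibss_individual, standardize


def _sim_xy(seed, n=600, J=50, n_causal=2, pve=0.3):
    from finemapss.simulate import SimScenario, simulate_dataset

    d = simulate_dataset(SimScenario(
        n_study=n, n_panel=100, J=J, n_causal=n_causal, pve=pve, seed=seed
    ))
    return d["X"], d["y"], d


class TestFitSusieSS:
    def test_null_data_prunes_everything(self):
        J = 20
        ss = SufficientStats(XtX=100 * np.eye(J), Xty=np.zeros(J),
                             yty=100.0, n=100)
        fit = fit_susie_ss(ss, L=5)
        assert np.all(fit.prior_vars == 0.0)
        np.testing.assert_array_equal(fit.pip, np.zeros(J))

    def test_matches_individual_data_oracle(self):
        """Fitting from exact sufficient statistics reproduces an
        independently coded individual-level coordinate ascent."""
        X, y, _ = _sim_xy(seed=42)
        Xs, ys = standardize(X, y)
        ss = suff_from_individual(X, y, standardize=True)
        fit = fit_susie_ss(ss, L=5, max_iter=40, tol=1e-12)
        ref = ibss_individual(Xs, ys, L=5, n_sweeps=40)
        np.testing.assert_allclose(fit.alpha, ref["alpha"], atol=1e-6)
        np.testing.assert_allclose(fit.pip, ref["pip"], atol=1e-6)
        assert fit.sigma2 == pytest.approx(ref["sigma2"], abs=1e-6)

    def test_elbo_trace_monotone(self):
        for seed in (0, 1, 2):
            X, y, _ = _sim_xy(seed=seed)
            ss = suff_from_individual(X, y, standardize=True)
            fit = fit_susie_ss(ss, L=10)
            diffs = np.diff(fit.elbo_trace)
            assert np.all(diffs > -1e-6), f"seed {seed}: ELBO decreased"

    def test_snp_permutation_equivariance(self):
        X, y, _ = _sim_xy(seed=5, J=20)
        ss = suff_from_individual(X, y, standardize=True)
        perm = np.random.default_rng(3).permutation(20)
        ss_p = SufficientStats(XtX=ss.XtX[np.ix_(perm, perm)],
                               Xty=ss.Xty[perm], yty=ss.yty, n=ss.n)
        fit = fit_susie_ss(ss, L=5)
        fit_p = fit_susie_ss(ss_p, L=5)
        np.testing.assert_allclose(fit_p.pip, fit.pip[perm], atol=1e-9)
        np.testing.assert_allclose(fit_p.alpha, fit.alpha[:, perm], atol=1e-9)

    def test_fixed_sigma2_stays_fixed(self):
        X, y, _ = _sim_xy(seed=9, J=20)
        ss = suff_from_individual(X, y, standardize=True)
        fit = fit_susie_ss(ss, L=3, fix_sigma2=True)
        assert fit.sigma2 == pytest.approx(ss.yty / ss.n)

    def test_bad_L_rejected(self):
        ss = SufficientStats(XtX=np.eye(3), Xty=np.zeros(3), yty=1.0, n=10)
        with pytest.raises(InputError):
            fit_susie_ss(ss, L=0)


class TestElbo:
    def test_zero_state_is_null_loglik(self):
        """With all effects pruned the ELBO is the Gaussian log-likelihood
        at b = 0."""
        J, n = 4, 50
        ss = SufficientStats(XtX=n * np.eye(J), Xty=np.zeros(J),
                             yty=float(n), n=n)
        state = SusieFit(alpha=np.full((2, J), 1.0 / J),
                         mu1=np.zeros((2, J)), mu2=np.zeros((2, J)),
                         prior_vars=np.zeros(2), sigma2=1.0)
        expected = -0.5 * n * np.log(2 * np.pi) - 0.5 * n
        assert elbo(state, ss) == pytest.approx(expected)

    def test_doubling_yty_at_null_state(self):
        """At b = 0 and fixed sigma2 the ELBO drops by the added
        yty/(2 sigma2) — the explicit quadratic form of the likelihood."""
        J, n = 3, 20
        state = SusieFit(alpha=np.full((1, J), 1.0 / J),
                         mu1=np.zeros((1, J)), mu2=np.zeros((1, J)),
                         prior_vars=np.zeros(1), sigma2=2.0)
        ss1 = SufficientStats(XtX=np.eye(J), Xty=np.zeros(J), yty=10.0, n=n)
        ss2 = SufficientStats(XtX=np.eye(J), Xty=np.zeros(J), yty=20.0, n=n)
        assert elbo(state, ss1) - elbo(state, ss2) == pytest.approx(
            10.0 / (2 * 2.0)
        )

    def test_point_mass_degenerate_limit(self):
        """Alpha concentrated on one SNP with vanishing effect variance and
        a matching (vanishing) prior slab: the KL term disappears and the
        ELBO reduces to the Gaussian log-likelihood at b = mu1 = 0."""
        J, n = 3, 40
        XtX = n * np.eye(J)
        Xty = np.array([2.0, 0.0, 0.0])
        yty = float(n)
        ss = SufficientStats(XtX=XtX, Xty=Xty, yty=yty, n=n)
        v_tiny = 1e-12
        post_var = 1.0 / (1.0 / v_tiny + n / 1.0)
        state = SusieFit(alpha=np.array([[1.0, 0.0, 0.0]]),
                         mu1=np.zeros((1, J)),
                         mu2=np.array([[post_var, 0.0, 0.0]]),
                         prior_vars=np.array([v_tiny]), sigma2=1.0,
                         prior_weights=np.array([1.0, 0.0, 0.0]))
        loglik_at_zero = -0.5 * n * np.log(2 * np.pi) - 0.5 * yty
        assert elbo(state, ss) == pytest.approx(loglik_at_zero, abs=1e-6)


class TestEstimateSigma2:
    def test_null_state_returns_yty_over_n(self):
        J, n = 5, 30
        ss = SufficientStats(XtX=n * np.eye(J), Xty=np.zeros(J),
                             yty=60.0, n=n)
        state = SusieFit(alpha=np.full((1, J), 1.0 / J),
                         mu1=np.zeros((1, J)), mu2=np.zeros((1, J)),
                         prior_vars=np.zeros(1), sigma2=1.0)
        assert estimate_sigma2(state, ss) == pytest.approx(2.0)

    def test_perfect_fit_drives_sigma2_to_floor(self, rng):
        n = 100
        x = rng.standard_normal(n)
        x -= x.mean()
        y = 2.0 * x
        ss = suff_from_individual(x[:, None], y)
        fit = fit_susie_ss(ss, L=1, tol=1e-10)
        assert fit.sigma2 <= 1e-6 * ss.yty / ss.n

    def test_recovers_generating_variance(self):
        """sigma2-hat lands within Monte-Carlo error of the generating
        residual variance on a well-powered simulation."""
        from finemapss.simulate import SimScenario, simulate_dataset

        d = simulate_dataset(SimScenario(
            n_study=5000, n_panel=100, J=20, n_causal=2, pve=0.2, seed=13
        ))
        ss = suff_from_individual(d["X"], d["y"])
        fit = fit_susie_ss(ss, L=5)
        # MC standard error of a variance estimate ~ sigma2 sqrt(2/n)
        se = d["sigma2_true"] * np.sqrt(2.0 / 5000)
        assert abs(fit.sigma2 - d["sigma2_true"]) < 3 * se + 0.02


class TestComputePips:
    def test_single_effect_is_alpha_row(self):
        a = np.array([[0.2, 0.5, 0.3]])
        np.testing.assert_allclose(compute_pips(a), a[0])

    def test_two_half_effects_combine(self):
        a = np.array([[0.5, 0.5], [0.5, 0.5]])
        np.testing.assert_allclose(compute_pips(a), [0.75, 0.75])

    def test_certainty_absorbs(self):
        a = np.array([[1.0, 0.0], [0.3, 0.7]])
        pips = compute_pips(a)
        assert pips[0] == pytest.approx(1.0)

    def test_null_effects_pruned(self):
        a = np.array([[0.9, 0.1], [0.5, 0.5]])
        pips = compute_pips(a, prior_vars=np.array([1.0, 0.0]))
        np.testing.assert_allclose(pips, a[0])


class TestFitSusieRss:
    def test_sufficient_vs_summary_mode_close_with_insample_ld(self):
        X, y, d = _sim_xy(seed=21, n=1000, J=30, pve=0.02)
        from finemapss.simulate import summarize_study

        sd = summarize_study(X, y)
        z = sd.zscores()
        fit_suff, _ = fit_susie_rss(z, d["R_insample"].R, n=1000,
                                    mode="sufficient", L=5)
        fit_summ, _ = fit_susie_rss(z, d["R_insample"].R, n=1000,
                                    mode="summary", L=5)
        # at small PVE sigma2 ~ 1 so the two regimes nearly agree
        np.testing.assert_allclose(fit_suff.pip, fit_summ.pip, atol=0.05)

    def test_unknown_mode_rejected(self):
        with pytest.raises(InputError):
            fit_susie_rss(np.zeros(2), np.eye(2), mode="bogus")
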