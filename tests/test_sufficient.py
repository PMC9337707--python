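"""Sufficient-statistic construction from the three data routes."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from finemapss import (
    LDMatrix,
    SummaryData,
    pve_adjusted_z,
    suff_from_effect_summary,
    suff_from_individual,
    suff_from_standardized_summary,
    zscores_from_effects,
)
from finemapss._exceptions import InputError, ValidationError
from finemapss.simulate import summarize_study


class TestZScores:
    @pytest.mark.parametrize(
        "bhat, shat, expected",
        [
            ([1.0], [0.5], [2.0]),
            ([0.0, 0.0], [1.0, 2.0], [0.0, 0.0]),
            ([0.3, -0.4], [0.1, 0.2], [3.0, -2.0]),
        ],
    )
    def test_quotient(self, bhat, shat, expected):
        sd = SummaryData(snp_ids=[f"s{i}" for i in range(len(bhat))],
                         bhat=bhat, shat=shat)
        np.testing.assert_allclose(zscores_from_effects(sd), expected)

    def test_missing_effects_rejected(self):
        sd = SummaryData(snp_ids=["a"], zhat=[1.0])
        with pytest.raises(InputError):
            zscores_from_effects(sd)

    def test_nonpositive_se_names_snp(self):
        with pytest.raises(ValidationError, match="rs2"):
            SummaryData(snp_ids=["rs1", "rs2"], bhat=[1.0, 1.0],
                        shat=[0.5, -0.1])

    def test_inconsistent_z_rejected(self):
        with pytest.raises(ValidationError):
            SummaryData(snp_ids=["a"], bhat=[1.0], shat=[0.5], zhat=[5.0])


class TestPveAdjustedZ:
    def test_zero_stays_zero(self):
        np.testing.assert_array_equal(
            pve_adjusted_z(np.zeros(3), 1000), np.zeros(3)
        )

    def test_hand_computed_value(self):
        # z = 2, n = 4: 2 * sqrt(4 / (4 + 4)) = sqrt(2)
        np.testing.assert_allclose(
            pve_adjusted_z(np.array([2.0]), 4), [np.sqrt(2.0)]
        )

    def test_large_n_limit(self):
        np.testing.assert_allclose(
            pve_adjusted_z(np.array([5.0]), 10**9), [5.0], atol=1e-6
        )

    def test_nonpositive_n_rejected(self):
        with pytest.raises(InputError):
            pve_adjusted_z(np.array([1.0]), 0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        z=st.lists(st.floats(-50, 50), min_size=1, max_size=20),
        n=st.integers(1, 10**6),
    )
    def test_contraction_and_sign(self, z, n):
        """|ztilde| <= |z| with equality iff z = 0; sign preserved;
        monotone in n toward z."""
        z = np.asarray(z)
        zt = pve_adjusted_z(z, n)
        assert np.all(np.abs(zt) <= np.abs(z) + 1e-15)
        # strict shrinkage wherever z^2/n is resolvable in floating point
        nz = z**2 / n > 1e-12
        assert np.all(np.abs(zt[nz]) < np.abs(z[nz]))
        assert np.all(np.sign(zt) == np.sign(z))
        zt_bigger_n = pve_adjusted_z(z, 2 * n)
        assert np.all(np.abs(zt_bigger_n) >= np.abs(zt) - 1e-15)


class TestSuffFromIndividual:
    def test_self_regression_toy(self):
        # one standardized column equal to y: all statistics equal N
        y = np.array([1.0, 2.0, 3.0, 6.0])
        X = y[:, None].copy()
        ss = suff_from_individual(X, y, standardize=True)
        np.testing.assert_allclose(ss.XtX, [[4.0]], atol=1e-12)
        np.testing.assert_allclose(ss.Xty, [4.0], atol=1e-12)
        assert ss.yty == pytest.approx(4.0)
        assert ss.n == 4

    def test_constant_phenotype_centers_to_zero(self):
        X = np.arange(8.0).reshape(4, 2)
        y = np.full(4, 3.3)
        ss = suff_from_individual(X, y)
        assert ss.yty == pytest.approx(0.0, abs=1e-20)
        np.testing.assert_allclose(ss.Xty, 0.0, atol=1e-12)

    def test_permutation_invariance(self, rng):
        X = rng.standard_normal((30, 5))
        y = rng.standard_normal(30)
        perm = rng.permutation(30)
        a = suff_from_individual(X, y)
        b = suff_from_individual(X[perm], y[perm])
        np.testing.assert_allclose(a.XtX, b.XtX, atol=1e-9)
        np.testing.assert_allclose(a.Xty, b.Xty, atol=1e-9)
        assert a.yty == pytest.approx(b.yty)

    def test_constant_column_under_standardize(self):
        X = np.ones((5, 2))
        X[:, 1] = np.arange(5.0)
        with pytest.raises(ValidationError, match="0"):
            suff_from_individual(X, np.arange(5.0), standardize=True)


class TestSuffFromSummary:
    def test_zero_z(self):
        R = LDMatrix(R=np.eye(3))
        ss = suff_from_standardized_summary(np.zeros(3), R, 100)
        np.testing.assert_array_equal(ss.Xty, np.zeros(3))
        assert ss.yty == 100

    def test_scalar_case(self):
        R = LDMatrix(R=np.eye(1))
        ss = suff_from_standardized_summary(np.array([3.0]), R, 9)
        assert ss.XtX[0, 0] == pytest.approx(9.0)
        assert ss.Xty[0] == pytest.approx(9.0)
        assert ss.yty == pytest.approx(9.0)

    def test_dimension_mismatch(self):
        with pytest.raises(InputError):
            suff_from_standardized_summary(np.zeros(3), LDMatrix(R=np.eye(2)), 10)

    def test_roundtrip_matches_individual(self, rng):
        """With in-sample LD and PVE-adjusted z-scores the summary route
        reproduces the individual-level sufficient statistics exactly."""
        n, J = 500, 8
        X = rng.standard_normal((n, J)) + rng.standard_normal((n, 1))
        beta = np.zeros(J)
        beta[2] = 0.5
        y = X @ beta + rng.standard_normal(n)
        ss_ind = suff_from_individual(X, y, standardize=True)
        sd = summarize_study(X, y)
        ztilde = pve_adjusted_z(sd.zscores(), n)
        R = LDMatrix(R=ss_ind.XtX / n)
        ss_sum = suff_from_standardized_summary(ztilde, R, n)
        np.testing.assert_allclose(ss_sum.XtX, ss_ind.XtX, rtol=1e-8)
        np.testing.assert_allclose(ss_sum.Xty, ss_ind.Xty, rtol=1e-8, atol=1e-8)
        assert ss_sum.yty == pytest.approx(ss_ind.yty, rel=1e-10)


class TestSuffFromEffectSummary:
    def test_roundtrip_single_snp(self, rng):
        n = 200
        x = rng.standard_normal(n)
        x -= x.mean()
        y = 0.7 * x + rng.standard_normal(n)
        y -= y.mean()
        d = float(x @ x)
        bhat = float(x @ y) / d
        rss = float((y - x * bhat) @ (y - x * bhat))
        shat = np.sqrt(rss / (n * d))
        sd = SummaryData(snp_ids=["s1"], bhat=[bhat], shat=[shat])
        ss = suff_from_effect_summary(
            sd, LDMatrix(R=np.eye(1)), n=n, var_y=float(y @ y) / n
        )
        assert ss.XtX[0, 0] == pytest.approx(d, rel=1e-8)
        assert ss.Xty[0] == pytest.approx(float(x @ y), rel=1e-8)

    def test_null_effects_give_zero_xty(self):
        sd = SummaryData(snp_ids=["a", "b"], bhat=[0.0, 0.0], shat=[0.1, 0.2])
        ss = suff_from_effect_summary(sd, LDMatrix(R=np.eye(2)), n=50)
        np.testing.assert_array_equal(ss.Xty, np.zeros(2))

    def test_agrees_with_standardized_route(self, rng):
        """On standardized data both summary routes coincide."""
        n, J = 400, 6
        X = rng.standard_normal((n, J))
        y = X[:, 0] * 0.4 + rng.standard_normal(n)
        Xc = X - X.mean(axis=0)
        Xc /= np.sqrt((Xc**2).mean(axis=0))
        yc = y - y.mean()
        yc /= np.sqrt((yc**2).mean())
        sd = summarize_study(Xc, yc)
        R = LDMatrix(R=(Xc.T @ Xc) / n)
        ss_eff = suff_from_effect_summary(sd, R, n=n, var_y=1.0)
        ztilde = pve_adjusted_z(sd.zscores(), n)
        ss_std = suff_from_standardized_summary(ztilde, R, n)
        np.testing.assert_allclose(ss_eff.XtX, ss_std.XtX, rtol=1e-6, atol=1e-8)
        np.testing.assert_allclose(ss_eff.Xty, ss_std.Xty, rtol=1e-6, atol=1e-8)
        assert ss_eff.yty == pytest.approx(ss_std.yty, rel=1e-8)
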