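import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from modquilt import integrate
from modquilt.synthdata import SimulationParams, simulate_cohort

from conftest import make_expression, make_genotypes


class TestGsmqtlMatrix:
    def test_probe_equal_to_genotype_gives_one(self):
        g = np.array([0.0, 1, 2, 0, 1, 2, 0, 1])
        geno = make_genotypes(g[:, None], snp_ids=["snpX"])
        expr = make_expression(g[None, :] * 2 + 3)
        out = integrate.gsmqtl_matrix(expr, geno, ["snpX"])
        assert out.loc["p0", "snpX"] == pytest.approx(1.0)

    def test_independent_noise_small_rho(self, rng):
        g = rng.binomial(2, 0.4, 200).astype(float)
        geno = make_genotypes(g[:, None], snp_ids=["snpX"])
        expr = make_expression(rng.standard_normal((5, 200)))
        out = integrate.gsmqtl_matrix(expr, geno, ["snpX"])
        assert (out["snpX"].abs() < 0.2).all()

    def test_missing_genotype_dropped_pairwise(self, rng):
        g = rng.binomial(2, 0.4, 50).astype(float)
        g_miss = g.copy()
        g_miss[0] = np.nan
        expr_vals = rng.standard_normal((3, 50))
        full = integrate.gsmqtl_matrix(
            make_expression(expr_vals[:, 1:]), make_genotypes(g[1:, None], snp_ids=["s"]), ["s"]
        )
        miss = integrate.gsmqtl_matrix(
            make_expression(expr_vals), make_genotypes(g_miss[:, None], snp_ids=["s"]), ["s"]
        )
        pd.testing.assert_frame_equal(full, miss)

    def test_monomorphic_snp_rejected(self):
        geno = make_genotypes(np.ones((20, 1)), snp_ids=["flat"])
        expr = make_expression(np.random.default_rng(0).standard_normal((2, 20)))
        with pytest.raises(ValueError, match="monomorphic"):
            integrate.gsmqtl_matrix(expr, geno, ["flat"])


class TestRankInverseNormal:
    def test_four_distinct_values_hit_normal_quantiles(self):
        z = integrate.rank_inverse_normal([10.0, 1.0, 5.0, 7.0])
        expected = stats.norm.ppf([0.875, 0.125, 0.375, 0.625])
        np.testing.assert_allclose(z, expected, atol=1e-4)
        np.testing.assert_allclose(sorted(z), [-1.1503, -0.3186, 0.3186, 1.1503], atol=1e-4)

    @given(st.lists(st.floats(-100, 100), min_size=5, max_size=40, unique=True))
    @settings(max_examples=50, derandomize=True)
    def test_invariant_under_monotone_transform(self, xs):
        # doubling is strictly increasing and exact in floating point, so the
        # ranks (and hence the transform) are untouched
        x = np.asarray(xs)
        np.testing.assert_allclose(
            integrate.rank_inverse_normal(x),
            integrate.rank_inverse_normal(2.0 * x),
            atol=1e-12,
        )

    def test_exponential_draws_become_normal(self, rng):
        passed = 0
        for _ in range(20):
            z = integrate.rank_inverse_normal(rng.exponential(size=1000))
            passed += stats.shapiro(z).pvalue > 0.01
        assert passed >= 19

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            integrate.rank_inverse_normal([2.0, 2.0, 2.0])


class TestFitLinear:
    def test_single_regressor_r2_051_gives_vif_204(self, rng):
        """The model VIF identity 1/(1-R^2): R^2 = 0.51 -> VIF = 2.04."""
        n = 1000
        x = rng.standard_normal(n)
        e = rng.standard_normal(n)
        # orthonormalize e against x so R^2 is exact by construction
        xs = (x - x.mean()) / np.linalg.norm(x - x.mean())
        e = e - e.mean() - (e @ xs) * xs
        es = e / np.linalg.norm(e)
        y = np.sqrt(0.51) * xs + np.sqrt(0.49) * es
        rep = integrate.fit_linear(y, pd.DataFrame({"x": xs}))
        assert rep.r_squared == pytest.approx(0.51, abs=1e-12)
        assert round(rep.model_vif, 2) == 2.04

    def test_exact_linear_response_r2_one(self):
        x = np.arange(20, dtype=float)
        y = 3 * x - 7
        rep = integrate.fit_linear(y, pd.DataFrame({"x": x}))
        assert rep.r_squared == pytest.approx(1.0)
        assert np.allclose(rep.residuals, 0.0, atol=1e-9)

    def test_orthonormal_predictors_recover_coefficients(self, rng):
        n = 50
        q, _ = np.linalg.qr(rng.standard_normal((n, 3)))
        X = pd.DataFrame(q, columns=["a", "b", "c"])
        y = 2.0 * q[:, 0] - 1.5 * q[:, 1] + 0.5 * q[:, 2]
        rep = integrate.fit_linear(y, X)
        np.testing.assert_allclose(
            rep.coefficients[["a", "b", "c"]], [2.0, -1.5, 0.5], atol=1e-10
        )

    def test_rank_deficient_design_names_aliased_column(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"x1": x, "x2": 2 * x})
        with pytest.raises(ValueError, match="x2"):
            integrate.fit_linear(rng.standard_normal(30), X)

    def test_model_vif_identity_holds_generally(self, rng):
        for _ in range(10):
            X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
            y = rng.standard_normal(40)
            rep = integrate.fit_linear(y, X)
            assert rep.model_vif == pytest.approx(1 / (1 - rep.r_squared))
            assert rep.adjusted_r_squared <= rep.r_squared + 1e-12


class TestStepwiseAic:
    def test_true_predictor_always_kept_spurious_rarely(self, rng):
        # AIC admits an independent noise predictor with probability
        # P(chi2_1 > 2) ~ 0.157, so with four noise columns the exactly-true
        # set {x1} appears in about half the runs; the reliable guarantees
        # are that x1 itself is never dropped and noise stays near that rate
        exact = 0
        kept_true = 0
        spurious = 0
        runs = 200
        for _ in range(runs):
            n = 100
            X = pd.DataFrame(rng.standard_normal((n, 5)),
                             columns=[f"x{i}" for i in range(1, 6)])
            y = 2 * X["x1"].to_numpy() + 0.3 * rng.standard_normal(n)
            rep = integrate.stepwise_aic(y, X)
            kept_true += "x1" in rep.predictors
            exact += rep.predictors == ["x1"]
            spurious += len(set(rep.predictors) - {"x1"})
        assert kept_true == runs
        assert exact >= int(0.35 * runs)
        assert spurious / (4 * runs) < 0.25  # per-noise-column inclusion rate

    def test_pure_noise_often_selects_empty_model(self, rng):
        # with 4 noise columns the all-dropped probability is ~0.843^4 ~ 0.5
        empties = 0
        runs = 100
        for _ in range(runs):
            X = pd.DataFrame(rng.standard_normal((80, 4)), columns=list("abcd"))
            y = rng.standard_normal(80)
            rep = integrate.stepwise_aic(y, X)
            empties += len(rep.predictors) == 0
        assert empties >= int(0.35 * runs)

    def test_duplicate_columns_rejected(self, rng):
        x = rng.standard_normal(30)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(ValueError, match="aliased"):
            integrate.stepwise_aic(rng.standard_normal(30), X)

    def test_never_worse_than_full_or_empty(self, rng):
        for _ in range(10):
            X = pd.DataFrame(rng.standard_normal((60, 4)), columns=list("abcd"))
            y = X["a"].to_numpy() + rng.standard_normal(60)
            rep = integrate.stepwise_aic(y, X)
            full = integrate.fit_linear(y, X)
            assert rep.aic <= full.aic + 1e-9
            empty = integrate._intercept_only_report(y, "y")
            assert rep.aic <= empty.aic + 1e-9


class TestAggregateAndFinalModel:
    def _fixture(self, rng, n=300):
        gsm = pd.DataFrame(
            rng.standard_normal((n, 3)), columns=["s1", "s2", "s3"],
            index=[f"p{i}" for i in range(n)],
        )
        y = 0.8 * gsm["s1"].to_numpy() - 0.8 * gsm["s2"].to_numpy() + 0.3 * rng.standard_normal(n)
        return gsm, y

    def test_signs_split_into_risk_and_protective(self, rng):
        gsm, y = self._fixture(rng)
        rep = integrate.stepwise_aic(y, gsm)
        risk, prot = integrate.aggregate_risk_protective(rep, gsm)
        pd.testing.assert_series_equal(risk, gsm["s1"], check_names=False)
        pd.testing.assert_series_equal(prot, gsm["s2"], check_names=False)

    def test_no_significant_variables_warns_and_zeroes(self, rng):
        gsm = pd.DataFrame(rng.standard_normal((50, 2)), columns=["a", "b"])
        y = rng.standard_normal(50)
        rep = integrate.stepwise_aic(y, gsm)
        with pytest.warns(UserWarning, match="no significant"):
            risk, prot = integrate.aggregate_risk_protective(rep, gsm, p_threshold=1e-12)
        assert (risk == 0).all() and (prot == 0).all()

    def test_sign_flip_migrates_column_and_preserves_fit(self, rng):
        # flipping one mQTL's allele coding negates its GSmQTL column: the
        # column span is unchanged (so the selected model fit is identical)
        # and the column migrates from the risk sum to the protective sum
        gsm, y = self._fixture(rng)
        rep = integrate.stepwise_aic(y, gsm)
        risk_a, prot_a = integrate.aggregate_risk_protective(rep, gsm)
        flipped = gsm.copy()
        flipped["s1"] = -flipped["s1"]
        rep_b = integrate.stepwise_aic(y, flipped)
        risk_b, prot_b = integrate.aggregate_risk_protective(rep_b, flipped)
        assert rep_b.r_squared == pytest.approx(rep.r_squared, abs=1e-10)
        assert (risk_b == 0).all()  # s1 left the risk sum
        pd.testing.assert_series_equal(
            prot_b, prot_a - gsm["s1"], check_names=False
        )  # and joined the protective sum with flipped sign

    def test_final_model_collapses_when_protective_is_zero(self, rng):
        gsm, y = self._fixture(rng)
        kme = pd.Series(rng.standard_normal(len(gsm)), index=gsm.index)
        zero = pd.Series(0.0, index=gsm.index)
        rep, fitted, rho = integrate.final_model(y, kme, zero, gsm["s1"])
        assert rep.predictors == ["kME", "GSmQTLRisk"]
        assert len(fitted) == len(gsm)

    def test_final_model_vif_identity(self, rng):
        gsm, y = self._fixture(rng)
        kme = pd.Series(rng.standard_normal(len(gsm)), index=gsm.index)
        rep, _, _ = integrate.final_model(y, kme, gsm["s2"], gsm["s1"])
        assert rep.model_vif == pytest.approx(1 / (1 - rep.r_squared))


class TestDichotomize:
    def test_all_eight_groups_populated_on_continuous_data(self, rng):
        n = 400
        kme = pd.Series(rng.standard_normal(n))
        risk = pd.Series(rng.standard_normal(n))
        prot = pd.Series(rng.standard_normal(n))
        gs = pd.Series(rng.standard_normal(n))
        out = integrate.dichotomize_groups(kme, risk, prot, gs)
        assert len(out) == 8
        assert (out["n"] > 0).all()
        assert out["n"].sum() == n

    def test_ordering_matches_planted_effects(self, rng):
        # positive kME and risk effects on GS: K+R+ groups top, K-R-P+ bottom
        n = 2000
        kme = pd.Series(rng.standard_normal(n))
        risk = pd.Series(rng.standard_normal(n))
        prot = pd.Series(rng.standard_normal(n))
        gs = 1.0 * kme + 1.0 * risk - 1.0 * prot + 0.3 * rng.standard_normal(n)
        out = integrate.dichotomize_groups(kme, risk, prot, gs)
        means = out["gs_mean"]
        assert means.idxmax() in ("K+R+P-", "K+R+P+")
        assert means.idxmin() == "K-R-P+"

    def test_constant_vector_warns(self, rng):
        n = 50
        const = pd.Series(1.0, index=range(n))
        with pytest.warns(UserWarning, match="constant"):
            out = integrate.dichotomize_groups(
                pd.Series(rng.standard_normal(n)), const,
                pd.Series(rng.standard_normal(n)), pd.Series(rng.standard_normal(n)),
            )
        # the R split degenerates: all probes in R-
        assert out.loc[out.index.str.contains("R\\+"), "n"].sum() == 0
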