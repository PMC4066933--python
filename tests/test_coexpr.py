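import numpy as np
import pandas as pd
import pytest
from scipy import stats

from modquilt import coexpr
from modquilt.coexpr import UNASSIGNED

from conftest import make_expression, make_phenotypes


def _corr_expr(cor, n=500, rng=None):
    """Expression whose probe correlation is ~cor via a shared factor."""
    rng = rng or np.random.default_rng(0)
    f = rng.standard_normal(n)
    a = np.sqrt(cor / (1 - cor))
    x = a * f + rng.standard_normal(n)
    y = a * f + rng.standard_normal(n)
    return make_expression(np.vstack([x, y]))


class TestAdjacency:
    def test_perfect_correlation_gives_one(self):
        x = np.arange(10, dtype=float)
        expr = make_expression(np.vstack([x, 3 - 2 * x]))  # cor = -1
        net = coexpr.adjacency(expr, beta=6)
        assert net.adjacency[0, 1] == pytest.approx(1.0)

    @pytest.mark.parametrize("cor,expected", [(0.5, 0.015625), (-0.86, 0.86**6)])
    def test_powered_absolute_correlation(self, cor, expected):
        # exact two-probe construction with the requested correlation
        x = np.array([1.0, -1.0, 1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        e = np.array([1.0, 1.0, -1.0, -1.0, 1.0, 1.0, -1.0, -1.0])
        y = cor * x + np.sqrt(1 - cor**2) * e
        net = coexpr.adjacency(make_expression(np.vstack([x, y])), beta=6)
        assert net.adjacency[0, 1] == pytest.approx(abs(expected), rel=1e-10)

    def test_zero_variance_probe_rejected(self):
        expr = make_expression(np.vstack([np.ones(5), np.arange(5)]))
        with pytest.raises(ValueError, match="zero-variance"):
            coexpr.adjacency(expr)

    def test_connectivity_sums_off_diagonal(self):
        net = coexpr.Network(["a", "b", "c"], 6, np.full((3, 3), 0.5))
        net.adjacency[np.diag_indices(3)] = 1.0
        k = coexpr.connectivity(net)
        assert np.allclose(k, 1.0)


class TestScaleFreeFit:
    def test_constructed_power_law_recovers_slope(self):
        # counts 512/64/8/1 at k = 1/4/16/64: p(k) proportional to k^-1.5 exactly;
        # symmetric micro-jitter keeps values distinct without moving bin means
        ks, counts = [1.0, 4.0, 16.0, 64.0], [512, 64, 8, 1]
        values = []
        for k, c in zip(ks, counts):
            half = c // 2
            jit = 1e-7 * (np.arange(half) + 1) if half else np.array([])
            vals = np.concatenate([k - jit, k + jit, [k] * (c - 2 * half)])
            values.extend(vals)
        fit = coexpr.scale_free_fit(np.asarray(values), n_bins=64)
        assert fit.slope == pytest.approx(-1.5, rel=1e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-5)
        assert fit.pearson_cor < 0

    def test_uniform_connectivity_fits_poorly(self, rng):
        k = rng.uniform(1, 10, size=5000)
        fit = coexpr.scale_free_fit(k, n_bins=10)
        assert fit.r_squared < 0.5
        assert abs(fit.slope) < 0.5

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            coexpr.scale_free_fit(np.ones(100), n_bins=10)

    def test_probabilities_sum_to_one_and_identity_holds(self, rng):
        fit = coexpr.scale_free_fit(rng.gamma(2, 2, size=1000), n_bins=10)
        assert fit.bin_p.sum() == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(fit.pearson_cor**2, abs=1e-14)


def brute_force_tom(a):
    """Double-loop topological overlap, the independent oracle."""
    a = a.copy()
    np.fill_diagonal(a, 0.0)
    n = a.shape[0]
    k = a.sum(axis=1)
    tom = np.ones((n, n))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            tom[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return tom


class TestTom:
    def test_matches_brute_force_on_random_adjacencies(self, rng):
        for _ in range(10):
            raw = rng.random((5, 5))
            a = (raw + raw.T) / 2
            np.fill_diagonal(a, 1.0)
            net = coexpr.Network(list("abcde"), 6, a)
            tom = coexpr.tom_similarity(net)
            np.testing.assert_allclose(tom, brute_force_tom(a), atol=1e-12)

    def test_isolated_uncorrelated_pair_has_zero_overlap(self):
        a = np.eye(4)
        net = coexpr.Network(list("abcd"), 6, a)
        tom = coexpr.tom_similarity(net)
        assert tom[0, 1] == 0.0

    def test_identical_fully_connected_rows_overlap_one(self):
        a = np.ones((3, 3))
        net = coexpr.Network(list("abc"), 6, a)
        tom = coexpr.tom_similarity(net)
        assert np.allclose(tom, 1.0)


class TestDetectModules:
    def _blocks(self, rng, n=120, block=40, within=0.8):
        a = np.sqrt(within / (1 - within))
        f1, f2 = rng.standard_normal(n), rng.standard_normal(n)
        vals = np.vstack(
            [
                a * f1 + rng.standard_normal((block, n)),
                a * f2 + rng.standard_normal((block, n)),
                rng.standard_normal((block, n)),
            ]
        )
        return make_expression(vals)

    def test_two_planted_blocks_recovered(self, rng):
        expr = self._blocks(rng)
        net = coexpr.adjacency(expr)
        tom = coexpr.tom_similarity(net)
        asg = coexpr.detect_modules(tom, expr)
        mods = asg.modules()
        assert len(mods) == 2
        truth = [set(f"p{i}" for i in range(40)), set(f"p{i}" for i in range(40, 80))]
        for mod in mods:
            members = set(asg.members(mod))
            assert max(
                len(members & t) / len(members | t) for t in truth
            ) >= 0.95

    def test_pure_noise_all_unassigned(self, rng):
        expr = make_expression(rng.standard_normal((200, 100)))
        net = coexpr.adjacency(expr)
        tom = coexpr.tom_similarity(net)
        asg = coexpr.detect_modules(tom, expr)
        assert asg.modules() == []
        assert (asg.labels == UNASSIGNED).all()

    def test_perfectly_correlated_halves_merged(self, rng):
        # one factor feeding two blocks -> eigengene correlation ~1 -> merged
        n = 150
        f = rng.standard_normal(n)
        vals = np.vstack(
            [
                3 * f + 0.3 * rng.standard_normal((40, n)),
                3 * f + 0.3 * rng.standard_normal((40, n)),
                rng.standard_normal((50, n)),
            ]
        )
        expr = make_expression(vals)
        net = coexpr.adjacency(expr)
        tom = coexpr.tom_similarity(net)
        asg = coexpr.detect_modules(tom, expr)
        assert len(asg.modules()) == 1
        members = set(asg.members("M1"))
        planted = {f"p{i}" for i in range(80)}
        assert planted <= members
        assert len(members - planted) <= 2  # stray noise probes at most


class TestEigengene:
    def test_identical_probes_yield_their_standardized_profile(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0, 9.0])
        expr = make_expression(np.vstack([x, x, x]))
        me, _, var = coexpr.module_eigengene(expr, ["p0", "p1", "p2"])
        z = (x - x.mean()) / x.std(ddof=1)
        np.testing.assert_allclose(me.to_numpy(), z, atol=1e-10)
        assert var == pytest.approx(1.0)

    def test_tracks_planted_factor(self, recovery_cohort):
        _, expr, _, truth = recovery_cohort
        me, _, _ = coexpr.module_eigengene(expr, truth.module_probes)
        rho = abs(np.corrcoef(me, truth.factor)[0, 1])
        assert rho >= 0.97

    def test_sign_invariant_to_global_flip(self, rng):
        vals = rng.standard_normal((10, 20)) + 2 * rng.standard_normal(20)
        expr = make_expression(vals)
        flipped = make_expression(-vals)
        me_a, _, _ = coexpr.module_eigengene(expr, expr.probe_ids)
        me_b, _, _ = coexpr.module_eigengene(flipped, flipped.probe_ids)
        # sign convention ties the eigengene to the mean expression profile,
        # so flipping all probes flips the mean too and the product is stable
        assert abs(np.corrcoef(me_a, me_b)[0, 1]) == pytest.approx(1.0)

    def test_unit_variance(self, small_cohort):
        _, expr, _, truth = small_cohort
        me, pc2, _ = coexpr.module_eigengene(expr, truth.module_probes)
        assert me.std(ddof=1) == pytest.approx(1.0)
        assert pc2.std(ddof=1) == pytest.approx(1.0)


class TestTraitCorrelationsAndProfile:
    def test_me_equal_to_trait_gives_rho_one(self):
        rng = np.random.default_rng(0)
        me = pd.DataFrame({"M1": rng.standard_normal(20)},
                          index=[f"s{i}" for i in range(20)])
        eig = coexpr.ModuleEigengenes(me=me, pc2=me * 0)
        grades = (stats.rankdata(me["M1"]) % 3 + 1).astype(int)
        pheno = make_phenotypes(list(grades))
        pheno.table["echo"] = me["M1"]
        tab = coexpr.module_trait_correlations(eig, pheno)
        row = tab[(tab["module"] == "M1") & (tab["trait"] == "echo")].iloc[0]
        assert row["spearman_rho"] == pytest.approx(1.0)

    def test_constant_trait_reported_missing(self):
        me = pd.DataFrame({"M1": np.arange(10.0)}, index=[f"s{i}" for i in range(10)])
        eig = coexpr.ModuleEigengenes(me=me, pc2=me * 0)
        pheno = make_phenotypes([1] * 10)
        pheno.table["flat"] = 3.0
        tab = coexpr.module_trait_correlations(eig, pheno)
        row = tab[tab["trait"] == "flat"].iloc[0]
        assert np.isnan(row["spearman_rho"])

    def test_profile_trivial_kin_and_kme(self):
        x = np.arange(12, dtype=float)
        expr = make_expression(np.vstack([x, 2 * x + 1]))
        me, _, _ = coexpr.module_eigengene(expr, ["p0", "p1"])
        prof = coexpr.module_profile(expr, ["p0", "p1"], me)
        # two perfectly correlated probes: kIN = 1 for both, |kME| = 1
        assert np.allclose(prof.table["kin"], 1.0)
        assert np.allclose(np.abs(prof.table["kme"]), 1.0)

    def test_profile_gs_one_for_probe_increasing_in_grade(self):
        # the probe is a strictly increasing function of grade, so it shares
        # the grade's tie structure and Spearman GS is exactly 1
        grade_vals = np.repeat([1.0, 2.0, 3.0], 4)
        probe = grade_vals * 2 + 1
        other = np.arange(12, dtype=float)
        expr = make_expression(np.vstack([probe, other]))
        me, _, _ = coexpr.module_eigengene(expr, ["p0", "p1"])
        grades = pd.DataFrame({"who_grade": grade_vals.astype(int)},
                              index=expr.values.columns)
        prof = coexpr.module_profile(expr, ["p0", "p1"], me, grades)
        assert prof.table["gs_who_grade"].loc["p0"] == pytest.approx(1.0)

    def test_kme_sixth_power_tracks_kin_on_planted_module(self, recovery_cohort):
        _, expr, _, truth = recovery_cohort
        me, _, _ = coexpr.module_eigengene(expr, truth.module_probes)
        prof = coexpr.module_profile(expr, truth.module_probes, me)
        rho = stats.spearmanr(prof.table["kme"] ** 6, prof.table["kin"]).statistic
        assert rho >= 0.8

    def test_expression_sd_monotone_in_connectivity_under_factor_model(self, recovery_cohort):
        # with x = u*f + noise at fixed residual sd, the loading u raises both
        # connectivity and total sd, so sd and kIN rise together here (real
        # tumor data showed the inverse relation, which this generator does
        # not emulate; see the methods note)
        _, expr, _, truth = recovery_cohort
        me, _, _ = coexpr.module_eigengene(expr, truth.module_probes)
        prof = coexpr.module_profile(expr, truth.module_probes, me)
        t = prof.table.sort_values("kin")
        lo = t.iloc[: len(t) // 4]["sd"].mean()
        hi = t.iloc[-len(t) // 4 :]["sd"].mean()
        assert lo < hi
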