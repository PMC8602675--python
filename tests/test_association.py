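"""Log-log regression, elasticities, and the rank-based tests."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from airburden import (
    ArgumentError,
    DomainError,
    SyntheticConfig,
    dunn_exact,
    dunn_posthoc,
    elasticity,
    fit_loglog,
    generate_panel,
    kruskal_wallis,
    kruskal_wallis_exact,
    spearman,
)

from conftest import end_year_slice


class TestFitLoglog:
    def test_noiseless_identity(self, noiseless_panel):
        e = end_year_slice(noiseless_panel)
        fit = fit_loglog(
            e["yll_rate"].to_numpy(),
            {"apm25": e["apm25"].to_numpy(), "hap": e["hap"].to_numpy()},
        )
        assert fit.intercept == pytest.approx(2.476, abs=1e-8)
        assert fit.coef["apm25"] == pytest.approx(1.623, abs=1e-8)
        assert fit.coef["hap"] == pytest.approx(0.15, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_four_point_exact_solution(self):
        # (apm25, hap, yll) rows solve to intercept 0, slopes (1, 0), R^2 = 1
        e = math.e
        x1 = np.array([e, e**2, e, e**2])
        x2 = np.array([1.0, 1.0, e, e])
        y = np.array([e, e**2, e, e**2])
        fit = fit_loglog(y, {"x1": x1, "x2": x2})
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.coef["x1"] == pytest.approx(1.0, abs=1e-12)
        assert fit.coef["x2"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_statsmodels_oracle(self, default_panel):
        sm = pytest.importorskip("statsmodels.api")
        e = end_year_slice(default_panel)
        fit = fit_loglog(
            e["yll_rate"].to_numpy(),
            {"apm25": e["apm25"].to_numpy(), "hap": e["hap"].to_numpy()},
        )
        X = sm.add_constant(np.column_stack([np.log(e["apm25"]), np.log(e["hap"])]))
        ref = sm.OLS(np.log(e["yll_rate"].to_numpy()), X).fit()
        assert fit.intercept == pytest.approx(ref.params[0], rel=1e-8)
        assert fit.coef["apm25"] == pytest.approx(ref.params[1], rel=1e-8)
        assert fit.coef["hap"] == pytest.approx(ref.params[2], rel=1e-8)
        assert fit.se["apm25"] == pytest.approx(ref.bse[1], rel=1e-8)
        assert fit.r_squared == pytest.approx(ref.rsquared, rel=1e-10)
        assert fit.f_stat == pytest.approx(ref.fvalue, rel=1e-8)
        assert fit.p_values["apm25"] == pytest.approx(ref.pvalues[1], rel=1e-6)

    def test_residuals_orthogonal_to_design(self, default_panel):
        e = end_year_slice(default_panel)
        fit = fit_loglog(
            e["yll_rate"].to_numpy(),
            {"apm25": e["apm25"].to_numpy(), "hap": e["hap"].to_numpy()},
        )
        inner = fit.design.T @ fit.residuals
        scale = np.linalg.norm(fit.design, axis=0) * np.linalg.norm(fit.residuals)
        assert np.all(np.abs(inner) <= 1e-8 * np.maximum(scale, 1.0))
        assert fit.df_resid == fit.n - 3

    def test_nonpositive_values_error_not_offset(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        with pytest.raises(DomainError):
            fit_loglog(y, {"x": np.array([1.0, 2.0, 0.0, 4.0, 5.0])})
        with pytest.raises(DomainError):
            fit_loglog(-y, {"x": y})

    def test_rank_deficient_design_errors(self):
        y = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        with pytest.raises(DomainError):
            fit_loglog(y, {"x1": x, "x2": x**2 / x})  # identical columns

    def test_irrelevant_predictor_barely_moves_r_squared(self):
        """A predictor with true zero coefficient changes R^2 by < 0.01 on a
        large sample (the rationale for excluding a pollutant that shows no
        relation to the outcome)."""
        rng = np.random.default_rng(7)
        n = 4000
        x1 = rng.lognormal(2.5, 0.5, n)
        z = rng.lognormal(3.5, 0.3, n)  # true coefficient zero
        y = np.exp(2.476 + 1.623 * np.log(x1) + rng.normal(0, 0.3, n))
        full = fit_loglog(y, {"x1": x1, "z": z})
        restricted = fit_loglog(y, {"x1": x1})
        assert abs(full.r_squared - restricted.r_squared) < 0.01


class TestElasticity:
    def test_unit_coefficient_is_identity(self):
        for p in (0.05, 0.10, 0.5):
            assert elasticity(1.0, p) == pytest.approx(100 * p)

    def test_headline_elasticities(self):
        assert round(elasticity(1.623, 0.10), 1) == 16.7
        assert round(elasticity(0.15, 0.10), 1) == 1.4

    def test_domain(self):
        with pytest.raises(ArgumentError):
            elasticity(1.0, -1.0)


class TestSpearman:
    def test_perfect_monotone(self):
        x = np.arange(1.0, 11.0)
        assert spearman(x, x**3).statistic == pytest.approx(1.0)
        assert spearman(x, -np.sqrt(x)).statistic == pytest.approx(-1.0)

    def test_hand_ranked_case(self):
        res = spearman([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(3)
        x = rng.integers(0, 6, 40).astype(float)  # heavy ties
        y = x + rng.normal(0, 1.5, 40)
        res = spearman(x, y)
        ref_r, ref_p = stats.spearmanr(x, y)
        assert res.statistic == pytest.approx(ref_r, rel=1e-12)
        assert res.p_value == pytest.approx(ref_p, rel=1e-8)

    @given(st.floats(0.1, 3.0))
    def test_invariant_under_monotone_transform(self, power):
        rng = np.random.default_rng(11)
        x = rng.uniform(1, 10, 25)
        y = rng.uniform(1, 10, 25)
        base = spearman(x, y).statistic
        assert spearman(x**power, np.exp(y / 10)).statistic == pytest.approx(base)

    def test_constant_vector_errors(self):
        with pytest.raises(DomainError):
            spearman([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])


class TestKruskalWallis:
    def test_identical_groups_give_zero(self):
        g = [1.0, 2.0, 3.0]
        assert kruskal_wallis([g, g, g]).statistic == pytest.approx(0.0)

    def test_matches_direct_formula_and_scipy(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        res = kruskal_wallis(groups)
        # brute-force rank-sum formula (no ties): H = 12/(N(N+1)) sum R_i^2/n_i - 3(N+1)
        n = 9
        rank_sums = [6.0, 15.0, 24.0]
        h = 12.0 / (n * (n + 1)) * sum(r**2 / 3 for r in rank_sums) - 3 * (n + 1)
        assert res.statistic == pytest.approx(h, abs=1e-12)
        ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)
        # the 5% chi-square(2) boundary sits at 5.991
        assert (res.p_value < 0.05) == (res.statistic > stats.chi2.ppf(0.95, 2))

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        ref = stats.kruskal(*groups)
        assert res.statistic == pytest.approx(ref.statistic, rel=1e-12)

    def test_two_group_case_is_squared_rank_sum_z(self):
        g1 = [1.2, 3.4, 5.6, 7.8, 2.2]
        g2 = [9.1, 10.4, 12.2, 8.8]
        res = kruskal_wallis([g1, g2])
        z = stats.ranksums(g1, g2).statistic
        assert res.statistic == pytest.approx(z**2, rel=1e-10)

    def test_argument_errors(self):
        with pytest.raises(ArgumentError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ArgumentError):
            kruskal_wallis([[1.0], [2.0], []])


class TestDunn:
    def test_identical_groups_all_null(self):
        g = [1.0, 2.0, 3.0]
        for res in dunn_posthoc([g, g, g]):
            assert res.statistic == pytest.approx(0.0)
            assert res.adjusted_p == 1.0

    def test_three_groups_three_pairs_bonferroni(self):
        groups = [[1.0, 2.0], [3.0, 4.0], [5.0, 6.0]]
        out = dunn_posthoc(groups, labels=["a", "b", "c"])
        assert len(out) == 3
        assert {r.pair for r in out} == {("a", "b"), ("a", "c"), ("b", "c")}
        for r in out:
            assert r.adjusted_p == pytest.approx(min(1.0, 3 * r.p_value))
            assert r.adjusted_p >= r.p_value

    def test_well_separated_groups_match_permutation_oracle(self):
        """Normal-approximation adjusted p agrees with the exact permutation
        oracle in ordering and flags the separated pair in both routes."""
        groups = [[1.0, 2.0, 3.0], [2.5, 3.5, 4.5], [10.0, 12.0, 14.0]]
        approx = dunn_posthoc(groups)
        exact = dunn_exact(groups)
        for a, e in zip(approx, exact):
            assert a.statistic == pytest.approx(e.statistic, abs=1e-12)
        # extreme pair (group1 vs group3) most significant under both
        a_order = np.argsort([r.p_value for r in approx])
        e_order = np.argsort([r.p_value for r in exact])
        assert a_order[0] == e_order[0]


class TestExactOracles:
    def test_exact_h_equals_approx_h(self):
        groups = [[3.1, 4.2, 1.0], [5.5, 6.6, 2.2], [9.9, 7.7, 8.8]]
        assert kruskal_wallis_exact(groups).statistic == pytest.approx(
            kruskal_wallis(groups).statistic, abs=1e-12
        )

    def test_exact_p_is_a_valid_permutation_fraction(self):
        groups = [[1.0, 5.0, 3.0], [2.0, 8.0, 9.0], [4.0, 6.0, 7.0]]
        res = kruskal_wallis_exact(groups)
        # 9!/(3!3!3!) = 1680 labelled assignments
        assert 0 < res.p_value <= 1
        assert res.p_value * 1680 == pytest.approx(round(res.p_value * 1680))

    def test_exact_limited_to_small_n(self):
        with pytest.raises(ArgumentError):
            kruskal_wallis_exact([list(range(6)), list(range(6))])


def test_slope_recovery_within_three_se(default_panel):
    """Default synthetic world: the fitted PM2.5 slope lands within 3
    estimated standard errors of the structural 1.623."""
    e = end_year_slice(default_panel)
    fit = fit_loglog(
        e["yll_rate"].to_numpy(),
        {"apm25": e["apm25"].to_numpy(), "hap": e["hap"].to_numpy()},
    )
    assert abs(fit.coef["apm25"] - 1.623) <= 3 * fit.se["apm25"]
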