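import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from adipoquant.stats import (
    assign_frax_group,
    bland_altman,
    brown_forsythe_anova,
    build_design,
    heteroscedastic_anova,
    kruskal_wallis,
    pearson_matrix,
    stepwise_interaction_fit,
    summarize_cohort,
    welch_anova,
)


class TestFraxGroups:
    @pytest.mark.parametrize("frax,expect", [
        (7.6, "LOW"), (25.0, "HIGH"), (9.999, "LOW"),
        (10.0, "MOD"), (20.0, "MOD"), (15.0, "MOD"), (0.0, "LOW"),
    ])
    def test_stratification(self, frax, expect):
        assert assign_frax_group(frax) == expect

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            assign_frax_group(-1.0)

    @given(st.floats(min_value=0, max_value=60, allow_nan=False))
    def test_partition(self, frax):
        """Every non-negative FRAX value maps to exactly one stratum."""
        assert assign_frax_group(frax) in ("LOW", "MOD", "HIGH")


class TestSummaries:
    @staticmethod
    def _two_point_group(mean, sd, group, var="frax"):
        # n=2 sample with exact mean and sample SD
        d = sd / np.sqrt(2)
        return pd.DataFrame({"group": group, var: [mean - d, mean + d]})

    @pytest.mark.parametrize("mean,sd,cv", [(7.6, 1.9, 25.0), (14.0, 2.7, 19.0)])
    def test_cv_formula(self, mean, sd, cv):
        df = self._two_point_group(mean, sd, "LOW")
        out = summarize_cohort(df, variables=("frax",))
        assert out["cv_pct"].iloc[0] == pytest.approx(100 * sd / mean, abs=1e-9)
        assert round(out["cv_pct"].iloc[0]) == pytest.approx(cv, abs=0.5)

    def test_constant_group_zero_cv(self):
        df = pd.DataFrame({"group": "LOW", "frax": [5.0, 5.0, 5.0]})
        out = summarize_cohort(df, variables=("frax",))
        assert out["sd"].iloc[0] == 0.0
        assert out["cv_pct"].iloc[0] == 0.0
        assert out["range"].iloc[0] == 0.0

    def test_zero_mean_flagged(self):
        df = pd.DataFrame({"group": "LOW", "frax": [-1.0, 1.0]})
        with pytest.warns(UserWarning, match="CV undefined"):
            out = summarize_cohort(df, variables=("frax",))
        assert np.isnan(out["cv_pct"].iloc[0])


class TestKruskalWallis:
    def test_hand_computed_rank_sum(self):
        """No ties: H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) = 7.2."""
        h, p = kruskal_wallis([1, 2, 3], [4, 5, 6], [7, 8, 9])
        assert h == pytest.approx(7.2, abs=1e-12)

    def test_identical_groups(self):
        h, p = kruskal_wallis([3, 3], [3, 3], [3, 3])
        assert h == 0.0 and p == 1.0

    def test_monotone_transform_invariance(self):
        g = ([1.0, 5.0, 2.0], [4.0, 8.0], [0.5, 9.0, 7.0])
        h1, _ = kruskal_wallis(*g)
        h2, _ = kruskal_wallis(*[np.exp(np.asarray(x)) for x in g])
        assert h1 == pytest.approx(h2, abs=1e-12)

    def test_chi2_p_near_exact_permutation_p(self):
        """Full-enumeration oracle at n=6: the chi-square approximation of
        the H-statistic p value is within 0.1 of the exact permutation p."""
        data = [1, 2, 3, 4, 5, 6]
        sizes = (2, 2, 2)
        h_obs, p_chi2 = kruskal_wallis(data[:2], data[2:4], data[4:])

        def h_of(perm):
            groups = [perm[:2], perm[2:4], perm[4:]]
            return kruskal_wallis(*groups)[0]

        hs = [h_of(p) for p in itertools.permutations(data)]
        p_exact = np.mean([h >= h_obs - 1e-12 for h in hs])
        assert abs(p_chi2 - p_exact) < 0.1


class TestHeteroscedasticAnova:
    def test_equal_means_zero_statistic(self):
        g1 = np.array([1.0, 3.0])     # mean 2
        g2 = np.array([-2.0, 6.0])    # mean 2
        g3 = np.array([1.5, 2.5])     # mean 2
        res = heteroscedastic_anova(g1, g2, g3)
        assert res["welch"].statistic == pytest.approx(0.0, abs=1e-12)
        assert res["brown_forsythe"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_two_groups_equal_welch_t_test(self):
        """Algebraic identity: two-group Welch ANOVA F = t^2 of Welch's
        t-test, with identical p."""
        rng = np.random.default_rng(5)
        a = rng.normal(0, 1, 14)
        b = rng.normal(0.8, 2.5, 9)
        res = welch_anova(a, b)
        t, p = sps.ttest_ind(a, b, equal_var=False)
        assert res.statistic == pytest.approx(t**2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)

    def test_matches_pingouin_reference(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(9)
        groups = [rng.normal(m, s, n) for m, s, n in
                  ((0, 1, 20), (0.5, 2, 25), (1, 0.5, 15))]
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [20, 25, 15]),
        })
        ref = pingouin.welch_anova(data=df, dv="y", between="g")
        res = welch_anova(*groups)
        assert res.statistic == pytest.approx(float(ref["F"][0]), rel=1e-9)
        assert res.p_value == pytest.approx(float(ref["p_unc"][0]), rel=1e-6)

    def test_brown_forsythe_formula_small_case(self):
        """Closed-form check of F* = sum n_i(m_i - m)^2 / sum (1-n_i/N)s_i^2."""
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 6.0])
        res = brown_forsythe_anova(a, b)
        num = 3 * (2.0 - 3.2) ** 2 + 2 * (5.0 - 3.2) ** 2
        den = (1 - 3 / 5) * 1.0 + (1 - 2 / 5) * 2.0
        assert res.statistic == pytest.approx(num / den, abs=1e-12)

    def test_degenerate_all_constant(self):
        res = welch_anova([2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0


class TestPearson:
    @staticmethod
    def _frame(x, y):
        df = pd.DataFrame({"a": x, "b": y})
        df["group"] = "LOW"
        return df

    def test_perfect_linear(self):
        x = np.arange(10.0)
        res = pearson_matrix(self._frame(x, 2 * x + 1), columns=("a", "b"))
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.significant.loc["a", "b"]

    def test_perfect_anticorrelation(self):
        x = np.arange(10.0)
        res = pearson_matrix(self._frame(x, -x), columns=("a", "b"))
        assert res.r.loc["a", "b"] == pytest.approx(-1.0)

    def test_p_matches_scipy(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=30), rng.normal(size=30)
        res = pearson_matrix(self._frame(x, y), columns=("a", "b"))
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.r.loc["a", "b"] == pytest.approx(r_ref, abs=1e-12)
        assert res.p.loc["a", "b"] == pytest.approx(p_ref, abs=1e-9)

    def test_monte_carlo_recovers_planted_rho(self):
        """Bivariate normal rho=0.54, n=42: mean estimated r within 0.03."""
        rng = np.random.default_rng(42)
        rho, n, reps = 0.54, 42, 1000
        rs = []
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + np.sqrt(1 - rho**2) * rng.standard_normal(n)
            rs.append(np.corrcoef(x, y)[0, 1])
        assert np.mean(rs) == pytest.approx(rho, abs=0.03)

    def test_constant_column_flagged(self):
        df = self._frame(np.ones(10), np.arange(10.0))
        with pytest.warns(UserWarning, match="constant"):
            res = pearson_matrix(df, columns=("a", "b"))
        assert np.isnan(res.r.loc["a", "b"])


def _planted_frame(rng, n=128, p=8, beta=None, interaction=None, sigma=0.1):
    X = rng.standard_normal((n, p))
    cols = [f"x{i}" for i in range(p)]
    df = pd.DataFrame(X, columns=cols)
    y = np.zeros(n)
    if beta:
        for c, b in beta.items():
            y += b * df[c]
    if interaction:
        (a, b), g = interaction
        y += g * df[a] * df[b]
    df["frax"] = y + sigma * rng.standard_normal(n)
    return df, cols


class TestStepwise:
    def test_planted_linear_truth_recovered(self):
        rng = np.random.default_rng(0)
        df, cols = _planted_frame(rng, beta={"x0": 3.0, "x1": -2.0})
        fit = stepwise_interaction_fit(df, predictors=tuple(cols), seed=0)
        assert {"x0", "x1"} <= set(fit.selected_terms)
        assert len(set(fit.selected_terms) - {"x0", "x1"}) <= 1

    def test_planted_pure_interaction_recovered(self):
        rng = np.random.default_rng(1)
        df, cols = _planted_frame(rng, n=200, interaction=(("x0", "x1"), 2.0))
        fit = stepwise_interaction_fit(df, predictors=tuple(cols), seed=0)
        assert "x0:x1" in fit.selected_terms

    def test_pure_noise_selects_little(self):
        rng = np.random.default_rng(2)
        sizes = []
        for _ in range(50):
            df, cols = _planted_frame(rng, sigma=1.0)
            fit = stepwise_interaction_fit(df, predictors=tuple(cols),
                                           seed=0, k=0)
            sizes.append(len(fit.selected_terms))
        assert np.median(sizes) <= 1

    def test_aic_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        df, cols = _planted_frame(rng, beta={"x0": 1.0, "x2": 0.5})
        fit = stepwise_interaction_fit(df, predictors=tuple(cols), seed=0)
        assert all(b <= a + 1e-9 for a, b in
                   zip(fit.aic_trace, fit.aic_trace[1:]))

    def test_forced_single_term_reduces_to_ols(self):
        """With interactions disabled and one forced term, the fit equals the
        closed-form normal-equations solution."""
        rng = np.random.default_rng(4)
        df, cols = _planted_frame(rng, p=3, beta={"x0": 2.0}, sigma=0.5)
        fit = stepwise_interaction_fit(
            df, predictors=("x0",), include_interactions=False,
            forced_terms=("x0",), k=0, seed=0)
        z = (df["x0"] - df["x0"].mean()) / df["x0"].std(ddof=0)
        X = np.column_stack([np.ones(len(df)), z])
        beta = np.linalg.solve(X.T @ X, X.T @ df["frax"].to_numpy())
        est = fit.coefficients.set_index("term")["estimate"]
        assert est["const"] == pytest.approx(beta[0], abs=1e-10)
        assert est["x0"] == pytest.approx(beta[1], abs=1e-10)

    def test_aic_matches_statsmodels(self):
        import statsmodels.api as sm

        from adipoquant.stats import _fit_rss, _gaussian_aic

        rng = np.random.default_rng(5)
        df, cols = _planted_frame(rng, p=3, beta={"x0": 1.0})
        X = sm.add_constant(df[["x0", "x1"]])
        ref = sm.OLS(df["frax"], X).fit()
        mine = _gaussian_aic(
            _fit_rss(X.to_numpy(), df["frax"].to_numpy()), len(df), 3)
        assert mine == pytest.approx(ref.aic, rel=1e-10)

    def test_cv_folds_partition_and_determinism(self):
        rng = np.random.default_rng(6)
        df, cols = _planted_frame(rng, beta={"x0": 3.0})
        f1 = stepwise_interaction_fit(df, predictors=tuple(cols), seed=7)
        f2 = stepwise_interaction_fit(df, predictors=tuple(cols), seed=7)
        assert f1.cv_scores == f2.cv_scores
        assert len(f1.cv_scores) == 5
        sizes = [len(fold) for fold in np.array_split(np.arange(len(df)), 5)]
        assert max(sizes) - min(sizes) <= 1

    def test_exact_collinearity_dropped(self):
        rng = np.random.default_rng(7)
        df, cols = _planted_frame(rng, p=3, beta={"x0": 1.0})
        df["x_dup"] = 2.0 * df["x0"] + 1.0  # same z-score as x0
        with pytest.warns(UserWarning, match="collinear"):
            design = build_design(df, predictors=("x0", "x1", "x2", "x_dup"),
                                  include_interactions=False)
        assert "x_dup" not in design.columns


class TestBlandAltman:
    def test_identity(self):
        ba = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert ba.bias == 0.0 and ba.loa_high - ba.loa_low == 0.0

    def test_constant_offset(self):
        ba = bland_altman([3.0, 4.0, 5.0], [1.0, 2.0, 3.0])
        assert ba.bias == pytest.approx(2.0)
        assert ba.loa_high - ba.loa_low == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_differences_loa(self):
        rng = np.random.default_rng(8)
        actual = np.zeros(10_000)
        pred = rng.standard_normal(10_000)
        ba = bland_altman(pred, actual)
        assert ba.loa_high == pytest.approx(1.96, abs=0.05)
        assert ba.loa_low == pytest.approx(-1.96, abs=0.05)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [1.0])
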