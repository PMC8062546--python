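"""Statistical battery: t-tests, Fisher exact, ANOVAs, mixed models, regressions."""

import warnings

import numpy as np
import pandas as pd
import pytest

from shiftsense.stats import (
    fisher_exact_2x2,
    lmm_ema,
    rm_anova_2x6,
    std_regression,
    three_way_anova,
    two_sample_ttest,
)


class TestTwoSampleTTest:
    def test_identical_groups(self):
        res = two_sample_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.t == 0.0 and res.p == 1.0
        assert res.df == 4

    def test_clear_separation(self):
        res = two_sample_ttest([0.0, 0.001], [1.0, 1.001])
        assert abs(res.t) > 100 and res.p < 1e-4

    def test_matches_closed_form(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(0, 1, 12), rng.normal(0.4, 1.3, 9)
        res = two_sample_ttest(x, y)
        n1, n2 = len(x), len(y)
        sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        t_oracle = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        assert res.t == pytest.approx(t_oracle, abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError):
            two_sample_ttest([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            two_sample_ttest([2.0, 2.0], [2.0, 2.0])


class TestFisherExact:
    @pytest.mark.parametrize(
        "table,expected_or",
        [
            ([[51, 18], [31, 13]], 1.19),  # gender split
            ([[59, 10], [33, 11]], 1.97),  # highest degree
            ([[39, 30], [25, 19]], 0.99),  # native language
        ],
    )
    def test_cohort_contingency_tables(self, table, expected_or):
        res = fisher_exact_2x2(table)
        assert round(res.odds_ratio, 2) == expected_or

    def test_identical_rows(self):
        res = fisher_exact_2x2([[10, 5], [10, 5]])
        assert res.odds_ratio == 1.0 and res.p == pytest.approx(1.0)

    def test_transpose_invariance_and_row_swap(self):
        t = np.array([[12, 7], [5, 20]])
        a = fisher_exact_2x2(t)
        assert fisher_exact_2x2(t.T).odds_ratio == pytest.approx(a.odds_ratio)
        assert fisher_exact_2x2(t[::-1]).odds_ratio == pytest.approx(1 / a.odds_ratio)

    def test_zero_cell_reports_infinite(self):
        res = fisher_exact_2x2([[5, 0], [3, 4]])
        assert res.infinite and np.isinf(res.odds_ratio)
        assert 0 <= res.p <= 1


def _factor_frame(n, rng, outcome=None):
    df = pd.DataFrame(
        {
            "shift": rng.choice(["day", "night"], n),
            "age_group": rng.choice(["<40", ">=40"], n),
            "gender": rng.choice(["female", "male"], n),
        }
    )
    df["y"] = rng.normal(0, 1, n) if outcome is None else outcome
    return df


class TestThreeWayAnova:
    def test_planted_shift_effect_dominates(self):
        rng = np.random.default_rng(4)
        df = _factor_frame(80, rng)
        df["y"] = (df["shift"] == "night").astype(float) + rng.normal(0, 1e-6, 80)
        res = three_way_anova(df, "y")
        assert res.terms["shift"][0] > 1e6 and res.terms["shift"][3] < 1e-10
        assert res.terms["gender"][3] > 1e-3

    def test_constant_outcome_is_an_error(self):
        rng = np.random.default_rng(4)
        df = _factor_frame(40, rng, outcome=np.full(40, 3.0))
        with pytest.raises(ValueError, match="constant"):
            three_way_anova(df, "y")

    def test_balanced_design_matches_classical_decomposition(self):
        # 2x2x2 with 2 replicates; hand-computable balanced main-effects SS
        rows = []
        y = iter([3.0, 3.4, 4.1, 4.5, 5.0, 5.2, 6.3, 6.1, 2.0, 2.6, 3.3, 3.1, 4.2, 4.4, 5.5, 5.3])
        for shift in ("day", "night"):
            for age in ("<40", ">=40"):
                for gender in ("female", "male"):
                    for _ in range(2):
                        rows.append((shift, age, gender, next(y)))
        df = pd.DataFrame(rows, columns=["shift", "age_group", "gender", "y"])
        res = three_way_anova(df, "y")
        yv = df["y"].to_numpy()
        grand = yv.mean()
        # balanced design: SS_factor = sum_level n_level * (mean_level - grand)^2
        sse_terms = {}
        for factor in ("shift", "age_group", "gender"):
            ss = sum(
                len(g) * (g["y"].mean() - grand) ** 2 for _, g in df.groupby(factor)
            )
            sse_terms[factor] = ss
        fitted = grand + sum(
            df.groupby(f)["y"].transform("mean") - grand for f in ("shift", "age_group", "gender")
        )
        sse = ((df["y"] - fitted) ** 2).sum()
        df_resid = 16 - 4
        for factor in ("shift", "age_group", "gender"):
            f_oracle = (sse_terms[factor] / 1) / (sse / df_resid)
            assert res.terms[factor][0] == pytest.approx(f_oracle, rel=1e-8)
        # on a balanced design the EMMs equal the raw level means
        for level in ("day", "night"):
            raw = df.loc[df["shift"] == level, "y"].mean()
            assert res.emmeans["shift"][level][0] == pytest.approx(raw, abs=1e-10)

    def test_cis_contain_their_estimate(self):
        rng = np.random.default_rng(9)
        res = three_way_anova(_factor_frame(60, rng), "y")
        for factor in res.emmeans.values():
            for est, se, lo, hi in factor.values():
                assert lo < est < hi and se > 0


def _rm_long(rng, n_per_group, bin_means_day, bin_means_night, subject_sd=0.5, noise=0.3):
    rows = []
    for g, means in (("day", bin_means_day), ("night", bin_means_night)):
        for i in range(n_per_group):
            pid = f"{g}{i}"
            u = rng.normal(0, subject_sd)
            for b in range(6):
                rows.append((pid, g, b, means[b] + u + rng.normal(0, noise)))
    return pd.DataFrame(rows, columns=["participant_id", "shift", "bin", "value"])


class TestRmAnova:
    def test_compound_symmetry_leaves_epsilon_near_one(self):
        rng = np.random.default_rng(12)
        df = _rm_long(rng, 30, [0, 1, 2, 1, 0, 1], [0, 1, 2, 1, 0, 1])
        res = rm_anova_2x6(df)
        assert res.gg_epsilon > 0.8
        assert 1 / 5 < res.gg_epsilon <= 1.0 + 1e-9

    def test_correction_never_increases_df(self):
        rng = np.random.default_rng(13)
        base = rng.normal(0, 1, 6)
        df = _rm_long(rng, 20, base, base + 0.4, noise=0.8)
        # induce non-sphericity: scale one bin's noise
        df.loc[df["bin"] == 2, "value"] += rng.normal(0, 3.0, (df["bin"] == 2).sum())
        res = rm_anova_2x6(df, alpha_sphericity=1.0)  # force the corrected branch
        assert res.corrected
        for term in ("time", "shift:time"):
            df1c, df2c, _ = res.corrected[term]
            assert df1c <= res.terms[term][1] + 1e-12
            assert df2c <= res.terms[term][2] + 1e-12

    def test_inverted_diurnal_profiles_give_interaction(self):
        profile = np.array([0.05, 0.08, 0.45, 0.45, 0.4, 0.2])
        hits = 0
        for seed in range(5):
            rng = np.random.default_rng(100 + seed)
            df = _rm_long(rng, 25, profile, profile[::-1], subject_sd=0.05, noise=0.08)
            res = rm_anova_2x6(df)
            p = (
                res.corrected["shift:time"][2]
                if "shift:time" in res.corrected
                else res.terms["shift:time"][3]
            )
            hits += p < 0.01
        assert hits == 5

    def test_flat_profiles_are_null(self):
        small = 0
        for seed in range(5):
            rng = np.random.default_rng(200 + seed)
            df = _rm_long(rng, 20, np.zeros(6), np.zeros(6), subject_sd=0.3, noise=1.0)
            res = rm_anova_2x6(df)
            small += res.terms["shift:time"][3] < 0.05
        assert small <= 1

    def test_listwise_deletion_and_pairwise(self):
        rng = np.random.default_rng(14)
        df = _rm_long(rng, 10, np.zeros(6), np.ones(6))
        df = df[~((df["participant_id"] == "day0") & (df["bin"] == 3))]  # incomplete subject
        res = rm_anova_2x6(df)
        assert res.n_per_group == {"day": 9, "night": 10}
        assert set(res.pairwise) == {"0", "1", "2", "3", "4", "5"}


class TestMixedModel:
    @staticmethod
    def _simulate(rng, n_subjects=30, n_obs=14, intercept_sd=0.0, work_effect=0.5):
        rows = []
        for i in range(n_subjects):
            shift = "day" if i < n_subjects // 2 else "night"
            u = rng.normal(0, intercept_sd) if intercept_sd else 0.0
            for j in range(n_obs):
                status = "workday" if j % 2 else "offday"
                y = 2.0 + work_effect * (status == "workday") + u + rng.normal(0, 1)
                rows.append((f"P{i}", shift, status, y))
        return pd.DataFrame(rows, columns=["participant_id", "shift", "status", "y"])

    def test_zero_variance_matches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        df = self._simulate(rng, intercept_sd=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lmm_ema(df, "y", min_emas=5)
        X = pd.DataFrame(
            {
                "d": (df["shift"] == "day").astype(float),
                "w": (df["status"] == "workday").astype(float),
            }
        )
        X["dw"] = X["d"] * X["w"]
        ols = sm.OLS(df["y"], sm.add_constant(X)).fit()
        assert res.fixed["intercept"][0] == pytest.approx(ols.params["const"], abs=1e-6)
        assert res.fixed["status[workday]"][0] == pytest.approx(ols.params["w"], abs=1e-6)
        assert res.random_intercept_var < 0.1  # little between-participant variance found

    def test_short_series_participants_excluded(self):
        rng = np.random.default_rng(22)
        df = self._simulate(rng, n_subjects=20, n_obs=14, intercept_sd=0.4)
        extra = pd.DataFrame(
            {
                "participant_id": "P_short",
                "shift": "day",
                "status": ["workday"] * 9,
                "y": rng.normal(0, 1, 9),
            }
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lmm_ema(pd.concat([df, extra], ignore_index=True), "y", min_emas=10)
        assert res.n_excluded == 1
        assert res.n_participants == 20

    def test_recovers_planted_effect(self):
        rng = np.random.default_rng(23)
        df = self._simulate(rng, n_subjects=60, n_obs=20, intercept_sd=0.6, work_effect=0.5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = lmm_ema(df, "y", min_emas=5)
        est, se, t, dof, p = res.fixed["status[workday]"]
        assert est == pytest.approx(0.5, abs=3 * se)
        assert res.random_intercept_var > 0.1
        assert dof == res.n_obs - 4


class TestStdRegression:
    @staticmethod
    def _frame(rng, n=60):
        return pd.DataFrame(
            {
                "shift": rng.choice(["day", "night"], n),
                "age_group": rng.choice(["<40", ">=40"], n),
                "gender": rng.choice(["female", "male"], n),
                "x": rng.normal(0, 2, n),
            }
        )

    def test_outcome_equal_to_feature(self):
        rng = np.random.default_rng(31)
        df = self._frame(rng)
        df["y"] = df["x"]
        res = std_regression(df, "y", "x")
        assert res.terms["x"][0] == pytest.approx(1.0, abs=1e-6)
        assert res.adj_r2 == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(32)
        df = self._frame(rng, n=20)
        df["y"] = rng.normal(0, 1, 20)
        res = std_regression(df, "y", "x")
        z = lambda v: (v - v.mean()) / v.std(ddof=1)
        X = np.column_stack(
            [
                np.ones(20),
                (df["age_group"] == "<40").astype(float),
                (df["gender"] == "female").astype(float),
                (df["shift"] == "day").astype(float),
                z(df["x"]),
                (df["shift"] == "day").astype(float) * z(df["x"]),
            ]
        )
        beta = np.linalg.solve(X.T @ X, X.T @ z(df["y"]))
        fitted = [
            res.terms[t][0]
            for t in ("intercept", "age[<40]", "gender[female]", "shift[day]", "x", "shift[day]:x")
        ]
        np.testing.assert_allclose(fitted, beta, atol=1e-8)

    def test_perfect_collinearity_detected(self):
        rng = np.random.default_rng(33)
        df = self._frame(rng)
        df["gender"] = np.where(df["shift"] == "day", "female", "male")
        df["y"] = rng.normal(0, 1, len(df))
        with pytest.raises(ValueError, match="collinear"):
            std_regression(df, "y", "x")

    def test_recovers_negative_shift_interaction_sign(self):
        """Day-shift x walking coupling on life satisfaction: sign recovered."""
        hits = 0
        rng = np.random.default_rng(34)
        for _ in range(100):
            n = 113
            day = rng.random(n) < 69 / 113
            zwalk = rng.normal(0, 1, n)
            y = 0.26 * 1.2 * zwalk - 0.62 * 1.2 * zwalk * day + rng.normal(0, 1, n)
            df = pd.DataFrame(
                {
                    "shift": np.where(day, "day", "night"),
                    "age_group": rng.choice(["<40", ">=40"], n),
                    "gender": rng.choice(["female", "male"], n),
                    "x": zwalk,
                    "y": y,
                }
            )
            res = std_regression(df, "y", "x")
            hits += res.terms["shift[day]:x"][0] < 0
        assert hits >= 90
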