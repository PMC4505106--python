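"""Statistical machinery against independent oracles: brute-force SS
decompositions, paired-t identity, closed-form Scheffé, normal equations,
re-centered refits, and pingouin as an external cross-check."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from nirslat.inference import (
    ModeratedRegression,
    hierarchical_regression,
    mixed_anova,
    oneway_anova,
    scheffe_posthoc,
    simple_effect_within,
    simple_slope_by_refit,
    simple_slopes,
)


def _mixed_data(rng, ns=(4, 3, 5), loc_effect=0.5, group_effect=1.0):
    rows = []
    for gi, (g, n) in enumerate(zip("ABC", ns)):
        for i in range(n):
            base = rng.normal(gi * group_effect, 1.0)
            rows.append(
                {
                    "participant_id": f"{g}{i}",
                    "group": g,
                    "right": base + rng.normal(),
                    "left": base + loc_effect + rng.normal(),
                }
            )
    return pd.DataFrame(rows)


def _brute_force_mixed_ss(df):
    """Naive loop-based split-plot SS decomposition (weighted means)."""
    y = {}
    for row in df.itertuples():
        y[(row.participant_id, "right")] = row.right
        y[(row.participant_id, "left")] = row.left
    subjects = list(df.participant_id)
    group_of = dict(zip(df.participant_id, df.group))
    locs = ["right", "left"]
    allv = list(y.values())
    grand = sum(allv) / len(allv)
    groups = sorted(set(group_of.values()))

    def mean(vals):
        vals = list(vals)
        return sum(vals) / len(vals)

    subj_mean = {s: mean(y[(s, l)] for l in locs) for s in subjects}
    grp_mean = {
        g: mean(y[(s, l)] for s in subjects if group_of[s] == g for l in locs)
        for g in groups
    }
    loc_mean = {l: mean(y[(s, l)] for s in subjects) for l in locs}
    cell = {
        (g, l): mean(y[(s, l)] for s in subjects if group_of[s] == g)
        for g in groups
        for l in locs
    }
    n_g = {g: sum(1 for s in subjects if group_of[s] == g) for g in groups}
    ss = {}
    ss["group"] = 2 * sum(n_g[g] * (grp_mean[g] - grand) ** 2 for g in groups)
    ss["subjects_within_group"] = 2 * sum(
        (subj_mean[s] - grp_mean[group_of[s]]) ** 2 for s in subjects
    )
    ss["location"] = len(subjects) * sum(
        (loc_mean[l] - grand) ** 2 for l in locs
    )
    ss["group_x_location"] = sum(
        n_g[g] * (cell[(g, l)] - grp_mean[g] - loc_mean[l] + grand) ** 2
        for g in groups
        for l in locs
    )
    ss["location_x_subjects"] = sum(
        (
            y[(s, l)]
            - cell[(group_of[s], l)]
            - subj_mean[s]
            + grp_mean[group_of[s]]
        )
        ** 2
        for s in subjects
        for l in locs
    )
    ss["total"] = sum((v - grand) ** 2 for v in allv)
    return ss


class TestMixedAnova:
    def test_identical_within_levels_give_zero_location_ss(self, rng):
        df = _mixed_data(rng)
        df["left"] = df["right"]
        res = mixed_anova(df)
        assert res["location"].ss == pytest.approx(0.0, abs=1e-12)
        assert res["location"].F == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_decomposition(self, rng):
        df = _mixed_data(rng, ns=(5, 4, 3))
        res = mixed_anova(df)
        brute = _brute_force_mixed_ss(df)
        for effect in (
            "group",
            "subjects_within_group",
            "location",
            "group_x_location",
            "location_x_subjects",
        ):
            assert res[effect].ss == pytest.approx(brute[effect], abs=1e-8)

    def test_ss_conservation(self, rng):
        df = _mixed_data(rng, ns=(6, 5, 7))
        res = mixed_anova(df)
        parts = sum(e.ss for e in res.effects.values())
        assert parts == pytest.approx(res.ss_total, abs=1e-8)

    def test_degrees_of_freedom_for_103_participants(self, rng):
        df = _mixed_data(rng, ns=(42, 35, 26))
        res = mixed_anova(df)
        assert res["group"].df == (2, 100)
        assert res["location"].df == (1, 100)
        assert res["group_x_location"].df == (2, 100)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        for ns in [(5, 5, 5), (6, 4, 8)]:
            df = _mixed_data(rng, ns=ns)
            res = mixed_anova(df)
            long = df.melt(
                id_vars=["participant_id", "group"],
                value_vars=["right", "left"],
                var_name="loc",
            )
            ref = pg.mixed_anova(
                data=long, dv="value", within="loc", between="group",
                subject="participant_id",
            ).set_index("Source")
            assert res["group"].F == pytest.approx(ref.loc["group", "F"])
            assert res["location"].F == pytest.approx(ref.loc["loc", "F"])
            assert res["group_x_location"].F == pytest.approx(
                ref.loc["Interaction", "F"]
            )

    def test_missing_value_names_subject(self, rng):
        df = _mixed_data(rng)
        df.loc[2, "left"] = np.nan
        with pytest.raises(ValueError, match=df.loc[2, "participant_id"]):
            mixed_anova(df)

    def test_two_level_between_factor_supported(self, rng):
        df = _mixed_data(rng, ns=(6, 5))[lambda d: d.group.isin(["A", "B"])]
        res = mixed_anova(df)
        assert res["group"].df == (1, 9)


class TestSimpleEffect:
    def test_equal_sides_give_zero_f(self):
        v = np.arange(5.0)
        res = simple_effect_within(v, v)
        assert res["location"].F == 0.0

    def test_f_equals_squared_paired_t(self, rng):
        a = rng.standard_normal(20)
        b = a + 0.3 + 0.5 * rng.standard_normal(20)
        res = simple_effect_within(a, b)
        t, p = stats.ttest_rel(a, b)
        assert res["location"].F == pytest.approx(t**2, abs=1e-10)
        assert res["location"].p == pytest.approx(p, abs=1e-12)

    def test_denominator_df_is_n_minus_1(self, rng):
        a = rng.standard_normal(35)
        b = rng.standard_normal(35)
        assert simple_effect_within(a, b)["location"].df == (1, 34)

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            simple_effect_within([1.0], [2.0])


class TestOnewayAnova:
    def test_equal_observations_give_zero_f(self):
        res = oneway_anova({"a": np.ones(4), "b": np.ones(5)})
        assert res["group"].F == 0.0

    def test_df_for_103_in_3_groups(self, rng):
        res = oneway_anova(
            {
                "Low": rng.standard_normal(42),
                "Middle": rng.standard_normal(35),
                "High": rng.standard_normal(26),
            }
        )
        assert res["group"].df == (2, 100)

    def test_matches_scipy_f_oneway(self, rng):
        vals = {g: rng.standard_normal(n) + i for i, (g, n) in
                enumerate([("a", 8), ("b", 12), ("c", 6)])}
        res = oneway_anova(vals)
        F, p = stats.f_oneway(*vals.values())
        assert res["group"].F == pytest.approx(F, abs=1e-10)
        assert res["group"].p == pytest.approx(p, abs=1e-12)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            oneway_anova({"a": [1.0], "b": [1.0, 2.0]})


class TestScheffe:
    def test_two_groups_collapse_to_omnibus(self, rng):
        vals = {"a": rng.standard_normal(10), "b": rng.standard_normal(12) + 1}
        omnibus = oneway_anova(vals)
        sch = scheffe_posthoc(vals, omnibus)
        assert sch.p_adj("a", "b") == pytest.approx(omnibus["group"].p, abs=1e-12)

    def test_identical_means_give_p_one(self):
        vals = {"a": np.array([1.0, 2.0, 3.0]), "b": np.array([3.0, 2.0, 1.0]),
                "c": np.array([2.0, 1.0, 3.0])}
        sch = scheffe_posthoc(vals)
        assert np.allclose(sch.contrasts.p_adj, 1.0)

    def test_matches_closed_formula(self, rng):
        vals = {g: rng.standard_normal(n) + m for g, n, m in
                [("a", 9, 0.0), ("b", 14, 0.8), ("c", 11, 1.5)]}
        omnibus = oneway_anova(vals)
        sch = scheffe_posthoc(vals, omnibus)
        k = 3
        N = sum(len(v) for v in vals.values())
        mse = omnibus["error"].ms
        for _, row in sch.contrasts.iterrows():
            a, b = vals[row.group_a], vals[row.group_b]
            t2 = (a.mean() - b.mean()) ** 2 / (mse * (1 / len(a) + 1 / len(b)))
            expected = stats.f.sf(t2 / (k - 1), k - 1, N - k)
            assert row.p_adj == pytest.approx(expected, abs=1e-12)


def _moderated_sample(rng, n=60, b=(2000.0, -20.0, -300.0, -50.0), sd=150.0):
    age = rng.uniform(84, 153, n)
    lr = rng.normal(0.3, 0.3, n)
    age_c = age - age.mean()
    lr_c = lr - lr.mean()
    y = b[0] + b[1] * age_c + b[2] * lr_c + b[3] * age_c * lr_c
    y = y + sd * rng.standard_normal(n)
    return y, age, lr


class TestHierarchicalRegression:
    def test_pure_linear_outcome_gives_r2_one(self, rng):
        age = rng.uniform(84, 153, 30)
        lr = rng.normal(0, 0.3, 30)
        y = 100.0 - 5.0 * (age - age.mean())
        res = hierarchical_regression(y, age, lr)
        assert res.step1.r2 == pytest.approx(1.0)
        assert res.step1.beta_of("age_months") == pytest.approx(-1.0, abs=1e-8)

    def test_coefficients_match_normal_equations(self, rng):
        y, age, lr = _moderated_sample(rng)
        res = hierarchical_regression(y, age, lr)
        age_c = age - age.mean()
        lr_c = lr - lr.mean()
        for step, cols in [
            (res.step1, [age_c, lr_c]),
            (res.step2, [age_c, lr_c, age_c * lr_c]),
        ]:
            X = np.column_stack([np.ones_like(y)] + cols)
            b = np.linalg.solve(X.T @ X, X.T @ y)
            np.testing.assert_allclose(step.b, b, atol=1e-8)

    def test_r2_monotone_and_delta_consistent(self, rng):
        y, age, lr = _moderated_sample(rng)
        res = hierarchical_regression(y, age, lr)
        assert res.step2.r2 >= res.step1.r2
        assert res.step2.delta_r2 == pytest.approx(
            res.step2.r2 - res.step1.r2, abs=1e-12
        )
        assert res.step1.adj_r2 <= res.step1.r2
        assert res.step2.adj_r2 <= res.step2.r2

    def test_standardized_beta_convention(self, rng):
        y, age, lr = _moderated_sample(rng)
        res = hierarchical_regression(y, age, lr)
        st = res.step2
        i = st.terms.index("age_months_x_lr_index")
        expected = st.b[i] * res.sds["age_months_x_lr_index"] / res.sd_y
        assert st.beta[i] == pytest.approx(expected, abs=1e-12)

    def test_affine_invariance_under_month_to_year_rescale(self, rng):
        y, age, lr = _moderated_sample(rng)
        res_m = hierarchical_regression(y, age, lr)
        res_y = hierarchical_regression(y, age / 12.0, lr)
        assert res_y.step2.r2 == pytest.approx(res_m.step2.r2, abs=1e-8)
        assert res_y.step2.delta_r2 == pytest.approx(
            res_m.step2.delta_r2, abs=1e-8
        )
        i = res_m.step2.terms.index("age_months")
        assert res_y.step2.b[i] == pytest.approx(res_m.step2.b[i] * 12, rel=1e-8)
        np.testing.assert_allclose(
            res_y.step2.beta[1:], res_m.step2.beta[1:], atol=1e-8
        )

    def test_delta_r2_f_test_matches_anova_of_nested_models(self, rng):
        y, age, lr = _moderated_sample(rng)
        res = hierarchical_regression(y, age, lr)
        # oracle: direct RSS comparison
        age_c, lr_c = age - age.mean(), lr - lr.mean()
        X1 = np.column_stack([np.ones_like(y), age_c, lr_c])
        X2 = np.column_stack([X1, age_c * lr_c])
        rss = lambda X: np.sum(
            (y - X @ np.linalg.lstsq(X, y, rcond=None)[0]) ** 2
        )
        f = (rss(X1) - rss(X2)) / (rss(X2) / (len(y) - X2.shape[1]))
        assert res.step2.f_change == pytest.approx(f, rel=1e-8)

    def test_constant_predictor_rejected(self, rng):
        y = rng.standard_normal(20)
        with pytest.raises(ValueError, match="rank"):
            hierarchical_regression(y, np.full(20, 100.0), rng.standard_normal(20))

    def test_too_few_cases_rejected(self, rng):
        with pytest.raises(ValueError, match="complete cases"):
            hierarchical_regression(
                rng.standard_normal(5), rng.uniform(84, 153, 5),
                rng.standard_normal(5),
            )


class TestSimpleSlopes:
    def test_zero_interaction_gives_equal_slopes(self, rng):
        age = rng.uniform(84, 153, 50)
        lr = rng.normal(0, 0.3, 50)
        y = 1000.0 - 10.0 * (age - age.mean()) + 20 * rng.standard_normal(50)
        res = hierarchical_regression(y, age, lr)
        # force the interaction coefficient to exactly zero
        i = res.step2.terms.index("age_months_x_lr_index")
        res.step2.b[i] = 0.0
        ss = simple_slopes(res)
        assert ss.slope_at("+1sd").slope == pytest.approx(
            ss.slope_at("-1sd").slope, abs=1e-12
        )

    def test_matches_recentered_refit_oracle(self, rng):
        y, age, lr = _moderated_sample(rng)
        res = hierarchical_regression(y, age, lr)
        ss = simple_slopes(res)
        for label, m in (("+1sd", ss.moderator_sd), ("-1sd", -ss.moderator_sd)):
            refit = simple_slope_by_refit(y, age, lr, m)
            assert ss.slope_at(label).slope == pytest.approx(refit, abs=1e-10)

    def test_negative_interaction_steepens_high_moderator_slope(self, rng):
        y, age, lr = _moderated_sample(rng, b=(2000, -20, -300, -80), sd=50.0)
        res = hierarchical_regression(y, age, lr)
        ss = simple_slopes(res)
        assert ss.slope_at("+1sd").slope < ss.slope_at("-1sd").slope

    def test_se_from_covariance_matches_refit_se(self, rng):
        import statsmodels.api as sm

        y, age, lr = _moderated_sample(rng)
        res = hierarchical_regression(y, age, lr)
        ss = simple_slopes(res)
        m = ss.moderator_sd
        x1 = age - age.mean()
        x2 = lr - lr.mean() - m
        fit = sm.OLS(y, sm.add_constant(np.column_stack([x1, x2, x1 * x2]))).fit()
        assert ss.slope_at("+1sd").se == pytest.approx(fit.bse[1], abs=1e-10)
        assert ss.slope_at("+1sd").p == pytest.approx(fit.pvalues[1], abs=1e-10)


class TestModeratedRegressionEstimator:
    def test_fit_predict_round_trip(self, rng):
        y, age, lr = _moderated_sample(rng, sd=0.0)
        est = ModeratedRegression().fit(np.column_stack([age, lr]), y)
        np.testing.assert_allclose(
            est.predict(np.column_stack([age, lr])), y, atol=1e-6
        )
        assert est.score(np.column_stack([age, lr]), y) == pytest.approx(1.0)

    def test_sklearn_clone_compatible(self, rng):
        from sklearn.base import clone

        est = ModeratedRegression(feature_names=("age", "lat"))
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_exposes_simple_slopes(self, rng):
        y, age, lr = _moderated_sample(rng)
        est = ModeratedRegression(feature_names=("age_months", "lr_index")).fit(
            np.column_stack([age, lr]), y
        )
        assert set(est.simple_slopes_.table["at"]) == {"+1sd", "-1sd"}

    def test_wrong_shape_rejected(self, rng):
        with pytest.raises(ValueError):
            ModeratedRegression().fit(rng.standard_normal((10, 3)),
                                      rng.standard_normal(10))
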