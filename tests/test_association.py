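"""Summaries, ANOVA, adjusted linear models, and the ancillary logistic."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tracttraj.association import (
    LogTransformRegistry,
    anova_by_trajectory,
    fit_negative_trajectory_logistic,
    fit_trajectory_model,
    ols_many,
    run_battery,
    summarize,
    trajectory_design,
)
from tracttraj.trajectory import FIVE_LABELS


def _toy_table(n=30, seed=0, outcome="hypertension"):
    rng = np.random.default_rng(seed)
    labels = rng.choice([l.value for l in FIVE_LABELS], size=n)
    labels[:5] = [l.value for l in FIVE_LABELS]  # every level present
    quart = rng.choice(["Q1", "Q2", "Q3", "Q4"], size=n)
    quart[:4] = ["Q1", "Q2", "Q3", "Q4"]
    return pd.DataFrame(
        {
            "tract_id": [f"48{i:09d}" for i in range(n)],
            "poverty_trajectory": labels,
            "share_trajectory": rng.choice([l.value for l in FIVE_LABELS], size=n),
            "density_quartile": quart,
            outcome: rng.normal(30, 5, size=n),
        }
    )


class TestSummarize:
    def test_constant_column_has_degenerate_range(self):
        table = _toy_table()
        table["gini"] = 0.4
        s = summarize(table, measures=["gini"])
        row = s[s["variable"] == "gini"].iloc[0]
        assert (row["median"], row["range_low"], row["range_high"]) == (0.4, 0.4, 0.4)

    def test_trajectory_shares_sum_to_hundred(self, analytic):
        table, _ = analytic
        s = summarize(table)
        for section in ("poverty_trajectories", "share_trajectories"):
            total = s.loc[s["section"] == section, "percent"].sum()
            assert total == pytest.approx(100.0, abs=1e-9)

    def test_shares_track_generator_mixture(self, analytic, small_config):
        table, _ = analytic
        s = summarize(table)
        probs = small_config.trajectory_probs["poverty"]
        got = s[s["section"] == "poverty_trajectories"].set_index("variable")["percent"]
        for lab in FIVE_LABELS:
            assert got[lab.value] == pytest.approx(100 * probs[lab], abs=5.0)

    def test_median_uses_the_shared_percentile_convention(self):
        table = _toy_table(n=40, seed=2)
        s = summarize(table, measures=["hypertension"])
        med = s.iloc[0]["median"]
        assert med == np.percentile(table["hypertension"], 50.0)

    def test_all_missing_column_reported_not_dropped(self):
        table = _toy_table()
        table["gini"] = np.nan
        s = summarize(table, measures=["gini"])
        assert s["variable"].tolist()[0] == "gini"
        assert np.isnan(s.iloc[0]["median"])


class TestAnova:
    def test_equal_group_means_give_zero_f(self):
        values = [1.0, 2.0, 3.0] * 3
        labels = ["a"] * 3 + ["b"] * 3 + ["c"] * 3
        res = anova_by_trajectory(values, labels)
        assert res.f_stat == pytest.approx(0.0, abs=1e-12)
        assert res.group_count == 3

    def test_two_groups_f_equals_squared_pooled_t(self):
        rng = np.random.default_rng(4)
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 15)
        res = anova_by_trajectory(
            np.concatenate([a, b]), ["x"] * 12 + ["y"] * 15
        )
        t, _ = stats.ttest_ind(a, b, equal_var=True)
        assert res.f_stat == pytest.approx(t**2, rel=1e-12)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError, match="2 non-empty groups"):
            anova_by_trajectory([1.0, 2.0], ["a", "a"])

    def test_missing_outcomes_dropped_pairwise(self):
        values = [1.0, np.nan, 3.0, 4.0]
        res = anova_by_trajectory(values, ["a", "a", "b", "b"])
        assert res.n == 3


class TestLinearModel:
    def test_matches_normal_equations_on_thirty_tracts(self):
        table = _toy_table(n=30, seed=5)
        res = fit_trajectory_model(table, "hypertension", registry=LogTransformRegistry({}))
        X, terms = trajectory_design(table)
        Xm = X.to_numpy()
        y = table["hypertension"].to_numpy()
        beta = np.linalg.solve(Xm.T @ Xm, Xm.T @ y)
        resid = y - Xm @ beta
        sigma2 = resid @ resid / (len(y) - Xm.shape[1])
        ses = np.sqrt(sigma2 * np.diag(np.linalg.inv(Xm.T @ Xm)))
        by_name = dict(zip(X.columns, zip(beta, ses)))
        assert res.intercept == pytest.approx(by_name["const"][0], abs=1e-10)
        for t in res.terms:
            assert t.beta == pytest.approx(by_name[t.term][0], abs=1e-10)
            assert t.se == pytest.approx(by_name[t.term][1], abs=1e-10)

    def test_log_transform_applies_exactly_to_registry_members(self):
        table = _toy_table(n=60, seed=6)
        table["crowded_housing"] = np.abs(table["hypertension"]) / 10
        in_reg = fit_trajectory_model(table, "crowded_housing")
        out_reg = fit_trajectory_model(
            table, "crowded_housing", registry=LogTransformRegistry({})
        )
        assert in_reg.log_transformed and not out_reg.log_transformed
        assert in_reg.terms[0].beta != pytest.approx(out_reg.terms[0].beta)
        # membership is exclusive: a non-registered outcome is untouched
        same = fit_trajectory_model(table, "hypertension")
        assert not same.log_transformed
        assert same.terms[0].beta == pytest.approx(
            fit_trajectory_model(
                table, "hypertension", registry=LogTransformRegistry({})
            ).terms[0].beta
        )

    def test_default_registry_membership(self):
        assert LogTransformRegistry().names == {
            "dist_ed", "dist_ob", "home_value",
            "crowded_housing", "public_assistance", "limited_english",
        }

    def test_absent_reference_level_aborts(self):
        table = _toy_table(n=30, seed=7)
        table["poverty_trajectory"] = "increasing"
        with pytest.raises(ValueError, match="reference level"):
            fit_trajectory_model(table, "hypertension")

    def test_empty_dummy_dropped_with_warning(self):
        table = _toy_table(n=40, seed=8)
        table.loc[table["poverty_trajectory"] == "decreasing", "poverty_trajectory"] = "increasing"
        with pytest.warns(UserWarning, match="dropped"):
            res = fit_trajectory_model(table, "hypertension", registry=LogTransformRegistry({}))
        assert "decreasing" in res.dropped
        assert "decreasing" not in [t.term for t in res.terms]

    def test_degenerate_density_drops_collinear_quartile_dummies(self):
        table = _toy_table(n=40, seed=9)
        table["density_quartile"] = "Q1"  # all tracts in one quartile
        with pytest.warns(UserWarning, match="dropped"):
            res = fit_trajectory_model(table, "hypertension", registry=LogTransformRegistry({}))
        assert {"Q1", "Q2", "Q3"} <= set(res.dropped)

    def test_ols_many_agrees_with_single_fits(self):
        table = _toy_table(n=50, seed=10)
        X, _ = trajectory_design(table)
        rng = np.random.default_rng(11)
        Y = rng.normal(0, 1, size=(50, 3))
        betas, ses, pvals = ols_many(X.to_numpy(), Y)
        for j in range(3):
            tbl = table.copy()
            tbl["hypertension"] = Y[:, j]
            res = fit_trajectory_model(tbl, "hypertension", registry=LogTransformRegistry({}))
            got = {t.term: t for t in res.terms}
            for i, name in enumerate(X.columns):
                if name == "const":
                    continue
                assert betas[i, j] == pytest.approx(got[name].beta, abs=1e-10)
                assert ses[i, j] == pytest.approx(got[name].se, abs=1e-10)
                assert pvals[i, j] == pytest.approx(got[name].p, abs=1e-10)


class TestBattery:
    def test_two_exposures_times_26_outcomes(self, analytic):
        table, _ = analytic
        battery = run_battery(table)
        assert len(battery.models) == 52
        assert len(battery.anovas) == 52
        assert battery.models_frame("poverty").shape[0] == 26

    def test_flags_monotone_in_alpha(self, analytic):
        table, _ = analytic
        strict = run_battery(table, alpha=0.001)
        loose = run_battery(table, alpha=0.05)

        def flagged(b):
            return {
                (m.outcome, m.exposure, t.term)
                for m in b.models
                for t in m.terms
                if t.significant
            }

        assert flagged(strict) <= flagged(loose)

    def test_unknown_outcome_rejected(self, analytic):
        table, _ = analytic
        with pytest.raises(ValueError, match="absent from table"):
            run_battery(table, outcomes=["not_a_measure"])


class TestNegativeTrajectoryLogistic:
    def _table(self, n, seed, coupled):
        rng = np.random.default_rng(seed)
        pov = rng.choice([l.value for l in FIVE_LABELS], size=n)
        if coupled:
            share = np.where(
                np.isin(pov, ["long_term_high", "increasing"]) & (rng.random(n) < 0.8),
                "long_term_low",
                rng.choice([l.value for l in FIVE_LABELS], size=n),
            )
        else:
            share = rng.choice([l.value for l in FIVE_LABELS], size=n)
        return pd.DataFrame(
            {"poverty_trajectory": pov, "share_trajectory": share,
             "density_quartile": rng.choice(["Q1", "Q2", "Q3", "Q4"], size=n)}
        )

    def test_independent_labels_give_or_near_one(self):
        res = fit_negative_trajectory_logistic(self._table(4000, 12, coupled=False))
        for level in res.levels:
            assert res.ci_lower[level] < 1.0 < res.ci_upper[level]

    def test_collapsed_two_by_two_equals_cross_product_ratio(self):
        table = self._table(2000, 13, coupled=True)
        sub = table[table["share_trajectory"].isin(["long_term_low", "long_term_high"])]
        res = fit_negative_trajectory_logistic(sub)
        y = sub["poverty_trajectory"].isin(["long_term_high", "increasing"])
        x = sub["share_trajectory"] == "long_term_low"
        a = (y & x).sum()
        b = (~y & x).sum()
        c = (y & ~x).sum()
        d = (~y & ~x).sum()
        assert res.odds_ratios["long_term_low"] == pytest.approx(a * d / (b * c), abs=1e-8)

    def test_strong_coupling_yields_large_or_with_ci_excluding_one(self):
        res = fit_negative_trajectory_logistic(self._table(4000, 14, coupled=True))
        assert res.odds_ratios["long_term_low"] > 3.0
        assert res.ci_lower["long_term_low"] > 1.0

    def test_one_outcome_class_rejected(self):
        table = self._table(100, 15, coupled=False)
        table["poverty_trajectory"] = "long_term_low"
        with pytest.raises(ValueError, match="both outcome classes"):
            fit_negative_trajectory_logistic(table)

    def test_perfect_separation_flagged(self):
        n = 200
        pov = np.array(["long_term_high"] * 100 + ["long_term_low"] * 100)
        share = np.array(["long_term_low"] * 100 + ["long_term_high"] * 100)
        table = pd.DataFrame({"poverty_trajectory": pov, "share_trajectory": share,
                              "density_quartile": ["Q1"] * n})
        res = fit_negative_trajectory_logistic(table)
        assert res.separation
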