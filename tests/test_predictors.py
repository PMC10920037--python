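"""Screening, chained-equation imputation, multinomial regression, pooling."""

import warnings

import numpy as np
import pandas as pd
import pytest

from psytraj.predictors import (coefficient_frame, compute_vif, fit_multinomial,
                                mice_impute, nagelkerke_r2, pool_rubin,
                                run_predictor_analysis, screen_predictors)


def simulate_labels(X, beta, rng, classes=("ref", "b", "c")):
    """Draw class labels from a baseline-category logit model."""
    logits = np.column_stack([np.zeros(len(X)), X @ beta])
    p = np.exp(logits - logits.max(axis=1, keepdims=True))
    p /= p.sum(axis=1, keepdims=True)
    draws = (rng.random(len(X))[:, None] > p.cumsum(axis=1)).sum(axis=1)
    return pd.Series(np.asarray(classes)[draws])


class TestScreening:
    def test_identical_group_means_not_selected(self):
        rng = np.random.default_rng(0)
        x = np.tile(np.arange(100, dtype=float), 3)
        labels = pd.Series(np.repeat(["a", "b", "c"], 100))
        table = pd.DataFrame({"v": x + rng.normal(0, 1e-6, 300)})
        res = screen_predictors(table, labels, {"v": "continuous"})
        assert res.loc[0, "statistic"] == pytest.approx(0.0, abs=1e-4)
        assert not res.loc[0, "selected"]

    def test_chi_square_matches_hand_formula(self):
        """2x2 table (10,20 / 20,10): uncorrected statistic 20/3."""
        x = pd.Series([0] * 30 + [1] * 30)
        labels = pd.Series(["a"] * 10 + ["b"] * 20 + ["a"] * 20 + ["b"] * 10)
        res = screen_predictors(pd.DataFrame({"v": x}), labels, {"v": "binary"})
        assert res.loc[0, "statistic"] == pytest.approx(20.0 / 3.0)
        assert res.loc[0, "test"] == "chi_square"
        assert res.loc[0, "selected"]

    def test_anova_matches_direct_formula(self):
        rng = np.random.default_rng(1)
        labels = pd.Series(np.repeat(["a", "b", "c"], 40))
        x = rng.normal(0, 1, 120) + np.repeat([0.0, 0.4, -0.2], 40)
        res = screen_predictors(pd.DataFrame({"v": x}), labels, {"v": "continuous"})
        groups = [x[:40], x[40:80], x[80:]]
        grand = x.mean()
        ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f = (ssb / 2) / (ssw / 117)
        assert res.loc[0, "statistic"] == pytest.approx(f)

    def test_shifted_continuous_variable_detected(self):
        rng = np.random.default_rng(2)
        labels = pd.Series(np.repeat(["a", "b"], 250))
        x = rng.normal(0, 1, 500) + np.repeat([0.0, 1.0], 250)
        res = screen_predictors(pd.DataFrame({"v": x}), labels, {"v": "continuous"})
        assert res.loc[0, "selected"]

    def test_single_level_variable_excluded_with_reason(self):
        labels = pd.Series(["a", "b"] * 20)
        res = screen_predictors(pd.DataFrame({"v": [1.0] * 40}), labels,
                                {"v": "continuous"})
        assert not res.loc[0, "selected"]
        assert "single observed level" in res.loc[0, "reason"]


class TestMice:
    @staticmethod
    def gaussian_table(n=300, missing=0.0, seed=0):
        rng = np.random.default_rng(seed)
        x1 = rng.normal(size=n)
        x2 = 0.6 * x1 + rng.normal(0, 0.8, n)
        x3 = rng.binomial(1, 0.4, n).astype(float)
        labels = simulate_labels(np.column_stack([x1, x3]),
                                 np.array([[0.8, -0.3], [0.2, 0.5]]).T, rng)
        table = pd.DataFrame({"x1": x1, "x2": x2, "x3": x3})
        if missing:
            holes = rng.random(n) < missing
            table.loc[holes, "x2"] = np.nan
        return table, labels

    def test_complete_table_returns_identical_copies(self):
        table, labels = self.gaussian_table()
        stack = mice_impute(table, labels, m=4, seed=1)
        assert stack.m == 4
        for t in stack.tables:
            pd.testing.assert_frame_equal(t, table)

    def test_observed_cells_identical_across_imputations(self):
        table, labels = self.gaussian_table(missing=0.15, seed=3)
        stack = mice_impute(table, labels, m=5, iterations=3, seed=2)
        obs = table["x2"].notna()
        for t in stack.tables:
            np.testing.assert_array_equal(t.loc[obs, "x2"], table.loc[obs, "x2"])
            assert t["x2"].notna().all()
        # imputed cells differ between chains (stochastic draws)
        imp = np.column_stack([t.loc[~obs, "x2"] for t in stack.tables])
        assert (imp.std(axis=1) > 0).any()

    def test_mcar_imputation_tracks_complete_data_estimate(self):
        """Pooled coefficient near the complete-data fit under 10% MCAR."""
        full, labels = self.gaussian_table(n=1200, seed=4)
        ref = fit_multinomial(full, labels, "ref").params.loc["x1", "b"]
        holey = full.copy()
        rng = np.random.default_rng(5)
        holey.loc[rng.random(len(holey)) < 0.10, "x2"] = np.nan
        stack = mice_impute(holey, labels, m=8, iterations=4, seed=6)
        fits = [fit_multinomial(t, labels, "ref") for t in stack.tables]
        pooled = pool_rubin([coefficient_frame(f) for f in fits])
        assert pooled.loc[("b", "x1"), "Qbar"] == pytest.approx(ref, abs=0.1)

    def test_fully_missing_variable_rejected(self):
        table, labels = self.gaussian_table()
        table["x2"] = np.nan
        with pytest.raises(ValueError, match="x2"):
            mice_impute(table, labels, m=2)


class TestMultinomial:
    def test_single_binary_predictor_equals_contingency_odds_ratio(self):
        rng = np.random.default_rng(7)
        x = rng.binomial(1, 0.4, 600).astype(float)
        labels = simulate_labels(x[:, None], np.array([[0.9, -0.4]]), rng)
        fitted = fit_multinomial(pd.DataFrame({"x": x}), labels, "ref")
        for cls in ("b", "c"):
            sub = labels.isin(["ref", cls])
            a = ((labels == cls) & (x == 1) & sub).sum()
            b_ = ((labels == "ref") & (x == 1) & sub).sum()
            c_ = ((labels == cls) & (x == 0) & sub).sum()
            d = ((labels == "ref") & (x == 0) & sub).sum()
            assert np.exp(fitted.params.loc["x", cls]) == pytest.approx(
                (a * d) / (b_ * c_), rel=1e-4)

    def test_constant_column_raises_rank_error(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame({"x": rng.normal(size=100), "z": np.zeros(100)})
        labels = pd.Series(rng.choice(["ref", "b"], 100))
        with pytest.raises(ValueError, match="rank"):
            fit_multinomial(table, labels, "ref", standardize=False,
                            types={"x": "continuous", "z": "binary"})

    def test_coefficient_recovery_with_known_truth(self):
        """True log-OR 0.7 on one class: small bias, CI covers the truth."""
        rng = np.random.default_rng(9)
        estimates, covered = [], 0
        reps = 20
        for _ in range(reps):
            x = rng.binomial(1, 0.35, 3000).astype(float)
            labels = simulate_labels(x[:, None], np.array([[0.7, 0.0]]), rng)
            f = fit_multinomial(pd.DataFrame({"x": x}), labels, "ref")
            est = f.params.loc["x", "b"]
            se = f.bse.loc["x", "b"]
            estimates.append(est)
            covered += (est - 1.96 * se) <= 0.7 <= (est + 1.96 * se)
        assert np.mean(estimates) == pytest.approx(0.7, abs=0.15)
        assert covered / reps >= 0.9

    def test_table_invariant_to_cluster_order(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=400)
        labels = simulate_labels(x[:, None], np.array([[0.6, -0.6]]), rng)
        f1 = fit_multinomial(pd.DataFrame({"x": x}), labels, "ref")
        shuffled = labels.iloc[::-1].reset_index(drop=True)
        x2 = x[::-1]
        f2 = fit_multinomial(pd.DataFrame({"x": x2}), shuffled, "ref")
        pd.testing.assert_frame_equal(f1.params, f2.params, atol=1e-6, rtol=0)


class TestPooling:
    @staticmethod
    def frame(est, se):
        idx = pd.MultiIndex.from_tuples([("b", "x")], names=["cluster", "predictor"])
        return pd.DataFrame({"estimate": [est], "se": [se]}, index=idx)

    def test_two_imputation_worked_example(self):
        pooled = pool_rubin([self.frame(1.0, 0.5), self.frame(2.0, 0.5)])
        row = pooled.loc[("b", "x")]
        assert row["Qbar"] == pytest.approx(1.5)
        assert row["W"] == pytest.approx(0.25)
        assert row["B"] == pytest.approx(0.5)
        assert row["T"] == pytest.approx(1.0)
        assert row["ci_low"] < row["OR"] < row["ci_high"]

    def test_identical_imputations_reduce_to_normal_theory(self):
        sets = [self.frame(0.8, 0.2)] * 5
        row = pool_rubin(sets).loc[("b", "x")]
        assert row["B"] == 0.0 and row["T"] == pytest.approx(row["W"])
        assert np.isinf(row["df"])
        assert row["ci_low"] == pytest.approx(np.exp(0.8 - 1.959964 * 0.2), rel=1e-5)

    def test_single_imputation_warns(self):
        with pytest.warns(UserWarning, match="single imputation"):
            pool_rubin([self.frame(1.0, 0.5)])

    def test_mismatched_names_rejected(self):
        idx2 = pd.MultiIndex.from_tuples([("b", "y")], names=["cluster", "predictor"])
        other = pd.DataFrame({"estimate": [1.0], "se": [0.5]}, index=idx2)
        with pytest.raises(ValueError, match="differ"):
            pool_rubin([self.frame(1.0, 0.5), other])

    def test_null_covariate_type_i_error_near_nominal(self):
        """Pooled p for a null effect rejects at ~5% over 200 replicates."""
        rng = np.random.default_rng(11)
        rejections = 0
        for _ in range(200):
            x = rng.normal(size=400)
            labels = pd.Series(rng.choice(["ref", "b"], 400))
            f = fit_multinomial(pd.DataFrame({"x": x}), labels, "ref")
            pooled = pool_rubin([coefficient_frame(f)] * 3)
            rejections += pooled.loc[("b", "x"), "p"] < 0.05
        assert rejections / 200 == pytest.approx(0.05, abs=0.03)


class TestFitMeasures:
    def test_nagelkerke_zero_when_model_adds_nothing(self):
        assert nagelkerke_r2(-100.0, -100.0, 50) == 0.0

    def test_nagelkerke_approaches_one_at_perfect_fit(self):
        assert nagelkerke_r2(-1e-9, -150.0, 100) == pytest.approx(1.0, abs=1e-6)

    def test_nagelkerke_matches_two_line_formula(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=200)
        labels = simulate_labels(x[:, None], np.array([[1.2, -0.5]]), rng)
        f = fit_multinomial(pd.DataFrame({"x": x}), labels, "ref")
        r2_cs = 1 - np.exp(2 * (f.llnull - f.llf) / f.n)
        expected = r2_cs / (1 - np.exp(2 * f.llnull / f.n))
        assert nagelkerke_r2(f.llf, f.llnull, f.n) == pytest.approx(expected)

    def test_vif_orthogonal_predictors_is_one(self):
        X = pd.DataFrame({"a": [1, 1, -1, -1.0], "b": [1, -1, 1, -1.0]})
        assert compute_vif(X).max() == pytest.approx(1.0)

    def test_vif_closed_form_at_r06(self):
        rng = np.random.default_rng(13)
        a = rng.normal(size=4000)
        resid = rng.normal(size=4000)
        resid -= resid.dot(a) / a.dot(a) * a  # exact orthogonality
        a_s = (a - a.mean()) / a.std()
        r_s = (resid - resid.mean()) / resid.std()
        b = 0.6 * a_s + np.sqrt(1 - 0.36) * r_s
        vif = compute_vif(pd.DataFrame({"a": a_s, "b": b}))
        assert vif["a"] == pytest.approx(1.5625, rel=1e-2)

    def test_duplicated_column_reports_infinite_vif(self):
        rng = np.random.default_rng(14)
        a = rng.normal(size=50)
        vif = compute_vif(pd.DataFrame({"a": a, "b": a.copy(), "c": rng.normal(size=50)}))
        assert np.isinf(vif["a"]) and np.isinf(vif["b"])


def test_end_to_end_sign_recovery_on_default_cohort():
    """screen -> impute -> fit -> pool recovers the large known coefficients."""
    from psytraj.cohort import CohortSpec, generate_cohort

    spec = CohortSpec(n_participants=2500, seed=42, item_missing_rate=0,
                      scale_missing_rate=0)
    cohort = generate_cohort(spec)
    cov = cohort.covariate_table.copy()
    rng = np.random.default_rng(0)
    cov.loc[rng.random(len(cov)) < 0.05, "caregiver_distress"] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        analysis = run_predictor_analysis(cov, cohort.true_labels.reset_index(drop=True),
                                          reference_cluster="unaffected", m=5,
                                          iterations=3, seed=1)
    beta = cohort.spec_echo.true_beta
    for pred, cls in [("female_sex", "internalizing"), ("autistic_traits", "internalizing"),
                      ("bullying_victim", "severe"), ("autistic_traits", "severe")]:
        row = analysis.pooled.loc[(cls, pred)]
        assert np.sign(row["Qbar"]) == np.sign(beta.loc[pred, cls])
        assert row["p"] < 0.05
    assert 0 < analysis.nagelkerke < 1
    assert analysis.vif.max() < 5
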