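"""Baseline statistics, correlation and logistic association modelling."""

import numpy as np
import pandas as pd
import pytest

from bileaxis import (
    SimulationConfig,
    baseline_table,
    fit_logistic,
    pearson_correlation,
    simulate_clinical,
    t_test_from_summary,
    univariate_screen,
)


class TestTFromSummary:
    def test_equal_means_p_one(self):
        t, p = t_test_from_summary(5, 1, 10, 5, 1, 10)
        assert t == 0.0
        assert p == 1.0

    def test_published_age_row_reproduced(self):
        # mean +/- SD 62.48 +/- 10.66 (n=23) vs 59.65 +/- 12.45 (n=23)
        t, p = t_test_from_summary(62.48, 10.66, 23, 59.65, 12.45, 23)
        assert p == pytest.approx(0.413, abs=0.005)

    def test_matches_raw_data_t_test(self, rng):
        from scipy import stats

        a = rng.normal(3, 1, 15)
        b = rng.normal(2.5, 1.2, 18)
        t_raw, p_raw = stats.ttest_ind(a, b, equal_var=True)
        t_sum, p_sum = t_test_from_summary(
            a.mean(), a.std(ddof=1), len(a), b.mean(), b.std(ddof=1), len(b))
        assert t_sum == pytest.approx(t_raw, abs=1e-10)
        assert p_sum == pytest.approx(p_raw, abs=1e-10)

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            t_test_from_summary(1, 0, 10, 2, 1, 10)
        with pytest.raises(ValueError):
            t_test_from_summary(1, 1, 1, 2, 1, 10)


class TestBaselineTable:
    @staticmethod
    def _table(n=23):
        rng = np.random.default_rng(5)
        groups = ["AF"] * n + ["control"] * n
        return pd.DataFrame({
            "group": groups,
            "age": rng.normal(60, 10, 2 * n),
            "FGF19": rng.lognormal(5, 0.9, 2 * n),
            "DM": np.r_[np.ones(1), np.zeros(n - 1),
                        np.ones(5), np.zeros(n - 5)],
        })

    def test_sparse_binary_takes_fisher_path(self):
        # DM counts 1/23 vs 5/23: expected cell below 5
        res = baseline_table(self._table()).set_index("variable")
        assert res.loc["DM", "test"] == "fisher"

    def test_normal_variable_takes_t_and_skewed_takes_mann_whitney(self):
        res = baseline_table(self._table()).set_index("variable")
        assert res.loc["age", "test"] == "t"
        assert res.loc["FGF19", "test"] == "mann-whitney"

    def test_identical_groups_give_p_one(self):
        n = 10
        x = np.r_[np.arange(n), np.arange(n)].astype(float)
        table = pd.DataFrame({
            "group": ["AF"] * n + ["control"] * n, "v": x,
            "b": np.r_[np.ones(5), np.zeros(5), np.ones(5), np.zeros(5)],
        })
        res = baseline_table(table).set_index("variable")
        assert res.loc["v", "p_value"] == pytest.approx(1.0)
        assert res.loc["b", "p_value"] == pytest.approx(1.0)

    def test_all_missing_variable_skipped_with_warning(self):
        table = self._table()
        table["empty"] = np.nan
        with pytest.warns(UserWarning, match="all-missing"):
            res = baseline_table(table)
        assert "empty" not in set(res["variable"])


class TestPearson:
    def test_perfect_linear(self):
        r, p = pearson_correlation([1, 2, 3], [2, 4, 6])
        assert r == pytest.approx(1.0)

    def test_anti_linear(self):
        r, _ = pearson_correlation([1, 2, 3, 4], [8, 6, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [2, 4, 6])

    def test_large_sample_recovery_of_generating_rho(self):
        cfg = SimulationConfig(
            n_af=2500, n_control=2500, fgf19_lad_rho=-0.3,
            fgf19_effect=0.0, lad_effect=0.0, seed=77)
        clin, _ = simulate_clinical(cfg)
        r, _ = pearson_correlation(clin["FGF19"], clin["LAD"])
        assert -0.35 < r < -0.25


class TestLogistic:
    @staticmethod
    def _binary_table(a, b, c, d):
        """2x2 layout: exposed/unexposed among AF (a,b) and control (c,d)."""
        rows = ([("AF", 1)] * a + [("AF", 0)] * b
                + [("control", 1)] * c + [("control", 0)] * d)
        return pd.DataFrame(rows, columns=["group", "x"])

    def test_single_binary_covariate_matches_ad_bc(self):
        a, b, c, d = 8, 12, 5, 15
        model = fit_logistic(self._binary_table(a, b, c, d), ["x"])
        assert model.coef["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)

    def test_published_dm_counts_give_or_0164(self):
        # AF: 1 exposed / 22 unexposed; control: 5 exposed / 18 unexposed
        model = fit_logistic(self._binary_table(1, 22, 5, 18), ["x"])
        assert model.odds_ratio["x"] == pytest.approx((1 * 18) / (22 * 5), rel=1e-5)

    def test_null_model_intercept_is_log_odds(self):
        table = self._binary_table(10, 5, 6, 9)
        model = fit_logistic(table, [])
        assert model.coef["const"] == pytest.approx(np.log(15 / 15), abs=1e-8)

    def test_wald_ci_brackets_or(self):
        model = fit_logistic(self._binary_table(8, 12, 5, 15), ["x"])
        assert model.ci_low["x"] < model.odds_ratio["x"] < model.ci_high["x"]
        assert (model.odds_ratio > 0).all()

    def test_continuous_coefficient_recovery_at_n5000(self):
        rng = np.random.default_rng(3)
        n = 5000
        x = rng.normal(size=n)
        z = rng.binomial(1, 0.4, size=n)
        logit = -0.2 + 0.8 * x + 0.6 * z
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        table = pd.DataFrame({
            "group": np.where(y, "AF", "control"), "x": x, "z": z})
        model = fit_logistic(table, ["x", "z"])
        assert model.coef["x"] == pytest.approx(0.8, abs=0.05)
        assert model.coef["z"] == pytest.approx(0.6, abs=0.1)


class TestScreen:
    def test_forced_variable_always_selected(self):
        clin, _ = simulate_clinical(SimulationConfig.clinical_default(seed=8))
        screen = univariate_screen(clin, forced=("DM",)).set_index("variable")
        assert screen.loc["DM", "selected"]

    def test_screen_is_deterministic(self):
        clin, _ = simulate_clinical(SimulationConfig.clinical_default(seed=8))
        s1 = univariate_screen(clin)
        s2 = univariate_screen(clin)
        pd.testing.assert_frame_equal(s1, s2)

    def test_separated_variable_flagged_and_retained(self):
        table = pd.DataFrame({
            "group": ["AF"] * 10 + ["control"] * 10,
            "sep": np.r_[np.ones(10), np.zeros(10)],
        })
        screen = univariate_screen(table).set_index("variable")
        assert "sep" in screen.index
        assert not screen.loc["sep", "converged"]
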