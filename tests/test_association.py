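"""Logistic fits, category ORs, trend test, stepwise selection, descriptives."""

import numpy as np
import pandas as pd
import pytest
import scipy.special
import scipy.stats

from smokemets.association import (
    RankDeficiencyError,
    SeparationError,
    build_design,
    category_association,
    crude_or,
    descriptive_table,
    fit_logistic,
    stepwise_select,
    trend_test,
)
from smokemets.exposure import make_coding


def table_to_data(a, b, c, d):
    """Long-format outcome/exposure data from 2x2 cells (exposed cases,
    exposed non-cases, unexposed cases, unexposed non-cases)."""
    y = np.concatenate([np.ones(a), np.zeros(b), np.ones(c), np.zeros(d)])
    x = np.concatenate([np.ones(a + b), np.zeros(c + d)])
    return y, x


class TestFitLogistic:
    def test_matches_two_by_two_closed_form(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            a, b, c, d = rng.integers(1, 11, 4)
            y, x = table_to_data(a, b, c, d)
            X = pd.DataFrame({"const": np.ones_like(x), "x": x})
            fit = fit_logistic(y, X)
            assert fit.params["x"] == pytest.approx(np.log(a * d / (b * c)), abs=1e-6)
            assert fit.se()["x"] == pytest.approx(
                np.sqrt(1 / a + 1 / b + 1 / c + 1 / d), abs=1e-6
            )

    def test_constant_predictor_is_rank_deficient(self):
        y, x = table_to_data(5, 5, 5, 5)
        X = pd.DataFrame({"const": np.ones_like(x), "flat": np.full_like(x, 2.0)})
        with pytest.raises(RankDeficiencyError, match="flat"):
            fit_logistic(y, X)

    def test_single_class_outcome_rejected(self):
        X = pd.DataFrame({"const": np.ones(20), "x": np.arange(20.0)})
        with pytest.raises(ValueError, match="both classes"):
            fit_logistic(np.zeros(20), X)

    def test_perfect_separation_diagnosed(self):
        x = np.concatenate([np.zeros(20), np.ones(20)])
        y = x.copy()
        X = pd.DataFrame({"const": np.ones_like(x), "x": x})
        with pytest.raises(SeparationError):
            fit_logistic(y, X)


class TestCategoryAssociation:
    def _cohort(self, n=4000, beta3=0.0, seed=3):
        rng = np.random.default_rng(seed)
        ever = rng.random(n) < 0.4
        csi = np.where(ever, rng.gamma(2.0, 1.0, n), 0.0)
        age = rng.normal(60, 8, n)
        coding = make_coding(csi, ever, "csi_tertiles")
        cats = coding.assign(csi, ever)
        top = (np.asarray(cats) == "tertile_3").astype(float)
        logit = -1.2 + 0.02 * (age - 60) + beta3 * top
        y = (rng.random(n) < scipy.special.expit(logit)).astype(int)
        df = pd.DataFrame({"csi": csi, "ever": ever, "age": age, "mets": y})
        return df, coding

    def test_null_effect_or_near_one(self):
        df, coding = self._cohort(n=20000, beta3=0.0)
        at = category_association(df, coding, "csi", "ever", "mets", ["age"])
        t = at.table.set_index("category")
        for cat in ("tertile_1", "tertile_2", "tertile_3"):
            assert t.loc[cat, "ci_low"] < 1.0 < t.loc[cat, "ci_high"]

    def test_recovers_injected_effect(self):
        df, coding = self._cohort(n=20000, beta3=np.log(2.0))
        at = category_association(df, coding, "csi", "ever", "mets", ["age"])
        t = at.table.set_index("category")
        assert t.loc["tertile_3", "ci_low"] < 2.0 < t.loc["tertile_3", "ci_high"]
        assert t.loc["never", "odds_ratio"] == 1.0

    def test_counts_partition_sample(self):
        df, coding = self._cohort(n=3000)
        at = category_association(df, coding, "csi", "ever", "mets", ["age"])
        assert at.table["n_total"].sum() == len(df)
        assert at.table["n_cases"].sum() == df["mets"].sum()

    def test_invariant_to_covariate_order_and_labels(self):
        df, coding = self._cohort(n=3000)
        df["bmi"] = np.random.default_rng(0).normal(24, 3, len(df))
        a = category_association(df, coding, "csi", "ever", "mets", ["age", "bmi"])
        b = category_association(df, coding, "csi", "ever", "mets", ["bmi", "age"])
        assert np.allclose(
            a.table["odds_ratio"].to_numpy()[1:], b.table["odds_ratio"].to_numpy()[1:]
        )

    def test_ci_width_shrinks_like_root_n(self):
        widths = {}
        for n in (2000, 32000):
            df, coding = self._cohort(n=n, beta3=np.log(1.8), seed=9)
            at = category_association(df, coding, "csi", "ever", "mets", ["age"])
            t = at.table.set_index("category")
            widths[n] = np.log(t.loc["tertile_3", "ci_high"]) - np.log(
                t.loc["tertile_3", "ci_low"]
            )
        ratio = widths[2000] / widths[32000]
        assert 3.0 < ratio < 5.5  # ~ sqrt(16) = 4

    def test_empty_category_is_an_error(self):
        df, coding = self._cohort(n=500)
        sub = df[df["csi"] <= coding.cutpoints[1]]  # drops tertile_3
        with pytest.raises(ValueError, match="tertile_3"):
            category_association(sub, coding, "csi", "ever", "mets", ["age"])


class TestTrendTest:
    def test_two_categories_equal_binary_wald(self):
        rng = np.random.default_rng(21)
        n = 3000
        ever = rng.random(n) < 0.5
        y = (rng.random(n) < scipy.special.expit(-1 + 0.5 * ever)).astype(int)
        df = pd.DataFrame({"v": ever.astype(float), "ever": ever, "mets": y})
        # single non-reference category: trend score is a rescaled dummy
        coding = make_coding(np.where(ever, 1.0, 0.0), ever, "intensity_bins")
        p_trend = trend_test(df, coding, "v", "ever", "mets")
        X = pd.DataFrame({"const": np.ones(n), "x": ever.astype(float)})
        p_wald = fit_logistic(y.astype(float), X).wald_p("x")
        assert p_trend == pytest.approx(p_wald, abs=1e-10)

    def test_detects_linear_trend(self):
        rng = np.random.default_rng(4)
        n = 5000
        ever = rng.random(n) < 0.5
        csi = np.where(ever, rng.gamma(2, 1, n), 0.0)
        coding = make_coding(csi, ever, "csi_tertiles")
        score = coding.median_scores(csi, ever)
        y = (rng.random(n) < scipy.special.expit(-1.5 + 0.4 * score)).astype(int)
        df = pd.DataFrame({"csi": csi, "ever": ever, "mets": y})
        assert trend_test(df, coding, "csi", "ever", "mets") < 1e-4

    def test_requires_two_distinct_medians(self):
        df = pd.DataFrame({"v": np.zeros(50), "ever": [False] * 50, "mets": [0, 1] * 25})
        coding = make_coding(np.array(["never"] * 50, dtype=object), df["ever"], "status")
        with pytest.raises(ValueError):
            trend_test(df, coding, "v", "ever", "mets")


class TestStepwise:
    def _data(self, n, seed, beta_real=1.0):
        rng = np.random.default_rng(seed)
        real = rng.standard_normal(n)
        noise = rng.standard_normal(n)
        y = (rng.random(n) < scipy.special.expit(-0.5 + beta_real * real)).astype(int)
        return pd.DataFrame({"mets": y, "real": real, "noise": noise})

    def test_selects_signal_drops_noise(self):
        hits, noise_in = 0, 0
        for r in range(30):
            df = self._data(2000, seed=100 + r)
            sel = stepwise_select(df, "mets", ["real", "noise"])
            hits += "real" in sel
            noise_in += "noise" in sel
        assert hits >= 28
        assert noise_in <= 5

    def test_no_candidates(self):
        df = self._data(200, seed=1)
        assert stepwise_select(df, "mets", []) == []

    def test_duplicated_covariate_never_enters_twice(self):
        df = self._data(2000, seed=7)
        df["real_copy"] = df["real"]
        sel = stepwise_select(df, "mets", ["real", "real_copy"])
        assert sel.count("real") + sel.count("real_copy") == 1

    def test_p_in_must_be_below_p_out(self):
        df = self._data(200, seed=1)
        with pytest.raises(ValueError):
            stepwise_select(df, "mets", ["real"], p_in=0.2, p_out=0.1)


class TestDescriptiveTable:
    def test_chi_square_matches_hand_computation(self):
        df = pd.DataFrame(
            {
                "group": ["a"] * 30 + ["b"] * 60,
                "var": ["x"] * 10 + ["y"] * 20 + ["x"] * 30 + ["y"] * 30,
            }
        )
        out = descriptive_table(df, "group", categorical=["var"])
        # cells (10,20,30,40): chi2 = 0.79365...
        chi2, p, _, _ = scipy.stats.chi2_contingency([[10, 30], [20, 30]], correction=False)
        assert out["p_value"].iloc[0] == pytest.approx(p, abs=1e-12)

    def test_identical_groups_t_p_one(self):
        vals = np.tile(np.arange(10.0), 2)
        df = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10, "x": vals})
        out = descriptive_table(df, "group", continuous=["x"])
        assert out["p_value"].iloc[0] == pytest.approx(1.0, abs=1e-9)

    def test_percentages_sum_to_100(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {"group": rng.choice(["a", "b"], 400), "var": rng.choice(["u", "v", "w"], 400)}
        )
        out = descriptive_table(df, "group", categorical=["var"])
        for g in ("a", "b"):
            pct = out[g].str.extract(r"\(([\d.]+)\)")[0].astype(float)
            assert pct.sum() == pytest.approx(100.0, abs=0.05)


class TestCrudeOr:
    def test_unit_table(self):
        res = crude_or(1, 1, 1, 1)
        assert res.odds_ratio == 1.0
        assert not res.continuity_corrected

    def test_printed_smoking_counts(self):
        """Current-smoker vs never 2x2 from the published Table-2 counts
        (455/1393 current, 3063/13739 never): crude OR ~ 1.691 (the
        published 1.66 is covariate-adjusted)."""
        res = crude_or(455, 1393 - 455, 3063, 13739 - 3063)
        assert res.odds_ratio == pytest.approx(1.691, abs=0.001)

    def test_zero_cell_continuity_correction(self):
        res = crude_or(10, 0, 10, 10)
        assert res.continuity_corrected
        assert np.isfinite(res.odds_ratio)

    def test_zero_margin_undefined(self):
        with pytest.raises(ValueError):
            crude_or(0, 0, 5, 5)


class TestBuildDesign:
    def test_categorical_reference_is_most_frequent(self):
        df = pd.DataFrame({"c": ["a", "b", "b", "b", "c"]})
        X = build_design(df, ["c"])
        assert set(X.columns) == {"const", "c[a]", "c[c]"}
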