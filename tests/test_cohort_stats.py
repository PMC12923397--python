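"""Tests of trajectory summaries, paired tests, screens and stepwise fits."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hefq.cohort import (
    bonferroni,
    paired_tests_vs_baseline,
    partial_r2,
    pearson_screen,
    resolution_counts,
    stepwise_fit,
    summarize_trajectories,
    univariable_screen,
)


def _visits(rows):
    base = {"va_letters": 70.0, "cst_um": 400.0}
    out = []
    for eye, week, total, csf, ir, or_ in rows:
        out.append(
            dict(eye_id=eye, week=week, he_total_mm3=total, he_csf_mm3=csf,
                 he_ir_mm3=ir, he_or_mm3=or_, **base)
        )
    return pd.DataFrame(out)


class TestTrajectories:
    def test_identity_cohort_gives_100_percent(self):
        rows = [("a", w, 0.02, 0.001, 0.005, 0.01) for w in (0, 4, 12)]
        summ = summarize_trajectories(_visits(rows))
        assert (summ["percent_of_baseline"] == 100.0).all()

    def test_percent_is_ratio_of_means(self):
        rows = [
            ("a", 0, 0.0293, 0.001, 0.005, 0.01),
            ("a", 4, 0.0328, 0.001, 0.005, 0.01),
        ]
        summ = summarize_trajectories(_visits(rows))
        row = summ[(summ.region == "total") & (summ.week == 4)].iloc[0]
        assert row["percent_of_baseline"] == 111.9

    def test_scale_invariance(self):
        rows = [("a", 0, 0.02, 0.001, 0.005, 0.01), ("a", 4, 0.03, 0.002, 0.006, 0.02)]
        v = _visits(rows)
        scaled = v.copy()
        for c in ("he_total_mm3", "he_csf_mm3", "he_ir_mm3", "he_or_mm3"):
            scaled[c] *= 7.3
        pd.testing.assert_series_equal(
            summarize_trajectories(v)["percent_of_baseline"],
            summarize_trajectories(scaled)["percent_of_baseline"],
        )

    def test_missing_baseline_errors(self):
        rows = [("a", 4, 0.02, 0.001, 0.005, 0.01)]
        with pytest.raises(ValueError, match="baseline"):
            summarize_trajectories(_visits(rows))


class TestPairedTests:
    def test_identical_pairs_give_null_result(self):
        rows = []
        for eye in "abc":
            rows += [(eye, 0, 0.02, 0.001, 0.005, 0.01),
                     (eye, 4, 0.02, 0.001, 0.005, 0.01)]
        res = paired_tests_vs_baseline(_visits(rows), "total", weeks=(4,))[0]
        assert res.t_statistic == 0.0
        assert res.p_raw == 1.0
        assert res.p_bonferroni == 1.0

    def test_hand_computed_t_on_three_pairs(self):
        # baseline (1,2,3) vs week (2,4,5): differences (1,2,2)
        # t = mean(d) / (sd(d)/sqrt(3)) = (5/3) / (0.57735/1.7321) = 5.0
        rows = []
        for eye, b, w in zip("abc", (1, 2, 3), (2, 4, 5)):
            rows += [(eye, 0, b, 0, 0, 0), (eye, 4, w, 0, 0, 0)]
        res = paired_tests_vs_baseline(_visits(rows), "total", weeks=(4,))[0]
        assert res.t_statistic == pytest.approx(5.0, rel=1e-12)
        assert res.df == 2
        assert res.p_raw == pytest.approx(2 * stats.t.sf(5.0, 2), rel=1e-12)
        assert res.mean_difference == pytest.approx(5 / 3)

    def test_complete_case_per_timepoint(self):
        rows = [("a", 0, 1, 0, 0, 0), ("a", 4, 2, 0, 0, 0), ("a", 12, 2, 0, 0, 0),
                ("b", 0, 2, 0, 0, 0), ("b", 4, 3, 0, 0, 0),
                ("c", 0, 3, 0, 0, 0), ("c", 4, 5, 0, 0, 0), ("c", 12, 4, 0, 0, 0)]
        res = paired_tests_vs_baseline(_visits(rows), "total", weeks=(4, 12))
        assert res[0].n_pairs == 3
        assert res[1].n_pairs == 2  # eye b missing week 12 dropped there only

    def test_too_few_pairs_errors(self):
        rows = [("a", 0, 1, 0, 0, 0), ("a", 4, 2, 0, 0, 0)]
        with pytest.raises(ValueError, match="pairs"):
            paired_tests_vs_baseline(_visits(rows), "total", weeks=(4,))

    def test_bonferroni_arithmetic(self):
        assert bonferroni(0.01, 4) == pytest.approx(0.04)
        assert bonferroni(0.5, 4) == 1.0  # capped
        assert bonferroni(0.2, 1) == pytest.approx(0.2)
        assert bonferroni(0.03, 4) >= 0.03  # never decreases


class TestResolution:
    def test_printed_fraction(self):
        rows = []
        for i in range(260):
            csf = 0.0 if i < 76 else 0.001
            rows.append((f"e{i}", 52, 0.01, csf, 0.002, 0.005))
            rows.append((f"e{i}", 0, 0.01, 0.001, 0.002, 0.005))
        res = resolution_counts(_visits(rows), week=52)
        row = res[res.region == "csf"].iloc[0]
        assert row["n_resolved"] == 76
        assert row["denominator"] == 260
        assert row["percent"] == 29.2

    def test_extremes(self):
        rows = [(f"e{i}", 52, 0.01, 0.001, 0.002, 0.005) for i in range(10)]
        res = resolution_counts(_visits(rows), week=52)
        assert (res["percent"] == 0.0).all()
        rows = [(f"e{i}", 52, 0.0, 0.0, 0.0, 0.0) for i in range(10)]
        res = resolution_counts(_visits(rows), week=52)
        assert (res["percent"] == 100.0).all()


class TestPearsonScreen:
    def test_identity_and_antithesis(self):
        df = pd.DataFrame({"x": [1.0, 2, 3, 4], "y": [1.0, 2, 3, 4]})
        df["neg"] = -df["x"]
        out = pearson_screen(df, ["x"], ["y", "neg"])
        assert out.loc[out.y == "y", "r"].iloc[0] == pytest.approx(1.0)
        assert out.loc[out.y == "neg", "r"].iloc[0] == pytest.approx(-1.0)

    def test_zero_variance_flagged(self):
        df = pd.DataFrame({"x": [1.0, 1, 1, 1], "y": [1.0, 2, 3, 4]})
        out = pearson_screen(df, ["x"], ["y"])
        assert np.isnan(out["r"].iloc[0])
        assert out["note"].iloc[0] == "zero variance"

    def test_pairwise_complete(self):
        df = pd.DataFrame({"x": [1.0, 2, np.nan, 4, 5], "y": [2.0, 4, 6, np.nan, 10]})
        out = pearson_screen(df, ["x"], ["y"])
        assert out["n"].iloc[0] == 3
        assert out["r"].iloc[0] == pytest.approx(1.0)


class TestUnivariableScreen:
    def test_outcome_as_candidate_passes(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(100)
        df = pd.DataFrame({"y": y, "x": y})
        out = univariable_screen(df, "y", ["x"])
        assert out["passed"].iloc[0]
        assert out["p"].iloc[0] < 1e-10

    def test_constant_candidate_fails_with_note(self):
        df = pd.DataFrame({"y": [1.0, 2, 3, 4], "x": [5.0, 5, 5, 5]})
        out = univariable_screen(df, "y", ["x"])
        assert not out["passed"].iloc[0]
        assert out["note"].iloc[0] == "constant candidate"

    def test_power_for_planted_effect(self):
        """A standardized effect of 0.3 at n=260 is essentially always screened in."""
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(100):
            x = rng.standard_normal(260)
            y = 0.3 * x + np.sqrt(1 - 0.09) * rng.standard_normal(260)
            out = univariable_screen(pd.DataFrame({"y": y, "x": x}), "y", ["x"])
            hits += int(out["passed"].iloc[0])
        assert hits >= 99


class TestStepwise:
    def test_recovers_single_true_predictor(self):
        rng = np.random.default_rng(3)
        n = 500
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)  # pure noise
        y = 2.0 * x1 + 0.1 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        model = stepwise_fit(df, "y", ["x1", "x2"])
        assert model.retained == ["x1"]
        beta = model.predictors[0].beta_standardized
        assert beta == pytest.approx(2.0 / np.sqrt(4.0 + 0.01), abs=0.05)

    def test_collinearity_guard_keeps_one_copy(self):
        rng = np.random.default_rng(4)
        x1 = rng.standard_normal(200)
        y = x1 + 0.2 * rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x1": x1, "x1_copy": x1})
        model = stepwise_fit(df, "y", ["x1", "x1_copy"])
        assert len(model.retained) == 1

    def test_candidate_order_invariance(self):
        rng = np.random.default_rng(5)
        n = 300
        x1, x2, x3 = rng.standard_normal((3, n))
        y = 0.8 * x1 - 0.5 * x2 + 0.3 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "a": x1, "b": x2, "c": x3})
        m1 = stepwise_fit(df, "y", ["a", "b", "c"])
        m2 = stepwise_fit(df, "y", ["c", "b", "a"])
        assert m1.retained == m2.retained

    def test_no_candidate_enters_gives_empty_model(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(
            {"y": rng.standard_normal(100), "x": rng.standard_normal(100)}
        )
        # force no entry with an extreme entry threshold
        model = stepwise_fit(df, "y", ["x"], entry_p=1e-12)
        assert model.retained == []
        assert model.r2 == 0.0


class TestPartialR2:
    def test_single_predictor_equals_r2(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        y = x + 0.5 * rng.standard_normal(200)
        df = pd.DataFrame({"y": y, "x": x})
        model = stepwise_fit(df, "y", ["x"])
        assert model.predictors[0].partial_r2 == pytest.approx(model.r2, abs=1e-10)

    def test_orthogonal_predictors_sum_to_r2(self):
        rng = np.random.default_rng(8)
        n = 400
        x1 = rng.standard_normal(n)
        x2 = rng.standard_normal(n)
        # orthogonalize in-sample so the identity is exact
        x1 = x1 - x1.mean()
        x2 = x2 - x2.mean()
        x2 = x2 - (x2 @ x1) / (x1 @ x1) * x1
        y = 0.6 * x1 + 0.4 * x2 + 0.5 * rng.standard_normal(n)
        df = pd.DataFrame({"y": y, "x1": x1, "x2": x2})
        model = stepwise_fit(df, "y", ["x1", "x2"])
        total = sum(p.partial_r2 for p in model.predictors)
        assert total == pytest.approx(model.r2, abs=1e-10)

    def test_matches_brute_force_refits_on_printed_fixture(self):
        # tiny fixture with two correlated predictors
        df = pd.DataFrame(
            {
                "y": [3.1, 4.0, 5.2, 6.1, 7.3, 8.0],
                "x1": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
                "x2": [1.2, 1.9, 3.4, 3.8, 5.5, 5.9],
            }
        )
        import statsmodels.api as sm

        def r2(cols):
            X = sm.add_constant(df[cols].to_numpy())
            return sm.OLS(df["y"].to_numpy(), X).fit().rsquared

        expected = r2(["x1", "x2"]) - r2(["x2"])
        assert partial_r2(df, "y", ["x1", "x2"], "x1") == pytest.approx(
            expected, abs=1e-12
        )

    def test_unknown_predictor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "x": [1.0, 2, 4]})
        with pytest.raises(ValueError, match="not among"):
            partial_r2(df, "y", ["x"], "z")
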