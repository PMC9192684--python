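"""Feed-efficiency scoring: ECM, predicted DMI, RFI and classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from efficow.feed_efficiency import (
    EfficiencyParams,
    classify_efficiency,
    compute_ecm,
    predict_dmi,
    regression_rfi,
    score_cow,
    score_herd,
)

PARAMS = EfficiencyParams()


def _cow_days(cow_id, days, dim, bw, dmi, milk, fat, prot, lact):
    n = len(days)
    return pd.DataFrame({
        "cow_id": cow_id, "day": days, "dim": np.broadcast_to(dim, n),
        "bw_kg": np.broadcast_to(bw, n), "dmi_kg": np.broadcast_to(dmi, n),
        "milk_kg": np.broadcast_to(milk, n), "fat_pct": fat,
        "protein_pct": prot, "lactose_pct": lact,
    })


class TestComputeEcm:
    def test_zero_milk_gives_zero(self):
        assert compute_ecm(0.0, 3.5, 3.5, 5.0) == 0.0

    def test_high_efficiency_group_means(self):
        # hand evaluation: 50.3*(0.3887*2.99+0.2356*2.86+0.1653*4.86)/3.1338
        assert compute_ecm(50.3, 2.99, 2.86, 4.86) == pytest.approx(42.364, abs=0.05)

    def test_standard_composition_cancels_divisor(self):
        # composition whose weighted sum equals the divisor maps milk to itself
        fat = prot = 3.5
        lact = (3.1338 - 0.3887 * fat - 0.2356 * prot) / 0.1653
        assert compute_ecm(31.7, fat, prot, lact) == pytest.approx(31.7, rel=1e-12)

    @given(milk=st.floats(0, 80), scale=st.floats(0.1, 10))
    @settings(max_examples=50, deadline=None)
    def test_homogeneous_in_milk(self, milk, scale):
        base = compute_ecm(milk, 3.0, 3.0, 4.9)
        assert compute_ecm(milk * scale, 3.0, 3.0, 4.9) == pytest.approx(
            base * scale, rel=1e-9, abs=1e-9)

    def test_negative_milk_rejected_by_name(self):
        with pytest.raises(ValueError, match="milk"):
            compute_ecm(-1.0, 3.0, 3.0, 4.9)


class TestPredictDmi:
    def test_hand_evaluation(self):
        # [(0.36*40.4)+(0.123*575.4^0.73)]*(1-exp(-0.22*(110/7+5.67)))
        assert predict_dmi(40.4, 575.4, 110) == pytest.approx(27.02, abs=0.05)

    def test_zero_ecm_late_lactation_approaches_maintenance(self):
        assert predict_dmi(0.0, 600.0, 5000) == pytest.approx(
            0.123 * 600.0 ** 0.73, rel=1e-6)

    @given(bw=st.floats(300, 900), dim=st.integers(1, 500), ecm=st.floats(0, 80))
    @settings(max_examples=100, deadline=None)
    def test_finite_positive_over_realistic_range(self, bw, dim, ecm):
        val = predict_dmi(ecm, bw, dim)
        assert np.isfinite(val) and val > 0

    @given(dim1=st.integers(1, 499), delta=st.integers(1, 100))
    @settings(max_examples=50, deadline=None)
    def test_monotone_in_dim(self, dim1, delta):
        assert predict_dmi(30.0, 600.0, dim1 + delta) > predict_dmi(30.0, 600.0, dim1)

    def test_nonpositive_bw_rejected(self):
        with pytest.raises(ValueError, match="bw"):
            predict_dmi(30.0, 0.0, 100)


class TestScoreCow:
    def test_perfect_prediction_gives_zero_rfi(self):
        days = np.arange(1, 6)
        df = _cow_days("c1", days, 100 + days, 600.0, 0.0, 40.0, 3.0, 3.0, 4.9)
        ecm = compute_ecm(df["milk_kg"], df["fat_pct"], df["protein_pct"],
                          df["lactose_pct"])
        df["dmi_kg"] = predict_dmi(ecm, df["bw_kg"], df["dim"])
        assert score_cow(df).rfi == pytest.approx(0.0, abs=1e-12)

    def test_constant_overeating_offset(self):
        days = np.arange(1, 4)
        df = _cow_days("c1", days, 110, 580.0, 0.0, 45.0, 3.1, 2.9, 4.9)
        ecm = compute_ecm(df["milk_kg"], df["fat_pct"], df["protein_pct"],
                          df["lactose_pct"])
        df["dmi_kg"] = predict_dmi(ecm, df["bw_kg"], df["dim"]) + 1.0
        assert score_cow(df).rfi == pytest.approx(1.0, abs=1e-12)

    def test_three_day_toy_matches_day_by_day_arithmetic(self):
        dims = np.array([100, 101, 102])
        bws = np.array([590.0, 591.0, 592.0])
        milks = np.array([44.0, 46.0, 45.0])
        dmis = np.array([25.0, 26.0, 27.0])
        df = pd.DataFrame({"cow_id": "c9", "day": [1, 2, 3], "dim": dims,
                           "bw_kg": bws, "dmi_kg": dmis, "milk_kg": milks,
                           "fat_pct": 3.0, "protein_pct": 3.0,
                           "lactose_pct": 4.9})
        # oracle: explicit per-day arithmetic
        preds = [predict_dmi(compute_ecm(m, 3.0, 3.0, 4.9), b, d)
                 for m, b, d in zip(milks, bws, dims)]
        score = score_cow(df)
        assert score.rfi == pytest.approx(dmis.mean() - np.mean(preds), rel=1e-12)
        assert score.ecm_per_dmi == pytest.approx(
            np.mean([compute_ecm(m, 3.0, 3.0, 4.9) for m in milks]) / dmis.mean(),
            rel=1e-12)

    def test_single_record_equals_direct_formula(self):
        df = _cow_days("c1", [1], 120, 600.0, 24.0, 42.0, 3.1, 3.0, 4.8)
        score = score_cow(df)
        ecm = compute_ecm(42.0, 3.1, 3.0, 4.8)
        assert score.mean_ecm == pytest.approx(ecm, rel=1e-12)
        assert score.rfi == pytest.approx(
            24.0 - predict_dmi(ecm, 600.0, 120), rel=1e-12)

    def test_empty_and_mixed_ids_rejected(self):
        df = _cow_days("c1", [1], 120, 600.0, 24.0, 42.0, 3.1, 3.0, 4.8)
        with pytest.raises(ValueError):
            score_cow(df.iloc[:0])
        mixed = pd.concat([df, df.assign(cow_id="c2")])
        with pytest.raises(ValueError, match="mix"):
            score_cow(mixed)


class TestClassify:
    def _scores(self, rfis, ids=None):
        ids = ids or [f"c{i:03d}" for i in range(len(rfis))]
        return pd.DataFrame({"cow_id": ids, "rfi": rfis,
                             "mean_dmi": 25.0, "mean_ecm": 40.0,
                             "mean_pred_dmi": 25.0, "ecm_per_dmi": 1.6,
                             "mean_bw": 590.0, "n_days": 35,
                             "efficiency_class": "MID"})

    def test_ten_cows_two_per_tail(self):
        out = classify_efficiency(self._scores(np.arange(10.0)), 0.2)
        counts = out["efficiency_class"].value_counts()
        assert counts["HEF"] == 2 and counts["LEF"] == 2 and counts["MID"] == 6
        # lowest RFI cows are the efficient (HEF) ones
        assert set(out.loc[out["efficiency_class"] == "HEF", "rfi"]) == {0.0, 1.0}

    def test_full_cohort_size_tails(self):
        out = classify_efficiency(self._scores(np.arange(155.0)), 0.2)
        counts = out["efficiency_class"].value_counts()
        assert counts["HEF"] == 31 and counts["LEF"] == 31  # floor(0.2*155)

    def test_all_tied_breaks_by_cow_id(self):
        out = classify_efficiency(self._scores([1.0] * 10), 0.2)
        hef = sorted(out.loc[out["efficiency_class"] == "HEF", "cow_id"])
        lef = sorted(out.loc[out["efficiency_class"] == "LEF", "cow_id"])
        assert hef == ["c000", "c001"] and lef == ["c008", "c009"]

    def test_no_cow_in_both_groups_and_sizes(self):
        for n in (5, 11, 23):
            out = classify_efficiency(self._scores(np.random.default_rng(n)
                                                   .normal(size=n)), 0.2)
            k = int(np.floor(0.2 * n))
            counts = out["efficiency_class"].value_counts()
            assert counts.get("HEF", 0) == k == counts.get("LEF", 0)

    def test_tiny_cohort_errors(self):
        with pytest.raises(ValueError, match="too small"):
            classify_efficiency(self._scores([1.0, 2.0]), 0.2)


class TestRegressionRfi:
    def _scores(self, dmi, ecm, bw):
        return pd.DataFrame({"cow_id": [f"c{i}" for i in range(len(dmi))],
                             "mean_dmi": dmi, "mean_ecm": ecm, "mean_bw": bw})

    def test_exact_linear_fit_gives_zero_residuals(self):
        ecm = np.array([35.0, 40.0, 45.0, 50.0])
        bw = np.array([550.0, 580.0, 610.0, 640.0])
        dmi = 2.0 + 0.4 * ecm + 0.05 * bw ** 0.75
        resid = regression_rfi(self._scores(dmi, ecm, bw))
        assert np.allclose(resid, 0.0, atol=1e-9)

    def test_residuals_sum_to_zero(self, small_herd):
        data, _ = small_herd
        resid = regression_rfi(score_herd(data))
        assert abs(resid.sum()) < 1e-9

    def test_overeater_has_largest_positive_residual(self):
        rng = np.random.default_rng(0)
        ecm = rng.uniform(35, 50, 8)
        bw = rng.uniform(550, 650, 8)
        dmi = 2.0 + 0.4 * ecm + 0.05 * bw ** 0.75
        dmi[1] += 3.0  # the over-eater
        resid = regression_rfi(self._scores(dmi, ecm, bw))
        # oracle: explicit normal equations on the same design
        X = np.column_stack([np.ones(8), ecm, bw ** 0.75])
        beta = np.linalg.solve(X.T @ X, X.T @ dmi)
        assert np.allclose(resid, dmi - X @ beta, atol=1e-9)
        assert resid.idxmax() == "c1" and resid["c1"] > 0


class TestHerdRecovery:
    def test_rfi_recovers_true_efficiency_ordering(self, small_herd):
        from scipy.stats import spearmanr
        data, truth = small_herd
        scores = score_herd(data).merge(truth, on="cow_id")
        rho = spearmanr(scores["rfi"], scores["true_offset"]).statistic
        assert rho >= 0.9
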