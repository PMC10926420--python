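import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutriscape.choice import (
    RegulationModel,
    characterize_preference,
    expected_random_intake,
    random_feeding_test,
    regulated_intake_point,
)
from nutriscape.diets import Diet
from nutriscape.simulate import Experiment2Design, generate_experiment2

# published mean cumulative intakes (mg over 16 days) per line and sex
PRINTED_MEANS = {
    ("CT", "F"): (15.65, 57.33),
    ("CT", "M"): (15.46, 55.45),
    ("US", "F"): (19.93, 64.39),
    ("US", "M"): (20.06, 64.55),
}


class TestExpectedRandomIntake:
    def test_one_to_one_vs_zero_to_one_pair(self):
        # 100 uL split evenly across 1:1 (180) and 0:1 (180): 50 uL x 0.09 P
        # and 50 uL x (0.09 + 0.18) C -> a 1:3 blend
        a, b = Diet(1, 1, 180), Diet(0, 1, 180)
        P, C = expected_random_intake(100.0, a, b)
        assert (P, C) == (pytest.approx(4.5), pytest.approx(13.5))
        assert C / P == pytest.approx(3.0)

    def test_zero_volume(self):
        assert expected_random_intake(0.0, Diet(1, 1, 180), Diet(0, 1, 360)) == (0.0, 0.0)

    def test_identical_diets_match_observed(self):
        d = Diet(1, 2, 180)
        P, C = expected_random_intake(80.0, d, d)
        obs_P, obs_C = 80.0 * d.protein_mg_per_uL, 80.0 * d.carb_mg_per_uL
        assert (P, C) == (pytest.approx(obs_P), pytest.approx(obs_C))

    @given(v=st.floats(0, 500),
           ca=st.sampled_from([45.0, 180.0, 360.0]),
           cb=st.sampled_from([45.0, 180.0, 360.0]))
    @settings(max_examples=60, deadline=None)
    def test_conservation(self, v, ca, cb):
        a, b = Diet(1, 1, ca), Diet(0, 1, cb)
        P, C = expected_random_intake(v, a, b)
        assert P + C == pytest.approx(v / 2 * (ca + cb) / 1000.0, abs=1e-9)


def choice_frame(P_obs, C_obs, vol_a, vol_b, pair=(Diet(1, 1, 180), Diet(0, 1, 180)),
                 line="CT", sex="F", replicate=None):
    n = len(P_obs)
    a, b = pair
    return pd.DataFrame({
        "fly_id": [f"f{i}" for i in range(n)],
        "line": line, "sex": sex,
        "replicate": replicate if replicate is not None else np.arange(n) % 4 + 1,
        "p_parts_a": a.p_parts, "c_parts_a": a.c_parts, "concentration_a": a.concentration,
        "p_parts_b": b.p_parts, "c_parts_b": b.c_parts, "concentration_b": b.concentration,
        "vol_a_total_uL": vol_a, "vol_b_total_uL": vol_b,
        "P_mg": P_obs, "C_mg": C_obs,
    })


class TestRandomFeedingTest:
    def test_exactly_random_feeding_gives_unit_p(self):
        a, b = Diet(1, 1, 180), Diet(0, 1, 180)
        vols = np.array([100.0, 120.0, 80.0, 90.0])
        P = vols / 2 * a.protein_mg_per_uL
        C = vols / 2 * (a.carb_mg_per_uL + b.carb_mg_per_uL)
        df = choice_frame(P, C, vols / 2, vols / 2)
        res = random_feeding_test(df)
        assert res.loc["protein", "t"] == 0.0 and res.loc["protein", "p"] == 1.0
        assert res.loc["carbohydrate", "p"] == 1.0

    def test_hand_computed_t_statistic(self):
        # observed-minus-expected protein differences (1, 3, 5):
        # mean 3, sd 2, n 3 -> t = 3 / (2/sqrt(3))
        a, b = Diet(1, 1, 180), Diet(0, 1, 180)
        vols = np.full(3, 100.0)
        exp_P = vols / 2 * a.protein_mg_per_uL
        exp_C = vols / 2 * (a.carb_mg_per_uL + b.carb_mg_per_uL)
        df = choice_frame(exp_P + np.array([1.0, 3.0, 5.0]), exp_C, vols / 2, vols / 2)
        res = random_feeding_test(df)
        assert res.loc["protein", "t"] == pytest.approx(3.0 / (2.0 / np.sqrt(3.0)))
        assert res.loc["carbohydrate", "t"] == 0.0

    def test_power_against_regulated_feeding(self):
        # flies systematically overshooting protein by ~2 mg should be
        # detected nearly always at n = 20
        detected = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            vols = rng.uniform(80, 120, 20)
            a, b = Diet(1, 1, 180), Diet(0, 1, 180)
            exp_P = vols / 2 * a.protein_mg_per_uL
            exp_C = vols / 2 * (a.carb_mg_per_uL + b.carb_mg_per_uL)
            df = choice_frame(exp_P + 2.0 + rng.normal(0, 1.0, 20), exp_C,
                              vols / 2, vols / 2)
            detected += random_feeding_test(df).loc["protein", "p"] < 0.05
        assert detected >= 18

    def test_too_few_flies_rejected(self):
        df = choice_frame(np.array([1.0, 2.0]), np.array([3.0, 4.0]),
                          np.array([50.0, 50.0]), np.array([50.0, 50.0]))
        with pytest.raises(ValueError):
            random_feeding_test(df)

    def test_preference_labels(self):
        rng = np.random.default_rng(1)
        vols = rng.uniform(80, 120, 15)
        a, b = Diet(1, 1, 180), Diet(0, 1, 180)
        exp_P = vols / 2 * a.protein_mg_per_uL
        exp_C = vols / 2 * (a.carb_mg_per_uL + b.carb_mg_per_uL)
        jitter = rng.normal(0, 0.05, 15)
        protein_pref = choice_frame(exp_P + 3.0 + jitter, exp_C, vols / 2, vols / 2)
        assert characterize_preference(protein_pref) == "protein-preferring"
        random_eater = choice_frame(exp_P + jitter, exp_C + jitter, vols / 2, vols / 2)
        assert characterize_preference(random_eater) == "random"


class TestRegulatedIntakePoint:
    def test_published_ct_ratio(self):
        # pooling the printed female and male means gives the 1:3.6 ratio
        P = np.array([PRINTED_MEANS[("CT", "F")][0], PRINTED_MEANS[("CT", "M")][0]])
        C = np.array([PRINTED_MEANS[("CT", "F")][1], PRINTED_MEANS[("CT", "M")][1]])
        df = choice_frame(P, C, np.full(2, 50.0), np.full(2, 50.0))
        pt = regulated_intake_point(df)
        assert pt.label == "1:3.6"

    def test_published_us_ratio(self):
        P = np.array([PRINTED_MEANS[("US", "F")][0], PRINTED_MEANS[("US", "M")][0]])
        C = np.array([PRINTED_MEANS[("US", "F")][1], PRINTED_MEANS[("US", "M")][1]])
        df = choice_frame(P, C, np.full(2, 50.0), np.full(2, 50.0))
        assert regulated_intake_point(df).label == "1:3.2"

    def test_single_fly(self):
        df = choice_frame(np.array([10.0]), np.array([30.0]),
                          np.array([50.0]), np.array([50.0]))
        pt = regulated_intake_point(df)
        assert (pt.mean_P, pt.mean_C, pt.n) == (10.0, 30.0, 1)
        assert pt.label == "1:3.0"

    def test_pure_carbohydrate_flag(self):
        df = choice_frame(np.array([0.0, 0.0, 0.0]), np.array([10.0, 12.0, 14.0]),
                          np.zeros(3), np.full(3, 60.0))
        pt = regulated_intake_point(df)
        assert pt.infinite_ratio and pt.C_to_P_ratio == np.inf

    def test_pooling_consistency(self, exp2_full_scale):
        # the line-level point is the fly-count-weighted mean of sex-level points
        ct = exp2_full_scale[exp2_full_scale.line == "CT"]
        whole = regulated_intake_point(ct)
        parts = [regulated_intake_point(g) for _, g in ct.groupby("sex")]
        wP = sum(p.mean_P * p.n for p in parts) / sum(p.n for p in parts)
        wC = sum(p.mean_C * p.n for p in parts) / sum(p.n for p in parts)
        assert whole.mean_P == pytest.approx(wP)
        assert whole.mean_C == pytest.approx(wC)

    def test_generator_recovers_target_ratio(self, exp2_full_scale):
        # with the default targets the recovered ratio is close to 1:3.2 (US)
        us = regulated_intake_point(exp2_full_scale[exp2_full_scale.line == "US"])
        assert abs(us.C_to_P_ratio - 3.2) < 0.2


class TestRegulationModel:
    def test_table_structure(self, exp2_full_scale):
        res = RegulationModel(exp2_full_scale, "line").fit()
        tbl = res.table()
        assert list(tbl.index) == ["protein", "line", "line_x_protein"]
        assert (tbl["df"] == 1).all()
        assert ((tbl["p"] >= 0) & (tbl["p"] <= 1)).all()

    def test_slope_difference_detected(self):
        # groups regulating toward different C-vs-P slopes: the interaction
        # term must pick it up
        rng = np.random.default_rng(2)
        n = 120
        P = rng.uniform(10, 25, n)
        line = np.repeat(["CT", "US"], n // 2)
        slope = np.where(line == "CT", 3.6, 2.0)
        C = slope * P + rng.normal(0, 3, n)
        df = pd.DataFrame({
            "line": line, "replicate": rng.integers(1, 5, n),
            "P_mg": P, "C_mg": C,
        })
        res = RegulationModel(df, "line").fit()
        assert res.pvalues["line_x_protein"] < 0.001
        assert res.pvalues["protein"] < 0.001

    def test_single_group_rejected(self, exp2_full_scale):
        ct = exp2_full_scale[exp2_full_scale.line == "CT"]
        with pytest.raises(ValueError):
            RegulationModel(ct, "line")

    def test_sex_comparison_within_line(self, exp2_full_scale):
        ct = exp2_full_scale[exp2_full_scale.line == "CT"]
        res = RegulationModel(ct, "sex").fit()
        assert set(res.chi2.index) == {"protein", "sex", "sex_x_protein"}
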