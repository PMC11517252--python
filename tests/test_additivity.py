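"""Expectation models, error propagation, supra/sub classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from eep.additivity import (
    classify_additivity,
    cluster_comparison,
    enhancer_additivity_summary,
    expectation_records,
    expected_additive,
    expected_multiplicative,
    model_preference,
    propagate_additive_sd,
    supra_sub_fractions,
)
from eep.boost import promoter_baselines, single_enhancer_estimates


class TestExpectationFormulas:
    @pytest.mark.parametrize("args, expected", [
        ((2, 3, 1), 4.0), ((5, 5, 5), 5.0), ((1, 1, 4), -2.0),
    ])
    def test_additive(self, args, expected):
        assert expected_additive(*args) == pytest.approx(expected)

    @pytest.mark.parametrize("args, expected", [
        ((2, 3, 1), 6.0), ((5, 5, 5), 5.0), ((4, 1, 2), 2.0),
    ])
    def test_multiplicative(self, args, expected):
        assert expected_multiplicative(*args) == pytest.approx(expected)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            expected_additive(2, 0, 1)
        with pytest.raises(ValueError):
            expected_multiplicative(2, 3, -1)

    @given(a=st.floats(1, 100), c=st.floats(1, 100), b=st.floats(0.01, 100))
    def test_multiplicative_dominates_additive_for_boosting_pairs(self, a, c, b):
        # (a-b)(c-b) >= 0  =>  ac/b >= a+c-b when both singles >= baseline
        if a >= b and c >= b:
            assert expected_multiplicative(a, c, b) >= expected_additive(a, c, b) - 1e-9

    @pytest.mark.parametrize("sds, expected", [
        ((3, 4, 0), 5.0), ((0, 0, 0), 0.0), ((1, 1, 1), np.sqrt(3)),
    ])
    def test_sd_propagation(self, sds, expected):
        assert propagate_additive_sd(*sds) == pytest.approx(expected)

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            propagate_additive_sd(-1, 0, 0)


class TestClassification:
    @pytest.mark.parametrize("obs, exp, sd, expected", [
        (10, 6, 3, "supra"), (8, 6, 3, "within"), (2, 6, 3, "sub"),
    ])
    def test_one_sd_band(self, obs, exp, sd, expected):
        assert classify_additivity(obs, exp, sd) == expected

    @given(exp=st.floats(0.1, 100), sd=st.floats(0.001, 50))
    def test_observed_equal_expected_always_within(self, exp, sd):
        assert classify_additivity(exp, exp, sd) == "within"

    def test_undefined_sd_rejected(self):
        with pytest.raises(ValueError):
            classify_additivity(1.0, 1.0, np.nan)


def _records(rows):
    """rows: (promoter, frag1, frag2, observed, exp_add, sd_add)"""
    df = pd.DataFrame(rows, columns=["promoter", "frag1", "frag2",
                                     "observed", "expected_additive", "sd_additive"])
    df["expected_multiplicative"] = df["expected_additive"] * 1.5
    df["valid"] = df["expected_additive"] > 0
    df["log2_obs_over_exp_add"] = np.where(
        df["valid"], np.log2(df["observed"] / df["expected_additive"].abs()), np.nan)
    df["log2_obs_over_exp_mult"] = np.log2(df["observed"] / df["expected_multiplicative"])
    df["sd_distance"] = (df["observed"] - df["expected_additive"]) / df["sd_additive"]
    df["class"] = ""
    v = df["valid"]
    df.loc[v, "class"] = classify_additivity(df.loc[v, "observed"],
                                             df.loc[v, "expected_additive"],
                                             df.loc[v, "sd_additive"])
    return df


class TestFractions:
    def test_all_exact_matches_are_within(self):
        recs = _records([("P1", "E1", "E2", 4.0, 4.0, 1.0)] * 4)
        frac = supra_sub_fractions(recs).set_index("promoter")
        assert frac.loc["P1", "pct_within_1sd"] == 100.0
        assert frac.loc["P1", "pct_within_2sd"] == 100.0

    def test_one_supra_of_four(self):
        recs = _records([("P1", "E1", "E2", 4.0, 4.0, 1.0),
                         ("P1", "E1", "E3", 4.0, 4.0, 1.0),
                         ("P1", "E2", "E3", 4.0, 4.0, 1.0),
                         ("P1", "E3", "E4", 9.0, 4.0, 1.0)])
        frac = supra_sub_fractions(recs).set_index("promoter")
        assert frac.loc["P1", "pct_supra"] == pytest.approx(25.0)

    def test_partition_sums_to_100(self, rng):
        rows = [("P1", f"E{i}", f"E{i+1}", rng.uniform(1, 10), 5.0, 1.5)
                for i in range(40)]
        frac = supra_sub_fractions(_records(rows)).set_index("promoter")
        total = (frac.loc["P1", "pct_supra"] + frac.loc["P1", "pct_sub"]
                 + frac.loc["P1", "pct_within_1sd"])
        assert total == pytest.approx(100.0)


class TestModelPreference:
    def test_obs_at_additive_prefers_additive(self):
        recs = _records([("P1", "E1", "E2", 4.0, 4.0, 1.0)])
        pref = model_preference(recs, min_gap=0.5)
        assert pref["frac_multiplicative"].iloc[0] == 0.0

    def test_obs_at_multiplicative_prefers_multiplicative(self):
        recs = _records([("P1", "E1", "E2", 6.0, 4.0, 1.0)])  # mult = 6
        pref = model_preference(recs, min_gap=0.5)
        assert pref["frac_multiplicative"].iloc[0] == 1.0

    def test_small_gap_excluded_from_denominator(self):
        recs = _records([("P1", "E1", "E2", 4.0, 4.0, 1.0)])
        # gap is log2(1.5) ~ 0.585: present at 0.5, absent at 0.6
        assert model_preference(recs, min_gap=0.5)["n_eligible"].iloc[0] == 1
        assert model_preference(recs, min_gap=0.6).empty


class TestEnhancerSummary:
    def test_no_flag_at_exact_additivity(self):
        recs = _records([("P1", "E1", "E2", 4.0, 4.0, 1.0),
                         ("P1", "E1", "E3", 4.0, 4.0, 1.0)])
        summary, counts = enhancer_additivity_summary(recs)
        assert (summary["mean_log2_obs_over_exp"] == 0).all()
        assert counts["n_flagged_ge1"] == 0

    def test_doubling_flags_enhancer(self):
        recs = _records([("P1", "E1", "E2", 8.0, 4.0, 1.0),
                         ("P2", "E1", "E2", 8.0, 4.0, 1.0)])
        summary, counts = enhancer_additivity_summary(recs)
        assert np.allclose(summary["mean_log2_obs_over_exp"], 1.0)
        assert counts["n_flagged_ge1"] == 2  # E1 and E2
        assert counts["n_flagged_ge2"] == 2  # both promoter contexts

    def test_mean_matches_brute_force_pair_list(self, rng):
        rows = []
        for i in range(6):
            for j in range(6):
                rows.append(("P1", f"E{i}", f"E{j}",
                             float(rng.uniform(2, 8)), 4.0, 1.0))
        recs = _records(rows)
        summary, _ = enhancer_additivity_summary(recs)
        target = summary.set_index(["enhancer", "promoter"])
        # brute force for enhancer E3: every pair containing it, either position
        sub = recs[(recs["frag1"] == "E3") | (recs["frag2"] == "E3")]
        assert target.loc[("E3", "P1"), "mean_log2_obs_over_exp"] == pytest.approx(
            sub["log2_obs_over_exp_add"].mean())
        assert target.loc[("E3", "P1"), "n_pairs"] == len(sub)


class TestClusterComparison:
    @staticmethod
    def _catalog():
        return pd.DataFrame({
            "fragment_id": ["E1", "E2", "E3", "E4", "C1"],
            "frag_class": ["enhancer"] * 4 + ["control"],
            "cluster": ["cl1", "cl1", "cl2", "cl2", "scrambled"],
        })

    def test_identical_groups_give_p_one(self):
        rows = [("P1", a, b, 4.0, 4.0, 1.0)
                for a, b in [("E1", "E2"), ("E3", "E4"),  # within cl1, cl2
                             ("E1", "E3"), ("E2", "E4")]]  # between
        res = cluster_comparison(_records(rows), self._catalog())
        assert res.p_value == 1.0
        assert res.n_within == 2 and res.n_between == 2

    def test_within_cluster_synergy_detected(self):
        rows = [("P1", "E1", "E2", 12.0, 4.0, 1.0),   # within, 1.58 log2 up
                ("P1", "E3", "E4", 11.0, 4.0, 1.0),   # within
                ("P1", "E1", "E3", 4.0, 4.0, 1.0),
                ("P1", "E1", "E4", 4.0, 4.0, 1.0),
                ("P1", "E2", "E3", 4.0, 4.0, 1.0),
                ("P1", "E2", "E4", 4.0, 4.0, 1.0)]
        res = cluster_comparison(_records(rows), self._catalog())
        assert res.within_median > res.between_median

    def test_pairs_partition(self):
        # ordered duplicates collapse onto one unordered pair per promoter
        rows = [("P1", "E1", "E2", 4.0, 4.0, 1.0),
                ("P1", "E2", "E1", 8.0, 4.0, 1.0),
                ("P1", "E1", "E3", 4.0, 4.0, 1.0)]
        res = cluster_comparison(_records(rows), self._catalog())
        assert res.n_within + res.n_between == 2


class TestExpectationRecordsIntegration:
    def test_invalid_records_flagged_and_excluded(self):
        # single-enhancer estimates below baseline -> negative expectation
        acts = pd.DataFrame({
            "promoter": "P1",
            "frag1": ["C1", "C2", "C1", "E1", "E2", "C1", "C1", "E1"],
            "frag2": ["C2", "C3", "C3", "C1", "C1", "E1", "E2", "E2"],
            "orient1": "+", "orient2": "+",
            "combo_class": ["CC", "CC", "CC", "EC", "EC", "CE", "CE", "EE"],
            "activity": [4.0, 4.0, 4.0, 1.0, 1.0, 1.0, 1.0, 1.0],
        })
        # add a second partner so SDs are defined
        extra = acts[acts["combo_class"].isin(["EC", "CE"])].copy()
        extra["frag1"] = extra["frag1"].replace({"C1": "C2"})
        extra["frag2"] = extra["frag2"].replace({"C1": "C2"})
        extra["activity"] = [1.2, 1.1, 1.15, 1.05]
        acts = pd.concat([acts, extra], ignore_index=True)
        baselines = promoter_baselines(acts)
        singles = single_enhancer_estimates(acts)
        recs = expectation_records(acts, baselines, singles)
        assert len(recs) == 1
        assert not recs["valid"].iloc[0]  # 1.x + 1.x - 4 < 0
        with pytest.raises(ValueError):
            supra_sub_fractions(recs)

    def test_recovers_additivity_on_simulated_library(self, small_bundle):
        recs = small_bundle["expectations"]
        assert recs["valid"].mean() > 0.9
        frac = small_bundle["fractions"].set_index("promoter")
        assert frac.loc["pooled", "pct_within_2sd"] >= 85.0
        # additive simulation: multiplicative model should rarely win
        pref = small_bundle["preference"].set_index("promoter")
        if "pooled" in pref.index:
            assert pref.loc["pooled", "frac_multiplicative"] <= 0.3
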