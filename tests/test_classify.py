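"""Eight-profile assignment: definitional cases, symmetry, ground-truth recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import make_counts
from heterosim.classify import (
    PROFILE_CATEGORY,
    PROFILE_COARSE,
    ROLE_SWAP,
    assign_profiles,
    classify_trio,
    midparent_test,
    profile_summary,
    trio_test_set,
)
from heterosim.simulate import TrioSimConfig, simulate_trio_counts


def make_row(q_hm=1.0, q_hp=1.0, q_mp=1.0, q_hmid=1.0, m=100.0, p=100.0, h=100.0):
    return pd.DataFrame(
        [
            {
                "mean_maternal": m, "mean_paternal": p, "mean_hybrid": h,
                "mid_parent": (m + p) / 2,
                "q_hm": q_hm, "q_hp": q_hp, "q_mp": q_mp, "q_hmid": q_hmid,
            }
        ]
    )


class TestDecisionTree:
    def test_transgressive_up(self):
        row = make_row(q_hm=0.001, q_hp=0.001, m=100, p=120, h=600)
        assert assign_profiles(row).iloc[0] == "P5"

    def test_transgressive_down(self):
        row = make_row(q_hm=0.001, q_hp=0.001, m=400, p=500, h=50)
        assert assign_profiles(row).iloc[0] == "P2"

    def test_maternal_dominance_high(self):
        # hybrid ~ maternal, maternal >> paternal -> P6
        row = make_row(q_hp=0.001, q_mp=0.001, m=400, p=100, h=410)
        assert assign_profiles(row).iloc[0] == "P6"

    def test_maternal_dominance_low(self):
        row = make_row(q_hp=0.001, q_mp=0.001, m=100, p=400, h=95)
        assert assign_profiles(row).iloc[0] == "P1"

    def test_paternal_dominance_both_directions(self):
        assert (
            assign_profiles(make_row(q_hm=0.001, m=400, p=100, h=105)).iloc[0] == "P3"
        )
        assert (
            assign_profiles(make_row(q_hm=0.001, m=100, p=400, h=390)).iloc[0] == "P4"
        )

    def test_additive_both_orientations(self):
        row = make_row(q_mp=0.001, q_hm=0.001, q_hp=0.001, m=100, p=400, h=250)
        assert assign_profiles(row).iloc[0] == "P0"
        row = make_row(q_mp=0.001, q_hm=0.001, q_hp=0.001, m=400, p=100, h=250)
        assert assign_profiles(row).iloc[0] == "P7"

    def test_all_indistinguishable_unclassified(self):
        assert assign_profiles(make_row()).iloc[0] == "unclassified"

    def test_exhaustive_and_exclusive_over_outcome_combinations(self):
        # brute force over all significance patterns and mean orderings:
        # exactly one label, always
        sigs = (0.01, 0.5)
        orders = [(100, 200, 300), (300, 200, 100), (200, 100, 300),
                  (100, 300, 200), (150, 150, 150)]
        for q_hm, q_hp, q_mp, q_hmid in itertools.product(sigs, repeat=4):
            for m, p, h in orders:
                lab = assign_profiles(
                    make_row(q_hm, q_hp, q_mp, q_hmid, m, p, h)
                ).iloc[0]
                assert lab in PROFILE_CATEGORY

    def test_alpha_monotonicity_never_transgressive_to_additive(self):
        # raising alpha can only move genes toward (not away from) the
        # stronger transgressive claim; brute force over outcomes
        sigs = (0.002, 0.02, 0.2)
        orders = [(100, 200, 300), (300, 200, 100), (100, 300, 200),
                  (300, 100, 200), (100, 200, 600), (400, 500, 50)]
        for qs in itertools.product(sigs, repeat=4):
            for m, p, h in orders:
                row = make_row(*qs, m, p, h)
                labels = [assign_profiles(row, alpha=a).iloc[0] for a in (0.01, 0.05, 0.25)]
                coarse = [PROFILE_COARSE[lab] for lab in labels]
                for lo, hi in zip(coarse, coarse[1:]):
                    if lo == "overdominant":
                        assert hi != "additive"


class TestMidparentTest:
    def test_hybrid_at_midparent_null(self):
        counts, samples = make_counts(
            np.tile([100.0, 300.0, 200.0], (300, 1)), seed=1
        )
        res = trio_test_set(counts, samples, condition="stress")
        assert res["q_hmid"].median() > 0.2
        assert abs(res["lfc_hmid"].median()) < 0.1

    def test_hybrid_fourfold_above_midparent_significant(self):
        counts, samples = make_counts(
            np.tile([100.0, 300.0, 800.0], (300, 1)), seed=2
        )
        norm = counts / 1.0
        h = samples[samples.role == "hybrid"]["sample_id"].tolist()
        m = samples[samples.role == "maternal"]["sample_id"].tolist()
        p = samples[samples.role == "paternal"]["sample_id"].tolist()
        res = midparent_test(
            norm[h].to_numpy(), norm[m].to_numpy(), norm[p].to_numpy()
        )
        assert res["log2_ratio"].median() == pytest.approx(2.0, abs=0.15)
        assert (res["p"] < 0.05).mean() > 0.9

    def test_zero_midparent_flagged(self):
        h = np.array([[3.0, 4.0, 5.0]])
        zero = np.zeros((1, 3))
        res = midparent_test(h, zero, zero)
        assert bool(res["undefined"].iloc[0])
        assert res["p"].iloc[0] == 1.0


class TestRecovery:
    def test_profile_and_category_recovery(self, small_trio):
        _, counts, samples, truth = small_trio
        assign = classify_trio(counts, samples, condition="stress")
        true_profile = truth["label"].replace({"null": "unclassified"})
        profile_acc = (assign["profile"] == true_profile).mean()
        coarse_acc = (assign["coarse"] == true_profile.map(PROFILE_COARSE)).mean()
        assert profile_acc >= 0.85
        assert coarse_acc >= 0.95

    def test_role_swap_symmetry_exact(self, small_trio):
        _, counts, samples, _ = small_trio
        swapped = samples.copy()
        swapped["role"] = samples["role"].map(
            {"maternal": "paternal", "paternal": "maternal", "hybrid": "hybrid"}
        )
        base = classify_trio(counts, samples, condition="stress")
        flip = classify_trio(counts, swapped, condition="stress")
        assert (flip["profile"] == base["profile"].map(ROLE_SWAP)).all()

    def test_universe_all_classifies_everything_deg_restricts(self, small_trio):
        _, counts, samples, _ = small_trio
        deg = classify_trio(counts, samples, condition="stress", universe="deg")
        allu = classify_trio(counts, samples, condition="stress", universe="all")
        assert deg["in_universe"].sum() < len(deg)
        # genes outside the DEG universe are never assigned a profile
        outside = ~deg["in_universe"]
        assert (deg.loc[outside, "profile"] == "unclassified").all()
        assert allu["in_universe"].all()

    def test_missing_role_errors(self, small_trio):
        _, counts, samples, _ = small_trio
        no_hybrid = samples[samples.role != "hybrid"]
        with pytest.raises(ValueError, match="hybrid"):
            classify_trio(counts, no_hybrid, condition="stress")


class TestSummary:
    def test_published_nonadditive_fraction_arithmetic(self):
        # 25,829 non-additive genes over a 65,547-gene DEG universe -> 39.41%
        universe = [f"g{i}" for i in range(65547)]
        profiles = np.array(["P0"] * (65547 - 25829) + ["P5"] * 25829)
        assignments = pd.DataFrame({"profile": profiles}, index=universe)
        out = profile_summary(assignments, deg_universe=universe)
        assert out["non_additive"] == 25829
        assert out["non_additive_pct"] == pytest.approx(39.41, abs=0.005)

    def test_all_additive_zero_fraction(self):
        assignments = pd.DataFrame({"profile": ["P0", "P7"]}, index=["a", "b"])
        out = profile_summary(assignments, deg_universe=["a", "b"])
        assert out["non_additive_pct"] == 0.0

    def test_universe_equals_nonadditive_set(self):
        assignments = pd.DataFrame(
            {"profile": ["P1", "P2", "P0"]}, index=["a", "b", "c"]
        )
        out = profile_summary(assignments, deg_universe=["a", "b"])
        assert out["non_additive_pct"] == 100.0

    def test_empty_universe_rejected(self):
        assignments = pd.DataFrame({"profile": ["P1"]}, index=["a"])
        with pytest.raises(ValueError):
            profile_summary(assignments, deg_universe=[])
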