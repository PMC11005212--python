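"""Normalization, RPKM, BH adjustment, and the two-group DE test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_counts
from heterosim import expression as ex
from heterosim.simulate import TrioSimConfig, simulate_trio_counts


def brute_force_bh(p):
    """Independent step-up oracle: q_(i) = min_{j>=i} p_(j) * n / j, capped."""
    p = np.asarray(p, dtype=float)
    n = p.size
    order = np.argsort(p, kind="mergesort")
    q = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * n / rank)
        q[idx] = running
    return q


class TestSizeFactors:
    def test_identical_columns_equal_factors(self):
        counts = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5]})
        f = ex.size_factors(counts)
        assert np.allclose(f, f.iloc[0])

    def test_scalar_multiple_recovered(self):
        rng = np.random.default_rng(1)
        col = rng.poisson(100, 200) + 1
        counts = pd.DataFrame({"a": col, "b": 2 * col})
        f = ex.size_factors(counts)
        assert f["b"] / f["a"] == pytest.approx(2.0)

    def test_single_gene_proportional_to_counts(self):
        counts = pd.DataFrame([[5, 10, 20]], columns=list("abc"))
        f = ex.size_factors(counts)
        assert np.allclose(f / f["a"], [1, 2, 4])

    def test_idempotent_after_normalization(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(rng.poisson(50, size=(300, 4)) + 1, columns=list("abcd"))
        norm = ex.normalize(counts)
        f2 = ex.size_factors(norm)
        assert np.allclose(f2, 1.0, atol=0.02)

    def test_fallback_total_count(self, caplog):
        # no gene nonzero everywhere -> total-count scaling
        counts = pd.DataFrame({"a": [10, 0], "b": [0, 30]})
        with caplog.at_level("WARNING"):
            f = ex.size_factors(counts)
        assert "total-count" in caplog.text
        assert f["b"] / f["a"] == pytest.approx(3.0)

    def test_library_factors_recovered_from_simulation(self):
        cfg = TrioSimConfig(n_genes=4000, seed=6)
        counts, samples, _ = simulate_trio_counts(cfg)
        f = ex.size_factors(counts)
        lf = samples.set_index("sample_id")["library_factor"]
        ratio = (f / lf).to_numpy()
        ratio /= np.exp(np.mean(np.log(ratio)))
        assert np.allclose(ratio, 1.0, atol=0.05)


class TestRPKM:
    def test_formula(self):
        counts = pd.DataFrame({"s": [10, 0]})
        out = ex.rpkm(counts, gene_length=[1000, 500], library_size=[1_000_000])
        assert out.iloc[0, 0] == pytest.approx(10.0)
        assert out.iloc[1, 0] == 0.0

    def test_library_scale_law(self):
        counts = pd.DataFrame({"s": [10]})
        a = ex.rpkm(counts, [1000], [1e6]).iloc[0, 0]
        b = ex.rpkm(counts, [1000], [2e6]).iloc[0, 0]
        assert a == pytest.approx(2 * b)

    def test_bad_lengths(self):
        with pytest.raises(ValueError):
            ex.rpkm(pd.DataFrame({"s": [1]}), [0], [1e6])


class TestBH:
    def test_four_value_example(self):
        q = ex.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert ex.bh_adjust([0.3]) == pytest.approx([0.3])
        assert np.allclose(ex.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ex.bh_adjust([0.5, 1.5])

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=1, max_size=10)
    )
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_oracle(self, p):
        assert np.allclose(ex.bh_adjust(p), brute_force_bh(p), atol=1e-12)

    @given(
        st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                 min_size=2, max_size=10)
    )
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_p(self, p):
        q = ex.bh_adjust(p)
        order = np.argsort(p, kind="mergesort")
        assert (np.diff(np.asarray(q)[order]) >= -1e-12).all()


class TestDETest:
    def test_identical_groups_null(self):
        counts, _ = make_counts(np.tile([200.0, 200.0, 200.0], (50, 1)), seed=3)
        a = [c for c in counts.columns if c.startswith("maternal")]
        b = [c for c in counts.columns if c.startswith("paternal")]
        # duplicate columns exactly: log2FC 0, p 1, never a DEG
        dup = counts[a].copy()
        dup.columns = b
        exact = pd.concat([counts[a], dup], axis=1)
        res = ex.de_test(exact, a, b)
        assert np.allclose(res["log2FC"], 0.0)
        assert (res["p"] > 0.99).all()
        assert not res["deg"].any()

    def test_symmetry_under_group_swap(self):
        counts, samples = make_counts(
            np.column_stack(
                [np.full(200, 100.0), np.full(200, 400.0), np.full(200, 150.0)]
            ),
            seed=4,
        )
        a = samples[samples.role == "maternal"]["sample_id"].tolist()
        b = samples[samples.role == "paternal"]["sample_id"].tolist()
        fwd = ex.de_test(counts, a, b)
        rev = ex.de_test(counts, b, a)
        assert np.allclose(fwd["log2FC"], -rev["log2FC"])
        assert np.allclose(fwd["p"], rev["p"])

    def test_strong_fold_change_detected_up(self):
        means = np.tile([100.0, 100.0, 100.0], (400, 1))
        means[:40, 2] = 800.0  # 8-fold hybrid genes
        counts, samples = make_counts(means, seed=5)
        h = samples[samples.role == "hybrid"]["sample_id"].tolist()
        m = samples[samples.role == "maternal"]["sample_id"].tolist()
        res = ex.de_test(counts, h, m)
        hits = res.iloc[:40]
        assert (hits["direction"] == "up").mean() > 0.9
        assert (res.iloc[40:]["deg"]).mean() < 0.02

    def test_null_type_one_error_calibrated(self):
        cfg = TrioSimConfig(
            n_genes=5000, class_proportions={"null": 1.0}, seed=123
        )
        counts, samples, _ = simulate_trio_counts(cfg)
        cond = samples[samples.condition == "stress"]
        h = cond[cond.role == "hybrid"]["sample_id"].tolist()
        m = cond[cond.role == "maternal"]["sample_id"].tolist()
        used = cond["sample_id"].tolist()
        res = ex.de_test(counts[used], h, m, ex.size_factors(counts[used]))
        assert 0.035 <= (res["p"] < 0.05).mean() <= 0.065

    def test_power_at_effect_size_four(self):
        # simulator genes with 4-fold separation at means >= 100: power > 0.9
        cfg = TrioSimConfig(n_genes=3000, seed=21)
        counts, samples, truth = simulate_trio_counts(cfg)
        cond = samples[samples.condition == "stress"]
        h = cond[cond.role == "hybrid"]["sample_id"].tolist()
        m = cond[cond.role == "maternal"]["sample_id"].tolist()
        used = cond["sample_id"].tolist()
        res = ex.de_test(counts[used], h, m, ex.size_factors(counts[used]))
        truth = truth.set_index("gene")
        fold = truth["mu_hybrid"] / truth["mu_maternal"]
        strong = (fold >= 4) | (fold <= 0.25)
        assert res.loc[strong.values, "deg"].mean() > 0.9

    def test_all_zero_gene_p_one(self):
        counts = pd.DataFrame(
            [[0, 0, 0, 0, 0, 0], [10, 12, 9, 11, 10, 13]],
            columns=list("abcdef"),
        )
        res = ex.de_test(counts, list("abc"), list("def"))
        assert res.iloc[0]["p"] == 1.0

    def test_too_few_replicates_rejected(self):
        counts = pd.DataFrame([[1, 2, 3]], columns=list("abc"))
        with pytest.raises(ValueError):
            ex.de_test(counts, ["a"], ["b", "c"])
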