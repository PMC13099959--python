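"""Frequencies, log2 fold-changes, Welch/BH statistics, and the
observed-vs-predicted machinery."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mfcomp import (
    adjust_pvalues,
    classify_volcano,
    compare_observed_predicted,
    condition_contrast,
    enrichment_table,
    infer_efficiencies,
    log2_fold_change,
    mating_cycle_update,
    predict_frequencies,
    to_frequencies,
    welch_t_test,
)


def welch_oracle(a, b):
    """Textbook Welch statistic with Satterthwaite df, independent of the
    implementation under test."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    from scipy.stats import t as tdist

    p = 2 * tdist.sf(abs(t), df)
    return t, df, p


def bh_oracle(p):
    """Brute-force step-up Benjamini-Hochberg."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adj[i] = running
    return np.clip(adj, 0, 1)


class TestFrequencies:
    def test_uniform_counts(self):
        f = to_frequencies(pd.DataFrame({"s": [10, 10]}), pseudocount=0)
        np.testing.assert_allclose(f["s"], [0.5, 0.5])

    def test_pseudocount_direct_value(self):
        f = to_frequencies(pd.DataFrame({"s": [0, 99]}), pseudocount=0.5)
        np.testing.assert_allclose(f["s"], [0.5 / 100, 99.5 / 100], rtol=1e-12)

    def test_columns_sum_to_one(self, rng):
        counts = pd.DataFrame(rng.integers(0, 100, size=(30, 4)))
        f = to_frequencies(counts)
        np.testing.assert_allclose(f.sum(axis=0), 1.0, atol=1e-9)

    def test_zero_read_sample_is_an_error(self):
        with pytest.raises(ValueError, match="zero matched"):
            to_frequencies(pd.DataFrame({"empty": [0, 0]}), pseudocount=0)


class TestLog2FoldChange:
    def test_identical_tables_give_zero(self):
        f = pd.DataFrame({"r1": [0.4, 0.6], "r2": [0.3, 0.7]})
        assert (log2_fold_change(f, f) == 0).all().all()

    def test_direct_value(self):
        end = pd.DataFrame({"r1": [0.04, 0.96]})
        start = pd.DataFrame({"r1": [0.01, 0.99]})
        lfc = log2_fold_change(end, start)
        assert lfc.loc[0, "r1"] == pytest.approx(2.0, abs=1e-12)

    def test_fourfold_is_the_volcano_cut(self):
        end = pd.DataFrame({"r1": [0.2, 0.8]})
        start = pd.DataFrame({"r1": [0.05, 0.95]})
        assert log2_fold_change(end, start).loc[0, "r1"] == pytest.approx(2.0)

    def test_unpaired_replicate_is_an_error(self):
        end = pd.DataFrame({"r1": [0.5, 0.5]})
        start = pd.DataFrame({"other": [0.5, 0.5]})
        with pytest.raises(ValueError):
            log2_fold_change(end, start)
        with pytest.raises(ValueError, match="unpaired"):
            log2_fold_change(end, start, {"r1": "missing"})

    def test_contrast_of_reference_against_itself_is_zero(self):
        ref = pd.DataFrame({"r1": [0.2, 0.8], "r2": [0.25, 0.75]})
        assert (condition_contrast(ref, ref) == 0).all().all()

    def test_thirtyfold_contrast_scale(self):
        cond = pd.DataFrame({"r1": [30 / 129, 99 / 129]})
        ref = pd.DataFrame({"r1": [1 / 100, 99 / 100]})
        lfc = condition_contrast(cond, ref)
        assert lfc.loc[0, "r1"] == pytest.approx(math.log2(30 * 100 / 129), rel=1e-9)


class TestWelch:
    def test_identical_groups(self):
        res = welch_t_test([1, 2, 3], [1, 2, 3])
        assert res.t == 0.0 and res.p == pytest.approx(1.0)

    @pytest.mark.parametrize(
        "a,b",
        [
            ([1, 2, 3], [4, 5, 6]),
            ([0.1, 0.5, 0.9, 1.3], [2.0, 2.1]),
            ([10, 11, 12, 13, 30], [9, 9.5, 10.5]),
        ],
    )
    def test_matches_independent_oracle(self, a, b):
        t0, df0, p0 = welch_oracle(a, b)
        res = welch_t_test(a, b)
        assert res.t == pytest.approx(t0, abs=1e-10)
        assert res.df == pytest.approx(df0, abs=1e-10)
        assert res.p == pytest.approx(p0, abs=1e-10)

    def test_satterthwaite_df_below_pooled(self):
        a, b = [1.0, 1.1, 0.9], [5.0, 9.0, 1.0, 13.0]
        res = welch_t_test(a, b)
        assert res.df < len(a) + len(b) - 2

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            welch_t_test([1.0], [1, 2, 3])

    def test_degenerate_zero_variance(self):
        assert welch_t_test([2, 2], [2, 2]).p == 1.0
        res = welch_t_test([3, 3], [2, 2])
        assert res.p == 0.0 and res.t == math.inf


class TestAdjustment:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03]), [0.03])

    def test_hand_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_all_ones(self):
        np.testing.assert_allclose(adjust_pvalues([1.0, 1.0, 1.0]), 1.0)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_bruteforce_and_never_below_raw(self, p):
        adj = adjust_pvalues(p)
        np.testing.assert_allclose(adj, bh_oracle(p), atol=1e-12)
        assert (adj >= np.asarray(p) - 1e-15).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_rank_idempotent(self, rng):
        p = rng.uniform(size=20)
        once = adjust_pvalues(p)
        twice = adjust_pvalues(once)
        # re-adjusting preserves the (weak) ordering of already-adjusted values
        order = np.argsort(once, kind="stable")
        assert (np.diff(twice[order]) >= -1e-15).all()
        # and ties stay ties
        for i in range(len(once) - 1):
            a, b = order[i], order[i + 1]
            if once[a] == once[b]:
                assert twice[a] == twice[b]

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            adjust_pvalues([0.5, 1.5])

    def test_alternative_methods(self):
        p = [0.01, 0.04]
        np.testing.assert_allclose(adjust_pvalues(p, "bonferroni"), [0.02, 0.08])
        np.testing.assert_allclose(adjust_pvalues(p, "holm"), [0.02, 0.04])


class TestVolcano:
    @pytest.mark.parametrize(
        "lfc,adj_p,expected",
        [
            (0.0, 1.0, "neutral"),
            (2.0, 0.04, "enriched"),  # boundary |log2FC| = 2 counts
            (-2.0, 0.04, "depleted"),
            (-3.0, 0.2, "neutral"),  # fails significance
            (1.9, 0.001, "neutral"),  # fails effect size
            (5.0, 0.05, "neutral"),  # alpha is strict
        ],
    )
    def test_rule(self, lfc, adj_p, expected):
        assert classify_volcano(lfc, adj_p) == expected


class TestPrediction:
    def test_zero_cycles_is_identity(self):
        f0 = np.array([0.2, 0.8])
        np.testing.assert_allclose(predict_frequencies(f0, [0.0, 1.0], 0), f0)

    def test_direct_value(self):
        np.testing.assert_allclose(
            predict_frequencies([0.5, 0.5], [1.0, 3.0], 1), [0.25, 0.75], rtol=1e-12
        )

    def test_equals_iterated_update(self, rng):
        # oracle: chain the per-cycle update T times
        for _ in range(10):
            n = int(rng.integers(2, 10))
            f0 = rng.dirichlet(np.ones(n))
            m = rng.uniform(0.05, 1.0, size=n)
            T = int(rng.integers(1, 8))
            f = f0.copy()
            for _ in range(T):
                f = mating_cycle_update(f, m)
            np.testing.assert_allclose(predict_frequencies(f0, m, T), f, rtol=1e-12)

    def test_all_dead_is_an_error(self):
        with pytest.raises(ValueError, match="extinct"):
            predict_frequencies([0.5, 0.5], [0.0, 0.0], 1)


class TestInference:
    def test_no_change_gives_unit_efficiencies(self):
        f = pd.Series([0.3, 0.7], index=["WT", "T2Q"])
        np.testing.assert_allclose(infer_efficiencies(f, f, 5), 1.0)

    def test_recovers_ratio_from_prediction(self):
        f0 = np.array([0.5, 0.5])
        fT = predict_frequencies(f0, [1.0, 3.0], 1)
        m_hat = infer_efficiencies(f0, fT, 1, reference_variant=0)
        np.testing.assert_allclose(m_hat, [1.0, 3.0], rtol=1e-12)

    def test_round_trip_composition(self, rng):
        n = 8
        f0 = rng.dirichlet(np.ones(n))
        m = rng.uniform(0.1, 1.0, size=n)
        fT = predict_frequencies(f0, m, 5)
        m_hat = infer_efficiencies(f0, fT, 5, reference_variant=0)
        np.testing.assert_allclose(m_hat, m / m[0], rtol=1e-10)

    def test_zero_frequency_advises_pseudocounts(self):
        with pytest.raises(ValueError, match="pseudocount"):
            infer_efficiencies(np.array([0.5, 0.5]), np.array([0.0, 1.0]), 5, 0)


class TestObservedPredicted:
    def test_perfect_agreement(self):
        c = compare_observed_predicted([0.1, 0.2, 0.7], [0.1, 0.2, 0.7])
        assert c.pearson_r == pytest.approx(1.0)

    def test_anticorrelation(self):
        c = compare_observed_predicted([1, 2, 3], [3, 2, 1])
        assert c.pearson_r == pytest.approx(-1.0)
        assert c.r_squared == pytest.approx(1.0)

    def test_hand_computed_four_points(self):
        x = np.array([1.0, 2.0, 3.0, 5.0])
        y = np.array([2.0, 1.0, 4.0, 6.0])
        # manual Pearson formula
        r0 = float(((x - x.mean()) * (y - y.mean())).sum()
                   / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()))
        c = compare_observed_predicted(x, y)
        assert c.pearson_r == pytest.approx(r0, abs=1e-12)
        assert c.r_squared == pytest.approx(r0 * r0, abs=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError, match="variance"):
            compare_observed_predicted([1, 1, 1], [1, 2, 3])


class TestEnrichmentTable:
    def test_columns_and_classes(self, rng):
        variants = [f"v{i}" for i in range(10)]
        base = rng.dirichlet(np.ones(10))
        reps = base[:, None] * (1 + rng.normal(0, 0.01, size=(10, 3)))  # tight replicates
        start = pd.DataFrame(reps / reps.sum(axis=0), index=variants, columns=["r1", "r2", "r3"])
        end = start.copy()
        end.loc["v0"] *= 40  # strongly enriched
        end = end / end.sum(axis=0)
        tbl = enrichment_table(end, start)
        assert list(tbl.columns) == [
            "log2fc_rep1", "log2fc_rep2", "log2fc_rep3",
            "log2fc_mean", "log2fc_sd", "p_value", "adj_p", "class",
        ]
        assert (tbl["adj_p"] >= tbl["p_value"] - 1e-15).all()
        assert tbl.loc["v0", "class"] == "enriched"
        assert tbl.loc["v0", "log2fc_mean"] > 2
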