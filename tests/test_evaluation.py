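"""Metrics, fold assignment and the statistical battery (toy-scale checks)."""

import itertools
from math import comb

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kbinding.classifier import ModelConfig
from kbinding.evaluation import (
    assign_folds,
    auprc,
    cross_validate,
    dunn_posthoc_fdr,
    f1_score,
    kruskal_wallis_epsilon,
    logistic_baseline,
    paired_and_unpaired_tests,
    sign_test,
)


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([[1, 0], [0, 1], [1, 1]])
        assert f1_score(y, y) == 1.0
        assert auprc(y, y.astype(float)) == 1.0

    def test_all_positive_prevalence_closed_form(self):
        rng = np.random.default_rng(0)
        y = (rng.random(200) < 0.3).astype(int)
        pred = np.ones(200, dtype=bool)
        pi = y.mean()
        assert f1_score(y, pred) == pytest.approx(2 * pi / (1 + pi))

    def test_auprc_matches_rank_sum_oracle(self):
        y = np.array([1, 0, 1, 0, 0])
        s = np.array([0.9, 0.8, 0.6, 0.4, 0.2])
        # oracle: mean precision at each positive's rank (descending scores)
        order = np.argsort(-s)
        hits, precisions = 0, []
        for rank, i in enumerate(order, start=1):
            if y[i]:
                hits += 1
                precisions.append(hits / rank)
        assert auprc(y, s) == pytest.approx(np.mean(precisions))

    def test_no_positives_is_missing(self):
        assert np.isnan(auprc(np.zeros(5), np.arange(5.0)))
        assert np.isnan(f1_score(np.zeros(5), np.zeros(5)))


class TestFolds:
    def test_partition_covers_all_rows_once(self):
        k = np.random.default_rng(0).integers(0, 8, size=1000)
        folds = assign_folds(k, 10, np.random.default_rng(1))
        assert folds.shape == (1000,)
        assert set(np.unique(folds)) == set(range(10))
        sizes = np.bincount(folds)
        assert sizes.max() - sizes.min() <= 8  # one per stratum at most

    def test_stratification_balances_strata(self):
        k = np.array([0] * 900 + [7] * 100)
        folds = assign_folds(k, 10, np.random.default_rng(0))
        for f in range(10):
            assert (k[folds == f] == 7).sum() == 10


class TestKruskalWallis:
    def test_identical_groups_have_zero_effect(self):
        res = kruskal_wallis_epsilon([[1.0, 1.0], [1.0, 1.0]])
        assert res.statistic == 0.0 and res.effect_size == 0.0 and res.pvalue == 1.0

    def test_separated_groups_match_rank_oracle(self):
        a = list(range(10))
        b = list(range(100, 110))
        res = kruskal_wallis_epsilon([a, b])
        # oracle: H from explicit mean ranks, no ties
        n = 20
        ra, rb = np.mean(range(1, 11)), np.mean(range(11, 21))
        H = 12 / (n * (n + 1)) * (10 * ra**2 + 10 * rb**2) - 3 * (n + 1)
        assert res.statistic == pytest.approx(H, abs=1e-10)
        assert res.effect_size == pytest.approx(H / (n - 1))
        assert 0 <= res.effect_size <= 1


class TestDunn:
    def test_identical_groups_give_q_near_one(self):
        out = dunn_posthoc_fdr([[1, 1, 1], [1, 1, 1], [1, 1, 1]])
        assert (out["qvalue"] > 0.99).all()

    def test_z_matches_hand_formula_without_ties(self):
        groups = [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0], [7.0, 8.0, 9.0]]
        out = dunn_posthoc_fdr(groups, labels=["a", "b", "c"])
        N = 9
        mean_ranks = [2.0, 5.0, 8.0]
        var = N * (N + 1) / 12.0
        for _, row in out.iterrows():
            i = ["a", "b", "c"].index(row["group_a"])
            j = ["a", "b", "c"].index(row["group_b"])
            z = (mean_ranks[i] - mean_ranks[j]) / np.sqrt(var * (2 / 3))
            assert row["z"] == pytest.approx(z, abs=1e-10)

    def test_bh_qvalues_monotone_in_pvalues(self):
        rng = np.random.default_rng(0)
        groups = [rng.normal(size=6) + i * 0.5 for i in range(4)]
        out = dunn_posthoc_fdr(groups).sort_values("pvalue")
        assert (out["qvalue"].diff().dropna() >= -1e-12).all()


class TestPairedUnpaired:
    def test_identical_paired_vectors_degenerate_wilcoxon(self):
        res = paired_and_unpaired_tests([1, 2, 3], [1, 2, 3], kind="wilcoxon_signed_rank")
        assert res.pvalue == 1.0

    def test_one_sample_t_at_null_mean(self):
        res = paired_and_unpaired_tests([-1.0, 1.0, -2.0, 2.0], kind="one_sample_t")
        assert res.statistic == pytest.approx(0.0)

    def test_u_statistic_matches_pair_count_oracle(self):
        a = [1.2, 3.4, 0.5, 7.7, 2.2, 9.9]
        b = [0.1, 4.4, 2.3, 1.1, 6.6, 0.9]
        res = paired_and_unpaired_tests(a, b, kind="mann_whitney")
        U = sum((x > y) + 0.5 * (x == y) for x in a for y in b)
        assert res.statistic == U

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError):
            paired_and_unpaired_tests([1], [2], kind="bootstrap")

    def test_sign_test_exact(self):
        res = sign_test(15, 20)
        assert res.pvalue == pytest.approx(
            sum(comb(20, i) for i in range(15, 21)) / 2**20
        )


def small_profiles(n=120, seed=0):
    """Learnable toy profile table over 7 pseudo-targets."""
    rng = np.random.default_rng(seed)
    letters = list("ARNDEGHILKMFPSTWYVQ")
    targets = [f"T{i}" for i in range(1, 8)]
    rows = []
    for _ in range(n):
        seq = "".join(rng.choice(letters, 6))
        row = {"cdr3_alpha": seq[:3], "cdr3_beta": seq[3:]}
        row["T1"] = seq[0] in "ARNDEGHIL"
        row["T2"] = seq[0] in "ARNDEGHIL" and seq[3] in "KRHILMF"
        for t in targets[2:]:
            row[t] = False
        rows.append(row)
    df = pd.DataFrame(rows)
    df["k"] = df[targets].sum(axis=1)
    return df, targets


class TestCrossValidate:
    def test_folds_partition_and_result_shape(self):
        df, targets = small_profiles()
        cfg = ModelConfig(hidden_sizes=(16,), epochs=2, batch_size=32, seed=0)
        res = cross_validate(df, targets, "VHSE8", cfg, n_folds=4, n_seed_reps=1)
        assert set(res["fold"]) == {0, 1, 2, 3}
        overall = res[(res.stratum == "all") & (res.target == "all")]
        assert len(overall) == 4
        assert res["f1"].dropna().between(0, 1).all()
        assert res["auprc"].dropna().between(0, 1).all()

    def test_micro_f1_between_min_and_max_per_target(self):
        df, targets = small_profiles(n=200, seed=2)
        cfg = ModelConfig(hidden_sizes=(32,), epochs=20, learning_rate=2e-3,
                          batch_size=32, seed=0)
        res = cross_validate(df, targets, "BLOSUM50", cfg, n_folds=3, n_seed_reps=1)
        for f in range(3):
            sub = res[(res.fold == f) & (res.stratum == "all")]
            micro = sub[sub.target == "all"]["f1"].iloc[0]
            per_t = sub[~sub.target.isin(["all", "all_macro"])]["f1"].dropna()
            if len(per_t) and not np.isnan(micro):
                assert per_t.min() - 1e-9 <= micro <= per_t.max() + 1e-9

    def test_logistic_baseline_aligns_with_mlp_cells(self):
        df, targets = small_profiles(n=150, seed=1)
        cfg = ModelConfig(hidden_sizes=(16,), epochs=2, batch_size=32, seed=0)
        folds = {0: assign_folds(df["k"].to_numpy(), 3, np.random.default_rng(0))}
        mlp = cross_validate(df, targets, "BLOSUM50", cfg, n_folds=3, n_seed_reps=1,
                             fold_assignments=folds)
        logi = logistic_baseline(df, targets, "BLOSUM50", cfg, n_folds=3,
                                 n_seed_reps=1, fold_assignments=folds)
        key = ["seed", "fold", "stratum", "target"]
        assert mlp[key].equals(logi[key])

    def test_logistic_separable_toy_is_perfect(self):
        df, targets = small_profiles(n=200, seed=3)
        res = logistic_baseline(df, targets, "ONEHOT", n_folds=4, n_seed_reps=1)
        t1 = res[(res.stratum == "all") & (res.target == "T1")]["f1"].dropna()
        assert (t1 > 0.9).all()
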