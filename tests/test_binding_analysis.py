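"""Binder calling, strata, binomial cross-reactivity test, logos, diagnostics."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from kbinding.binding_analysis import (
    build_logo,
    call_binders,
    crossreactivity_binomial_test,
    logo_grid,
    multi_binding_null_rate,
    observed_universe,
    panning_diagnostics,
    profile_variants,
    stratum_counts,
)
from kbinding.synthetic_data import DEFAULT_TARGETS


def panning_fixture():
    """Ten variants with printed round-3 counts for both replicates."""
    seqs = [
        "DSWAAA", "DSWDDD", "DSWEEE", "DSWFFF", "DSWGGG",
        "AAAAAA", "DDDDDD", "EEEEEE", "FFFFFF", "GGGGGG",
    ]
    reads_rep1 = [5, 2, 0, 7, 1, 0, 3, 0, 9, 1]
    reads_rep2 = [2, 0, 4, 1, 1, 0, 5, 0, 0, 2]
    rows = []
    for rep, reads in [(1, reads_rep1), (2, reads_rep2)]:
        for s, r in zip(seqs, reads):
            rows.append(
                {"target": "Tax", "replicate": rep, "round": 3,
                 "cdr3_alpha": s[:3], "cdr3_beta": s[3:], "reads": r}
            )
    return pd.DataFrame(rows), seqs, reads_rep1, reads_rep2


class TestCallBinders:
    def test_presence_in_both_replicates(self):
        pan, seqs, r1, r2 = panning_fixture()
        called = call_binders(pan, "Tax")
        # independent oracle: exhaustive row scan
        expected = {s for s, a, b in zip(seqs, r1, r2) if a >= 1 and b >= 1}
        assert called == expected
        assert "DSWAAA" in called  # (5, 2)
        assert "DSWDDD" not in called  # (2, 0)

    def test_monotone_in_min_reads(self):
        pan, *_ = panning_fixture()
        prev = call_binders(pan, "Tax", min_reads=1)
        for mr in (2, 3, 5):
            cur = call_binders(pan, "Tax", min_reads=mr)
            assert cur <= prev
            prev = cur

    def test_missing_replicate_raises_with_names(self):
        pan, *_ = panning_fixture()
        with pytest.raises(ValueError, match="replicate=2"):
            call_binders(pan[pan["replicate"] == 1], "Tax", final_round=3)
        with pytest.raises(ValueError, match="no panning data"):
            call_binders(pan, "HUD")


class TestProfiles:
    def test_k_and_membership(self):
        universe = ["AAAAAA", "DDDDDD", "EEEEEE"]
        binder_sets = {t: set() for t in DEFAULT_TARGETS}
        binder_sets["Tax"].add("AAAAAA")
        for t in DEFAULT_TARGETS:
            binder_sets[t].add("DDDDDD")
        prof = profile_variants(binder_sets, universe, DEFAULT_TARGETS)
        by_seq = prof.set_index(prof["cdr3_alpha"] + prof["cdr3_beta"])
        assert by_seq.loc["AAAAAA", "k"] == 1 and by_seq.loc["AAAAAA", "Tax"]
        assert by_seq.loc["DDDDDD", "k"] == 7
        assert by_seq.loc["EEEEEE", "k"] == 0

    def test_strata_sum_to_universe(self, tiny_profiles):
        counts = stratum_counts(tiny_profiles)
        assert sum(counts.values()) == len(tiny_profiles)
        assert set(counts) == set(range(8))

    def test_missing_binder_set_raises(self):
        with pytest.raises(ValueError, match="HOM"):
            profile_variants({"Tax": set()}, ["AAAAAA"], DEFAULT_TARGETS)


class TestBinomial:
    def test_null_rate_closed_form(self):
        # q = P(k>=2 | 7 x Bernoulli(0.1)) = 1 - 0.9^7 - 7*0.1*0.9^6
        q = multi_binding_null_rate([0.1] * 7)
        assert q == pytest.approx(1 - 0.9**7 - 7 * 0.1 * 0.9**6, abs=1e-12)

    def test_pvalue_matches_direct_tail_sum(self):
        strata = {0: 60, 1: 10, 2: 20, 3: 10, **{k: 0 for k in range(4, 8)}}
        q = multi_binding_null_rate([0.1] * 7)
        res = crossreactivity_binomial_test(strata, [0.1] * 7)
        n, obs = 100, 30
        # oracle: explicit binomial tail summation
        from math import comb

        tail = sum(comb(n, i) * q**i * (1 - q) ** (n - i) for i in range(obs, n + 1))
        assert res.observed_multi == obs and res.n_universe == n
        assert res.pvalue == pytest.approx(tail, rel=1e-10)

    def test_degenerate_null(self):
        res = crossreactivity_binomial_test({0: 5, 2: 1}, [0.0] * 7)
        assert res.null_rate == 0.0 and res.pvalue == 0.0

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            multi_binding_null_rate([0.5, 1.2] + [0.1] * 5)

    def test_synthetic_crossreactivity_is_detected(self, desk_profiles, landscape):
        """The shared alpha motif produces far more multi-binders than the
        independent-binding null."""
        strata = stratum_counts(desk_profiles)
        n = len(desk_profiles)
        rates = [desk_profiles[t].sum() / n for t in landscape.targets]
        res = crossreactivity_binomial_test(strata, rates)
        assert res.observed_multi > res.null_rate * n
        assert res.pvalue < 1e-20


class TestLogos:
    def test_identical_sequences_have_maximal_information(self):
        logo = build_logo(["DSWLAG"] * 4)
        assert np.allclose(logo.info.to_numpy(), np.log2(20))

    def test_uniform_usage_has_zero_information(self):
        from kbinding.sequence_space import CANONICAL_AA

        seqs = [aa * 6 for aa in CANONICAL_AA]
        logo = build_logo(seqs)
        assert np.allclose(logo.info.to_numpy(), 0.0, atol=1e-12)

    def test_toy_frequencies_and_entropy_by_hand(self):
        seqs = ["DSWLAG", "DSWLAG", "DAWLAG", "DAWLAG"]
        logo = build_logo(seqs)
        assert logo.freq.loc["a99", "D"] == 1.0
        assert logo.freq.loc["a100", "S"] == 0.5 == logo.freq.loc["a100", "A"]
        # H(a100) = 1 bit -> IC = log2(20) - 1
        assert logo.info["a100"] == pytest.approx(np.log2(20) - 1.0)
        assert logo.info["a99"] == pytest.approx(np.log2(20))

    def test_frequencies_sum_to_one(self, tiny_profiles):
        seqs = (tiny_profiles["cdr3_alpha"] + tiny_profiles["cdr3_beta"]).tolist()
        logo = build_logo(seqs)
        assert np.allclose(logo.freq.sum(axis=1), 1.0, atol=1e-9)
        assert ((logo.info >= 0) & (logo.info <= np.log2(20))).all()

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_logo([])

    def test_logo_grid_class_counts(self):
        # construct one variant per S-class for |S| in {1, 2}
        rows = []
        for S in itertools.chain(
            itertools.combinations(DEFAULT_TARGETS, 1),
            itertools.combinations(DEFAULT_TARGETS, 2),
        ):
            seq = "DSWLAG"
            row = {"cdr3_alpha": seq[:3], "cdr3_beta": seq[3:]}
            for t in DEFAULT_TARGETS:
                row[t] = t in S
            row["k"] = len(S)
            rows.append(row)
        prof = pd.DataFrame(rows)
        grid = logo_grid(prof, DEFAULT_TARGETS)
        assert len(grid) == 7 + 21 == 28
        three = logo_grid(prof, DEFAULT_TARGETS[:3])
        assert len(three) <= 3 + 3

    def test_two_binding_logos_are_richer_at_alpha_positions(
        self, desk_profiles, landscape
    ):
        """Cross-reactive classes concentrate on the shared alpha motif, so
        2-binding logos carry more alpha-position information than 1-binding
        logos on average."""
        grid = logo_grid(desk_profiles, landscape.targets)
        alpha_pos = ["a99", "a100", "a101"]
        ic1 = [m.info[alpha_pos].mean() for S, m in grid.items() if len(S) == 1]
        ic2 = [m.info[alpha_pos].mean() for S, m in grid.items() if len(S) == 2]
        assert len(ic1) > 0 and len(ic2) > 0
        assert np.mean(ic2) > np.mean(ic1)


class TestDiagnostics:
    def test_top_share_is_one_with_few_variants(self):
        pan, *_ = panning_fixture()
        d = panning_diagnostics(pan)
        assert (d["top100_share"] == 1.0).all()

    def test_matches_sort_and_sum_oracle(self, tiny_panning):
        d = panning_diagnostics(tiny_panning, top_n=10)
        grp = tiny_panning[
            (tiny_panning["target"] == "Tax")
            & (tiny_panning["replicate"] == 1)
            & (tiny_panning["round"] == 2)
        ]
        expected = (
            grp.sort_values("reads", ascending=False)["reads"].head(10).sum()
            / grp["reads"].sum()
        )
        row = d[(d["target"] == "Tax") & (d["replicate"] == 1) & (d["round"] == 2)]
        assert row["top10_share"].iloc[0] == pytest.approx(expected)

    def test_universe_is_sorted_and_unique(self, tiny_panning):
        uni = observed_universe(tiny_panning)
        assert uni == sorted(set(uni))
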