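"""Enrichment-score statistic, fold histogram, repertoire split, shifts."""

import math

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.proportion import proportions_ztest

from panenrich.enrichment import (
    EnrichmentError,
    EsContext,
    compute_es,
    es_table,
    fold_histogram,
    kabat_h3_labels,
    positional_shifts,
    split_by_fold,
    two_proportion_ztest,
)
from panenrich.ingest import CountTable


def reference_es(n_pre, n_post, N_pre, N_post, med_pre, med_post):
    """Spreadsheet-style independent evaluation of the ES formula."""
    a_pre = 0.5 if n_pre == 0 else n_pre
    a_post = 0.5 if n_post == 0 else n_post
    return math.log2((a_post / N_post) / (a_pre / N_pre)) * (
        (a_post + a_pre) / (med_post + med_pre)
    )


class TestComputeEs:
    def test_equal_frequencies_score_zero(self):
        ctx = EsContext(1000, 1000, 7, 13)
        assert compute_es(5, 5, ctx) == 0.0

    def test_hand_evaluated_case(self):
        ctx = EsContext(1e6, 1e6, 10, 20)
        assert compute_es(10, 40, ctx) == pytest.approx(10 / 3, abs=1e-12)

    def test_antisymmetric_under_pre_post_exchange(self):
        ctx = EsContext(1e6, 1e6, 10, 20)
        swapped = EsContext(1e6, 1e6, 20, 10)
        assert compute_es(40, 10, swapped) == pytest.approx(-10 / 3, abs=1e-12)

    def test_matches_reference_evaluation_on_random_tuples(self, rng):
        for _ in range(1000):
            n_pre, n_post = rng.integers(0, 500, size=2)
            if n_pre == 0 and n_post == 0:
                n_post = 1
            N_pre, N_post = rng.integers(10_000, 1_000_000, size=2)
            med_pre, med_post = rng.integers(1, 50, size=2)
            ctx = EsContext(N_pre, N_post, med_pre, med_post)
            expected = reference_es(n_pre, n_post, N_pre, N_post, med_pre, med_post)
            assert compute_es(n_pre, n_post, ctx) == pytest.approx(expected, abs=1e-12)

    def test_antisymmetry_property_on_random_tuples(self, rng):
        for _ in range(1000):
            n_pre, n_post = rng.integers(1, 500, size=2)
            N_pre, N_post = rng.integers(10_000, 1_000_000, size=2)
            med_pre, med_post = rng.integers(1, 50, size=2)
            forward = compute_es(n_pre, n_post, EsContext(N_pre, N_post, med_pre, med_post))
            backward = compute_es(n_post, n_pre, EsContext(N_post, N_pre, med_post, med_pre))
            assert forward == pytest.approx(-backward, abs=1e-12)

    def test_scale_invariance_on_random_tuples(self, rng):
        for _ in range(1000):
            n_pre, n_post = rng.integers(1, 500, size=2)
            N_pre, N_post = rng.integers(10_000, 1_000_000, size=2)
            med_pre, med_post = rng.integers(1, 50, size=2)
            k = int(rng.integers(2, 10))
            base = compute_es(n_pre, n_post, EsContext(N_pre, N_post, med_pre, med_post))
            scaled = compute_es(
                k * n_pre, k * n_post,
                EsContext(k * N_pre, k * N_post, k * med_pre, k * med_post),
            )
            assert scaled == pytest.approx(base, abs=1e-9)

    def test_unobserved_sequence_errors(self):
        with pytest.raises(EnrichmentError, match="unobserved_sequence"):
            compute_es(0, 0, EsContext(1000, 1000, 5, 5))


class TestEsTable:
    @staticmethod
    def _table(counts):
        t = CountTable("H3")
        for seq, (pre, post) in counts.items():
            if pre:
                t.add(seq, "pre", pre)
            if post:
                t.add(seq, "post", post)
            t.counts.setdefault(seq, {"pre": 0, "post": 0})
        return t

    def test_medians_and_signs(self):
        t = self._table({"A" * 9: (10, 10), "D" * 9: (10, 20), "G" * 9: (10, 5)})
        df, ctx = es_table(t)
        assert (ctx.med_pre, ctx.med_post) == (10, 10)
        es = df.set_index("aa_seq")["es"]
        # equal totals would give sign(0,+,-); with N_post=35 vs N_pre=30 the
        # frequency ratios shift, so compare against the reference evaluation
        for seq, (pre, post) in {"A" * 9: (10, 10), "D" * 9: (10, 20), "G" * 9: (10, 5)}.items():
            assert es[seq] == pytest.approx(
                reference_es(pre, post, 30, 35, 10, 10), abs=1e-12
            )

    def test_equal_totals_give_expected_signs(self):
        t = self._table({"A" * 9: (10, 10), "D" * 9: (10, 20), "G" * 9: (15, 5)})
        df, _ = es_table(t)
        es = df.set_index("aa_seq")["es"]
        assert es["A" * 9] == 0.0
        assert es["D" * 9] > 0
        assert es["G" * 9] < 0

    def test_doubling_counts_leaves_es_unchanged(self, small_panning):
        df1, _ = es_table(small_panning.table)
        doubled = self._table(
            {s: (2 * c["pre"], 2 * c["post"]) for s, c in small_panning.table.counts.items()}
        )
        df2, _ = es_table(doubled)
        merged = df1.merge(df2, on="aa_seq", suffixes=("_1", "_2"))
        # pseudocounted records change (0 -> 0.5 is not scaled), others do not
        clean = merged[~merged["pseudocounted_1"]]
        assert len(clean) > 0
        assert np.allclose(clean["es_1"], clean["es_2"], atol=1e-9)

    def test_single_sequence_weight_is_one(self):
        t = self._table({"A" * 9: (7, 3)})
        df, ctx = es_table(t)
        expected_log = math.log2((3 / 3) / (7 / 7))
        assert df["es"].iloc[0] == pytest.approx(expected_log * 1.0)

    def test_pseudocount_flag(self):
        t = self._table({"A" * 9: (10, 0), "D" * 9: (10, 20)})
        df, _ = es_table(t)
        flags = df.set_index("aa_seq")["pseudocounted"]
        assert bool(flags["A" * 9]) and not bool(flags["D" * 9])


class TestFoldHistogram:
    def test_counts_match_brute_force_binning(self, rng):
        log10_fold = rng.uniform(-2, 2, size=100)
        records = pd.DataFrame({"log10_fold": log10_fold})
        hist = fold_histogram(records)
        assert hist["count"].sum() == 100
        for i in range(len(hist)):
            left = hist["bin_left"].iloc[i]
            right = hist["bin_right"].iloc[i]
            expected = int(np.sum((log10_fold >= left) & (log10_fold < right)))
            if i == len(hist) - 1:  # numpy closes the final bin
                expected += int(np.sum(log10_fold == right))
            assert hist["count"].iloc[i] == expected

    def test_twenty_fold_record_lands_in_tail(self):
        records = pd.DataFrame({"log10_fold": [math.log10(20.0), 0.0]})
        hist = fold_histogram(records)
        assert hist.attrs["n_above_tail"] == 1
        assert hist.attrs["n_below_tail"] == 0

    def test_ratio_one_in_zero_bin(self):
        records = pd.DataFrame({"log10_fold": [0.0, 0.5]})
        hist = fold_histogram(records)
        zero_bin = hist[(hist["bin_left"] <= 0.0) & (hist["bin_right"] > 0.0)]
        assert zero_bin["count"].iloc[0] >= 1


class TestSplitByFold:
    def test_threshold_strictness(self):
        records = pd.DataFrame(
            {
                "aa_seq": ["A", "B", "C", "D", "E"],
                "log10_fold": [math.log10(r) for r in (2.5, 0.4, 1.0, 2.0, 0.5)],
            }
        )
        enriched, depleted = split_by_fold(records)
        assert list(enriched["aa_seq"]) == ["A"]
        assert list(depleted["aa_seq"]) == ["B"]


class TestPositionalShifts:
    @staticmethod
    def _records(seq_counts):
        rows = [
            {"aa_seq": s, "length": len(s), "n_pre": pre, "n_post": post}
            for s, (pre, post) in seq_counts.items()
        ]
        return pd.DataFrame(rows)

    def test_identical_repertoires_show_no_shift(self):
        recs = self._records({"GY": (50, 50), "SY": (50, 50)})
        out = positional_shifts(recs, 2, labels=["p1", "p2"])
        assert np.allclose(out["delta"], 0.0)
        assert (out["p_value"] > 0.99).all()

    def test_planted_shift_detected(self):
        # G at position 1 goes 10% -> 30% of 10,000 reads per repertoire
        recs = self._records({"GY": (1000, 3000), "SY": (9000, 7000)})
        out = positional_shifts(recs, 2, labels=["p1", "p2"]).set_index(["position", "residue"])
        row = out.loc[("p1", "G")]
        assert row["delta"] == pytest.approx(0.20, abs=1e-12)
        assert row["p_value"] < 0.01
        assert row["stars"] == "**"

    def test_pvalues_match_statsmodels(self):
        recs = self._records({"GY": (120, 180), "SY": (380, 320), "AY": (60, 55)})
        out = positional_shifts(recs, 2, labels=["p1", "p2"])
        for row in out[out["position"] == "p1"].itertuples(index=False):
            counts = {"G": (120, 180), "S": (380, 320), "A": (60, 55)}[row.residue]
            _, expected = proportions_ztest(
                [counts[1], counts[0]], [555, 560], alternative="two-sided"
            )
            assert row.p_value == pytest.approx(expected, abs=1e-10)

    def test_deltas_sum_to_zero_per_position(self, small_panning):
        df, _ = es_table(small_panning.table)
        out = positional_shifts(df, 9)
        sums = out.groupby("position")["delta"].sum()
        assert np.allclose(sums, 0.0, atol=1e-12)


class TestKabatLabels:
    def test_length_nine_inserts_after_h100(self):
        assert kabat_h3_labels(9) == [
            "H95", "H96", "H97", "H98", "H99", "H100", "H100A", "H101", "H102",
        ]

    def test_label_count_matches_length(self):
        for length in range(9, 17):
            assert len(kabat_h3_labels(length)) == length


def test_two_proportion_ztest_matches_statsmodels(rng):
    for _ in range(50):
        n1, n2 = rng.integers(50, 5000, size=2)
        x1 = int(rng.integers(0, n1 + 1))
        x2 = int(rng.integers(0, n2 + 1))
        z, p = two_proportion_ztest(x1, n1, x2, n2)
        z_ref, p_ref = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
        assert z == pytest.approx(z_ref, abs=1e-10)
        assert p == pytest.approx(p_ref, abs=1e-10)
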