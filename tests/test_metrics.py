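"""Metric computations: purity/completeness averages, ARI, accuracy, recovery."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest

from binmetrics import (
    Binning,
    GoldStandard,
    accuracy,
    adjusted_rand_index,
    average_completeness,
    average_purity,
    build_contingency,
    evaluate_all,
    genome_recovery_counts,
    map_bins_majority,
    per_bin_metrics,
    per_bp_purity_completeness,
    percentage_assigned,
    perfect_binning,
    rank_binnings,
)
from binmetrics.metrics import BinMetrics, truncated_bin_set
from conftest import brute_force_ari, expand_items, random_instance


@pytest.fixture
def f1_bins(f1):
    ct = build_contingency(*f1)
    mapping = map_bins_majority(ct)
    return ct, mapping, per_bin_metrics(ct, mapping)


def _mk_bins(sizes_purities):
    """Synthetic BinMetrics records for average/truncation tests."""
    return [
        BinMetrics(
            bin_id=f"b{i}",
            size_bp=size,
            purity=p,
            completeness=0.5,
            contamination=1.0 - p,
            mapped_genome=f"g{i}",
        )
        for i, (size, p) in enumerate(sizes_purities)
    ]


class TestPerBinMetrics:
    def test_f1_values(self, f1_bins):
        _, _, bins = f1_bins
        by_id = {b.bin_id: b for b in bins}
        assert by_id["X"].purity == pytest.approx(2 / 3, rel=1e-12)
        assert by_id["X"].completeness == 1.0
        assert by_id["X"].contamination == pytest.approx(1 / 3, rel=1e-12)
        assert by_id["Y"].purity == 1.0
        assert by_id["Y"].completeness == 0.5

    def test_purity_plus_contamination_is_one(self, f1_bins):
        _, _, bins = f1_bins
        for b in bins:
            assert b.purity + b.contamination == 1.0

    def test_completeness_of_bins_on_one_genome_sums_to_at_most_one(self):
        """Several bins mapping to one genome can jointly cover it at most once."""
        gold = GoldStandard(
            {f"s{i}": "A" for i in range(4)}, {f"s{i}": 10 for i in range(4)}
        )
        binning = Binning("q", {"s0": "x", "s1": "x", "s2": "y"})
        ct = build_contingency(gold, binning)
        bins = per_bin_metrics(ct, map_bins_majority(ct))
        assert sum(b.completeness for b in bins) <= 1.0 + 1e-12


class TestAveragePurity:
    def test_f1_macro_average(self, f1_bins):
        _, _, bins = f1_bins
        p_bar, c_bar, p_alpha, n_p, n_pa, _ = average_purity(bins, alpha=100)
        assert p_bar == pytest.approx(5 / 6, rel=1e-12)
        assert c_bar == pytest.approx(1 / 6, rel=1e-12)
        assert p_alpha == p_bar
        assert (n_p, n_pa) == (2, 2)

    def test_truncation_97_2_1(self):
        bins = _mk_bins([(97, 1.0), (2, 0.5), (1, 0.0)])
        p_bar, _, p99, n_p, n_pa, _ = average_purity(bins, alpha=99)
        assert p_bar == pytest.approx(0.5, rel=1e-12)
        assert p99 == pytest.approx(0.75, rel=1e-12)
        assert (n_p, n_pa) == (3, 2)

    def test_equally_sized_bins_at_threshold_are_kept_together(self):
        # removing one 1-bp bin would cross 1%; its equal-sized twin stays too
        bins = _mk_bins([(98, 1.0), (1, 0.4), (1, 0.2)])
        retained = truncated_bin_set(bins, alpha=99)
        assert len(retained) == 3

    def test_alpha_100_is_identity(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            sizes = rng.integers(1, 1000, size=rng.integers(1, 10))
            purities = rng.random(len(sizes))
            bins = _mk_bins(list(zip(sizes.tolist(), purities.tolist())))
            p_bar, _, p100, _, n_pa, _ = average_purity(bins, alpha=100)
            assert p100 == p_bar
            assert n_pa == len(bins)

    def test_single_bin_stderr_zero(self):
        bins = _mk_bins([(10, 0.8)])
        p_bar, _, p_alpha, _, _, se = average_purity(bins)
        assert p_bar == p_alpha == 0.8
        assert se == 0.0

    def test_stderr_is_sample_sd_over_sqrt_n(self):
        bins = _mk_bins([(10, 0.4), (10, 0.6), (10, 0.8)])
        *_, se = average_purity(bins, alpha=100)
        expected = np.std([0.4, 0.6, 0.8], ddof=1) / math.sqrt(3)
        assert se == pytest.approx(expected, rel=1e-12)

    def test_alpha_out_of_range(self):
        with pytest.raises(ValueError):
            average_purity(_mk_bins([(10, 1.0)]), alpha=0)


class TestAverageCompleteness:
    def test_f1_includes_unmapped_genome(self, f1_bins):
        _, mapping, bins = f1_bins
        r_bar, n_r, _ = average_completeness(bins, mapping)
        assert n_r == 3
        assert r_bar == pytest.approx(0.5, rel=1e-12)

    def test_perfect_binning_is_one(self, f1_gold):
        ct = build_contingency(f1_gold, perfect_binning(f1_gold))
        mapping = map_bins_majority(ct)
        bins = per_bin_metrics(ct, mapping)
        r_bar, n_r, _ = average_completeness(bins, mapping)
        assert r_bar == 1.0
        assert n_r == 3


class TestSampleWideMetrics:
    def test_f1_per_bp(self, f1_bins):
        ct, _, _ = f1_bins
        p_bp, r_bp = per_bp_purity_completeness(ct)
        assert p_bp == pytest.approx(0.75, rel=1e-12)
        assert r_bp == pytest.approx(150 / 230, rel=1e-12)

    def test_one_bin_two_equal_genomes(self):
        gold = GoldStandard(
            {"a": "A", "b": "B"}, {"a": 100, "b": 100}
        )
        ct = build_contingency(gold, Binning("q", {"a": "x", "b": "x"}))
        p_bp, r_bp = per_bp_purity_completeness(ct)
        assert p_bp == 0.5
        assert r_bp == 1.0

    def test_f1_accuracy(self, f1_bins):
        ct, _, _ = f1_bins
        assert accuracy(ct) == pytest.approx(150 / 230, rel=1e-12)

    def test_f1_percentage_assigned(self, f1_bins):
        ct, _, _ = f1_bins
        assert percentage_assigned(ct, "bp") == pytest.approx(
            200 / 230, rel=1e-12
        )
        assert percentage_assigned(ct, "seq") == pytest.approx(0.8, rel=1e-12)

    @pytest.mark.parametrize("seed", range(20))
    def test_accuracy_never_exceeds_per_bp_purity(self, seed):
        """Same numerator; accuracy's denominator is enlarged by U."""
        rng = np.random.default_rng(400 + seed)
        gold, binning = random_instance(rng)
        ct = build_contingency(gold, binning)
        p_bp, _ = per_bp_purity_completeness(ct)
        a = accuracy(ct)
        assert a <= p_bp + 1e-12
        if ct.unassigned_bp == 0:
            assert a == pytest.approx(p_bp, rel=1e-12)

    def test_unassigning_reduces_assigned_fraction_only(self, f1):
        """Dropping sequences never raises pct_assigned nor touches other bins."""
        gold, binning = f1
        ct_full = build_contingency(gold, binning)
        reduced = Binning(
            "less", {s: b for s, b in binning.assignment.items() if s != "b2"}
        )
        ct_less = build_contingency(gold, reduced)
        assert percentage_assigned(ct_less) <= percentage_assigned(ct_full)
        bins_full = {
            b.bin_id: b.purity
            for b in per_bin_metrics(ct_full, map_bins_majority(ct_full))
        }
        bins_less = {
            b.bin_id: b.purity
            for b in per_bin_metrics(ct_less, map_bins_majority(ct_less))
        }
        assert bins_less["X"] == bins_full["X"]


class TestAdjustedRandIndex:
    def test_f1_bp_exact_rational(self, f1_bins):
        ct, _, _ = f1_bins
        assert adjusted_rand_index(ct, "bp") == pytest.approx(
            float(Fraction(196, 793)), rel=1e-12
        )

    def test_f1_seq_is_zero(self, f1_bins):
        ct, _, _ = f1_bins
        assert adjusted_rand_index(ct, "seq") == 0.0

    def test_perfect_binning_is_one(self, f1_gold):
        ct = build_contingency(f1_gold, perfect_binning(f1_gold))
        assert adjusted_rand_index(ct, "bp") == 1.0
        assert adjusted_rand_index(ct, "seq") == 1.0

    def test_single_bin_single_genome_degenerate(self):
        gold = GoldStandard({"a": "A", "b": "A"}, {"a": 5, "b": 5})
        ct = build_contingency(gold, Binning("q", {"a": "x", "b": "x"}))
        assert adjusted_rand_index(ct, "bp") == 1.0
        assert adjusted_rand_index(ct, "seq") == 1.0

    def test_single_bin_two_genomes_degenerate_is_zero(self):
        gold = GoldStandard({"a": "A", "b": "B"}, {"a": 5, "b": 5})
        ct = build_contingency(gold, Binning("q", {"a": "x", "b": "x"}))
        # both partitions trivial on one side: row partition lumps all
        assert adjusted_rand_index(ct, "seq") == 0.0

    @pytest.mark.parametrize("seed", range(30))
    @pytest.mark.parametrize("currency", ["bp", "seq"])
    def test_matches_brute_force_pair_counting(self, seed, currency):
        rng = np.random.default_rng(1000 + seed)
        gold, binning = random_instance(rng)
        ct = build_contingency(gold, binning)
        xs, ys = expand_items(gold, binning, currency)
        expected = brute_force_ari(xs, ys)
        assert adjusted_rand_index(ct, currency) == pytest.approx(
            expected, abs=1e-9
        )

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_sklearn_on_assigned_sequences(self, seed):
        sklearn_metrics = pytest.importorskip("sklearn.metrics")
        rng = np.random.default_rng(2000 + seed)
        gold, binning = random_instance(rng)
        ct = build_contingency(gold, binning)
        xs, ys = expand_items(gold, binning, "seq")
        if len(set(xs)) == 1 and len(set(ys)) == 1:
            pytest.skip("degenerate case handled by convention")
        expected = sklearn_metrics.adjusted_rand_score(ys, xs)
        assert adjusted_rand_index(ct, "seq") == pytest.approx(
            expected, abs=1e-9
        )


class TestGenomeRecovery:
    def test_f1_recovers_nothing_at_default_bounds(self, f1_bins):
        _, _, bins = f1_bins
        counts = genome_recovery_counts(bins)
        assert set(counts) == {
            (c, r) for c in (0.05, 0.10) for r in (0.5, 0.7, 0.9)
        }
        assert all(v == 0 for v in counts.values())

    def test_strict_inequalities(self):
        # completeness exactly at the bound does not count ("more than")
        bins = _mk_bins([(10, 1.0)])
        bins[0].completeness = 0.5
        counts = genome_recovery_counts(bins)
        assert counts[(0.05, 0.5)] == 0
        bins[0].completeness = 0.5 + 1e-9
        assert genome_recovery_counts(bins)[(0.05, 0.5)] == 1

    def test_perfect_binning_counts_every_genome(self, f1_gold):
        ct = build_contingency(f1_gold, perfect_binning(f1_gold))
        bins = per_bin_metrics(ct, map_bins_majority(ct))
        counts = genome_recovery_counts(bins)
        assert all(v == 3 for v in counts.values())

    def test_genome_counted_once_across_qualifying_bins(self):
        gold = GoldStandard(
            {"a": "A", "b": "A"}, {"a": 95, "b": 95}
        )
        binning = Binning("q", {"a": "x", "b": "y"})
        ct = build_contingency(gold, binning)
        bins = per_bin_metrics(ct, map_bins_majority(ct))
        # both bins pure, each 50% complete: neither passes r > 0.5,
        # but contamination < 0.05 with completeness > 0.4 would double-count
        counts = genome_recovery_counts(bins, (0.05,), (0.4,))
        assert counts[(0.05, 0.4)] == 1

    def test_bad_bounds_rejected(self):
        with pytest.raises(ValueError):
            genome_recovery_counts(_mk_bins([(1, 1.0)]), (0.05,), (1.5,))


class TestRanking:
    def test_purity_order(self, f1):
        gold, binning = f1
        s1 = evaluate_all(gold, binning)
        s2 = evaluate_all(gold, perfect_binning(gold, "perfect"))
        ranked = rank_binnings([s1, s2], "purity")
        assert [s.label for s in ranked] == ["perfect", "F1"]

    def test_tie_breaks_by_label(self, f1):
        gold, binning = f1
        a = evaluate_all(gold, Binning("zeta", dict(binning.assignment)))
        b = evaluate_all(gold, Binning("alpha", dict(binning.assignment)))
        ranked = rank_binnings([a, b], "purity_plus_completeness")
        assert [s.label for s in ranked] == ["alpha", "zeta"]

    def test_sum_matches_brute_force_sort(self, f1):
        gold, binning = f1
        summaries = [
            evaluate_all(gold, perfect_binning(gold, "p")),
            evaluate_all(gold, Binning("q", dict(binning.assignment))),
            evaluate_all(
                gold, Binning("r", {"a1": "u", "b1": "u", "c1": "u"})
            ),
        ]
        ranked = rank_binnings(summaries, "purity_plus_completeness")
        brute = sorted(
            summaries,
            key=lambda s: (
                -(s.truncated_avg_purity + s.avg_completeness),
                s.label,
            ),
        )
        assert [s.label for s in ranked] == [s.label for s in brute]


class TestEvaluateAll:
    def test_f1_summary_vector(self, f1):
        s = evaluate_all(*f1)
        assert s.avg_purity == pytest.approx(5 / 6, rel=1e-12)
        assert s.avg_completeness == pytest.approx(0.5, rel=1e-12)
        assert s.avg_purity_bp == pytest.approx(0.75, rel=1e-12)
        assert s.avg_completeness_bp == pytest.approx(150 / 230, rel=1e-12)
        assert s.accuracy == pytest.approx(150 / 230, rel=1e-12)
        assert s.ari_bp == pytest.approx(float(Fraction(196, 793)), rel=1e-12)
        assert s.ari_seq == 0.0
        assert s.pct_assigned_bp == pytest.approx(200 / 230, rel=1e-12)

    def test_macro_contamination_complement(self, f1):
        s = evaluate_all(*f1)
        assert s.avg_contamination == 1.0 - s.avg_purity

    def test_deterministic(self, f1):
        assert evaluate_all(*f1) == evaluate_all(*f1)

    def test_empty_binning_convention(self, f1_gold):
        empty = Binning("none", {"outsider": "b"})
        s = evaluate_all(f1_gold, empty)
        assert s.empty_binning
        assert s.avg_purity == 0.0
        assert s.avg_completeness == 0.0
        assert s.n_r == 3
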