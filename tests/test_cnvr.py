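import numpy as np
import pandas as pd
import pytest

from popcnv.cnvr import (degree_of_match, gene_overlap, merge_cnvrs,
                         cnvr_frequency, overlap_percent, singleton_filter,
                         summarize_catalog, syndrome_overlap)


def _calls(rows):
    return pd.DataFrame(
        [(s, c, a, b, cn, 10, 1.0, "CONSENSUS") for s, c, a, b, cn in rows],
        columns=["sample_id", "chrom", "start", "end", "cn", "n_probes",
                 "score", "source"],
    )


def _manifest(pairs):
    return pd.DataFrame([(s, p, "female") for s, p in pairs],
                        columns=["sample_id", "population", "reported_sex"])


class TestMerge:
    def test_single_call_identity(self):
        out = merge_cnvrs(_calls([("S", "1", 100, 200, 1)]))
        assert len(out) == 1
        assert (out.iloc[0]["start"], out.iloc[0]["end"], out.iloc[0]["type"]) == (100, 200, "DEL")

    def test_hand_union(self):
        out = merge_cnvrs(_calls([
            ("S1", "1", 100, 200, 1), ("S2", "1", 150, 300, 1), ("S3", "1", 400, 500, 1),
        ]))
        assert [(r["start"], r["end"]) for _, r in out.iterrows()] == [(100, 300), (400, 500)]

    def test_mixed_directions_are_complex(self):
        out = merge_cnvrs(_calls([("S1", "1", 100, 200, 1), ("S2", "1", 150, 250, 3)]))
        assert len(out) == 1
        assert out.iloc[0]["type"] == "COMPLEX"
        assert (out.iloc[0]["start"], out.iloc[0]["end"]) == (100, 250)

    def test_abutting_closed_intervals_merge(self):
        out = merge_cnvrs(_calls([("S1", "1", 100, 200, 1), ("S2", "1", 201, 300, 1)]))
        assert len(out) == 1

    def test_regions_disjoint_and_conserve_coverage(self, small_dataset):
        from popcnv.hmm import call_all_hmm

        calls = call_all_hmm(small_dataset.signals, small_dataset.probe_map)
        out = merge_cnvrs(calls)
        for _, g in out.groupby("chrom"):
            g = g.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()
        # conservation: independent sweep over the raw calls gives the same
        # union length as the merged regions
        for chrom, g in calls.groupby("chrom"):
            ivs = g[["start", "end"]].sort_values("start").to_numpy()
            union = 0
            cur_s, cur_e = ivs[0]
            for s, e in ivs[1:]:
                if s <= cur_e + 1:
                    cur_e = max(cur_e, e)
                else:
                    union += cur_e - cur_s + 1
                    cur_s, cur_e = s, e
            union += cur_e - cur_s + 1
            reg = out[out["chrom"] == chrom]
            assert int((reg["end"] - reg["start"] + 1).sum()) == union


class TestFrequency:
    def test_carrier_fraction(self):
        calls = _calls([(f"S{i}", "1", 100, 200, 1) for i in range(5)])
        mani = _manifest([(f"S{i}", "A") for i in range(10)])
        out = cnvr_frequency(merge_cnvrs(calls), calls, mani)
        assert out["freq_A"].iloc[0] == 0.5

    def test_carrier_with_two_calls_counted_once(self):
        calls = _calls([("S0", "1", 100, 150, 1), ("S0", "1", 160, 200, 1),
                        ("S1", "1", 140, 180, 1)])
        mani = _manifest([("S0", "A"), ("S1", "A")])
        out = cnvr_frequency(merge_cnvrs(calls), calls, mani)
        assert len(out) == 1
        assert out["carriers_A"].iloc[0] == 2

    def test_common_flag_at_five_percent(self):
        calls = _calls([(f"S{i}", "1", 100, 200, 1) for i in range(5)])
        mani = _manifest([(f"S{i}", "A") for i in range(100)])
        out = cnvr_frequency(merge_cnvrs(calls), calls, mani)
        assert bool(out["common"].iloc[0])  # 5/100 = exactly the 5% threshold

    def test_invariant_to_call_order(self):
        rows = [(f"S{i}", "1", 100 + 7 * i, 300 + 7 * i, 1) for i in range(10)]
        mani = _manifest([(f"S{i}", "A") for i in range(10)])
        a = cnvr_frequency(merge_cnvrs(_calls(rows)), _calls(rows), mani)
        b = cnvr_frequency(merge_cnvrs(_calls(rows[::-1])), _calls(rows[::-1]), mani)
        pd.testing.assert_frame_equal(a, b)

    def test_unlabeled_sample_raises(self):
        calls = _calls([("S0", "1", 100, 200, 1)])
        with pytest.raises(KeyError):
            cnvr_frequency(merge_cnvrs(calls), calls, _manifest([("S9", "A")]))


class TestSingletonFilter:
    def _freq(self, carrier_counts):
        calls = _calls([(f"S{i}_{k}", "1", 100 + 1000 * k, 200 + 1000 * k, 1)
                        for k, n in enumerate(carrier_counts) for i in range(n)])
        mani = _manifest([(s, "A") for s in calls["sample_id"].unique()])
        return cnvr_frequency(merge_cnvrs(calls), calls, mani)

    def test_all_singletons_empty(self):
        assert singleton_filter(self._freq([1, 1, 1])).empty

    def test_multi_carrier_subset_kept(self):
        out = singleton_filter(self._freq([1, 2, 3]))
        assert sorted(out["carriers_total"]) == [2, 3]

    def test_idempotent(self):
        once = singleton_filter(self._freq([1, 2, 3]))
        pd.testing.assert_frame_equal(singleton_filter(once), once)


class TestSummary:
    def test_uniform_counts(self):
        calls = _calls([(f"S{i}", "1", 1000 * i + 1, 1000 * i + 500, 1)
                        for i in range(3)])
        s = summarize_catalog(calls, merge_cnvrs(calls), {"1": 1_000_000})
        assert s.median_calls_per_genome == 1 and s.mean_calls_per_genome == 1

    def test_coverage_arithmetic(self):
        calls = _calls([("S", "1", 1, 1_000_000, 1)])
        s = summarize_catalog(calls, merge_cnvrs(calls), {"1": 100_000_000})
        assert s.coverage_percent == pytest.approx(1.0)

    def test_deletion_fraction_tracks_spiked_ratio(self, small_dataset):
        from popcnv.hmm import call_all_hmm
        from scipy.stats import binom

        calls = call_all_hmm(small_dataset.signals, small_dataset.probe_map)
        s = summarize_catalog(calls, merge_cnvrs(calls), {"1": 1})
        # expected DEL share from the planted loci's carrier draws
        truth_dirs = [t.direction for t in small_dataset.truth for _ in t.carrier_ids]
        p = truth_dirs.count("DEL") / len(truth_dirs)
        lo, hi = binom.interval(0.999, s.n_calls, p)
        assert lo <= s.n_deletions <= hi

    def test_empty_catalog_all_zero(self):
        empty = _calls([])
        s = summarize_catalog(empty, merge_cnvrs(empty), {"1": 1000})
        assert s.n_calls == 0 and s.coverage_percent == 0


class TestSyndromeOverlap:
    def test_published_style_percentage(self):
        assert overlap_percent(766, 23458) == 3.27

    def test_empty_syndrome_list(self):
        calls = _calls([("S", "1", 100, 200, 1)])
        count, pct = syndrome_overlap(calls, pd.DataFrame(
            columns=["chrom", "start", "end", "direction"]))
        assert (count, pct) == (0, 0.0)

    def test_direction_matched_counting(self):
        calls = _calls([("S1", "1", 100, 200, 1), ("S2", "1", 100, 200, 3),
                        ("S3", "2", 100, 200, 1), ("S4", "3", 100, 200, 1)])
        syn = pd.DataFrame({"chrom": ["1", "1"], "start": [150, 150],
                            "end": [300, 300], "direction": ["DEL", "DUP"]})
        count, pct = syndrome_overlap(calls, syn)
        assert (count, pct) == (2, 50.0)


class TestGeneOverlap:
    GENES = pd.DataFrame({"symbol": ["G1", "G2"], "chrom": ["1", "1"],
                          "start": [100, 500], "end": [200, 600]})

    def test_contained_gene_listed(self):
        cnvrs = merge_cnvrs(_calls([("S", "1", 50, 250, 1)]))
        assert gene_overlap(cnvrs, self.GENES)["CNVR_1"] == ["G1"]

    def test_intergenic_region_empty(self):
        cnvrs = merge_cnvrs(_calls([("S", "1", 300, 400, 1)]))
        assert gene_overlap(cnvrs, self.GENES)["CNVR_1"] == []

    def test_spanning_region_lists_in_order(self):
        cnvrs = merge_cnvrs(_calls([("S", "1", 150, 550, 1)]))
        assert gene_overlap(cnvrs, self.GENES)["CNVR_1"] == ["G1", "G2"]


class TestDegreeOfMatch:
    def test_identical_catalogs_fully_matched(self):
        a = merge_cnvrs(_calls([("S", "1", 100, 200, 1), ("S", "1", 500, 600, 1)]))
        out = degree_of_match(a, a, freq=[0.5, 0.03])
        occupied = out[out["n"] > 0]
        assert (occupied["fraction"] == 1.0).all()

    def test_disjoint_catalogs_unmatched(self):
        a = merge_cnvrs(_calls([("S", "1", 100, 200, 1)]))
        b = merge_cnvrs(_calls([("S", "2", 100, 200, 1)]))
        out = degree_of_match(a, b, freq=[0.5])
        assert (out.loc[out["n"] > 0, "fraction"] == 0.0).all()

    def test_common_loci_match_in_top_bin(self):
        # two cohorts sharing every locus above 20% frequency
        shared = [("S", "1", 100, 200, 1), ("S", "2", 100, 200, 1)]
        only_a = [("S", "3", 100, 200, 1)]
        a = merge_cnvrs(_calls(shared + only_a))
        b = merge_cnvrs(_calls(shared))
        freq = [0.5, 0.3, 0.02]  # aligned with a's (chrom-sorted) regions
        out = degree_of_match(a, b, freq=freq)
        top = out[out["bin"] == "(0.2,1]"]
        assert top["fraction"].iloc[0] == 1.0
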