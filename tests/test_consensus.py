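import numpy as np
import pandas as pd
import pytest

from popcnv.consensus import (Concordance, FilterConfig, apply_filters,
                              concordance_fraction, concordance_percent,
                              consensus_calls, reciprocal_overlap)


def _calls(rows, source):
    return pd.DataFrame(
        [(s, c, a, b, cn, np_, 1.0, source) for s, c, a, b, cn, np_ in rows],
        columns=["sample_id", "chrom", "start", "end", "cn", "n_probes",
                 "score", "source"],
    )


EMPTY_REGIONS = pd.DataFrame(columns=["chrom", "start", "end"])


class TestReciprocalOverlap:
    def test_identical_intervals(self):
        fa, fb, inter = reciprocal_overlap(("1", 10, 20), ("1", 10, 20))
        assert (fa, fb, inter) == (1.0, 1.0, ("1", 10, 20))

    def test_hand_computed_fractions(self):
        fa, fb, inter = reciprocal_overlap(("1", 10000, 20000), ("1", 14000, 22000))
        assert fa == pytest.approx(6001 / 10001)   # 0.60004
        assert fb == pytest.approx(6001 / 8001)    # 0.75003
        assert inter == ("1", 14000, 20000)

    def test_disjoint_and_cross_chromosome(self):
        assert reciprocal_overlap(("1", 1, 5), ("1", 10, 20)) == (0.0, 0.0, None)
        assert reciprocal_overlap(("1", 1, 5), ("2", 1, 5)) == (0.0, 0.0, None)


class TestConsensus:
    def test_qualifying_pair_emits_intersection(self):
        h = _calls([("S", "1", 10000, 20000, 1, 8)], "HMM")
        c = _calls([("S", "1", 14000, 22000, 1, 7)], "CBS")
        out = consensus_calls(h, c)
        assert len(out) == 1
        r = out.iloc[0]
        assert (r["start"], r["end"], r["cn"], r["source"]) == (14000, 20000, 1, "CONSENSUS")

    def test_below_threshold_pair_dropped(self):
        h = _calls([("S", "1", 1000, 2000, 1, 8)], "HMM")
        c = _calls([("S", "1", 1500, 2500, 1, 8)], "CBS")  # ~50% of each
        assert consensus_calls(h, c).empty

    def test_direction_mismatch_never_pairs(self):
        h = _calls([("S", "1", 1000, 2000, 1, 8)], "HMM")
        c = _calls([("S", "1", 1000, 2000, 3, 8)], "CBS")
        assert consensus_calls(h, c).empty

    def test_geometry_symmetric_under_swap(self):
        rng = np.random.default_rng(4)
        rows_a, rows_b = [], []
        for k in range(20):
            s = int(rng.integers(1, 100000))
            rows_a.append(("S", "1", s, s + int(rng.integers(50, 3000)), 1, 5))
            s2 = s + int(rng.integers(-200, 200))
            rows_b.append(("S", "1", max(1, s2), max(2, s2) + int(rng.integers(50, 3000)), 1, 5))
        a, b = _calls(rows_a, "HMM"), _calls(rows_b, "CBS")
        ab = consensus_calls(a, b)[["chrom", "start", "end"]]
        ba = consensus_calls(b, a)[["chrom", "start", "end"]]
        pd.testing.assert_frame_equal(
            ab.sort_values(["start", "end"]).reset_index(drop=True),
            ba.sort_values(["start", "end"]).reset_index(drop=True),
        )

    def test_one_to_one_matching(self):
        h = _calls([("S", "1", 1000, 2000, 1, 8)], "HMM")
        c = _calls([("S", "1", 1000, 2000, 1, 8), ("S", "1", 900, 2100, 1, 9)], "CBS")
        out = consensus_calls(h, c)
        assert len(out) == 1  # the single HMM call pairs with one CBS call only


class TestApplyFilters:
    def test_small_deletion_rejected_on_probe_minimum(self):
        calls = _calls([("S", "1", 1000, 9000, 1, 4)], "CONSENSUS")
        pm = pd.DataFrame({"probe_id": ["p"], "chrom": ["1"], "pos": [1], "pfb": [0.5]})
        kept, ledger = apply_filters(calls, pm, EMPTY_REGIONS)
        assert kept.empty
        assert "del_size" in ledger["rule"].iloc[0]

    def test_sparse_call_rejected_on_density(self):
        calls = _calls([("S", "1", 1, 100_000, 1, 2)], "CONSENSUS")
        pm = pd.DataFrame({"probe_id": ["p"], "chrom": ["1"], "pos": [1], "pfb": [0.5]})
        kept, ledger = apply_filters(calls, pm, EMPTY_REGIONS)
        assert kept.empty
        assert "density" in ledger["rule"].iloc[0]

    def test_centromeric_call_rejected(self):
        calls = _calls([("S", "1", 1000, 10999, 1, 20)], "CONSENSUS")
        regions = pd.DataFrame({"chrom": ["1"], "start": [1000], "end": [7000]})
        pm = pd.DataFrame({"probe_id": ["p"], "chrom": ["1"], "pos": [1], "pfb": [0.5]})
        kept, ledger = apply_filters(calls, pm, regions)  # 60% inside
        assert kept.empty
        assert "centromere_telomere" in ledger["rule"].iloc[0]

    def test_kept_calls_satisfy_every_predicate(self, small_dataset):
        from popcnv.cbs import call_all_cbs
        from popcnv.hmm import call_all_hmm

        cfg = FilterConfig()
        h = call_all_hmm(small_dataset.signals, small_dataset.probe_map)
        c = call_all_cbs(small_dataset.signals, seed=1)
        cons = consensus_calls(h, c, cfg, probe_map=small_dataset.probe_map)
        kept, ledger = apply_filters(cons, small_dataset.probe_map, EMPTY_REGIONS, cfg)
        assert len(kept) + len(ledger) == len(cons)
        for _, r in kept.iterrows():
            length = r["end"] - r["start"] + 1
            assert r["chrom"] != "X"
            assert r["n_probes"] / length >= 1 / cfg.density_bp_per_probe
            if r["cn"] < 2:
                assert r["n_probes"] >= cfg.del_min_probes and length > cfg.del_min_bp
            else:
                assert r["n_probes"] >= cfg.dup_min_probes and length > cfg.dup_min_bp

    def test_relaxing_thresholds_is_monotone(self):
        rng = np.random.default_rng(2)
        rows = []
        for k in range(60):
            s = int(rng.integers(1, 10_000_000))
            ln = int(rng.integers(1000, 60_000))
            rows.append((f"S{k % 5}", "1", s, s + ln, int(rng.choice([0, 1, 3])),
                         int(rng.integers(2, 30))))
        calls = _calls(rows, "CONSENSUS")
        pm = pd.DataFrame({"probe_id": ["p"], "chrom": ["1"], "pos": [1], "pfb": [0.5]})
        base, _ = apply_filters(calls, pm, EMPTY_REGIONS, FilterConfig())
        for relaxed in [FilterConfig(del_min_probes=1), FilterConfig(dup_min_bp=1),
                        FilterConfig(density_bp_per_probe=1e9)]:
            kept, _ = apply_filters(calls, pm, EMPTY_REGIONS, relaxed)
            assert len(kept) >= len(base)

    def test_sample_cap_drops_whole_sample(self):
        rows = [("S", "1", 1 + 20_000 * k, 15_000 + 20_000 * k, 1, 10)
                for k in range(101)]
        calls = _calls(rows, "CONSENSUS")
        pm = pd.DataFrame({"probe_id": ["p"], "chrom": ["1"], "pos": [1], "pfb": [0.5]})
        kept, ledger = apply_filters(calls, pm, EMPTY_REGIONS)
        assert kept.empty
        assert (ledger["rule"] == "sample_cnv_cap").all()


class TestConcordance:
    def test_identical_sets_fully_replicated(self):
        h = _calls([("S", "1", 1000, 2000, 1, 8)], "HMM")
        assert concordance_fraction(h, h.assign(source="CBS")).fraction == 1.0

    def test_disjoint_sets_zero(self):
        h = _calls([("S", "1", 1000, 2000, 1, 8)], "HMM")
        c = _calls([("S", "1", 9000, 9900, 1, 8)], "CBS")
        assert concordance_fraction(h, c).fraction == 0.0

    def test_empty_denominator_undefined(self):
        h = _calls([("S", "1", 1000, 2000, 1, 8)], "HMM")
        out = concordance_fraction(h, h.iloc[0:0])
        assert out.fraction is None

    def test_published_style_rounding(self):
        # 29,436 of 42,290 replicated rounds to 70% at integer precision
        assert concordance_percent(29436, 42290) == 70
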