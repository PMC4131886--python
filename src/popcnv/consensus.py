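"""Dual-algorithm consensus calling and CNV-level quality filters.

A CNV is considered replicable when the HMM and CBS callers both report it
in the same sample, same chromosome and same direction (deletion vs
duplication) with at least 60% reciprocal overlap; the intersection becomes
the consensus call.  Surviving calls then pass a ledger of filters: probe
density of at least 1 SNP per 30 kb, minimum probe count and span per
direction, at most 50% of the call inside centromeric/telomeric regions, no
sex chromosomes, and whole-sample exclusion above 100 calls.

All intervals are 1-based and closed; length = end - start + 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .hmm import empty_calls


@dataclass(frozen=True)
class FilterConfig:
    overlap_min: float = 0.60
    density_bp_per_probe: float = 30_000.0  # reject below 1 probe per this span
    del_min_probes: int = 5
    del_min_bp: int = 5_000      # strict: length must exceed this
    dup_min_probes: int = 10
    dup_min_bp: int = 10_000
    region_overlap_max: float = 0.50
    per_sample_max: int = 100
    reciprocal: bool = True  # require the overlap fraction of BOTH calls

    def __post_init__(self) -> None:
        if not 0 < self.overlap_min <= 1:
            raise ValueError("overlap_min must be in (0, 1]")


def direction_of(cn: int) -> str:
    return "DEL" if cn < 2 else "DUP"


def reciprocal_overlap(a, b):
    """Overlap fractions of two closed intervals (chrom, start, end).

    Returns (fraction_of_a, fraction_of_b, intersection or None).
    """
    (ca, sa, ea), (cb, sb, eb) = a, b
    if ca != cb:
        return 0.0, 0.0, None
    lo, hi = max(sa, sb), min(ea, eb)
    ov = hi - lo + 1
    if ov <= 0:
        return 0.0, 0.0, None
    return ov / (ea - sa + 1), ov / (eb - sb + 1), (ca, lo, hi)


def _count_probes(probe_map: pd.DataFrame, chrom, start, end) -> np.ndarray:
    """Vectorized probe count inside closed intervals."""
    out = np.zeros(len(chrom), dtype=np.int64)
    for c in np.unique(chrom):
        pos = np.sort(probe_map.loc[probe_map["chrom"] == c, "pos"].to_numpy())
        m = chrom == c
        out[m] = (np.searchsorted(pos, end[m], side="right")
                  - np.searchsorted(pos, start[m], side="left"))
    return out


def match_pairs(
    hmm_calls: pd.DataFrame,
    cbs_calls: pd.DataFrame,
    config: FilterConfig | None = None,
) -> list[tuple[int, int, tuple]]:
    """Greedy one-to-one pairing of HMM and CBS calls.

    A pair qualifies when sample, chromosome and direction agree and the
    overlap covers >= ``overlap_min`` of both calls (or of either, in
    either-of mode).  Pairs are consumed by descending overlap length, ties
    by leftmost intersection start.  Returns (hmm_index, cbs_index,
    intersection) triples using the input frames' index labels.
    """
    config = config or FilterConfig()
    candidates = []
    h = hmm_calls.assign(direction=[direction_of(c) for c in hmm_calls["cn"]])
    c = cbs_calls.assign(direction=[direction_of(c) for c in cbs_calls["cn"]])
    for key, hg in h.groupby(["sample_id", "chrom", "direction"], sort=False):
        cg = c[(c["sample_id"] == key[0]) & (c["chrom"] == key[1])
               & (c["direction"] == key[2])]
        if cg.empty:
            continue
        for hi, hrow in hg.iterrows():
            for ci, crow in cg.iterrows():
                fa, fb, inter = reciprocal_overlap(
                    (key[1], hrow["start"], hrow["end"]),
                    (key[1], crow["start"], crow["end"]),
                )
                if inter is None:
                    continue
                ok = (fa >= config.overlap_min and fb >= config.overlap_min
                      if config.reciprocal
                      else fa >= config.overlap_min or fb >= config.overlap_min)
                if ok:
                    ov_len = inter[2] - inter[1] + 1
                    candidates.append((-ov_len, inter[1], hi, ci, inter))
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    used_h: set = set()
    used_c: set = set()
    pairs = []
    for _negov, _s, hi, ci, inter in candidates:
        if hi in used_h or ci in used_c:
            continue
        used_h.add(hi)
        used_c.add(ci)
        pairs.append((hi, ci, inter))
    return pairs


def consensus_calls(
    hmm_calls: pd.DataFrame,
    cbs_calls: pd.DataFrame,
    config: FilterConfig | None = None,
    probe_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Intersection calls from replicable HMM/CBS pairs.

    The emitted interval is the intersection; the copy-number class is taken
    from the HMM member; the probe count is recounted within the
    intersection when a probe map is supplied (min of the members otherwise).
    """
    pairs = match_pairs(hmm_calls, cbs_calls, config)
    if not pairs:
        return empty_calls()
    rows = []
    for hi, ci, (chrom, lo, hi_bp) in pairs:
        hrow, crow = hmm_calls.loc[hi], cbs_calls.loc[ci]
        rows.append({
            "sample_id": hrow["sample_id"], "chrom": chrom,
            "start": int(lo), "end": int(hi_bp), "cn": int(hrow["cn"]),
            "n_probes": int(min(hrow["n_probes"], crow["n_probes"])),
            "score": float(hrow["score"]), "source": "CONSENSUS",
        })
    out = pd.DataFrame(rows)
    if probe_map is not None:
        out["n_probes"] = _count_probes(
            probe_map, out["chrom"].to_numpy(), out["start"].to_numpy(),
            out["end"].to_numpy(),
        )
    return out.sort_values(["sample_id", "chrom", "start"]).reset_index(drop=True)


def _merge_intervals(df: pd.DataFrame) -> dict[str, np.ndarray]:
    """Per-chromosome merged (start, end) arrays from possibly overlapping rows."""
    merged: dict[str, np.ndarray] = {}
    for chrom, g in df.groupby("chrom", sort=False):
        ivs = g[["start", "end"]].sort_values("start").to_numpy()
        out = []
        for s, e in ivs:
            if out and s <= out[-1][1] + 1:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[str(chrom)] = np.asarray(out, dtype=np.int64)
    return merged


def _excluded_fraction(calls: pd.DataFrame, regions: pd.DataFrame) -> np.ndarray:
    merged = _merge_intervals(regions) if len(regions) else {}
    frac = np.zeros(len(calls))
    for k, (_, row) in enumerate(calls.iterrows()):
        ivs = merged.get(str(row["chrom"]))
        if ivs is None:
            continue
        ov = np.maximum(
            0, np.minimum(ivs[:, 1], row["end"]) - np.maximum(ivs[:, 0], row["start"]) + 1
        ).sum()
        frac[k] = ov / (row["end"] - row["start"] + 1)
    return frac


def apply_filters(
    calls: pd.DataFrame,
    probe_map: pd.DataFrame,
    excluded_regions: pd.DataFrame,
    config: FilterConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply every CNV-level and sample-level filter; return (kept, ledger).

    The rejection ledger carries one row per rejected call with the
    comma-joined names of every rule it failed; sample-cap rejections are
    tagged ``sample_cnv_cap``.
    """
    config = config or FilterConfig()
    if excluded_regions is None:
        raise ValueError("excluded_regions is required (pass an empty frame if none)")
    if calls.empty:
        return calls.copy(), calls.assign(rule=pd.Series(dtype=str)).copy()
    c = calls.reset_index(drop=True).copy()
    length = c["end"] - c["start"] + 1
    direction = np.array([direction_of(x) for x in c["cn"]])
    rules = [[] for _ in range(len(c))]
    density_ok = c["n_probes"] / length >= 1.0 / config.density_bp_per_probe
    for k in np.flatnonzero(~density_ok):
        rules[k].append("density")
    is_del = direction == "DEL"
    bad_del = is_del & ((c["n_probes"] < config.del_min_probes)
                        | (length <= config.del_min_bp))
    bad_dup = ~is_del & ((c["n_probes"] < config.dup_min_probes)
                         | (length <= config.dup_min_bp))
    for k in np.flatnonzero(bad_del.to_numpy()):
        rules[k].append("del_size")
    for k in np.flatnonzero(bad_dup.to_numpy()):
        rules[k].append("dup_size")
    frac = _excluded_fraction(c, excluded_regions)
    for k in np.flatnonzero(frac > config.region_overlap_max):
        rules[k].append("centromere_telomere")
    for k in np.flatnonzero((c["chrom"] == "X").to_numpy()):
        rules[k].append("sex_chromosome")
    rejected = np.array([bool(r) for r in rules])
    kept = c[~rejected].copy()
    ledger_rows = c[rejected].copy()
    ledger_rows["rule"] = [",".join(r) for r, rej in zip(rules, rejected) if rej]
    # whole-sample exclusion above the per-sample call cap
    counts = kept["sample_id"].value_counts()
    bad_samples = set(counts[counts > config.per_sample_max].index)
    if bad_samples:
        capped = kept[kept["sample_id"].isin(bad_samples)].copy()
        capped["rule"] = "sample_cnv_cap"
        ledger_rows = pd.concat([ledger_rows, capped], ignore_index=True)
        kept = kept[~kept["sample_id"].isin(bad_samples)]
    return kept.reset_index(drop=True), ledger_rows.reset_index(drop=True)


@dataclass
class Concordance:
    fraction: float | None
    n_replicated: int
    n_total: int


def concordance_fraction(
    hmm_calls: pd.DataFrame,
    cbs_calls: pd.DataFrame,
    config: FilterConfig | None = None,
) -> Concordance:
    """Fraction of CBS calls replicated by the HMM caller.

    The denominator is the full CBS call set; the numerator the CBS calls
    participating in a consensus pair.  Undefined (None) when the
    denominator is empty.
    """
    n_total = len(cbs_calls)
    if n_total == 0:
        return Concordance(None, 0, 0)
    pairs = match_pairs(hmm_calls, cbs_calls, config)
    n_rep = len({ci for _hi, ci, _inter in pairs})
    return Concordance(n_rep / n_total, n_rep, n_total)


def concordance_percent(n_replicated: int, n_total: int) -> int:
    """Replication rate as an integer-rounded percentage."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100 * n_replicated / n_total)
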