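"""Copy Number Variable Regions: merging, frequencies and catalog summaries.

A CNVR is the union of transitively overlapping CNV calls across all
samples — a discrete region of the genome seen as copy-number variable.
Regions whose member calls include both deletions and duplications are
typed COMPLEX.  Population frequency counts each individual once per CNVR
no matter how many member calls they contribute.

Closed 1-based intervals; calls abutting at one base merge.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from .consensus import direction_of

COMMON_FREQ = 0.05  # minimum frequency for a CNVR to count as common


def merge_cnvrs(calls: pd.DataFrame) -> pd.DataFrame:
    """Single-pass union of overlapping calls into disjoint regions.

    Returns one row per CNVR: cnvr_id, chrom, start, end, type
    (DEL/DUP/COMPLEX) and n_calls.
    """
    rows = []
    for chrom, g in calls.groupby("chrom", sort=False):
        g = g.sort_values(["start", "end"])
        cur = None
        for _, r in g.iterrows():
            d = direction_of(int(r["cn"]))
            if cur is not None and r["start"] <= cur["end"] + 1:
                cur["end"] = max(cur["end"], int(r["end"]))
                cur["dirs"].add(d)
                cur["n_calls"] += 1
            else:
                if cur is not None:
                    rows.append(cur)
                cur = {"chrom": chrom, "start": int(r["start"]), "end": int(r["end"]),
                       "dirs": {d}, "n_calls": 1}
        if cur is not None:
            rows.append(cur)
    out = pd.DataFrame(
        [{
            "chrom": r["chrom"], "start": r["start"], "end": r["end"],
            "type": "COMPLEX" if len(r["dirs"]) > 1 else next(iter(r["dirs"])),
            "n_calls": r["n_calls"],
        } for r in rows]
    )
    if out.empty:
        return pd.DataFrame(columns=["cnvr_id", "chrom", "start", "end", "type", "n_calls"])
    out = out.sort_values(["chrom", "start"]).reset_index(drop=True)
    out.insert(0, "cnvr_id", [f"CNVR_{i + 1}" for i in range(len(out))])
    return out


def assign_calls_to_cnvrs(cnvrs: pd.DataFrame, calls: pd.DataFrame) -> pd.Series:
    """cnvr_id for each call by any-bp overlap (CNVRs are disjoint per chromosome)."""
    ids = pd.Series(index=calls.index, dtype=object)
    for chrom, g in calls.groupby("chrom", sort=False):
        reg = cnvrs[cnvrs["chrom"] == chrom].sort_values("start")
        if reg.empty:
            continue
        starts = reg["start"].to_numpy()
        ends = reg["end"].to_numpy()
        rid = reg["cnvr_id"].to_numpy()
        k = np.searchsorted(starts, g["start"].to_numpy(), side="right") - 1
        for local, (ci, r) in zip(k, g.iterrows()):
            # candidate regions: the one starting at/before the call, and the next
            for cand in (local, local + 1):
                if 0 <= cand < len(reg) and starts[cand] <= r["end"] and ends[cand] >= r["start"]:
                    ids.loc[ci] = rid[cand]
                    break
    return ids


def cnvr_frequency(cnvrs: pd.DataFrame, calls: pd.DataFrame,
                   manifest: pd.DataFrame) -> pd.DataFrame:
    """Carrier counts and frequencies per CNVR and population.

    A sample carries a CNVR when any of its calls overlaps it; duplicates
    are collapsed so each individual counts once.  Adds a ``common`` flag at
    frequency >= 5% in any population.
    """
    pop = dict(zip(manifest["sample_id"], manifest["population"]))
    missing = set(calls["sample_id"]) - set(pop)
    if missing:
        raise KeyError(f"samples without a population label: {sorted(missing)[:5]}")
    pops = sorted(manifest["population"].unique())
    totals = manifest["population"].value_counts().to_dict()
    ids = assign_calls_to_cnvrs(cnvrs, calls)
    tagged = calls.assign(cnvr_id=ids).dropna(subset=["cnvr_id"])
    tagged = tagged.assign(population=tagged["sample_id"].map(pop))
    carriers = (
        tagged.drop_duplicates(["cnvr_id", "sample_id"])
        .groupby(["cnvr_id", "population"], observed=True).size()
        .unstack("population", fill_value=0)
        .reindex(columns=pops, fill_value=0)
    )
    out = cnvrs.set_index("cnvr_id").copy()
    for p in pops:
        out[f"carriers_{p}"] = carriers[p].reindex(out.index).fillna(0).astype(int)
        out[f"freq_{p}"] = out[f"carriers_{p}"] / totals[p]
    out["carriers_total"] = out[[f"carriers_{p}" for p in pops]].sum(axis=1)
    out["common"] = out[[f"freq_{p}" for p in pops]].max(axis=1) >= COMMON_FREQ
    return out.reset_index()


def singleton_filter(freq_table: pd.DataFrame) -> pd.DataFrame:
    """Keep CNVRs seen in more than one individual (total carriers >= 2)."""
    return freq_table[freq_table["carriers_total"] >= 2].reset_index(drop=True)


@dataclass
class CatalogSummary:
    n_calls: int
    n_deletions: int
    n_duplications: int
    n_cnvrs: int
    n_cnvr_del: int
    n_cnvr_dup: int
    n_cnvr_complex: int
    median_calls_per_genome: float
    mean_calls_per_genome: float
    median_size_bp: float
    median_del_size_bp: float
    median_dup_size_bp: float
    coverage_bp: int
    coverage_percent: float

    def as_dict(self) -> dict:
        return asdict(self)


def summarize_catalog(calls: pd.DataFrame, cnvrs: pd.DataFrame,
                      autosome_lengths: dict[str, int],
                      n_samples: int | None = None) -> CatalogSummary:
    """Genome-wide catalog statistics.

    Coverage is the union length of CNVRs over the summed autosome lengths.
    Per-genome call counts are over ``n_samples`` genomes when given (zeros
    included), else over the samples present in the calls.
    """
    genome = sum(autosome_lengths.values())
    if calls.empty:
        return CatalogSummary(0, 0, 0, 0, 0, 0, 0, 0.0, 0.0, 0.0, 0.0, 0.0, 0, 0.0)
    length = (calls["end"] - calls["start"] + 1).astype(float)
    is_del = np.array([direction_of(c) == "DEL" for c in calls["cn"]])
    per_genome = calls["sample_id"].value_counts()
    if n_samples is not None:
        per_genome = per_genome.reindex(
            per_genome.index.tolist()
            + [f"__zero_{i}" for i in range(n_samples - len(per_genome))],
            fill_value=0,
        )
    cov = int((cnvrs["end"] - cnvrs["start"] + 1).sum()) if len(cnvrs) else 0
    med = lambda x: float(np.median(x)) if len(x) else 0.0
    return CatalogSummary(
        n_calls=int(len(calls)),
        n_deletions=int(is_del.sum()),
        n_duplications=int((~is_del).sum()),
        n_cnvrs=int(len(cnvrs)),
        n_cnvr_del=int((cnvrs["type"] == "DEL").sum()) if len(cnvrs) else 0,
        n_cnvr_dup=int((cnvrs["type"] == "DUP").sum()) if len(cnvrs) else 0,
        n_cnvr_complex=int((cnvrs["type"] == "COMPLEX").sum()) if len(cnvrs) else 0,
        median_calls_per_genome=float(per_genome.median()),
        mean_calls_per_genome=float(per_genome.mean()),
        median_size_bp=med(length),
        median_del_size_bp=med(length[is_del]),
        median_dup_size_bp=med(length[~is_del]),
        coverage_bp=cov,
        coverage_percent=100.0 * cov / genome,
    )


def syndrome_overlap(calls: pd.DataFrame, syndromes: pd.DataFrame) -> tuple[int, float]:
    """Calls overlapping a known imbalance-syndrome region of matched direction.

    ``syndromes`` rows carry chrom, start, end and direction (DEL/DUP).
    Returns (count, percent of all calls to 2 decimals).
    """
    if calls.empty:
        return 0, 0.0
    count = 0
    for _, r in calls.iterrows():
        d = direction_of(int(r["cn"]))
        sy = syndromes[(syndromes["chrom"] == r["chrom"])
                       & (syndromes["direction"] == d)] if len(syndromes) else syndromes
        if len(sy) and ((sy["start"] <= r["end"]) & (sy["end"] >= r["start"])).any():
            count += 1
    return count, overlap_percent(count, len(calls))


def overlap_percent(count: int, total: int) -> float:
    """Share of calls as a percentage, reported to 2 decimals."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 2)


def gene_overlap(cnvrs: pd.DataFrame, genes: pd.DataFrame) -> dict[str, list[str]]:
    """Gene symbols overlapping each CNVR (any bp), in positional order."""
    out: dict[str, list[str]] = {}
    for _, r in cnvrs.iterrows():
        g = genes[(genes["chrom"] == r["chrom"]) & (genes["start"] <= r["end"])
                  & (genes["end"] >= r["start"])]
        out[r["cnvr_id"]] = list(g.sort_values("start")["symbol"])
    return out


def degree_of_match(
    cnvrs_a: pd.DataFrame,
    cnvrs_b: pd.DataFrame,
    freq: pd.Series | np.ndarray,
    bin_edges: tuple[float, ...] = (0.01, 0.05, 0.10, 0.20, 1.0),
) -> pd.DataFrame:
    """Fraction of A regions found in B, per frequency bin.

    A region matches when it overlaps any region of B by at least one base.
    Bins are (0, e1], (e1, e2], ...; both inputs should be singleton-filtered
    merged catalogs.
    """
    freq = np.asarray(freq, dtype=float)
    matched = np.zeros(len(cnvrs_a), dtype=bool)
    for k, (_, r) in enumerate(cnvrs_a.iterrows()):
        b = cnvrs_b[(cnvrs_b["chrom"] == r["chrom"]) & (cnvrs_b["start"] <= r["end"])
                    & (cnvrs_b["end"] >= r["start"])]
        matched[k] = len(b) > 0
    edges = (0.0,) + tuple(bin_edges)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (freq > lo) & (freq <= hi)
        rows.append({
            "bin": f"({lo:g},{hi:g}]", "n": int(m.sum()),
            "n_matched": int(matched[m].sum()),
            "fraction": float(matched[m].mean()) if m.any() else np.nan,
        })
    return pd.DataFrame(rows)
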