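"""Circular binary segmentation (CBS) CNV caller on LRR, with BAF-aided
segment classification.

CBS recursively splits an ordered signal at the circular arc maximizing a
two-sample t-like statistic against its complement, accepting each split by
a within-window permutation test (empirical p = (b+1)/(R+1)).  Accepted
segments are classified into copy-number classes from their mean LRR and the
shape of the BAF distribution: deletions lose the heterozygote band near
0.5, duplications split it into clusters at 1/3 and 2/3.

This is a compact re-implementation of the classic changepoint recursion;
the full pruning/undo machinery of the canonical implementation is out of
scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from zlib import crc32

from .hmm import CALL_COLUMNS, empty_calls

_CLASS_CN = {"HOMDEL": 0, "HETDEL": 1, "DUP": 3}


@dataclass(frozen=True)
class SegmentThresholds:
    """Copy-number classification rules applied to each segment.

    ``baf_het_fraction`` is the fraction of segment BAF in (0.25, 0.75);
    ``baf_mid_fraction`` the fraction in the narrow (0.4, 0.6) band.  The
    duplication rule tests the narrow band: three-copy heterozygote clusters
    sit at 1/3 and 2/3 — away from 0.5 but still inside the wide band.
    """

    homdel_lrr_max: float = -2.0
    del_lrr_max: float = -0.3
    del_het_max: float = 0.05
    dup_lrr_min: float = 0.2
    dup_mid_max: float = 0.15


@dataclass(frozen=True)
class CBSParams:
    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 2
    thresholds: SegmentThresholds = field(default_factory=SegmentThresholds)


@dataclass
class Segment:
    chrom: str
    first_probe: int  # probe index range, closed
    last_probe: int
    start_bp: int
    end_bp: int
    mean_lrr: float
    n_probes: int
    baf_het_fraction: float
    baf_mid_fraction: float


def _t_from_d(d: np.ndarray, sstc: np.ndarray, L: int, n: int) -> np.ndarray:
    """t-like statistic from the arc-vs-complement mean difference.

    Uses the ANOVA identity: within-group SS = total centered SS minus the
    between-group SS L(n-L)/n * d^2, so T is monotone in |d| at fixed L.
    """
    w = L * (n - L) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        var = np.maximum(sstc - w * d**2, 0.0) / max(n - 2, 1)
        t = np.abs(d) / np.sqrt(var * (1 / L + 1 / (n - L)))
    return np.where(var == 0.0, np.where(d == 0.0, 0.0, np.inf), t)


def _row_max_t(x2d: np.ndarray, min_width: int) -> np.ndarray:
    """Max circular-split T per row, scanning arcs by length via moving sums."""
    p, n = x2d.shape
    s = np.concatenate([np.zeros((p, 1)), np.cumsum(x2d, axis=1)], axis=1)
    total = s[:, -1]
    sstc = np.sum(x2d**2, axis=1) - total**2 / n  # total centered SS, constant per row
    best = np.zeros(p)
    for L in range(min_width, n - min_width + 1):
        sums = s[:, L:] - s[:, :-L]
        d = sums / L - (total[:, None] - sums) / (n - L)
        dmax = np.abs(d).max(axis=1)
        best = np.maximum(best, _t_from_d(dmax, sstc, L, n))
    return best


def max_t_statistic(values, min_width: int = 1) -> tuple[int, int, float]:
    """Best circular split of an ordered vector.

    Returns (i, j, T) where the arc ``values[i+1..j]`` (0-based, inclusive)
    maximizes the two-sample t-like statistic against its complement, over
    all ordered pairs with both arcs at least ``min_width`` long.  Arcs
    starting at position 0 are reported through their complement, which has
    the same statistic.  A constant vector returns T = 0.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if n < 4:
        raise ValueError("need at least 4 values")
    s = np.concatenate([[0.0], np.cumsum(x)])
    total = s[-1]
    sstc = float(np.sum(x**2) - total**2 / n)
    best = (0.0, 0, n - 1)
    for L in range(min_width, n - min_width + 1):
        sums = s[L:] - s[:-L]
        d = sums / L - (total - sums) / (n - L)
        a = int(np.argmax(np.abs(d)))
        t = float(_t_from_d(np.array(d[a]), np.array(sstc), L, n))
        if t > best[0]:
            if a > 0:
                best = (t, a - 1, a + L - 1)      # arc x[a .. a+L-1]
            else:
                best = (t, L - 1, n - 1)          # report via the complement arc
    return best[1], best[2], best[0]


def _perm_exceedances(xw, t_obs, min_width, n_perm, b_stop, rng) -> int:
    """Count permutations whose max T reaches t_obs; stop early once > b_stop.

    Batches escalate so null windows are rejected after a few dozen
    permutations while genuine changepoints still get the full budget.
    """
    b = 0
    done = 0
    batch = 32
    while done < n_perm:
        p = min(batch, n_perm - done)
        xp = rng.permuted(np.tile(xw, (p, 1)), axis=1)
        b += int(np.sum(_row_max_t(xp, min_width) >= t_obs - 1e-12))
        done += p
        if b > b_stop:
            break
        batch = min(batch * 4, 512)
    return b


def cbs_segment(
    values,
    alpha: float = 0.01,
    n_perm: int = 1000,
    min_width: int = 2,
    seed: int = 0,
) -> list[int]:
    """Recursive segmentation; returns sorted cut-after probe indices.

    Each candidate split is assessed by shuffling the values within the
    tested stretch; it is accepted when the empirical p-value (b+1)/(R+1)
    is at most ``alpha``.  Windows draw their permutations from an rng
    keyed on (seed, window), so decisions per window do not depend on the
    recursion history and lowering alpha can only remove breakpoints.
    """
    x = np.asarray(values, dtype=float)
    b_stop = int(np.floor(alpha * (n_perm + 1) - 1))  # reject once b exceeds this
    cuts: list[int] = []
    stack = [(0, len(x))]
    while stack:
        lo, hi = stack.pop()
        n = hi - lo
        if n < 4 or n < 2 * min_width:
            continue
        xw = x[lo:hi]
        i, j, t_obs = max_t_statistic(xw, min_width)
        if t_obs <= 0.0 or b_stop < 0:
            continue
        rng = np.random.default_rng((seed, lo, hi))
        b = _perm_exceedances(xw, t_obs, min_width, n_perm, b_stop, rng)
        if b > b_stop:  # p > alpha
            continue
        cuts.append(lo + i)
        stack.append((lo, lo + i + 1))
        if j < n - 1:
            cuts.append(lo + j)
            stack.append((lo + j + 1, hi))
        stack.append((lo + i + 1, lo + j + 1))
    return sorted(set(cuts))


def make_segments(chrom: str, pos: np.ndarray, lrr: np.ndarray, baf: np.ndarray,
                  cuts: list[int]) -> list[Segment]:
    """Partition a chromosome's probes into segments at the given cuts."""
    bounds = [-1] + list(cuts) + [len(pos) - 1]
    segs = []
    for a, b in zip(bounds[:-1], bounds[1:]):
        lo, hi = a + 1, b  # probe index range, closed
        bafs = baf[lo:hi + 1]
        segs.append(Segment(
            chrom=chrom, first_probe=lo, last_probe=hi,
            start_bp=int(pos[lo]), end_bp=int(pos[hi]),
            mean_lrr=float(np.mean(lrr[lo:hi + 1])), n_probes=hi - lo + 1,
            baf_het_fraction=float(np.mean((bafs > 0.25) & (bafs < 0.75))),
            baf_mid_fraction=float(np.mean((bafs > 0.4) & (bafs < 0.6))),
        ))
    return segs


def classify_segment(seg: Segment, thresholds: SegmentThresholds | None = None) -> str:
    """Copy-number class of a segment, or NORMAL."""
    th = thresholds or SegmentThresholds()
    if seg.mean_lrr < th.homdel_lrr_max:
        return "HOMDEL"
    if seg.mean_lrr < th.del_lrr_max and seg.baf_het_fraction < th.del_het_max:
        return "HETDEL"
    if seg.mean_lrr > th.dup_lrr_min and seg.baf_mid_fraction < th.dup_mid_max:
        return "DUP"
    return "NORMAL"


def cbs_call(
    signal: pd.DataFrame,
    params: CBSParams | None = None,
    sample_id: str | None = None,
    seed: int = 0,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Segment and classify one sample's signal; emit non-normal segments.

    Adjacent segments assigned the same non-normal class are merged into a
    single call before emission.
    """
    params = params or CBSParams()
    sample_id = sample_id or str(signal.attrs.get("sample_id", "sample"))
    df = signal[signal["chrom"] != "X"] if autosomes_only else signal
    calls = []
    for ci, (chrom, g) in enumerate(df.groupby("chrom", sort=False)):
        g = g.sort_values("pos")
        pos = g["pos"].to_numpy()
        lrr = g["lrr"].to_numpy()
        baf = g["baf"].to_numpy()
        if len(g) < 4:
            continue
        cuts = cbs_segment(lrr, params.alpha, params.n_perm, params.min_width,
                           seed=int((seed * 1_000_003 + ci) % 2**31))
        segs = make_segments(str(chrom), pos, lrr, baf, cuts)
        labeled = [(classify_segment(s, params.thresholds), s) for s in segs]
        merged: list[tuple[str, Segment]] = []
        for cls, s in labeled:
            if merged and merged[-1][0] == cls:
                prev = merged[-1][1]
                ntot = prev.n_probes + s.n_probes
                merged[-1] = (cls, Segment(
                    chrom=s.chrom, first_probe=prev.first_probe, last_probe=s.last_probe,
                    start_bp=prev.start_bp, end_bp=s.end_bp,
                    mean_lrr=(prev.mean_lrr * prev.n_probes + s.mean_lrr * s.n_probes) / ntot,
                    n_probes=ntot,
                    baf_het_fraction=(prev.baf_het_fraction * prev.n_probes
                                      + s.baf_het_fraction * s.n_probes) / ntot,
                    baf_mid_fraction=(prev.baf_mid_fraction * prev.n_probes
                                      + s.baf_mid_fraction * s.n_probes) / ntot,
                ))
            else:
                merged.append((cls, s))
        for cls, s in merged:
            if cls == "NORMAL":
                continue
            calls.append({
                "sample_id": sample_id, "chrom": s.chrom,
                "start": s.start_bp, "end": s.end_bp,
                "cn": _CLASS_CN[cls], "n_probes": s.n_probes,
                "score": abs(s.mean_lrr) * s.n_probes, "source": "CBS",
            })
    return pd.DataFrame(calls, columns=CALL_COLUMNS) if calls else empty_calls()


def call_all_cbs(signals: dict[str, pd.DataFrame], params: CBSParams | None = None,
                 seed: int = 0) -> pd.DataFrame:
    """Run the CBS caller on every sample; per-sample rng keyed on the id."""
    frames = []
    for s, df in sorted(signals.items()):
        frames.append(cbs_call(df, params, sample_id=s,
                               seed=(seed * 7 + crc32(s.encode())) % 2**31))
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else empty_calls()
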