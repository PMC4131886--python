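"""Four-state hidden Markov model CNV caller on LRR/BAF signals.

States are the copy-number classes homozygous deletion (cn 0), heterozygous
deletion (cn 1), normal (cn 2) and duplication (cn 3 and above, aggregated).
Emissions combine a per-state Gaussian on LRR with a per-state BAF mixture
whose cluster weights depend on the probe's population B-allele frequency
(PFB).  Transition probability between neighbouring probes decays with
genomic distance.  Decoding is exact Viterbi in log space, per chromosome.

BAF values of exactly 0 or 1 are handled as truncated-cluster point masses:
the mass of each Gaussian cluster falling outside [0, 1] collapses onto the
boundary.  All states use the same convention, so likelihood comparisons at
the boundary remain meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

STATES = ("HOMDEL", "HETDEL", "NORMAL", "DUP")
STATE_CN = (0, 1, 2, 3)
NORMAL_IDX = 2
_TINY = 1e-300


@dataclass(frozen=True)
class HMMParams:
    """Emission and transition parameters.

    ``p_off`` is the saturating probability of leaving the current state
    between two infinitely distant probes; ``d_bp`` the distance scale of the
    exponential decay.  Defaults keep the expected number of spurious
    segments on null data far below one per genome.
    """

    lrr_mean: tuple[float, float, float, float] = (-3.5, -0.66, 0.0, 0.40)
    lrr_sd: tuple[float, float, float, float] = (1.3, 0.25, 0.18, 0.20)
    baf_sd: float = 0.03
    homdel_boundary_mass: float = 0.01  # nominal point mass of uniform BAF at {0,1}
    p_off: float = 1e-4
    d_bp: float = 100_000.0

    def __post_init__(self) -> None:
        if not 0 < self.p_off < 0.5:
            raise ValueError("p_off must be in (0, 0.5)")
        if self.d_bp <= 0:
            raise ValueError("d_bp must be positive")


def _cluster_model(state: int, pfb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """BAF cluster centers and pfb-dependent weights for a state (not HOMDEL)."""
    p = np.asarray(pfb, dtype=float)
    if state == 1:  # one copy: A or B allele
        centers = np.array([0.0, 1.0])
        weights = np.stack([1 - p, p], axis=-1)
    elif state == 2:  # diploid Hardy-Weinberg clusters
        centers = np.array([0.0, 0.5, 1.0])
        weights = np.stack([(1 - p) ** 2, 2 * p * (1 - p), p**2], axis=-1)
    elif state == 3:  # three copies: binomial(3, pfb) B-allele dosage
        centers = np.array([0.0, 1 / 3, 2 / 3, 1.0])
        weights = np.stack(
            [(1 - p) ** 3, 3 * p * (1 - p) ** 2, 3 * p**2 * (1 - p), p**3], axis=-1
        )
    else:
        raise ValueError(f"no cluster model for state {state}")
    return centers, weights


def _baf_loglik(baf: np.ndarray, pfb: np.ndarray, state: int, params: HMMParams) -> np.ndarray:
    baf = np.asarray(baf, dtype=float)
    pfb = np.broadcast_to(np.asarray(pfb, dtype=float), baf.shape)
    if state == 0:
        # uniform noise; nominal boundary mass so cn-0 is not ruled out at 0/1
        out = np.where(
            (baf == 0.0) | (baf == 1.0), np.log(params.homdel_boundary_mass), 0.0
        )
        return out
    centers, weights = _cluster_model(state, pfb)
    s = params.baf_sd
    dens = np.sum(weights * norm.pdf((baf[..., None] - centers) / s) / s, axis=-1)
    mass0 = np.sum(weights * norm.cdf((0.0 - centers) / s), axis=-1)
    mass1 = np.sum(weights * norm.sf((1.0 - centers) / s), axis=-1)
    dens = np.where(baf == 0.0, mass0, dens)
    dens = np.where(baf == 1.0, mass1, dens)
    return np.log(np.maximum(dens, _TINY))


def emission_loglik(lrr: float, baf: float, pfb: float, state: int | str,
                    params: HMMParams | None = None) -> float:
    """Joint log-density of one probe's (LRR, BAF) under a copy-number state."""
    params = params or HMMParams()
    if isinstance(state, str):
        state = STATES.index(state)
    if not 0.0 <= baf <= 1.0:
        raise ValueError(f"BAF must be in [0, 1], got {baf}")
    lrr_part = norm.logpdf(lrr, params.lrr_mean[state], params.lrr_sd[state])
    return float(lrr_part + _baf_loglik(np.asarray(baf), np.asarray(pfb), state, params))


def emission_matrix(lrr: np.ndarray, baf: np.ndarray, pfb: np.ndarray,
                    params: HMMParams) -> np.ndarray:
    """(n_probes, 4) emission log-likelihood matrix."""
    lrr = np.asarray(lrr, dtype=float)
    baf = np.asarray(baf, dtype=float)
    if ((baf < 0) | (baf > 1)).any():
        raise ValueError("BAF values must be in [0, 1]")
    out = np.empty((len(lrr), 4))
    for k in range(4):
        out[:, k] = (
            norm.logpdf(lrr, params.lrr_mean[k], params.lrr_sd[k])
            + _baf_loglik(baf, pfb, k, params)
        )
    return out


def transition_matrix(distance_bp: float, params: HMMParams | None = None) -> np.ndarray:
    """Distance-dependent 4x4 stochastic matrix.

    Off-diagonal mass ``p_off * (1 - exp(-d/D))`` is split evenly among the
    three other states; it vanishes as d -> 0 and saturates at ``p_off``.
    """
    params = params or HMMParams()
    if distance_bp <= 0:
        raise ValueError("distance_bp must be positive")
    m = params.p_off * (1.0 - np.exp(-distance_bp / params.d_bp))
    t = np.full((4, 4), m / 3.0)
    np.fill_diagonal(t, 1.0 - m)
    return t


def _argmax_prefer_normal(values: np.ndarray) -> int:
    """Index of the maximum, preferring NORMAL on exact ties."""
    best = float(np.max(values))
    if values[NORMAL_IDX] == best:
        return NORMAL_IDX
    return int(np.argmax(values))


def viterbi_path(emissions: np.ndarray, log_trans: np.ndarray,
                 log_init: np.ndarray) -> tuple[np.ndarray, float]:
    """Exact max-probability decoding.

    ``emissions`` is (n, 4); ``log_trans`` is (n-1, 4, 4) of log transition
    matrices between consecutive probes.  Returns (state path, path log-prob).
    Ties break toward the NORMAL state.
    """
    n = emissions.shape[0]
    delta = log_init + emissions[0]
    back = np.zeros((n, 4), dtype=np.int8)
    for t in range(1, n):
        cand = delta[:, None] + log_trans[t - 1]  # (from, to)
        for j in range(4):
            back[t, j] = _argmax_prefer_normal(cand[:, j])
        delta = cand[back[t], np.arange(4)] + emissions[t]
    path = np.empty(n, dtype=np.int8)
    path[-1] = _argmax_prefer_normal(delta)
    logp = float(delta[path[-1]])
    for t in range(n - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return path, logp


def _runs_to_calls(path, emissions, pos, chrom, sample_id, source):
    calls = []
    n = len(path)
    i = 0
    while i < n:
        if path[i] == NORMAL_IDX:
            i += 1
            continue
        j = i
        while j + 1 < n and path[j + 1] == path[i]:
            j += 1
        state = int(path[i])
        score = float(np.sum(emissions[i:j + 1, state] - emissions[i:j + 1, NORMAL_IDX]))
        calls.append({
            "sample_id": sample_id, "chrom": chrom,
            "start": int(pos[i]), "end": int(pos[j]),
            "cn": STATE_CN[state], "n_probes": j - i + 1,
            "score": score, "source": source,
        })
        i = j + 1
    return calls


CALL_COLUMNS = ["sample_id", "chrom", "start", "end", "cn", "n_probes", "score", "source"]


def empty_calls() -> pd.DataFrame:
    return pd.DataFrame(columns=CALL_COLUMNS).astype(
        {"start": np.int64, "end": np.int64, "cn": np.int64, "n_probes": np.int64,
         "score": float}
    )


def viterbi_call(
    signal: pd.DataFrame,
    probe_map: pd.DataFrame,
    params: HMMParams | None = None,
    sample_id: str | None = None,
    autosomes_only: bool = True,
) -> pd.DataFrame:
    """Call CNVs for one sample: maximal runs of non-normal Viterbi states.

    A call spans the first to the last probe of the run; its score is the
    summed emission log-likelihood margin of the decoded state over the
    forced-normal alternative.
    """
    params = params or HMMParams()
    sample_id = sample_id or str(signal.attrs.get("sample_id", "sample"))
    pfb = dict(zip(probe_map["probe_id"], probe_map["pfb"]))
    df = signal.copy()
    df["pfb"] = df["probe_id"].map(pfb)
    if df["pfb"].isna().any():
        raise KeyError("signal contains probes absent from the probe map")
    if autosomes_only:
        df = df[df["chrom"] != "X"]
    log_init = np.log(np.array([params.p_off] * 4))
    log_init[NORMAL_IDX] = np.log(1 - 3 * params.p_off)
    calls = []
    for chrom, g in df.groupby("chrom", sort=False):
        g = g.sort_values("pos")
        if len(g) < 2:
            warnings.warn(f"chromosome {chrom}: fewer than 2 probes, no calls made")
            continue
        pos = g["pos"].to_numpy()
        em = emission_matrix(g["lrr"].to_numpy(), g["baf"].to_numpy(),
                             g["pfb"].to_numpy(), params)
        gaps = np.diff(pos).astype(float)
        m = params.p_off * (1.0 - np.exp(-np.maximum(gaps, 1.0) / params.d_bp))
        log_trans = np.empty((len(gaps), 4, 4))
        log_off = np.log(np.maximum(m / 3.0, _TINY))
        log_diag = np.log(1.0 - m)
        log_trans[:] = log_off[:, None, None]
        for k in range(4):
            log_trans[:, k, k] = log_diag
        path, _ = viterbi_path(em, log_trans, log_init)
        calls.extend(_runs_to_calls(path, em, pos, chrom, sample_id, "HMM"))
    return pd.DataFrame(calls, columns=CALL_COLUMNS) if calls else empty_calls()


def call_all_hmm(signals: dict[str, pd.DataFrame], probe_map: pd.DataFrame,
                 params: HMMParams | None = None) -> pd.DataFrame:
    """Run the HMM caller on every sample and concatenate the calls."""
    frames = [
        viterbi_call(df, probe_map, params, sample_id=s) for s, df in sorted(signals.items())
    ]
    frames = [f for f in frames if len(f)]
    return pd.concat(frames, ignore_index=True) if frames else empty_calls()


def estimate_pfb(signals: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Estimate per-probe PFB as the across-sample mean BAF, clipped to [0.01, 0.99]."""
    long = pd.concat(
        [df[["probe_id", "baf"]] for df in signals.values()], ignore_index=True
    )
    pfb = long.groupby("probe_id")["baf"].mean().clip(0.01, 0.99)
    return pfb.rename("pfb").reset_index()
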