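"""Synthetic multi-population SNP-array datasets with spiked copy-number events.

The generator emulates the signal structure that array-based CNV callers
consume: per-probe Log R Ratio (LRR, ~0 at two copies, negative for losses,
positive for gains) and B Allele Frequency (BAF, clustering at {0, 1/2, 1}
for a diploid genotype).  Ground-truth events are spiked at chosen loci with
per-population carrier frequencies so that every downstream stage — QC,
calling, consensus filtering, CNVR cataloguing and cross-population
comparison — can be tested against a known truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

AUTOSOMES = tuple(str(c) for c in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X",)

#: Scaled-down chromosome lengths (bp) giving ~6 kb probe spacing at the
#: default probe counts.  Real genome sizes are not needed for any of the
#: interval arithmetic downstream; only relative densities matter.
DEFAULT_CHROM_LENGTHS: dict[str, int] = {
    **{str(c): 1_300_000 for c in range(1, 23)},
    "X": 1_000_000,
}


@dataclass(frozen=True)
class SignalModel:
    """Per-copy-number emission model for LRR and BAF.

    ``lrr_mean``/``lrr_sd`` are indexed by copy number 0..3.  BAF cluster
    centers are implied by the copy number (uniform noise for cn 0, {0,1}
    for cn 1, {0,1/2,1} for cn 2, {0,1/3,2/3,1} for cn 3); ``baf_sd`` is the
    within-cluster SD.  ``nocall_rate`` is the fraction of probes emitted
    without a genotype call, driving the call-rate QC.
    """

    lrr_mean: tuple[float, float, float, float] = (-3.5, -0.66, 0.0, 0.40)
    lrr_sd: tuple[float, float, float, float] = (1.3, 0.25, 0.18, 0.20)
    baf_sd: float = 0.03
    nocall_rate: float = 0.005

    def __post_init__(self) -> None:
        if not (self.lrr_mean[0] < self.lrr_mean[1] < self.lrr_mean[2] < self.lrr_mean[3]):
            raise ValueError("LRR means must be ordered cn0 < cn1 < cn2 < cn3")
        if any(s <= 0 for s in self.lrr_sd) or self.baf_sd <= 0:
            raise ValueError("all SDs must be positive")
        if not 0 <= self.nocall_rate < 1:
            raise ValueError("nocall_rate must be in [0, 1)")


@dataclass
class TruthCNV:
    """A spiked ground-truth event and who carries it."""

    chrom: str
    start_bp: int
    end_bp: int
    copy_number: int  # one of {0, 1, 3}
    carrier_ids: frozenset[str]
    pop_freq: dict[str, float]  # target frequency per population
    n_probes: int

    @property
    def direction(self) -> str:
        return "DEL" if self.copy_number < 2 else "DUP"

    @property
    def length(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass
class SyntheticDataset:
    """Bundle returned by :func:`simulate_dataset`."""

    probe_map: pd.DataFrame
    manifest: pd.DataFrame
    signals: dict[str, pd.DataFrame]
    truth: list[TruthCNV]
    model: SignalModel = field(default_factory=SignalModel)


def make_probe_map(
    n_probes_per_chrom: int | dict[str, int],
    chrom_lengths: dict[str, int] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniformly spaced, jittered probe positions with a PFB per probe.

    Positions are strictly increasing within each chromosome (jitter is
    bounded below half the grid spacing).  PFB — the population frequency of
    the B allele used as a prior by the BAF emission model — is drawn
    uniform on [0.05, 0.95].
    """
    chrom_lengths = dict(chrom_lengths or DEFAULT_CHROM_LENGTHS)
    rng = np.random.default_rng(seed)
    frames = []
    for chrom, length in chrom_lengths.items():
        n = n_probes_per_chrom[chrom] if isinstance(n_probes_per_chrom, dict) else n_probes_per_chrom
        if n < 2:
            raise ValueError(f"need at least 2 probes per chromosome, got {n} for {chrom}")
        spacing = length / n
        grid = (np.arange(n) + 0.5) * spacing
        pos = np.clip(np.round(grid + rng.uniform(-0.49, 0.49, n) * spacing), 1, length)
        pos = np.unique(pos).astype(np.int64)  # jitter bound keeps all n distinct
        frames.append(
            pd.DataFrame(
                {
                    "probe_id": [f"rs_{chrom}_{i}" for i in range(len(pos))],
                    "chrom": chrom,
                    "pos": pos,
                    "pfb": rng.uniform(0.05, 0.95, len(pos)),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def spike_cnvs(
    probe_map: pd.DataFrame,
    populations: list[tuple[str, int]],
    loci: list[tuple[str, int, int, int, dict[str, float]]],
    seed: int = 0,
) -> tuple[list[TruthCNV], dict[str, list[int]]]:
    """Assign carriers for each truth locus by independent Bernoulli draws.

    ``loci`` rows are (chrom, start_bp, end_bp, copy_number, {pop: freq}).
    Returns the truth list and a mapping sample_id -> indices into it.
    Loci containing no probes are skipped with a warning; loci on the X
    chromosome are rejected (only autosomes carry spiked events).
    """
    rng = np.random.default_rng(seed)
    sample_ids = {pop: [f"{pop}_{i:04d}" for i in range(n)] for pop, n in populations}
    carriers: dict[str, list[int]] = {s: [] for ids in sample_ids.values() for s in ids}
    truth: list[TruthCNV] = []
    for chrom, start, end, cn, freqs in loci:
        if chrom not in AUTOSOMES:
            raise ValueError(f"spiked CNVs must be autosomal, got chromosome {chrom}")
        if start > end:
            raise ValueError(f"locus start {start} > end {end}")
        if any(not 0 <= f <= 1 for f in freqs.values()):
            raise ValueError("carrier frequencies must be in [0, 1]")
        on = probe_map[(probe_map["chrom"] == chrom)
                       & (probe_map["pos"] >= start) & (probe_map["pos"] <= end)]
        if on.empty:
            warnings.warn(f"locus {chrom}:{start}-{end} contains no probes; skipped")
            continue
        carrier_ids = []
        for pop, _n in populations:
            f = freqs.get(pop, 0.0)
            take = rng.random(len(sample_ids[pop])) < f
            carrier_ids.extend(s for s, t in zip(sample_ids[pop], take) if t)
        idx = len(truth)
        truth.append(
            TruthCNV(chrom, int(start), int(end), cn, frozenset(carrier_ids),
                     dict(freqs), n_probes=len(on))
        )
        for s in carrier_ids:
            carriers[s].append(idx)
    return truth, carriers


def make_manifest(populations: list[tuple[str, int]], seed: int = 0) -> pd.DataFrame:
    rng = np.random.default_rng(seed)
    rows = []
    for pop, n in populations:
        sexes = rng.choice(["male", "female"], n)
        rows += [(f"{pop}_{i:04d}", pop, sexes[i]) for i in range(n)]
    return pd.DataFrame(rows, columns=["sample_id", "population", "reported_sex"])


def _baf_and_genotype(
    cn: np.ndarray, pfb: np.ndarray, sd: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw BAF and the genotype call implied by the BAF cluster.

    cn 2: clusters {0, 1/2, 1} with Hardy-Weinberg weights from pfb;
    cn 1: {0, 1} weighted (1-p, p); cn 3: {0, 1/3, 2/3, 1} with binomial
    weights; cn 0: uniform noise, genotype no-call.
    """
    n = len(cn)
    baf = np.empty(n)
    geno = np.empty(n, dtype=object)
    u = rng.random(n)
    b_copies = np.zeros(n, dtype=np.int64)
    for c in (1, 2, 3):
        m = cn == c
        if not m.any():
            continue
        # number of B alleles ~ Binomial(c, pfb), drawn via inverse CDF on u
        from scipy.stats import binom

        b_copies[m] = binom.ppf(u[m], c, pfb[m]).astype(np.int64)
    centers = np.where(cn > 0, b_copies / np.maximum(cn, 1), 0.0)
    noise = rng.normal(0.0, sd, n)
    baf = np.clip(centers + noise, 0.0, 1.0)
    m0 = cn == 0
    baf[m0] = rng.random(m0.sum())
    geno[:] = "NC"
    het = (centers > 0.0) & (centers < 1.0) & ~m0
    geno[~m0 & (centers == 0.0)] = "AA"
    geno[~m0 & (centers == 1.0)] = "BB"
    geno[het] = "AB"
    return baf, geno


def emit_signals(
    probe_map: pd.DataFrame,
    carriers: dict[str, list[int]],
    truth: list[TruthCNV],
    manifest: pd.DataFrame,
    model: SignalModel | None = None,
    seed: int = 0,
    noisy_samples: dict[str, float] | None = None,
) -> dict[str, pd.DataFrame]:
    """Emit one signal table per sample (probe_id, chrom, pos, genotype, lrr, baf).

    Outside truth events LRR ~ Normal(0, sd_cn2) and BAF follows the diploid
    cluster model; inside an event the carrier's copy number drives both
    channels.  Male samples are hemizygous on X (cn-1 emission there).
    ``noisy_samples`` maps sample ids to an inflated diploid LRR SD, used to
    exercise the LRR-SD QC rule.
    """
    model = model or SignalModel()
    sex = dict(zip(manifest["sample_id"], manifest["reported_sex"]))
    ss = np.random.SeedSequence(seed)
    child = {s: np.random.default_rng(c)
             for s, c in zip(sorted(carriers), ss.spawn(len(carriers)))}
    pm = probe_map.reset_index(drop=True)
    chrom = pm["chrom"].to_numpy()
    pos = pm["pos"].to_numpy()
    pfb = pm["pfb"].to_numpy()
    lrr_mean = np.asarray(model.lrr_mean)
    lrr_sd = np.asarray(model.lrr_sd)
    out: dict[str, pd.DataFrame] = {}
    for sample in sorted(carriers):
        rng = child[sample]
        cn = np.full(len(pm), 2, dtype=np.int64)
        if sex.get(sample) == "male":
            cn[chrom == "X"] = 1
        for ti in carriers[sample]:
            t = truth[ti]
            cn[(chrom == t.chrom) & (pos >= t.start_bp) & (pos <= t.end_bp)] = t.copy_number
        sd = lrr_sd.copy()
        if noisy_samples and sample in noisy_samples:
            sd = np.maximum(sd, noisy_samples[sample])
        lrr = rng.normal(lrr_mean[cn], sd[cn])
        baf, geno = _baf_and_genotype(cn, pfb, model.baf_sd, rng)
        if model.nocall_rate > 0:
            geno[rng.random(len(pm)) < model.nocall_rate] = "NC"
        out[sample] = pd.DataFrame(
            {"probe_id": pm["probe_id"], "chrom": chrom, "pos": pos,
             "genotype": geno, "lrr": lrr, "baf": baf}
        )
    return out


# ---------------------------------------------------------------------------
# Standard fixture: three populations with frequency-differentiated loci

#: (chrom, start-probe, n-probes, copy_number, {pop: freq}) — resolved to bp
#: against the probe map at build time.  Frequencies span the rare-to-common
#: range {0.01, 0.05, 0.2, 0.5} and differ by population so that the
#: association test and the frequency clustering have planted structure.
DEMO_LOCI_PLAN = [
    ("1", 60, 30, 1, {"POPA": 0.5, "POPB": 0.5, "POPC": 0.1}),
    ("2", 80, 25, 3, {"POPA": 0.2, "POPB": 0.2, "POPC": 0.6}),
    ("3", 50, 20, 0, {"POPA": 0.05, "POPB": 0.01, "POPC": 0.01}),
    ("4", 100, 22, 1, {"POPA": 0.05, "POPB": 0.3, "POPC": 0.3}),
    ("5", 40, 20, 3, {"POPA": 0.01, "POPB": 0.01, "POPC": 0.3}),
    ("6", 120, 20, 1, {"POPA": 0.2, "POPB": 0.01, "POPC": 0.01}),
    ("7", 90, 3, 1, {"POPA": 0.2, "POPB": 0.2, "POPC": 0.2}),   # too small: QC bait
    ("8", 30, 24, 1, {"POPA": 0.01, "POPB": 0.2, "POPC": 0.01}),
]


def demo_loci(probe_map: pd.DataFrame) -> list[tuple[str, int, int, int, dict[str, float]]]:
    """Resolve the standard locus plan to bp intervals on a probe map."""
    loci = []
    for chrom, i0, n, cn, freqs in DEMO_LOCI_PLAN:
        on = probe_map[probe_map["chrom"] == chrom]["pos"].to_numpy()
        start, end = int(on[i0]), int(on[i0 + n - 1])
        loci.append((chrom, start, end, cn, freqs))
    return loci


def demo_genes(probe_map: pd.DataFrame) -> pd.DataFrame:
    """One gene spanning each planted locus (symbol, chrom, start, end)."""
    rows = []
    for k, (chrom, start, end, _cn, _f) in enumerate(demo_loci(probe_map)):
        rows.append((f"GENE{k + 1}", chrom, start, end))
    return pd.DataFrame(rows, columns=["symbol", "chrom", "start", "end"])


def simulate_dataset(
    populations: list[tuple[str, int]] | None = None,
    n_probes_per_chrom: int | dict[str, int] | None = None,
    loci: list | None = None,
    model: SignalModel | None = None,
    seed: int = 0,
    noisy_samples: dict[str, float] | None = None,
) -> SyntheticDataset:
    """Build the full synthetic study: probe map, manifest, truth and signals.

    Defaults reproduce the standard fixture: three populations of 50 samples
    each on ~5,000 probes (220 per autosome, 160 on X) with the
    :data:`DEMO_LOCI_PLAN` events.
    """
    populations = populations or [("POPA", 50), ("POPB", 50), ("POPC", 50)]
    if n_probes_per_chrom is None:
        n_probes_per_chrom = {**{c: 220 for c in AUTOSOMES}, "X": 160}
    ss = np.random.SeedSequence(seed)
    s_map, s_spike, s_manifest, s_emit = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(4)]
    model = model or SignalModel()
    pmap = make_probe_map(n_probes_per_chrom, seed=s_map)
    if loci is None:
        loci = demo_loci(pmap)
    truth, carriers = spike_cnvs(pmap, populations, loci, seed=s_spike)
    manifest = make_manifest(populations, seed=s_manifest)
    signals = emit_signals(pmap, carriers, truth, manifest, model, seed=s_emit,
                           noisy_samples=noisy_samples)
    return SyntheticDataset(pmap, manifest, signals, truth, model)


def make_group_frequency_matrix(
    n_loci: int,
    groups: dict[str, list[str]],
    within_spread: float = 0.04,
    between_spread: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Frequency matrix (loci x populations) with planted group structure.

    Each group gets its own per-locus base frequency; populations within a
    group deviate by at most ``within_spread`` while group bases are spread
    over ``between_spread`` so that between-group distances dominate.
    """
    rng = np.random.default_rng(seed)
    cols = {}
    group_names = list(groups)
    for li in range(n_loci):
        bases = 0.1 + between_spread * rng.permutation(len(group_names)) / max(1, len(group_names) - 1)
        for g, base in zip(group_names, bases):
            for pop in groups[g]:
                cols.setdefault(pop, []).append(
                    float(np.clip(base + rng.uniform(-within_spread / 2, within_spread / 2), 0, 1))
                )
    return pd.DataFrame(cols, index=[f"locus_{i}" for i in range(n_loci)])
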