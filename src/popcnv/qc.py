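"""Sample- and probe-level quality control.

Sample exclusion follows the standard array-QC ledger: autosomal LRR SD
strictly above 0.3, SNP call rate strictly below 98%, or a mismatch between
reported and genotype-derived sex.  Probe exclusion removes SNPs out of
Hardy-Weinberg equilibrium at p < 1e-5 (1-df chi-square), computed per
population, before any CNV prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2


@dataclass
class SampleQCMetrics:
    sample_id: str
    lrr_sd: float
    call_rate: float
    inferred_sex: str
    reported_sex: str
    passed: bool
    reasons: tuple[str, ...]


def infer_sex(x_baf: np.ndarray, min_probes: int = 50) -> str:
    """Classify sex from the X-chromosome BAF heterozygote band.

    Two X copies produce a band near 0.5; one copy cannot.  Returns
    ``unknown`` below ``min_probes`` X probes or in the ambiguous range.
    """
    x_baf = np.asarray(x_baf, dtype=float)
    if len(x_baf) < min_probes:
        return "unknown"
    het = float(np.mean((x_baf > 0.25) & (x_baf < 0.75)))
    if het >= 0.10:
        return "female"
    if het < 0.02:
        return "male"
    return "unknown"


def sample_qc(
    signals: dict[str, pd.DataFrame],
    manifest: pd.DataFrame,
    lrr_sd_max: float = 0.3,
    call_rate_min: float = 0.98,
) -> pd.DataFrame:
    """Per-sample QC metrics and pass/fail with reasons.

    Exclusion is by strict inequality: a sample at exactly the LRR-SD or
    call-rate threshold passes.  Sex mismatch only fails when sex is
    inferable (not ``unknown``).
    """
    reported = dict(zip(manifest["sample_id"], manifest["reported_sex"]))
    rows = []
    for sample in sorted(signals):
        if sample not in reported:
            raise KeyError(f"sample {sample!r} missing from manifest")
        df = signals[sample]
        auto = df[df["chrom"] != "X"]
        if len(auto) < 2:
            raise ValueError(f"sample {sample!r} has fewer than 2 autosomal probes")
        lrr_sd = float(auto["lrr"].std(ddof=1))
        call_rate = float((df["genotype"] != "NC").mean())
        sex = infer_sex(df.loc[df["chrom"] == "X", "baf"].to_numpy())
        reasons = []
        if lrr_sd > lrr_sd_max:
            reasons.append("lrr_sd")
        if call_rate < call_rate_min:
            reasons.append("call_rate")
        if sex != "unknown" and sex != reported[sample]:
            reasons.append("sex_mismatch")
        rows.append((sample, lrr_sd, call_rate, sex, reported[sample],
                     not reasons, ",".join(reasons)))
    return pd.DataFrame(
        rows,
        columns=["sample_id", "lrr_sd", "call_rate", "inferred_sex",
                 "reported_sex", "passed", "reasons"],
    )


def hwe_test(n_aa, n_ab, n_bb):
    """1-df chi-square goodness-of-fit p-value against Hardy-Weinberg counts.

    Expected counts come from the observed allele frequency; monomorphic
    probes return p = 1.  Accepts scalars or equal-length arrays.
    """
    n_aa = np.asarray(n_aa, dtype=float)
    n_ab = np.asarray(n_ab, dtype=float)
    n_bb = np.asarray(n_bb, dtype=float)
    if (n_aa < 0).any() or (n_ab < 0).any() or (n_bb < 0).any():
        raise ValueError("genotype counts must be non-negative")
    n = n_aa + n_ab + n_bb
    if (n < 1).any():
        raise ValueError("total genotype count must be >= 1")
    p = (2 * n_aa + n_ab) / (2 * n)
    q = 1 - p
    with np.errstate(divide="ignore", invalid="ignore"):
        e_aa, e_ab, e_bb = n * p**2, n * 2 * p * q, n * q**2
        stat = ((n_aa - e_aa) ** 2 / e_aa
                + (n_ab - e_ab) ** 2 / e_ab
                + (n_bb - e_bb) ** 2 / e_bb)
    mono = (p == 0) | (q == 0)
    stat = np.where(mono, 0.0, stat)
    pval = chi2.sf(stat, df=1)
    pval = np.where(stat == 0.0, 1.0, pval)
    return float(pval) if pval.ndim == 0 else pval


def compute_hwe(
    signals: dict[str, pd.DataFrame],
    manifest: pd.DataFrame,
    populations: bool = True,
) -> pd.DataFrame:
    """Genotype counts and HWE p-values per probe (per population by default).

    Only called genotypes (AA/AB/BB) contribute.  Returns one row per
    (probe, population) — or per probe with population 'ALL' when
    ``populations`` is False.
    """
    pop = dict(zip(manifest["sample_id"], manifest["population"]))
    frames = []
    for sample, df in signals.items():
        frames.append(pd.DataFrame({
            "probe_id": df["probe_id"],
            "chrom": df["chrom"],
            "genotype": df["genotype"],
            "population": pop[sample] if populations else "ALL",
        }))
    long = pd.concat(frames, ignore_index=True)
    long = long[long["genotype"].isin(["AA", "AB", "BB"])]
    counts = (
        long.groupby(["probe_id", "population", "genotype"], observed=True)
        .size().unstack("genotype", fill_value=0)
        .reindex(columns=["AA", "AB", "BB"], fill_value=0)
        .reset_index()
    )
    counts = counts[(counts[["AA", "AB", "BB"]].sum(axis=1)) >= 1].reset_index(drop=True)
    counts["p_value"] = hwe_test(counts["AA"], counts["AB"], counts["BB"])
    return counts.rename(columns={"AA": "n_aa", "AB": "n_ab", "BB": "n_bb"})


def filter_probes(
    signals: dict[str, pd.DataFrame],
    hwe_results: pd.DataFrame,
    threshold: float = 1e-5,
) -> tuple[dict[str, pd.DataFrame], list[str]]:
    """Drop probes failing HWE (p < threshold in any population) from all samples."""
    bad = sorted(set(hwe_results.loc[hwe_results["p_value"] < threshold, "probe_id"]))
    if not bad:
        return dict(signals), []
    bad_set = set(bad)
    out = {
        s: df[~df["probe_id"].isin(bad_set)].reset_index(drop=True)
        for s, df in signals.items()
    }
    return out, bad


def exclusion_percent(n_total: int, n_kept: int, decimals: int = 3) -> float:
    """Percentage of samples excluded by QC, rounded for reporting."""
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    return round(100.0 * (n_total - n_kept) / n_total, decimals)
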