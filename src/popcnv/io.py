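"""Readers and writers for the pipeline's tabular formats.

One coordinate convention holds internally — 1-based closed intervals —
and conversion happens only at BED boundaries (BED is 0-based half-open).
Call tables use the PLINK-style .cnv layout: FID IID CHR BP1 BP2 TYPE SCORE
SITES, with TYPE the integer copy number (0, 1 or 3).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

SIGNAL_COLUMNS = ["probe_id", "chrom", "pos", "genotype", "lrr", "baf"]
CNV_HEADER = ["FID", "IID", "CHR", "BP1", "BP2", "TYPE", "SCORE", "SITES"]


def write_signal_tsv(signal: pd.DataFrame, path) -> None:
    signal.to_csv(path, sep="\t", index=False, columns=SIGNAL_COLUMNS)


def read_signal_tsv(path) -> pd.DataFrame:
    """Read one sample's signal table, validating domains row by row.

    Malformed rows raise with 1-based data line numbers; an empty file
    returns an empty frame with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SIGNAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty signal file")
        return df[SIGNAL_COLUMNS]
    bad = df.index[(df["baf"] < 0) | (df["baf"] > 1) | df["baf"].isna()]
    if len(bad):
        raise ValueError(f"{path}: BAF out of [0,1] at line {int(bad[0]) + 2}")
    bad = df.index[(df["pos"] < 1) | df["pos"].isna()]
    if len(bad):
        raise ValueError(f"{path}: invalid position at line {int(bad[0]) + 2}")
    df["pos"] = df["pos"].astype(np.int64)
    return df[SIGNAL_COLUMNS]


def write_signals(signals: dict[str, pd.DataFrame], directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for sample, df in signals.items():
        write_signal_tsv(df, directory / f"{sample}.tsv")


def read_signals(directory) -> dict[str, pd.DataFrame]:
    directory = Path(directory)
    out = {}
    for path in sorted(directory.glob("*.tsv")):
        out[path.stem] = read_signal_tsv(path)
    return out


def write_probe_map(probe_map: pd.DataFrame, path) -> None:
    probe_map.to_csv(path, sep="\t", index=False,
                     columns=["probe_id", "chrom", "pos", "pfb"])


def read_probe_map(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in ["probe_id", "chrom", "pos", "pfb"]:
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    df["pos"] = df["pos"].astype(np.int64)
    return df


def write_manifest(manifest: pd.DataFrame, path) -> None:
    manifest.to_csv(path, sep="\t", index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    for c in ["sample_id", "population", "reported_sex"]:
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    return df


def read_bed(path, extra_names: tuple[str, ...] = ("name",)) -> pd.DataFrame:
    """Read a BED file into 1-based closed intervals, sorted.

    Source coordinates are 0-based half-open; start must be strictly below
    end in those coordinates.  A 4th column, when present, is kept under
    ``extra_names[0]``.
    """
    rows = []
    with open(path) as fh:
        for ln, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 3:
                raise ValueError(f"{path}: line {ln}: fewer than 3 BED columns")
            chrom, s, e = parts[0].removeprefix("chr"), int(parts[1]), int(parts[2])
            if s >= e:
                raise ValueError(f"{path}: line {ln}: start {s} >= end {e}")
            row = {"chrom": chrom, "start": s + 1, "end": e}
            for k, v in zip(extra_names, parts[3:]):
                row[k] = v
            rows.append(row)
    df = pd.DataFrame(rows)
    if df.empty:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def write_cnv_table(calls: pd.DataFrame, path) -> None:
    """Write calls as PLINK-style .cnv (FID IID CHR BP1 BP2 TYPE SCORE SITES)."""
    out = pd.DataFrame({
        "FID": calls["sample_id"], "IID": calls["sample_id"],
        "CHR": calls["chrom"], "BP1": calls["start"], "BP2": calls["end"],
        "TYPE": calls["cn"], "SCORE": calls["score"], "SITES": calls["n_probes"],
    })
    out.to_csv(path, sep="\t", index=False)


def read_cnv_table(path, source: str = "UNKNOWN") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in CNV_HEADER if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if (df["BP1"] > df["BP2"]).any():
        ln = int(df.index[df["BP1"] > df["BP2"]][0]) + 2
        raise ValueError(f"{path}: BP1 > BP2 at line {ln}")
    return pd.DataFrame({
        "sample_id": df["IID"], "chrom": df["CHR"],
        "start": df["BP1"].astype(np.int64), "end": df["BP2"].astype(np.int64),
        "cn": df["TYPE"].astype(np.int64), "n_probes": df["SITES"].astype(np.int64),
        "score": df["SCORE"].astype(float), "source": source,
    })[["sample_id", "chrom", "start", "end", "cn", "n_probes", "score", "source"]]


def write_genes(genes: pd.DataFrame, path) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_genes(path) -> pd.DataFrame:
    """Gene list TSV (symbol, chrom, start, end); malformed rows are skipped."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for c in ["symbol", "chrom", "start", "end"]:
        if c not in df.columns:
            raise ValueError(f"{path}: missing column {c!r}")
    ok = df["start"].notna() & df["end"].notna() & (df["start"] <= df["end"])
    if (~ok).any():
        warnings.warn(f"{path}: skipped {int((~ok).sum())} malformed gene row(s)")
    df = df[ok].copy()
    df["start"] = df["start"].astype(np.int64)
    df["end"] = df["end"].astype(np.int64)
    return df.reset_index(drop=True)


def read_syndromes(path) -> pd.DataFrame:
    """Syndrome regions as BED with a direction (DEL/DUP) in the 4th column."""
    df = read_bed(path, extra_names=("direction",))
    if len(df) and ("direction" not in df.columns or df["direction"].isna().any()):
        raise ValueError(f"{path}: every syndrome region needs a DEL/DUP direction")
    return df


def write_truth(truth, path) -> None:
    """Ground-truth events as BED-like TSV with a copy-number column."""
    rows = [{
        "chrom": t.chrom, "start": t.start_bp, "end": t.end_bp,
        "copy_number": t.copy_number, "n_probes": t.n_probes,
        "carriers": ",".join(sorted(t.carrier_ids)),
    } for t in truth]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
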