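"""End-to-end orchestration: QC -> dual calling -> consensus -> catalog ->
population comparison, in memory or driven by a YAML config on disk."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as pio
from .cbs import CBSParams, SegmentThresholds, call_all_cbs
from .cnvr import (cnvr_frequency, merge_cnvrs, summarize_catalog,
                   syndrome_overlap)
from .compare import (associate_loci, hierarchical_cluster, scale_rows,
                      top_gene_selection)
from .consensus import (FilterConfig, apply_filters, concordance_fraction,
                        consensus_calls)
from .hmm import HMMParams, call_all_hmm
from .qc import compute_hwe, filter_probes, sample_qc

log = logging.getLogger("popcnv")


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run; serializes to/from YAML."""

    signals_dir: str = ""
    probe_map: str = ""
    manifest: str = ""
    exclude_bed: str | None = None
    genes: str | None = None
    syndromes: str | None = None
    out_dir: str = "popcnv_out"
    seed: int = 0
    ref_pop: str | None = None
    n_perm: int = 5000
    lrr_sd_max: float = 0.3
    call_rate_min: float = 0.98
    hwe_threshold: float = 1e-5
    filter: FilterConfig = field(default_factory=FilterConfig)
    hmm: HMMParams = field(default_factory=HMMParams)
    cbs: CBSParams = field(default_factory=CBSParams)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key, typ in [("filter", FilterConfig), ("hmm", HMMParams), ("cbs", CBSParams)]:
            if key in raw and isinstance(raw[key], dict):
                d = dict(raw[key])
                if key == "cbs" and isinstance(d.get("thresholds"), dict):
                    d["thresholds"] = SegmentThresholds(**d["thresholds"])
                for tup in ("lrr_mean", "lrr_sd"):
                    if tup in d and isinstance(d[tup], list):
                        d[tup] = tuple(d[tup])
                raw[key] = typ(**d)
        return cls(**raw)


@dataclass
class PipelineResult:
    qc: pd.DataFrame
    excluded_probes: list[str]
    hmm_calls: pd.DataFrame
    cbs_calls: pd.DataFrame
    consensus: pd.DataFrame
    kept: pd.DataFrame
    rejection_ledger: pd.DataFrame
    concordance: object
    cnvrs: pd.DataFrame
    frequency_table: pd.DataFrame
    summary: object
    syndrome: tuple[int, float] | None = None
    association: pd.DataFrame | None = None
    top_loci: list[str] | None = None
    frequency_matrix: pd.DataFrame | None = None
    scaled_matrix: pd.DataFrame | None = None
    cluster: object | None = None


def gene_carrier_table(kept: pd.DataFrame, genes: pd.DataFrame,
                       manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-gene carrier counts per population.

    A sample carries a gene locus when any of its filtered calls overlaps
    the gene by at least one base.
    """
    pop = dict(zip(manifest["sample_id"], manifest["population"]))
    pops = sorted(manifest["population"].unique())
    rows = []
    for _, g in genes.iterrows():
        hit = kept[(kept["chrom"] == g["chrom"]) & (kept["start"] <= g["end"])
                   & (kept["end"] >= g["start"])]
        samples = set(hit["sample_id"])
        row = {"locus": g["symbol"], "chrom": g["chrom"], "pos": int(g["start"])}
        for p in pops:
            row[f"carriers_{p}"] = sum(1 for s in samples if pop[s] == p)
        rows.append(row)
    return pd.DataFrame(rows)


def run_analysis(
    signals: dict[str, pd.DataFrame],
    probe_map: pd.DataFrame,
    manifest: pd.DataFrame,
    excluded_regions: pd.DataFrame | None = None,
    genes: pd.DataFrame | None = None,
    syndromes: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
    autosome_lengths: dict[str, int] | None = None,
) -> PipelineResult:
    """Run every analysis stage on in-memory tables.

    Stage order: sample QC, HWE probe filtering, HMM and CBS calling,
    consensus intersection, CNV-level filters, CNVR cataloguing and — when a
    gene list is supplied — permutation association, top-locus selection and
    population clustering.  Identical inputs and seed give identical output.
    """
    cfg = config or PipelineConfig()
    if excluded_regions is None:
        excluded_regions = pd.DataFrame(columns=["chrom", "start", "end"])
    qc = sample_qc(signals, manifest, cfg.lrr_sd_max, cfg.call_rate_min)
    passing = set(qc.loc[qc["passed"], "sample_id"])
    log.info("sample QC: %d/%d pass", len(passing), len(qc))
    signals = {s: df for s, df in signals.items() if s in passing}
    manifest_ok = manifest[manifest["sample_id"].isin(passing)].reset_index(drop=True)

    hwe = compute_hwe(signals, manifest_ok)
    signals, removed = filter_probes(signals, hwe, cfg.hwe_threshold)
    pmap = probe_map[~probe_map["probe_id"].isin(set(removed))].reset_index(drop=True)
    log.info("HWE filter: removed %d probes", len(removed))

    hmm_calls = call_all_hmm(signals, pmap, cfg.hmm)
    cbs_calls = call_all_cbs(signals, cfg.cbs, seed=cfg.seed)
    log.info("calls: HMM %d, CBS %d", len(hmm_calls), len(cbs_calls))

    cons = consensus_calls(hmm_calls, cbs_calls, cfg.filter, probe_map=pmap)
    conc = concordance_fraction(hmm_calls, cbs_calls, cfg.filter)
    kept, ledger = apply_filters(cons, pmap, excluded_regions, cfg.filter)
    log.info("consensus %d -> kept %d (rejected %d)", len(cons), len(kept), len(ledger))

    cnvrs = merge_cnvrs(kept) if len(kept) else merge_cnvrs(kept.assign())
    freq = (cnvr_frequency(cnvrs, kept, manifest_ok)
            if len(cnvrs) else pd.DataFrame())
    if autosome_lengths is None:
        auto = pmap[pmap["chrom"] != "X"]
        autosome_lengths = auto.groupby("chrom")["pos"].max().astype(int).to_dict()
    summary = summarize_catalog(kept, cnvrs, autosome_lengths,
                                n_samples=len(manifest_ok))
    syn = syndrome_overlap(kept, syndromes) if syndromes is not None else None

    association = top = fmat = scaled = cluster = None
    if genes is not None and len(kept):
        pops = sorted(manifest_ok["population"].unique())
        ref = cfg.ref_pop or pops[0]
        table = gene_carrier_table(kept, genes, manifest_ok)
        association = associate_loci(table, manifest_ok, ref, cfg.n_perm, cfg.seed)
        top = top_gene_selection(association)
        totals = manifest_ok["population"].value_counts().to_dict()
        use = table[table["locus"].isin(top)] if top else table
        fmat = pd.DataFrame(
            {p: use[f"carriers_{p}"].to_numpy() / totals[p] for p in pops},
            index=list(use["locus"]),
        )
        if len(fmat) >= 1 and fmat.shape[1] >= 2:
            scaled, _flags = scale_rows(fmat)
            cluster = hierarchical_cluster(scaled)
    return PipelineResult(qc, removed, hmm_calls, cbs_calls, cons, kept, ledger,
                          conc, cnvrs, freq, summary, syn, association, top,
                          fmat, scaled, cluster)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """File-driven run: read inputs per config, analyse, write every output."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("resolved filter config: %s", config.filter)
    signals = pio.read_signals(config.signals_dir)
    pmap = pio.read_probe_map(config.probe_map)
    manifest = pio.read_manifest(config.manifest)
    excl = pio.read_bed(config.exclude_bed) if config.exclude_bed else None
    genes = pio.read_genes(config.genes) if config.genes else None
    syndromes = pio.read_syndromes(config.syndromes) if config.syndromes else None
    res = run_analysis(signals, pmap, manifest, excl, genes, syndromes, config)

    res.qc.to_csv(out / "sample_qc.tsv", sep="\t", index=False)
    pd.Series(res.excluded_probes, name="probe_id").to_csv(
        out / "excluded_probes.tsv", sep="\t", index=False)
    pio.write_cnv_table(res.hmm_calls, out / "calls_hmm.cnv")
    pio.write_cnv_table(res.cbs_calls, out / "calls_cbs.cnv")
    pio.write_cnv_table(res.kept, out / "calls_consensus.cnv")
    res.rejection_ledger.to_csv(out / "rejections.tsv", sep="\t", index=False)
    res.cnvrs.to_csv(out / "cnvrs.tsv", sep="\t", index=False)
    if len(res.frequency_table):
        res.frequency_table.to_csv(out / "cnvr_frequencies.tsv", sep="\t", index=False)
    payload = {"summary": res.summary.as_dict(),
               "concordance": {"fraction": res.concordance.fraction,
                               "n_replicated": res.concordance.n_replicated,
                               "n_total": res.concordance.n_total}}
    if res.syndrome is not None:
        payload["syndrome_overlap"] = {"count": res.syndrome[0],
                                       "percent": res.syndrome[1]}
    (out / "summary.json").write_text(json.dumps(payload, indent=2))
    if res.association is not None:
        res.association.to_csv(out / "association.tsv", sep="\t", index=False)
    if res.scaled_matrix is not None:
        res.scaled_matrix.to_csv(out / "scaled_frequencies.tsv", sep="\t")
    if res.cluster is not None:
        (out / "dendrogram.nwk").write_text(res.cluster.newick + "\n")
        pd.DataFrame(res.cluster.linkage,
                     columns=["left", "right", "height", "count"]).to_csv(
            out / "linkage.tsv", sep="\t", index=False)
    return res
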