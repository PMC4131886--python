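"""From dual call sets to a filtered CNVR catalog.

Runs both callers over a cohort, intersects them with the 60% reciprocal
overlap rule, applies the quality filters, merges the survivors into
copy-number-variable regions and prints the catalog summary.
"""

import pandas as pd

import popcnv as pc

ds = pc.simulate_dataset(populations=[("POPA", 15), ("POPB", 15)], seed=11)
qc = pc.sample_qc(ds.signals, ds.manifest)
passing = {s: ds.signals[s] for s in qc.loc[qc["passed"], "sample_id"]}
print(f"QC: {len(passing)}/{len(ds.signals)} samples pass")

hmm_calls = pc.call_all_hmm(passing, ds.probe_map)
cbs_calls = pc.call_all_cbs(passing, seed=11)
conc = pc.concordance_fraction(hmm_calls, cbs_calls)
print(f"HMM {len(hmm_calls)} calls, CBS {len(cbs_calls)} calls; "
      f"{conc.n_replicated}/{conc.n_total} CBS calls replicated "
      f"({100 * conc.fraction:.0f}%)")

cons = pc.consensus_calls(hmm_calls, cbs_calls, probe_map=ds.probe_map)
empty_regions = pd.DataFrame(columns=["chrom", "start", "end"])
kept, ledger = pc.apply_filters(cons, ds.probe_map, empty_regions)
print(f"consensus {len(cons)} -> kept {len(kept)} "
      f"(rejected {len(ledger)}: {ledger['rule'].value_counts().to_dict()})")

cnvrs = pc.merge_cnvrs(kept)
freq = pc.cnvr_frequency(cnvrs, kept, ds.manifest)
cols = ["cnvr_id", "chrom", "start", "end", "type", "freq_POPA", "freq_POPB", "common"]
print("\nCNVR catalog (carrier frequency per population; common = >=5%):")
print(freq[cols].to_string(index=False))

summary = pc.summarize_catalog(kept, cnvrs, autosome_lengths={
    c: int(ds.probe_map.loc[ds.probe_map.chrom == c, "pos"].max())
    for c in ds.probe_map.chrom.unique() if c != "X"}, n_samples=len(passing))
print(f"\nmedian {summary.median_calls_per_genome:.0f} calls/genome, "
      f"{100 * summary.n_deletions / max(summary.n_calls, 1):.0f}% deletions, "
      f"genome coverage {summary.coverage_percent:.2f}%")
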