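"""Cross-population frequency comparison on the full synthetic study.

Runs the whole pipeline on three populations whose spiked-locus frequencies
differ, then shows the permutation association results, the selected
most-differentiated gene loci, and the population dendrogram.
"""

import popcnv as pc
from popcnv.pipeline import PipelineConfig, run_analysis
from popcnv.simulate import demo_genes

ds = pc.simulate_dataset(seed=2)  # POPA/POPB/POPC x 50 samples
res = run_analysis(ds.signals, ds.probe_map, ds.manifest,
                   genes=demo_genes(ds.probe_map),
                   config=PipelineConfig(seed=2, n_perm=5000, ref_pop="POPA"))

sig = res.association[res.association["significant"]]
print("significant locus/population pairs (empirical p at the 1/5001 floor):")
print(sig[["locus", "other_pop", "freq_ref", "freq_other", "p_value"]]
      .to_string(index=False))

print(f"\nmost differentiated loci vs POPA: {res.top_loci}")
print("\nscaled frequency matrix (rows mean 0, variance 1):")
print(res.scaled_matrix.round(2).to_string())
print(f"\ndendrogram: {res.cluster.newick}")
print("\nPopulations sharing spiked frequencies merge first; the diverged "
      "population joins last — the ancestry grouping this analysis shows "
      "on real cohorts.")
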