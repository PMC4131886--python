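# Methods

## Signal model and what the simulator emulates

SNP arrays report two per-probe channels. The Log R Ratio (LRR) is the
normalized log2 ratio of observed to expected total intensity: ~0 at copy
number 2, strongly negative for homozygous loss, mildly negative for
hemizygous loss, mildly positive for gain. The B Allele Frequency (BAF) is
the normalized B-allele signal fraction: diploid genotypes cluster at
{0, ½, 1}; one copy removes the ½ cluster; three copies split it into
{⅓, ⅔}; zero copies leave unstructured noise.

The generator draws, per probe and sample,

- LRR ~ Normal(μ_cn, σ_cn) with defaults μ = (−3.5, −0.66, 0, +0.40) and
  σ = (1.3, 0.25, 0.18, 0.20) for copy numbers (0, 1, 2, 3) — canonical
  Illumina-like values giving realistic caller difficulty while remaining
  recoverable;
- BAF from the cluster model above with within-cluster SD 0.03, cluster
  weights from the probe's population B-allele frequency (PFB, uniform on
  [0.05, 0.95]): Hardy–Weinberg weights at two copies, (1−p, p) at one,
  Binomial(3, p) at three; uniform noise at zero copies;
- a genotype call consistent with the BAF cluster, plus a configurable
  no-call fraction (default 0.5%) to drive the call-rate QC.

Probes sit on a jittered uniform grid (the real spacing distribution of the
arrays is not modelled); the scaled-down genome is 22 autosomes of ~1.3 Mb
plus an X of 1 Mb at 220/160 probes each, ~6 kb spacing, so a 20-probe
event spans ~120 kb. Truth events are spiked as Bernoulli carrier draws per
population at stated frequencies (autosomes only; X is generated solely
for the sex check, with males hemizygous). Not emulated: raw two-channel
intensities, GC waves and batch effects, linkage disequilibrium between
probes, family structure, and multi-allelic loci — so passing tests show
correctness of the pipeline's logic and its statistical calibration under
the stated noise model, not robustness to array artifacts.

The standard fixture (3 populations × 50 samples, ~5,000 probes) spikes
eight loci at frequencies spanning {0.01, 0.05, 0.2, 0.5}, mixing cn-1 and
cn-0 deletions and cn-3 duplications, with per-population frequency
differences that give the association test and the clustering planted
structure. The cn-0 locus is kept rare (5%/1%/1%): on a ~4,800-probe
genome a 20-probe homozygous deletion at mean −3.5 measurably inflates the
carrier's plain autosomal LRR SD, and at high carrier frequency the QC rule
would systematically exclude carriers — a pure scale artifact of the
compressed genome (on a 550k-probe array the same event moves the SD by
<1%). Keeping the locus rare preserves the realistic QC interplay without
biasing recovery. Problem sizes throughout (fixture size, permutation
counts in unit tests, null-rate checks at n=500 over 40 seeds) are the
package's chosen desk-scale study conditions.

## HMM caller

Four states — HOMDEL (cn 0), HETDEL (cn 1), NORMAL (cn 2), DUP (cn ≥ 3
aggregated) — decoded per chromosome by exact log-space Viterbi.

Emissions are the product of the state's LRR Gaussian and its BAF mixture.
BAF values of exactly 0 or 1 are treated as truncated-cluster point masses
(each Gaussian cluster's out-of-[0,1] mass collapses onto the boundary);
interior values use mixture densities. Because every state follows the same
convention, boundary likelihood comparisons stay meaningful; the uniform
HOMDEL distribution gets a nominal boundary mass of 0.01 so copy number 0
is not ruled out by a clipped BAF. Transition probability between probes
d bp apart leaves the current state with probability
p_off · (1 − exp(−d/D)), split evenly among the other states, with
p_off = 10⁻⁴ and D = 100 kb — chosen so the expected number of spurious
segments on null data is far below one per genome (measured: ≤1% of
pure-noise samples receive any call). Ties in the dynamic program break
toward NORMAL. Calls span the first to last probe of a non-normal run (no
midpoint extension); the score is the summed emission log-likelihood margin
of the decoded state over forced-normal, a transition-free approximation
that orders calls by evidence.

## CBS caller

Circular binary segmentation recursively splits each chromosome's LRR
vector at the arc (i, j] maximizing the two-sample t-like statistic against
its complement. The scan uses the ANOVA identity — within-group SS equals
total centered SS minus L(n−L)/n · d² for an arc of length L with
arc-vs-complement mean difference d — so T is monotone in |d| at fixed L
and the maximum is found from the extreme moving sums of each length, O(n)
per length with trivial memory. An exhaustive double-loop oracle in the
test suite checks equivalence.

Each candidate split is validated by permuting the values within the tested
window, p = (b+1)/(R+1) with R = 1000 and acceptance at p ≤ α = 0.01
(standard CBS defaults; the canonical implementation's pruning/undo
machinery is not reproduced). Permutations for a window are drawn from an
rng keyed on (seed, window), so each window's decision is independent of
recursion history; this makes breakpoint sets monotone in α and lets the
rejection early-stop (batches of 32→512 permutations, stopping once the
exceedance count already forces p > α) without changing any decision.
Constant windows (T = 0) and windows shorter than 4 probes are never split.

Segments are classified from mean LRR and the BAF distribution:
HOMDEL below −2.0; HETDEL below −0.3 with <5% of BAF in the wide
heterozygote band (0.25, 0.75); DUP above +0.2 with <15% of BAF in the
narrow (0.4, 0.6) band. The duplication rule deliberately uses the narrow
band: three-copy heterozygote clusters sit at ⅓ and ⅔ — inside the wide
band but away from ½ — so absence of mass near 0.5 is the discriminating
feature, while a wide-band rule could never fire on a true duplication.
Thresholds are configurable surrogates for an unpublished likelihood rule.
Adjacent segments of identical class are merged before calls are emitted.

## Consensus and filters

Calls from the two algorithms pair when sample, chromosome and direction
(DEL = cn<2 vs DUP) agree and the intersection covers ≥ 60% of *both*
calls (reciprocal mode; an either-of mode is configurable). Matching is
greedy one-to-one by descending overlap length, ties to the leftmost
intersection, so concordance counts are well defined. The consensus call is
the intersection interval; its copy-number class comes from the HMM member
(the model that distinguishes cn 0 from cn 1); probes are recounted inside
the intersection. Concordance is reported with CBS calls as denominator.

Filters, all on 1-based closed intervals (length = end − start + 1):
probe density n/length ≥ 1/30,000; deletions need ≥ 5 probes and length
strictly > 5 kb, duplications ≥ 10 probes and > 10 kb; > 50% overlap with
centromere/telomere regions rejects; sex-chromosome calls reject; samples
with > 100 surviving calls are dropped entirely (array failure signature).
Boundary semantics are strict exactly where stated (SD > 0.3, rate < 98%,
length > 5 kb); every rejection is tagged with its rule in a ledger so
kept + rejected = input at each stage.

## CNVR catalog

CNVRs are the transitive union of overlapping calls across samples;
closed intervals abutting at one base merge (consistent with "overlap" on
closed coordinates). A region containing both directions is COMPLEX. An
individual counts once per region regardless of how many member calls they
contribute; "fell within" is interpreted as any-bp overlap (full
containment would contradict the union construction). Regions at ≥ 5%
frequency are flagged common; singleton regions (one carrier) are dropped
before cross-catalog comparison. Genome coverage uses the summed provided
autosome lengths as denominator (probe-map extent by default). The
multi-allelic exclusion (HLA/immunoglobulin/olfactory-receptor families) is
an optional exclusion list applied by the caller of the frequency table,
not hard-coded gene names.

## Population comparison

The association statistic is the absolute carrier-frequency difference; the
null is generated by shuffling population labels over the pooled carrier
vector, implemented as hypergeometric draws of the group-1 carrier count
(exactly equivalent, and cross-validated against the exact hypergeometric
tail). Empirical p = (b+1)/(R+1) with R = 5,000 never reaches 0; the floor
is 1/(R+1) ≈ 0.0002, so the significance flag fires at p < 2·10⁻⁴ *or* at
the floor itself (otherwise the stated cut would be unattainable), and a
zero statistic is never flagged. Because the statistic is discrete, the
test is slightly conservative: measured type-I at nominal 0.05 is ≈ 0.035
with 200 samples per group at 10% frequency.

Per population pair, the 10 most positive and 10 most negative significant
frequency differences are selected (ties by smaller p, then genome order),
unioned and de-duplicated across pairs. The locus unit is the
gene-overlapping CNV locus: a gene's carrier set is the samples with ≥ 1
filtered call overlapping the gene. Frequencies are row-scaled to mean 0
and unit variance (ddof = 1; constant rows centered and flagged, not
divided) and populations are clustered by Ward linkage on Euclidean
distances (scipy), emitted as a merge table and a Newick string with branch
lengths from merge-height differences. A brute-force Lance–Williams
implementation serves as the oracle in tests.

## Numerical and degenerate-input choices

- One coordinate convention internally (1-based closed); BED converts at
  the boundary only.
- HWE is computed per population label; a probe failing in any population
  is excluded. Monomorphic probes return p = 1. The χ² form (not the exact
  test) matches common GWAS-QC practice and is deterministic.
- Sex inference: female if ≥ 10% of X BAF lies in (0.25, 0.75), male if
  < 2%, unknown below 50 X probes or in between; unknown never fails a
  sample. Thresholds are not from any cohort protocol — they cleanly
  separate simulated XX/XY.
- Zero-length inputs: empty call sets produce empty catalogs and zeroed
  summaries; empty concordance denominators report "undefined" rather
  than 0.
- All stochastic stages accept a single seed; per-sample and per-window
  generators derive from it deterministically (stable across subsetting),
  so identical config + seed gives byte-identical outputs.

## Known limitations

- The HMM aggregates cn ≥ 3 into one duplication state; no 5/6-state
  variant, GC-wave correction, trio calling, or confidence re-estimation.
- CBS omits the canonical pruning/undo steps; breakpoints on very gradual
  trends may over-segment.
- Recovery and false-positive guarantees are demonstrated under the
  generator's noise model only (see above for what it omits).
- The per-segment score is an emission-margin approximation, not a full
  likelihood-ratio against the decoded path.
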