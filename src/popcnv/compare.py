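"""Cross-population CNV frequency comparison.

Per-locus carrier frequencies are compared between a reference population
and each other population with a label-permutation test on the absolute
frequency difference (implemented by hypergeometric draws of the group-1
carrier count, which is exactly equivalent to shuffling population labels
over the pooled carrier vector).  Empirical p-values use the (b+1)/(R+1)
estimator, so the attainable floor at R permutations is 1/(R+1); the
significance flag fires at p < 2e-4 or at the floor itself.

Downstream: selection of the most differentiated gene loci per population
pair, row scaling of the frequency matrix, and Ward/Euclidean hierarchical
clustering of populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

SIGNIFICANCE_P = 0.0002


@dataclass
class AssociationResult:
    carriers_1: int
    n_1: int
    carriers_2: int
    n_2: int
    statistic: float          # |f1 - f2|
    p_value: float            # empirical, (b+1)/(R+1)
    n_perm: int
    significant: bool

    @property
    def freq_1(self) -> float:
        return self.carriers_1 / self.n_1

    @property
    def freq_2(self) -> float:
        return self.carriers_2 / self.n_2


def permutation_association(
    carriers_1: int,
    n_1: int,
    carriers_2: int,
    n_2: int,
    n_perm: int = 5000,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> AssociationResult:
    """Permutation test of a carrier-frequency difference between two groups."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if not (0 <= carriers_1 <= n_1 and 0 <= carriers_2 <= n_2):
        raise ValueError("carrier counts must be within group totals")
    rng = rng or np.random.default_rng(seed)
    obs = abs(carriers_1 / n_1 - carriers_2 / n_2)
    total = carriers_1 + carriers_2
    k1 = rng.hypergeometric(total, n_1 + n_2 - total, n_1, size=n_perm)
    stat = np.abs(k1 / n_1 - (total - k1) / n_2)
    b = int(np.sum(stat >= obs - 1e-12))
    p = (b + 1) / (n_perm + 1)
    floor = 1.0 / (n_perm + 1)
    return AssociationResult(
        carriers_1, n_1, carriers_2, n_2, obs, p, n_perm,
        significant=(p < SIGNIFICANCE_P or p <= floor) and obs > 0,
    )


def associate_loci(
    carrier_table: pd.DataFrame,
    manifest: pd.DataFrame,
    ref_pop: str,
    n_perm: int = 5000,
    seed: int = 0,
) -> pd.DataFrame:
    """Reference-vs-each-population association over a locus carrier table.

    ``carrier_table`` has one row per locus with columns ``locus``,
    ``chrom``, ``pos`` and ``carriers_<POP>``.  Returns one row per (locus,
    other population) pair.
    """
    totals = manifest["population"].value_counts().to_dict()
    others = [p for p in sorted(totals) if p != ref_pop]
    ss = np.random.SeedSequence(seed)
    rngs = {p: np.random.default_rng(c) for p, c in zip(others, ss.spawn(len(others)))}
    rows = []
    for _, r in carrier_table.iterrows():
        for p in others:
            res = permutation_association(
                int(r[f"carriers_{ref_pop}"]), totals[ref_pop],
                int(r[f"carriers_{p}"]), totals[p],
                n_perm=n_perm, rng=rngs[p],
            )
            rows.append({
                "locus": r["locus"], "chrom": r["chrom"], "pos": r["pos"],
                "other_pop": p,
                "freq_ref": res.freq_1, "freq_other": res.freq_2,
                "diff": res.freq_1 - res.freq_2,
                "statistic": res.statistic, "p_value": res.p_value,
                "significant": res.significant,
            })
    return pd.DataFrame(rows)


def top_gene_selection(results: pd.DataFrame, k_each: int = 10) -> list[str]:
    """Most differentiated loci: per pair, the ``k_each`` largest positive and
    largest negative significant frequency differences, de-duplicated.

    Ties break by smaller p-value then genome order.  Returns locus names
    sorted by (chrom, pos).
    """
    chosen: dict[str, tuple] = {}
    for _pop, g in results.groupby("other_pop", sort=True):
        sig = g[g["significant"]]
        up = sig[sig["diff"] > 0].sort_values(
            ["diff", "p_value", "chrom", "pos"], ascending=[False, True, True, True]
        ).head(k_each)
        down = sig[sig["diff"] < 0].sort_values(
            ["diff", "p_value", "chrom", "pos"], ascending=[True, True, True, True]
        ).head(k_each)
        for _, r in pd.concat([up, down]).iterrows():
            chosen[r["locus"]] = (r["chrom"], r["pos"])
    return sorted(chosen, key=lambda k: (chosen[k][0], chosen[k][1]))


def scale_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Center each row at 0 and scale to unit variance (ddof=1).

    Constant rows are centered but not divided; the returned flag series
    marks them.  Requires at least two columns.
    """
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to scale")
    mean = matrix.mean(axis=1)
    sd = matrix.std(axis=1, ddof=1)
    constant = sd == 0
    centered = matrix.sub(mean, axis=0)
    scaled = centered.div(sd.where(~constant, 1.0), axis=0)
    return scaled, constant


@dataclass
class ClusterResult:
    linkage: np.ndarray          # scipy linkage matrix over populations
    labels: list[str]            # column order used as leaves
    newick: str


def _newick(node, labels) -> str:
    if node.is_leaf():
        return labels[node.id]
    dl = max(node.dist - node.left.dist, 0.0)
    dr = max(node.dist - node.right.dist, 0.0)
    return f"({_newick(node.left, labels)}:{dl:.6g},{_newick(node.right, labels)}:{dr:.6g})"


def hierarchical_cluster(scaled: pd.DataFrame) -> ClusterResult:
    """Ward-linkage clustering of populations on Euclidean distances.

    Columns are populations, rows scaled locus frequencies.  NaN entries are
    rejected with the offending locus named.
    """
    if scaled.shape[1] < 2:
        raise ValueError("need at least 2 populations")
    bad = scaled.index[scaled.isna().any(axis=1)]
    if len(bad):
        raise ValueError(f"NaN frequencies at locus {bad[0]!r}")
    x = scaled.to_numpy().T  # observations = populations
    z = linkage(x, method="ward", metric="euclidean")
    labels = list(scaled.columns)
    tree = to_tree(z)
    return ClusterResult(z, labels, _newick(tree, labels) + ";")


def cut_clusters(result: ClusterResult, k: int) -> dict[str, int]:
    """Flat cluster membership for the populations at k clusters."""
    from scipy.cluster.hierarchy import fcluster

    assign = fcluster(result.linkage, t=k, criterion="maxclust")
    return dict(zip(result.labels, (int(a) for a in assign)))


def homdel_proportion(total_freq: float, homdel_freq: float) -> float | None:
    """Share of carriers that are homozygous deletions, to 3 decimals.

    Undefined (None) when the total frequency is zero.
    """
    if total_freq == 0:
        return None
    return round(homdel_freq / total_freq, 3)


def homdel_bookkeeping(zygosity: pd.DataFrame, manifest: pd.DataFrame) -> pd.DataFrame:
    """Per-population deletion frequencies at a locus, split by zygosity.

    ``zygosity`` has one row per carrier: sample_id and zygosity
    (HOMDEL/HETDEL).  Returns total frequency, homozygous-deletion frequency
    and the homozygous proportion (3 decimals; missing when no carriers).
    """
    pop = dict(zip(manifest["sample_id"], manifest["population"]))
    totals = manifest["population"].value_counts().to_dict()
    z = zygosity.drop_duplicates("sample_id").assign(
        population=lambda d: d["sample_id"].map(pop)
    )
    rows = []
    for p in sorted(totals):
        g = z[z["population"] == p]
        tot = len(g) / totals[p]
        hom = (g["zygosity"] == "HOMDEL").sum() / totals[p]
        rows.append({
            "population": p,
            "total_frequency": round(tot, 3),
            "homdel_frequency": round(hom, 3),
            "homdel_proportion": homdel_proportion(round(tot, 3), round(hom, 3)),
        })
    return pd.DataFrame(rows)
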