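import numpy as np
import pandas as pd
import pytest

import popcnv as pc
from popcnv.simulate import demo_genes


@pytest.fixture(scope="session")
def small_dataset():
    """Three populations x 10 samples on the standard probe map."""
    return pc.simulate_dataset(
        populations=[("POPA", 10), ("POPB", 10), ("POPC", 10)], seed=11
    )


@pytest.fixture(scope="session")
def small_genes(small_dataset):
    return demo_genes(small_dataset.probe_map)


@pytest.fixture
def toy_calls():
    """Hand-sized call table used by interval-logic tests."""
    return pd.DataFrame([
        ("S1", "1", 100, 200, 1, 10, 1.0, "CONSENSUS"),
        ("S2", "1", 150, 300, 1, 12, 1.0, "CONSENSUS"),
        ("S3", "1", 400, 500, 3, 15, 1.0, "CONSENSUS"),
    ], columns=["sample_id", "chrom", "start", "end", "cn", "n_probes", "score", "source"])


def naive_max_t(x, min_width=1):
    """Brute-force double loop over every circular split (independent oracle)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    best = (0.0, 0, n - 1)
    for i in range(n):
        for j in range(i + 1, n):
            n1 = j - i
            if n1 < min_width or n - n1 < min_width:
                continue
            arc = x[i + 1:j + 1]
            comp = np.concatenate([x[:i + 1], x[j + 1:]])
            ssw = ((arc - arc.mean()) ** 2).sum() + ((comp - comp.mean()) ** 2).sum()
            var = ssw / (n - 2)
            d = abs(arc.mean() - comp.mean())
            if var > 0:
                t = d / np.sqrt(var * (1 / len(arc) + 1 / len(comp)))
            else:
                t = 0.0 if d == 0 else np.inf
            if t > best[0]:
                best = (t, i, j)
    return best


def brute_force_ward(x):
    """Naive Ward agglomeration via the Lance-Williams recurrence on squared
    distances (independent oracle).  Returns the merge heights in order.
    """
    x = np.asarray(x, dtype=float)
    n = len(x)
    sizes = {i: 1 for i in range(n)}
    d2 = {(i, j): float(((x[i] - x[j]) ** 2).sum())
          for i in range(n) for j in range(i + 1, n)}

    def get(i, j):
        return d2[(min(i, j), max(i, j))]

    heights = []
    active = set(range(n))
    next_id = n
    while len(active) > 1:
        a, b = min(((i, j) for i in active for j in active if i < j),
                   key=lambda p: get(*p))
        h2 = get(a, b)
        heights.append(float(np.sqrt(h2)))
        na, nb = sizes[a], sizes[b]
        active -= {a, b}
        for k in active:
            nk = sizes[k]
            d2[(min(k, next_id), max(k, next_id))] = (
                (na + nk) * get(a, k) + (nb + nk) * get(b, k) - nk * h2
            ) / (na + nb + nk)
        sizes[next_id] = na + nb
        active.add(next_id)
        next_id += 1
    return heights
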