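"""Brute-force oracles, independent of the library code they check.

Each oracle recomputes a quantity by exhaustive enumeration or direct
formula evaluation so library results can be verified on small instances.
"""

from __future__ import annotations

import itertools
from math import comb, inf

import numpy as np

PAIR_ENERGY = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}
MIN_LOOP = 3


def bh_stepup(p):
    """Hand-executed Benjamini-Hochberg step-up adjustment."""
    p = list(p)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [0.0] * m
    prev = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        val = min(prev, p[i] * m / rank)
        adj[i] = val
        prev = val
    return adj


def fisher_two_sided(table):
    """Two-sided Fisher p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        if k < 0 or k > r1 or c1 - k < 0 or c1 - k > r2:
            return 0.0
        return comb(r1, k) * comb(r2, c1 - k) / comb(n, c1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(0, c1 + 1) if prob(k) <= p_obs * (1 + 1e-9))


def wilcoxon_exact(x, y):
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    nx, ny = len(x), len(y)
    pooled = sorted(list(x) + list(y))
    ranks = {v: i + 1 for i, v in enumerate(pooled)}  # no ties assumed
    obs_r = sum(ranks[v] for v in x)
    mean_r = nx * (nx + ny + 1) / 2
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, nx + ny + 1), nx):
        total += 1
        if abs(sum(combo) - mean_r) >= abs(obs_r - mean_r) - 1e-9:
            count += 1
    return count / total


def ks_statistic(x, y):
    """D = sup |ECDF_x - ECDF_y| by direct scan over pooled values."""
    pooled = sorted(set(list(x) + list(y)))
    d = 0.0
    for v in pooled:
        fx = sum(1 for t in x if t <= v) / len(x)
        fy = sum(1 for t in y if t <= v) / len(y)
        d = max(d, abs(fx - fy))
    return d


def spearman_rho(x, y):
    """Rank-then-Pearson with midranks."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / np.sqrt(np.sum(rx**2) * np.sum(ry**2)))


def silhouette_direct(X, labels):
    """Per-point silhouette by direct formula evaluation."""
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    n = len(labels)
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    out = np.zeros(n)
    if len(set(labels)) < 2:
        return out
    for i in range(n):
        own = labels == labels[i]
        if own.sum() == 1:
            out[i] = 0.0
            continue
        a = D[i][own].sum() / (own.sum() - 1)
        b = min(D[i][labels == c].mean() for c in set(labels) if c != labels[i])
        out[i] = (b - a) / max(a, b) if max(a, b) > 0 else 0.0
    return out


def pam_exhaustive(X, k):
    """Globally optimal medoid set by exhaustive enumeration."""
    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    best_cost, best = inf, None
    for medoids in itertools.combinations(range(n), k):
        cost = D[:, medoids].min(axis=1).sum()
        if cost < best_cost:
            best_cost, best = cost, medoids
    return best_cost, best


def mfe_enumerate(seq):
    """Minimum energy over all nested structures by explicit recursion.

    Pairs the *first* position (or leaves it unpaired), unlike the
    library's last-position DP, and enumerates rather than memoises.
    """
    s = seq.upper().replace("T", "U")

    def best(i, j):  # over s[i:j]
        if j - i < MIN_LOOP + 2:
            return 0.0
        e = best(i + 1, j)  # i unpaired
        for k in range(i + MIN_LOOP + 1, j):
            pe = PAIR_ENERGY.get((s[i], s[k]))
            if pe is None:
                continue
            e = min(e, pe + best(i + 1, k) + best(k + 1, j))
        return e

    return best(0, len(s))


def translate_first_stop(seq):
    """Codon index of the first stop in frame 0, or None (direct scan)."""
    from Bio.Seq import Seq

    prot = str(Seq(seq[: len(seq) - len(seq) % 3]).translate())
    idx = prot.find("*")
    return None if idx < 0 else idx


# ----------------------------------------------------------------------
# oracle-equivalence runner (shared by the test suite and the acceptance
# script): fraction of random small instances on which the library agrees
# with the enumeration oracle, per operation


def run_oracle_suite(seed: int, n_instances: int = 200) -> dict:
    import pandas as pd

    from dparkit import profile_clustering as pc
    from dparkit import regulatory_features as rf
    from dparkit import stats_core as sc
    from dparkit.intron_retention import ptc_scan

    rng = np.random.default_rng(seed)
    agree = {}

    hits = 0
    for _ in range(n_instances):
        p = rng.uniform(size=rng.integers(1, 40))
        hits += np.allclose(sc.bh_fdr(p), bh_stepup(p), atol=1e-12)
    agree["bh_fdr"] = hits / n_instances

    hits = total = 0
    while total < n_instances:
        a, b, c, d = rng.integers(0, 9, size=4)
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            continue
        total += 1
        table = [[a, b], [c, d]]
        hits += abs(
            sc.fisher_exact_2x2(table).p_value - fisher_two_sided(table)
        ) < 1e-9
    agree["fisher_exact"] = hits / n_instances

    hits = 0
    for _ in range(n_instances):
        nx, ny = rng.integers(2, 7, size=2)
        pooled = rng.permutation(np.arange(1.0, nx + ny + 1))
        x, y = list(pooled[:nx]), list(pooled[nx:])
        hits += abs(
            sc.wilcoxon_rank_sum(x, y).p_value - wilcoxon_exact(x, y)
        ) < 1e-9
    agree["wilcoxon"] = hits / n_instances

    hits = 0
    for _ in range(n_instances):
        x = rng.normal(size=rng.integers(3, 15))
        y = rng.normal(size=rng.integers(3, 15))
        hits += abs(sc.ks_two_sample(x, y).statistic - ks_statistic(x, y)) < 1e-12
    agree["ks"] = hits / n_instances

    hits = 0
    for _ in range(n_instances):
        n = int(rng.integers(4, 12))
        X = rng.normal(size=(n, 3))
        labels = rng.integers(0, 3, size=n)
        s, _ = pc.silhouette_widths(X, labels)
        hits += np.allclose(s, silhouette_direct(X, labels), atol=1e-9)
    agree["silhouette"] = hits / n_instances

    hits = 0
    for _ in range(n_instances):
        n = int(rng.integers(4, 9))
        k = int(rng.integers(1, 4))
        X = rng.normal(size=(n, 3))
        medoids, _ = pc.pam_cluster(X, k)
        D = np.sqrt(((X[:, None] - X[None, :]) ** 2).sum(-1))
        cost = D[:, medoids].min(axis=1).sum()
        best_cost, _ = pam_exhaustive(X, k)
        hits += abs(cost - best_cost) < 1e-9
    agree["pam"] = hits / n_instances

    bases = np.array(list("ACGU"))
    hits = 0
    for _ in range(n_instances):
        seq = "".join(rng.choice(bases, size=int(rng.integers(1, 13))))
        hits += abs(rf.mfe_proxy(seq) - mfe_enumerate(seq)) < 1e-9
    agree["mfe"] = hits / n_instances

    dna = np.array(list("ACGT"))
    hits = total = 0
    while total < n_instances:
        e1 = "ATG" + "".join(rng.choice(dna, size=3 * int(rng.integers(2, 8))))
        e2 = "".join(rng.choice(dna, size=3 * int(rng.integers(2, 8)))) + "TGA"
        intron = "".join(rng.choice(dna, size=int(rng.integers(4, 15))))
        genome = e1 + intron + e2
        spliced_stop = translate_first_stop(e1 + e2)
        if spliced_stop is None:
            continue
        total += 1
        model = {
            "cds_exons": [(0, len(e1)), (len(e1) + len(intron), len(genome))],
            "strand": "+",
        }
        out = ptc_scan(model, (len(e1), len(e1) + len(intron)), genome)
        stop = translate_first_stop(e1 + intron + e2)
        expected_last = spliced_stop + (len(intron) // 3 if len(intron) % 3 == 0 else 0)
        ok = (
            out["first_stop_codon"] == stop
            and out["has_ptc"] == (stop is not None and stop < expected_last)
            and out["frame_preserved"] == (len(intron) % 3 == 0)
        )
        hits += ok
    agree["ptc_scan"] = hits / n_instances
    return agree
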