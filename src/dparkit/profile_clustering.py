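"""Expression-profile clustering with PAM and silhouette-based k selection.

Genes that become translationally regulated only under DR are clustered on
their mean-centred log2-CPM profiles over the four experimental groups.
Clustering uses Partitioning Around Medoids (deterministic BUILD seeding
followed by best-improvement SWAP to a local optimum, Euclidean
dissimilarity).  The number of clusters is chosen by running PAM for
k = 2..k_max and keeping the largest k for which every cluster's mean
silhouette width is at least the "substantial structure" cutoff of 0.25;
if no k qualifies the data are treated as a single cluster.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = [
    "center_profiles",
    "pam_cluster",
    "silhouette_widths",
    "select_k",
    "pca_variance",
]

SILHOUETTE_CUTOFF = 0.25


def center_profiles(group_means: pd.DataFrame) -> pd.DataFrame:
    """Mean-centre each gene's 4-group profile (rows sum to zero)."""
    return group_means.sub(group_means.mean(axis=1), axis=0)


def _dist_matrix(X: np.ndarray) -> np.ndarray:
    sq = np.sum(X**2, axis=1)
    d2 = sq[:, None] + sq[None, :] - 2.0 * X @ X.T
    np.fill_diagonal(d2, 0.0)
    return np.sqrt(np.maximum(d2, 0.0))


def pam_cluster(X, k: int, exact_small: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Partitioning Around Medoids; returns (medoid indices, labels).

    BUILD greedily seeds medoids minimising total dissimilarity; SWAP
    applies the best medoid/non-medoid exchange until no exchange lowers
    the objective.  Deterministic given the input row order.  Instances
    small enough to enumerate (<= 5000 candidate medoid sets) are solved
    exactly, since the swap neighbourhood can have local optima even at
    tiny n.
    """
    from math import comb

    X = np.asarray(X, dtype=float)
    n = X.shape[0]
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    D = _dist_matrix(X)

    if exact_small and comb(n, k) <= 5000:
        import itertools

        best_cost, best = np.inf, None
        for med in itertools.combinations(range(n), k):
            cost = D[:, med].min(axis=1).sum()
            if cost < best_cost - 1e-12:
                best_cost, best = cost, med
        medoids = np.array(best)
        return medoids, np.argmin(D[:, medoids], axis=1)

    # BUILD
    medoids = [int(np.argmin(D.sum(axis=1)))]
    d_near = D[:, medoids[0]].copy()
    while len(medoids) < k:
        gain = np.sum(np.maximum(d_near[:, None] - D, 0.0), axis=0)
        gain[medoids] = -np.inf
        best = int(np.argmax(gain))
        medoids.append(best)
        d_near = np.minimum(d_near, D[:, best])

    # SWAP (best improvement)
    medoids = np.array(medoids)
    while True:
        cost = np.sum(np.min(D[:, medoids], axis=1))
        best_cost, best_swap = cost, None
        for mi, m in enumerate(medoids):
            others = np.delete(medoids, mi)
            if others.size:
                d_rest = np.min(D[:, others], axis=1)
            else:
                d_rest = np.full(n, np.inf)
            # candidate costs for replacing m by every point h at once
            cand = np.minimum(d_rest[:, None], D).sum(axis=0)
            cand[medoids] = np.inf
            h = int(np.argmin(cand))
            if cand[h] < best_cost - 1e-12:
                best_cost, best_swap = cand[h], (mi, h)
        if best_swap is None:
            break
        medoids[best_swap[0]] = best_swap[1]

    labels = np.argmin(D[:, medoids], axis=1)
    return medoids, labels


def silhouette_widths(X, labels) -> tuple[np.ndarray, pd.Series]:
    """Per-point silhouette widths and per-cluster means.

    s(i) = (b - a) / max(a, b) with a the mean distance to the point's own
    cluster (excluding itself) and b the smallest mean distance to another
    cluster.  Points in singleton clusters get s = 0; with a single
    cluster all widths are 0.
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if labels.shape[0] != X.shape[0]:
        raise ValueError("labels and rows mismatch")
    D = _dist_matrix(X)
    uniq = np.unique(labels)
    n = X.shape[0]
    s = np.zeros(n)
    if uniq.size > 1:
        sums = np.stack([D[:, labels == c].sum(axis=1) for c in uniq], axis=1)
        sizes = np.array([(labels == c).sum() for c in uniq])
        own_idx = np.searchsorted(uniq, labels)
        own_size = sizes[own_idx]
        with np.errstate(invalid="ignore", divide="ignore"):
            a = sums[np.arange(n), own_idx] / np.maximum(own_size - 1, 1)
            mean_to = sums / sizes[None, :]
            mean_to[np.arange(n), own_idx] = np.inf
            b = mean_to.min(axis=1)
            denom = np.maximum(a, b)
            s = np.where((own_size > 1) & (denom > 0), (b - a) / denom, 0.0)
    means = pd.Series({c: s[labels == c].mean() for c in uniq})
    return s, means


def select_k(
    X, k_max: int, cutoff: float = SILHOUETTE_CUTOFF
) -> tuple[int, pd.DataFrame]:
    """Largest k in 2..k_max whose clusters all have mean silhouette >= cutoff.

    Returns (chosen k, diagnostics with per-k minimum cluster-mean
    silhouette); k = 1 if no candidate qualifies.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    X = np.asarray(X, dtype=float)
    diag = []
    chosen = 1
    for k in range(2, min(k_max, X.shape[0]) + 1):
        _, labels = pam_cluster(X, k)
        _, cluster_means = silhouette_widths(X, labels)
        worst = float(cluster_means.min())
        ok = worst >= cutoff
        diag.append({"k": k, "min_cluster_silhouette": worst, "qualifies": ok})
        if ok:
            chosen = k
    return chosen, pd.DataFrame(diag)


def pca_variance(X) -> np.ndarray:
    """Variance fraction per principal component of the column covariance."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 columns")
    Xc = X - X.mean(axis=0, keepdims=True)
    if np.allclose(Xc, 0):
        raise ValueError("constant matrix has no principal components")
    sv = np.linalg.svd(Xc, compute_uv=False)
    var = sv**2
    return var / var.sum()
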