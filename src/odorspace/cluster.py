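"""Partitioning of 2-D embeddings: k-means, Ward AHC and cluster-count selection.

Each embedding is partitioned twice — by Lloyd's k-means (best of several
seeded restarts) and by agglomerative hierarchical clustering under Ward's
minimum-variance criterion on Euclidean distances (the squared-distance
Lance-Williams update, i.e. the "ward.D2" dialect).  The number of clusters
is either fixed or selected from the AHC tree with an elbow curve and the
Kelley penalty.  Cluster ids are 1-based and ordered by decreasing size.

The Kelley penalty at a cut into k clusters is the normalized average
within-cluster spread plus k itself; the spread of a cluster is the mean of
its pairwise distances (singletons contribute nothing).  The average spreads
are rescaled over the evaluated range of k so they span the same interval as
the cluster-count term — over the full range k = 2..n-1 this is the original
(n-2)*(AvSp-min)/(max-min) + 1 normalization onto [1, n-1] — and the
penalty-minimizing k is selected, ties going to the smaller k.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import pdist, squareform

from .embed import Embedding2D

_MAX_LLOYD_ITER = 300


@dataclass
class ClusterConfig:
    k: int | str = "auto"
    k_max: int = 20
    kmeans_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.k, str):
            if self.k != "auto":
                raise ValueError("k must be an integer or 'auto'")
        elif self.k < 2:
            raise ValueError("explicit k must be >= 2")
        if self.k_max < 2 or self.kmeans_restarts < 1:
            raise ValueError("k_max >= 2 and kmeans_restarts >= 1 required")


@dataclass
class Partition:
    compound_ids: list[str]
    labels: np.ndarray                  # 1..k
    method: str                        # reduction that produced the coords
    clustering: str                    # "kmeans" | "ahc"
    k: int
    merge_order: list[tuple[tuple[int, ...], tuple[int, ...], float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.labels) != len(self.compound_ids):
            raise ValueError("labels must align with compound_ids")
        present = set(np.unique(self.labels))
        if present != set(range(1, self.k + 1)):
            raise ValueError("labels must be 1..k with every cluster nonempty")

    def members(self, cluster: int) -> list[str]:
        return [cid for cid, lab in zip(self.compound_ids, self.labels) if lab == cluster]

    def sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class IntersectionMatrix:
    counts: np.ndarray                  # k1 x k2
    row_clusters: list[int]
    col_clusters: list[int]


def _relabel_by_size(raw: np.ndarray) -> tuple[np.ndarray, dict[int, int]]:
    """Map raw labels to 1..k ordered by decreasing cluster size (ties by
    the raw label) and return the mapping used."""
    vals, counts = np.unique(raw, return_counts=True)
    order = sorted(range(len(vals)), key=lambda i: (-counts[i], vals[i]))
    mapping = {int(vals[i]): rank + 1 for rank, i in enumerate(order)}
    return np.array([mapping[int(v)] for v in raw]), mapping


def _lloyd(X: np.ndarray, k: int, rng: np.random.Generator) -> tuple[np.ndarray, float]:
    """One Lloyd run from a random k-distinct-points init.

    Point assignment breaks centroid ties toward the lower cluster index
    (argmin convention); the within-cluster sum of squares is checked to be
    non-increasing across iterations.
    """
    n = X.shape[0]
    centers = X[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    last_wss = np.inf
    for _ in range(_MAX_LLOYD_ITER):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        reseeded = False
        for c in range(k):                      # re-seed emptied clusters
            if not np.any(new_labels == c):
                far = int(d2[np.arange(n), new_labels].argmax())
                new_labels[far] = c
                reseeded = True
        wss = float(d2[np.arange(n), new_labels].sum())
        assert reseeded or wss <= last_wss + 1e-8, "Lloyd WSS increased"
        last_wss = wss
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = X[labels == c].mean(axis=0)
    final_wss = float(((X - centers[labels]) ** 2).sum())
    return labels, final_wss


def kmeans_partition(embedding: Embedding2D, config: ClusterConfig, k: int | None = None) -> Partition:
    """Best-of-restarts Lloyd k-means on the 2-D coordinates."""
    X = embedding.coords
    n = X.shape[0]
    k = k if k is not None else config.k
    if k == "auto":
        k = select_k(embedding, config)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    best_labels, best_wss = None, np.inf
    for r in range(config.kmeans_restarts):
        labels, wss = _lloyd(X, k, np.random.default_rng(config.seed + r))
        if wss < best_wss - 1e-12:
            best_labels, best_wss = labels, wss
    labels, _ = _relabel_by_size(best_labels + 1)
    return Partition(list(embedding.compound_ids), labels,
                     embedding.provenance.method, "kmeans", int(labels.max()))


def ward_linkage(X: np.ndarray) -> np.ndarray:
    """Ward minimum-variance linkage on Euclidean distances (ward.D2)."""
    return linkage(X, method="ward")


def _merge_order(Z: np.ndarray, raw_labels: np.ndarray, mapping: dict[int, int], k: int) -> list:
    """The last k-1 merges expressed over the final (size-ordered) labels."""
    n = Z.shape[0] + 1
    node_sets: dict[int, frozenset[int]] = {
        i: frozenset([mapping[int(raw_labels[i])]]) for i in range(n)
    }
    merges = []
    for j, (a, b, height, _) in enumerate(Z):
        sa, sb = node_sets[int(a)], node_sets[int(b)]
        node_sets[n + j] = sa | sb
        if j >= n - 1 - (k - 1):  # merges above the k-cluster cut
            merges.append((tuple(sorted(sa)), tuple(sorted(sb)), float(height)))
    return merges


def ahc_partition(embedding: Embedding2D, config: ClusterConfig, k: int | None = None) -> Partition:
    """Ward AHC of the 2-D coordinates, cut at k, with merge-order metadata."""
    X = embedding.coords
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 points")
    k = k if k is not None else config.k
    if k == "auto":
        k = select_k(embedding, config)
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    Z = ward_linkage(X)
    raw = fcluster(Z, t=k, criterion="maxclust")
    labels, mapping = _relabel_by_size(raw)
    k_eff = int(labels.max())
    return Partition(list(embedding.compound_ids), labels,
                     embedding.provenance.method, "ahc", k_eff,
                     merge_order=_merge_order(Z, raw, mapping, k_eff))


def _wss(X: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        pts = X[labels == c]
        total += float(((pts - pts.mean(axis=0)) ** 2).sum())
    return total


def elbow_curve(embedding: Embedding2D, clustering: str, k_max: int,
                config: ClusterConfig | None = None) -> list[tuple[int, float]]:
    """(k, within-cluster sum of squares) for k = 1..k_max."""
    config = config or ClusterConfig()
    X = embedding.coords
    if k_max >= X.shape[0]:
        raise ValueError("k_max must be smaller than n")
    curve = [(1, _wss(X, np.zeros(X.shape[0], dtype=int)))]
    Z = ward_linkage(X) if clustering == "ahc" else None
    for k in range(2, k_max + 1):
        if clustering == "ahc":
            labels = fcluster(Z, t=k, criterion="maxclust")
        elif clustering == "kmeans":
            labels = kmeans_partition(embedding, config, k=k).labels
        else:
            raise ValueError("clustering must be 'kmeans' or 'ahc'")
        curve.append((k, _wss(X, labels)))
    return curve


def kelley_penalty(Z: np.ndarray, D: np.ndarray,
                   k_range: Sequence[int] | None = None,
                   k_max: int = 20) -> tuple[list[tuple[int, float]], int]:
    """Kelley penalty curve over cuts of an AHC tree and the selected k*.

    ``Z`` is the linkage; ``D`` the square distance matrix of the clustered
    points.  Cuts where every cluster is a singleton are skipped; if every
    average spread is identical the normalized spread is 1 by convention.
    """
    n = D.shape[0]
    ks = list(k_range) if k_range is not None else list(range(2, min(k_max, n - 1) + 1))
    if not ks or min(ks) < 2 or max(ks) > n - 1:
        raise ValueError("k_range must lie within [2, n-1]")
    avsp, kept = [], []
    for k in ks:
        labels = fcluster(Z, t=k, criterion="maxclust")
        spreads = []
        for c in np.unique(labels):
            idx = np.flatnonzero(labels == c)
            if idx.size >= 2:
                sub = D[np.ix_(idx, idx)]
                spreads.append(float(sub[np.triu_indices(idx.size, 1)].mean()))
        if spreads:
            kept.append(k)
            avsp.append(float(np.mean(spreads)))
    av = np.array(avsp)
    span = av.max() - av.min()
    if span == 0:
        norm = np.ones_like(av)
    else:
        norm = len(kept) * (av - av.min()) / span + 1.0
    penalties = norm + np.array(kept, dtype=float)
    k_star = kept[int(np.argmin(penalties))]
    return list(zip(kept, penalties.tolist())), k_star


def select_k(embedding: Embedding2D, config: ClusterConfig) -> int:
    """Cluster-count selection from the AHC tree via the Kelley penalty."""
    X = embedding.coords
    Z = ward_linkage(X)
    D = squareform(pdist(X))
    _, k_star = kelley_penalty(Z, D, k_max=min(config.k_max, X.shape[0] - 1))
    return k_star


def intersection_matrix(p_km: Partition, p_ahc: Partition) -> IntersectionMatrix:
    """Cross-tabulation: counts[x, y] = molecules in k-means cluster x and
    AHC cluster y.  Row/column marginals equal the cluster sizes."""
    if p_km.compound_ids != p_ahc.compound_ids:
        raise ValueError("partitions must cover the same compounds in the same order")
    rows = sorted(set(p_km.labels.tolist()))
    cols = sorted(set(p_ahc.labels.tolist()))
    counts = np.zeros((len(rows), len(cols)), dtype=int)
    ri = {c: i for i, c in enumerate(rows)}
    ci = {c: i for i, c in enumerate(cols)}
    for a, b in zip(p_km.labels, p_ahc.labels):
        counts[ri[int(a)], ci[int(b)]] += 1
    return IntersectionMatrix(counts, rows, cols)


def switched_count(inter: IntersectionMatrix) -> tuple[dict[int, int], int]:
    """Maximum-overlap one-to-one cluster correspondence and the number of
    molecules falling outside the matched cells.  Invariant to relabeling."""
    counts = inter.counts
    r, c = linear_sum_assignment(-counts)
    matching = {inter.row_clusters[i]: inter.col_clusters[j] for i, j in zip(r, c)}
    n_switched = int(counts.sum() - counts[r, c].sum())
    return matching, n_switched
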