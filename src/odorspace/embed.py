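"""2-D embeddings of binary fingerprint matrices.

Four reductions are supported on the same n x n_bits binary input: PCA (top-2
components of the column-centered 0/1 matrix), classical Torgerson MDS on the
pairwise Jaccard distance matrix, t-SNE on the same precomputed distances,
and UMAP with the Jaccard metric (defaults n_neighbors=15, min_dist=0).  The
Jaccard/Tanimoto distance — one minus the fraction of shared on-bits — is the
default metric throughout; Dice and cosine are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import pdist, squareform

METHODS = ("pca", "mds", "tsne", "umap")
METRICS = ("jaccard", "dice", "cosine")


@dataclass
class ReductionConfig:
    method: str = "umap"
    n_components: int = 2
    metric: str = "jaccard"
    n_neighbors: int = 15
    min_dist: float = 0.0
    perplexity: float = 30.0
    seed: int = 42

    def __post_init__(self) -> None:
        self.method = self.method.lower()
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")
        if self.n_components != 2:
            raise ValueError("this pipeline embeds to exactly 2 components")
        if self.n_neighbors < 2 or self.min_dist < 0:
            raise ValueError("n_neighbors >= 2 and min_dist >= 0 required")


@dataclass
class Embedding2D:
    compound_ids: list[str]
    coords: np.ndarray                   # n x 2
    provenance: ReductionConfig = field(default_factory=ReductionConfig)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.compound_ids), 2):
            raise ValueError("coords must be n x 2 aligned with compound_ids")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


def jaccard_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - |a AND b| / |a OR b| on binary vectors; 0 if both are all-zero."""
    a = np.asarray(a).astype(bool)
    b = np.asarray(b).astype(bool)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return 1.0 - np.count_nonzero(a & b) / union


def pairwise_distances(bits: np.ndarray, metric: str = "jaccard") -> np.ndarray:
    """Square pairwise distance matrix on binary rows."""
    _check_binary(bits, metric)
    X = bits.astype(bool) if metric in ("jaccard", "dice") else bits.astype(float)
    D = squareform(pdist(X, metric=metric))
    return np.nan_to_num(D, nan=0.0)  # all-zero pairs -> distance 0 by convention


def _check_binary(bits: np.ndarray, metric: str) -> None:
    if metric in ("jaccard", "dice") and not np.isin(np.unique(bits), (0, 1)).all():
        raise ValueError(f"{metric} metric requires a binary matrix")


def classical_mds(D: np.ndarray, n_components: int = 2) -> np.ndarray:
    """Torgerson scaling: eigendecomposition of the doubly-centered -D^2/2.

    Deterministic; axis signs are fixed so each column's largest-magnitude
    entry is positive.  Components with non-positive eigenvalues map to zero.
    """
    from scipy.linalg import eigh

    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.shape != (n, n):
        raise ValueError("D must be square")
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D ** 2) @ J
    vals, vecs = eigh(B, subset_by_index=(n - n_components, n - 1))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    coords = vecs * np.sqrt(np.clip(vals, 0.0, None))
    for j in range(coords.shape[1]):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] = -coords[:, j]
    return coords


def embed(bits: np.ndarray, config: ReductionConfig, compound_ids: list[str] | None = None) -> Embedding2D:
    """Embed binary fingerprint rows to 2-D with the configured method.

    Row order is preserved for every method; PCA/MDS are deterministic given
    the input, t-SNE and UMAP are deterministic given ``config.seed``.
    """
    bits = np.asarray(bits)
    n = bits.shape[0]
    if n < 3:
        raise ValueError("need at least 3 compounds to embed")
    if config.method in ("tsne", "umap") and n < config.n_neighbors + 1:
        raise ValueError("n must be at least n_neighbors + 1 for neighbor-based methods")
    if compound_ids is None:
        compound_ids = [str(i) for i in range(n)]

    if config.method == "pca":
        from sklearn.decomposition import PCA

        _check_binary(bits, config.metric)
        coords = PCA(n_components=2, svd_solver="full").fit_transform(bits.astype(float))
        # sign convention: largest-magnitude loading positive per axis
        for j in range(2):
            i = np.argmax(np.abs(coords[:, j]))
            if coords[i, j] < 0:
                coords[:, j] = -coords[:, j]
    elif config.method == "mds":
        coords = classical_mds(pairwise_distances(bits, config.metric))
    elif config.method == "tsne":
        from sklearn.manifold import TSNE

        D = pairwise_distances(bits, config.metric)
        perplexity = min(config.perplexity, (n - 1) / 3.0)
        coords = TSNE(n_components=2, metric="precomputed", init="random",
                      perplexity=perplexity, random_state=config.seed).fit_transform(D)
    else:  # umap
        import umap

        _check_binary(bits, config.metric)
        reducer = umap.UMAP(n_components=2, metric=config.metric,
                            n_neighbors=config.n_neighbors, min_dist=config.min_dist,
                            random_state=config.seed)
        coords = reducer.fit_transform(bits.astype(np.float32))

    return Embedding2D(list(compound_ids), np.asarray(coords, dtype=float),
                       provenance=replace(config))


def write_embedding(emb: Embedding2D, csv_path, json_path=None) -> None:
    """Coordinates CSV (compound_id, x, y) plus a provenance JSON sidecar."""
    import csv as _csv
    import dataclasses
    import json

    with open(csv_path, "w", newline="") as fh:
        writer = _csv.writer(fh)
        writer.writerow(["compound_id", "x", "y"])
        for cid, (x, y) in zip(emb.compound_ids, emb.coords):
            writer.writerow([cid, f"{x:.6g}", f"{y:.6g}"])
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(dataclasses.asdict(emb.provenance), fh, indent=2)
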