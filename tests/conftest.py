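import itertools

import numpy as np
import pytest

from odorspace.records import CompoundRecord


@pytest.fixture
def hand_records():
    """Ten compounds with hand-tallied odor notes (no SMILES needed)."""
    notes = [
        {"fruity", "green"},
        {"fruity", "sweet"},
        {"fruity"},
        {"green", "woody"},
        {"woody", "spicy"},
        {"woody"},
        {"sulfurous"},
        {"sulfurous", "citrus"},
        {"odorless"},
        {"fruity", "woody"},
    ]
    return [CompoundRecord(f"M{i}", "C", ns) for i, ns in enumerate(notes)]


@pytest.fixture
def blob_embedding():
    """Four tight, far-separated 2-D blobs (30 points each) as an Embedding2D."""
    from odorspace.embed import Embedding2D, ReductionConfig

    rng = np.random.default_rng(11)
    centers = np.array([[0.0, 0.0], [40.0, 0.0], [0.0, 40.0], [40.0, 40.0]])
    pts = np.vstack([c + rng.normal(scale=0.8, size=(30, 2)) for c in centers])
    truth = np.repeat(np.arange(4), 30)
    ids = [f"P{i}" for i in range(len(pts))]
    emb = Embedding2D(ids, pts, provenance=ReductionConfig(method="pca"))
    return emb, truth


# --------------------------------------------------------------------------
# Independent oracles (never call the implementation under test)

def exhaustive_kmeans_wss(X: np.ndarray, k: int = 2) -> float:
    """Minimum within-cluster sum of squares over every k-partition."""
    n = len(X)

    def wss(groups):
        total = 0.0
        for g in groups:
            pts = X[list(g)]
            total += float(((pts - pts.mean(axis=0)) ** 2).sum())
        return total

    best = np.inf
    if k == 2:
        # point n-1 pinned to side a; enumerate the other points' sides
        for mask in range(2 ** (n - 1) - 1):
            a = [n - 1] + [i for i in range(n - 1) if (mask >> i) & 1]
            b = [i for i in range(n - 1) if not (mask >> i) & 1]
            best = min(best, wss([a, b]))
        return best
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) != k:
            continue
        groups = [[i for i in range(n) if labels[i] == c] for c in range(k)]
        best = min(best, wss(groups))
    return best


def lance_williams_ward(X: np.ndarray):
    """Naive O(n^3) Ward agglomeration under the squared-distance
    (ward.D2) Lance-Williams update; returns [(leaves_a, leaves_b, height)]."""
    n = len(X)
    leaves = {i: frozenset([i]) for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = float(np.linalg.norm(X[i] - X[j]))

    def d(a, b):
        return dist[(a, b) if a < b else (b, a)]

    active = set(range(n))
    merges = []
    nxt = n
    while len(active) > 1:
        a, b = min(((i, j) for i in active for j in active if i < j), key=lambda p: d(*p))
        h = d(a, b)
        merges.append((leaves[a], leaves[b], h))
        na, nb = size[a], size[b]
        for c in active - {a, b}:
            nc = size[c]
            val = np.sqrt(((na + nc) * d(a, c) ** 2 + (nb + nc) * d(b, c) ** 2
                           - nc * h ** 2) / (na + nb + nc))
            dist[(min(nxt, c), max(nxt, c))] = float(val)
        leaves[nxt] = leaves[a] | leaves[b]
        size[nxt] = na + nb
        active -= {a, b}
        active.add(nxt)
        nxt += 1
    return merges


def scipy_linkage_merges(Z: np.ndarray):
    """scipy linkage rows as [(leaves_a, leaves_b, height)] for comparison."""
    n = Z.shape[0] + 1
    leaves = {i: frozenset([i]) for i in range(n)}
    merges = []
    for j, (a, b, h, _) in enumerate(Z):
        sa, sb = leaves[int(a)], leaves[int(b)]
        merges.append((sa, sb, float(h)))
        leaves[n + j] = sa | sb
    return merges


def torgerson_oracle(D: np.ndarray, ncomp: int = 2) -> np.ndarray:
    """Brute-force double-centering + full eigendecomposition."""
    n = D.shape[0]
    B = np.empty((n, n))
    row = (D ** 2).mean(axis=1)
    grand = (D ** 2).mean()
    for i in range(n):
        for j in range(n):
            B[i, j] = -0.5 * (D[i, j] ** 2 - row[i] - row[j] + grand)
    vals, vecs = np.linalg.eigh(B)
    idx = np.argsort(vals)[::-1][:ncomp]
    return vecs[:, idx] * np.sqrt(np.clip(vals[idx], 0, None))
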