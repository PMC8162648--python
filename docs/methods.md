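# Methods

## Overview

`odorspace` implements a comparative structure–odor analysis: binary
molecular fingerprints are embedded into 2-D chemical maps by four
reduction techniques, each map is partitioned by two clustering methods,
and the resulting clusters are characterized by odor-note enrichment
statistics and functional-group frequencies. The package's claims are
exercised on synthetic data with planted structure; what that does and does
not show about real odorant collections is discussed at the end.

## Input model

A dataset is a list of compounds, each with a unique id, a SMILES string
and a set of odor notes. Notes are normalized (lower-cased, trimmed,
internal whitespace collapsed) and the descriptor "odorless" is kept as an
ordinary vocabulary entry: a compound is odorless iff its note set is
exactly `{"odorless"}`. Notes with fewer than `min_occurrence` (default 5)
occurrences dataset-wide are removed once, before any analysis; compounds
stripped of all notes by this filter are retained and logged as note-free.
Compounds whose SMILES fails to parse are dropped with a logged warning
rather than aborting a long run; the count appears in the run manifest.

## Fingerprints and substructure flags

Structures are encoded as folded radius-2 circular (Morgan) fingerprints,
1024 bits — the ECFP4-equivalent binary encoding, well suited to
Tanimoto-type similarity. In parallel, 62 functional-group/substructure
flags are computed by SMARTS matching (flag = 1 iff the pattern matches at
least once). The shipped catalog (`src/odorspace/data/substructures.csv`)
covers carbonyl, ester, aldehyde, ketone, alcohol, phenol, carboxylic acid,
aliphatic and aromatic amines, thiol, sulfide, allylic groups, bicyclic
systems, unsaturated rings, aryl-methyl, furan, lactone and a
long-unbranched-chain pattern, padded to 62 with standard functional-group
SMARTS. Two definitions are package choices because no standard exists:

* **long unbranched chain** — ≥8 contiguous acyclic carbon atoms, each with
  at most two carbon neighbours (sp3 or sp2), approximated as a SMARTS
  chain;
* **bicyclic** — any atom in two SSSR rings (`[R2]`), i.e. fused or bridged
  ring systems; disconnected biaryls do not count.

Aromaticity follows RDKit's default perception. The catalog is a plain CSV
so users can substitute their own.

## Dimension reduction

All four methods produce n×2 coordinates aligned with the input rows:

* **PCA** — top-2 components of the column-centered raw 0/1 matrix, no
  variance scaling (unit-scaling near-constant bits is pathological);
  deterministic, axis signs fixed by a largest-loading-positive convention.
* **Classical MDS** — Torgerson scaling of the precomputed Jaccard distance
  matrix: eigendecomposition of the doubly-centered −D²/2, coordinates
  scaled by √eigenvalue. Chosen over SMACOF-style metric MDS because it is
  the standard treatment of a precomputed dissimilarity and is
  deterministic, which the test suite requires.
* **t-SNE** — on the precomputed Jaccard matrix, random init, perplexity 30
  (configurable; no canonical value exists for this analysis), seeded.
* **UMAP** — Jaccard metric, `n_neighbors=15`, `min_dist=0`, seeded. These
  defaults balance local/global structure for chemical maps and are
  configurable.

The Jaccard/Tanimoto distance of two all-zero bit vectors is defined as 0.
Dice and cosine metrics are accepted as alternatives. Every stochastic
method takes an explicit seed (pipeline default 42) recorded in the
embedding's provenance.

## Clustering and cluster-count selection

Both clusterings operate on the 2-D coordinates (not the 1024-bit space),
deliberately: clustering the map is what links the visualization to the
statistics.

* **k-means** — Lloyd iterations to convergence, best of
  `kmeans_restarts=10` runs initialized from random distinct points with
  seeds `seed..seed+9`; equidistant-centroid ties break toward the lower
  cluster index; the within-cluster sum of squares (WSS) is asserted
  non-increasing across iterations of every run.
* **Ward AHC** — agglomeration under Ward's minimum-variance criterion on
  Euclidean distances, i.e. the squared-distance Lance–Williams update
  ("ward.D2"); the tree is cut at k and the last k−1 merges are reported as
  merge-order metadata (which final clusters aggregate, at what height).

The cluster count is selected from the AHC tree by the **Kelley penalty**.
At a cut into k clusters, the spread of a cluster with m ≥ 2 members is the
mean of its pairwise distances; singletons contribute nothing, and a cut
where every cluster is a singleton is skipped. AvSp(k) is the mean spread
over contributing clusters. Over the evaluated range of k the spreads are
linearly rescaled to span the same interval as the cluster-count term —
with L evaluated cuts, AvSp\*(k) = L·(AvSp(k)−min)/(max−min) + 1, which for
the full range k = 2..n−1 reduces to the original normalization onto
[1, n−1] — and P(k) = AvSp\*(k) + k is minimized, ties going to the smaller
k. If all spreads are equal, AvSp\* ≡ 1 by convention. The evaluation range
is capped at `k_max=20`: the full sweep is quadratic in n and optimal
counts for these maps are small. Rescaling over the evaluated range (rather
than the full tree) is the documented consequence of that cap; without it
the spread term dwarfs the +k term and the selection degenerates.

Cluster ids are 1-based and ordered by decreasing size, a stable reporting
convention; no scientific meaning attaches to the numbering.

## Comparing and combining partitions

For one embedding, the k-means and AHC partitions are compared by the
intersection matrix counts[x, y] = |cluster x ∩ cluster y|, whose marginals
equal the cluster sizes. A one-to-one cluster correspondence is the
maximum-total-overlap assignment (Hungarian algorithm on the counts); the
**switched-molecule count** is n minus the matched-cell total, and is
invariant to relabeling either partition. Matched pairs can be merged into
combined clusters by member-set **union** (unmatched clusters in
rectangular cases become logged residual groups). Union rather than
intersection is a package choice: it keeps every molecule attributed to
exactly the pair of clusters that claimed it, at the cost of combined
clusters overlapping in the switched molecules, so per-note conservation
(Σ %ON = 100) holds only for single partitions, not across combined
clusters.

## Odor-note statistics

For a note with T occurrences dataset-wide, of which o fall in a cluster of
size s: %ON = 100·o/T and %OM = 100·o/s. All comparisons and thresholds use
unrounded values; one-decimal rounding is applied only when writing
reports. The **discriminant capacity** of a partition is the number of top
notes (default: the 17 most frequent, "odorless" included, ties broken
alphabetically and logged) whose maximum %ON over clusters is strictly
greater than 50 — a note split exactly 50/50 is not counted.

## Substructure network

freq(group, cluster) is the fraction of the cluster's molecules carrying
the group; groups are retained when max over clusters of freq ≥ 0.05
(inclusive). The network has three node kinds — notes, groups, clusters —
and edges only between a cluster and a note/group. Edge weight is the
relative frequency of occurrence within the cluster on a common [0, 1]
scale: freq for groups and %OM/100 for notes by default (%ON/100 available
via `note_weight="pct_on"`; which view a reader wants depends on whether
they ask "what is this cluster made of" or "where does this note live").
Edges below 0.1 are omitted. Export: GraphML and edge-list CSV.

## Synthetic data generator

The generator emulates the statistical shape of a large curated odorant
collection: defaults of 6038 compounds, a 162-note vocabulary whose
popularity follows a truncated power law with exponent 1.3 (long-tailed: a
handful of notes above 1000 occurrences at full size, a practical floor
near 5), 2–5 notes per non-odorless compound, and an odorless fraction of
0.043. Latent chemical families (default 4) each own 48 random core bits
of the 1024; a member's bit vector is the family signature with independent
per-bit flip noise (default 0.02). Note sampling mixes the family's profile
(one dominant note at weight 0.6 plus six mid-rank secondaries) 50/50 with
the global popularity law, so no note is family-exclusive — mirroring the
empirical fact that no descriptor is confined to one structural cluster.
Odorless compounds carry only "odorless" and draw bits from a featureless
background at the families' overall bit density; their ground-truth family
label is −1 and family-recovery scores are computed over compounds that
have a family. A SMILES-level mode decorates per-family scaffolds (ester,
thiol, bicyclic, aromatic chemistry) with short unbranched alkyl chains so
the fingerprinting stage is exercised from real structures.

What the generator does *not* model: real chemistry's continuous similarity
gradients (families are discrete), correlated note semantics ("citrus"
implying "fresh"), perceptual noise in human descriptions, and the
structural heterogeneity of real odorless compounds. Passing the recovery
tests therefore shows the pipeline's machinery is correct and sensitive
under its own assumptions — not that four clusters or any particular
discriminant-capacity value will be found in a real collection.

## Problem sizes and numerical choices

The planted-family study runs at n = 2000 compounds and the SMILES-level
substructure study at n = 600 — large enough for stable neighbor graphs
(≫ n_neighbors) and tight ARI estimates, small enough to re-run routinely.
Degenerate inputs are handled explicitly: all-zero fingerprint pairs get
Jaccard distance 0; emptied k-means clusters are re-seeded with the point
farthest from its centroid; Kelley cuts with only singletons are skipped;
non-positive MDS eigenvalues map to zero coordinates. Floats are written
with 6 significant digits, percentages with 1 decimal.

## Known limitations

* The 62-group catalog reproduces the named functional chemistry of
  odorants but any specific historical 62-group list is unpublished; counts
  that depend on the catalog's tail (e.g. how many groups survive the 5%
  filter) are catalog-relative.
* t-SNE and UMAP results depend on the seed; only seeded determinism, not
  seed-independence, is claimed or tested.
* Clustering the 2-D map inherits the map's distortions; the package does
  not cluster in fingerprint space.
* The Kelley evaluation range is capped at k_max=20 (see above).
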