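"""Odor-note statistics per cluster.

Two complementary ratios describe how an odor note distributes over clusters:

* %ON — the percent of a note's dataset-wide occurrences that fall inside a
  cluster (how concentrated the note is);
* %OM — the percent of a cluster's molecules that carry the note (how
  characteristic the note is of the cluster).

Both are computed unrounded; one-decimal rounding is applied only when
reporting.  The "odorless" descriptor is treated as an ordinary note.  The
discriminant capacity of an embedding x clustering combination is the number
of top notes whose maximum %ON over clusters exceeds 50 — a partition that
concentrates many frequent notes in single clusters discriminates well.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .cluster import Partition
from .records import CompoundRecord, OdorVocabulary

log = logging.getLogger(__name__)

STATS_COLUMNS = ["note", "cluster", "occ", "pct_on", "pct_om"]


def pct_on(occ_in_cluster: int, occ_total: int) -> float:
    """Percent of a note's total occurrences found in one cluster."""
    if occ_total < 1:
        raise ValueError("note has no occurrences in the dataset")
    if occ_in_cluster > occ_total:
        raise ValueError("cluster occurrences cannot exceed the total")
    return 100.0 * occ_in_cluster / occ_total


def pct_om(occ_in_cluster: int, cluster_size: int) -> float:
    """Percent of a cluster's molecules carrying the note."""
    if cluster_size < 1:
        raise ValueError("cluster is empty")
    return 100.0 * occ_in_cluster / cluster_size


def stats_table(records: list[CompoundRecord], partition: Partition,
                vocabulary: OdorVocabulary) -> pd.DataFrame:
    """Full (note x cluster) table of occurrences, %ON and %OM."""
    label_of = dict(zip(partition.compound_ids, partition.labels.tolist()))
    missing = [r.compound_id for r in records if r.compound_id not in label_of]
    if missing:
        raise ValueError(f"records missing from partition: {missing[:5]}")
    clusters = sorted(set(partition.labels.tolist()))
    sizes = partition.sizes()
    occ = {(note, c): 0 for note in vocabulary.notes for c in clusters}
    for rec in records:
        c = label_of[rec.compound_id]
        for note in rec.odor_notes:
            if note in vocabulary.occurrences:
                occ[(note, c)] += 1
    rows = []
    for note in vocabulary.notes:
        total = vocabulary.occurrences[note]
        for c in clusters:
            o = occ[(note, c)]
            rows.append((note, c, o, pct_on(o, total), pct_om(o, sizes[c])))
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def group_stats(records: list[CompoundRecord], groups: dict[str, set[str]],
                vocabulary: OdorVocabulary) -> pd.DataFrame:
    """Same table for arbitrary (possibly overlapping) compound groups,
    e.g. combined clusters; the cluster column holds the group name."""
    by_id = {r.compound_id: r for r in records}
    rows = []
    for name, member_ids in groups.items():
        members = [by_id[c] for c in member_ids if c in by_id]
        size = len(members)
        counts: dict[str, int] = {}
        for rec in members:
            for note in rec.odor_notes:
                if note in vocabulary.occurrences:
                    counts[note] = counts.get(note, 0) + 1
        for note, o in sorted(counts.items()):
            rows.append((note, name, o, pct_on(o, vocabulary.occurrences[note]),
                         pct_om(o, size)))
    return pd.DataFrame(rows, columns=STATS_COLUMNS)


def discriminant_capacity(stats: pd.DataFrame, top_notes: list[str]) -> int:
    """Number of ``top_notes`` whose maximum %ON over clusters is strictly
    greater than 50."""
    sub = stats[stats["note"].isin(top_notes)]
    best = sub.groupby("note")["pct_on"].max()
    return int((best > 50.0).sum())


def top_note_selection(vocabulary: OdorVocabulary, n: int = 17) -> list[str]:
    """The n most frequent notes ("odorless" included), ties alphabetical."""
    top = vocabulary.top_notes(n)
    if len(top) == n and len(vocabulary.notes) > n:
        boundary = vocabulary.occurrences[top[-1]]
        tied = [m for m in vocabulary.notes if vocabulary.occurrences[m] == boundary]
        if len(tied) > 1:
            log.info("top-%d note selection broke a tie at %d occurrences among: %s",
                     n, boundary, ", ".join(tied))
    return top


@dataclass
class CombinedCluster:
    """Union of a matched (k-means cluster, AHC cluster) pair."""

    name: str
    member_ids: set[str]
    source: tuple[int | None, int | None]


def combine_clusters(p_km: Partition, p_ahc: Partition,
                     matching: dict[int, int]) -> list[CombinedCluster]:
    """One combined cluster per matched pair (member-set union).  Clusters
    left unmatched in a rectangular case become residual groups."""
    combined = []
    for x, y in sorted(matching.items()):
        members = set(p_km.members(x)) | set(p_ahc.members(y))
        combined.append(CombinedCluster(f"C{x}k{y}h", members, (x, y)))
    for x in sorted(set(p_km.labels.tolist()) - set(matching.keys())):
        members = set(p_km.members(x))
        log.info("k-means cluster %d unmatched; kept as residual group (%d molecules)",
                 x, len(members))
        combined.append(CombinedCluster(f"C{x}k", members, (x, None)))
    for y in sorted(set(p_ahc.labels.tolist()) - set(matching.values())):
        members = set(p_ahc.members(y))
        log.info("AHC cluster %d unmatched; kept as residual group (%d molecules)",
                 y, len(members))
        combined.append(CombinedCluster(f"C{y}h", members, (None, y)))
    return combined


def note_pair_frequency(records: list[CompoundRecord], cluster_members: set[str],
                        note_a: str, note_b: str) -> float:
    """Percent of the cluster's molecules carrying both notes."""
    members = [r for r in records if r.compound_id in cluster_members]
    if not members:
        raise ValueError("empty cluster")
    both = sum(1 for r in members if note_a in r.odor_notes and note_b in r.odor_notes)
    return 100.0 * both / len(members)


def rounded(stats: pd.DataFrame) -> pd.DataFrame:
    """Reporting view: percentages to one decimal."""
    out = stats.copy()
    out["pct_on"] = out["pct_on"].round(1)
    out["pct_om"] = out["pct_om"].round(1)
    return out
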