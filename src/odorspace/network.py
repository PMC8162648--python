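"""Per-cluster functional-group frequencies and the odor-group-cluster network.

Groups are retained when present in at least 5% of the molecules of some
cluster.  The network is tripartite in node kind — odor notes, chemical
groups, clusters — with edges only between a cluster and a note or group.
An edge's weight is the relative frequency of the note/group within the
cluster on a common [0, 1] scale (%OM/100 for notes by default, the flag
frequency for groups); edges below the visibility threshold (default 0.1)
are omitted.
"""

from __future__ import annotations

import csv
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .cluster import Partition
from .fingerprints import FingerprintMatrix

PROFILE_COLUMNS = ["group", "cluster", "n_with_group", "freq"]


def group_profiles(flags: FingerprintMatrix, partition: Partition) -> pd.DataFrame:
    """freq(group, cluster) = fraction of the cluster's molecules carrying
    the group, for every catalog group."""
    if flags.group_flags is None or flags.group_names is None:
        raise ValueError("FingerprintMatrix has no group flags")
    if flags.compound_ids != partition.compound_ids:
        raise ValueError("flags and partition must cover the same compounds in order")
    labels = partition.labels
    rows = []
    for c in sorted(set(labels.tolist())):
        mask = labels == c
        size = int(mask.sum())
        hits = flags.group_flags[mask].sum(axis=0)
        for name, h in zip(flags.group_names, hits):
            rows.append((name, c, int(h), float(h) / size))
    return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def retain_groups(profile: pd.DataFrame, threshold: float = 0.05) -> list[str]:
    """Groups present in at least ``threshold`` of the molecules of some
    cluster (inclusive boundary)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must lie in (0, 1)")
    best = profile.groupby("group")["freq"].max()
    kept = best[best >= threshold].index.tolist()
    order = {g: i for i, g in enumerate(dict.fromkeys(profile["group"]))}
    return sorted(kept, key=lambda g: order[g])


def build_network(stats: pd.DataFrame, profile: pd.DataFrame,
                  edge_threshold: float = 0.1,
                  note_weight: str = "pct_om") -> nx.Graph:
    """Assemble the note/group/cluster network.

    ``note_weight`` selects which note statistic feeds the edge weight:
    ``"pct_om"`` (default, cluster-composition view) or ``"pct_on"``
    (note-concentration view); either is divided by 100 onto [0, 1].
    """
    if note_weight not in ("pct_om", "pct_on"):
        raise ValueError("note_weight must be 'pct_om' or 'pct_on'")
    clusters_s = set(stats["cluster"].unique().tolist())
    clusters_p = set(profile["cluster"].unique().tolist())
    if clusters_s != clusters_p:
        raise ValueError("stats and profile must share the same cluster set")

    G = nx.Graph()
    for c in sorted(clusters_s):
        G.add_node(f"cluster:{c}", kind="cluster", label=f"C{c}")
    for _, row in stats.iterrows():
        w = float(row[note_weight]) / 100.0
        if w >= edge_threshold:
            node = f"note:{row['note']}"
            if node not in G:
                G.add_node(node, kind="note", label=row["note"])
            G.add_edge(node, f"cluster:{row['cluster']}", weight=round(w, 6))
    for _, row in profile.iterrows():
        w = float(row["freq"])
        if w >= edge_threshold:
            node = f"group:{row['group']}"
            if node not in G:
                G.add_node(node, kind="group", label=row["group"])
            G.add_edge(node, f"cluster:{row['cluster']}", weight=round(w, 6))
    return G


def write_network(G: nx.Graph, graphml_path: str | Path | None = None,
                  edges_csv_path: str | Path | None = None) -> None:
    """Export as GraphML and/or an edge-list CSV (source, target, weight,
    source/target kinds)."""
    if graphml_path is not None:
        nx.write_graphml(G, graphml_path)
    if edges_csv_path is not None:
        with open(edges_csv_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["source", "target", "weight", "source_kind", "target_kind"])
            for u, v, data in sorted(G.edges(data=True)):
                writer.writerow([u, v, f"{data['weight']:.6g}",
                                 G.nodes[u]["kind"], G.nodes[v]["kind"]])


def profile_summary(profile: pd.DataFrame, retained: list[str]) -> pd.DataFrame:
    """Wide per-cluster frequency table restricted to the retained groups."""
    sub = profile[profile["group"].isin(retained)]
    wide = sub.pivot(index="group", columns="cluster", values="freq")
    return wide.reindex(retained).round(6)
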