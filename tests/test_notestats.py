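import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odorspace.cluster import Partition, intersection_matrix, switched_count
from odorspace.notestats import (combine_clusters, discriminant_capacity,
                                 group_stats, note_pair_frequency, pct_om, pct_on,
                                 rounded, stats_table, top_note_selection)
from odorspace.records import CompoundRecord, OdorVocabulary


def partition_of(records, labels):
    ids = [r.compound_id for r in records]
    return Partition(ids, np.array(labels), "umap", "kmeans", max(labels))


def test_pct_on_and_om_boundaries():
    assert pct_on(0, 50) == 0.0
    assert pct_om(7, 7) == 100.0
    with pytest.raises(ValueError):
        pct_on(1, 0)
    with pytest.raises(ValueError):
        pct_on(5, 3)
    with pytest.raises(ValueError):
        pct_om(1, 0)


def test_stats_table_matches_hand_tally(hand_records):
    labels = [1, 1, 1, 2, 2, 2, 3, 3, 3, 2]
    vocab = OdorVocabulary.from_records(hand_records)
    table = stats_table(hand_records, partition_of(hand_records, labels), vocab)
    row = table.set_index(["note", "cluster"])
    # "fruity": 4 total; M0,M1,M2 in C1, M9 in C2
    assert row.loc[("fruity", 1), "occ"] == 3
    assert row.loc[("fruity", 1), "pct_on"] == pytest.approx(75.0)
    assert row.loc[("fruity", 2), "pct_on"] == pytest.approx(25.0)
    # C2 = {M3, M4, M5, M9}: all four carry "woody"
    assert row.loc[("woody", 2), "occ"] == 4
    assert row.loc[("woody", 2), "pct_om"] == pytest.approx(100.0)
    # "spicy" occurs once, on M4 in C2
    assert row.loc[("spicy", 2), "pct_om"] == pytest.approx(25.0)
    assert row.loc[("odorless", 3), "occ"] == 1


def test_single_cluster_gives_full_pct_on(hand_records):
    vocab = OdorVocabulary.from_records(hand_records)
    table = stats_table(hand_records, partition_of(hand_records, [1] * 10), vocab)
    assert (table["pct_on"] == 100.0).all()


def test_note_wholly_in_one_cluster(hand_records):
    labels = [2, 2, 2, 2, 2, 2, 1, 1, 2, 2]   # sulfurous only in cluster 1
    vocab = OdorVocabulary.from_records(hand_records)
    table = stats_table(hand_records, partition_of(hand_records, labels), vocab)
    sulf = table[table["note"] == "sulfurous"].set_index("cluster")["pct_on"]
    assert sulf[1] == pytest.approx(100.0)
    assert sulf[2] == pytest.approx(0.0)


def test_pct_on_sums_to_100_per_note(hand_records):
    vocab = OdorVocabulary.from_records(hand_records)
    table = stats_table(hand_records, partition_of(hand_records,
                                                   [1, 2, 3, 1, 2, 3, 1, 2, 3, 1]), vocab)
    sums = table.groupby("note")["pct_on"].sum()
    assert np.allclose(sums.to_numpy(), 100.0)


def test_occ_conservation_per_cluster(hand_records):
    labels = [1, 1, 2, 2, 2, 1, 2, 1, 1, 2]
    vocab = OdorVocabulary.from_records(hand_records)
    table = stats_table(hand_records, partition_of(hand_records, labels), vocab)
    for c in (1, 2):
        members = [r for r, l in zip(hand_records, labels) if l == c]
        assert table[table["cluster"] == c]["occ"].sum() == \
            sum(len(r.odor_notes) for r in members)


def test_missing_record_errors(hand_records):
    part = partition_of(hand_records[:-1], [1, 1, 1, 1, 2, 2, 2, 2, 2])
    vocab = OdorVocabulary.from_records(hand_records)
    with pytest.raises(ValueError):
        stats_table(hand_records, part, vocab)


def test_rounding_only_at_reporting():
    # 3/1523 -> 0.19698...%, reported as 0.2
    raw = pct_om(3, 1523)
    assert raw != pytest.approx(0.2, abs=1e-6)
    import pandas as pd

    frame = pd.DataFrame({"note": ["beefy"], "cluster": [1], "occ": [3],
                          "pct_on": [15.0], "pct_om": [raw]})
    assert rounded(frame)["pct_om"].iloc[0] == 0.2


def test_discriminant_capacity_counts_and_boundary(hand_records):
    vocab = OdorVocabulary.from_records(hand_records)
    # every note wholly in one cluster -> capacity = number of top notes
    table = stats_table(hand_records, partition_of(hand_records, [1] * 10), vocab)
    top = top_note_selection(vocab, 5)
    assert discriminant_capacity(table, top) == 5
    # a note split exactly 50/50 is not counted (strict > 50)
    recs = [CompoundRecord(f"A{i}", "C", {"split"}) for i in range(4)]
    vocab2 = OdorVocabulary.from_records(recs)
    table2 = stats_table(recs, partition_of(recs, [1, 1, 2, 2]), vocab2)
    assert discriminant_capacity(table2, ["split"]) == 0


def test_discriminant_capacity_monotone_under_purification():
    """Moving a note's occurrences into a single cluster can only raise the
    number of notes whose max %ON exceeds 50."""
    rng = np.random.default_rng(0)
    notes = [f"n{i}" for i in range(6)]
    caps = []
    for purity in (0.5, 0.75, 1.0):
        recs = []
        for i, note in enumerate(notes):
            home = (i % 2) + 1
            for j in range(20):
                c = home if rng.random() < purity else 3 - home
                recs.append(CompoundRecord(f"{note}_{j}", "C", {note, f"c{c}"}))
        labels = [1 if f"c1" in r.odor_notes else 2 for r in recs]
        vocab = OdorVocabulary.from_records(recs)
        table = stats_table(recs, partition_of(recs, labels), vocab)
        caps.append(discriminant_capacity(table, notes))
    assert caps == sorted(caps)
    assert caps[-1] == len(notes)


def test_combine_clusters_union_and_residuals(hand_records):
    ids = [r.compound_id for r in hand_records]
    km = Partition(ids, np.array([1, 1, 1, 1, 2, 2, 2, 2, 2, 1]), "umap", "kmeans", 2)
    ah = Partition(ids, np.array([2, 2, 2, 2, 1, 1, 1, 1, 1, 1]), "umap", "ahc", 2)
    matching, n_sw = switched_count(intersection_matrix(km, ah))
    assert matching == {1: 2, 2: 1}
    combined = combine_clusters(km, ah, matching)
    by_name = {c.name: c for c in combined}
    # union: km cluster 1 (5 members) U ahc cluster 2 (first four) -> M9 absorbed
    assert by_name["C1k2h"].member_ids == {"M0", "M1", "M2", "M3", "M9"}
    assert by_name["C2k1h"].member_ids == {"M4", "M5", "M6", "M7", "M8", "M9"}
    for c in combined:
        a = set(km.members(c.source[0]))
        b = set(ah.members(c.source[1]))
        assert max(len(a), len(b)) <= len(c.member_ids) <= len(a) + len(b)


def test_combine_identical_partitions_is_identity(hand_records):
    ids = [r.compound_id for r in hand_records]
    labels = np.array([1, 1, 1, 2, 2, 2, 2, 2, 2, 2])
    km = Partition(ids, labels, "umap", "kmeans", 2)
    ah = Partition(ids, labels, "umap", "ahc", 2)
    matching, _ = switched_count(intersection_matrix(km, ah))
    combined = combine_clusters(km, ah, matching)
    assert {frozenset(c.member_ids) for c in combined} == \
        {frozenset(km.members(1)), frozenset(km.members(2))}


def test_combine_rectangular_residual(hand_records):
    ids = [r.compound_id for r in hand_records]
    km = Partition(ids, np.array([1, 1, 1, 1, 1, 2, 2, 2, 3, 3]), "umap", "kmeans", 3)
    ah = Partition(ids, np.array([1, 1, 1, 1, 1, 2, 2, 2, 2, 2]), "umap", "ahc", 2)
    matching, _ = switched_count(intersection_matrix(km, ah))
    combined = combine_clusters(km, ah, matching)
    residual = [c for c in combined if None in c.source]
    assert len(residual) == 1 and len(combined) == 3


def test_group_stats_on_overlapping_groups(hand_records):
    vocab = OdorVocabulary.from_records(hand_records)
    groups = {"G1": {"M0", "M1", "M2", "M9"}, "G2": {"M9", "M3", "M4", "M5"}}
    table = group_stats(hand_records, groups, vocab)
    row = table.set_index(["note", "cluster"])
    assert row.loc[("fruity", "G1"), "occ"] == 4
    assert row.loc[("woody", "G2"), "pct_om"] == pytest.approx(100.0)


def test_note_pair_frequency(hand_records):
    members = {"M3", "M4", "M5", "M9"}
    # both woody & spicy: only M4 -> 25%
    assert note_pair_frequency(hand_records, members, "woody", "spicy") == pytest.approx(25.0)
    assert note_pair_frequency(hand_records, members, "fruity", "sulfurous") == 0.0
    # degenerate pair equals that note's %OM
    assert note_pair_frequency(hand_records, members, "woody", "woody") == pytest.approx(100.0)


@settings(deadline=None, max_examples=40)
@given(st.lists(st.integers(min_value=1, max_value=3), min_size=6, max_size=30))
def test_pct_on_conservation_property(raw_labels):
    labels = list(raw_labels)
    for c in (1, 2, 3):                      # ensure every cluster nonempty
        if c not in labels:
            labels[c - 1] = c
    recs = [CompoundRecord(f"R{i}", "C", {f"note{i % 4}"}) for i in range(len(labels))]
    vocab = OdorVocabulary.from_records(recs)
    table = stats_table(recs, partition_of(recs, labels), vocab)
    sums = table.groupby("note")["pct_on"].sum()
    assert np.allclose(sums, 100.0)
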