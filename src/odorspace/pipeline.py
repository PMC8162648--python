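"""End-to-end orchestration: ingest/simulate -> fingerprint -> embed x4 ->
cluster x2 -> note statistics -> substructure network.

Every stage writes its artifacts under the output directory so any stage can
be re-run from the previous stage's files; a JSON manifest records seeds,
configuration, record counts and the per-method discriminant-capacity
summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import network as net
from . import notestats as ns
from .cluster import (ClusterConfig, Partition, ahc_partition, intersection_matrix,
                      kmeans_partition, switched_count)
from .embed import METHODS, Embedding2D, ReductionConfig, embed, write_embedding
from .fingerprints import FingerprintConfig, encode_dataset, load_catalog
from .records import CompoundRecord, OdorVocabulary
from .synthetic import SyntheticConfig, generate_dataset, generate_smiles_dataset
from .table_io import read_compound_table, write_results_bundle

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_path: str | None = None            # compound table; None -> synthetic
    synthetic: SyntheticConfig | None = None
    use_smiles: bool = True                  # synthetic mode: emit SMILES & fingerprint them
    fingerprint: FingerprintConfig = field(default_factory=FingerprintConfig)
    methods: tuple[str, ...] = METHODS
    metric: str = "jaccard"
    n_neighbors: int = 15
    min_dist: float = 0.0
    perplexity: float = 30.0
    cluster: ClusterConfig = field(default_factory=lambda: ClusterConfig(k="auto"))
    min_occurrence: int = 5
    retention_threshold: float = 0.05
    edge_threshold: float = 0.1
    discriminant_cut: float = 50.0
    top_n_notes: int = 17
    out_dir: str = "odorspace_out"
    seed: int = 42


@dataclass
class PipelineResult:
    records: list[CompoundRecord]
    vocabulary: OdorVocabulary
    embeddings: dict[str, Embedding2D]
    partitions: dict[tuple[str, str], Partition]
    stats: dict[tuple[str, str], "object"]
    manifest: dict


def _reduction_config(cfg: PipelineConfig, method: str) -> ReductionConfig:
    return ReductionConfig(method=method, metric=cfg.metric,
                           n_neighbors=cfg.n_neighbors, min_dist=cfg.min_dist,
                           perplexity=cfg.perplexity, seed=cfg.seed)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config": _jsonable(config)}
    t0 = time.time()
    stage = "ingest"
    try:
        # ---- ingest / simulate -------------------------------------------
        flags = None
        if config.input_path is not None:
            records, vocab = read_compound_table(config.input_path,
                                                 min_occurrence=config.min_occurrence)
            enc = encode_dataset(records, config.fingerprint, load_catalog())
            kept = set(enc.compound_ids)
            records = [r for r in records if r.compound_id in kept]
            bits, flags = enc.bits, enc
            manifest["stages"]["ingest"] = {"n_records": len(records),
                                            "n_dropped_smiles": len(enc.dropped_ids)}
        else:
            syn_cfg = config.synthetic or SyntheticConfig(seed=config.seed)
            if config.use_smiles:
                dataset = generate_smiles_dataset(syn_cfg)
                enc = encode_dataset(dataset.records, config.fingerprint, load_catalog())
                records, bits, flags = dataset.records, enc.bits, enc
            else:
                dataset = generate_dataset(syn_cfg)
                records, bits = dataset.records, dataset.bits
            vocab = dataset.vocabulary
            manifest["stages"]["ingest"] = {"n_records": len(records),
                                            "synthetic": True,
                                            "n_families": syn_cfg.n_families}
        n_odorless = sum(1 for r in records if r.odorless)
        manifest["stages"]["ingest"]["n_odorless"] = n_odorless
        log.info("ingest: %d compounds (%d odorless), %d notes",
                 len(records), n_odorless, len(vocab.notes))

        ids = [r.compound_id for r in records]

        # ---- embed x methods ---------------------------------------------
        stage = "embed"
        embeddings: dict[str, Embedding2D] = {}
        for method in config.methods:
            t = time.time()
            emb = embed(bits, _reduction_config(config, method), compound_ids=ids)
            embeddings[method] = emb
            write_embedding(emb, out / f"coords_{method}.csv",
                            out / f"reduction_{method}.json")
            manifest["stages"].setdefault("embed", {})[method] = {
                "n": len(ids), "seconds": round(time.time() - t, 2)}

        # ---- cluster x2 ---------------------------------------------------
        stage = "cluster"
        partitions: dict[tuple[str, str], Partition] = {}
        selected_k: dict[str, int] = {}
        for method, emb in embeddings.items():
            km = kmeans_partition(emb, config.cluster)
            ah = ahc_partition(emb, config.cluster, k=km.k if config.cluster.k == "auto" else None)
            partitions[(method, "kmeans")] = km
            partitions[(method, "ahc")] = ah
            selected_k[method] = km.k
            with open(out / f"merge_order_{method}.json", "w") as fh:
                json.dump([{"left": a, "right": b, "height": h}
                           for a, b, h in ah.merge_order], fh, indent=2)
        manifest["stages"]["cluster"] = {"selected_k": selected_k}

        # ---- statistics ---------------------------------------------------
        stage = "stats"
        top = ns.top_note_selection(vocab, config.top_n_notes)
        stats = {}
        capacity = {}
        switched = {}
        for key, part in partitions.items():
            stats[key] = ns.stats_table(records, part, vocab)
            capacity["_".join(key)] = ns.discriminant_capacity(stats[key], top)
        for method in config.methods:
            inter = intersection_matrix(partitions[(method, "kmeans")],
                                        partitions[(method, "ahc")])
            _, n_sw = switched_count(inter)
            switched[method] = n_sw
        manifest["stages"]["stats"] = {"discriminant_capacity": capacity,
                                       "switched": switched,
                                       "top_notes": top}

        # ---- network (needs group flags, i.e. SMILES input) ---------------
        stage = "network"
        if flags is not None:
            ref = config.methods[-1]
            profile = net.group_profiles(flags, partitions[(ref, "kmeans")])
            retained = net.retain_groups(profile, config.retention_threshold)
            G = net.build_network(stats[(ref, "kmeans")],
                                  profile[profile["group"].isin(retained)],
                                  edge_threshold=config.edge_threshold)
            net.write_network(G, out / "network.graphml", out / "network_edges.csv")
            profile.to_csv(out / "group_profiles.csv", index=False)
            manifest["stages"]["network"] = {"reference_method": ref,
                                             "n_groups_retained": len(retained),
                                             "n_edges": G.number_of_edges()}
        else:
            log.info("no SMILES available; skipping substructure network stage")
            manifest["stages"]["network"] = {"skipped": "no SMILES/group flags"}

        # ---- bundle -------------------------------------------------------
        stage = "bundle"
        rounded = {k: ns.rounded(v) for k, v in stats.items()}
        bundle = write_results_bundle(rounded, partitions, out, embeddings=embeddings)
        manifest["stages"]["bundle"] = {"n_files": len(bundle["files"])}
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["seconds_total"] = round(time.time() - t0, 2)
    with open(out / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return PipelineResult(records, vocab, embeddings, partitions, stats, manifest)


def _jsonable(obj) -> dict:
    def convert(x):
        if dataclasses.is_dataclass(x) and not isinstance(x, type):
            return {k: convert(v) for k, v in dataclasses.asdict(x).items()}
        if isinstance(x, (np.integer, np.floating)):
            return x.item()
        if isinstance(x, (list, tuple)):
            return [convert(v) for v in x]
        if isinstance(x, dict):
            return {k: convert(v) for k, v in x.items()}
        return x

    return convert(obj)
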