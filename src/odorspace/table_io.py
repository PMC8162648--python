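"""Reading and writing compound-odor tables and derived artifacts.

The input format is a CSV/TSV table with one row per compound: an identifier
column, a SMILES column and an odor-note column holding ``;``-separated
descriptors.  Notes occurring fewer than ``min_occurrence`` times dataset-wide
are dropped from every record and from the vocabulary before any analysis.
"""

from __future__ import annotations

import csv
import json
import logging
from pathlib import Path
from typing import TYPE_CHECKING

import pandas as pd

from .records import ODORLESS, CompoundRecord, OdorVocabulary, normalize_note

if TYPE_CHECKING:  # pragma: no cover
    from .cluster import Partition
    from .embed import Embedding2D

log = logging.getLogger(__name__)


def _delimiter(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_compound_table(
    path: str | Path,
    min_occurrence: int = 5,
    id_col: str = "compound_id",
    smiles_col: str = "smiles",
    notes_col: str = "odor_notes",
) -> tuple[list[CompoundRecord], OdorVocabulary]:
    """Read a compound-odor table and apply the occurrence floor.

    Returns the records (note sets normalized, rare notes removed) and the
    retained vocabulary.  Compounds stripped of all their notes by the filter
    are kept and logged as note-free.

    Raises ``ValueError`` on duplicate compound ids (naming the id), rows that
    cannot be parsed (naming the line number) and empty files.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if min_occurrence < 1:
        raise ValueError("min_occurrence must be a positive integer")

    records: list[CompoundRecord] = []
    seen: set[str] = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=_delimiter(path))
        if reader.fieldnames is None:
            raise ValueError(f"empty file: {path}")
        for col in (id_col, smiles_col, notes_col):
            if col not in reader.fieldnames:
                raise ValueError(f"missing column {col!r} in {path}")
        for lineno, row in enumerate(reader, start=2):
            try:
                cid = (row[id_col] or "").strip()
                smiles = (row[smiles_col] or "").strip()
                raw_notes = row[notes_col] or ""
            except (KeyError, TypeError) as exc:
                raise ValueError(f"unparsable row at line {lineno} of {path}") from exc
            if not cid or not smiles:
                raise ValueError(f"unparsable row at line {lineno} of {path}")
            if cid in seen:
                raise ValueError(f"duplicate compound_id {cid!r}")
            seen.add(cid)
            notes = {normalize_note(n) for n in raw_notes.split(";") if n.strip()}
            records.append(CompoundRecord(cid, smiles, notes))
    if not records:
        raise ValueError(f"no data rows in {path}")

    vocab = OdorVocabulary.from_records(records)
    rare = {n for n, c in vocab.occurrences.items() if c < min_occurrence}
    if rare:
        for rec in records:
            rec.odor_notes -= rare
            if rec.odorless and ODORLESS in rare:
                rec.odorless = False
    note_free = [r.compound_id for r in records if not r.odor_notes]
    if note_free:
        log.info("%d compounds left note-free after the >=%d-occurrence filter: %s",
                 len(note_free), min_occurrence, ", ".join(note_free[:10]))
    vocab = OdorVocabulary.from_records(records)
    return records, vocab


def write_compound_table(records: list[CompoundRecord], path: str | Path) -> None:
    """Write records back out in the canonical table layout."""
    path = Path(path)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=_delimiter(path))
        writer.writerow(["compound_id", "smiles", "odor_notes"])
        for rec in records:
            writer.writerow([rec.compound_id, rec.smiles, ";".join(sorted(rec.odor_notes))])


def _fmt(x: float) -> str:
    return f"{x:.6g}"


def write_results_bundle(
    stats: dict[tuple[str, str], pd.DataFrame],
    partitions: dict[tuple[str, str], "Partition"],
    out_dir: str | Path,
    embeddings: dict[str, "Embedding2D"] | None = None,
) -> dict:
    """Write per-cluster statistics, coordinates and labels; return a manifest.

    ``stats`` and ``partitions`` are keyed by ``(method, clustering)``.  One
    coordinates+labels CSV is written per reduction method (compound id, x, y,
    then one label column per clustering), mirroring the layout of a combined
    coordinates/cluster supplementary table.  Percentages are written with one
    decimal, other floats with six significant digits.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        probe = out_dir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"output directory not writable: {out_dir}") from exc

    manifest: dict = {"files": []}

    for (method, clustering), table in stats.items():
        fname = f"note_stats_{method}_{clustering}.csv"
        out = table.copy()
        for col in ("pct_on", "pct_om"):
            if col in out.columns:
                out[col] = out[col].map(lambda v: f"{v:.1f}")
        out.to_csv(out_dir / fname, index=False)
        manifest["files"].append({"file": fname, "rows": len(out)})

    methods = {m for m, _ in partitions}
    embeddings = embeddings or {}
    for method in sorted(methods):
        fname = f"coords_{method}.csv"
        cols: dict[str, list] = {}
        ids: list[str] | None = None
        emb = embeddings.get(method)
        if emb is not None:
            ids = list(emb.compound_ids)
            cols["x"] = [_fmt(v) for v in emb.coords[:, 0]]
            cols["y"] = [_fmt(v) for v in emb.coords[:, 1]]
        for (m, clustering), part in sorted(partitions.items()):
            if m != method:
                continue
            if ids is None:
                ids = list(part.compound_ids)
            cols[f"cluster_{clustering}"] = list(part.labels)
        frame = pd.DataFrame({"compound_id": ids, **cols})
        frame.to_csv(out_dir / fname, index=False)
        manifest["files"].append({"file": fname, "rows": len(frame)})

    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest


def read_labels(path: str | Path, column: str) -> pd.Series:
    """Read one cluster-label column from a coordinates+labels CSV."""
    frame = pd.read_csv(path)
    return frame.set_index("compound_id")[column]
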