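"""Circular fingerprints and functional-group flags for odorant molecules.

Structures are encoded as folded radius-2 circular (Morgan) fingerprints —
the ECFP4-equivalent binary encoding — plus a catalog of SMARTS-defined
functional-group/substructure flags.  The shipped catalog holds 62 groups
covering the functional chemistry typical of odorants (carbonyls, esters,
thiols, allylic and bicyclic systems, unsaturated rings, long unbranched
chains, ...); users may substitute their own two-column CSV.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from rdkit import Chem
from rdkit.Chem import DataStructs, rdFingerprintGenerator

from .records import CompoundRecord

log = logging.getLogger(__name__)


@dataclass
class FingerprintConfig:
    radius: int = 2
    n_bits: int = 1024

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.n_bits <= 0 or self.n_bits & (self.n_bits - 1):
            raise ValueError("n_bits must be a positive power of two")


@dataclass
class SubstructureCatalog:
    """Named SMARTS patterns; every pattern is validated at load time."""

    entries: list[tuple[str, str]]
    _patterns: list = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate group names in catalog")
        self._patterns = []
        for name, smarts in self.entries:
            patt = Chem.MolFromSmarts(smarts)
            if patt is None:
                raise ValueError(f"unparsable SMARTS for group {name!r}: {smarts!r}")
            self._patterns.append(patt)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def load_catalog(path: str | Path | None = None) -> SubstructureCatalog:
    """Load a substructure catalog CSV (default: the shipped 62-group file).

    Lines starting with ``#`` are comments; the header row is ``name,smarts``.
    """
    if path is None:
        source = resources.files("odorspace.data").joinpath("substructures.csv")
        text = source.read_text()
    else:
        text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip() and not ln.lstrip().startswith("#")]
    reader = csv.DictReader(lines)
    entries = [(row["name"].strip(), row["smarts"].strip()) for row in reader]
    return SubstructureCatalog(entries)


@dataclass
class FingerprintMatrix:
    """Binary fingerprint rows (and optionally group flags) for a dataset."""

    compound_ids: list[str]
    bits: np.ndarray | None = None         # n x n_bits, uint8
    group_flags: np.ndarray | None = None  # n x G, uint8
    group_names: list[str] | None = None
    dropped_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for mat in (self.bits, self.group_flags):
            if mat is not None and mat.shape[0] != len(self.compound_ids):
                raise ValueError("matrix row count must match compound_ids")


def _mols(records: list[CompoundRecord]) -> tuple[list, list[CompoundRecord], list[str]]:
    mols, kept, dropped = [], [], []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.smiles) if rec.smiles else None
        if mol is None:
            dropped.append(rec.compound_id)
        else:
            mols.append(mol)
            kept.append(rec)
    if dropped:
        log.warning("dropping %d compounds with unparsable SMILES (e.g. %s)",
                    len(dropped), ", ".join(dropped[:5]))
    if not kept:
        raise ValueError("no valid SMILES in input")
    return mols, kept, dropped


def compute_fingerprints(
    records: list[CompoundRecord],
    config: FingerprintConfig | None = None,
) -> FingerprintMatrix:
    """Fold each molecule's radius-``config.radius`` circular environments
    into a binary row.  Compounds whose SMILES fails to parse are dropped and
    listed in ``dropped_ids``; identical structures yield identical rows."""
    config = config or FingerprintConfig()
    mols, kept, dropped = _mols(records)
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=config.radius, fpSize=config.n_bits)
    bits = np.zeros((len(mols), config.n_bits), dtype=np.uint8)
    row = np.zeros(config.n_bits, dtype=np.uint8)
    for i, mol in enumerate(mols):
        DataStructs.ConvertToNumpyArray(gen.GetFingerprint(mol), row)
        bits[i] = row
    return FingerprintMatrix([r.compound_id for r in kept], bits, dropped_ids=dropped)


def compute_group_flags(
    records: list[CompoundRecord],
    catalog: SubstructureCatalog | None = None,
) -> FingerprintMatrix:
    """Flag = 1 iff the group's SMARTS matches the molecule at least once."""
    catalog = catalog or load_catalog()
    mols, kept, dropped = _mols(records)
    flags = np.zeros((len(mols), len(catalog)), dtype=np.uint8)
    for i, mol in enumerate(mols):
        for j, patt in enumerate(catalog._patterns):
            if mol.HasSubstructMatch(patt):
                flags[i, j] = 1
    ids = [r.compound_id for r in kept]
    return FingerprintMatrix(ids, group_flags=flags,
                             group_names=catalog.names, dropped_ids=dropped)


def encode_dataset(
    records: list[CompoundRecord],
    config: FingerprintConfig | None = None,
    catalog: SubstructureCatalog | None = None,
) -> FingerprintMatrix:
    """Fingerprint bits and group flags in one aligned matrix."""
    fp = compute_fingerprints(records, config)
    kept = [r for r in records if r.compound_id not in set(fp.dropped_ids)]
    gf = compute_group_flags(kept, catalog)
    return FingerprintMatrix(fp.compound_ids, fp.bits, group_flags=gf.group_flags,
                             group_names=gf.group_names, dropped_ids=fp.dropped_ids)
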