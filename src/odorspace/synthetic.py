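"""Synthetic odorant datasets with planted structure-odor coupling.

The generator emulates the statistical shape of a large curated odorant
collection: ~6000 compounds, a vocabulary of ~162 notes whose occurrence
distribution is long-tailed (a handful of notes above 1000 occurrences, a
floor of 5), 2-5 notes per odorant, ~4.3% odorless compounds, and latent
chemical families that tie fingerprint bits to note profiles.  Each family
owns a set of "core" fingerprint bits (its structural signature) and a note
profile concentrated on one dominant descriptor; compounds inherit the
family's bits with independent flip noise, so structurally close compounds
share notes — the premise the downstream embedding/clustering analysis
is designed to expose.

Odorless compounds carry the single note "odorless" and draw their bits from
a featureless background distribution; their ground-truth family label is -1.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .records import ODORLESS, CompoundRecord, OdorVocabulary

# Seed descriptors, most popular first; the long-tailed popularity law is
# applied over this ordering.  Padded with generic note names up to n_notes.
BASE_NOTES = [
    "fruity", "green", "sweet", "floral", "woody", "spicy", "herbal", "fatty",
    "balsamic", "citrus", "sulfurous", "waxy", "nutty", "earthy", "minty",
    "roasted", "fresh", "oily", "caramellic", "winey", "apple", "rose",
    "creamy", "musty", "camphoreous", "tropical", "berry", "honey", "vanilla",
    "smoky", "leafy", "mushroom", "meaty", "almond", "anise", "banana",
    "buttery", "cedar", "cheesy", "chocolate", "cinnamon", "coconut",
    "coffee", "cooling", "dairy", "dry", "ethereal", "garlic", "grassy",
    "jasmine", "lemon", "malty", "melon", "metallic", "onion", "orange",
    "peach", "pear", "phenolic", "pine", "pineapple", "plum", "powdery",
    "pungent", "sandalwood", "tobacco", "vegetable", "violet", "woody-amber",
]


@dataclass
class FamilySpec:
    """One latent chemical family: a bit signature plus a note profile."""

    family_id: str
    core_bits: np.ndarray          # sorted bit indices in [0, n_bits)
    bit_noise: float               # per-bit flip probability
    note_profile: dict[str, float]  # note -> sampling weight (sums to 1)
    size: int

    def __post_init__(self) -> None:
        if self.size < 1:
            raise ValueError("family size must be >= 1")
        if not 0.0 <= self.bit_noise <= 1.0:
            raise ValueError("bit_noise must lie in [0, 1]")


@dataclass
class SyntheticConfig:
    n_compounds: int = 6038
    n_families: int = 4
    n_bits: int = 1024
    n_notes: int = 162                       # including "odorless"
    notes_per_compound: tuple[int, int] = (2, 5)
    odorless_fraction: float = 0.043         # 261/6038 in the reference corpus
    occurrence_tail: float = 1.3             # power-law exponent of note popularity
    bit_noise: float = 0.02
    bits_per_family: int = 48
    family_mix: float = 0.5                  # family profile vs global popularity
    seed: int = 7

    def __post_init__(self) -> None:
        lo, hi = self.notes_per_compound
        if not (self.n_compounds > 0 and self.n_families > 0 and self.n_bits > 0
                and self.n_notes > 2 and 1 <= lo <= hi):
            raise ValueError("all counts must be positive and the note range ordered")
        if not 0.0 <= self.odorless_fraction < 1.0:
            raise ValueError("odorless_fraction must lie in [0, 1)")
        if self.n_families > self.n_compounds:
            raise ValueError("n_families cannot exceed n_compounds")


@dataclass
class SyntheticDataset:
    records: list[CompoundRecord]
    bits: np.ndarray                 # n x n_bits uint8
    vocabulary: OdorVocabulary
    family_labels: np.ndarray        # ground truth; -1 for odorless/background
    family_specs: list[FamilySpec]
    dominant_notes: list[str] = field(default_factory=list)  # one per family


def note_vocabulary(n_notes: int) -> list[str]:
    """Non-odorless note names, most popular first (n_notes - 1 entries)."""
    names = list(BASE_NOTES)
    i = 1
    while len(names) < n_notes - 1:
        names.append(f"note{i:03d}")
        i += 1
    return names[: n_notes - 1]


def _popularity(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def make_family_specs(config: SyntheticConfig, rng: np.random.Generator) -> list[FamilySpec]:
    """Draw the family signatures and note profiles.

    Family f's dominant note is the f-th most popular note, so each family
    champions a distinct frequent descriptor; six mid-rank secondary notes are
    shared into the profile so that no note is family-exclusive.
    """
    notes = note_vocabulary(config.n_notes)
    sizes = np.full(config.n_families, config.n_compounds // config.n_families)
    sizes[: config.n_compounds % config.n_families] += 1
    specs = []
    for f in range(config.n_families):
        core = np.sort(rng.choice(config.n_bits, size=config.bits_per_family, replace=False))
        dominant = notes[f % len(notes)]
        lo = min(config.n_families, len(notes) - 1)
        secondary_pool = [n for n in notes[lo : lo + 36] if n != dominant]
        k = min(6, len(secondary_pool))
        secondary = list(rng.choice(secondary_pool, size=k, replace=False)) if k else []
        profile = {dominant: 0.6}
        for s in secondary:
            profile[s] = 0.4 / max(k, 1)
        specs.append(FamilySpec(f"F{f + 1}", core, config.bit_noise, profile, int(sizes[f])))
    return specs


def generate_dataset(
    config: SyntheticConfig,
    family_specs: list[FamilySpec] | None = None,
) -> SyntheticDataset:
    """Generate a seeded synthetic dataset; same config -> identical output."""
    rng = np.random.default_rng(config.seed)
    specs = family_specs if family_specs is not None else make_family_specs(config, rng)
    if sum(s.size for s in specs) != config.n_compounds:
        raise ValueError("family sizes must sum to n_compounds")

    notes = note_vocabulary(config.n_notes)
    global_p = _popularity(len(notes), config.occurrence_tail)
    note_index = {n: i for i, n in enumerate(notes)}

    family_of = np.concatenate([np.full(s.size, f) for f, s in enumerate(specs)])
    n = config.n_compounds
    n_odorless = int(round(config.odorless_fraction * n))
    odorless_idx = rng.choice(n, size=n_odorless, replace=False) if n_odorless else np.array([], dtype=int)
    is_odorless = np.zeros(n, dtype=bool)
    is_odorless[odorless_idx] = True

    # Bits: family core signature with flip noise; odorless -> background draw
    # at the same overall density (core density + noise floor).
    bits = np.zeros((n, config.n_bits), dtype=np.uint8)
    bg_density = config.bits_per_family / config.n_bits + config.bit_noise
    for i in range(n):
        spec = specs[family_of[i]]
        if is_odorless[i]:
            bits[i] = rng.random(config.n_bits) < bg_density
        else:
            bits[i, spec.core_bits] = 1
            flips = rng.random(config.n_bits) < spec.bit_noise
            bits[i] ^= flips

    lo, hi = config.notes_per_compound
    records: list[CompoundRecord] = []
    mix = config.family_mix
    profile_vectors = []
    for spec in specs:
        v = np.zeros(len(notes))
        for note, w in spec.note_profile.items():
            v[note_index[note]] = w
        v = mix * v / max(v.sum(), 1e-12) + (1.0 - mix) * global_p
        profile_vectors.append(v / v.sum())
    for i in range(n):
        cid = f"SYN{i:05d}"
        if is_odorless[i]:
            records.append(CompoundRecord(cid, "", {ODORLESS}, odorless=True))
            continue
        m = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(notes), size=m, replace=False, p=profile_vectors[family_of[i]])
        records.append(CompoundRecord(cid, "", {notes[j] for j in chosen}))

    family_labels = np.where(is_odorless, -1, family_of)
    vocab = OdorVocabulary.from_records(records)
    dominant = [max(s.note_profile, key=s.note_profile.get) for s in specs]
    return SyntheticDataset(records, bits, vocab, family_labels, specs, dominant)


# ---------------------------------------------------------------------------
# SMILES-level generation (exercises fingerprinting end-to-end)

#: Scaffolds covering ester, thiol, terpenoid-like bicyclic and aromatic
#: chemistry; indices into this list are assigned to families in order.
DEFAULT_SCAFFOLDS = [
    "CCOC(C)=O",        # ethyl acetate (ester)
    "CCS",              # ethanethiol (thiol)
    "C1CC2CCC1C2",      # norbornane-like bicyclic
    "Cc1ccccc1O",       # cresol (aromatic / phenol)
    "CC(=O)CC",         # butanone (ketone)
    "OCC=C",            # allyl alcohol
]


def _decorate(scaffold_smiles: str, chain_len: int, rng: np.random.Generator) -> str:
    """Attach a linear alkyl chain of ``chain_len`` carbons at a random
    substitutable carbon; ``chain_len`` 0 returns the scaffold unchanged."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise ValueError(f"invalid scaffold SMILES: {scaffold_smiles!r}")
    if chain_len == 0:
        return Chem.MolToSmiles(mol)
    rw = Chem.RWMol(mol)
    sites = [a.GetIdx() for a in rw.GetAtoms()
             if a.GetSymbol() == "C" and a.GetTotalNumHs() > 0]
    if not sites:
        return Chem.MolToSmiles(mol)
    anchor = int(rng.choice(sites))
    prev = anchor
    for _ in range(chain_len):
        idx = rw.AddAtom(Chem.Atom(6))
        rw.AddBond(prev, idx, Chem.BondType.SINGLE)
        prev = idx
    out = rw.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def generate_smiles_dataset(
    config: SyntheticConfig,
    scaffold_library: list[str] | None = None,
    max_decoration: int = 4,
) -> SyntheticDataset:
    """Like :func:`generate_dataset` but each family is a decorated scaffold.

    Every compound of family f is ``scaffold_library[f]`` with a random
    0..max_decoration-carbon unbranched chain attached, so fingerprints are
    computed from real SMILES.  Bit vectors in the returned dataset are left
    empty (compute them with the fingerprint module).
    """
    from rdkit import Chem

    scaffolds = scaffold_library if scaffold_library is not None else DEFAULT_SCAFFOLDS
    if len(scaffolds) < config.n_families:
        raise ValueError("scaffold_library must provide at least one scaffold per family")
    for s in scaffolds[: config.n_families]:
        if Chem.MolFromSmiles(s) is None:
            raise ValueError(f"invalid scaffold SMILES: {s!r}")

    base = generate_dataset(config)
    rng = np.random.default_rng(config.seed + 1)
    for i, rec in enumerate(base.records):
        fam = base.family_labels[i]
        scaffold = scaffolds[fam if fam >= 0 else int(rng.integers(config.n_families))]
        chain = int(rng.integers(0, max_decoration + 1))
        base.records[i] = replace(rec, smiles=_decorate(scaffold, chain, rng))
    return base


def write_synthetic_csv(dataset: SyntheticDataset, path, truth_path=None) -> None:
    """Write the compound table (and optionally the ground-truth families)."""
    from .table_io import write_compound_table

    write_compound_table(dataset.records, path)
    if truth_path is not None:
        import csv

        with open(truth_path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["compound_id", "family"])
            for rec, fam in zip(dataset.records, dataset.family_labels):
                writer.writerow([rec.compound_id, int(fam)])
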