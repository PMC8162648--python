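"""Core containers shared across the pipeline.

A compound is a molecule with an identifier, a SMILES string and a set of
verbal odor descriptors ("odor notes"). Compounds with no perceived smell
(salts, amino acids, polymers, ...) carry the single note ``"odorless"`` and
the ``odorless`` flag; the two representations are kept in lock-step.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field

ODORLESS = "odorless"

_WS = re.compile(r"\s+")


def normalize_note(note: str) -> str:
    """Canonical form of an odor note: lower-case, trimmed, single-spaced."""
    return _WS.sub(" ", note.strip().lower())


@dataclass
class CompoundRecord:
    """One molecule with its odor description.

    ``odor_notes`` is a set of normalized note strings.  ``odorless`` is true
    iff the compound was described odorless, in which case ``odor_notes`` is
    exactly ``{"odorless"}``.  An empty note set with ``odorless=False`` can
    only arise after vocabulary filtering (a "note-free" compound).
    """

    compound_id: str
    smiles: str
    odor_notes: set[str] = field(default_factory=set)
    odorless: bool = False

    def __post_init__(self) -> None:
        self.odor_notes = {normalize_note(n) for n in self.odor_notes if n.strip()}
        if self.odorless or self.odor_notes == {ODORLESS}:
            self.odorless = True
            self.odor_notes = {ODORLESS}


@dataclass
class OdorVocabulary:
    """The dataset-wide odor-note vocabulary with occurrence counts.

    ``notes`` is ordered by decreasing occurrence (ties alphabetical) so the
    "17 most frequent notes" style selections are reproducible.
    """

    notes: list[str]
    occurrences: dict[str, int]

    @classmethod
    def from_records(cls, records: list[CompoundRecord]) -> "OdorVocabulary":
        counts = Counter(n for r in records for n in r.odor_notes)
        ordered = sorted(counts, key=lambda n: (-counts[n], n))
        return cls(notes=ordered, occurrences=dict(counts))

    def top_notes(self, n: int) -> list[str]:
        """The ``n`` most frequent notes, ties broken alphabetically."""
        return self.notes[:n]

    def total_occurrences(self) -> int:
        return sum(self.occurrences.values())
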