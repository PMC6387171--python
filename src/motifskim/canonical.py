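"""Motif canonicalization and per-read deduplicated counting.

A tandem unit detected in a read is an arbitrary rotation of the
underlying motif on an arbitrary strand: TTA, TAT, ATT, AAT, ATA and TAA
are all the same repeat.  The canonical representative of a motif class
is obtained by reducing the motif to its primitive unit and then taking
the lexicographically smallest string (A < C < G < T) among all
rotations of the unit and all rotations of its reverse complement.

Counting is per read: a read contributes at most once to a motif's count
no matter how many arrays of that motif it contains, because read counts
feed directly into genomic-proportion estimates downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .detect import TandemHit, primitive_unit

__all__ = [
    "CanonicalMotif",
    "reverse_complement",
    "canonical_form",
    "merge_hits",
    "MergeResult",
    "COUNT_COLUMNS",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: columns of the motif-count table produced by :func:`merge_hits`
COUNT_COLUMNS = ["species", "library", "motif", "motif_length", "read_count"]


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class CanonicalMotif:
    """Rotation/strand-invariant representative of a motif class."""

    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return self.sequence


def canonical_form(motif: str) -> CanonicalMotif:
    """Canonical representative of ``motif``'s rotation/strand class.

    The motif is first reduced to its primitive unit, then the minimum
    over the 2p rotation/strand variants is taken.  Deterministic and
    idempotent; characters outside {A, C, G, T} (including N) raise
    ``ValueError`` — ambiguous consensus units are dropped upstream.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if any(c not in "ACGT" for c in motif):
        raise ValueError(f"motif {motif!r} contains characters outside ACGT")
    unit = primitive_unit(motif)
    rc = reverse_complement(unit)
    doubled, rc_doubled = unit + unit, rc + rc
    p = len(unit)
    best = min(
        min(doubled[i : i + p], rc_doubled[i : i + p]) for i in range(p)
    )
    return CanonicalMotif(best)


@dataclass
class MergeResult:
    """Motif-count table plus exclusion bookkeeping.

    ``counts`` has columns species, library, motif (canonical sequence),
    motif_length, read_count.  ``excluded_short`` counts hits whose
    canonical length fell below ``min_length``; ``excluded_ambiguous``
    counts hits whose unit contained non-ACGT characters.
    """

    counts: pd.DataFrame
    excluded_short: int = 0
    excluded_ambiguous: int = 0


def merge_hits(hits: Iterable[TandemHit], min_length: int = 3) -> MergeResult:
    """Collapse tandem hits into per-library canonical motif read counts.

    Each (read, canonical motif) pair contributes at most 1 to the
    motif's ``read_count`` regardless of how many arrays of that motif
    the read carries.  Counts from distinct libraries are kept separate.
    Motifs whose canonical (primitive) length is below ``min_length``
    are excluded and tallied, as are hits with ambiguous units.
    """
    rows = []
    excluded_short = 0
    excluded_ambiguous = 0
    for hit in hits:
        unit = hit.unit.upper()
        if any(c not in "ACGT" for c in unit):
            excluded_ambiguous += 1
            continue
        motif = canonical_form(unit)
        if motif.length < min_length:
            excluded_short += 1
            continue
        rows.append((hit.species, hit.library, hit.read_id, motif.sequence, motif.length))

    if not rows:
        counts = pd.DataFrame(columns=COUNT_COLUMNS).astype(
            {"motif_length": int, "read_count": int}
        )
        return MergeResult(counts, excluded_short, excluded_ambiguous)

    df = pd.DataFrame(rows, columns=["species", "library", "read_id", "motif", "motif_length"])
    df = df.drop_duplicates()
    counts = (
        df.groupby(["species", "library", "motif", "motif_length"], as_index=False)
        .size()
        .rename(columns={"size": "read_count"})
        .sort_values(["species", "library", "motif"], ignore_index=True)
    )[COUNT_COLUMNS]
    return MergeResult(counts, excluded_short, excluded_ambiguous)
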