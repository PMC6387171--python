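"""Base-composition statistics for consensus monomers and read sets.

GC content of satellite monomers is a simple but discriminating
descriptor: long satellites in AT-rich genomes are often markedly more
GC-rich than the genome average.  Percentages are rounded half-up to one
decimal so that printed tables reproduce exactly (e.g. 296/750 =
39.466...% -> 39.5%).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable

from .io import SequenceRead

__all__ = ["CompositionRecord", "base_composition", "readset_gc", "round_half_up"]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (half-up), to ``decimals`` places."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompositionRecord:
    """A/T and G/C composition of one sequence.

    ``n_count`` positions (N or other ambiguity codes) are excluded from
    the percentage denominator.  ``at_percent`` is defined as the
    complement of ``gc_percent`` so the two always sum to 100.0.
    """

    name: str
    monomer_length: int
    at_count: int
    gc_count: int
    gc_percent: float
    at_percent: float
    n_count: int = 0

    @classmethod
    def from_counts(
        cls, name: str, monomer_length: int, at_count: int, gc_count: int, n_count: int = 0
    ) -> "CompositionRecord":
        """Build a record from tabulated A/T and G/C counts."""
        informative = at_count + gc_count
        if informative <= 0:
            raise ValueError(f"{name!r}: no informative bases")
        gc_percent = round_half_up(100 * gc_count / informative, 1)
        return cls(
            name=name,
            monomer_length=monomer_length,
            at_count=at_count,
            gc_count=gc_count,
            gc_percent=gc_percent,
            at_percent=round(100.0 - gc_percent, 1),
            n_count=n_count,
        )


def base_composition(sequence: str, name: str = "") -> CompositionRecord:
    """A/T vs G/C composition of one sequence, percents to 1 decimal."""
    if not sequence:
        raise ValueError("sequence must be non-empty")
    seq = sequence.upper()
    at = sum(seq.count(b) for b in "AT")
    gc = sum(seq.count(b) for b in "GC")
    n = len(seq) - at - gc
    return CompositionRecord.from_counts(
        name=name, monomer_length=len(seq), at_count=at, gc_count=gc, n_count=n
    )


def readset_gc(reads: Iterable[SequenceRead]) -> float:
    """Pooled GC% over all non-N bases of a read set, to 1 decimal."""
    at = gc = 0
    seen = False
    for read in reads:
        seen = True
        seq = read.sequence.upper()
        at += seq.count("A") + seq.count("T")
        gc += seq.count("G") + seq.count("C")
    if not seen:
        raise ValueError("need at least one read")
    if at + gc == 0:
        raise ValueError("read set has no informative bases")
    return round_half_up(100 * gc / (at + gc), 1)
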