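"""Genomic-proportion and telomere-length arithmetic.

In genome skimming, the fraction of reads carrying a repeat estimates
the repeat's fraction of the genome.  With a known genome size (from the
1C value at 978 Mbp per pg) that fraction converts to absolute DNA
content in bp per haploid genome, and for a telomeric motif, dividing by
the number of chromosome ends (2x for chromosome base number x) gives
the average telomere length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import islice
from typing import Dict, Iterable, Optional, Sequence

import pandas as pd

from .canonical import canonical_form
from .detect import DetectorParams, detect_arrays_batch
from .io import SequenceRead

__all__ = [
    "BP_PER_PG",
    "GenomeModel",
    "ProportionEstimate",
    "pg_to_bp",
    "pg_to_gb",
    "round_sig",
    "estimate_proportion",
    "recalc_table",
    "count_variant_reads",
]

#: base pairs per picogram of DNA (1 pg ~ 978 Mbp)
BP_PER_PG = 978e6


def pg_to_bp(c_value_pg: float) -> int:
    """Convert a 1C value in pg to base pairs (1 pg = 978 Mbp)."""
    if c_value_pg <= 0:
        raise ValueError(f"1C value must be positive, got {c_value_pg}")
    return round(c_value_pg * BP_PER_PG)


def pg_to_gb(c_value_pg: float) -> float:
    """Convert a 1C value in pg to Gb, rounded to 2 decimals for reporting."""
    return round(pg_to_bp(c_value_pg) / 1e9, 2)


def round_sig(x: float, sig: int = 3) -> float:
    """Round to ``sig`` significant figures (0 stays 0)."""
    if x == 0:
        return 0.0
    return round(x, -int(math.floor(math.log10(abs(x)))) + (sig - 1))


@dataclass(frozen=True)
class GenomeModel:
    """Genome size model for one species.

    ``genome_bp`` is the haploid genome size used in all conversions.
    ``from_c_value`` derives it exactly from the 1C value; ``from_gb``
    takes a genome size already expressed in Gb (the form in which
    genome sizes are usually quoted, and the form whose arithmetic the
    published estimates follow).  ``x`` is the chromosome base number;
    a haploid chromosome set has ``2x`` telomere ends.
    """

    species: str
    genome_bp: int
    x: int
    c_value_pg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.genome_bp <= 0:
            raise ValueError(f"genome size must be positive, got {self.genome_bp}")
        if self.x < 1:
            raise ValueError(f"chromosome base number must be >= 1, got {self.x}")
        if self.c_value_pg is not None:
            implied = self.genome_bp / self.c_value_pg
            if abs(implied - BP_PER_PG) / BP_PER_PG > 0.005:
                raise ValueError(
                    f"genome_bp/c_value_pg = {implied:.4g} bp/pg deviates more than "
                    f"0.5% from {BP_PER_PG:.4g}"
                )

    @classmethod
    def from_c_value(cls, species: str, c_value_pg: float, x: int) -> "GenomeModel":
        return cls(species=species, genome_bp=pg_to_bp(c_value_pg), x=x, c_value_pg=c_value_pg)

    @classmethod
    def from_gb(cls, species: str, genome_gb: float, x: int) -> "GenomeModel":
        return cls(species=species, genome_bp=round(genome_gb * 1e9), x=x)

    @property
    def telomere_ends(self) -> int:
        return 2 * self.x

    @property
    def genome_gb(self) -> float:
        return round(self.genome_bp / 1e9, 2)


@dataclass(frozen=True)
class ProportionEstimate:
    """Read-count-derived genomic proportion and absolute DNA content.

    ``percent`` is reported at 3 significant figures; ``bp_per_haploid``
    and ``bp_per_telomere`` are unrounded (use the ``kb_*`` properties
    for 3-decimal kb display).  ``bp_per_telomere`` is only meaningful
    for telomeric motifs.
    """

    motif: str
    reads_detected: int
    total_reads: int
    genome: GenomeModel
    fraction: float
    percent: float
    bp_per_haploid: float
    bp_per_telomere: float
    rounding: str = "unrounded"

    @property
    def kb_per_haploid(self) -> float:
        return round(self.bp_per_haploid / 1000, 3)

    @property
    def kb_per_telomere(self) -> float:
        return round(self.bp_per_telomere / 1000, 3)


def estimate_proportion(
    reads_detected: int,
    total_reads: int,
    genome: GenomeModel,
    rounding: str = "unrounded",
    motif: str = "",
) -> ProportionEstimate:
    """Convert a read count into genomic proportion and DNA content.

    ``rounding`` selects where the percent rounding enters the bp
    arithmetic: ``"unrounded"`` (default) computes bp from the exact
    fraction; ``"percent_3sf"`` computes bp from the percent already
    rounded to 3 significant figures (the order of operations behind
    some published telomere estimates).  The displayed percent is always
    3 significant figures.
    """
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    if reads_detected < 0 or reads_detected > total_reads:
        raise ValueError(
            f"reads_detected must be in [0, total_reads], got {reads_detected}/{total_reads}"
        )
    if rounding not in ("unrounded", "percent_3sf"):
        raise ValueError(f"unknown rounding mode {rounding!r}")
    fraction = reads_detected / total_reads
    percent = round_sig(100 * fraction, 3)
    if rounding == "percent_3sf":
        bp_per_haploid = (percent / 100) * genome.genome_bp
    else:
        bp_per_haploid = fraction * genome.genome_bp
    bp_per_telomere = bp_per_haploid / genome.telomere_ends
    return ProportionEstimate(
        motif=motif,
        reads_detected=reads_detected,
        total_reads=total_reads,
        genome=genome,
        fraction=fraction,
        percent=percent,
        bp_per_haploid=bp_per_haploid,
        bp_per_telomere=bp_per_telomere,
        rounding=rounding,
    )


def recalc_table(genome_bp: float, sample_reads: int) -> pd.DataFrame:
    """Decade grid mapping read counts to genomic proportion and bp.

    For reads_detected in 1, 10, 100, ... up to ``sample_reads``:
    relative_frequency = reads/sample_reads, percent = 100x that, and
    bp_per_genome = relative_frequency x genome_bp.
    """
    if sample_reads <= 0:
        raise ValueError(f"sample_reads must be positive, got {sample_reads}")
    rows = []
    reads = 1
    while reads <= sample_reads:
        freq = reads / sample_reads
        rows.append(
            {
                "reads_detected": reads,
                "relative_frequency": freq,
                "percent": 100 * freq,
                "bp_per_genome": freq * genome_bp,
            }
        )
        reads *= 10
    return pd.DataFrame(rows)


def _batched(iterable: Iterable, size: int):
    it = iter(iterable)
    while True:
        chunk = list(islice(it, size))
        if not chunk:
            return
        yield chunk


def count_variant_reads(
    reads: Iterable[SequenceRead],
    variant_motif: str,
    params: DetectorParams | None = None,
    batch_size: int = 4096,
) -> Dict[str, int]:
    """Count reads per library carrying arrays of one named motif.

    Rotation- and strand-insensitive: a read is counted when any of its
    detected arrays canonicalizes to ``canonical_form(variant_motif)``.
    Each read counts at most once in its library.
    """
    params = params or DetectorParams()
    if not params.min_unit <= len(variant_motif) <= params.max_unit:
        raise ValueError(
            f"variant motif length {len(variant_motif)} outside detector window "
            f"[{params.min_unit}, {params.max_unit}]"
        )
    target = canonical_form(variant_motif)
    counts: Dict[str, int] = {}
    for chunk in _batched(reads, batch_size):
        for read, hits in zip(chunk, detect_arrays_batch(chunk, params)):
            for hit in hits:
                if set(hit.unit) <= set("ACGT") and canonical_form(hit.unit) == target:
                    counts[read.library] = counts.get(read.library, 0) + 1
                    break
    return counts
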