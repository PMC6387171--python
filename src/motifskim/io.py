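"""Read input/output: FASTQ/FASTA streaming, subsampling, and import of
Tandem Repeats Finder ``.dat`` output.

Reads are tagged with a library label at load time (one label per input
file, mirroring the convention of prefixing read headers by
sample-library), never parsed out of the identifiers.  Pair-mate
information is carried along when recognisable from the id suffix but is
ignored by the tandem-motif pipeline.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator, List, Optional

from Bio import SeqIO

__all__ = [
    "SequenceRead",
    "read_sequences",
    "write_fastq",
    "sample_reads",
    "import_trf_dat",
    "export_trf_dat",
    "TrfImportResult",
]

_FASTA_EXTS = {".fasta", ".fa", ".fna", ".ffn", ".frn"}
_FASTQ_EXTS = {".fastq", ".fq"}


@dataclass(frozen=True)
class SequenceRead:
    """A single sequencing read.

    ``pair_mate`` is 1, 2, or None; it is recorded when the id ends in
    ``/1`` or ``/2`` but plays no role downstream (tandem motifs are
    counted per read regardless of mate pairing).
    """

    id: str
    sequence: str
    library: str = ""
    species: str = ""
    pair_mate: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r} has an empty sequence")


def _mate_from_id(read_id: str) -> Optional[int]:
    if read_id.endswith("/1"):
        return 1
    if read_id.endswith("/2"):
        return 2
    return None


def _open_maybe_gzip(path: Path) -> IO[str]:
    with open(path, "rb") as probe:
        magic = probe.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _sniff_format(path: Path) -> str:
    suffixes = [s.lower() for s in path.suffixes]
    if suffixes and suffixes[-1] == ".gz":
        suffixes = suffixes[:-1]
    if suffixes:
        if suffixes[-1] in _FASTQ_EXTS:
            return "fastq"
        if suffixes[-1] in _FASTA_EXTS:
            return "fasta"
    with _open_maybe_gzip(path) as handle:
        for line in handle:
            if line.strip():
                first = line.lstrip()[0]
                if first == "@":
                    return "fastq"
                if first == ">":
                    return "fasta"
                break
    raise ValueError(f"cannot detect sequence format of {path}")


def read_sequences(
    path: str | Path,
    format: str = "auto",
    library: str = "",
    species: str = "",
) -> Iterator[SequenceRead]:
    """Stream reads from a FASTA/FASTQ file (plain or gzipped).

    Sequences are uppercased; ids are preserved verbatim.  An empty file
    yields an empty stream.  A malformed record raises ``ValueError``
    naming the 1-based record index at which parsing failed.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        try:
            format = _sniff_format(path)
        except ValueError:
            if path.stat().st_size == 0:
                return
            raise
    if format not in ("fastq", "fasta"):
        raise ValueError(f"unsupported format {format!r}")

    with _open_maybe_gzip(path) as handle:
        parser = SeqIO.parse(handle, format)
        index = 0
        while True:
            index += 1
            try:
                record = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise ValueError(
                    f"malformed {format} record {index} in {path}: {exc}"
                ) from exc
            yield SequenceRead(
                id=record.id,
                sequence=str(record.seq).upper(),
                library=library,
                species=species,
                pair_mate=_mate_from_id(record.id),
            )


def write_fastq(reads: Iterable[SequenceRead], path: str | Path, quality_char: str = "I") -> None:
    """Write reads as FASTQ with a constant quality string (gzip if *.gz)."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "wt") as handle:
        for read in reads:
            handle.write(f"@{read.id}\n{read.sequence}\n+\n{quality_char * len(read.sequence)}\n")


def sample_reads(stream: Iterable[SequenceRead], n: int, seed: int) -> List[SequenceRead]:
    """Reservoir-sample exactly min(n, available) reads without replacement.

    Reproducible for a fixed seed; the relative order of the retained
    reads follows reservoir slot assignment, not file order.
    """
    if n < 0:
        raise ValueError(f"sample size must be >= 0, got {n}")
    rng = random.Random(seed)
    reservoir: List[SequenceRead] = []
    for i, read in enumerate(stream):
        if i < n:
            reservoir.append(read)
        else:
            j = rng.randrange(i + 1)
            if j < n:
                reservoir[j] = read
    return reservoir


@dataclass
class TrfImportResult:
    """Hits kept from a ``.dat`` file plus a count of filtered rows."""

    hits: list
    skipped: int


def import_trf_dat(
    path: str | Path,
    min_period: int = 3,
    max_period: int = 55,
    min_copies: float = 3.0,
) -> TrfImportResult:
    """Import Tandem Repeats Finder ``.dat`` output.

    Understands both the classic ``Sequence: <id>`` headers and the
    ``@<id>`` headers of -ngs mode.  Rows whose period falls outside
    ``[min_period, max_period]`` or whose copy number is below
    ``min_copies`` are dropped and counted in the result's ``skipped``
    field.  A row that starts like a data row but cannot be parsed
    raises ``ValueError`` with its line number.
    """
    from .detect import TandemHit  # deferred: avoid import cycle

    path = Path(path)
    hits: List[TandemHit] = []
    skipped = 0
    read_id: Optional[str] = None
    with _open_maybe_gzip(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("Sequence:"):
                read_id = stripped.split(":", 1)[1].split()[0]
                continue
            if stripped.startswith("@"):
                read_id = stripped[1:].split()[0]
                continue
            if not stripped[0].isdigit():
                continue  # preamble (program banner, parameters, ...)
            fields = stripped.split()
            try:
                if len(fields) < 14:
                    raise ValueError(f"expected >= 14 fields, found {len(fields)}")
                start_1b = int(fields[0])
                end_1b = int(fields[1])
                period = int(fields[2])
                copies = float(fields[3])
                pct_match = float(fields[5])
                consensus = fields[13].upper()
            except ValueError as exc:
                raise ValueError(f"unparseable row at line {lineno} of {path}: {exc}") from exc
            if read_id is None:
                raise ValueError(f"data row before any sequence header at line {lineno} of {path}")
            if period < min_period or period > max_period or copies < min_copies:
                skipped += 1
                continue
            span = end_1b - start_1b + 1
            hits.append(
                TandemHit(
                    read_id=read_id,
                    start=start_1b - 1,
                    end=end_1b,
                    unit=consensus,
                    copies=copies,
                    mismatches=int(round((1.0 - pct_match / 100.0) * span)),
                )
            )
    return TrfImportResult(hits=hits, skipped=skipped)


def export_trf_dat(hits: Iterable, path: str | Path) -> None:
    """Write hits back out in the ``.dat`` dialect (``@id`` headers).

    Round-trips with :func:`import_trf_dat` on coordinates, period,
    copies, and consensus.
    """
    path = Path(path)
    with open(path, "wt") as handle:
        current = None
        for hit in hits:
            if hit.read_id != current:
                handle.write(f"@{hit.read_id}\n")
                current = hit.read_id
            unit = hit.unit
            span = hit.end - hit.start
            pct_match = 100.0 * (1.0 - hit.mismatches / span) if span else 100.0
            comp = {b: 100 * unit.count(b) // len(unit) for b in "ACGT"}
            handle.write(
                f"{hit.start + 1} {hit.end} {len(unit)} {hit.copies:.1f} "
                f"{len(unit)} {pct_match:.0f} 0 {2 * span} "
                f"{comp['A']} {comp['C']} {comp['G']} {comp['T']} 1.90 "
                f"{unit} {unit * int(hit.copies)}\n"
            )
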