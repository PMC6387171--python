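"""Synthetic read-set generator with a machine-readable truth table.

Emulates genome-skimming libraries from a large AT-rich genome: 151-nt
reads whose background bases are i.i.d. at a configurable GC content
(default 33%), with planted tandem-repeat families (unit 3-55 nt,
variable copy number and per-base divergence) and telomere-motif reads
at stated fractions, organised as several technical-replicate libraries
per species drawn from the same family mix.  An optional outlier
injection multiplies one family's fraction in one library, mimicking a
library-preparation artefact.

Planted arrays are inserted at uniform random strand and rotation so
that downstream canonicalization is genuinely exercised.  Everything is
deterministic for a fixed seed: regeneration reproduces files
byte-for-byte.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .canonical import canonical_form, reverse_complement
from .io import SequenceRead, write_fastq

__all__ = [
    "PlantedFamily",
    "OutlierInjection",
    "SimConfig",
    "SimResult",
    "simulate_reads",
    "simulate_readset",
    "make_paper_fixture",
    "FIXTURE_SEED",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: fixed seed used by :func:`make_paper_fixture`
FIXTURE_SEED = 7331


@dataclass(frozen=True)
class PlantedFamily:
    """One tandem-repeat family to plant.

    ``fraction`` is the per-read probability that a read carries an
    array of this family.  ``copy_range`` bounds the (integer) copy
    number drawn per read; by default 3 up to as many full units as fit
    in the read.  ``substitution_rate`` applies uniform per-base
    substitutions to the planted array.
    """

    motif: str
    fraction: float
    substitution_rate: float = 0.0
    copy_range: Optional[Tuple[int, int]] = None


@dataclass(frozen=True)
class OutlierInjection:
    """Multiply one family's fraction in one library (0-based index)."""

    library_index: int
    motif: str
    multiplier: float


@dataclass(frozen=True)
class SimConfig:
    """Configuration of one simulated species.

    Defaults mirror the emulated study design: 151-nt reads, three
    technical-replicate libraries per species, 33% GC background.
    """

    seed: int
    species: str = "species1"
    n_reads: int = 10_000
    read_length: int = 151
    n_libraries: int = 3
    background_gc: float = 0.33
    families: Tuple[PlantedFamily, ...] = ()
    telomere_fractions: Tuple[Tuple[str, float], ...] = ()
    outlier: Optional[OutlierInjection] = None
    library_names: Optional[Tuple[str, ...]] = None

    def __post_init__(self) -> None:
        if self.n_reads < 0 or self.n_libraries < 1:
            raise ValueError("n_reads must be >= 0 and n_libraries >= 1")
        if not 0.0 <= self.background_gc <= 1.0:
            raise ValueError(f"background_gc must be in [0,1], got {self.background_gc}")
        fams = self.all_families()
        for fam in fams:
            if not fam.motif or any(c not in "ACGT" for c in fam.motif):
                raise ValueError(f"planted motif {fam.motif!r} must be over ACGT")
            if not 0.0 <= fam.substitution_rate <= 0.2:
                raise ValueError(
                    f"substitution rate must be in [0, 0.2], got {fam.substitution_rate}"
                )
            if self.read_length < 3 * len(fam.motif):
                raise ValueError(
                    f"read_length {self.read_length} cannot hold 3 copies of "
                    f"{fam.motif!r} ({len(fam.motif)} nt)"
                )
        for li in range(self.n_libraries):
            total = sum(f.fraction for f in self.library_families(li))
            if total > 1.0 + 1e-12:
                raise ValueError(
                    f"planted fractions sum to {total:.4g} > 1 in library index {li}"
                )
        if self.library_names is not None and len(self.library_names) != self.n_libraries:
            raise ValueError("library_names length must equal n_libraries")

    def all_families(self) -> Tuple[PlantedFamily, ...]:
        telo = tuple(
            PlantedFamily(motif=m, fraction=f) for m, f in self.telomere_fractions
        )
        return self.families + telo

    def library_families(self, library_index: int) -> Tuple[PlantedFamily, ...]:
        """Effective families for one library, with any outlier applied."""
        fams = self.all_families()
        out = self.outlier
        if out is None or out.library_index != library_index:
            return fams
        boosted = []
        for fam in fams:
            if fam.motif == out.motif:
                fam = PlantedFamily(
                    motif=fam.motif,
                    fraction=fam.fraction * out.multiplier,
                    substitution_rate=fam.substitution_rate,
                    copy_range=fam.copy_range,
                )
            boosted.append(fam)
        return tuple(boosted)

    def library_name(self, library_index: int) -> str:
        if self.library_names is not None:
            return self.library_names[library_index]
        return f"L{library_index + 1}"


@dataclass
class SimResult:
    """Simulated reads (or file paths) plus the planting truth table."""

    reads: Dict[str, List[SequenceRead]]
    truth: pd.DataFrame
    fastq_paths: Dict[str, Path] = field(default_factory=dict)
    truth_path: Optional[Path] = None


def _library_rng(seed: int, species: str, library_index: int) -> np.random.Generator:
    species_key = zlib.crc32(species.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, species_key, library_index]))


def _plant_array(
    row: np.ndarray, motif: str, fam: PlantedFamily, rng: np.random.Generator
) -> None:
    p = len(motif)
    read_len = row.size
    cmin, cmax = fam.copy_range or (3, read_len // p)
    cmax = min(cmax, read_len // p)
    cmin = max(3, cmin)
    copies = int(rng.integers(cmin, cmax + 1))
    span = copies * p
    strand = int(rng.integers(2))
    unit = motif if strand == 0 else reverse_complement(motif)
    rot = int(rng.integers(p))
    unit = unit[rot:] + unit[:rot]
    arr = np.frombuffer((unit * copies).encode("ascii"), dtype=np.uint8).copy()
    if fam.substitution_rate > 0:
        sub_mask = rng.random(span) < fam.substitution_rate
        idx = np.nonzero(sub_mask)[0]
        if idx.size:
            base_idx = np.searchsorted(_BASES, arr[idx])
            shift = rng.integers(1, 4, size=idx.size)
            arr[idx] = _BASES[(base_idx + shift) % 4]
    offset = int(rng.integers(0, read_len - span + 1))
    row[offset : offset + span] = arr


def simulate_reads(config: SimConfig) -> SimResult:
    """Generate all libraries of one species in memory.

    Each read is assigned to a planted family (or background) by a
    categorical draw with the configured fractions; planted reads carry
    one array of their family's motif at random strand, rotation, copy
    number, and offset, with substitutions at the family's rate.  The
    truth table records realized planted read counts per (species,
    library, canonical motif) alongside the configured fraction.
    """
    gc = config.background_gc
    probs_bg = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    reads_by_library: Dict[str, List[SequenceRead]] = {}
    truth_rows = []
    for li in range(config.n_libraries):
        rng = _library_rng(config.seed, config.species, li)
        lib = config.library_name(li)
        fams = config.library_families(li)
        fracs = np.array([f.fraction for f in fams], dtype=float)
        # index len(fams) = background
        p_assign = np.append(fracs, max(1.0 - fracs.sum(), 0.0))
        p_assign = p_assign / p_assign.sum()
        assign = rng.choice(len(fams) + 1, size=config.n_reads, p=p_assign)
        mat = _BASES[rng.choice(4, size=(config.n_reads, config.read_length), p=probs_bg)]
        planted_counts = np.zeros(len(fams), dtype=int)
        for i in np.nonzero(assign < len(fams))[0]:
            fam = fams[assign[i]]
            _plant_array(mat[i], fam.motif, fam, rng)
            planted_counts[assign[i]] += 1
        reads = [
            SequenceRead(
                id=f"{config.species}.{lib}.{i:06d}",
                sequence=mat[i].tobytes().decode("ascii"),
                library=lib,
                species=config.species,
            )
            for i in range(config.n_reads)
        ]
        reads_by_library[lib] = reads
        for fam, count in zip(fams, planted_counts):
            truth_rows.append(
                {
                    "species": config.species,
                    "library": lib,
                    "motif": canonical_form(fam.motif).sequence,
                    "planted_reads": int(count),
                    "planted_fraction": fam.fraction,
                    "substitution_rate": fam.substitution_rate,
                }
            )
    truth = pd.DataFrame(
        truth_rows,
        columns=[
            "species",
            "library",
            "motif",
            "planted_reads",
            "planted_fraction",
            "substitution_rate",
        ],
    )
    return SimResult(reads=reads_by_library, truth=truth)


def simulate_readset(
    config: SimConfig, out_dir: str | Path, gzip_output: bool = False
) -> SimResult:
    """Simulate one species and write FASTQ files plus the truth table.

    Writes ``<species>_<library>.fastq[.gz]`` per library,
    ``<species>_truth.tsv``, and ``<species>_config.json``.  The
    configuration is validated (including fraction feasibility) before
    any file is written; regeneration with the same config is
    byte-identical.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    result = simulate_reads(config)
    suffix = ".fastq.gz" if gzip_output else ".fastq"
    for lib, reads in result.reads.items():
        path = out_dir / f"{config.species}_{lib}{suffix}"
        write_fastq(reads, path)
        result.fastq_paths[lib] = path
    truth_path = out_dir / f"{config.species}_truth.tsv"
    result.truth.to_csv(truth_path, sep="\t", index=False)
    result.truth_path = truth_path
    config_path = out_dir / f"{config.species}_config.json"
    with open(config_path, "w") as handle:
        json.dump(asdict(config), handle, indent=2, default=str)
    return result


def _fixture_configs(n_reads: int = 10_000, seed: int = FIXTURE_SEED) -> List[SimConfig]:
    """Three-species fixture configs with distinguishable planted mixes.

    The planted motifs echo the kinds of repeat the pipeline targets: an
    abundant tetranucleotide (TTAA), a pentanucleotide (ATCCG), a 27-nt
    species-enriched satellite monomer, the 12-nt telomeric minisatellite
    (CTCGGTTATGGG, planted in every species), and a trace ancestral-type
    telomere variant (TTTAGGG).
    """
    sat27 = "AATCGTTTTCAATTCAATTCATTTCGA"
    telo = "CTCGGTTATGGG"
    return [
        SimConfig(
            seed=seed,
            species="speciesA",
            n_reads=n_reads,
            library_names=("S1", "S2", "S3"),
            families=(
                PlantedFamily("TTAA", 0.020),
                PlantedFamily("ATCCG", 0.008),
                PlantedFamily(sat27, 0.001),
            ),
            telomere_fractions=((telo, 0.003), ("TTTAGGG", 0.0005)),
        ),
        SimConfig(
            seed=seed,
            species="speciesB",
            n_reads=n_reads,
            library_names=("S4", "S5", "S6"),
            families=(
                PlantedFamily("ATCCG", 0.018),
                PlantedFamily("TTAA", 0.004),
                PlantedFamily(sat27, 0.002),
            ),
            telomere_fractions=((telo, 0.006), ("TTTAGGG", 0.0005)),
        ),
        SimConfig(
            seed=seed,
            species="speciesC",
            n_reads=n_reads,
            library_names=("S7", "S8", "S9"),
            families=(
                PlantedFamily(sat27, 0.025),
                PlantedFamily("TTAA", 0.001),
                PlantedFamily("ATCCG", 0.002),
            ),
            telomere_fractions=((telo, 0.004), ("TTTAGGG", 0.0005)),
        ),
    ]


def make_paper_fixture(
    out_dir: Optional[str | Path] = None,
    n_reads: int = 10_000,
    seed: int = FIXTURE_SEED,
) -> Dict[str, SimResult]:
    """Deterministic three-species demonstration dataset.

    3 species x 3 libraries x ``n_reads`` 151-nt reads with planted
    repeat families at distinguishable fractions and the telomeric
    minisatellite in every species.  Returns results keyed by species;
    with ``out_dir`` set, FASTQ files and truth tables are written
    there.  Regeneration with the same seed is byte-identical.
    """
    results: Dict[str, SimResult] = {}
    for config in _fixture_configs(n_reads=n_reads, seed=seed):
        if out_dir is None:
            results[config.species] = simulate_reads(config)
        else:
            results[config.species] = simulate_readset(config, out_dir)
    return results
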