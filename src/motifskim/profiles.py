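"""Comparative per-species motif summaries.

Builds the comparative views of a motif-count table: per-length
abundance (reads carrying motifs of each unit length) and diversity
(distinct canonical motifs per unit length), cross-species sharing
partitions (Venn regions), top-motif rankings, and a replicate-library
outlier flag for triplicate count patterns.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Set, Tuple

import pandas as pd

__all__ = [
    "SpeciesProfile",
    "length_profiles",
    "shared_motifs",
    "top_motifs",
    "flag_outlier_library",
    "plot_length_profile",
]


@dataclass
class SpeciesProfile:
    """Per-species motif catalog with derived length profiles.

    ``counts`` holds one row per (library, motif) with read counts;
    ``length_abundance`` maps unit length -> total read count pooled
    over motifs and libraries; ``length_diversity`` maps unit length ->
    number of distinct canonical motifs of that length.
    """

    species: str
    counts: pd.DataFrame
    length_abundance: Dict[int, int] = field(default_factory=dict)
    length_diversity: Dict[int, int] = field(default_factory=dict)

    @property
    def motifs(self) -> Set[str]:
        if self.counts.empty:
            return set()
        return set(self.counts["motif"])

    def pooled_counts(self) -> pd.DataFrame:
        """Motif counts summed over libraries."""
        if self.counts.empty:
            return pd.DataFrame(columns=["motif", "motif_length", "read_count"])
        return (
            self.counts.groupby(["motif", "motif_length"], as_index=False)["read_count"]
            .sum()
        )


def length_profiles(counts: pd.DataFrame, species: str | None = None) -> SpeciesProfile:
    """Build a :class:`SpeciesProfile` from a single-species count table.

    Abundance sums read counts by motif length (pooled over libraries);
    diversity counts distinct canonical motifs by length.  A table
    containing more than one species raises ``ValueError``.
    """
    if counts.empty:
        return SpeciesProfile(species=species or "", counts=counts.copy())
    seen = counts["species"].unique()
    if len(seen) > 1:
        raise ValueError(f"expected counts from one species, found {sorted(seen)}")
    if species is None:
        species = str(seen[0])
    abundance = counts.groupby("motif_length")["read_count"].sum()
    diversity = counts.groupby("motif_length")["motif"].nunique()
    return SpeciesProfile(
        species=species,
        counts=counts.copy(),
        length_abundance={int(k): int(v) for k, v in abundance.items()},
        length_diversity={int(k): int(v) for k, v in diversity.items()},
    )


def shared_motifs(
    profiles: Sequence[SpeciesProfile], presence_threshold: int = 1
) -> Dict[Tuple[str, ...], Set[str]]:
    """Partition the union of motif catalogs into Venn regions.

    A motif is present in a species when its pooled read count is at
    least ``presence_threshold`` (default 1 read).  Every motif in the
    union is assigned to exactly one region, keyed by the sorted tuple
    of species in which it is present; all non-empty species subsets
    appear as keys, possibly with empty sets.  Region sizes therefore
    sum to the union size.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two species profiles")
    names = [p.species for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate species in profiles: {names}")
    present: Dict[str, Set[str]] = {}
    for prof in profiles:
        pooled = prof.pooled_counts()
        if pooled.empty:
            present[prof.species] = set()
        else:
            keep = pooled["read_count"] >= presence_threshold
            present[prof.species] = set(pooled.loc[keep, "motif"])

    regions: Dict[Tuple[str, ...], Set[str]] = {}
    n = len(names)
    for mask in range(1, 2**n):
        key = tuple(sorted(names[i] for i in range(n) if mask & (1 << i)))
        regions[key] = set()
    union = set().union(*present.values())
    for motif in union:
        key = tuple(sorted(sp for sp in names if motif in present[sp]))
        regions[key].add(motif)
    return regions


def top_motifs(profile: SpeciesProfile, k: int) -> pd.DataFrame:
    """Top-k motifs by pooled read count, ties broken lexicographically."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    pooled = profile.pooled_counts()
    if pooled.empty:
        return pooled
    return (
        pooled.sort_values(["read_count", "motif"], ascending=[False, True])
        .head(k)
        .reset_index(drop=True)
    )


def flag_outlier_library(
    replicate_counts: Sequence[float],
    fold: float = 10.0,
    min_excess: float = 50.0,
) -> Set[int]:
    """Flag replicate libraries with an implausibly inflated count.

    For one motif counted across >= 3 replicate libraries of the same
    species, a library is flagged when its count exceeds ``fold`` times
    the replicate median AND exceeds the median by at least
    ``min_excess`` reads.  Both conditions together keep small-count
    jitter (e.g. 1 vs 8 reads) from being flagged while catching
    hundredfold artefacts.  Returns 0-based indices of flagged
    libraries.
    """
    if len(replicate_counts) < 3:
        raise ValueError(
            f"outlier rule is defined for >= 3 replicates, got {len(replicate_counts)}"
        )
    med = statistics.median(replicate_counts)
    return {
        i
        for i, count in enumerate(replicate_counts)
        if count > fold * med and (count - med) >= min_excess
    }


def plot_length_profile(profile: SpeciesProfile, kind: str = "abundance", ax=None):
    """Bar chart of a length profile (cosmetic helper; needs matplotlib)."""
    import matplotlib.pyplot as plt

    data = profile.length_abundance if kind == "abundance" else profile.length_diversity
    if ax is None:
        _, ax = plt.subplots()
    lengths = sorted(data)
    ax.bar(lengths, [data[L] for L in lengths])
    ax.set_xlabel("motif length (nt)")
    ax.set_ylabel("reads" if kind == "abundance" else "distinct motifs")
    ax.set_title(profile.species)
    return ax
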