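"""Tandem-array detection inside individual sequencing reads.

A short tandem motif (STM) is a repeat unit of 3-55 nt occurring in at
least three adjacent copies within a read.  Detection works directly on
unassembled reads: for each candidate period ``p`` the read is compared
against itself shifted by ``p`` and maximal self-matching runs long
enough to contain ``min_copies`` full units are reported.

Two detection routes exist on purpose:

* :func:`detect_arrays` / :func:`detect_arrays_batch` -- the production
  implementation (vectorized over periods and reads with numpy).
* :func:`brute_force_detect` -- an independent, deliberately naive
  per-position oracle used to verify the production route on small reads.

Exact matching is the default; an approximate mode tolerates a bounded
per-array mismatch fraction against the majority-vote periodic consensus
(substitutions only, no indels).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Sequence

import numpy as np

from .io import SequenceRead

__all__ = [
    "DetectorParams",
    "TandemHit",
    "primitive_unit",
    "detect_arrays",
    "detect_arrays_batch",
    "brute_force_detect",
]

# base -> small integer code; 0 is the "never matches" sentinel used for
# N, padding, and any unexpected character
_CODE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate("ACGT", start=1):
    _CODE[ord(_b)] = _i
_DECODE = np.frombuffer(b"?ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class DetectorParams:
    """Detection thresholds.

    Parameters
    ----------
    min_unit, max_unit:
        Inclusive bounds on the repeat-unit (period) length in nt.  The
        default window is 3-52; the upper bound can be raised to 55 to
        mirror a wider external-detector MaxPeriod setting.
    min_copies:
        Minimum number of full unit copies an array must span.
    max_mismatch_fraction:
        0 selects exact matching.  A positive value enables approximate
        detection: an array is accepted when its mismatch count against
        the majority-vote periodic consensus is at most this fraction of
        the array span.
    """

    min_unit: int = 3
    max_unit: int = 52
    min_copies: int = 3
    max_mismatch_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.min_unit < 1 or self.min_unit > self.max_unit:
            raise ValueError(
                f"require 1 <= min_unit <= max_unit, got {self.min_unit}..{self.max_unit}"
            )
        if self.min_copies < 2:
            raise ValueError(f"min_copies must be >= 2, got {self.min_copies}")
        if not 0.0 <= self.max_mismatch_fraction <= 1.0:
            raise ValueError(
                f"max_mismatch_fraction must be in [0, 1], got {self.max_mismatch_fraction}"
            )


@dataclass
class TandemHit:
    """One detected tandem array within a read.

    Coordinates are 0-based, half-open, on the read as given in the
    input file.  ``unit`` is the array's monomer as oriented in the read
    (exact mode: the first period of the array; approximate mode: the
    majority-vote consensus).  ``copies`` is span / unit length and may
    be fractional when a trailing partial unit extends the array.
    """

    read_id: str
    start: int
    end: int
    unit: str
    copies: float
    mismatches: int = 0
    library: str = ""
    species: str = ""

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def unit_length(self) -> int:
        return len(self.unit)


def primitive_unit(motif: str) -> str:
    """Shortest string whose integer repetition reconstructs ``motif``.

    ``"ACGACG" -> "ACG"``; a primitive motif is returned unchanged.
    Idempotent.
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    n = len(motif)
    for d in range(1, n // 2 + 1):
        if n % d == 0 and motif[:d] * (n // d) == motif:
            return motif[:d]
    return motif


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def detect_arrays(read: SequenceRead, params: DetectorParams | None = None) -> List[TandemHit]:
    """Detect all maximal tandem arrays in one read.

    Exact mode reports every maximal substring with primitive period
    ``p`` in ``[min_unit, max_unit]`` spanning at least
    ``min_copies * p`` nt, exactly once, sorted by start.  Overlapping
    arrays with different primitive periods are all reported.  Reads
    shorter than ``min_copies * min_unit`` yield an empty list.
    """
    params = params or DetectorParams()
    if params.max_mismatch_fraction > 0:
        return _detect_approx_read(read, params)
    return detect_arrays_batch([read], params)[0]


def detect_arrays_batch(
    reads: Sequence[SequenceRead], params: DetectorParams | None = None
) -> List[List[TandemHit]]:
    """Vectorized exact detection over a batch of reads.

    Returns one hit list per input read, in input order.  With a
    positive ``max_mismatch_fraction`` each read falls back to the
    per-read approximate scanner.
    """
    params = params or DetectorParams()
    if params.max_mismatch_fraction > 0:
        return [_detect_approx_read(r, params) for r in reads]
    if not reads:
        return []

    seqs = [r.sequence for r in reads]
    n = len(seqs)
    maxlen = max(len(s) for s in seqs)
    out: List[List[TandemHit]] = [[] for _ in range(n)]
    if maxlen < params.min_copies * params.min_unit:
        return out

    mat = np.zeros((n, maxlen), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = _encode(s)

    p_hi = min(params.max_unit, maxlen // params.min_copies)
    for p in range(params.min_unit, p_hi + 1):
        left = mat[:, :-p]
        right = mat[:, p:]
        # equal and non-sentinel: N and padding never match anything
        eq = (left == right) & (right != 0)
        padded = np.zeros((n, eq.shape[1] + 2), dtype=np.int8)
        padded[:, 1:-1] = eq
        diff = np.diff(padded, axis=1)
        run_rows, run_starts = np.nonzero(diff == 1)
        _, run_ends = np.nonzero(diff == -1)
        min_run = (params.min_copies - 1) * p
        keep = (run_ends - run_starts) >= min_run
        for r, a, b in zip(run_rows[keep], run_starts[keep], run_ends[keep]):
            unit = seqs[r][a : a + p]
            if primitive_unit(unit) != unit:
                continue
            span = int(b - a) + p
            rd = reads[r]
            out[r].append(
                TandemHit(
                    read_id=rd.id,
                    start=int(a),
                    end=int(a) + span,
                    unit=unit,
                    copies=span / p,
                    mismatches=0,
                    library=rd.library,
                    species=rd.species,
                )
            )
    for hits in out:
        hits.sort(key=lambda h: (h.start, len(h.unit)))
    return out


def _true_runs(mask: np.ndarray) -> List[tuple[int, int]]:
    """Maximal runs of True in a 1-D boolean array as (start, stop)."""
    padded = np.zeros(mask.size + 2, dtype=np.int8)
    padded[1:-1] = mask
    diff = np.diff(padded)
    starts = np.nonzero(diff == 1)[0]
    stops = np.nonzero(diff == -1)[0]
    return list(zip(starts.tolist(), stops.tolist()))


def _detect_approx_read(read: SequenceRead, params: DetectorParams) -> List[TandemHit]:
    """Approximate per-read scanner.

    Exact self-match runs at each period are greedily merged across gaps
    of at most two positions (the footprint of an isolated substitution
    in the lag-p match profile), then the merged region is accepted if
    its mismatch count against the majority-vote periodic consensus is
    within budget.  Substitutions only; indels shift the phase and
    truncate arrays instead of being absorbed.
    """
    s = read.sequence
    length = len(s)
    hits: List[TandemHit] = []
    if length < params.min_copies * params.min_unit:
        return hits
    codes = _encode(s)
    frac = params.max_mismatch_fraction
    p_hi = min(params.max_unit, length // params.min_copies)
    for p in range(params.min_unit, p_hi + 1):
        eq = (codes[:-p] == codes[p:]) & (codes[p:] != 0) & (codes[:-p] != 0)
        runs = _true_runs(eq)
        if not runs:
            continue
        # group exact runs across gaps of <= 2 lag positions (the
        # footprint of an isolated substitution); noise runs further
        # away stay separate
        groups: List[List[tuple[int, int]]] = [[runs[0]]]
        for a, b in runs[1:]:
            if a - groups[-1][-1][1] <= 2:
                groups[-1].append((a, b))
            else:
                groups.append([(a, b)])
        accepted: List[tuple[int, int]] = []  # (start, end) in read space
        for group in groups:
            if (group[-1][1] - group[0][0]) + p < params.min_copies * p:
                continue
            # the full group may be too divergent while a sub-window
            # qualifies: enumerate windows over run boundaries, widest
            # first, and keep maximal qualifying ones
            k = len(group)
            windows = [
                (group[i][0], group[j][1])
                for i in range(k)
                for j in range(i, k)
            ]
            windows.sort(key=lambda w: w[0] - w[1])  # widest first
            for a, b in windows:
                span = (b - a) + p
                if span < params.min_copies * p:
                    continue
                if any(a >= wa and (a + span) <= wb for wa, wb in accepted):
                    continue
                seg = codes[a : a + span]
                cons = np.empty(p, dtype=np.uint8)
                degenerate = False
                for c in range(p):
                    col = seg[c::p]
                    col = col[col != 0]
                    if col.size == 0:
                        degenerate = True
                        break
                    # majority vote; ties broken toward the smaller base code
                    votes = np.bincount(col, minlength=5)
                    cons[c] = int(np.argmax(votes[1:])) + 1
                if degenerate:
                    continue
                tiled = np.resize(cons, span)
                mismatches = int(np.count_nonzero(seg != tiled))
                if mismatches > frac * span:
                    continue
                unit = _DECODE[cons].tobytes().decode("ascii")
                if primitive_unit(unit) != unit:
                    continue
                accepted.append((a, a + span))
                hits.append(
                    TandemHit(
                        read_id=read.id,
                        start=int(a),
                        end=int(a) + span,
                        unit=unit,
                        copies=span / p,
                        mismatches=mismatches,
                        library=read.library,
                        species=read.species,
                    )
                )
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits


def brute_force_detect(
    read: SequenceRead, params: DetectorParams | None = None
) -> List[TandemHit]:
    """Independent exact-mode oracle: test every (start, period) pair.

    Same contract as :func:`detect_arrays` in exact mode, implemented by
    plain per-position extension with no shared code path.  O(L^2 * p);
    intended for reads up to ~1000 nt.
    """
    params = params or DetectorParams()
    s = read.sequence
    length = len(s)
    hits: List[TandemHit] = []

    def match(k: int, p: int) -> bool:
        a, b = s[k], s[k + p]
        return a == b and a in "ACGT"

    p_hi = min(params.max_unit, length // params.min_copies)
    for p in range(params.min_unit, p_hi + 1):
        i = 0
        while i < length - p:
            if not match(i, p):
                i += 1
                continue
            j = i
            while j < length - p and match(j, p):
                j += 1
            span = (j - i) + p
            unit = s[i : i + p]
            if span >= params.min_copies * p and primitive_unit(unit) == unit:
                hits.append(
                    TandemHit(
                        read_id=read.id,
                        start=i,
                        end=i + span,
                        unit=unit,
                        copies=span / p,
                        mismatches=0,
                        library=read.library,
                        species=read.species,
                    )
                )
            i = j + 1
    hits.sort(key=lambda h: (h.start, len(h.unit)))
    return hits
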