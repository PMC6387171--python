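import numpy as np
import pytest

from motifskim import (
    DetectorParams,
    SequenceRead,
    brute_force_detect,
    detect_arrays,
    detect_arrays_batch,
    primitive_unit,
    reverse_complement,
)

from conftest import BASES, random_read, read_with_array


def hit_keys(hits):
    return [(h.start, h.end, h.unit) for h in hits]


class TestPrimitiveUnit:
    def test_exact_doubling(self):
        assert primitive_unit("ACGACG") == "ACG"

    def test_already_primitive_and_idempotent(self):
        assert primitive_unit("ACG") == "ACG"
        assert primitive_unit(primitive_unit("ATATAT")) == primitive_unit("ATATAT") == "AT"

    def test_all_trinucleotides(self):
        # exhaustively: trinucleotides are primitive unless homopolymeric
        for a in "ACGT":
            for b in "ACGT":
                for c in "ACGT":
                    m = a + b + c
                    expected = a if a == b == c else m
                    assert primitive_unit(m) == expected

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            primitive_unit("")


class TestDetectExamples:
    def test_embedded_trinucleotide_array(self):
        # maximal period-3 array ACGx4 inside flanks; values frozen from
        # the brute-force oracle
        read = SequenceRead("r", "TTACGACGACGACGCCA")
        hits = detect_arrays(read)
        assert hit_keys(hits) == [(2, 14, "ACG")]
        assert hits[0].copies == 4.0
        assert hits == brute_force_detect(read)

    def test_27mer_satellite_in_151nt_read(self, rng):
        unit = "AATCGTTTTCAATTCAATTCATTTCGA"
        read = read_with_array(rng, 151, unit, 5)
        hits = [h for h in detect_arrays(read) if len(h.unit) == 27]
        assert len(hits) == 1
        assert hits[0].copies >= 5
        # detected unit is a rotation of the planted monomer
        assert hits[0].unit in (unit + unit)

    def test_minisatellite_12mer_three_copies(self):
        read = SequenceRead("r", "CTCGGTTATGGG" * 3)
        hits = detect_arrays(read)
        assert hit_keys(hits) == [(0, 36, "CTCGGTTATGGG")]
        assert hits[0].copies == 3.0

    def test_homopolymer_yields_nothing(self):
        assert detect_arrays(SequenceRead("r", "A" * 40)) == []

    def test_tetranucleotide_ten_copies(self):
        hits = detect_arrays(SequenceRead("r", "ACGT" * 10))
        assert hit_keys(hits) == [(0, 40, "ACGT")]
        assert hits[0].copies == 10.0

    def test_partial_trailing_unit_gives_fractional_copies(self):
        read = SequenceRead("r", "ACGACGACGAC")  # 3 full copies + "AC"
        (hit,) = detect_arrays(read)
        assert (hit.start, hit.end) == (0, 11)
        assert hit.copies == pytest.approx(11 / 3)

    def test_n_never_matches(self):
        assert detect_arrays(SequenceRead("r", "ACGNACGNACGNACGN")) == []

    def test_short_read_empty_not_error(self):
        assert detect_arrays(SequenceRead("r", "ACGTA")) == []

    def test_param_validation(self):
        with pytest.raises(ValueError):
            DetectorParams(min_unit=10, max_unit=5)
        with pytest.raises(ValueError):
            DetectorParams(min_copies=1)
        with pytest.raises(ValueError):
            DetectorParams(max_mismatch_fraction=1.5)


class TestOracleEquivalence:
    def test_random_and_planted_reads(self, rng):
        """Vectorized detector and the naive per-position oracle agree."""
        units = ["ACG", "AATT", "CTCGGTTATGGG", "ATCCG", "TTTAGGG"]
        for i in range(250):
            length = int(rng.integers(15, 500))
            if i % 2:
                read = random_read(rng, length, f"r{i}")
            else:
                unit = units[i % len(units)]
                copies = max(3, int(rng.integers(3, max(4, length // len(unit) + 1))))
                copies = min(copies, length // len(unit))
                if copies < 3:
                    read = random_read(rng, length, f"r{i}")
                else:
                    read = read_with_array(rng, length, unit, copies, f"r{i}")
            assert hit_keys(detect_arrays(read)) == hit_keys(brute_force_detect(read))

    def test_batch_matches_single(self, rng):
        reads = [random_read(rng, int(rng.integers(20, 200)), f"r{i}") for i in range(50)]
        batch = detect_arrays_batch(reads)
        for read, hits in zip(reads, batch):
            assert hit_keys(hits) == hit_keys(detect_arrays(read))


class TestInvariants:
    def test_strand_symmetry(self, rng):
        """Reverse-complementing a read mirrors hits with rc'd units."""
        for i in range(30):
            read = read_with_array(rng, 120, "ATCCG", int(rng.integers(3, 10)), f"r{i}")
            fwd = detect_arrays(read)
            rev = detect_arrays(SequenceRead(read.id, reverse_complement(read.sequence)))
            L = len(read.sequence)
            # mirrored coordinates; the unit re-reads as a rotation of
            # the reverse complement (the array starts at another phase)
            mirrored = sorted(
                (L - h.end, L - h.start, reverse_complement(h.unit)) for h in fwd
            )
            observed = sorted(hit_keys(rev))
            assert [(a, b) for a, b, _ in mirrored] == [(a, b) for a, b, _ in observed]
            for (_, _, expect_unit), (_, _, got_unit) in zip(mirrored, observed):
                assert got_unit in (expect_unit + expect_unit)

    def test_span_equals_copies_times_unit_length(self, rng):
        for i in range(30):
            read = random_read(rng, 300, f"r{i}")
            for h in detect_arrays(read):
                assert h.end - h.start == pytest.approx(h.copies * len(h.unit))
                assert h.copies >= 3
                assert primitive_unit(h.unit) == h.unit

    def test_hits_sorted_and_unique(self, rng):
        for i in range(20):
            read = read_with_array(rng, 200, "AAT", 12, f"r{i}")
            hits = detect_arrays(read)
            keys = hit_keys(hits)
            assert keys == sorted(keys) and len(keys) == len(set(keys))


class TestApproximateMode:
    def test_single_substitution_recovered_with_consensus(self):
        unit = "CTCGGTTATGGG"
        array = list(unit * 5)
        array[17] = "A" if array[17] != "A" else "C"  # one substitution
        read = SequenceRead("r", "".join(array))
        assert detect_arrays(read, DetectorParams()) != []  # clean flank run still found
        hits = detect_arrays(read, DetectorParams(max_mismatch_fraction=0.05))
        full = [h for h in hits if h.span == 60]
        assert len(full) == 1
        assert full[0].unit == unit  # majority vote restores the monomer
        assert full[0].mismatches == 1

    def test_exact_hits_still_reported_in_approx_mode(self, rng):
        read = read_with_array(rng, 151, "TTTAGGG", 6)
        exact = hit_keys(detect_arrays(read))
        approx = detect_arrays(read, DetectorParams(max_mismatch_fraction=0.05))
        # every exact array is contained in some approximate-mode hit of
        # the same period
        for start, end, unit in exact:
            assert any(
                h.start <= start and h.end >= end and len(h.unit) == len(unit)
                for h in approx
            )

    def test_over_budget_array_rejected(self):
        unit = "ACGTTGCATTGG"
        array = list(unit * 3)
        for pos in (2, 14, 20, 27, 33):  # 5 substitutions in 36 nt >> 5% budget
            array[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[array[pos]]
        read = SequenceRead("r", "".join(array))
        hits = detect_arrays(read, DetectorParams(max_mismatch_fraction=0.05))
        assert all(h.mismatches <= 0.05 * h.span for h in hits)
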