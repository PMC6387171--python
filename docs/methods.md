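# Methods

## Model

The pipeline treats low-coverage whole-genome reads as a uniform sample of
the genome.  For a repeat class observed in `k` of `N` sampled reads, the
genomic proportion is estimated as `f = k/N`; with genome size `G` (bp per
haploid genome) the absolute content is `f·G` bp, and for a telomeric motif
the average telomere length is `f·G/(2x)`, where `x` is the chromosome base
number (a haploid chromosome set has `2x` telomere ends).  The estimator
assumes (i) unbiased read sampling (PCR-free libraries), (ii) that a read
carrying a tandem array is wholly attributable to that repeat class (read
length 151 nt is small against satellite array lengths), and (iii) that a
repeat's reads are recognisable, i.e. the array inside a single read passes
the detection thresholds.  Assumption (iii) degrades for unit lengths
approaching a third of the read length (only three copies fit in a read) and
for highly diverged families; estimates for such motifs are semiquantitative.

Genome sizes come from 1C values at 978 Mbp/pg.  `GenomeModel` supports
both the exact conversion (`from_c_value`) and a genome size stated directly
in Gb (`from_gb`); since published genome sizes are quoted to two decimals
in Gb, downstream arithmetic meant to match published numbers should use
`from_gb`.  `estimate_proportion` exposes two rounding orders because both
occur in practice: `unrounded` (default) computes bp from the exact read
fraction; `percent_3sf` computes bp from the percentage already rounded to
three significant figures.  The two differ by ~0.1% — documented, not
resolved, because the choice is a reporting convention, not a model issue.

## Detection

An STM array is a substring with primitive period `p ∈ [min_unit, max_unit]`
spanning at least `min_copies·p` positions.  Defaults: `min_unit = 3`,
`max_unit = 52` (raisable to 55), `min_copies = 3`.  Exact mode reports each
maximal run of the lag-`p` self-match profile `s[i] == s[i+p]` whose span is
at least `3p` and whose leading unit is primitive; partial trailing units
extend the span, so copy numbers may be fractional.  Coordinates are 0-based
half-open on the read as given; `N` matches nothing, so arrays never cross
ambiguous bases.  Overlapping arrays with different primitive periods are
all reported; deduplication to per-read motif presence happens at the
merging stage.

The production detector vectorizes this scan over periods and reads with
numpy.  An independent brute-force oracle (`brute_force_detect`, plain
per-position extension) implements the same contract and the test suite
asserts exact agreement on 1000+ seeded random and planted reads; this is
the primary correctness guarantee.

Approximate mode (`max_mismatch_fraction > 0`) targets diverged arrays:
exact match-runs at the same period are grouped across gaps of ≤ 2 lag
positions (the footprint of an isolated substitution), candidate windows
over run boundaries are scored against the majority-vote periodic consensus
(ties toward the alphabetically smaller base), and maximal windows whose
mismatch count is within `fraction × span` are reported with the consensus
as the unit.  It models substitutions only — indels shift the phase and
truncate arrays rather than being absorbed.  This is deliberately simpler
than alignment-based detectors that use weighted match/mismatch/indel
scoring; on simulated arrays at 2% per-base divergence with a 5% mismatch
budget it recovers ≥ 98% of planted reads (measured in the test suite),
which bounds what the exact default would miss.

## Canonicalization and counting

A detected unit is an arbitrary rotation of its motif on an arbitrary
strand.  The canonical representative is computed by primitive reduction
followed by the lexicographic minimum (A < C < G < T) over all `2p`
rotations of the unit and its reverse complement.  Any canonical choice
would do; the minimum is reproducible and cheap.  Counting is per read:
each (read, canonical motif) pair contributes at most once per library, and
libraries are never silently pooled.  Canonical motifs shorter than 3 nt
(e.g. an `ATATAT` unit reducing to `AT`) and units containing `N` are
excluded with logged counts.  No similarity clustering is attempted:
degenerate variants of an abundant motif that fail the detection thresholds
fragment into separate classes, a known limitation of threshold-based
merging.

## Replicate outlier rule

For a motif counted across ≥ 3 technical-replicate libraries, a library is
flagged when its count exceeds 10× the replicate median **and** exceeds the
median by ≥ 50 reads.  The fold condition catches only gross inflation; the
absolute condition keeps small-count jitter (1 vs 8 reads) unflagged.  Both
thresholds are configurable.  Against the 36 printed triplicate counts used
as a regression set, the rule flags exactly the one triplicate whose middle
value is inflated ~230-fold (8, 1843, 6) and nothing else.

## Synthetic data

The generator emulates the study design the pipeline assumes: 151-nt reads,
i.i.d. background bases at 33% GC (the AT-rich genome average), three
technical-replicate libraries per species drawn from the same family mix,
planted tandem families (each planted read carries one array at uniform
random strand, rotation, copy number within range, and offset, with uniform
per-base substitutions at the family rate), telomere-motif reads at stated
fractions, and an optional outlier injection multiplying one family's
fraction in one library.  Per-read family assignment is categorical, so
planted counts are multinomial and the truth table records the realized
counts.  Randomness is a per-(seed, species, library) numpy PCG64 stream;
regeneration is byte-identical.

What the generator does *not* model: genomic k-mer structure, quality-score
realism, sequencing error profiles beyond uniform substitution, indels, and
paired-end inserts.  Consequently, passing recovery tests demonstrate the
pipeline's counting arithmetic and invariances, not robustness to real
instrument error.  One real-data feature the i.i.d. background *does*
reproduce, and the tests must account for: short AT-rich motifs (e.g. the
AATT class) arise by chance in an AT-rich background at a measurable rate
(~6×10⁻⁴ per read at 33% GC), so raw pipeline counts for such motifs exceed
planted counts.  Recovery tests therefore subtract a background count
measured on a matched zero-family simulation before comparing against the
exact (Clopper–Pearson) binomial interval of the planted count — the false
positive rate is measured, never assumed.

The bundled fixture (`make_paper_fixture`, seed 7331) plants an abundant
tetranucleotide, a pentanucleotide, a 27-nt satellite monomer, the 12-nt
telomeric minisatellite in all three species, and a trace 7-nt ancestral
telomere variant, at fractions ordered differently per species so that
top-motif rankings discriminate.

## Problem sizes and numerics

The acceptance computations use printed inputs where arithmetic is being
reproduced (read counts, genome sizes, triplicate tables, monomer base
counts) and a 10⁵-read single-library simulation for the end-to-end round
trip — large enough that binomial intervals are tight (±~6% on a 0.01
fraction) while the whole script stays under a minute on one CPU.  Detector
TSV/percent outputs round half-up (GC percentages to 1 decimal, kb to 3
decimals, percentages to 3 significant figures) to match conventional
reporting.  Ties in top-motif rankings break lexicographically on the
canonical sequence; majority-vote ties in the approximate consensus break
toward the alphabetically smaller base.  Reads shorter than `3·min_unit`
yield empty hit lists rather than errors; empty inputs produce empty (but
schema-valid) tables throughout.

## Known limitations

- Exact detection misses arrays whose every window of `min_copies` units is
  interrupted by a substitution; approximate mode recovers most but is
  substitution-only.
- Proportion estimates for units ≳ 50 nt rest on as few as three copies per
  read and are qualitative.
- Read-level deduplication means a read with two *different* motifs counts
  once for each; abundance totals are therefore motif-read pairs, not reads.
- The external-detector `.dat` import trusts the file's consensus and copy
  numbers; only period/copy filters and coordinate conventions are applied.
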