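# motifskim

Short tandem motif (STM) profiling from genome-skimming reads.

Giant plant genomes — onion-family species reach 16–31 Gb per haploid
genome — are rich in tandem repeats that are hard to assemble but easy to
*count*: in low-coverage whole-genome sequencing, the fraction of reads
carrying a repeat directly estimates the repeat's fraction of the genome.
`motifskim` implements that read-counting pipeline for short tandem motifs
(unit length 3–55 nt, at least three adjacent copies within a read):

1. **Detection** — find every maximal tandem array inside each unassembled
   read (exact periodic matching by default; an approximate mode tolerates a
   bounded mismatch fraction against the majority-vote periodic consensus).
2. **Canonicalization** — motifs identical up to rotation and reverse
   complement (TTA ≡ TAT ≡ ATT ≡ AAT ≡ ATA ≡ TAA) are merged into one class,
   represented by the lexicographically smallest rotation over both strands,
   and counted once per read per library.
3. **Comparative profiles** — per-length abundance and diversity profiles,
   cross-species sharing (Venn regions), top-motif rankings, and an outlier
   flag for technical-replicate libraries (count > 10× the replicate median
   *and* ≥ 50 reads above it).
4. **Abundance arithmetic** — with a genome model (1C value in pg at
   978 Mbp/pg, or a genome size in Gb; chromosome base number *x*), a read
   count converts to a genomic proportion *f* = reads/total, absolute content
   *f*·G bp per haploid genome, and — for a telomeric motif — an average
   telomere length *f*·G/(2*x*) over the 2*x* chromosome ends.
5. **Synthetic data** — a deterministic read simulator (151-nt reads,
   AT-rich background, planted repeat families with random strand, rotation,
   copy number and divergence, triplicate libraries, optional outlier
   injection) with a truth table, so the entire chain is testable offline.

Intended users: plant (cyto)genomicists and repeat biologists profiling the
satellite/microsatellite fraction of large genomes from shallow sequencing,
without assembly.

## Worked example

Estimate an average telomere length from a read count, exactly as done for
real data — 1519 telomere-motif reads among 30 million reads of a 15.89 Gb,
*x* = 8 genome:

```bash
motifskim estimate --reads-detected 1519 --total-reads 30000000 \
    --genome-gb 15.89 --x 8 --species garlic --motif CTCGGTTATGGG
```

```
species	motif	reads_detected	total_reads	percent	bp_per_haploid	kb_per_haploid	bp_per_telomere	kb_per_telomere
garlic	CTCGGTTATGGG	1519	30000000	0.00506	804564	804.564	50285	50.285
```

Reading: 1519/30 M reads is 0.00506% of the genome, i.e. ~804.6 kb of
telomeric repeat per haploid genome; spread over 2·8 = 16 chromosome ends
that is an average telomere of ~50.3 kb.

The same arithmetic, and the detection/merging stages that produce the read
counts, run end to end on simulated data:

```bash
motifskim simulate --fixture --n-reads 5000 --out-dir sim
motifskim detect sim/speciesA_S*.fastq --species speciesA \
    --library S1 --library S2 --library S3 --out hitsA.tsv
motifskim merge hitsA.tsv --out countsA.tsv
head -4 countsA.tsv
```

```
species	library	motif	motif_length	read_count
speciesA	S1	AAAACGATTTCGAAATGAATTGAATTG	27	4
speciesA	S1	AAAAT	5	1
speciesA	S1	AAAC	4	2
```

Each row is a canonical motif class with the number of distinct reads in
that library carrying at least one qualifying array of it (the 27-mer is the
canonical form of a planted satellite monomer).  `motifskim report` then
assembles catalog sizes, sharing regions and telomere estimates across
species into one TSV bundle with a human-readable summary.

The same works from the library API (`motifskim.detect_arrays`,
`merge_hits`, `length_profiles`, `estimate_proportion`, ...); see the module
docstrings and `docs/methods.md`.

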