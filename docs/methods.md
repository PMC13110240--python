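# Methods

## Scope and model

`aquasrna` classifies small-RNA sequencing reads from environmental
exosome/sEV fractions into seven categories — piRNA, miRNA, rRNA,
tRNA, snRNA, other ncRNAs, unknown — and computes piRNA-level
statistics. The underlying operational model:

* a read is a single 18–40 nt DNA-space sequence (U normalised to T at
  ingestion; paired-end merging is upstream of this package);
* a read belongs to the target species iff it matches the species
  genome *exactly* somewhere on either strand; no mismatch budget is
  spent at this gate, so sequencing errors deflate the mapped fraction
  rather than contaminate it;
* annotation is hierarchical and exclusive: the first matching rule
  assigns the single category. piRNAs are defined negatively, as
  genome-mapped 25–32 nt reads that match no non-coding reference, no
  mature miRNA, and are not tandem repeats. This mirrors how piRNAs
  are called in invertebrate small-RNA surveys, where no Piwi-bound
  library is available;
* the 1U bias — the hallmark first-position uridine enrichment of
  primary piRNAs — is computed at two levels: over distinct sequence
  types and over read occurrences. Both levels are reported because a
  few high-copy sequences can decouple them (the rearing-tank sample
  in the bundled survey is exactly such a case).

## Matching semantics

`map_exact` returns *all* zero-mismatch occurrences of the read or its
reverse complement (the multi-hit, zero-mismatch alignment policy);
`map_one_mismatch` implements best-stratum reporting: all 0-mismatch
hits if any exist, otherwise all 1-mismatch hits. Both are backed by a
fixed-k seed table (k = 8) over the reference forward strand; the
one-mismatch search seeds the prefixes of the read's two halves
(pigeonhole: a ≤1-mismatch hit leaves one half exact), and queries
shorter than 2k fall back to a full scan. `N` matches nothing,
including another `N`; a read containing `N` therefore cannot produce
an exact hit. Coordinates are 0-based half-open; a hit's strand is the
reference strand the read sequence equals. Both searches are verified
against an independent numpy sliding-window Hamming oracle on
randomized instances.

Unannotated rRNA fragments (species-specific sequences absent from
general ncRNA references) are rescued by Smith–Waterman local
alignment (Biopython `PairwiseAligner`; match +1, mismatch −2, gap −2)
against a small rRNA rescue set, on both strands. A rescue requires
identity ≥ 0.85 over the aligned columns (gap columns count against
identity) and coverage ≥ 0.8 of the read. Identity/coverage thresholds
replace E-values deliberately: they are deterministic and independent
of database size. Numerical choice: within one reference, only the
aligner's first optimal alignment is scored; a qualifying alignment
strictly below the optimum of that reference would be missed. For
≤40 nt reads against short rescue references this is immaterial, and
the accepted hit's score is checked against a hand-written DP oracle
in the tests. Ties across references break by sorted reference id.

## Cascade order

rRNA > tRNA > snRNA > other ncRNAs (exact) → rRNA rescue → miRNA
(best stratum ≤1 mismatch, canonical 20–24 nt gate; a miRNA-matching
read of non-canonical length goes to *unknown*, not to piRNA) →
tandem-repeat exclusion → 25–32 nt piRNA window → unknown. Rescue runs
before the miRNA comparison; because rescue references are rRNA-only,
placing it after would categorise rRNA-derived reads identically —
the earlier position just keeps all rRNA evidence adjacent. A read is
one counting unit regardless of how many loci it hits, and reads
failing the genome gate are reported separately, never in the count
table.

Tandem repeats are detected with a single SSR scanner standing in for
the MISA + TRF pair: motif lengths 1–6 with minimum contiguous repeat
counts 10 (mono), 6 (di), 5 (tri–hexa) — MISA's defaults — and a call
excludes the read when the repeated span covers ≥ 80% of it. A full
alignment-based repeat model is unnecessary at ≤ 40 nt.

## Preprocessing

The 3′ adapter is removed as the longest read suffix aligning to an
adapter prefix with mismatch fraction ≤ 0.1 and overlap ≥ 3, then 4
fixed bases are cut from each end (the random bases NEXTFLEX-style
kits place around the insert; set `fixed_trim_5/3 = 0` for other
chemistries). Trimming is single-pass, as in standard trimmers: with a
3-base minimum overlap, any sequence ending in the adapter's first
bases would be re-trimmed on a second pass, so "trim until fixed
point" is not a meaningful specification; the length/quality filter,
by contrast, is a true fixed point and is tested as such. The length
window 18–40 nt is inclusive on both ends; mean Phred quality must
reach 20 (skipped for quality-less reads). Every input read is
accounted for in exactly one of: kept, too_short, too_long,
low_quality.

Percentages throughout the statistics layer are rounded to one
decimal, half-up (matching how such tables are conventionally
printed); aggregation (mean, n−1 SD) always runs on the unrounded
per-sample values. In the bundled survey tables one printed value is
internally inconsistent: the tank type-level bias prints 31.3% while
its own counts give 863/2930 = 29.5%. The package computes from
counts and does not special-case the printed value; the four
open-water samples are internally consistent and reproduce exactly.

## Synthetic data: what it emulates and what it does not

`generate_references` builds a uniform-random genome (default 50 kb)
and plants the role sequences — 3 rRNAs (300–500 nt), 4 tRNAs
(70–90 nt), 2 snRNAs, 3 other ncRNAs, 10 miRNAs (20–24 nt), 20 known
piRNAs (25–32 nt), 2 rescue-only rRNAs, 3 tandem-repeat stretches — as
exact substrings at disjoint recorded loci (the genome must be ≥ 10×
the total footprint). `generate_reads` draws read classes from a
configurable mix, decorates each insert with 4 random bases per side
plus the adapter, and emits uniform-Q40 FASTQ plus a per-read truth
table. Construction is *unambiguous*: every candidate insert is
checked against the package's own matchers (no cross-role hit, no
spurious rescue, no accidental SSR, piRNA inserts off all planted
loci, background reads absent from the genome) and resampled on the
rare collision. Classification of such a sample must recover the
planted truth exactly, so end-to-end accuracy 1.0 is a consistency
check of the rule order and matchers — it says nothing about accuracy
on real data, where references are incomplete, reads carry errors
(an optional per-base substitution rate exists for robustness
experiments; it is off by default because the exact-match stages
would silently reclassify erroneous reads), and category boundaries
are genuinely ambiguous.

Preset conditions mirror the bundled survey: the `tank` preset uses
the tank category composition with a 4.6% genome-mapped fraction and a
planted 1U fraction of 0.191 (the tank's frequency-level value, since
the generator plants first bases per read); the `aquaculture` preset
uses the largest open-water sample's composition, 2.8% mapped, 1U
0.154. Where the survey gives no value, defaults were fixed once at
plausible magnitudes: 10% of unknown-class reads are tandem repeats,
10% of rRNA reads derive from rescue-only references, 5% of piRNA
reads are exact known-catalog copies.

## Problem sizes and determinism

All randomness flows from a single integer seed through
`random.Random`; regenerating with the same seed is byte-identical,
and a pipeline rerun on identical inputs produces byte-identical
reports (no timestamps are emitted; the manifest records parameters
and input SHA-256 checksums). The test suite and the acceptance script
run synthetic samples of 10⁴–2×10⁴ reads against 50 kb genomes, sizes
at which the realised mapped fraction has a sampling SD of ~0.15
percentage points and a full run takes seconds; the matcher oracle
checks 500 randomized cases against a 35 kb two-contig reference.

## Known limitations

* The matcher is a desk-scale tool: the seed table lives in memory and
  is rebuilt per run; it is not a genome-scale aligner.
* Rescue considers only the optimal local alignment per reference
  (see above).
* No ping-pong (10A) signature, positional profiles beyond the first
  base, hairpin validation for miRNAs, or covariance-model ncRNA
  search; the cascade is string-identity-based by design.
* Paired-end mate merging and deduplication policy are outside the
  package; it consumes single sequences.
* The raw→filtered read-count drops and absolute occurrence counts of
  a real survey depend on instrument- and run-specific parameters and
  are not reproduced by the synthetic benchmark.
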