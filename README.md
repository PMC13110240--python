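# aquasrna

Classification of environmental small-RNA sequencing reads and piRNA
statistics for aquatic eRNA monitoring.

## The problem

Aquatic organisms shed extracellular vesicles (exosomes/sEVs) into the
water around them. These vesicles protect their RNA cargo from
environmental RNases, so small RNAs recovered from filtered seawater —
including PIWI-interacting RNAs (piRNAs), which are strongly
species-specific — can act as a signature of which species are present
and active. Reading that signature from a sequencing library is an
annotation problem: most reads are rRNA fragments or non-target
(microbial) sequence, and the piRNA signal is a small residual class
that is defined by *exclusion*, so the order and strictness of every
annotation step matters.

`aquasrna` implements that annotation chain as a tested library for
researchers analysing environmental small-RNA-seq libraries:

1. **Preprocessing** — 3′ adapter removal (longest suffix/prefix
   overlap within an error budget), fixed trimming of the library
   kit's 4 random end bases, and an inclusive 18–40 nt length window.
2. **Genome gate** — only reads mapping *exactly* (0 mismatches,
   either strand, all hits) to the target-species genome enter
   classification; the rest are counted as non-target background.
3. **Annotation cascade** — first matching rule wins:
   rRNA > tRNA > snRNA > other ncRNA (exact hits) →
   species-specific rRNA *rescue* by Smith–Waterman local alignment
   (identity ≥ 0.85 over aligned columns, coverage ≥ 0.8 of the read) →
   mature-miRNA comparison (best stratum, ≤ 1 mismatch) with a
   canonical 20–24 nt length gate → tandem-repeat (SSR) exclusion →
   **piRNA = any remaining 25–32 nt read** → unknown.
4. **piRNA statistics** — the 1U bias (fraction of predicted piRNAs
   whose first base is U, i.e. T in DNA space), computed over distinct
   *sequence types* and over read *occurrences*:

   `bias = 100 · #U-start / (#U-start + #non-U-start)`,

   cross-sample mean ± SD (n−1), top-occurrence ranking, per-category
   shares, and exact full-length matching against a known-piRNA
   catalog.

A seeded synthetic-data generator (`aquasrna.simulate`) produces
samples with per-read ground truth that mimic the structure of real
environmental libraries — rRNA-dominated composition, a few percent of
reads genome-mapped, tandem-repeat contaminants, a planted 1U
fraction — so the whole chain is testable without any sequencing data.
The published summary tables of a pearl-oyster aquaculture survey ship
as `aquasrna.datasets` and drive the worked examples.

## Worked example

```sh
python examples/01_survey_statistics.py
```

prints

```
sample  types%  freq%   (1U bias at sequence-type / occurrence level)
AM1      23.6   19.9
AM2      23.9   19.8
PM1      19.4   14.2
PM2      22.9    7.6

open-water mean +/- SD:  types 22.4 +/- 2.1 %,  frequencies 15.4 +/- 5.8 %
tank frequency-level 1U bias: 19.1 %
tank piRNA share of mapped reads: 2.5 %
```

Per sample, `types%` is the share of distinct predicted-piRNA
sequences starting with U and `freq%` the same share weighting each
sequence by its read count; the tank sample's piRNA class holds 2.5%
of all genome-mapped reads — far above what co-isolated debris would
explain, which is the survey's core observation. The other examples
cover the matchers (`03_read_matching.py`), a synthetic end-to-end run
with ground-truth recovery (`02_synthetic_pipeline.py`, accuracy 1.0
by construction), and a full configured report run
(`04_full_report_run.py`).

A thin CLI wraps the same functions: `aquasrna run --config cfg.yaml`,
plus `simulate`, `preprocess`, `classify`, `match` and `validate`
subcommands for single stages.

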