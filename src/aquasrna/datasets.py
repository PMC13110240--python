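"""Bundled example dataset: summary tables from a small-RNA survey of
environmental exosome/sEV fractions in Akoya pearl-oyster aquaculture
waters (one rearing-tank sample and four open-water samples, AM/PM
duplicates).

Only the published summary numbers are bundled — per-category read
counts, first-base counts of the predicted piRNAs, and the most
frequent piRNA sequences — not the underlying reads.  They serve as
worked-example inputs for the statistics layer and as the default
composition of the synthetic-data presets.
"""

from __future__ import annotations

from aquasrna.io_formats import CountTable, ReferenceSet
from aquasrna.pirna_stats import BiasSummary, OccurrenceTable

#: Per-sample read counts by RNA category (genome-mapped reads).
CATEGORY_COUNTS: dict[str, dict[str, int]] = {
    "Tank": {
        "piRNA": 19_248, "miRNA": 27, "rRNA": 373_789, "tRNA": 45_384,
        "snRNA": 1_239, "other_ncRNAs": 2_293, "unknown": 338_564,
    },
    "AM1": {
        "piRNA": 372, "miRNA": 30, "rRNA": 361_592, "tRNA": 4_174,
        "snRNA": 1_638, "other_ncRNAs": 830, "unknown": 8_702,
    },
    "AM2": {
        "piRNA": 81, "miRNA": 9, "rRNA": 103_368, "tRNA": 1_606,
        "snRNA": 589, "other_ncRNAs": 173, "unknown": 3_025,
    },
    "PM1": {
        "piRNA": 246, "miRNA": 2, "rRNA": 171_123, "tRNA": 4_321,
        "snRNA": 717, "other_ncRNAs": 342, "unknown": 5_376,
    },
    "PM2": {
        "piRNA": 145, "miRNA": 27, "rRNA": 107_696, "tRNA": 2_328,
        "snRNA": 1_347, "other_ncRNAs": 1_088, "unknown": 3_306,
    },
}

AQUACULTURE_SAMPLES: tuple[str, ...] = ("AM1", "AM2", "PM1", "PM2")

#: First-base counts of predicted piRNAs per sample:
#: (U types, non-U types, U occurrences, non-U occurrences).
FIRST_BASE_COUNTS: dict[str, tuple[int, int, int, int]] = {
    "Tank": (863, 2_067, 3_679, 15_569),
    "AM1": (71, 230, 74, 298),
    "AM2": (16, 51, 16, 65),
    "PM1": (27, 112, 35, 211),
    "PM2": (8, 27, 11, 134),
}

#: Most frequent predicted piRNAs in the rearing-tank sample:
#: (sequence, occurrences in the survey).
TOP_TANK_PIRNAS: tuple[tuple[str, int], ...] = (
    ("GGAAGGTCCGGAGAGTCTAGGTTACCCAATT", 198),
    ("GGAAGGTCCGGAGAGTCTAGGTTACCCAATTC", 171),
    ("TGGGAATACCGGGTGTTGTAGGCAT", 110),
    ("GGGGTGAGCCGTGGCGTGCTTGGGTTCAAATC", 79),
    ("ATGGAAGGTCCGGAGAGTCTAGGTTACCCAAT", 34),
)

#: Open-water piRNAs that matched the hemolymph-exosome catalog:
#: sample -> tuples of (sequence, occurrences in the survey).
KNOWN_MATCHED_PIRNAS: dict[str, tuple[tuple[str, int], ...]] = {
    "AM1": (
        ("GATAAATGAAGTCAGCTTATTATCTCTGAGT", 1),
        ("GGCCGTGATCGTATAGTGGTTAGTACTTCGCG", 3),
        ("GATTGTCAATGGGTTTTGAGAGAAAACC", 1),
        ("GAGGTCTGCTGCCGATGGACTTTACGATTTCT", 1),
        ("TGTCAATGTACTTTGGATGAGCTGCAGG", 1),
    ),
    "PM1": (("TCAATACCCCTAGCTCAATATTCGACCTTCTC", 2),),
    "PM2": (("GGCCGTGATCGTATAGTGGTTAGTACTTCGCG", 13),),
}


def count_table(sample: str) -> CountTable:
    """The category count table of one survey sample."""
    return CountTable(sample, dict(CATEGORY_COUNTS[sample]))


def bias_summary(sample: str) -> BiasSummary:
    """The first-base bias summary of one survey sample, built from
    the published U / non-U counts."""
    ut, nt, uf, nf = FIRST_BASE_COUNTS[sample]
    return BiasSummary(sample, ut, nt, uf, nf)


def _synthetic_sequence(index: int, first: str, length: int = 28) -> str:
    """Deterministic distinct DNA string with a fixed first base
    (fixed-width base-4 encoding of the index, constant tail)."""
    digits = "".join("ACGT"[(index >> (2 * k)) & 3] for k in range(6))
    return (first + digits + "GTCA" * 8)[:length]


def occurrence_table_from_first_base_counts(sample: str) -> OccurrenceTable:
    """Reconstruct an occurrence table consistent with a sample's
    published first-base counts.

    The published summary gives only (U types, non-U types,
    U occurrences, non-U occurrences); this builds synthetic distinct
    sequences realising exactly those totals (the excess occurrence
    mass is assigned to the first sequence of each group), so the
    statistics layer can be exercised on the published numbers.
    """
    ut, nt, uf, nf = FIRST_BASE_COUNTS[sample]
    entries: list[tuple[str, int, int]] = []
    for n_types, n_occ, first in ((ut, uf, "T"), (nt, nf, "A")):
        for i in range(n_types):
            seq = _synthetic_sequence(i, first)
            count = n_occ - n_types + 1 if i == 0 else 1
            entries.append((seq, len(seq), count))
    return OccurrenceTable(sample, tuple(entries))


def known_pirna_catalog(sample: str) -> ReferenceSet:
    """A known-piRNA catalog containing the sequences that matched in
    one open-water sample (synthetic stand-in for the full catalog,
    which holds only the published matching sequences)."""
    records = tuple(
        (f"catalog_{i + 1}", seq)
        for i, (seq, _count) in enumerate(KNOWN_MATCHED_PIRNAS[sample])
    )
    return ReferenceSet(f"{sample}_catalog", "known_pirna", records)
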