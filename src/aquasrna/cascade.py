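"""Hierarchical annotation cascade for genome-mapped small-RNA reads.

Every read is assigned to exactly one of the seven categories
{rRNA, tRNA, snRNA, other_ncRNAs, miRNA, piRNA, unknown} by the first
matching rule:

1. zero-mismatch hit in an Rfam-style set, priority
   rRNA > tRNA > snRNA > other_ncRNAs;
2. local-alignment rescue against species-specific rRNA references
   -> rRNA;
3. mature-miRNA hit (best stratum, <= 1 mismatch): canonical length
   20-24 nt -> miRNA, any other length -> unknown;
4. tandem-repeat (SSR) call -> unknown;
5. length 25-32 nt -> piRNA (the operational piRNA definition:
   an unannotated genome-mapped read in the piRNA length window);
6. otherwise unknown.

Only reads with at least one exact genome hit enter the cascade when
``require_genome_hit`` is set (the default); unmapped reads are
reported separately and never appear in the count table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from aquasrna.io_formats import CATEGORY_ORDER, CountTable, ReferenceSet, SmallRNARead
from aquasrna.matcher import (
    LocalHit,
    MatchHit,
    SubstringIndex,
    build_index,
    local_align_rescue,
    map_exact,
    map_one_mismatch,
)

#: Rfam-style roles in cascade priority order.
NCRNA_PRIORITY: tuple[tuple[str, str], ...] = (
    ("rrna", "rRNA"),
    ("trna", "tRNA"),
    ("snrna", "snRNA"),
    ("other_ncrna", "other_ncRNAs"),
)

#: MISA-default minimum repeat counts per motif length.
DEFAULT_SSR_MIN_REPEATS: dict[int, int] = {1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


@dataclass(frozen=True)
class CascadeParams:
    """Length windows and repeat thresholds for the cascade.

    The canonical-miRNA window (20-24 nt) and the piRNA window
    (25-32 nt) are inclusive and disjoint.  ``ssr_min_repeats`` maps
    motif length (1-6) to the minimum contiguous repeat count for an
    SSR call; a call excludes a read from piRNA prediction when the
    repeated span covers at least ``ssr_min_span`` of the read.
    """

    mirna_min_len: int = 20
    mirna_max_len: int = 24
    pirna_min_len: int = 25
    pirna_max_len: int = 32
    ssr_motif_min: int = 1
    ssr_motif_max: int = 6
    ssr_min_repeats: Mapping[int, int] = field(
        default_factory=lambda: dict(DEFAULT_SSR_MIN_REPEATS)
    )
    ssr_min_span: float = 0.8
    rescue_min_identity: float = 0.85
    rescue_min_coverage: float = 0.8
    require_genome_hit: bool = True

    def __post_init__(self) -> None:
        if self.mirna_min_len > self.mirna_max_len:
            raise ValueError("miRNA window inverted")
        if self.pirna_min_len > self.pirna_max_len:
            raise ValueError("piRNA window inverted")
        if self.mirna_max_len >= self.pirna_min_len:
            raise ValueError("miRNA and piRNA windows must be disjoint")


@dataclass(frozen=True)
class RepeatCall:
    """Result of the SSR scan over one sequence."""

    is_repeat: bool
    motif: str = ""
    repeat_count: int = 0
    span: float = 0.0


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-read category assignment with the evidence that produced it."""

    read_id: str
    sequence: str
    category: str
    stage: str
    evidence: str = ""
    mismatches: int | None = None
    genome_mapped: bool = True


@dataclass
class ClassifyResult:
    """Output of :func:`classify_sample`.

    ``pirna_occurrences`` preserves read-level multiplicity (one entry
    per piRNA-classified read); ``unmapped_read_ids`` lists reads that
    failed the genome gate and were excluded before classification.
    ``skipped_stages`` names cascade stages without a configured
    reference set.
    """

    count_table: CountTable
    records: list[ClassificationRecord]
    pirna_occurrences: list[str]
    unmapped_read_ids: list[str]
    skipped_stages: list[str]


def detect_tandem_repeat(sequence: str, params: CascadeParams | None = None) -> RepeatCall:
    """Scan a sequence for short sequence repeats (SSRs).

    All motif lengths from ``ssr_motif_min`` to ``ssr_motif_max`` are
    scanned at every start position; among runs meeting the per-motif
    minimum repeat count, the one with the longest repeated span is
    reported (ties: shorter motif, then leftmost).  ``is_repeat`` is
    true iff that span covers at least ``ssr_min_span`` of the read.
    """
    params = params or CascadeParams()
    n = len(sequence)
    if n < 1:
        raise ValueError("sequence must be non-empty")
    best: tuple[int, str, int, int] | None = None  # (span_len, motif, count, start)
    for m in range(params.ssr_motif_min, params.ssr_motif_max + 1):
        min_rep = params.ssr_min_repeats.get(m, DEFAULT_SSR_MIN_REPEATS.get(m, 5))
        i = 0
        while i + m <= n:
            motif = sequence[i : i + m]
            if "N" in motif:
                i += 1
                continue
            count = 1
            while sequence[i + count * m : i + (count + 1) * m] == motif:
                count += 1
            if count >= min_rep:
                span_len = count * m
                cand = (span_len, motif, count, i)
                if best is None or span_len > best[0]:
                    best = cand
                i += span_len  # skip past this run
            else:
                i += 1
    if best is None:
        return RepeatCall(False)
    span_len, motif, count, _ = best
    span = span_len / n
    return RepeatCall(span >= params.ssr_min_span, motif, count, span)


def classify_read(
    read: SmallRNARead,
    hits: Mapping[str, Sequence[MatchHit] | LocalHit | None],
    repeat: RepeatCall,
    params: CascadeParams,
    genome_mapped: bool = True,
) -> ClassificationRecord:
    """Assign one read to a category by the first matching cascade rule.

    ``hits`` maps role names to precomputed match results: lists of
    :class:`MatchHit` for ``rrna``/``trna``/``snrna``/``other_ncrna``
    (0 mismatches) and ``mirna`` (best stratum, <= 1 mismatch), and an
    optional :class:`LocalHit` under ``rrna_rescue``.  Roles missing
    from ``hits`` are treated as stages without evidence.
    """
    n = len(read)
    # rule 1: Rfam-style exact annotation, fixed priority
    for role, category in NCRNA_PRIORITY:
        role_hits = hits.get(role)
        if role_hits:
            hit = role_hits[0]
            return ClassificationRecord(
                read.read_id, read.sequence, category, f"ncrna:{role}",
                hit.ref_id, hit.mismatches, genome_mapped,
            )
    # rule 2: species-specific rRNA rescue
    rescue = hits.get("rrna_rescue")
    if isinstance(rescue, LocalHit):
        return ClassificationRecord(
            read.read_id, read.sequence, "rRNA", "rrna_rescue",
            rescue.ref_id, None, genome_mapped,
        )
    # rule 3: mature-miRNA comparison; canonical length gate
    mirna_hits = hits.get("mirna")
    if mirna_hits:
        hit = mirna_hits[0]
        if params.mirna_min_len <= n <= params.mirna_max_len:
            return ClassificationRecord(
                read.read_id, read.sequence, "miRNA", "mirna",
                hit.ref_id, hit.mismatches, genome_mapped,
            )
        return ClassificationRecord(
            read.read_id, read.sequence, "unknown", "mirna_noncanonical_length",
            hit.ref_id, hit.mismatches, genome_mapped,
        )
    # rule 4: tandem-repeat exclusion
    if repeat.is_repeat:
        return ClassificationRecord(
            read.read_id, read.sequence, "unknown", "tandem_repeat",
            f"({repeat.motif})x{repeat.repeat_count}", None, genome_mapped,
        )
    # rule 5: piRNA length window
    if params.pirna_min_len <= n <= params.pirna_max_len:
        return ClassificationRecord(
            read.read_id, read.sequence, "piRNA", "pirna_length_window",
            "", None, genome_mapped,
        )
    # rule 6: residual
    return ClassificationRecord(
        read.read_id, read.sequence, "unknown", "unclassified", "", None, genome_mapped
    )


def classify_sample(
    reads: Iterable[SmallRNARead],
    bundle: Mapping[str, ReferenceSet],
    params: CascadeParams | None = None,
    sample_id: str = "sample",
) -> ClassifyResult:
    """Classify a preprocessed sample against a reference bundle.

    Reads with no exact genome hit (any configured genome contig,
    either strand) are excluded before classification when
    ``require_genome_hit`` is set; stages whose reference role is
    absent from the bundle are skipped and listed in
    ``skipped_stages``.  Multi-mapping reads count once: a read is one
    unit regardless of its hit count.
    """
    params = params or CascadeParams()
    indexes: dict[str, SubstringIndex] = {}
    for role in ("genome", "rrna", "trna", "snrna", "other_ncrna", "mirna"):
        if role in bundle:
            indexes[role] = build_index(bundle[role])
    skipped = sorted(
        {"genome", "rrna", "trna", "snrna", "other_ncrna", "mirna", "rrna_rescue"}
        - set(indexes)
        - ({"rrna_rescue"} if "rrna_rescue" in bundle else set())
    )
    gate = params.require_genome_hit and "genome" in indexes

    table = CountTable.zero(sample_id)
    records: list[ClassificationRecord] = []
    pirna_occurrences: list[str] = []
    unmapped: list[str] = []

    for read in reads:
        genome_mapped = True
        if gate:
            genome_mapped = bool(map_exact(read, indexes["genome"]))
            if not genome_mapped:
                unmapped.append(read.read_id)
                continue
        hits: dict[str, object] = {}
        for role, _cat in NCRNA_PRIORITY:
            if role in indexes:
                role_hits = map_exact(read, indexes[role])
                if role_hits:
                    hits[role] = role_hits
                    break  # higher-priority exact hit decides the category
        if not hits and "rrna_rescue" in bundle:
            hits["rrna_rescue"] = local_align_rescue(
                read,
                bundle["rrna_rescue"],
                params.rescue_min_identity,
                params.rescue_min_coverage,
            )
        if not hits.get("rrna_rescue") and not any(
            hits.get(r) for r, _ in NCRNA_PRIORITY
        ):
            if "mirna" in indexes:
                mirna_hits = map_one_mismatch(read, indexes["mirna"])
                if mirna_hits:
                    hits["mirna"] = mirna_hits
        repeat = detect_tandem_repeat(read.sequence, params)
        record = classify_read(read, hits, repeat, params, genome_mapped)
        records.append(record)
        table.rows[record.category] += 1
        if record.category == "piRNA":
            pirna_occurrences.append(record.sequence)

    return ClassifyResult(table, records, pirna_occurrences, unmapped, skipped)
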