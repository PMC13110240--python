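"""piRNA-level statistics: first-base (1U) bias, cross-sample
aggregation, occurrence ranking, category fractions, and exact
matching against a known-piRNA catalog.

piRNAs in most model systems carry a uridine at their first position
(the "1U bias").  Reads are DNA-space, so the test is for a leading T.
The bias is computed at two levels: *sequence types* (each distinct
sequence counts once) and *frequencies* (each read occurrence counts).
Percentages are reported at one decimal place, half-up; the raw counts
are retained so aggregation never accumulates rounding error.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from statistics import mean, stdev
from typing import Iterable, Sequence

from aquasrna.io_formats import CountTable, ReferenceSet


def round1(x: float) -> float:
    """Round to 1 decimal place, half-up (the convention of the
    reported tables; Python's bankers' rounding would differ)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class OccurrenceTable:
    """Distinct predicted-piRNA sequences with their occurrence counts."""

    sample_id: str
    entries: tuple[tuple[str, int, int], ...]  # (sequence, length, count)

    def __post_init__(self) -> None:
        seqs = [s for s, _, _ in self.entries]
        if len(seqs) != len(set(seqs)):
            raise ValueError("duplicate sequences in occurrence table")
        for seq, length, count in self.entries:
            if length != len(seq):
                raise ValueError(f"length column {length} != len({seq!r})")
            if count < 1:
                raise ValueError("occurrence counts must be >= 1")

    @classmethod
    def from_occurrences(cls, sample_id: str, occurrences: Iterable[str]) -> "OccurrenceTable":
        counts = Counter(occurrences)
        entries = tuple(
            (seq, len(seq), n) for seq, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
        )
        return cls(sample_id, entries)

    @property
    def n_types(self) -> int:
        return len(self.entries)

    @property
    def total(self) -> int:
        return sum(n for _, _, n in self.entries)


@dataclass(frozen=True)
class BiasSummary:
    """U vs non-U first-base counts at type and occurrence level.

    ``u_types``/``non_u_types`` count distinct sequences;
    ``u_freq``/``non_u_freq`` weight each sequence by its occurrence
    count.  Sequences starting with N are excluded and tallied in
    ``n_excluded_types``.
    """

    sample_id: str
    u_types: int
    non_u_types: int
    u_freq: int
    non_u_freq: int
    n_excluded_types: int = 0

    @property
    def bias_types_raw(self) -> float:
        return 100.0 * self.u_types / (self.u_types + self.non_u_types)

    @property
    def bias_freq_raw(self) -> float:
        return 100.0 * self.u_freq / (self.u_freq + self.non_u_freq)

    @property
    def bias_types_pct(self) -> float:
        return round1(self.bias_types_raw)

    @property
    def bias_freq_pct(self) -> float:
        return round1(self.bias_freq_raw)


@dataclass(frozen=True)
class AggregateBias:
    """Mean +/- sample SD of per-sample bias percentages."""

    level: str  # "types" | "frequencies"
    mean_pct: float
    sd_pct: float
    n_samples: int


def first_base_bias(occ: OccurrenceTable) -> BiasSummary:
    """First-base U (=T) bias of an occurrence table at both levels.

    Raises ``ValueError`` on an empty table (the bias is undefined).
    """
    if not occ.entries:
        raise ValueError(f"occurrence table {occ.sample_id!r} is empty; 1U bias undefined")
    u_types = non_u_types = u_freq = non_u_freq = n_excluded = 0
    for seq, _length, count in occ.entries:
        first = seq[0]
        if first == "N":
            n_excluded += 1
            continue
        if first == "T":
            u_types += 1
            u_freq += count
        else:
            non_u_types += 1
            non_u_freq += count
    if u_types + non_u_types == 0:
        raise ValueError("all sequences start with N; 1U bias undefined")
    return BiasSummary(occ.sample_id, u_types, non_u_types, u_freq, non_u_freq, n_excluded)


def aggregate_bias(summaries: Sequence[BiasSummary], level: str) -> AggregateBias:
    """Arithmetic mean and sample SD (n-1) of per-sample percentages.

    The unrounded per-sample percentages feed the aggregation; only the
    mean and SD are rounded (1 dp).  Requires at least two summaries.
    """
    if level not in ("types", "frequencies"):
        raise ValueError(f"level must be 'types' or 'frequencies', got {level!r}")
    if len(summaries) < 2:
        raise ValueError("aggregate bias requires >= 2 samples")
    values = [
        s.bias_types_raw if level == "types" else s.bias_freq_raw for s in summaries
    ]
    return AggregateBias(level, round1(mean(values)), round1(stdev(values)), len(values))


def category_fraction(table: CountTable, category: str) -> float:
    """Percentage share of one category in a count table (1 dp)."""
    if table.total == 0:
        raise ValueError(f"count table {table.sample_id!r} has zero total")
    if category not in table.rows:
        raise ValueError(f"unknown category {category!r}")
    return round1(100.0 * table.rows[category] / table.total)


def top_sequences(occ: OccurrenceTable, n: int) -> list[tuple[int, str, int, int]]:
    """Top-``n`` sequences by occurrence count.

    Rows are ``(rank, sequence, length, count)``, descending by count
    with ties broken lexicographically by sequence.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    ranked = sorted(occ.entries, key=lambda e: (-e[2], e[0]))[:n]
    return [(i + 1, seq, length, count) for i, (seq, length, count) in enumerate(ranked)]


def match_known_pirnas(
    predicted: OccurrenceTable, catalog: ReferenceSet
) -> list[tuple[str, int, str]]:
    """Predicted sequences exactly identical to a catalog sequence.

    A match requires full-length identity in the same orientation
    (both sides U->T normalised at ingestion).  Rows are
    ``(sequence, this-study count, catalog id)`` sorted by this-study
    count descending, then sequence.
    """
    if catalog.role != "known_pirna":
        raise ValueError(f"catalog role must be 'known_pirna', got {catalog.role!r}")
    by_seq: dict[str, str] = {}
    for cid, seq in catalog.records:
        by_seq.setdefault(seq, cid)  # first catalog id wins for duplicates
    matches = [
        (seq, count, by_seq[seq])
        for seq, _length, count in predicted.entries
        if seq in by_seq
    ]
    matches.sort(key=lambda row: (-row[1], row[0]))
    return matches
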