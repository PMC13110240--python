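"""Adapter trimming, fixed-end trimming, quality filtering and the
18-40 nt length window.

Small-RNA library preparations ligate a 3' adapter to every insert;
with NEXTFLEX-style kits the insert is additionally flanked by 4
random bases on each side.  The stage removes the adapter (longest 3'
suffix of the read matching a prefix of the adapter within an error
budget), strips the fixed random ends, then keeps reads inside an
inclusive length window with sufficient mean base quality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from aquasrna.io_formats import SmallRNARead


@dataclass(frozen=True)
class PreprocessParams:
    """Trimming and filtering parameters.

    ``adapter3`` is the 3' adapter sequence; an adapter match needs
    overlap >= ``min_overlap`` bases with mismatch fraction
    <= ``max_error_rate``.  ``fixed_trim_5``/``fixed_trim_3`` remove
    the kit's random bases after adapter removal.  The length window
    [``min_len``, ``max_len``] is inclusive on both ends.
    """

    adapter3: str = "TGGAATTCTCGGGTGCCAAGG"
    min_overlap: int = 3
    max_error_rate: float = 0.1
    fixed_trim_5: int = 4
    fixed_trim_3: int = 4
    min_len: int = 18
    max_len: int = 40
    min_mean_quality: float = 20.0

    def __post_init__(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError(f"min_len {self.min_len} > max_len {self.max_len}")
        if self.min_overlap < 1:
            raise ValueError("min_overlap must be >= 1")
        if not 0.0 <= self.max_error_rate <= 1.0:
            raise ValueError("max_error_rate must be in [0, 1]")
        if self.fixed_trim_5 < 0 or self.fixed_trim_3 < 0:
            raise ValueError("fixed trims must be >= 0")


def trim_adapter(read: SmallRNARead, params: PreprocessParams) -> SmallRNARead | None:
    """Remove the 3' adapter and fixed random ends from one read.

    The longest 3' suffix of the read aligning (ungapped) to a prefix
    of the adapter with mismatch fraction <= ``max_error_rate`` and
    overlap >= ``min_overlap`` is removed; if no such suffix exists the
    read is left unchanged.  ``fixed_trim_5``/``fixed_trim_3`` bases
    are then cut from the ends.  Returns ``None`` when nothing of the
    read survives (such reads are dropped downstream).
    """
    seq = read.sequence
    adapter = params.adapter3
    if not adapter:
        raise ValueError("adapter3 must be non-empty")
    cut = len(seq)
    max_o = min(len(seq), len(adapter))
    for o in range(max_o, params.min_overlap - 1, -1):
        suffix = seq[len(seq) - o :]
        prefix = adapter[:o]
        mismatches = sum(a != b for a, b in zip(suffix, prefix))
        if mismatches <= int(params.max_error_rate * o):
            cut = len(seq) - o
            break
    start = params.fixed_trim_5
    end = cut - params.fixed_trim_3
    if end <= start:
        return None
    qual = read.quality[start:end] if read.quality is not None else None
    return SmallRNARead(read.read_id, seq[start:end], qual)


#: Drop-reason keys reported by :func:`length_quality_filter`.
DROP_REASONS = ("too_short", "too_long", "low_quality")


def length_quality_filter(
    reads: Iterable[SmallRNARead], params: PreprocessParams
) -> tuple[list[SmallRNARead], dict[str, int]]:
    """Keep reads inside the inclusive length window with adequate quality.

    Returns ``(kept, stats)`` where ``stats`` partitions the dropped
    reads by reason (``too_short``, ``too_long``, ``low_quality``).
    Every input read lands in exactly one of kept or one drop bin.
    Reads without qualities skip the quality test.
    """
    kept: list[SmallRNARead] = []
    stats = {reason: 0 for reason in DROP_REASONS}
    for read in reads:
        n = len(read)
        if n < params.min_len:
            stats["too_short"] += 1
        elif n > params.max_len:
            stats["too_long"] += 1
        elif (
            read.quality is not None
            and sum(read.quality) / n < params.min_mean_quality
        ):
            stats["low_quality"] += 1
        else:
            kept.append(read)
    return kept, stats


def preprocess_reads(
    reads: Iterable[SmallRNARead], params: PreprocessParams
) -> tuple[list[SmallRNARead], dict[str, int]]:
    """Full preprocessing: adapter + fixed-end trimming, then the
    length/quality filter.

    Reads trimmed to nothing are counted under ``too_short``.
    Conservation holds: ``len(kept) + sum(stats.values())`` equals the
    number of input reads.
    """
    trimmed: list[SmallRNARead] = []
    n_emptied = 0
    for read in reads:
        out = trim_adapter(read, params)
        if out is None:
            n_emptied += 1
        else:
            trimmed.append(out)
    kept, stats = length_quality_filter(trimmed, params)
    stats["too_short"] += n_emptied
    return kept, stats
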