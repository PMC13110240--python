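"""Short-read matching against reference sets.

Three search modes mirror the alignment semantics used for small-RNA
annotation:

* :func:`map_exact` — all zero-mismatch occurrences of a read (or its
  reverse complement) inside any reference sequence (``-v 0 -a``).
* :func:`map_one_mismatch` — best-stratum search allowing one
  mismatch: all 0-mismatch hits if any exist, otherwise all
  1-mismatch hits (``-v 1 -a --best --strata``).
* :func:`local_align_rescue` — Smith-Waterman local alignment with
  identity/coverage thresholds, used to rescue unannotated rRNA
  fragments (the role BLASTn plays at database scale).

The index is a fixed-k seed table over the forward strand; reverse
complements are handled at query time.  ``N`` never matches any base,
including another ``N``, so reads containing ``N`` cannot produce
zero-mismatch hits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio import Align

from aquasrna.io_formats import ReferenceSet

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class MatchHit:
    """An ungapped full-length hit of a read inside a reference.

    ``start`` is a 0-based offset on the reference forward strand; the
    hit occupies ``[start, start + read length)``.  ``strand`` is
    ``+`` when the read sequence itself matches the reference and
    ``-`` when its reverse complement does.
    """

    read_id: str
    ref_id: str
    start: int
    strand: str
    mismatches: int


@dataclass(frozen=True)
class LocalHit:
    """Best local alignment of a read against a rescue reference."""

    read_id: str
    ref_id: str
    identity: float
    coverage: float
    score: float


class SubstringIndex:
    """Seed table of all ``k``-mers of a reference set (forward strand).

    Exact search seeds with the read's first k-mer; one-mismatch search
    seeds with the prefixes of the read's two halves (pigeonhole: a hit
    with <= 1 mismatch leaves at least one half exact).  ``k`` must be
    at most half the shortest query, so the default of 8 supports
    queries down to 16 nt; shorter queries fall back to a sliding scan.
    """

    def __init__(self, refset: ReferenceSet, k: int = 8) -> None:
        if len(refset.records) == 0:
            raise ValueError(f"reference set {refset.name!r} is empty; cannot index")
        self.refset = refset
        self.k = k
        self._seqs: dict[str, str] = dict(refset.records)
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for rid, seq in refset.records:
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                self._seeds.setdefault(kmer, []).append((rid, i))

    def candidate_starts(self, query: str, offset: int) -> Iterable[tuple[str, int]]:
        """Reference positions where ``query[offset:offset+k]`` occurs,
        shifted so the returned start corresponds to ``query[0]``."""
        seed = query[offset : offset + self.k]
        if len(seed) < self.k or "N" in seed:
            return self._scan_starts(query, offset)
        return [(rid, pos - offset) for rid, pos in self._seeds.get(seed, ())]

    def _scan_starts(self, query: str, offset: int) -> list[tuple[str, int]]:
        # fallback for queries too short to seed: scan every position
        out = []
        for rid, seq in self._seqs.items():
            out.extend((rid, i) for i in range(len(seq) - len(query) + 1))
        return out

    def sequences(self) -> dict[str, str]:
        return self._seqs


def build_index(refset: ReferenceSet, k: int = 8) -> SubstringIndex:
    """Build a :class:`SubstringIndex` over a non-empty reference set."""
    return SubstringIndex(refset, k=k)


def _hamming(a: str, b: str, limit: int) -> int:
    """Mismatch count between equal-length strings, treating N as a
    mismatch against everything; returns ``limit + 1`` on early abort."""
    if a == b and "N" not in a:
        return 0
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if mm > limit:
                return mm
    return mm


def _search(read_id: str, seq: str, index: SubstringIndex, max_mm: int) -> list[MatchHit]:
    n = len(seq)
    hits: dict[tuple[str, int, str], int] = {}
    for strand, query in (("+", seq), ("-", reverse_complement(seq))):
        if max_mm == 0:
            offsets = (0,)
        else:
            # pigeonhole over two halves: at least one is exact for <=1 mm
            offsets = (0, n // 2)
        seen: set[tuple[str, int]] = set()
        for offset in offsets:
            for rid, start in index.candidate_starts(query, offset):
                if start < 0 or (rid, start) in seen:
                    continue
                seen.add((rid, start))
                ref = index.sequences()[rid]
                if start + n > len(ref):
                    continue
                mm = _hamming(query, ref[start : start + n], max_mm)
                if mm <= max_mm:
                    key = (rid, start, strand)
                    if key not in hits or mm < hits[key]:
                        hits[key] = mm
    out = [
        MatchHit(read_id, rid, start, strand, mm)
        for (rid, start, strand), mm in hits.items()
    ]
    out.sort(key=lambda h: (h.ref_id, h.start, h.strand))
    return out


def map_exact(read, index: SubstringIndex) -> list[MatchHit]:
    """All zero-mismatch hits of a read on either strand.

    Reads containing ``N`` return no hits (``N`` cannot match with
    zero mismatches).  Hits are ordered by (ref_id, start, strand).
    """
    seq = read.sequence if hasattr(read, "sequence") else read
    rid = read.read_id if hasattr(read, "read_id") else "query"
    if "N" in seq or not seq:
        return []
    return _search(rid, seq, index, max_mm=0)


def map_one_mismatch(read, index: SubstringIndex) -> list[MatchHit]:
    """Best-stratum search with at most one mismatch.

    If any zero-mismatch hit exists, exactly the zero-mismatch hits are
    returned; otherwise all one-mismatch hits; otherwise an empty list.
    """
    seq = read.sequence if hasattr(read, "sequence") else read
    rid = read.read_id if hasattr(read, "read_id") else "query"
    if not seq:
        return []
    hits = _search(rid, seq, index, max_mm=1)
    best = min((h.mismatches for h in hits), default=None)
    if best is None:
        return []
    return [h for h in hits if h.mismatches == best]


# ---------------------------------------------------------------------------
# Local-alignment rescue

_ALIGNER = Align.PairwiseAligner(
    mode="local",
    match_score=1,
    mismatch_score=-2,
    open_gap_score=-2,
    extend_gap_score=-2,
)


def _alignment_stats(alignment) -> tuple[float, int, int]:
    """(matches, alignment columns, aligned query span) of a local alignment."""
    ref_blocks, query_blocks = alignment.aligned
    target = alignment.target
    query = alignment.query
    matches = 0
    aligned_cols = 0
    prev_r_end = prev_q_end = None
    for (rs, re), (qs, qe) in zip(ref_blocks, query_blocks):
        if prev_r_end is not None:
            aligned_cols += (rs - prev_r_end) + (qs - prev_q_end)  # gap columns
        aligned_cols += re - rs
        matches += sum(a == b for a, b in zip(target[rs:re], query[qs:qe]))
        prev_r_end, prev_q_end = re, qe
    if query_blocks.size == 0:
        return 0.0, 0, 0
    q_span = int(query_blocks[-1][1] - query_blocks[0][0])
    return float(matches), aligned_cols, q_span


def local_align_rescue(
    read,
    rescue_set: ReferenceSet,
    min_identity: float = 0.85,
    min_coverage: float = 0.8,
) -> LocalHit | None:
    """Best Smith-Waterman local hit of a read against a rescue set.

    Scoring is match +1 / mismatch -2 / gap -2.  Both strands of the
    read are searched.  A hit qualifies when identity over the aligned
    columns (gap columns count against identity) is >= ``min_identity``
    and the aligned span covers >= ``min_coverage`` of the read.  The
    highest-scoring qualifying hit wins; ties break by (ref_id, then
    the aligner's first optimal alignment).  Returns ``None`` when no
    hit qualifies.
    """
    if not 0 < min_identity <= 1 or not 0 < min_coverage <= 1:
        raise ValueError("thresholds must be in (0, 1]")
    seq = read.sequence if hasattr(read, "sequence") else read
    rid = read.read_id if hasattr(read, "read_id") else "query"
    best: LocalHit | None = None
    for ref_id, ref_seq in sorted(rescue_set.records):
        for query in (seq, reverse_complement(seq)):
            alignments = _ALIGNER.align(ref_seq, query)
            try:
                aln = alignments[0]
            except IndexError:
                continue
            if aln.score <= 0:
                continue
            matches, cols, q_span = _alignment_stats(aln)
            if cols == 0:
                continue
            identity = matches / cols
            coverage = q_span / len(seq)
            if identity < min_identity or coverage < min_coverage:
                continue
            hit = LocalHit(rid, ref_id, identity, coverage, float(aln.score))
            if best is None or hit.score > best.score:
                best = hit
    return best
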