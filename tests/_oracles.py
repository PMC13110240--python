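"""Independent brute-force oracles the matcher is checked against.

These deliberately share no code with ``aquasrna.matcher``: exact and
Hamming search use a numpy sliding-window comparison over every
reference offset; local alignment re-derives the best score with a
plain Smith-Waterman dynamic program.
"""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def rc(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def hamming_scan(query: str, refs: dict[str, str], max_mm: int) -> set[tuple[str, int, str, int]]:
    """All (ref_id, start, strand, mismatches) with <= max_mm
    mismatches, N mismatching everything including N."""
    hits: set[tuple[str, int, str, int]] = set()
    n_code = ord("N")
    for strand, q in (("+", query), ("-", rc(query))):
        q_arr = _encode(q)
        for ref_id, ref in refs.items():
            if len(ref) < len(q):
                continue
            windows = np.lib.stride_tricks.sliding_window_view(_encode(ref), len(q))
            mism = ((windows != q_arr) | (windows == n_code) | (q_arr == n_code)).sum(axis=1)
            for start in np.nonzero(mism <= max_mm)[0]:
                hits.add((ref_id, int(start), strand, int(mism[start])))
    return hits


def best_stratum(hits: set[tuple[str, int, str, int]]) -> set[tuple[str, int, str, int]]:
    if not hits:
        return set()
    best = min(mm for _, _, _, mm in hits)
    return {h for h in hits if h[3] == best}


def smith_waterman_score(a: str, b: str, match: int = 1, mismatch: int = -2, gap: int = -2) -> int:
    """Best local alignment score by direct dynamic programming."""
    prev = [0] * (len(b) + 1)
    best = 0
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            sub = match if a[i - 1] == b[j - 1] else mismatch
            cur[j] = max(0, prev[j - 1] + sub, prev[j] + gap, cur[j - 1] + gap)
            if cur[j] > best:
                best = cur[j]
        prev = cur
    return best
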