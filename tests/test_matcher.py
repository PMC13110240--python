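import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from _oracles import best_stratum, hamming_scan, rc, smith_waterman_score
from conftest import make_refset
from aquasrna.matcher import (
    build_index,
    local_align_rescue,
    map_exact,
    map_one_mismatch,
    reverse_complement,
)


def hitset(hits):
    return {(h.ref_id, h.start, h.strand, h.mismatches) for h in hits}


class TestIndex:
    def test_exact_lookup(self):
        index = build_index(make_refset("genome", {"a": "ACGTACGT"}))
        assert map_exact("CGTA", index)
        assert not map_exact("AAAA", index)

    def test_shared_substring_reported_in_both_references(self):
        index = build_index(make_refset("genome", {"a": "TTACGTACGTTT", "b": "GGACGTACGAA"}))
        assert {h.ref_id for h in map_exact("ACGTACG", index)} == {"a", "b"}

    def test_empty_reference_set_rejected(self):
        from aquasrna.io_formats import ReferenceSet

        with pytest.raises(ValueError, match="empty"):
            build_index(ReferenceSet("e", "genome", ()))

    def test_n_in_reference_never_matches(self):
        random.seed(0)
        ref = "".join(random.choice("ACGTN") for _ in range(300))
        refs = {"a": ref}
        index = build_index(make_refset("genome", refs))
        for _ in range(50):
            start = random.randrange(0, 280)
            query = ref[start : start + 20].replace("N", "A")
            assert hitset(map_exact(query, index)) == hamming_scan(query, refs, 0)


class TestMapExact:
    def test_plus_strand_hit_position(self):
        index = build_index(make_refset("genome", {"a": "TTAAGTTT"}))
        (hit,) = map_exact("AAGT", index)
        assert (hit.ref_id, hit.start, hit.strand, hit.mismatches) == ("a", 2, "+", 0)

    def test_reverse_complement_hit(self):
        index = build_index(make_refset("genome", {"a": "GGCCTTGG"}))
        (hit,) = map_exact("AAGG", index)  # rc(AAGG) = CCTT at offset 2
        assert (hit.start, hit.strand) == (2, "-")

    def test_read_with_n_returns_no_hits(self):
        index = build_index(make_refset("genome", {"a": "ACGTNACGT"}))
        assert map_exact("GTNA", index) == []

    def test_brute_force_equivalence_random_25mers(self):
        rng = random.Random(1)
        refs = {"chr": "".join(rng.choice("ACGT") for _ in range(10_000))}
        index = build_index(make_refset("genome", refs))
        for i in range(200):
            if i % 2:
                start = rng.randrange(0, 9_975)
                query = refs["chr"][start : start + 25]
            else:
                query = "".join(rng.choice("ACGT") for _ in range(25))
            assert hitset(map_exact(query, index)) == hamming_scan(query, refs, 0)


class TestMapOneMismatch:
    def test_single_mismatch_hit(self):
        ref = "GGGGACGTACGTACGTACGTACGGGG"
        index = build_index(make_refset("mirna", {"a": ref}))
        query = "ACGTACGTACTTACGTACG"  # one substitution vs offset 4
        (hit,) = map_one_mismatch(query, index)
        assert hit.mismatches == 1 and hit.start == 4

    def test_best_stratum_suppresses_one_mismatch_hits(self):
        # query occurs exactly in ref a, and with 1 mismatch in ref b
        query = "ACGTACGTACGTACGTAC"
        refs = {"a": "TT" + query + "TT", "b": "TT" + "ACGTACGTACTTACGTAC" + "TT"}
        index = build_index(make_refset("mirna", refs))
        hits = map_one_mismatch(query, index)
        assert {h.ref_id for h in hits} == {"a"}
        assert all(h.mismatches == 0 for h in hits)

    def test_brute_force_equivalence_with_planted_mismatches(self):
        rng = random.Random(2)
        refs = {"chr": "".join(rng.choice("ACGT") for _ in range(8_000))}
        index = build_index(make_refset("genome", refs))
        for i in range(100):
            start = rng.randrange(0, 7_970)
            query = list(refs["chr"][start : start + 22])
            for _ in range(i % 3):  # 0, 1 or 2 substitutions
                pos = rng.randrange(22)
                query[pos] = rng.choice([b for b in "ACGT" if b != query[pos]])
            query = "".join(query)
            assert hitset(map_one_mismatch(query, index)) == best_stratum(
                hamming_scan(query, refs, 1)
            )


class TestStrandSymmetry:
    @settings(max_examples=60, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_mapping_rc_swaps_strands(self, seed):
        rng = random.Random(seed)
        refs = {"a": "".join(rng.choice("ACGT") for _ in range(400))}
        index = build_index(make_refset("genome", refs))
        start = rng.randrange(0, 380)
        query = refs["a"][start : start + 20]
        fwd = hitset(map_exact(query, index))
        rev = hitset(map_exact(reverse_complement(query), index))
        flipped = {(r, s, "+-"[strand == "+"], m) for r, s, strand, m in fwd}
        assert rev == flipped


class TestLocalRescue:
    def _rescue_set(self, seq):
        return make_refset("rrna_rescue", {"rescue_1": seq})

    def test_exact_slice_has_full_identity_and_coverage(self):
        rng = random.Random(3)
        ref = "".join(rng.choice("ACGT") for _ in range(400))
        hit = local_align_rescue(ref[100:130], self._rescue_set(ref), 0.85, 0.8)
        assert hit is not None
        assert hit.identity == 1.0 and hit.coverage == 1.0 and hit.score == 30

    def test_three_scattered_mismatches_accepted_at_identity_090(self):
        rng = random.Random(4)
        ref = "".join(rng.choice("ACGT") for _ in range(400))
        read = list(ref[50:80])
        for pos in (5, 14, 22):
            read[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[pos]]
        hit = local_align_rescue("".join(read), self._rescue_set(ref), 0.85, 0.8)
        assert hit is not None
        assert hit.identity == pytest.approx(27 / 30)
        assert hit.score == 27 - 2 * 3  # hand-scored: 27 matches, 3 mismatches

    def test_unrelated_read_rejected(self):
        rng = random.Random(5)
        ref = "".join(rng.choice("ACGT") for _ in range(400))
        read = "".join(rng.choice("ACGT") for _ in range(30))
        # guard against an accidental plant
        assert smith_waterman_score(ref, read) < 0.44 * 30
        assert local_align_rescue(read, self._rescue_set(ref), 0.85, 0.8) is None

    def test_reverse_complement_orientation_found(self):
        rng = random.Random(6)
        ref = "".join(rng.choice("ACGT") for _ in range(300))
        hit = local_align_rescue(rc(ref[40:70]), self._rescue_set(ref), 0.85, 0.8)
        assert hit is not None and hit.coverage == 1.0

    def test_score_agrees_with_dp_oracle_on_accepted_hits(self):
        rng = random.Random(7)
        ref = "".join(rng.choice("ACGT") for _ in range(300))
        rescue = self._rescue_set(ref)
        for _ in range(30):
            start = rng.randrange(0, 270)
            read = list(ref[start : start + 28])
            for _ in range(rng.randrange(3)):
                pos = rng.randrange(28)
                read[pos] = rng.choice([b for b in "ACGT" if b != read[pos]])
            read = "".join(read)
            hit = local_align_rescue(read, rescue, 0.85, 0.8)
            oracle = max(smith_waterman_score(ref, read), smith_waterman_score(ref, rc(read)))
            if hit is not None:
                assert hit.score == oracle

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            local_align_rescue("ACGT", self._rescue_set("ACGTACGT"), 0.0, 0.5)
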