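import random

import pytest

from conftest import make_read, make_refset
from aquasrna.cascade import (
    CascadeParams,
    ClassifyResult,
    RepeatCall,
    classify_read,
    classify_sample,
    detect_tandem_repeat,
)
from aquasrna.io_formats import CATEGORY_ORDER
from aquasrna.matcher import LocalHit, MatchHit

PARAMS = CascadeParams()
NO_REPEAT = RepeatCall(False)


def fake_hit(ref_id="ref1", mismatches=0):
    return [MatchHit("r1", ref_id, 0, "+", mismatches)]


class TestTandemRepeat:
    def test_pure_dinucleotide_repeat(self):
        call = detect_tandem_repeat("AT" * 13)
        assert call.is_repeat and call.motif == "AT" and call.repeat_count == 13

    def test_non_repetitive_sequence(self):
        assert not detect_tandem_repeat("ACGTACGGTTACGATCGGATACGGATCA").is_repeat

    def test_mononucleotide_below_threshold(self):
        assert not detect_tandem_repeat("AAAAAAAAA").is_repeat  # 9 < 10

    def test_mononucleotide_at_threshold(self):
        call = detect_tandem_repeat("A" * 10)
        assert call.is_repeat and call.repeat_count == 10

    def test_qualifying_run_below_span_rule_is_not_a_repeat(self):
        seq = "A" * 12 + "CGTGACTGACGTGCATCGAGTCAGTTCG"  # span 12/40 = 0.3
        call = detect_tandem_repeat(seq)
        assert not call.is_repeat and call.motif == "A" and call.span == pytest.approx(0.3)

    def test_exhaustive_scan_agrees_with_oracle(self):
        # oracle: check every motif length and start by direct expansion
        def oracle(seq, thresholds={1: 10, 2: 6, 3: 5, 4: 5, 5: 5, 6: 5}, span=0.8):
            best = 0
            for m in range(1, 7):
                for i in range(len(seq) - m + 1):
                    motif = seq[i : i + m]
                    k = 1
                    while seq[i + k * m : i + (k + 1) * m] == motif:
                        k += 1
                    if k >= thresholds[m]:
                        best = max(best, k * m)
            return best / len(seq) >= span if best else False

        rng = random.Random(8)
        seqs = ["".join(rng.choice("ACGT") for _ in range(rng.randint(18, 40))) for _ in range(200)]
        seqs += ["CAG" * 9, "ACAC" * 7, "T" * 25, "GGC" * 4 + "ACGTACGTACGTAA"]
        for seq in seqs:
            assert detect_tandem_repeat(seq).is_repeat == oracle(seq), seq


class TestClassifyRead:
    def test_rrna_exact_hit_wins(self):
        read = make_read("ACG" * 10)
        rec = classify_read(read, {"rrna": fake_hit()}, NO_REPEAT, PARAMS)
        assert rec.category == "rRNA" and rec.stage == "ncrna:rrna"

    def test_ncrna_priority_order(self):
        read = make_read("ACG" * 10)
        hits = {"trna": fake_hit("t"), "snrna": fake_hit("s")}
        assert classify_read(read, hits, NO_REPEAT, PARAMS).category == "tRNA"

    def test_rescue_hit_assigns_rrna(self):
        read = make_read("ACG" * 10)
        rescue = LocalHit("r1", "rescue_1", 0.93, 1.0, 22.0)
        rec = classify_read(read, {"rrna_rescue": rescue}, NO_REPEAT, PARAMS)
        assert rec.category == "rRNA" and rec.stage == "rrna_rescue"

    def test_canonical_mirna_length_gate(self):
        rec = classify_read(make_read("A" * 22), {"mirna": fake_hit(mismatches=1)}, NO_REPEAT, PARAMS)
        assert rec.category == "miRNA" and rec.mismatches == 1

    def test_mirna_hit_outside_canonical_window_is_unknown(self):
        rec = classify_read(make_read("ACGTT" * 6), {"mirna": fake_hit()}, NO_REPEAT, PARAMS)
        assert rec.category == "unknown" and rec.stage == "mirna_noncanonical_length"

    def test_repeat_call_excludes_from_pirna(self):
        repeat = RepeatCall(True, "AT", 13, 1.0)
        rec = classify_read(make_read("AT" * 13), {}, repeat, PARAMS)
        assert rec.category == "unknown" and rec.stage == "tandem_repeat"

    @pytest.mark.parametrize("length, category", [(24, "unknown"), (25, "piRNA"), (32, "piRNA"), (33, "unknown")])
    def test_pirna_window_boundaries(self, length, category):
        base = "ACGTTGCAA" * 4  # 36 nt, sliced below
        rec = classify_read(make_read(base[:length]), {}, NO_REPEAT, PARAMS)
        assert rec.category == category


class TestClassifySample:
    def test_truth_composition_recovered_exactly(self, tank_sample):
        from aquasrna.preprocess import PreprocessParams, preprocess_reads
        from aquasrna.simulate import evaluate_recovery

        config, refs, reads, truth = tank_sample
        kept, _ = preprocess_reads(reads, PreprocessParams())
        result = classify_sample(kept, refs.bundle, sample_id="tank")
        recovery = evaluate_recovery(truth, result.records, result.unmapped_read_ids)
        assert recovery.overall_accuracy == 1.0
        from collections import Counter

        truth_counts = Counter(t.true_category for t in truth)
        for cat in CATEGORY_ORDER:
            assert result.count_table.rows[cat] == truth_counts.get(cat, 0)

    def test_zero_reads_gives_zero_table(self):
        bundle = {"rrna": make_refset("rrna", {"x": "ACGT" * 10})}
        result = classify_sample([], bundle, CascadeParams(require_genome_hit=False))
        assert result.count_table.total == 0

    def test_duplicate_pirna_reads_counted_per_occurrence(self):
        seq = "ATCGGATTCAGGACTTACGGATCAGGCA"  # 28 nt, no hits, not a repeat
        reads = [make_read(seq, read_id=f"r{i}") for i in range(50)]
        result = classify_sample(reads, {}, CascadeParams(require_genome_hit=False))
        assert result.count_table.rows["piRNA"] == 50
        assert len(set(result.pirna_occurrences)) == 1
        assert len(result.pirna_occurrences) == 50

    def test_order_insensitivity_of_count_table(self, tank_sample):
        from aquasrna.preprocess import PreprocessParams, preprocess_reads

        config, refs, reads, truth = tank_sample
        kept, _ = preprocess_reads(reads[:400], PreprocessParams())
        fwd = classify_sample(kept, refs.bundle, sample_id="s")
        rev = classify_sample(list(reversed(kept)), refs.bundle, sample_id="s")
        assert fwd.count_table == rev.count_table

    def test_partition_and_window_invariants(self, tank_sample):
        from aquasrna.preprocess import PreprocessParams, preprocess_reads

        config, refs, reads, truth = tank_sample
        kept, _ = preprocess_reads(reads, PreprocessParams())
        result = classify_sample(kept, refs.bundle, sample_id="tank")
        assert result.count_table.total + len(result.unmapped_read_ids) == len(kept)
        assert result.count_table.total == len(result.records)
        for rec in result.records:
            if rec.category == "piRNA":
                assert 25 <= len(rec.sequence) <= 32
            if rec.category == "miRNA":
                assert 20 <= len(rec.sequence) <= 24

    def test_missing_genome_role_skips_gate(self):
        seq = "ATCGGATTCAGGACTTACGGATCAGGCA"
        result = classify_sample([make_read(seq)], {}, CascadeParams())
        assert result.count_table.total == 1
        assert "genome" in result.skipped_stages


class TestCascadeParams:
    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="disjoint"):
            CascadeParams(mirna_max_len=26)

    def test_inverted_pirna_window_rejected(self):
        with pytest.raises(ValueError):
            CascadeParams(pirna_min_len=33, pirna_max_len=32)
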