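import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_refset
from aquasrna.io_formats import CountTable, ReferenceSet
from aquasrna.pirna_stats import (
    BiasSummary,
    OccurrenceTable,
    aggregate_bias,
    category_fraction,
    first_base_bias,
    match_known_pirnas,
    round1,
    top_sequences,
)

occ_entries = st.dictionaries(
    st.text(alphabet="ACGT", min_size=25, max_size=32),
    st.integers(1, 50),
    min_size=1,
    max_size=40,
)


def occ_from_dict(d, sample="s"):
    return OccurrenceTable(sample, tuple((seq, len(seq), n) for seq, n in sorted(d.items())))


class TestFirstBaseBias:
    def test_counts_and_percentages_from_mixed_table(self):
        occ = occ_from_dict({"T" + "ACG" * 9: 4, "A" + "CGT" * 9: 1, "TGCA" * 7: 5})
        bias = first_base_bias(occ)
        assert (bias.u_types, bias.non_u_types) == (2, 1)
        assert (bias.u_freq, bias.non_u_freq) == (9, 1)
        assert bias.bias_types_pct == 66.7 and bias.bias_freq_pct == 90.0

    def test_all_u_table_is_100_percent(self):
        occ = occ_from_dict({"TGGG" + "ACG" * 8: 10})
        bias = first_base_bias(occ)
        assert bias.bias_types_pct == 100.0 and bias.bias_freq_pct == 100.0

    def test_empty_table_raises(self):
        with pytest.raises(ValueError, match="empty"):
            first_base_bias(OccurrenceTable("s", ()))

    @settings(max_examples=100, derandomize=True)
    @given(occ_entries)
    def test_partition_invariant(self, d):
        occ = occ_from_dict(d)
        bias = first_base_bias(occ)
        assert bias.u_types + bias.non_u_types == occ.n_types
        assert bias.u_freq + bias.non_u_freq == occ.total
        assert 0 <= bias.bias_types_pct <= 100 and 0 <= bias.bias_freq_pct <= 100


class TestAggregateBias:
    def test_equal_inputs_have_zero_sd(self):
        summaries = [BiasSummary(f"s{i}", 10, 30, 20, 60) for i in range(4)]
        agg = aggregate_bias(summaries, "types")
        assert agg.mean_pct == 25.0 and agg.sd_pct == 0.0 and agg.n_samples == 4

    def test_fewer_than_two_samples_raises(self):
        with pytest.raises(ValueError, match=">= 2"):
            aggregate_bias([BiasSummary("s", 1, 1, 1, 1)], "types")

    def test_unknown_level_raises(self):
        with pytest.raises(ValueError, match="level"):
            aggregate_bias([BiasSummary("s", 1, 1, 1, 1)] * 2, "reads")

    def test_mean_bounded_by_extremes(self):
        summaries = [BiasSummary("a", 10, 90, 1, 1), BiasSummary("b", 30, 70, 1, 1)]
        agg = aggregate_bias(summaries, "types")
        assert 10.0 <= agg.mean_pct <= 30.0


class TestCategoryFraction:
    def test_single_category_table_is_100(self):
        rows = dict.fromkeys(("piRNA", "miRNA", "rRNA", "tRNA", "snRNA", "other_ncRNAs", "unknown"), 0)
        rows["rRNA"] = 7
        assert category_fraction(CountTable("s", rows), "rRNA") == 100.0

    def test_zero_total_raises(self):
        with pytest.raises(ValueError, match="zero total"):
            category_fraction(CountTable.zero("s"), "piRNA")

    def test_unknown_category_raises(self):
        rows = dict.fromkeys(("piRNA", "miRNA", "rRNA", "tRNA", "snRNA", "other_ncRNAs", "unknown"), 1)
        with pytest.raises(ValueError, match="category"):
            category_fraction(CountTable("s", rows), "mRNA")


class TestTopSequences:
    def test_highest_count_wins(self):
        occ = occ_from_dict({"A" * 30: 5, "T" * 28: 9})
        assert top_sequences(occ, 1) == [(1, "T" * 28, 28, 9)]

    def test_ties_break_lexicographically(self):
        occ = occ_from_dict({"TTTT" + "A" * 24: 3, "AAAA" + "T" * 24: 3})
        ranks = top_sequences(occ, 2)
        assert [r[1][:4] for r in ranks] == ["AAAA", "TTTT"]

    def test_rank_rows_carry_length(self):
        seq = "GGAAGGTCCGGAGAGTCTAGGTTACCCAATT"
        occ = occ_from_dict({seq: 198})
        assert top_sequences(occ, 1) == [(1, seq, 31, 198)]

    def test_invalid_n_raises(self):
        with pytest.raises(ValueError):
            top_sequences(occ_from_dict({"A" * 25: 1}), 0)


class TestMatchKnownPirnas:
    def test_exact_full_length_match_found(self):
        seq = "GGCCGTGATCGTATAGTGGTTAGTACTTCGCG"
        occ = occ_from_dict({seq: 13})
        catalog = make_refset("known_pirna", {"cat_1": seq})
        assert match_known_pirnas(occ, catalog) == [(seq, 13, "cat_1")]

    def test_one_mismatch_variant_not_matched(self):
        seq = "GGCCGTGATCGTATAGTGGTTAGTACTTCGCG"
        variant = "A" + seq[1:]
        occ = occ_from_dict({variant: 5})
        catalog = make_refset("known_pirna", {"cat_1": seq})
        assert match_known_pirnas(occ, catalog) == []

    def test_empty_catalog_gives_no_matches(self):
        occ = occ_from_dict({"A" * 28: 1})
        assert match_known_pirnas(occ, ReferenceSet("c", "known_pirna", ())) == []

    def test_wrong_catalog_role_rejected(self):
        occ = occ_from_dict({"A" * 28: 1})
        with pytest.raises(ValueError, match="role"):
            match_known_pirnas(occ, make_refset("mirna", {"m": "A" * 22}))

    @settings(max_examples=60, derandomize=True)
    @given(occ_entries)
    def test_reflexivity(self, d):
        occ = occ_from_dict(d)
        catalog = ReferenceSet(
            "self", "known_pirna", tuple((f"c{i}", seq) for i, (seq, _l, _n) in enumerate(occ.entries))
        )
        matched = match_known_pirnas(occ, catalog)
        assert {seq for seq, _n, _c in matched} == {seq for seq, _l, _n in occ.entries}


class TestRounding:
    @pytest.mark.parametrize("value, expected", [(22.45, 22.5), (19.114, 19.1), (23.588, 23.6), (0.05, 0.1)])
    def test_half_up_at_one_decimal(self, value, expected):
        assert round1(value) == expected
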