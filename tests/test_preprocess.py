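"""Read cleaning, tag collapsing, and library profiling."""

import pytest
from hypothesis import given, settings, strategies as st

from halomir import preprocess
from halomir.preprocess import RawRead, filter_reads, trim_adapter

ADAPTER = "TGGAATTCTCGG"


def naive_trim(seq: str, adapter: str, min_overlap: int) -> str:
    """Exhaustive scan over all adapter-prefix placements (oracle)."""
    for pos in range(len(seq)):
        for k in range(len(adapter), min_overlap - 1, -1):
            if seq[pos : pos + k] == adapter[:k] and pos + k <= len(seq):
                return seq[:pos]
    return seq


class TestTrimAdapter:
    def test_trims_at_leftmost_adapter_prefix(self):
        read = RawRead("r", "TGACAGAAGAGAGTGAGCAC" + "TGGAATTC")
        out = trim_adapter(read, ADAPTER, min_overlap=6)
        assert out.sequence == "TGACAGAAGAGAGTGAGCAC"
        assert out.sequence == naive_trim(read.sequence, ADAPTER, 6)

    def test_read_without_adapter_unchanged(self):
        read = RawRead("r", "ACGTACGTACGTACGTAC")
        assert trim_adapter(read, ADAPTER, 6).sequence == read.sequence

    def test_adapter_only_read_trims_to_empty(self):
        assert trim_adapter(RawRead("r", ADAPTER), ADAPTER, 6).sequence == ""

    def test_quality_trimmed_with_sequence(self):
        read = RawRead("r", "ACGTACGT" + ADAPTER, "I" * (8 + len(ADAPTER)))
        out = trim_adapter(read, ADAPTER, 6)
        assert len(out.quality) == len(out.sequence) == 8

    def test_empty_adapter_rejected(self):
        with pytest.raises(ValueError):
            trim_adapter(RawRead("r", "ACGT"), "", 1)

    @given(st.text(alphabet="ACGT", min_size=1, max_size=40))
    @settings(max_examples=200, derandomize=True)
    def test_matches_exhaustive_scan(self, seq):
        out = trim_adapter(RawRead("r", seq), ADAPTER, 4)
        assert out.sequence == naive_trim(seq, ADAPTER, 4)


class TestFilterReads:
    def test_three_rules_applied(self):
        reads = (
            [RawRead(f"short{i}", "ACGT" * 4) for i in range(3)]  # 16 nt
            + [RawRead("ambig", "ACGTNACGTACGTACGTACGTACGT")]  # N
            + [RawRead("contam", "A" * 20)]
            + [RawRead(f"ok{i}", "ACGT" * 5 + "AC") for i in range(5)]  # 22 nt
        )
        kept = filter_reads(reads, contaminants={"A" * 20})
        assert [r.identifier for r in kept] == [f"ok{i}" for i in range(5)]

    @pytest.mark.parametrize(
        "seq,kept",
        [
            ("A" * 17 + "C", True),  # 18 nt boundary
            ("A" * 17, False),  # 17 nt
            ("ACGT" * 6 + "A", True),  # 25 nt
            ("ACGT" * 6 + "AC", False),  # 26 nt
            ("ACGT" * 5 + "NACGT", False),  # ambiguous
        ],
    )
    def test_length_and_ambiguity_boundaries(self, seq, kept):
        assert bool(filter_reads([RawRead("r", seq)])) is kept

    def test_refiltering_is_idempotent(self):
        reads = [RawRead("a", "ACGT" * 5), RawRead("b", "ACGT" * 7)]
        once = filter_reads(reads)
        assert filter_reads(once) == once

    @given(st.lists(st.text(alphabet="ACGT", min_size=18, max_size=25), max_size=20))
    @settings(max_examples=100, derandomize=True)
    def test_trim_then_filter_identity_on_clean_reads(self, seqs):
        # adapter-free, valid-length reads pass cleaning unchanged
        reads = [RawRead(str(i), s) for i, s in enumerate(seqs) if naive_trim(s, ADAPTER, 4) == s]
        out = preprocess.clean_library(reads, ADAPTER, min_overlap=4)
        assert [r.sequence for r in out] == [r.sequence for r in reads]


class TestCollapseTags:
    def test_counting(self):
        x, y = "ACGTACGTACGTACGTAC", "TGCATGCATGCATGCATG"
        reads = [RawRead("1", x), RawRead("2", x), RawRead("3", y)]
        tags, profiles = preprocess.collapse_tags({"lib": reads})
        assert {t.sequence: t.count("lib") for t in tags} == {x: 2, y: 1}
        assert profiles["lib"].total_clean_reads == 3

    def test_unique_histogram_fractions(self):
        mers21 = [b + "A" * 20 for b in "CGT"]
        mers24 = [b + "C" * 23 for b in "ACGT"] + ["GG" + "C" * 22]
        reads = [RawRead(str(i), s) for i, s in enumerate(mers21 + mers24)]
        tags, profiles = preprocess.collapse_tags({"lib": reads})
        hist = profiles["lib"].unique_size_histogram
        assert hist[21] == 3 and hist[24] == 5
        assert hist[21] / sum(hist.values()) == pytest.approx(0.375)

    def test_tag_counts_conserve_clean_reads(self, cleaned):
        _, tags, profiles = cleaned
        for library, profile in profiles.items():
            assert sum(t.count(library) for t in tags) == profile.total_clean_reads
            assert sum(profile.redundant_size_histogram.values()) == profile.total_clean_reads
            assert sum(profile.unique_size_histogram.values()) == sum(
                1 for t in tags if t.count(library)
            )

    def test_surviving_lengths_in_range(self, cleaned):
        _, tags, _ = cleaned
        assert all(18 <= len(t.sequence) <= 25 for t in tags)

    def test_first_nt_rows_sum_to_one(self, cleaned):
        _, _, profiles = cleaned
        for profile in profiles.values():
            for fractions in profile.first_nt_by_length.values():
                assert sum(fractions.values()) == pytest.approx(1.0, abs=1e-9)
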