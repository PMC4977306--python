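"""Expectation scoring, target scanning, and inhibition-mode classification."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from halomir import seqio
from halomir.targets import (
    ScoringScheme,
    classify_inhibition,
    scan,
    score_duplex,
)

MIRNA = "TGACAGAAGAGAGTGAGCAC"  # 20 nt


def site_for(mirna: str) -> str:
    return seqio.reverse_complement(mirna)


def mutate_site(mirna: str, mirna_pos_1based: int, wobble: bool = False) -> str:
    """Site with the base opposite one miRNA position altered."""
    site = list(site_for(mirna))
    idx = len(site) - mirna_pos_1based  # site index opposite miRNA position
    base = mirna[mirna_pos_1based - 1]
    if wobble:
        replacement = {"G": "T", "T": "G"}[base]  # G:U wobble partner
    else:
        replacement = {"A": "C", "C": "A", "G": "G", "T": "C"}[base]
    site[idx] = replacement
    return "".join(site)


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        expectation, unpaired = score_duplex(MIRNA, site_for(MIRNA))
        assert expectation == 0.0 and unpaired == ()

    def test_gu_outside_seed_scores_half(self):
        site = mutate_site(MIRNA, 15, wobble=True)
        expectation, unpaired = score_duplex(MIRNA, site)
        assert expectation == pytest.approx(0.5)
        assert unpaired == ()  # wobble still pairs

    def test_seed_mismatch_scores_one_and_a_half(self):
        site = mutate_site(MIRNA, 5)
        expectation, unpaired = score_duplex(MIRNA, site)
        assert expectation == pytest.approx(1.5)
        assert unpaired == (5,)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            score_duplex(MIRNA, "ACGT")

    @given(st.sets(st.integers(1, 20), max_size=6))
    @settings(max_examples=100, derandomize=True)
    def test_expectation_monotone_under_added_mismatches(self, positions):
        # scoring a site is monotone: each extra mismatch adds a penalty
        ordered = sorted(positions)
        site = site_for(MIRNA)
        previous = 0.0
        for k in range(len(ordered) + 1):
            current = list(site)
            for pos in ordered[:k]:
                current[len(site) - pos] = mutate_site(MIRNA, pos)[len(site) - pos]
            expectation, _ = score_duplex(MIRNA, "".join(current))
            assert expectation >= previous - 1e-12
            previous = expectation


class TestScan:
    def test_exact_reverse_complement_found_with_zero_expectation(self):
        transcript = "A" * 40 + site_for(MIRNA) + "C" * 40
        sites = scan("m", MIRNA, {"t": transcript})
        exact = [s for s in sites if s.expectation == 0.0]
        assert len(exact) == 1
        assert exact[0].site_span == (40, 40 + len(MIRNA))
        assert exact[0].inhibition == "cleavage"

    def test_seed_mismatch_reported_three_suppressed(self):
        one_mm = "A" * 30 + mutate_site(MIRNA, 5) + "G" * 30
        sites = scan("m", MIRNA, {"t": one_mm})
        assert any(s.expectation == pytest.approx(1.5) for s in sites)
        three = list(site_for(MIRNA))
        for pos in (3, 5, 7):
            three[len(three) - pos] = mutate_site(MIRNA, pos)[len(three) - pos]
        sites = scan("m", MIRNA, {"t": "A" * 30 + "".join(three) + "G" * 30})
        assert all(s.expectation <= 3.0 for s in sites)
        assert not any(s.site_span == (30, 50) for s in sites)  # 4.5 > cutoff

    def test_empty_transcript_set(self):
        assert scan("m", MIRNA, {}) == []

    def test_agrees_with_brute_force_scorer(self):
        rng = random.Random(9)
        transcript = "".join(rng.choice("ACGT") for _ in range(400))
        transcript = transcript[:150] + site_for(MIRNA) + transcript[150:]
        got = {
            (s.site_span, s.expectation)
            for s in scan("m", MIRNA, {"t": transcript}, max_expectation=5.0)
        }
        expected = set()
        m = len(MIRNA)
        for offset in range(len(transcript) - m + 1):
            e, _ = score_duplex(MIRNA, transcript[offset : offset + m])
            if e <= 5.0:
                expected.add(((offset, offset + m), e))
        assert got == expected

    def test_region_labels_from_orf_annotation(self):
        transcript = site_for(MIRNA) + "A" * 100 + site_for(MIRNA) + "A" * 100 + site_for(MIRNA)
        sites = scan(
            "m", MIRNA, {"t": transcript}, orf_annotations={"t": (60, 180)}
        )
        regions = [s.region for s in sites if s.expectation == 0.0]
        assert sorted(regions) == ["3' UTR", "5' UTR", "ORF"]

    def test_planted_synthetic_sites_found(self, dataset):
        transcripts = {
            t.transcript_id: dataset.contigs[t.transcript_id]
            for t in dataset.truth.targets
        }
        for planted in dataset.truth.targets:
            mirna = next(h.mirna for h in dataset.truth.hairpins if h.name == planted.mirna_name)
            sites = scan(planted.mirna_name, mirna, transcripts)
            assert any(
                s.transcript_id == planted.transcript_id
                and s.site_span == tuple(planted.site_span)
                and s.expectation == planted.expectation
                for s in sites
            )


class TestInhibition:
    @pytest.mark.parametrize(
        "unpaired,mode",
        [((), "cleavage"), ((10,), "translation"), ((11,), "translation"), ((3,), "cleavage")],
    )
    def test_rule(self, unpaired, mode):
        assert classify_inhibition(unpaired) == mode

    def test_mismatch_at_position_ten_detected_from_alignment(self):
        site = mutate_site(MIRNA, 10)
        _, unpaired = score_duplex(MIRNA, site)
        assert classify_inhibition(unpaired) == "translation"
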