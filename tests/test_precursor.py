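"""Anchoring, window extraction, duplex criteria, and thermodynamic stats."""

import numpy as np
import pytest

from halomir import seqio
from halomir.precursor import (
    Anchor,
    amfe,
    anchor_tags,
    discover,
    evaluate_candidate,
    extract_window,
    mfei,
    thermo_stats,
)
from halomir.preprocess import UniqueTag
from halomir.synthetic import SyntheticConfig, _build_hairpin_contig


def naive_anchor_scan(tag_seq, contigs):
    """Brute-force occurrence list (oracle for anchor_tags)."""
    hits = []
    rc = seqio.reverse_complement(tag_seq)
    for contig_id, contig in sorted(contigs.items()):
        for query, strand in ((tag_seq, "+"), (rc, "-")):
            if strand == "-" and rc == tag_seq:
                continue
            for pos in range(len(contig) - len(query) + 1):
                if contig[pos : pos + len(query)] == query:
                    hits.append((contig_id, pos, strand))
    return hits


def make_hairpin(seed=5, arm_mutations=(), context_len=120, config=None):
    rng = np.random.default_rng(seed)
    config = config or SyntheticConfig()
    mirna = "T" + "".join("ACGTGC"[i] for i in rng.integers(0, 6, config.mirna_len - 1))
    contig, mspan, sspan, star = _build_hairpin_contig(
        rng, mirna, config, context_len, arm_mutations=arm_mutations
    )
    return mirna, star, contig, mspan, sspan


class TestAnchorTags:
    def test_forward_reverse_and_absent(self):
        contigs = {"c1": "AAAACCCCGGGGTTTTAAAACCCCGGGGTTTT" + "ACGTACGTACGTACGTACGTAC"}
        tag_fwd = UniqueTag("ACGTACGTACGTACGTACGTAC", {})
        tag_rev = UniqueTag(seqio.reverse_complement("AAAACCCCGGGGTTTTAA"), {})
        tag_absent = UniqueTag("TTTTTTTTTTGGGGGGGGGG", {})
        anchors = anchor_tags([tag_fwd, tag_rev, tag_absent], contigs)
        got = [(a.tag.sequence, a.contig_id, a.position, a.strand) for a in anchors]
        for tag in (tag_fwd, tag_rev, tag_absent):
            expected = naive_anchor_scan(tag.sequence, contigs)
            mine = [(c, p, s) for t, c, p, s in got if t == tag.sequence]
            assert mine == expected
        assert not [g for g in got if g[0] == tag_absent.sequence]

    def test_every_occurrence_reported(self):
        contigs = {"c": "ACGTACGTACGTACGTACGTAC" * 3}
        tag = UniqueTag("ACGTACGTACGTACGTACGTAC", {})
        anchors = [a for a in anchor_tags([tag], contigs) if a.strand == "+"]
        assert [a.position for a in anchors] == [0, 22, 44]


class TestExtractWindow:
    def test_clipping_at_contig_start(self):
        contigs = {"c": "ACGTACGTACGTACGTACGTAC" + "A" * 300}
        anchor = Anchor(UniqueTag("ACGTACGTACGTACGTACGTAC", {}), "c", 0, "+")
        window = extract_window(anchor, contigs)
        assert window.start == 0 and window.tag_start == 0

    def test_mid_contig_window_length(self):
        tag = "G" * 21
        contigs = {"c": "A" * 300 + tag + "C" * 300}
        anchor = Anchor(UniqueTag(tag, {}), "c", 300, "+")
        window = extract_window(anchor, contigs)
        assert window.end - window.start == 421 == len(window.sequence)
        assert window.sequence[window.tag_start : window.tag_start + 21] == tag

    def test_minus_strand_reverse_complement(self):
        tag = "ACGTACGTACGTACGTACGTA"
        insert = seqio.reverse_complement(tag)
        contigs = {"c": "A" * 50 + insert + "C" * 50}
        anchor = Anchor(UniqueTag(tag, {}), "c", 50, "-")
        window = extract_window(anchor, contigs)
        assert window.sequence == seqio.reverse_complement(contigs["c"])
        assert window.sequence[window.tag_start : window.tag_start + 21] == tag


class TestThermoStats:
    def test_amfe_identity_on_published_row(self):
        assert round(amfe(-92.0, 258), 2) == -35.66
        stats = thermo_stats("A" * 129 + "G" * 129, -92.0)
        assert round(stats.amfe, 2) == -35.66

    def test_mfei_identity_on_published_row(self):
        assert round(mfei(-43.33, 44.96), 2) == 0.96

    def test_zero_mfe(self):
        stats = thermo_stats("ACGT" * 10, 0.0)
        assert stats.amfe == 0.0 and stats.mfei == 0.0

    def test_zero_gc_flags_mfei_undefined(self):
        stats = thermo_stats("AT" * 20, -1.0)
        assert stats.mfei is None

    def test_gc_percent_from_sequence(self):
        stats = thermo_stats("GGCCAATT", -1.0)
        assert stats.gc_percent == pytest.approx(50.0)


class TestCriteria:
    def evaluate(self, mirna, star, contig, mature=100, star_reads=None, **kwargs):
        contigs = {"c": contig}
        tag = UniqueTag(mirna, {"lib": mature})
        anchors = [a for a in anchor_tags([tag], contigs) if a.strand == "+"]
        window = extract_window(anchors[0], contigs)
        lookup = {star: star_reads} if star_reads is not None else {}
        return evaluate_candidate(window, {"lib": mature}, star_lookup=lookup, **kwargs)

    def test_well_formed_hairpin_passes_all_criteria(self):
        mirna, star, contig, _, _ = make_hairpin()
        candidate = self.evaluate(mirna, star, contig, mature=100, star_reads=10)
        assert candidate.criteria_verdicts == {
            "mfe": True, "duplex_mismatches": True, "asymmetric_bulge": True,
            "read_ratio": True, "overhang": True,
        }
        assert candidate.valid
        assert candidate.duplex.mismatches == 0

    def test_five_arm_mismatches_fail_criterion_two(self):
        mirna, star, contig, _, _ = make_hairpin(arm_mutations=(4, 7, 10, 13, 16))
        candidate = self.evaluate(mirna, star, contig, mature=100, star_reads=10)
        assert candidate.criteria_verdicts["duplex_mismatches"] is False
        assert not candidate.valid

    def test_read_ratio_four_to_one_fails_criterion_four(self):
        mirna, star, contig, _, _ = make_hairpin()
        candidate = self.evaluate(mirna, star, contig, mature=100, star_reads=25)
        assert candidate.criteria_verdicts["read_ratio"] is False
        assert not candidate.valid

    def test_unseen_star_flags_ratio_not_evaluable(self):
        mirna, star, contig, _, _ = make_hairpin()
        candidate = self.evaluate(mirna, star, contig, mature=100, star_reads=0)
        assert candidate.criteria_verdicts["read_ratio"] is None
        assert candidate.star_unseen and not candidate.valid

    def test_mismatch_monotonicity(self):
        # adding arm mutations never flips criterion 2 back to passing
        verdicts = []
        for k in range(0, 8):
            positions = (3, 5, 7, 9, 11, 13, 15, 17)[:k]
            mirna, star, contig, _, _ = make_hairpin(arm_mutations=positions)
            c = self.evaluate(mirna, star, contig, mature=100, star_reads=10)
            verdicts.append(c.criteria_verdicts["duplex_mismatches"])
        failed = False
        for v in verdicts:
            failed = failed or v is False
            if failed:
                assert v is False

    def test_ratio_monotonicity(self):
        # raising the star count never flips criterion 4 from fail to pass
        mirna, star, contig, _, _ = make_hairpin()
        passed = True
        for star_reads in (10, 20, 21, 50, 100):
            c = self.evaluate(mirna, star, contig, mature=100, star_reads=star_reads)
            v = c.criteria_verdicts["read_ratio"]
            if v is False:
                passed = False
            assert (v is True) == (100 / star_reads >= 5.0)
        assert passed is False

    def test_short_window_rejected_without_error(self):
        tag = "ACGTACGTACGTACGTACGTA"
        contigs = {"c": tag + "ACG"}  # 24 nt, below the folding minimum
        anchors = anchor_tags([UniqueTag(tag, {})], contigs)
        window = extract_window(anchors[0], contigs)
        candidate = evaluate_candidate(window, {"lib": 5})
        assert candidate.structure is None and not candidate.valid


class TestPipelineRecovery:
    def test_planted_hairpins_recovered_decoys_rejected(self, dataset, cleaned):
        """Noise-free discovery attains precision = recall = 1."""
        _, tags, _ = cleaned
        candidates = discover(tags, dataset.contigs)
        truth = {
            (h.contig_id, h.mirna): h for h in dataset.truth.hairpins
        }
        recovered = set()
        for c in [c for c in candidates if c.valid]:
            window = c.window
            mirna = window.sequence[window.tag_start : window.tag_start + window.tag_length]
            key = (window.contig_id, mirna)
            assert key in truth and truth[key].kind == "valid", (
                f"false positive on {window.contig_id}"
            )
            recovered.add(key)
        expected = {k for k, h in truth.items() if h.kind == "valid"}
        assert recovered == expected  # recall = 1
        # every decoy is rejected for (at least) its planted violation
        by_key = {}
        for c in candidates:
            window = c.window
            mirna = window.sequence[window.tag_start : window.tag_start + window.tag_length]
            by_key.setdefault((window.contig_id, mirna), []).append(c)
        for key, hairpin in truth.items():
            if hairpin.violated is None:
                continue
            assert any(
                c.criteria_verdicts[hairpin.violated] is False for c in by_key[key]
            ), f"{key} did not fail {hairpin.violated}"
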