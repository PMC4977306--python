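"""Hairpin precursor discovery and the five-criterion validity filter.

Unique tags are anchored to transcriptome contigs by exact match (both
strands), a window extending up to 200 nt on each side of the anchor is
extracted and folded, the miRNA/miRNA* duplex is located from the
structure using the 2-nt 3'-overhang rule, and each candidate is judged
against five criteria:

1. hairpin minimum free energy at or below -35 kcal/mol;
2. at most four mismatches (unpaired miRNA bases) in the miRNA/miRNA*
   duplex — G:U counts as a pair;
3. at most one asymmetric bulge in the duplex, of size <= 2 nt;
4. miRNA : miRNA* read ratio of at least 5:1;
5. 2-nt 3' overhangs on both arms of the duplex.

Thermodynamic descriptors accompany each candidate: MFE (kcal/mol), AMFE
(MFE per 100 nt of hairpin), GC%, and MFEI (|AMFE| / GC%, reported as a
magnitude), the standard discriminator of miRNA precursors from other
structured RNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import seqio
from .folding import HairpinStructure, fold
from .preprocess import UniqueTag

DEFAULT_FLANK = 200
MFE_CUTOFF = -35.0
MAX_DUPLEX_MISMATCHES = 4
MAX_ASYM_BULGES = 1
MAX_ASYM_BULGE_SIZE = 2
MIN_READ_RATIO = 5.0
OVERHANG = 2
MIN_FOLD_LEN = 30
MAX_FOLD_LEN = 500

CRITERIA_NAMES = ("mfe", "duplex_mismatches", "asymmetric_bulge", "read_ratio", "overhang")


@dataclass(frozen=True)
class Anchor:
    tag: UniqueTag
    contig_id: str
    position: int  # 0-based start on the forward strand
    strand: str  # '+' or '-'


@dataclass(frozen=True)
class PrecursorWindow:
    contig_id: str
    start: int  # 0-based half-open, forward-strand coordinates
    end: int
    strand: str
    sequence: str  # reverse-complemented for '-' anchors
    tag_start: int  # tag offset within `sequence`
    tag_length: int


@dataclass
class DuplexReport:
    mirna_span: tuple[int, int] | None
    star_span: tuple[int, int] | None
    mismatches: int | None
    asymmetric_bulges: list[tuple[int, str]] = field(default_factory=list)
    overhang_mirna: int | None = None
    overhang_star: int | None = None
    read_ratio: float | None = None  # inf when star unseen
    star_sequence: str | None = None


@dataclass
class ThermoStats:
    mfe: float
    hairpin_length: int
    amfe: float
    gc_percent: float
    mfei: float | None  # None when GC% is zero (undefined)


@dataclass
class PrecursorCandidate:
    window: PrecursorWindow
    structure: HairpinStructure | None
    duplex: DuplexReport
    stats: ThermoStats | None
    criteria_verdicts: dict[str, bool | None]
    star_unseen: bool = False

    @property
    def valid(self) -> bool:
        return all(v is True for v in self.criteria_verdicts.values())


def anchor_tags(
    tags: Sequence[UniqueTag], contigs: Mapping[str, str]
) -> list[Anchor]:
    """Every exact occurrence of each tag on either strand of each contig."""
    anchors = []
    for tag in tags:
        seq = tag.sequence
        rc = seqio.reverse_complement(seq)
        for contig_id in sorted(contigs):
            contig = contigs[contig_id]
            for query, strand in ((seq, "+"), (rc, "-")):
                if strand == "-" and rc == seq:
                    continue  # palindromic tag: forward hit already reported
                pos = contig.find(query)
                while pos != -1:
                    anchors.append(Anchor(tag, contig_id, pos, strand))
                    pos = contig.find(query, pos + 1)
    return anchors


def extract_window(
    anchor: Anchor, contigs: Mapping[str, str], flank: int = DEFAULT_FLANK
) -> PrecursorWindow:
    """Anchor plus up to ``flank`` nt on each side, clipped at contig ends.

    Minus-strand anchors are returned reverse-complemented with the
    forward-strand coordinates recorded.
    """
    contig = contigs[anchor.contig_id]
    tag_len = len(anchor.tag.sequence)
    start = max(0, anchor.position - flank)
    end = min(len(contig), anchor.position + tag_len + flank)
    sequence = contig[start:end]
    if anchor.strand == "-":
        sequence = seqio.reverse_complement(sequence)
        tag_start = end - (anchor.position + tag_len)
    else:
        tag_start = anchor.position - start
    return PrecursorWindow(
        contig_id=anchor.contig_id,
        start=start,
        end=end,
        strand=anchor.strand,
        sequence=sequence,
        tag_start=tag_start,
        tag_length=tag_len,
    )


def amfe(mfe: float, hairpin_length: int) -> float:
    """Adjusted MFE: kcal/mol per 100 nt of hairpin."""
    if hairpin_length <= 0:
        raise ValueError("hairpin length must be positive")
    return mfe / hairpin_length * 100.0


def mfei(amfe_value: float, gc_percent: float) -> float:
    """MFE index: |AMFE| / GC%, reported as a magnitude."""
    if gc_percent <= 0:
        raise ValueError("MFEI is undefined at zero GC content")
    return abs(amfe_value) / gc_percent


def thermo_stats(sequence: str, mfe: float) -> ThermoStats:
    """AMFE = MFE / length x 100; MFEI = |AMFE| / GC%.

    Values are kept at full precision; rounding to two decimals happens at
    report time. A GC% of zero leaves MFEI undefined (None).
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if mfe > 0:
        raise ValueError("mfe must be <= 0")
    length = len(sequence)
    gc = sum(1 for b in sequence if b in "GC") / length * 100.0
    amfe_value = amfe(mfe, length)
    mfei_value = mfei(amfe_value, gc) if gc > 0 else None
    return ThermoStats(
        mfe=mfe, hairpin_length=length, amfe=amfe_value, gc_percent=gc, mfei=mfei_value
    )


def _locate_duplex(
    window: PrecursorWindow, structure: HairpinStructure
) -> DuplexReport:
    """Locate the miRNA* arm from the fold using the 2-nt 3'-overhang rule.

    The star 5' end sits opposite the third nucleotide from the miRNA 3'
    end, and the star 3' end extends two nucleotides past the partner of
    the miRNA 5' end; unpaired duplex ends fall back to the nearest paired
    position within the miRNA.
    """
    a = window.tag_start
    b = a + window.tag_length
    partner = structure.partner_map()
    paired = [i for i in range(a, b) if i in partner and not a <= partner[i] < b]
    if not paired:
        return DuplexReport(mirna_span=(a, b), star_span=None, mismatches=None)

    def partner_of(pos: int, lo: int, hi: int) -> int | None:
        # nearest paired miRNA position to `pos`, searched within [lo, hi)
        candidates = [i for i in paired if lo <= i < hi]
        if not candidates:
            return None
        nearest = min(candidates, key=lambda i: abs(i - pos))
        return partner[nearest] + (nearest - pos)

    star_start = partner_of(b - 1 - OVERHANG, a, b)
    star_end_anchor = partner_of(a, a, b)
    if star_start is None or star_end_anchor is None:
        return DuplexReport(mirna_span=(a, b), star_span=None, mismatches=None)
    star_end = star_end_anchor + OVERHANG + 1
    n = len(window.sequence)
    star_start = max(0, min(star_start, n))
    star_end = max(0, min(star_end, n))
    if star_end <= star_start or (star_start < b and star_end > a):
        return DuplexReport(mirna_span=(a, b), star_span=None, mismatches=None)

    star_span = (star_start, star_end)
    in_star = lambda p: star_start <= p < star_end
    duplex_paired = [i for i in range(a, b) if i in partner and in_star(partner[i])]
    # the 2-nt 3' overhang is unpaired by construction and is not a mismatch
    mismatches = sum(
        1 for i in range(a, b - OVERHANG) if i not in partner or not in_star(partner[i])
    )

    # asymmetric bulges: walk consecutive paired miRNA positions and compare
    # the unpaired run on each side of the duplex
    bulges: list[tuple[int, str]] = []
    for prev, nxt in zip(duplex_paired, duplex_paired[1:]):
        gap_m = nxt - prev - 1
        gap_s = partner[prev] - partner[nxt] - 1
        if gap_m != gap_s:
            size = abs(gap_m - gap_s)
            side = "mirna" if gap_m > gap_s else "star"
            bulges.append((size, side))

    overhang_mirna = (b - 1) - max(duplex_paired) if duplex_paired else None
    star_paired = [p for p in range(star_start, star_end) if p in partner and a <= partner[p] < b]
    overhang_star = (star_end - 1) - max(star_paired) if star_paired else None

    return DuplexReport(
        mirna_span=(a, b),
        star_span=star_span,
        mismatches=mismatches,
        asymmetric_bulges=bulges,
        overhang_mirna=overhang_mirna,
        overhang_star=overhang_star,
        star_sequence=window.sequence[star_start:star_end],
    )


def evaluate_criteria(
    window: PrecursorWindow,
    structure: HairpinStructure,
    mirna_reads: int,
    star_reads: int | None,
    mfe_cutoff: float = MFE_CUTOFF,
    min_ratio: float = MIN_READ_RATIO,
) -> tuple[DuplexReport, dict[str, bool | None]]:
    """Apply the five validity criteria to a folded candidate.

    ``star_reads`` of ``None`` means no read evidence for the star arm was
    looked up; a count of 0 means the star was unseen — criterion 4 is then
    recorded as not evaluable (None) and the candidate is reported flagged,
    mirroring the retention of hairpins whose star was never sequenced.
    """
    duplex = _locate_duplex(window, structure)
    verdicts: dict[str, bool | None] = {}
    verdicts["mfe"] = structure.mfe <= mfe_cutoff
    if duplex.star_span is None:
        verdicts["duplex_mismatches"] = False
        verdicts["asymmetric_bulge"] = False
        verdicts["overhang"] = False
    else:
        verdicts["duplex_mismatches"] = duplex.mismatches <= MAX_DUPLEX_MISMATCHES
        big = [b for b in duplex.asymmetric_bulges if b[0] > MAX_ASYM_BULGE_SIZE]
        verdicts["asymmetric_bulge"] = (
            len(duplex.asymmetric_bulges) <= MAX_ASYM_BULGES and not big
        )
        verdicts["overhang"] = (
            duplex.overhang_mirna == OVERHANG and duplex.overhang_star == OVERHANG
        )
    if star_reads is None or star_reads == 0:
        duplex.read_ratio = math.inf
        verdicts["read_ratio"] = None
    else:
        duplex.read_ratio = mirna_reads / star_reads
        verdicts["read_ratio"] = duplex.read_ratio >= min_ratio
    # order verdicts canonically
    ordered = {name: verdicts[name] for name in CRITERIA_NAMES}
    return duplex, ordered


def evaluate_candidate(
    window: PrecursorWindow,
    tag_counts: Mapping[str, int],
    library_totals: Mapping[str, int] | None = None,
    mfe_cutoff: float = MFE_CUTOFF,
    min_ratio: float = MIN_READ_RATIO,
    star_lookup: Mapping[str, int] | None = None,
) -> PrecursorCandidate:
    """Fold one window and evaluate it.

    ``tag_counts`` maps library id to miRNA-arm read counts; ``star_lookup``
    maps tag sequences to total read counts and is used to find star-arm
    read support once the star span is located.
    """
    n = len(window.sequence)
    if not MIN_FOLD_LEN <= n <= MAX_FOLD_LEN:
        duplex = DuplexReport(mirna_span=None, star_span=None, mismatches=None)
        verdicts = {name: False for name in CRITERIA_NAMES}
        return PrecursorCandidate(window, None, duplex, None, verdicts)
    structure = fold(window.sequence)
    mirna_reads = sum(tag_counts.values())
    # find star read support from the located duplex
    probe_duplex = _locate_duplex(window, structure)
    star_reads: int | None = 0
    if probe_duplex.star_sequence and star_lookup:
        star_reads = star_lookup.get(probe_duplex.star_sequence, 0)
    duplex, verdicts = evaluate_criteria(
        window, structure, mirna_reads, star_reads, mfe_cutoff, min_ratio
    )
    stats = thermo_stats(window.sequence, min(structure.mfe, 0.0))
    return PrecursorCandidate(
        window,
        structure,
        duplex,
        stats,
        verdicts,
        star_unseen=verdicts["read_ratio"] is None,
    )


def discover(
    tags: Sequence[UniqueTag],
    contigs: Mapping[str, str],
    flank: int = DEFAULT_FLANK,
    mfe_cutoff: float = MFE_CUTOFF,
    min_ratio: float = MIN_READ_RATIO,
) -> list[PrecursorCandidate]:
    """Anchor tags, extract windows, fold, and evaluate every candidate.

    One candidate per distinct (contig, window, strand, tag) combination;
    star-arm read support is looked up in the full tag set.
    """
    star_lookup = {tag.sequence: tag.total_count for tag in tags}
    anchors = anchor_tags(tags, contigs)
    seen = set()
    candidates = []
    for anchor in anchors:
        window = extract_window(anchor, contigs, flank)
        key = (window.contig_id, window.start, window.end, window.strand, anchor.tag.sequence)
        if key in seen:
            continue
        seen.add(key)
        candidates.append(
            evaluate_candidate(
                window,
                anchor.tag.count_per_library,
                mfe_cutoff=mfe_cutoff,
                min_ratio=min_ratio,
                star_lookup=star_lookup,
            )
        )
    return candidates
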