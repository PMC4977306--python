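"""miRNA target-site scanning with expectation scoring.

A miRNA is aligned antiparallel to a candidate transcript site and the
alignment is scored as a penalty sum: perfect pair 0, G:U wobble 0.5,
mismatch 1.0, gap 2.0, with penalties multiplied by 1.5 within the seed
(miRNA positions 2-13, counted 1-based from the 5' end). Sites at or below
the expectation cutoff (default 3.0) are reported; an unpaired miRNA
position 10 or 11 marks translational inhibition, otherwise the site is
classed as cleavage. The scheme follows the documented defaults of the
standard plant target-prediction server and every weight is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from . import seqio

SEED_START = 2
SEED_END = 13
SEED_MULTIPLIER = 1.5
GU_PENALTY = 0.5
MISMATCH_PENALTY = 1.0
GAP_PENALTY = 2.0
DEFAULT_MAX_EXPECTATION = 3.0

_WC = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU = {("G", "T"), ("T", "G")}


@dataclass(frozen=True)
class ScoringScheme:
    match: float = 0.0
    gu: float = GU_PENALTY
    mismatch: float = MISMATCH_PENALTY
    gap: float = GAP_PENALTY
    seed_start: int = SEED_START
    seed_end: int = SEED_END
    seed_multiplier: float = SEED_MULTIPLIER


@dataclass
class TargetSite:
    mirna_name: str
    transcript_id: str
    site_span: tuple[int, int]  # transcript coordinates, 0-based half-open
    expectation: float
    region: str  # 5' UTR / ORF / 3' UTR / unknown
    inhibition: str  # cleavage / translation
    manual: bool = False
    unpaired_positions: tuple[int, ...] = field(default_factory=tuple)


def _pair_kind(mirna_base: str, target_base: str) -> str:
    """Classify one antiparallel position: the miRNA base pairs the target base."""
    if (mirna_base, target_base) in _WC:
        return "match"
    if (mirna_base, target_base) in _GU:
        return "gu"
    return "mismatch"


def score_duplex(
    mirna: str,
    site: str,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[float, tuple[int, ...]]:
    """Expectation of an ungapped antiparallel miRNA/site alignment.

    ``site`` is given in transcript (sense) orientation; position i of the
    miRNA (0-based from its 5' end) is paired with site position
    ``len(site) - 1 - i``. Returns the penalty sum and the 1-based miRNA
    positions that are not perfectly or wobble paired.
    """
    mirna = seqio.normalize(mirna)
    site = seqio.normalize(site)
    if len(mirna) != len(site):
        raise ValueError("ungapped alignment requires equal lengths")
    total = 0.0
    unpaired = []
    for i, base in enumerate(mirna):
        kind = _pair_kind(base, site[len(site) - 1 - i])
        if kind == "match":
            penalty = scheme.match
        elif kind == "gu":
            penalty = scheme.gu
        else:
            penalty = scheme.mismatch
            unpaired.append(i + 1)
        pos = i + 1
        if scheme.seed_start <= pos <= scheme.seed_end:
            penalty *= scheme.seed_multiplier
        total += penalty
    return total, tuple(unpaired)


def classify_inhibition(unpaired_positions: Sequence[int]) -> str:
    """Translation iff miRNA position 10 or 11 is unpaired, else cleavage."""
    return "translation" if {10, 11} & set(unpaired_positions) else "cleavage"


def _label_region(
    span: tuple[int, int], orf: tuple[int, int] | None
) -> str:
    if orf is None:
        return "unknown"
    start, end = span
    orf_start, orf_end = orf
    mid = (start + end) // 2
    if mid < orf_start:
        return "5' UTR"
    if mid >= orf_end:
        return "3' UTR"
    return "ORF"


def scan(
    mirna_name: str,
    mirna: str,
    transcripts: Mapping[str, str],
    max_expectation: float = DEFAULT_MAX_EXPECTATION,
    orf_annotations: Mapping[str, tuple[int, int]] | None = None,
    scheme: ScoringScheme = ScoringScheme(),
) -> list[TargetSite]:
    """All sites with expectation <= cutoff across transcripts, best first.

    Ungapped scan at every offset; region labels come from the optional ORF
    interval table. Ties are ordered by transcript id then position.
    """
    mirna = seqio.normalize(mirna)
    sites = []
    for transcript_id in sorted(transcripts):
        seq = seqio.normalize(transcripts[transcript_id])
        m = len(mirna)
        for offset in range(0, len(seq) - m + 1):
            window = seq[offset : offset + m]
            expectation, unpaired = score_duplex(mirna, window, scheme)
            if expectation <= max_expectation:
                orf = orf_annotations.get(transcript_id) if orf_annotations else None
                sites.append(
                    TargetSite(
                        mirna_name=mirna_name,
                        transcript_id=transcript_id,
                        site_span=(offset, offset + m),
                        expectation=expectation,
                        region=_label_region((offset, offset + m), orf),
                        inhibition=classify_inhibition(unpaired),
                        unpaired_positions=unpaired,
                    )
                )
    sites.sort(key=lambda s: (s.expectation, s.transcript_id, s.site_span))
    return sites


def write_targets_tsv(path, sites: Sequence[TargetSite]) -> None:
    with open(path, "w") as handle:
        handle.write("mirna\ttranscript\tstart\tend\texpectation\tlocation\tinhibition\tmanual\n")
        for s in sites:
            handle.write(
                f"{s.mirna_name}\t{s.transcript_id}\t{s.site_span[0]}\t{s.site_span[1]}"
                f"\t{s.expectation:g}\t{s.region}\t{s.inhibition}"
                f"\t{'yes' if s.manual else 'no'}\n"
            )
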