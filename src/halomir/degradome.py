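"""Degradome (PARE) t-plots, peak categorization, and cleavage confirmation.

Degradome tags are 5' ends of uncapped mRNA fragments. For each transcript
a t-plot (position -> tag count profile) is built, every occupied position
is categorized on the five-level scheme used in the CleaveLand lineage:

* 4 — singleton (count of 1);
* 0 — count above 1 and the unique maximum of the profile;
* 1 — count above 1, tied with the maximum;
* 2 — count above 1, below the maximum but above the median of non-zero
  counts;
* 3 — anything else above 1 (at or below the median).

miRNA-guided cleavage leaves the 5' end of the 3' fragment opposite miRNA
positions 10-11, so a predicted target site is confirmed when a peak of
category <= 2 lies within a +-1 nt window of that position.
"""

from __future__ import annotations

from dataclasses import dataclass
from statistics import median
from typing import Iterable, Mapping, Sequence

from .targets import TargetSite


@dataclass(frozen=True)
class DegradomeTag:
    sequence: str
    transcript_id: str
    five_prime_position: int  # 0-based transcript coordinate of the tag 5' end
    count: int = 1

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("tag count must be >= 1")
        if self.five_prime_position < 0:
            raise ValueError("position must be >= 0")


@dataclass
class TPlotPeak:
    transcript_id: str
    position: int
    count: int
    category: int
    paired_mirna: str | None = None
    site_expectation: float | None = None
    note: str = ""


def build_tplot(tags: Iterable[DegradomeTag]) -> dict[int, int]:
    """Position -> count profile for the tags of one transcript."""
    profile: dict[int, int] = {}
    transcript_ids = set()
    for tag in tags:
        transcript_ids.add(tag.transcript_id)
        profile[tag.five_prime_position] = profile.get(tag.five_prime_position, 0) + tag.count
    if len(transcript_ids) > 1:
        raise ValueError("a t-plot covers a single transcript")
    return profile


def categorize(profile: Mapping[int, int], position: int) -> int:
    """Category of one occupied position of a t-plot profile."""
    if not profile:
        raise ValueError("profile must be non-empty")
    count = profile.get(position, 0)
    if count == 0:
        raise ValueError(f"position {position} has zero count")
    if count == 1:
        return 4
    counts = list(profile.values())
    maximum = max(counts)
    if count == maximum:
        return 0 if counts.count(maximum) == 1 else 1
    if count > median(counts):
        return 2
    return 3


CLEAVAGE_OFFSET = 10  # cleavage between miRNA positions 10 and 11


def expected_cleavage_position(site: TargetSite) -> int:
    """5' end of the 3' fragment: the transcript base opposite miRNA position 10."""
    return site.site_span[1] - CLEAVAGE_OFFSET


def confirm_cleavage(
    sites: Sequence[TargetSite],
    profiles: Mapping[str, Mapping[int, int]],
    window: int = 1,
    max_category: int = 2,
) -> list[TPlotPeak]:
    """One peak record per predicted site; confirmed iff a category <= 2 peak
    lies within ``window`` nt of the expected slice position."""
    results = []
    for site in sites:
        profile = profiles.get(site.transcript_id)
        expected = expected_cleavage_position(site)
        if not profile:
            results.append(
                TPlotPeak(site.transcript_id, expected, 0, -1, site.mirna_name,
                          site.expectation, note="no data")
            )
            continue
        best = None
        for pos in range(expected - window, expected + window + 1):
            if profile.get(pos, 0) == 0:
                continue
            category = categorize(profile, pos)
            if category <= max_category and (best is None or category < best.category):
                best = TPlotPeak(
                    site.transcript_id, pos, profile[pos], category,
                    site.mirna_name, site.expectation, note="confirmed",
                )
        if best is not None:
            results.append(best)
        else:
            results.append(
                TPlotPeak(site.transcript_id, expected, profile.get(expected, 0),
                          -1, site.mirna_name, site.expectation, note="not confirmed")
            )
    return results


def map_tags(
    sequences_with_counts: Iterable[tuple[str, int]],
    transcripts: Mapping[str, str],
) -> list[DegradomeTag]:
    """Map degradome 5'-end sequences to transcripts by exact match.

    Every occurrence on every transcript is reported (the tag 5' end marks
    the match start); unmapped sequences are dropped.
    """
    tags = []
    for seq, count in sequences_with_counts:
        for transcript_id in sorted(transcripts):
            transcript = transcripts[transcript_id]
            pos = transcript.find(seq)
            while pos != -1:
                tags.append(DegradomeTag(seq, transcript_id, pos, count))
                pos = transcript.find(seq, pos + 1)
    return tags


def profiles_from_tags(tags: Iterable[DegradomeTag]) -> dict[str, dict[int, int]]:
    """Per-transcript t-plot profiles from a mixed tag list."""
    by_transcript: dict[str, list[DegradomeTag]] = {}
    for tag in tags:
        by_transcript.setdefault(tag.transcript_id, []).append(tag)
    return {tid: build_tplot(ts) for tid, ts in by_transcript.items()}


def confirmed(peaks: Iterable[TPlotPeak]) -> list[TPlotPeak]:
    return [p for p in peaks if p.note == "confirmed"]


def write_confirmation_tsv(path, peaks: Sequence[TPlotPeak]) -> None:
    with open(path, "w") as handle:
        handle.write("mirna\ttranscript\tposition\tcount\tcategory\texpectation\tstatus\n")
        for p in peaks:
            expectation = "" if p.site_expectation is None else f"{p.site_expectation:g}"
            handle.write(
                f"{p.paired_mirna or ''}\t{p.transcript_id}\t{p.position}\t{p.count}"
                f"\t{p.category}\t{expectation}\t{p.note}\n"
            )
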