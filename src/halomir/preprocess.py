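"""Small-RNA read cleaning, tag collapsing, and library profiling.

Raw reads are 3'-adapter-trimmed, filtered to 18-25 nt, purged of ambiguous
bases and exact t/rRNA contaminants, then collapsed to unique tags with
per-library counts. Per-library profiles record the redundant and unique
size distributions and the 5'-nucleotide composition by length.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import seqio

MIN_LEN = 18
MAX_LEN = 25

#: Illumina TruSeq small-RNA 3' adapter; configurable everywhere it is used.
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


@dataclass(frozen=True)
class RawRead:
    """A sequencing read prior to (or during) cleaning."""

    identifier: str
    sequence: str
    quality: str | None = None

    def __post_init__(self) -> None:
        # adapter trimming of an adapter-only read leaves an empty insert,
        # so empty sequences are representable; filtering removes them
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError("quality length must equal sequence length")


@dataclass
class UniqueTag:
    """A collapsed small-RNA sequence with per-library read counts."""

    sequence: str
    count_per_library: dict[str, int] = field(default_factory=dict)

    def count(self, library_id: str) -> int:
        return self.count_per_library.get(library_id, 0)

    @property
    def total_count(self) -> int:
        return sum(self.count_per_library.values())


@dataclass
class LibraryProfile:
    """Size distribution and 5'-nucleotide composition of one clean library."""

    library_id: str
    total_clean_reads: int
    redundant_size_histogram: dict[int, int]
    unique_size_histogram: dict[int, int]
    first_nt_by_length: dict[int, dict[str, float]]


def trim_adapter(read: RawRead, adapter: str, min_overlap: int = 6) -> RawRead:
    """Trim the 3' adapter by exact prefix match.

    The read is truncated at the leftmost position where a prefix of the
    adapter of length >= ``min_overlap`` matches exactly; reads without any
    such occurrence are returned unchanged.
    """
    adapter = seqio.normalize(adapter)
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if not 1 <= min_overlap <= len(adapter):
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = seqio.normalize(read.sequence)
    probe = adapter[:min_overlap]
    best = seq.find(probe)
    if best == -1:
        return RawRead(read.identifier, seq, read.quality)
    quality = read.quality[:best] if read.quality is not None else None
    return RawRead(read.identifier, seq[:best], quality)


def filter_reads(
    reads: Sequence[RawRead],
    contaminants: Iterable[str] = (),
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> list[RawRead]:
    """Keep reads of 18-25 nt with no ambiguous base and no exact contaminant match."""
    contaminant_set = {seqio.normalize(c) for c in contaminants}
    kept = []
    for read in reads:
        seq = seqio.normalize(read.sequence)
        if not min_len <= len(seq) <= max_len:
            continue
        if "N" in seq or not seqio.is_dna(seq):
            continue
        if seq in contaminant_set:
            continue
        kept.append(RawRead(read.identifier, seq, read.quality))
    return kept


def collapse_tags(
    reads_per_library: Mapping[str, Sequence[RawRead]],
) -> tuple[list[UniqueTag], dict[str, LibraryProfile]]:
    """Collapse clean reads to unique tags and build per-library profiles.

    The sum of tag counts per library equals the number of clean reads in
    that library; histograms and first-nucleotide fractions are derived from
    the same counts.
    """
    counts: dict[str, Counter[str]] = {}
    for library_id, reads in reads_per_library.items():
        counter: Counter[str] = Counter()
        for read in reads:
            counter[seqio.normalize(read.sequence)] += 1
        counts[library_id] = counter

    sequences = sorted(set().union(*[set(c) for c in counts.values()]) if counts else set())
    tags = [
        UniqueTag(seq, {lib: counts[lib][seq] for lib in counts if counts[lib][seq]})
        for seq in sequences
    ]

    profiles = {}
    for library_id, counter in counts.items():
        redundant: dict[int, int] = {}
        unique: dict[int, int] = {}
        first_nt_counts: dict[int, Counter[str]] = {}
        total = 0
        for seq, n in counter.items():
            length = len(seq)
            total += n
            redundant[length] = redundant.get(length, 0) + n
            unique[length] = unique.get(length, 0) + 1
            first_nt_counts.setdefault(length, Counter())[seqio.to_rna(seq[0])] += n
        first_nt = {
            length: {nt: c / sum(counter.values()) for nt, c in counter.items()}
            for length, counter in first_nt_counts.items()
        }
        profiles[library_id] = LibraryProfile(
            library_id=library_id,
            total_clean_reads=total,
            redundant_size_histogram=dict(sorted(redundant.items())),
            unique_size_histogram=dict(sorted(unique.items())),
            first_nt_by_length=first_nt,
        )
    return tags, profiles


def clean_library(
    reads: Sequence[RawRead],
    adapter: str = DEFAULT_ADAPTER,
    min_overlap: int = 6,
    contaminants: Iterable[str] = (),
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> list[RawRead]:
    """Trim then filter one library of raw reads."""
    trimmed = [trim_adapter(r, adapter, min_overlap) for r in reads]
    return filter_reads(trimmed, contaminants, min_len, max_len)


def write_collapsed_fasta(path: str | Path, tags: Sequence[UniqueTag]) -> None:
    """Write collapsed tags as FASTA with ``>tag<serial>_x<count>`` headers."""
    records = [
        (f"tag{i + 1}_x{tag.total_count}", tag.sequence) for i, tag in enumerate(tags)
    ]
    seqio.write_fasta(path, records)


def write_profile_tsv(path: str | Path, profiles: Mapping[str, LibraryProfile]) -> None:
    with open(path, "w") as handle:
        handle.write("library\tlength\tredundant_count\tunique_count\tfirst_nt_fractions\n")
        for library_id, profile in profiles.items():
            for length in sorted(profile.redundant_size_histogram):
                fracs = profile.first_nt_by_length.get(length, {})
                frac_str = ",".join(f"{nt}:{f:.4f}" for nt, f in sorted(fracs.items()))
                handle.write(
                    f"{library_id}\t{length}\t{profile.redundant_size_histogram[length]}"
                    f"\t{profile.unique_size_histogram.get(length, 0)}\t{frac_str}\n"
                )
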