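"""Conserved miRNA family assignment and RPM quantitation.

Cleaned 20-22 nt tags are matched against a mature plant miRNA reference by
equal-length Hamming distance (at most two substitutions; no indels), and
family abundances are expressed in reads per million (RPM): the read count
matched to a family divided by the total 18-25 nt clean reads of the same
library, times 1e6.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from . import seqio
from .preprocess import UniqueTag

#: Families the literature reports jointly (sequence classes overlap).
DEFAULT_FAMILY_MERGE = {
    "miR156": "miR156/157",
    "miR157": "miR156/157",
    "miR165": "miR165/166",
    "miR166": "miR165/166",
}

CONSERVED_MIN_LEN = 20
CONSERVED_MAX_LEN = 22

_FAMILY_RE = re.compile(r"^(?:[a-z]{2,4}-)?(miR[0-9]+)", re.IGNORECASE)


def family_from_name(name: str, merge_table: Mapping[str, str] | None = None) -> str:
    """Derive a family label from a miRBase-style name.

    ``ath-miR156a`` -> ``miR156/157`` under the default merge table;
    species prefix and letter/number suffixes are stripped.
    """
    merge = DEFAULT_FAMILY_MERGE if merge_table is None else dict(merge_table)
    match = _FAMILY_RE.match(name)
    if not match:
        raise ValueError(f"cannot derive a family from name {name!r}")
    family = "miR" + match.group(1)[3:]
    return merge.get(family, family)


@dataclass(frozen=True)
class ReferenceEntry:
    name: str
    family: str
    sequence: str


@dataclass
class MatureReference:
    """A mature-miRNA reference with unique names and derived families."""

    entries: list[ReferenceEntry] = field(default_factory=list)

    @classmethod
    def from_records(
        cls,
        records: Iterable[tuple[str, str]],
        merge_table: Mapping[str, str] | None = None,
    ) -> "MatureReference":
        entries = []
        seen = set()
        for name, seq in records:
            if name in seen:
                raise ValueError(f"duplicate reference name {name!r}")
            seen.add(name)
            entries.append(
                ReferenceEntry(name, family_from_name(name, merge_table), seqio.normalize(seq))
            )
        return cls(entries)

    @classmethod
    def from_fasta(
        cls, path: str | Path, merge_table: Mapping[str, str] | None = None
    ) -> "MatureReference":
        return cls.from_records(seqio.read_fasta(path), merge_table)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class FamilyMatch:
    tag: UniqueTag
    reference_name: str
    family: str
    mismatches: int


@dataclass
class FamilyAbundance:
    family: str
    rpm_per_library: dict[str, float]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("Hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))


def match_tag(
    tag: UniqueTag, reference: MatureReference, max_mismatches: int = 2
) -> list[FamilyMatch]:
    """All equal-length reference entries within ``max_mismatches`` substitutions.

    Tags outside 20-22 nt are skipped (empty result). Matches are ordered
    best distance first, ties broken by reference name.
    """
    if not reference.entries:
        raise ValueError("reference must be non-empty")
    if not CONSERVED_MIN_LEN <= len(tag.sequence) <= CONSERVED_MAX_LEN:
        return []
    matches = []
    for entry in reference.entries:
        if len(entry.sequence) != len(tag.sequence):
            continue
        d = hamming(tag.sequence, entry.sequence)
        if d <= max_mismatches:
            matches.append(FamilyMatch(tag, entry.name, entry.family, d))
    matches.sort(key=lambda m: (m.mismatches, m.reference_name))
    return matches


def compute_rpm(matched_read_count: int, total_clean_reads_18_25: int) -> float:
    """Reads per million: matched / total x 1e6."""
    if total_clean_reads_18_25 <= 0:
        raise ValueError("total clean reads must be positive")
    if not 0 <= matched_read_count <= total_clean_reads_18_25:
        raise ValueError("matched count must lie in [0, total]")
    return matched_read_count / total_clean_reads_18_25 * 1e6


def quantify_families(
    tags: Sequence[UniqueTag],
    reference: MatureReference,
    totals_per_library: Mapping[str, int],
    max_mismatches: int = 2,
) -> list[FamilyAbundance]:
    """Family RPM per library. A tag matching several families counts once per family."""
    family_counts: dict[str, dict[str, int]] = {}
    for tag in tags:
        families = {m.family for m in match_tag(tag, reference, max_mismatches)}
        for family in families:
            bucket = family_counts.setdefault(family, {})
            for library_id, count in tag.count_per_library.items():
                bucket[library_id] = bucket.get(library_id, 0) + count
    abundances = []
    for family in sorted(family_counts):
        rpm = {
            library_id: compute_rpm(family_counts[family].get(library_id, 0), total)
            for library_id, total in totals_per_library.items()
        }
        abundances.append(FamilyAbundance(family, rpm))
    return abundances


def write_abundance_tsv(path: str | Path, abundances: Sequence[FamilyAbundance]) -> None:
    libraries = sorted({lib for a in abundances for lib in a.rpm_per_library})
    with open(path, "w") as handle:
        handle.write("family\t" + "\t".join(f"{lib}_rpm" for lib in libraries) + "\n")
        for abundance in abundances:
            row = "\t".join(f"{abundance.rpm_per_library.get(lib, 0.0):.2f}" for lib in libraries)
            handle.write(f"{abundance.family}\t{row}\n")
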