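"""Sequence I/O helpers.

All internal sequences use the uppercase DNA alphabet (U is normalized to T
at ingest). Mature miRNAs may be printed with U on output via
:func:`to_rna`. FASTA/FASTQ parsing is delegated to Biopython.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

_VALID_DNA = re.compile(r"^[ACGTN]*$")


def normalize(sequence: str) -> str:
    """Uppercase a nucleotide string and convert U to T."""
    return sequence.upper().replace("U", "T")


def to_rna(sequence: str) -> str:
    """Render an internal DNA-alphabet sequence with U (for reports)."""
    return sequence.upper().replace("T", "U")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


def is_dna(sequence: str) -> bool:
    return bool(_VALID_DNA.match(sequence))


def read_fasta(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (identifier, normalized sequence) pairs from a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, normalize(str(record.seq))


def read_fastq(path: str | Path) -> Iterator[tuple[str, str, str]]:
    """Yield (identifier, normalized sequence, quality string) from FASTQ (Phred+33)."""
    for record in SeqIO.parse(str(path), "fastq"):
        quals = record.letter_annotations.get("phred_quality", [])
        quality = "".join(chr(q + 33) for q in quals)
        yield record.id, normalize(str(record.seq)), quality


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    with open(path, "w") as handle:
        for name, seq in records:
            handle.write(f">{name}\n{seq}\n")


def write_fastq(path: str | Path, records: Iterable[tuple[str, str, str]]) -> None:
    with open(path, "w") as handle:
        for name, seq, qual in records:
            handle.write(f"@{name}\n{seq}\n+\n{qual}\n")
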