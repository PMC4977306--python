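"""Published precursor and target tables, packaged as TSV fixtures.

The package ships the 19 conserved and 24 novel hairpin records (mature
sequence, strand, per-condition RPM, hairpin length, MFE, AMFE, GC%, MFEI,
star sequence) and the predicted-target records, transcribed verbatim.
Each hairpin record carries consistency flags for the AMFE and MFEI
identities: a few printed rows do not satisfy AMFE = MFE / hairpin-length
x 100 at two decimals (the printed hairpin length is evidently not always
the length that produced the printed AMFE), and those rows are flagged
rather than reconciled. MFEI values are printed as positive magnitudes
while AMFE is negative; the magnitude convention is adopted throughout.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import pandas as pd

_CHECKSUMS = {
    "table1_conserved.tsv": "4bd39c1237558973d92c86e884f87b0897e047ec2147cb5ba5ec5bc970a0b798",
    "table2_novel.tsv": "4a45c8b0a9e4466593370181212ee2fc771ceec4200e117009529f7c917a7b76",
    "table3_targets.tsv": "170b352fd3478eef5cb1069797b07b6a04de0a25239d02b12e984065f51974df",
}

_TOLERANCE = 0.011  # half-ulp at two printed decimals, plus float slack


class FixtureCorruptionError(RuntimeError):
    """A packaged fixture file does not match its recorded checksum."""


def _data_path(filename: str) -> Path:
    path = resources.files("halomir").joinpath("data", filename)
    with resources.as_file(path) as concrete:
        return Path(concrete)


def _verified(filename: str) -> Path:
    path = _data_path(filename)
    digest = hashlib.sha256(path.read_bytes()).hexdigest()
    if digest != _CHECKSUMS[filename]:
        raise FixtureCorruptionError(f"{filename}: checksum mismatch ({digest})")
    return path


def _flag_consistency(frame: pd.DataFrame) -> pd.DataFrame:
    amfe_recomputed = (frame["mfe"] / frame["hairpin_length"] * 100).round(2)
    mfei_recomputed = (frame["amfe"].abs() / frame["gc_percent"]).round(2)
    frame = frame.copy()
    frame["amfe_consistent"] = (amfe_recomputed - frame["amfe"]).abs() <= _TOLERANCE
    frame["mfei_consistent"] = (mfei_recomputed - frame["mfei"]).abs() <= _TOLERANCE
    return frame


def load_conserved_table() -> pd.DataFrame:
    """The 19 conserved hairpin records with consistency flags."""
    frame = pd.read_csv(_verified("table1_conserved.tsv"), sep="\t")
    return _flag_consistency(frame)


def load_novel_table() -> pd.DataFrame:
    """The 24 novel hairpin records with consistency flags."""
    frame = pd.read_csv(_verified("table2_novel.tsv"), sep="\t")
    return _flag_consistency(frame)


def load_target_table() -> pd.DataFrame:
    """Predicted target records (expectation, location, inhibition mode)."""
    return pd.read_csv(_verified("table3_targets.tsv"), sep="\t")


@dataclass
class PaperFixtures:
    conserved: pd.DataFrame
    novel: pd.DataFrame
    targets: pd.DataFrame


def load_paper_fixtures() -> PaperFixtures:
    return PaperFixtures(load_conserved_table(), load_novel_table(), load_target_table())
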