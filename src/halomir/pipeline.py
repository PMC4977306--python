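"""End-to-end pipeline: clean reads -> families -> hairpins -> targets ->
degradome confirmation -> expression, with a serializable configuration.

Every stage is a pure function of its declared inputs, so a rerun with the
same configuration and seed produces byte-identical reports.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import yaml

from . import degradome as degradome_mod
from . import expression as expression_mod
from . import precursor as precursor_mod
from . import preprocess, seqio, targets as targets_mod
from .conserved import MatureReference, quantify_families, write_abundance_tsv
from .preprocess import DEFAULT_ADAPTER

logger = logging.getLogger("halomir")


@dataclass
class PipelineConfig:
    reads: dict[str, str] = field(default_factory=dict)  # library -> FASTQ path
    transcriptome: str = ""
    mature_reference: str = ""
    contaminants: str | None = None
    degradome: str | None = None
    ct_table: str | None = None
    adapter: str = DEFAULT_ADAPTER
    min_len: int = 18
    max_len: int = 25
    max_mismatches: int = 2
    flank: int = 200
    mfe_cutoff: float = -35.0
    min_ratio: float = 5.0
    max_expectation: float = 3.0
    degradome_window: int = 1
    alpha: float = 0.05
    seed: int = 1

    def validate(self) -> None:
        if not 0 < self.min_len <= self.max_len:
            raise ValueError("length bounds must satisfy 0 < min <= max")
        if self.max_mismatches < 0 or self.flank < 0:
            raise ValueError("mismatches and flank must be non-negative")
        if self.mfe_cutoff > 0:
            raise ValueError("MFE cutoff must be <= 0")
        if self.min_ratio <= 0 or self.max_expectation < 0 or not 0 < self.alpha < 1:
            raise ValueError("threshold out of range")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as handle:
            yaml.safe_dump(asdict(self), handle, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as handle:
            return cls(**yaml.safe_load(handle))


@dataclass
class ReportBundle:
    tags: list
    profiles: dict
    abundances: list
    candidates: list
    target_sites: list
    confirmations: list
    expression_results: list


def _require(path: str | None, stage: str) -> Path:
    if not path or not Path(path).exists():
        raise FileNotFoundError(f"[{stage}] input not found: {path!r}")
    return Path(path)


def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> ReportBundle:
    """Run every stage for which the configuration names inputs."""
    config.validate()
    logger.info(
        "thresholds: len %d-%d, mismatches <= %d, flank %d, MFE <= %.1f, "
        "ratio >= %.1f, expectation <= %.1f, alpha %.2f",
        config.min_len, config.max_len, config.max_mismatches, config.flank,
        config.mfe_cutoff, config.min_ratio, config.max_expectation, config.alpha,
    )
    contaminant_seqs: list[str] = []
    if config.contaminants:
        contaminant_seqs = [seq for _, seq in seqio.read_fasta(_require(config.contaminants, "preprocess"))]

    clean_per_library = {}
    for library, path in config.reads.items():
        raw = [
            preprocess.RawRead(name, seq, qual or None)
            for name, seq, qual in seqio.read_fastq(_require(path, "preprocess"))
        ]
        clean_per_library[library] = preprocess.clean_library(
            raw, config.adapter, contaminants=contaminant_seqs,
            min_len=config.min_len, max_len=config.max_len,
        )
        logger.info("library %s: %d raw, %d clean", library, len(raw), len(clean_per_library[library]))
    tags, profiles = preprocess.collapse_tags(clean_per_library)
    totals = {lib: p.total_clean_reads for lib, p in profiles.items()}

    reference = MatureReference.from_fasta(_require(config.mature_reference, "families"))
    abundances = quantify_families(tags, reference, totals, config.max_mismatches)

    contigs = dict(seqio.read_fasta(_require(config.transcriptome, "discover")))
    candidates = precursor_mod.discover(
        tags, contigs, config.flank, config.mfe_cutoff, config.min_ratio
    )
    valid = [c for c in candidates if c.valid]
    logger.info("discovery: %d candidates, %d valid", len(candidates), len(valid))

    target_sites = []
    for index, candidate in enumerate(valid):
        window = candidate.window
        mirna = window.sequence[window.tag_start : window.tag_start + window.tag_length]
        name = f"candidate_{index + 1}_{window.contig_id}"
        target_sites.extend(
            targets_mod.scan(name, mirna, contigs, config.max_expectation)
        )

    confirmations = []
    if config.degradome:
        seq_counts = []
        for header, seq in seqio.read_fasta(_require(config.degradome, "degradome")):
            count = int(header.rsplit("_x", 1)[1]) if "_x" in header else 1
            seq_counts.append((seq, count))
        tags_mapped = degradome_mod.map_tags(seq_counts, contigs)
        deg_profiles = degradome_mod.profiles_from_tags(tags_mapped)
        confirmations = degradome_mod.confirm_cleavage(
            target_sites, deg_profiles, config.degradome_window
        )

    expression_results = []
    if config.ct_table:
        records = expression_mod.read_ct_table(_require(config.ct_table, "expression"))
        libraries = list(config.reads) or ["control", "salt"]
        base, treat = (libraries + ["salt"])[:2]
        expression_results = [
            expression_mod.delta_delta_ct(record, base, treat, config.alpha)
            for record in records
        ]

    bundle = ReportBundle(
        tags=tags, profiles=profiles, abundances=abundances,
        candidates=candidates, target_sites=target_sites,
        confirmations=confirmations, expression_results=expression_results,
    )
    if outdir is not None:
        write_reports(bundle, outdir)
    return bundle


def write_reports(bundle: ReportBundle, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    preprocess.write_collapsed_fasta(outdir / "tags.fasta", bundle.tags)
    preprocess.write_profile_tsv(outdir / "profiles.tsv", bundle.profiles)
    write_abundance_tsv(outdir / "family_rpm.tsv", bundle.abundances)
    write_candidate_tsv(outdir / "candidates.tsv", bundle.candidates)
    targets_mod.write_targets_tsv(outdir / "targets.tsv", bundle.target_sites)
    if bundle.confirmations:
        degradome_mod.write_confirmation_tsv(outdir / "degradome.tsv", bundle.confirmations)
    if bundle.expression_results:
        expression_mod.write_expression_tsv(outdir / "expression.tsv", bundle.expression_results)


def write_candidate_tsv(path: str | Path, candidates) -> None:
    """Candidate table with the standard hairpin descriptor columns."""
    with open(path, "w") as handle:
        handle.write(
            "contig\tstrand\tsequence\tlength\thairpin_length\tmfe\tamfe\tgc_percent"
            "\tmfei\tstar_sequence\tmismatches\tread_ratio\tvalid\tcriteria\n"
        )
        for c in candidates:
            window = c.window
            mirna = window.sequence[window.tag_start : window.tag_start + window.tag_length]
            stats = c.stats
            mfei = "" if stats is None or stats.mfei is None else f"{stats.mfei:.2f}"
            star = seqio.to_rna(c.duplex.star_sequence) if c.duplex.star_sequence else "ND"
            ratio = "" if c.duplex.read_ratio is None else f"{c.duplex.read_ratio:.2f}"
            crit = ";".join(
                f"{k}={'NA' if v is None else ('pass' if v else 'fail')}"
                for k, v in c.criteria_verdicts.items()
            )
            handle.write(
                f"{window.contig_id}\t{window.strand}\t{seqio.to_rna(mirna)}\t{len(mirna)}"
                f"\t{'' if stats is None else stats.hairpin_length}"
                f"\t{'' if stats is None else f'{stats.mfe:.2f}'}"
                f"\t{'' if stats is None else f'{stats.amfe:.2f}'}"
                f"\t{'' if stats is None else f'{stats.gc_percent:.2f}'}"
                f"\t{mfei}\t{star}\t{'' if c.duplex.mismatches is None else c.duplex.mismatches}"
                f"\t{ratio}\t{'yes' if c.valid else 'no'}\t{crit}\n"
            )
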