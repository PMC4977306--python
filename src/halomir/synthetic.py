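"""Synthetic inputs with machine-readable ground truth.

Generates a toy transcriptome with planted hairpin precursors, small-RNA
reads (mature and star strands with 3' adapters, a t/rRNA contaminant
fraction, and filler reads with a configured length mixture), degradome
tags concentrated opposite miRNA position 10, and replicate qPCR Ct tables
with planted treatment shifts — everything the pipeline consumes, plus a
truth object that enumerates what each stage should recover.

Planted hairpins embed a designed stem: five extension bases plus the
mature sequence pair perfectly with their reverse complement across a
short loop, which makes the star strand inferred by the 2-nt 3'-overhang
rule a known substring of the 3' arm. Decoys violate exactly one validity
criterion each: a weak AT-only stem on a short contig (MFE above -35), a
planted 4:1 mature:star read ratio, or five non-pairing substitutions in
the star arm (duplex mismatches above four).

Read depths are deliberately desk-scale (hundreds to a few thousand reads
per library) so that every stage runs in seconds; abundances are drawn
log-uniformly to mimic the wide dynamic range of real miRNA families.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from . import seqio
from .preprocess import DEFAULT_ADAPTER, RawRead, trim_adapter

_COMPLEMENT_BREAKER = {"A": "C", "C": "A", "G": "G", "T": "C"}


@dataclass
class SyntheticConfig:
    n_valid_hairpins: int = 5
    decoy_kinds: tuple[str, ...] = ("mfe", "mfe", "ratio", "ratio", "mismatch")
    n_background_contigs: int = 8
    background_contig_len: int = 900
    mirna_len: int = 21
    stem_extension: int = 5  # extra stem bases 5' of the mature sequence
    loop_len: int = 10
    context_len: int = 120  # contig context on each side of a planted hairpin
    mature_count_range: tuple[int, int] = (200, 2000)  # log-uniform per library
    star_ratio: float = 8.0  # mature:star read ratio for valid hairpins
    decoy_star_ratio: float = 4.0  # below the 5:1 acceptance threshold
    n_background_reads: int = 2000
    length_mixture: dict[int, float] = field(
        default_factory=lambda: {
            18: 0.03, 19: 0.03, 20: 0.08, 21: 0.25, 22: 0.10,
            23: 0.12, 24: 0.33, 25: 0.06,
        }
    )
    contaminant_fraction: float = 0.05
    n_junk_reads: int = 40  # too short / too long / ambiguous, removed by filtering
    adapter: str = DEFAULT_ADAPTER
    libraries: tuple[str, ...] = ("control", "salt")
    n_target_transcripts: int = 5
    degradome_peak_count: int = 30
    degradome_background_positions: int = 12
    ct_replicates: int = 6
    ct_noise_sd: float = 0.15
    ct_shifts: dict[str, float] = field(
        default_factory=lambda: {
            "syn-miR101": 2.0, "syn-miR102": 1.2, "syn-miR103": 0.0,
            "syn-miR104": -1.0, "syn-miR105": 0.0,
        }
    )
    seed: int = 1

    def validate(self) -> None:
        if self.loop_len < 3:
            raise ValueError("hairpin loop must be at least 3 nt")
        if self.mirna_len < 18 or self.mirna_len > 25:
            raise ValueError("mature length must lie in 18-25 nt")
        if self.n_valid_hairpins < 1:
            raise ValueError("need at least one planted hairpin")
        if abs(sum(self.length_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("length mixture must sum to 1")
        if any(not 18 <= l <= 25 for l in self.length_mixture):
            raise ValueError("length mixture must cover 18-25 nt only")


@dataclass
class PlantedHairpin:
    name: str
    kind: str  # "valid" or the violated criterion name
    violated: str | None
    contig_id: str
    mirna: str
    star: str
    mirna_contig_span: tuple[int, int]
    star_contig_span: tuple[int, int]
    counts: dict[str, dict[str, int]]  # library -> {"mature": n, "star": n}


@dataclass
class PlantedTarget:
    mirna_name: str
    transcript_id: str
    site_span: tuple[int, int]
    expectation: float
    inhibition: str
    cleavage_position: int
    confirmed_expected: bool


@dataclass
class SyntheticTruth:
    seed: int
    hairpins: list[PlantedHairpin]
    targets: list[PlantedTarget]
    degradome_profiles: dict[str, dict[int, int]]
    ct_shifts: dict[str, float]
    background_length_counts: dict[str, dict[int, int]]
    clean_read_totals: dict[str, int]
    contaminants: list[str]

    def to_yaml(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "hairpins": [asdict(h) for h in self.hairpins],
            "targets": [asdict(t) for t in self.targets],
            "degradome_profiles": self.degradome_profiles,
            "ct_shifts": self.ct_shifts,
            "background_length_counts": self.background_length_counts,
            "clean_read_totals": self.clean_read_totals,
            "contaminants": self.contaminants,
        }
        with open(path, "w") as handle:
            yaml.safe_dump(payload, handle, sort_keys=True)


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    truth: SyntheticTruth
    contigs: dict[str, str]  # transcriptome: hairpin contigs + targets + background
    raw_reads: dict[str, list[RawRead]]  # per library, adapters still attached
    mature_reference: list[tuple[str, str]]  # (miRBase-style name, sequence)
    contaminants: list[str]
    degradome_tags: dict[str, dict[int, int]]  # transcript -> position -> count
    degradome_sequences: list[tuple[str, str, int, int]]  # (transcript, seq, pos, count)
    ct_table: list[dict]  # rows: assay, condition, replicate, target_ct, control_ct

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seqio.write_fasta(outdir / "transcriptome.fasta", sorted(self.contigs.items()))
        for library, reads in self.raw_reads.items():
            seqio.write_fastq(
                outdir / f"reads_{library}.fastq",
                [(r.identifier, r.sequence, r.quality or "I" * len(r.sequence)) for r in reads],
            )
        seqio.write_fasta(outdir / "mature_reference.fasta", self.mature_reference)
        seqio.write_fasta(
            outdir / "contaminants.fasta",
            [(f"contaminant{i + 1}", seq) for i, seq in enumerate(self.contaminants)],
        )
        seqio.write_fasta(
            outdir / "degradome.fasta",
            [
                (f"deg_{transcript}_{pos}_x{count}", seq)
                for transcript, seq, pos, count in self.degradome_sequences
            ],
        )
        with open(outdir / "ct_table.tsv", "w") as handle:
            handle.write("assay\tcondition\treplicate\ttarget_ct\tcontrol_ct\n")
            for row in self.ct_table:
                handle.write(
                    f"{row['assay']}\t{row['condition']}\t{row['replicate']}"
                    f"\t{row['target_ct']:.3f}\t{row['control_ct']:.3f}\n"
                )
        self.truth.to_yaml(outdir / "truth.yaml")


def _random_seq(rng: np.random.Generator, length: int, alphabet: str = "ACGT") -> str:
    return "".join(alphabet[i] for i in rng.integers(0, len(alphabet), length))


def _adapter_safe(rng: np.random.Generator, length: int, adapter: str,
                  alphabet: str = "ACGT", min_overlap: int = 6) -> str:
    """A random sequence whose adapter-appended read trims back to itself."""
    for _ in range(200):
        candidate = _random_seq(rng, length, alphabet)
        probe = RawRead("probe", candidate + adapter)
        if trim_adapter(probe, adapter, min_overlap).sequence == candidate:
            return candidate
    raise RuntimeError("could not generate an adapter-safe sequence")


def _log_uniform(rng: np.random.Generator, low: int, high: int) -> int:
    return int(round(math.exp(rng.uniform(math.log(low), math.log(high)))))


def _build_hairpin_contig(
    rng: np.random.Generator,
    mirna: str,
    config: SyntheticConfig,
    context_len: int,
    alphabet: str = "ACGT",
    arm_mutations: Sequence[int] = (),
) -> tuple[str, tuple[int, int], tuple[int, int], str]:
    """Contig with an embedded stem-loop; returns contig, miRNA span, star span, star seq.

    The stem is ``extension + mirna`` paired with its reverse complement;
    ``arm_mutations`` lists 0-based miRNA positions whose partners in the
    3' arm are substituted with non-pairing bases.
    """
    ext = config.stem_extension
    ctx5 = _random_seq(rng, context_len, alphabet)
    extension = _random_seq(rng, ext, alphabet)
    loop = _random_seq(rng, config.loop_len, alphabet)
    arm5 = extension + mirna
    arm3 = list(seqio.reverse_complement(arm5))
    for i in arm_mutations:
        # miRNA position i sits at stem offset ext + i and pairs arm3 offset
        # len(arm5) - 1 - (ext + i)
        j = len(arm5) - 1 - (ext + i)
        arm3[j] = _COMPLEMENT_BREAKER[mirna[i]]
    arm3 = "".join(arm3)
    ctx3 = _random_seq(rng, context_len, alphabet)
    contig = ctx5 + arm5 + loop + arm3 + ctx3
    a = len(ctx5) + ext  # miRNA start
    b = a + len(mirna)
    r0 = len(ctx5) + len(arm5) + len(loop)  # 3' arm start
    # star by the 2-nt 3'-overhang rule: [partner(b-3), partner(a)+3)
    star_span = (r0 + 2, r0 + 2 + len(mirna))
    star = contig[star_span[0] : star_span[1]]
    return contig, (a, b), star_span, star


def generate(config: SyntheticConfig | None = None, outdir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full synthetic input bundle; deterministic in the seed."""
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    adapter = seqio.normalize(config.adapter)

    contigs: dict[str, str] = {}
    hairpins: list[PlantedHairpin] = []
    mature_reference: list[tuple[str, str]] = []

    # --- planted valid hairpins -----------------------------------------
    mirnas: list[tuple[str, str]] = []  # (name, sequence)
    for i in range(config.n_valid_hairpins):
        name = f"syn-miR{101 + i}"
        # mature sequences start with U and lean GC-rich for a stable stem
        mirna = "T" + _adapter_safe(rng, config.mirna_len - 1, adapter, "ACGTGC")
        contig, mspan, sspan, star = _build_hairpin_contig(
            rng, mirna, config, config.context_len
        )
        contig_id = f"hp_valid_{i + 1}"
        contigs[contig_id] = contig
        hairpins.append(
            PlantedHairpin(
                name=name, kind="valid", violated=None, contig_id=contig_id,
                mirna=mirna, star=star, mirna_contig_span=mspan,
                star_contig_span=sspan, counts={},
            )
        )
        mirnas.append((name, mirna))
        mature_reference.append((f"{name}a", mirna))

    # --- decoys with one named criterion violation each ------------------
    for d, kind in enumerate(config.decoy_kinds):
        contig_id = f"hp_decoy_{kind}_{d + 1}"
        if kind == "mfe":
            # AT-only weak stem on a short contig: hairpin folds but stays
            # far above the -35 kcal/mol stability threshold
            mirna = _adapter_safe(rng, config.mirna_len, adapter, "AT")
            contig, mspan, sspan, star = _build_hairpin_contig(
                rng, mirna, config, context_len=15, alphabet="AT"
            )
            violated = "mfe"
        elif kind == "ratio":
            mirna = "T" + _adapter_safe(rng, config.mirna_len - 1, adapter, "ACGTGC")
            contig, mspan, sspan, star = _build_hairpin_contig(
                rng, mirna, config, config.context_len
            )
            violated = "read_ratio"
        elif kind == "mismatch":
            mirna = "T" + _adapter_safe(rng, config.mirna_len - 1, adapter, "GCGCAT")
            positions = [4, 7, 10, 13, 16][: 5]
            contig, mspan, sspan, star = _build_hairpin_contig(
                rng, mirna, config, config.context_len, arm_mutations=positions
            )
            violated = "duplex_mismatches"
        else:
            raise ValueError(f"unknown decoy kind {kind!r}")
        contigs[contig_id] = contig
        hairpins.append(
            PlantedHairpin(
                name=f"syn-decoy{d + 1}", kind=f"decoy_{kind}", violated=violated,
                contig_id=contig_id, mirna=mirna, star=star,
                mirna_contig_span=mspan, star_contig_span=sspan, counts={},
            )
        )

    # --- background contigs ----------------------------------------------
    for i in range(config.n_background_contigs):
        contigs[f"bg_{i + 1}"] = _random_seq(rng, config.background_contig_len)

    # --- target transcripts + degradome ----------------------------------
    targets: list[PlantedTarget] = []
    degradome: dict[str, dict[int, int]] = {}
    n_targets = min(config.n_target_transcripts, len(mirnas))
    for i in range(n_targets):
        name, mirna = mirnas[i]
        transcript_id = f"target_{i + 1}"
        site = seqio.reverse_complement(mirna)
        utr5 = _random_seq(rng, 80)
        pre = _random_seq(rng, 70)
        post = _random_seq(rng, 150)
        transcript = utr5 + pre + site + post
        start = len(utr5) + len(pre)
        end = start + len(site)
        contigs[transcript_id] = transcript
        cleavage = end - 10  # 5' end of the 3' fragment, opposite position 10
        # last planted site gets its peak displaced 5 nt: predicted but
        # unconfirmed, exercising the window rule
        displaced = i == n_targets - 1
        peak_pos = cleavage + (5 if displaced else 0)
        profile = {peak_pos: config.degradome_peak_count}
        placed = 0
        while placed < config.degradome_background_positions:
            pos = int(rng.integers(0, len(transcript) - 20))
            if abs(pos - cleavage) <= 2 or pos in profile:
                continue
            profile[pos] = 1
            placed += 1
        degradome[transcript_id] = profile
        targets.append(
            PlantedTarget(
                mirna_name=name, transcript_id=transcript_id,
                site_span=(start, end), expectation=0.0, inhibition="cleavage",
                cleavage_position=cleavage, confirmed_expected=not displaced,
            )
        )

    degradome_sequences = [
        (transcript_id, contigs[transcript_id][pos : pos + 20], pos, count)
        for transcript_id in sorted(degradome)
        for pos, count in sorted(degradome[transcript_id].items())
    ]

    # --- small-RNA reads --------------------------------------------------
    contaminants = [_adapter_safe(rng, int(rng.integers(18, 26)), adapter) for _ in range(3)]
    raw_reads: dict[str, list[RawRead]] = {}
    background_length_counts: dict[str, dict[int, int]] = {}
    clean_totals: dict[str, int] = {}
    serial = 0

    def _emit(reads: list[RawRead], sequence: str, count: int, label: str) -> None:
        nonlocal serial
        for _ in range(count):
            serial += 1
            full = sequence + adapter
            reads.append(RawRead(f"{label}_{serial}", full, "I" * len(full)))

    for library in config.libraries:
        reads: list[RawRead] = []
        clean = 0
        for hp in hairpins:
            low, high = config.mature_count_range
            mature_n = _log_uniform(rng, low, high)
            ratio = config.decoy_star_ratio if hp.kind == "decoy_ratio" else config.star_ratio
            star_n = max(1, int(round(mature_n / ratio)))
            hp.counts[library] = {"mature": mature_n, "star": star_n}
            _emit(reads, hp.mirna, mature_n, f"{hp.name}_m")
            _emit(reads, hp.star, star_n, f"{hp.name}_s")
            clean += mature_n + star_n
        # filler reads with the configured exact length mixture
        lengths = sorted(config.length_mixture)
        counts = [int(round(config.length_mixture[l] * config.n_background_reads)) for l in lengths]
        background_length_counts[library] = dict(zip(lengths, counts))
        for length, count in zip(lengths, counts):
            for _ in range(count):
                _emit(reads, _adapter_safe(rng, length, adapter), 1, "bg")
        clean += sum(counts)
        # contaminant reads: removed by filtering, absent from clean totals
        n_contaminant = int(round(config.contaminant_fraction * config.n_background_reads))
        for _ in range(n_contaminant):
            _emit(reads, contaminants[int(rng.integers(0, len(contaminants)))], 1, "trrna")
        # junk removed by the length / ambiguity rules
        for _ in range(config.n_junk_reads):
            choice = int(rng.integers(0, 3))
            if choice == 0:
                seq = _random_seq(rng, int(rng.integers(10, 18)))
            elif choice == 1:
                seq = _random_seq(rng, int(rng.integers(26, 40)))
            else:
                base = list(_adapter_safe(rng, 21, adapter))
                base[int(rng.integers(0, len(base)))] = "N"
                seq = "".join(base)
            _emit(reads, seq, 1, "junk")
        order = rng.permutation(len(reads))
        raw_reads[library] = [reads[i] for i in order]
        clean_totals[library] = clean

    # a couple of near-miss reference entries to exercise mismatch matching
    if mirnas:
        name, mirna = mirnas[0]
        variant = list(mirna)
        variant[5] = _COMPLEMENT_BREAKER[variant[5]]
        mature_reference.append((f"{name}b", "".join(variant)))

    # --- qPCR Ct tables ---------------------------------------------------
    ct_rows: list[dict] = []
    base_ct = 24.0
    control_gene_ct = 18.0
    for assay, shift in config.ct_shifts.items():
        for condition in config.libraries:
            # planted fold change = dCt(control) - dCt(salt) = -shift under
            # this sign convention: positive shift raises the treated Ct
            offset = shift if condition != config.libraries[0] else 0.0
            for replicate in range(config.ct_replicates):
                ct_rows.append(
                    {
                        "assay": assay,
                        "condition": condition,
                        "replicate": replicate + 1,
                        "target_ct": base_ct + offset + rng.normal(0, config.ct_noise_sd),
                        "control_ct": control_gene_ct + rng.normal(0, config.ct_noise_sd),
                    }
                )

    truth = SyntheticTruth(
        seed=config.seed,
        hairpins=hairpins,
        targets=targets,
        degradome_profiles=degradome,
        ct_shifts=dict(config.ct_shifts),
        background_length_counts=background_length_counts,
        clean_read_totals=clean_totals,
        contaminants=contaminants,
    )
    dataset = SyntheticDataset(
        config=config,
        truth=truth,
        contigs=contigs,
        raw_reads=raw_reads,
        mature_reference=mature_reference,
        contaminants=contaminants,
        degradome_tags=degradome,
        degradome_sequences=degradome_sequences,
        ct_table=ct_rows,
    )
    if outdir is not None:
        dataset.write(outdir)
    return dataset
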