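"""End-to-end pipeline orchestration.

One :class:`PipelineConfig` drives a full run: load the reference
database, prepare the reads of one pipeline variant, assign every read
by both paradigms (alignment and k-mer), and write per-sample
assignment tables, genus profiles and a richness table plus a manifest
recording the configuration hash and seed. Reruns with identical
config and seed are byte-identical.

Variants:

* ``short_paired`` — mate pairs; joinable pairs are merged and
  assigned as single full-amplicon reads, the rest go through the
  paired concordance filter.
* ``long_trim``    — long reads, adapter end-trimming + concatemer
  splitting (the least-removal baseline).
* ``long_extract`` — long reads, strict primer-to-primer amplicon
  extraction (discards reads missing either primer; never assigns
  more reads than ``long_trim``).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__
from .align_assign import (
    ScoredAssignment,
    align_pair_to_db,
    align_to_db,
    assign_read,
    assign_single,
    pair_filter,
    profile_sample,
    write_assignments,
)
from .kmer_classify import TaxTree, build_index, classify_reads, kmer_profile
from .read_prep import demultiplex, join_pairs, prep_long_reads, read_fastq
from .reference_db import ReferenceDatabase, read_reference_fasta
from .report import pollen_richness, richness_table, write_profile
from .synthetic_data import DEFAULT_ADAPTER_LEADER, ITS2F, ITS4R

VARIANTS = ("short_paired", "long_trim", "long_extract")


class ConfigurationError(ValueError):
    """Invalid pipeline configuration (exit code 2)."""


class InputError(ValueError):
    """Missing or malformed inputs (exit code 3)."""


@dataclass
class PipelineConfig:
    """Everything a run needs; flags mirror these keys one-to-one."""

    reference: str
    output_dir: str
    variant: str
    seed: int = 0
    # short variant: [{sample_id, r1, r2}]; long variants: [{sample_id, reads}]
    samples: list[dict] = field(default_factory=list)
    # long variants alternative input: one pooled FASTQ plus barcodes
    pooled_reads: str | None = None
    barcodes: dict[str, str] = field(default_factory=dict)
    adapter_leader: str = DEFAULT_ADAPTER_LEADER
    fwd_primer: str = ITS2F
    rev_primer: str = ITS4R
    # assignment thresholds
    min_len: int = 50
    min_identity: float = 0.98
    min_identity_long: float | None = None  # defaults to min_identity
    tiebreak_priority: list[str] = field(default_factory=list)
    max_candidates: int = 8
    # read preparation thresholds
    trim_max_mismatch: float = 0.30
    demux_max_mismatch: float = 0.25
    min_fragment: int = 50
    join_min_overlap: int = 10
    join_max_mismatch: float = 0.08
    # k-mer arm
    kmer_k: int = 21
    # reporting
    richness_min_count: int = 1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def validate_config(config: PipelineConfig) -> list[str]:
    """Rule-by-rule validation; each violation names the field and range."""
    v = []
    if config.variant not in VARIANTS:
        v.append(f"variant: must be one of {VARIANTS}, got {config.variant!r}")
    if config.min_len < 1:
        v.append(f"min_len: must be >= 1, got {config.min_len}")
    for name in ("min_identity", "min_identity_long"):
        val = getattr(config, name)
        if val is not None and not 0.0 <= val <= 1.0:
            v.append(f"{name}: must be in [0, 1], got {val}")
    for name in ("trim_max_mismatch", "demux_max_mismatch", "join_max_mismatch"):
        val = getattr(config, name)
        if not 0.0 <= val < 0.5:
            v.append(f"{name}: must be in [0, 0.5), got {val}")
    if config.min_fragment < 1:
        v.append(f"min_fragment: must be >= 1, got {config.min_fragment}")
    if config.join_min_overlap < 1:
        v.append(f"join_min_overlap: must be >= 1, got {config.join_min_overlap}")
    if config.kmer_k % 2 == 0 or not 11 <= config.kmer_k <= 31:
        v.append(f"kmer_k: must be odd and in [11, 31], got {config.kmer_k}")
    if config.max_candidates < 1:
        v.append(f"max_candidates: must be >= 1, got {config.max_candidates}")
    if config.richness_min_count < 1:
        v.append(f"richness_min_count: must be >= 1, got {config.richness_min_count}")
    if config.seed < 0:
        v.append(f"seed: must be >= 0, got {config.seed}")
    if not config.samples and not config.pooled_reads:
        v.append("samples: at least one sample (or pooled_reads + barcodes) required")
    if config.pooled_reads and not config.barcodes:
        v.append("barcodes: required when pooled_reads is set")
    return v


def _config_hash(config: PipelineConfig) -> str:
    # output_dir identifies where results land, not what was computed
    d = {k: v for k, v in config.to_dict().items() if k != "output_dir"}
    canon = json.dumps(d, sort_keys=True).encode()
    return hashlib.sha256(canon).hexdigest()


def _load_reads_by_sample(config: PipelineConfig) -> dict[str, list]:
    """Long-read input: per-sample files, or demultiplex a pooled file."""
    if config.pooled_reads:
        path = Path(config.pooled_reads)
        if not path.exists():
            raise InputError(f"pooled reads file not found: {path}")
        reads = read_fastq(path, platform="long_single")
        bins, _unassigned = demultiplex(
            reads, config.barcodes, config.demux_max_mismatch
        )
        return bins
    out = {}
    for entry in config.samples:
        path = Path(entry["reads"])
        if not path.exists():
            raise InputError(f"reads file not found: {path}")
        out[entry["sample_id"]] = read_fastq(path, platform="long_single")
    return out


def _assign_long_sample(
    sample_id: str, reads, db: ReferenceDatabase, config: PipelineConfig, mode: str
):
    flanks = [config.adapter_leader + bc for bc in config.barcodes.values()] or [
        config.adapter_leader
    ]
    prepped, trim_report = prep_long_reads(
        reads,
        flank_motifs=flanks,
        mode="extract" if mode == "long_extract" else "trim",
        fwd_primer=config.fwd_primer,
        rev_primer=config.rev_primer,
        max_mismatch_frac=config.trim_max_mismatch,
        min_fragment=config.min_fragment,
    )
    min_ident = (
        config.min_identity_long
        if config.min_identity_long is not None
        else config.min_identity
    )
    assignments = []
    for read in prepped:
        hits = align_to_db(
            read.bases, db, read_id=read.read_id,
            max_candidates=config.max_candidates, per_genus=True,
        )
        assignments.append(
            assign_single(
                hits,
                db,
                min_len=config.min_len,
                min_identity=min_ident,
                tiebreak_priority=config.tiebreak_priority,
                read_id=read.read_id,
                mode="single",
            )
        )
    return prepped, assignments, trim_report


def _assign_short_sample(sample_id: str, r1s, r2s, db: ReferenceDatabase, config: PipelineConfig):
    if len(r1s) != len(r2s):
        raise InputError(
            f"sample {sample_id}: R1 has {len(r1s)} reads but R2 has {len(r2s)}"
        )
    assignments: list[ScoredAssignment] = []
    prepped = []
    for r1, r2 in zip(r1s, r2s):
        joined = join_pairs(
            r1, r2, config.join_min_overlap, config.join_max_mismatch
        )
        if joined is not None:
            prepped.append(joined)
            hits = align_to_db(
                joined.bases, db, read_id=joined.read_id,
                max_candidates=config.max_candidates, per_genus=True,
            )
            assignments.append(
                assign_single(
                    hits, db, config.min_len, config.min_identity,
                    config.tiebreak_priority, read_id=joined.read_id, mode="joined",
                )
            )
        else:
            prepped.extend([r1, r2])
            stem = r1.read_id.rsplit("/", 1)[0]
            h1, h2 = align_pair_to_db(
                r1.bases, r2.bases, db, read_id=stem,
                max_candidates=config.max_candidates,
            )
            candidates = pair_filter(h1, h2, config.min_len, config.min_identity)
            assignments.append(
                assign_read(
                    candidates, db, config.tiebreak_priority, read_id=stem, mode="paired"
                )
            )
    return prepped, assignments


def run_pipeline(config: PipelineConfig) -> Path:
    """Run one pipeline variant end to end; returns the output directory."""
    violations = validate_config(config)
    if violations:
        raise ConfigurationError("; ".join(violations))
    ref_path = Path(config.reference)
    if not ref_path.exists():
        raise InputError(f"reference FASTA not found: {ref_path}")
    records = read_reference_fasta(ref_path)
    db = ReferenceDatabase(records)
    tree = TaxTree.from_reference(db)
    index = build_index(db, tree, config.kmer_k)

    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    marker = out_dir / "RUN_FAILED"
    marker.write_text("run did not complete\n")

    profiles = []
    log_lines = [f"pollenpipe {__version__} variant={config.variant} seed={config.seed}"]
    if config.variant == "short_paired":
        for entry in config.samples:
            sid = entry["sample_id"]
            for key in ("r1", "r2"):
                if not Path(entry[key]).exists():
                    raise InputError(f"sample {sid}: {key} file not found: {entry[key]}")
            r1s = read_fastq(entry["r1"], platform="short_paired")
            r2s = read_fastq(entry["r2"], platform="short_paired")
            prepped, assignments = _assign_short_sample(sid, r1s, r2s, db, config)
            _write_sample_outputs(out_dir, sid, prepped, assignments, db, tree, index, config)
            profiles.append(profile_sample(assignments, sid))
            log_lines.append(
                f"{sid}: pairs={len(r1s)} assigned={profiles[-1].n_assigned}"
            )
    else:
        reads_by_sample = _load_reads_by_sample(config)
        for sid in sorted(reads_by_sample):
            prepped, assignments, trim_report = _assign_long_sample(
                sid, reads_by_sample[sid], db, config, config.variant
            )
            _write_sample_outputs(out_dir, sid, prepped, assignments, db, tree, index, config)
            profiles.append(profile_sample(assignments, sid))
            log_lines.append(
                f"{sid}: reads_in={trim_report.n_reads_in} reads_out={trim_report.n_reads_out} "
                f"split={trim_report.n_split_concatemers} assigned={profiles[-1].n_assigned}"
            )

    table = richness_table({config.variant: profiles}, config.richness_min_count)
    table.to_csv(out_dir / "richness.tsv", sep="\t")
    per_sample = "\n".join(
        f"{p.sample_id}\t{pollen_richness(p, config.richness_min_count)}\t{p.n_assigned}\t{p.n_unassigned}"
        for p in profiles
    )
    (out_dir / "richness_per_sample.tsv").write_text(
        "sample_id\trichness\tn_assigned\tn_unassigned\n" + per_sample + "\n"
    )

    thresholds = {
        k: v
        for k, v in config.to_dict().items()
        if k not in ("samples", "reference", "output_dir", "pooled_reads")
    }
    log_lines.append("thresholds: " + json.dumps(thresholds, sort_keys=True))
    (out_dir / "run.log").write_text("\n".join(log_lines) + "\n")
    manifest = dict(
        pollenpipe_version=__version__,
        config_sha256=_config_hash(config),
        seed=config.seed,
        variant=config.variant,
        n_samples=len(profiles),
    )
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    marker.unlink()
    return out_dir


def _write_sample_outputs(out_dir, sample_id, prepped, assignments, db, tree, index, config):
    write_assignments(assignments, out_dir / f"{sample_id}.assignments.tsv")
    write_profile(profile_sample(assignments, sample_id), out_dir / f"{sample_id}.profile.tsv")
    classifications = classify_reads(prepped, index, tree)
    write_profile(
        kmer_profile(classifications, tree, sample_id),
        out_dir / f"{sample_id}.kmer_profile.tsv",
    )
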