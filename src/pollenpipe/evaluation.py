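"""Desk-scale evaluation studies on ground-truthed synthetic data.

This module packages the standard validation experiments the test
suite and the reproduction script both run: a six-sample study
(15 genera per sample, 5,000 amplicon molecules each, drawn from a
20-genus reference) sequenced on both simulated platforms, plus
focused experiments for mate-pair join-rate analytics and concatemer
handling. Each function recomputes its metrics from scratch for a
given seed.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .align_assign import (
    SampleProfile,
    align_pair_to_db,
    align_to_db,
    assign_read,
    assign_single,
    pair_filter,
    profile_sample,
)
from .kmer_classify import (
    TaxTree,
    build_index,
    classify_read,
    kmer_profile,
)
from .read_prep import join_pairs, prep_long_reads
from .reference_db import ReferenceDatabase
from .report import concordance, pollen_richness, rank_abundance
from .synthetic_data import (
    DEFAULT_ADAPTER_LEADER,
    ITS2F,
    ITS4R,
    ErrorModel,
    Molecule,
    amplicon_length_distribution,
    default_barcode_map,
    generate_reference_set,
    generate_sample_truths,
    simulate_long_reads,
    simulate_sample,
    simulate_short_pairs,
)

# study defaults: 6 samples of 15 genera each over a 20-genus reference,
# 5,000 amplicon molecules per sample
N_SAMPLES = 6
N_GENERA_DB = 20
SPECIES_PER_GENUS = 3
N_GENERA_PER_SAMPLE = 15
N_AMPLICONS = 5000

NOISY_RATES = dict(sub_rate=0.03, ins_rate=0.03, del_rate=0.03)
RELAXED_IDENTITY = 0.80


@dataclass
class Study:
    """Reference database, sample truths and drawn molecules."""

    db: ReferenceDatabase
    tree: TaxTree
    truths: list
    molecules: dict[str, list[Molecule]]
    barcode_map: dict[str, str]

    @property
    def sample_ids(self) -> list[str]:
        return [t.sample_id for t in self.truths]

    def truth_profile(self, sample_id: str) -> SampleProfile:
        """Ground-truth genus counts, cross-tabulated from provenance."""
        counts = Counter(m.genus for m in self.molecules[sample_id])
        return SampleProfile(sample_id=sample_id, counts=dict(sorted(counts.items())))


def build_study(
    seed: int,
    n_samples: int = N_SAMPLES,
    n_amplicons: int = N_AMPLICONS,
    n_genera_db: int = N_GENERA_DB,
    species_per_genus: int = SPECIES_PER_GENUS,
    n_genera_per_sample: int = N_GENERA_PER_SAMPLE,
) -> Study:
    records = generate_reference_set(n_genera_db, species_per_genus, seed=seed)
    db = ReferenceDatabase(records, derep=True)
    truths = generate_sample_truths(
        db.genera, n_samples, n_amplicons, seed=seed + 1,
        n_genera_per_sample=n_genera_per_sample,
    )
    molecules = {t.sample_id: simulate_sample(records, t) for t in truths}
    return Study(
        db=db,
        tree=TaxTree.from_reference(db),
        truths=truths,
        molecules=molecules,
        barcode_map=default_barcode_map([t.sample_id for t in truths]),
    )


@dataclass
class LongArmResult:
    """Per-sample outcome of one long-read pipeline variant."""

    mode: str
    profiles: dict[str, SampleProfile]
    kmer_profiles: dict[str, SampleProfile]
    n_assigned: dict[str, int]
    genus_agreement: dict[str, tuple[int, int]]  # (both-genus agree, both-genus total)
    prepped_counts: dict[str, int] = field(default_factory=dict)


def run_long_arm(
    study: Study,
    error: ErrorModel,
    seed: int,
    mode: str = "trim",
    min_identity: float = RELAXED_IDENTITY,
    min_len: int = 50,
    kmer_k: int = 21,
) -> LongArmResult:
    """Simulate, prepare and assign long reads for every sample.

    Returns alignment and k-mer genus profiles plus, per sample, the
    count of reads where both paradigms produced a genus and agreed.
    """
    index = build_index(study.db, study.tree, kmer_k)
    profiles, kprofiles, n_assigned, agreement, prepped_counts = {}, {}, {}, {}, {}
    for i, sid in enumerate(study.sample_ids):
        bc = study.barcode_map[sid]
        reads, _truth = simulate_long_reads(
            study.molecules[sid], bc, error=error, seed=seed + 17 * i
        )
        flanks = [(error.adapter_leader or DEFAULT_ADAPTER_LEADER) + bc]
        prepped, _report = prep_long_reads(
            reads, flanks, mode=mode, fwd_primer=ITS2F, rev_primer=ITS4R
        )
        prepped_counts[sid] = len(prepped)
        assignments = []
        agree = total = 0
        classifications = []
        for read in prepped:
            hits = align_to_db(read.bases, study.db, read_id=read.read_id, per_genus=True)
            a = assign_single(
                hits, study.db, min_len=min_len, min_identity=min_identity,
                read_id=read.read_id,
            )
            assignments.append(a)
            c, _ = classify_read(read.bases, index, study.tree, read_id=read.read_id)
            classifications.append(c)
            kg = study.tree.genus_of(c.taxon) if c.classified else None
            if a.assigned and kg is not None:
                total += 1
                agree += a.genus == kg
        profiles[sid] = profile_sample(assignments, sid)
        kprofiles[sid] = kmer_profile(classifications, study.tree, sid)
        n_assigned[sid] = profiles[sid].n_assigned
        agreement[sid] = (agree, total)
    return LongArmResult(
        mode=mode, profiles=profiles, kmer_profiles=kprofiles,
        n_assigned=n_assigned, genus_agreement=agreement,
        prepped_counts=prepped_counts,
    )


def run_short_arm(
    study: Study,
    seed: int,
    min_identity: float = 0.98,
    min_len: int = 50,
    join_min_overlap: int = 10,
) -> dict[str, SampleProfile]:
    """Simulate and assign 2x150 paired-end reads for every sample.

    Joinable pairs are merged and assigned as single reads; the rest go
    through the paired concordance filter (both mates on one entry,
    >98% identity, >=50 columns each, mate scores summed).
    """
    profiles = {}
    for i, sid in enumerate(study.sample_ids):
        r1s, r2s, _ = simulate_short_pairs(
            study.molecules[sid], seed=seed + 31 * i
        )
        assignments = []
        for r1, r2 in zip(r1s, r2s):
            stem = r1.read_id.rsplit("/", 1)[0]
            joined = join_pairs(r1, r2, min_overlap=join_min_overlap)
            if joined is not None:
                hits = align_to_db(joined.bases, study.db, read_id=stem, per_genus=True)
                assignments.append(
                    assign_single(
                        hits, study.db, min_len=min_len, min_identity=min_identity,
                        read_id=stem, mode="joined",
                    )
                )
            else:
                h1, h2 = align_pair_to_db(r1.bases, r2.bases, study.db, read_id=stem)
                cands = pair_filter(h1, h2, min_len=min_len, min_identity=min_identity)
                assignments.append(
                    assign_read(cands, study.db, read_id=stem, mode="paired")
                )
        profiles[sid] = profile_sample(assignments, sid)
    return profiles


def top10_membership_matches(
    profiles: dict[str, SampleProfile],
    reference_profiles: dict[str, SampleProfile],
    top_n: int = 10,
) -> int:
    """Samples whose top-n genus membership equals the reference's."""
    n = 0
    for sid, prof in profiles.items():
        rep = concordance(prof, reference_profiles[sid], top_n)
        n += rep.identical_membership
    return n


def richness_errors(
    profiles: dict[str, SampleProfile], study: Study, min_count: int = 1
) -> list[int]:
    """Per-sample |observed richness - true richness|."""
    out = []
    for sid, prof in profiles.items():
        true_r = pollen_richness(study.truth_profile(sid))
        out.append(abs(pollen_richness(prof, min_count) - true_r))
    return out


def join_rate_experiment(seed: int, n_pairs: int = 10000, min_overlap: int = 10):
    """Observed vs analytic join rate for error-free 2x150 pairs.

    A pair of 150 nt mates can only overlap by >= min_overlap when the
    amplicon is at most 300 - min_overlap nt, so the joined fraction
    should match the amplicon-length CDF at that point. Amplicon
    lengths are drawn iid from the length law (one molecule per draw;
    a genus-weighted mixture over a finite species set would not obey
    the binomial error bar). Lengths are rounded to whole bases, hence
    the half-base continuity correction on the CDF.
    """
    from ._dna import random_dna
    from .synthetic_data import ITS2F, ITS4R, PRIMER_LEN, default_length_sampler
    from ._dna import revcomp as _rc

    rng = np.random.default_rng(seed + 5)
    lengths = default_length_sampler(rng, n_pairs)
    molecules = [
        Molecule(
            molecule_id=f"m{i}", sample_id="joinexp", record_id=f"m{i}", genus="X",
            amplicon=ITS2F + random_dna(rng, int(L) - PRIMER_LEN) + _rc(ITS4R),
        )
        for i, L in enumerate(lengths)
    ]
    error = ErrorModel.short_paired(sub_rate=0.0)
    r1s, r2s, _ = simulate_short_pairs(molecules, error=error, seed=seed + 7)
    n_joined = sum(
        join_pairs(r1, r2, min_overlap=min_overlap) is not None
        for r1, r2 in zip(r1s, r2s)
    )
    observed = n_joined / n_pairs
    expected = float(amplicon_length_distribution().cdf(300 - min_overlap + 0.5))
    sd = float(np.sqrt(expected * (1 - expected) / n_pairs))
    return observed, expected, sd


def concatemer_experiment(
    seed: int, n_concatemers: int = 500, min_identity: float = RELAXED_IDENTITY
):
    """Split simulated concatemers and assign both fragments.

    Returns the fraction of concatemer reads that were split into two
    fragments whose assigned genera match the two source molecules.
    """
    study = build_study(seed + 9, n_samples=1, n_amplicons=2 * n_concatemers)
    sid = study.sample_ids[0]
    bc = study.barcode_map[sid]
    error = ErrorModel.long_single(concatemer_prob=1.0, **NOISY_RATES)
    reads, truth = simulate_long_reads(study.molecules[sid], bc, error=error, seed=seed + 10)
    flanks = [DEFAULT_ADAPTER_LEADER + bc]
    truth_by_read: dict[str, list[str]] = {}
    for row in truth.itertuples():
        truth_by_read.setdefault(row.read_id, []).append(row.genus)
    n_ok = 0
    n_reads = 0
    from .read_prep import find_and_trim_flanks, split_concatemers

    for read in reads:
        if len(truth_by_read[read.read_id]) != 2:
            continue
        n_reads += 1
        trimmed, _ = find_and_trim_flanks(read, flanks)
        frags = split_concatemers(trimmed, flanks)
        if len(frags) != 2:
            continue
        genera = []
        for frag in frags:
            hits = align_to_db(frag.bases, study.db, per_genus=True)
            a = assign_single(hits, study.db, min_identity=min_identity)
            genera.append(a.genus)
        if sorted(g or "" for g in genera) == sorted(truth_by_read[read.read_id]):
            n_ok += 1
    return n_ok / n_reads if n_reads else float("nan"), n_reads
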