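"""Ground-truthed synthetic ITS2 amplicon data.

Emulates the two sequencing arms of a pollen-metabarcoding study at
desk scale:

* a reference set of genus-structured ITS2 sequences with realistic
  length variability (amplicons average ~354 nt, some exceeding 600 nt);
* per-sample genus abundance profiles (a few dominant genera plus a
  rare tail);
* short paired-end reads (2 x 150 nt, ~Q30, substitution errors only);
* long single reads (~Q8.5) with substitutions *and* indels, wrapped in
  a ~65 nt barcoded adapter flank at each end, occasionally two
  amplicons ligated into one read (concatemers).

Every generator takes an explicit integer seed and is bit-reproducible.
Truth tables (read id -> source sample/genus/record) accompany every
simulated read set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._dna import decode, encode, random_dna, revcomp
from .read_prep import ReadRecord
from .reference_db import ReferenceRecord

# The ITS2 amplification primers (20 nt each); amplicons carry the
# forward primer at the 5' end and the reverse complement of the
# reverse primer at the 3' end, so 2 x 40 nt of every amplicon pair is
# primer sequence.
ITS2F = "ATGCGATACTTGGTGTGAAT"
ITS4R = "TCCTCCGCTTATTGATATGC"

PRIMER_LEN = len(ITS2F) + len(ITS4R)  # 40

# Amplicon length distribution: truncated normal, mean 354 nt, sd 60,
# support [150, 700] — full-length amplicons average ~354 nt while the
# upper tail admits the >600 nt ITS2 variants.
AMPLICON_MEAN = 354.0
AMPLICON_SD = 60.0
AMPLICON_MIN = 150
AMPLICON_MAX = 700

# Native-barcoding adapter geometry: a full flank is ~65 nt of which
# the actual barcode is 24 nt.
BARCODE_LEN = 24
ADAPTER_LEADER_LEN = 41


def _trunc_norm(mean: float, sd: float, lo: float, hi: float):
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm(a, b, loc=mean, scale=sd)


def amplicon_length_distribution():
    """The default amplicon-length law (scipy frozen distribution)."""
    return _trunc_norm(AMPLICON_MEAN, AMPLICON_SD, AMPLICON_MIN, AMPLICON_MAX)


def default_length_sampler(rng: np.random.Generator, n: int) -> np.ndarray:
    """Draw n amplicon lengths from the default truncated normal."""
    dist = amplicon_length_distribution()
    return np.round(dist.rvs(size=n, random_state=rng)).astype(int)


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class SimulatedLocus:
    """One amplifiable locus: a reference record plus its amplicon."""

    reference: ReferenceRecord
    amplicon: str

    def __post_init__(self):
        if not self.amplicon.startswith(ITS2F) or not self.amplicon.endswith(revcomp(ITS4R)):
            raise ValueError("amplicon must be primer-flanked")

    @property
    def spacer_length(self) -> int:
        return len(self.amplicon) - PRIMER_LEN


@dataclass(frozen=True)
class Molecule:
    """One amplicon molecule drawn for a sample, with provenance."""

    molecule_id: str
    sample_id: str
    record_id: str
    genus: str
    amplicon: str


@dataclass
class SampleTruth:
    """Ground-truth composition of one simulated pollen sample."""

    sample_id: str
    genus_proportions: dict[str, float]
    n_amplicons: int
    seed: int

    def __post_init__(self):
        props = np.array(list(self.genus_proportions.values()), dtype=float)
        if (props < 0).any():
            raise ValueError("genus proportions must be non-negative")
        if props.size and abs(props.sum() - 1.0) > 1e-9:
            raise ValueError(f"genus proportions sum to {props.sum()}, not 1")
        if self.n_amplicons < 0:
            raise ValueError("n_amplicons must be >= 0")


@dataclass
class ErrorModel:
    """Per-base error process of one sequencing platform."""

    platform: str  # "short_paired" | "long_single"
    sub_rate: float
    ins_rate: float = 0.0
    del_rate: float = 0.0
    mean_q: float = 30.0
    q_sd: float = 2.5
    concatemer_prob: float = 0.0
    adapter_leader: str = ""
    flank_q_penalty: float = 0.0  # adapter-flank bases read this much worse

    def __post_init__(self):
        for name in ("sub_rate", "ins_rate", "del_rate"):
            rate = getattr(self, name)
            if not 0 <= rate < 1:
                raise ValueError(f"{name} must be in [0, 1), got {rate}")
        if not 0 <= self.concatemer_prob <= 1:
            raise ValueError("concatemer_prob must be in [0, 1]")

    @classmethod
    def short_paired(cls, **kw) -> "ErrorModel":
        """~Q30 substitution-only model (polymerase short reads)."""
        kw.setdefault("sub_rate", 0.001)
        kw.setdefault("mean_q", 30.0)
        kw.setdefault("q_sd", 2.5)
        return cls(platform="short_paired", **kw)

    @classmethod
    def long_single(cls, **kw) -> "ErrorModel":
        """~Q8.5 sub+indel model with adapter flanks and rare concatemers."""
        kw.setdefault("sub_rate", 0.06)
        kw.setdefault("ins_rate", 0.04)
        kw.setdefault("del_rate", 0.04)
        kw.setdefault("mean_q", 8.5)
        kw.setdefault("q_sd", 3.0)
        kw.setdefault("concatemer_prob", 0.01)
        kw.setdefault("adapter_leader", DEFAULT_ADAPTER_LEADER)
        kw.setdefault("flank_q_penalty", 2.0)
        return cls(platform="long_single", **kw)


# deterministic adapter leader and well-separated barcode set
_bc_rng = np.random.default_rng(20170523)
DEFAULT_ADAPTER_LEADER = random_dna(_bc_rng, ADAPTER_LEADER_LEN)


def _make_barcodes(rng: np.random.Generator, n: int, min_hamming: int = 14) -> list[str]:
    barcodes: list[str] = []
    while len(barcodes) < n:
        cand = random_dna(rng, BARCODE_LEN)
        ok = all(
            sum(a != b for a, b in zip(cand, bc)) >= min_hamming for bc in barcodes
        )
        if ok:
            barcodes.append(cand)
    return barcodes


DEFAULT_BARCODES = _make_barcodes(_bc_rng, 12)
del _bc_rng


def default_barcode_map(sample_ids: Sequence[str]) -> dict[str, str]:
    """Assign the built-in well-separated 24-nt barcodes to samples."""
    if len(sample_ids) > len(DEFAULT_BARCODES):
        raise ValueError(f"only {len(DEFAULT_BARCODES)} built-in barcodes available")
    return {s: DEFAULT_BARCODES[i] for i, s in enumerate(sample_ids)}


# ---------------------------------------------------------------------------
# reference generation


def _mutate(rng: np.random.Generator, codes: np.ndarray, frac: float) -> np.ndarray:
    """Substitute a ``frac`` fraction of positions to a different base."""
    out = codes.copy()
    k = int(round(frac * len(codes)))
    if k == 0:
        return out
    pos = rng.choice(len(codes), size=k, replace=False)
    out[pos] = (out[pos] + rng.integers(1, 4, size=k)) % 4
    return out


def generate_reference_set(
    n_genera: int,
    species_per_genus: int,
    seed: int,
    length_sampler: Callable[[np.random.Generator, int], np.ndarray] | None = None,
    divergence_between: float = 0.20,
    divergence_within: float = 0.02,
) -> list[ReferenceRecord]:
    """Genus-structured synthetic ITS2 references.

    All sequences descend from one random core: each genus substitutes
    ``divergence_between`` of the core's positions, each species a
    further ``divergence_within`` of its genus consensus, and each
    species keeps a prefix of sampler-drawn length. Within-genus
    sequences are therefore closer (in Hamming fraction on the shared
    core coordinates) than between-genus ones.
    """
    if n_genera < 1 or species_per_genus < 1:
        raise ValueError("n_genera and species_per_genus must be >= 1")
    if divergence_within >= divergence_between:
        raise ValueError(
            f"divergence_within ({divergence_within}) must be < "
            f"divergence_between ({divergence_between})"
        )
    rng = np.random.default_rng(seed)
    sampler = length_sampler or default_length_sampler
    core = encode(random_dna(rng, AMPLICON_MAX))
    records = []
    for g in range(n_genera):
        genus_core = _mutate(rng, core, divergence_between)
        genus_name = f"Genus{g + 1:03d}"
        lengths = sampler(rng, species_per_genus)
        for s in range(species_per_genus):
            sp_core = _mutate(rng, genus_core, divergence_within)
            spacer_len = int(np.clip(lengths[s], AMPLICON_MIN, AMPLICON_MAX)) - PRIMER_LEN
            records.append(
                ReferenceRecord(
                    record_id=f"REF_{g + 1:03d}_{s + 1:02d}",
                    sequence=decode(sp_core[:spacer_len]),
                    species=f"{genus_name} species{s + 1:02d}",
                )
            )
    return records


def locus_for(record: ReferenceRecord) -> SimulatedLocus:
    """Primer-flanked amplicon for a reference record."""
    return SimulatedLocus(
        reference=record, amplicon=ITS2F + record.sequence + revcomp(ITS4R)
    )


def generate_sample_truths(
    genera: Sequence[str],
    n_samples: int,
    n_amplicons: int,
    seed: int,
    n_genera_per_sample: int = 15,
    n_abundant: int = 10,
    abundant_mass: float = 0.96,
) -> list[SampleTruth]:
    """Per-sample compositions: dominant genera plus a rare tail.

    Each sample draws ``n_genera_per_sample`` genera; ``n_abundant`` of
    them share ``abundant_mass`` of the reads (jittered weights, so the
    rank order differs between samples and is sensitive to sampling
    noise), the rest share the remainder. This emulates a handful of
    mass-flowering/woody taxa dominating each pollen load over a rare
    tail.
    """
    if n_genera_per_sample > len(genera):
        raise ValueError("not enough genera in the reference for the requested design")
    if not 0 < n_abundant <= n_genera_per_sample:
        raise ValueError("n_abundant must be in (0, n_genera_per_sample]")
    rng = np.random.default_rng(seed)
    truths = []
    for i in range(n_samples):
        chosen = list(rng.choice(list(genera), size=n_genera_per_sample, replace=False))
        w_ab = rng.uniform(0.5, 1.5, size=n_abundant)
        w_ab = w_ab / w_ab.sum() * abundant_mass
        n_rare = n_genera_per_sample - n_abundant
        if n_rare:
            w_ra = rng.uniform(0.5, 1.5, size=n_rare)
            w_ra = w_ra / w_ra.sum() * (1.0 - abundant_mass)
            weights = np.concatenate([w_ab, w_ra])
        else:
            weights = w_ab / w_ab.sum()
        props = {g: float(w) for g, w in zip(chosen, weights)}
        # exact renormalisation against float drift
        total = sum(props.values())
        props = {g: w / total for g, w in props.items()}
        truths.append(
            SampleTruth(
                sample_id=f"sample{i + 1:02d}",
                genus_proportions=props,
                n_amplicons=n_amplicons,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        )
    return truths


def simulate_sample(
    reference: Iterable[ReferenceRecord], truth: SampleTruth
) -> list[Molecule]:
    """Multinomial draw of amplicon molecules for one sample.

    Genus counts follow the truth proportions; the species within a
    genus is chosen uniformly. Every molecule records its provenance.
    """
    by_genus: dict[str, list[ReferenceRecord]] = {}
    for rec in reference:
        by_genus.setdefault(rec.genus, []).append(rec)
    missing = sorted(set(truth.genus_proportions) - set(by_genus))
    if missing:
        raise ValueError(f"genera absent from reference: {', '.join(missing)}")
    rng = np.random.default_rng(truth.seed)
    genera = list(truth.genus_proportions)
    props = np.array([truth.genus_proportions[g] for g in genera])
    counts = rng.multinomial(truth.n_amplicons, props)
    molecules = []
    m = 0
    for genus, count in zip(genera, counts):
        recs = by_genus[genus]
        picks = rng.integers(0, len(recs), size=count)
        for p in picks:
            rec = recs[p]
            molecules.append(
                Molecule(
                    molecule_id=f"{truth.sample_id}_m{m:06d}",
                    sample_id=truth.sample_id,
                    record_id=rec.record_id,
                    genus=rec.genus,
                    amplicon=locus_for(rec).amplicon,
                )
            )
            m += 1
    # shuffle so genus blocks are not contiguous in the library
    order = rng.permutation(len(molecules))
    return [molecules[i] for i in order]


# ---------------------------------------------------------------------------
# per-base error machinery


def _phred_mu_for_target(
    target_mean_q: float,
    sd: float,
    flank_fraction: float = 0.0,
    flank_penalty: float = 0.0,
) -> float:
    """Gaussian location whose drawn qualities give the target read-mean Q.

    Read-mean Q is the Phred of the mean error probability; drawing
    integer qualities from round(N(mu, sd)) clipped to [2, 41] biases
    the mean error probability toward the low-q tail, so mu must sit
    above the target. When a ``flank_fraction`` of bases is drawn at
    ``mu - flank_penalty`` (adapter flanks read worse), the mixture is
    what must hit the target. Solved by bisection on the discretised
    expectation.
    """
    qs = np.arange(2, 42)
    errs = np.power(10.0, -qs / 10.0)
    edges = np.concatenate([[-np.inf], qs[:-1] + 0.5, [np.inf]])

    def mean_err(mu: float) -> float:
        w = np.diff(stats.norm.cdf(edges, loc=mu, scale=sd))
        return float((w * errs).sum())

    def mean_q_of(mu: float) -> float:
        e = (1.0 - flank_fraction) * mean_err(mu) + flank_fraction * mean_err(
            mu - flank_penalty
        )
        return -10.0 * np.log10(e)

    lo, hi = 2.0, 60.0
    for _ in range(60):
        mid = (lo + hi) / 2
        if mean_q_of(mid) < target_mean_q:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _draw_quals(rng: np.random.Generator, n: int, mu: float, sd: float) -> np.ndarray:
    q = np.rint(rng.normal(mu, sd, size=n))
    return np.clip(q, 2, 41).astype(int)


def _apply_errors(
    rng: np.random.Generator, codes: np.ndarray, sub: float, ins: float, dele: float
) -> np.ndarray:
    """Substitutions, then deletions, then insertions (all per-base iid)."""
    out = codes
    if sub > 0:
        mask = rng.random(len(out)) < sub
        if mask.any():
            out = out.copy()
            idx = np.nonzero(mask)[0]
            out[idx] = (out[idx] + rng.integers(1, 4, size=len(idx))) % 4
    if dele > 0:
        keep = rng.random(len(out)) >= dele
        out = out[keep]
    if ins > 0 and len(out):
        mask = rng.random(len(out)) < ins
        pos = np.nonzero(mask)[0]
        if len(pos):
            out = np.insert(out, pos, rng.integers(0, 4, size=len(pos)).astype(np.uint8))
    return out


# ---------------------------------------------------------------------------
# platform simulators


def simulate_short_pairs(
    molecules: Sequence[Molecule],
    error: ErrorModel | None = None,
    seed: int = 0,
    read_len: int = 150,
) -> tuple[list[ReadRecord], list[ReadRecord], pd.DataFrame]:
    """2 x ``read_len`` paired-end reads off each amplicon molecule.

    R1 is the amplicon's first ``read_len`` bases, R2 the first
    ``read_len`` bases of its reverse complement (standard paired-end
    geometry); substitution errors only. Mate order is preserved
    between the two returned lists; the third element is the truth
    table.
    """
    if read_len < 1:
        raise ValueError("read_len must be >= 1")
    error = error or ErrorModel.short_paired()
    rng = np.random.default_rng(seed)
    mu = _phred_mu_for_target(error.mean_q, error.q_sd)
    r1s, r2s, truth_rows = [], [], []
    for i, mol in enumerate(molecules):
        amp = encode(mol.amplicon)
        rid = f"{mol.sample_id}_sr{i:06d}"
        for mate, codes in (("1", amp[:read_len]), ("2", encode(revcomp(mol.amplicon))[:read_len])):
            codes = _apply_errors(rng, codes, error.sub_rate, 0.0, 0.0)
            quals = _draw_quals(rng, len(codes), mu, error.q_sd)
            rec = ReadRecord(
                read_id=f"{rid}/{mate}",
                bases=decode(codes),
                quals=tuple(int(q) for q in quals),
                platform="short_paired",
            )
            (r1s if mate == "1" else r2s).append(rec)
        truth_rows.append(
            dict(
                read_id=rid,
                sample_id=mol.sample_id,
                genus=mol.genus,
                record_id=mol.record_id,
                is_concatemer=False,
            )
        )
    return r1s, r2s, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


TRUTH_COLUMNS = ["read_id", "sample_id", "genus", "record_id", "is_concatemer"]


def simulate_long_reads(
    molecules: Sequence[Molecule],
    barcode: str,
    error: ErrorModel | None = None,
    seed: int = 0,
) -> tuple[list[ReadRecord], pd.DataFrame]:
    """Long single reads: adapter+barcode flanks, sub+indel errors.

    Each library molecule is ``leader+barcode + amplicon +
    revcomp(leader+barcode)``; with probability ``concatemer_prob`` two
    library molecules are ligated into one read. Half the reads are
    emitted reverse-complemented (both strands pass the pore). Adapter
    flank bases draw lower qualities than insert bases by
    ``flank_q_penalty``. The truth table lists one row per source
    molecule, so concatemer reads contribute two rows.
    """
    error = error or ErrorModel.long_single()
    rng = np.random.default_rng(seed)
    flank5 = (error.adapter_leader or DEFAULT_ADAPTER_LEADER) + barcode
    flank_frac = 2 * len(flank5) / (2 * len(flank5) + AMPLICON_MEAN)
    mu = _phred_mu_for_target(
        error.mean_q, error.q_sd, flank_frac, error.flank_q_penalty
    )
    flank3 = revcomp(flank5)
    reads, truth_rows = [], []
    i = 0
    n = len(molecules)
    ridx = 0
    while i < n:
        concat = error.concatemer_prob > 0 and i + 1 < n and rng.random() < error.concatemer_prob
        parts = [flank5, molecules[i].amplicon, flank3]
        sources = [molecules[i]]
        flank_mask = [True, False, True]
        if concat:
            parts += [flank5, molecules[i + 1].amplicon, flank3]
            sources.append(molecules[i + 1])
            flank_mask += [True, False, True]
            i += 2
        else:
            i += 1
        read_id = f"{sources[0].sample_id}_lr{ridx:06d}"
        ridx += 1
        # per-part error application keeps the flank/insert boundary known
        # for quality assignment; error rates are identical everywhere.
        out_codes, out_flank = [], []
        for part, is_flank in zip(parts, flank_mask):
            codes = _apply_errors(
                rng, encode(part), error.sub_rate, error.ins_rate, error.del_rate
            )
            out_codes.append(codes)
            out_flank.append(np.full(len(codes), is_flank))
        codes = np.concatenate(out_codes)
        is_flank = np.concatenate(out_flank)
        quals = _draw_quals(rng, len(codes), mu, error.q_sd)
        if error.flank_q_penalty:
            quals = np.where(
                is_flank,
                np.clip(quals - int(round(error.flank_q_penalty)), 2, 41),
                quals,
            )
        bases = decode(codes)
        quals = tuple(int(q) for q in quals)
        if rng.random() < 0.5:  # strand flip
            bases = revcomp(bases)
            quals = quals[::-1]
        reads.append(
            ReadRecord(read_id=read_id, bases=bases, quals=quals, platform="long_single")
        )
        for src in sources:
            truth_rows.append(
                dict(
                    read_id=read_id,
                    sample_id=src.sample_id,
                    genus=src.genus,
                    record_id=src.record_id,
                    is_concatemer=concat,
                )
            )
    return reads, pd.DataFrame(truth_rows, columns=TRUTH_COLUMNS)


def write_truth_table(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, sep="\t", index=False)


def read_truth_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
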