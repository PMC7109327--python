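"""Alignment-based genus assignment.

The core procedure: local-align reads against the ITS2 reference
database, score every hit as alignment length x alignment identity,
keep read pairs only when both mates hit the same database entry with
at least 50 aligned columns each and identity strictly above 98%, sum
the two mates' scores, take the top-scoring reference, and collapse to
genus (many congeneric species share near-identical ITS2, so species
calls are unreliable).

Identity is BLAST-style: matched columns / alignment columns, gaps
included. Ties across genera are resolved by an explicit priority list
(the reproducible stand-in for regional expert knowledge), then
lexicographically, and are flagged so downstream reports can quantify
ambiguity.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np

from ._dna import encode, revcomp
from ._sw import sw_align_codes
from .reference_db import ReferenceDatabase

DEFAULT_MIN_LEN = 50
DEFAULT_MIN_IDENTITY = 0.98


@dataclass(frozen=True)
class Scoring:
    """Local alignment scoring scheme (gap_open is the first gap column)."""

    match: int = 1
    mismatch: int = -2
    gap_open: int = -3
    gap_extend: int = -1


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment of a read against a reference entry.

    ``length`` counts alignment columns including gap columns;
    ``identity`` = matches / length. Intervals are 0-based half-open on
    the forward strand of each sequence.
    """

    read_id: str
    ref_id: str
    score: int  # raw DP score
    length: int
    identity: float
    matches: int
    mismatches: int
    gap_columns: int
    gap_opens: int
    query_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    strand: str  # '+' or '-'

    def __post_init__(self):
        if not 0 < self.length:
            raise ValueError("alignment length must be positive")
        if not 0.0 <= self.identity <= 1.0:
            raise ValueError("identity must be in [0, 1]")


def hit_score(hit: AlignmentHit) -> float:
    """Alignment quality score: alignment length x alignment identity."""
    return hit.length * hit.identity


@dataclass(frozen=True)
class ScoredAssignment:
    """Per-read outcome of the assignment procedure."""

    read_id: str
    genus: str | None
    species: str | None
    score: float
    tied: bool
    mode: str  # 'paired' | 'single' | 'joined'

    @property
    def assigned(self) -> bool:
        return self.genus is not None


def unassigned(read_id: str, mode: str = "single") -> ScoredAssignment:
    return ScoredAssignment(read_id, None, None, 0.0, False, mode)


# ---------------------------------------------------------------------------
# alignment


def _hit_from_dp(dp: dict, read_id: str, ref_id: str, strand: str, qlen: int) -> AlignmentHit:
    qs, qe = dp["q_start"], dp["q_end"]
    if strand == "-":
        qs, qe = qlen - qe, qlen - qs  # map back to forward coordinates
    return AlignmentHit(
        read_id=read_id,
        ref_id=ref_id,
        score=dp["score"],
        length=dp["length"],
        identity=dp["matches"] / dp["length"],
        matches=dp["matches"],
        mismatches=dp["mismatches"],
        gap_columns=dp["gap_columns"],
        gap_opens=dp["gap_opens"],
        query_interval=(qs, qe),
        ref_interval=(dp["r_start"], dp["r_end"]),
        strand=strand,
    )


def local_align(
    query: str,
    reference: str,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "",
    ref_id: str = "",
    strands: str = "both",
) -> AlignmentHit | None:
    """Optimal affine-gap local alignment; both strands searched.

    Returns the higher-scoring strand's hit (forward wins score ties)
    or None when no positive-scoring alignment exists.
    """
    if not query or not reference:
        raise ValueError("query and reference must be non-empty")
    r = encode(reference)
    best = None
    strand_list = {"both": ("+", "-"), "+": ("+",), "-": ("-",)}[strands]
    for strand in strand_list:
        seq = query if strand == "+" else revcomp(query)
        dp = sw_align_codes(
            encode(seq), r, scoring.match, scoring.mismatch, scoring.gap_open, scoring.gap_extend
        )
        if dp is None:
            continue
        if best is None or dp["score"] > best[0]["score"]:
            best = (dp, strand)
    if best is None:
        return None
    return _hit_from_dp(best[0], read_id, ref_id, best[1], len(query))


def _screen_one(query: str, rc: str, ref: str) -> tuple[float, str]:
    """Normalised edit distance of a read/reference pair and best strand.

    Unit-cost semi-global alignment of the shorter sequence inside the
    longer — a cheap surrogate for alignment quality. Strand '?' means
    the two strands are too close to call and both deserve exact DP.
    """
    if len(query) <= len(ref):
        d_f = edlib.align(query, ref, mode="HW", task="distance")["editDistance"]
        d_r = edlib.align(rc, ref, mode="HW", task="distance")["editDistance"]
        norm = 1.0 / max(len(query), 1)
    else:
        d_f = edlib.align(ref, query, mode="HW", task="distance")["editDistance"]
        d_r = edlib.align(ref, rc, mode="HW", task="distance")["editDistance"]
        norm = 1.0 / max(len(ref), 1)
    if abs(d_f - d_r) <= 2:
        strand = "?"
    elif d_f < d_r:
        strand = "+"
    else:
        strand = "-"
    return min(d_f, d_r) * norm, strand


def _select_candidates(
    scored: list[tuple[float, str, str]],
    db: ReferenceDatabase,
    max_candidates: int,
    margin: float,
    per_genus: bool,
) -> list[tuple[str, str]]:
    scored.sort(key=lambda t: (t[0], t[1]))
    best = scored[0][0]
    out = []
    seen_genera = set()
    for norm, ref_id, strand in scored:
        if norm > best + margin or len(out) >= max_candidates:
            break
        if per_genus:
            genus = db[ref_id].genus
            if genus in seen_genera:
                continue
            seen_genera.add(genus)
        out.append((ref_id, strand))
    return out


def align_to_db(
    query: str,
    db: ReferenceDatabase,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "",
    max_candidates: int = 8,
    prescreen_margin: float = 0.05,
    prescreen: bool = True,
    per_genus: bool = False,
) -> list[AlignmentHit]:
    """Best local alignment of one read against each plausible reference.

    With ``prescreen=False`` every reference is aligned by exact DP
    (exhaustive); the default prescreens candidates by edit distance
    first. ``per_genus=True`` keeps only the closest reference of each
    genus — a safe acceleration for genus-level single-read assignment
    (never use it for the paired filter, whose mates must agree on one
    database entry). Only the best alignment per (read, reference) is
    kept.
    """
    if prescreen and len(db) > max_candidates:
        rc = revcomp(query)
        scored = []
        for rec in db:
            norm, strand = _screen_one(query, rc, rec.sequence)
            scored.append((norm, rec.record_id, strand))
        cands = _select_candidates(scored, db, max_candidates, prescreen_margin, per_genus)
    else:
        cands = [(rec.record_id, "?") for rec in db]
    hits = []
    for ref_id, strand in cands:
        strands = "both" if strand == "?" else strand
        hit = local_align(
            query, db[ref_id].sequence, scoring, read_id=read_id, ref_id=ref_id,
            strands=strands,
        )
        if hit is not None:
            hits.append(hit)
    return hits


def align_pair_to_db(
    r1: str,
    r2: str,
    db: ReferenceDatabase,
    scoring: Scoring = DEFAULT_SCORING,
    read_id: str = "",
    max_candidates: int = 8,
    prescreen_margin: float = 0.05,
) -> tuple[list[AlignmentHit], list[AlignmentHit]]:
    """Align both mates of a pair against one shared candidate list.

    Candidates are ranked by the summed normalised edit distance of the
    two mates, so both mates are aligned to exactly the same references
    — the form the paired concordance filter needs.
    """
    if len(db) > max_candidates:
        rc1, rc2 = revcomp(r1), revcomp(r2)
        scored = []
        for rec in db:
            n1, _ = _screen_one(r1, rc1, rec.sequence)
            n2, _ = _screen_one(r2, rc2, rec.sequence)
            scored.append(((n1 + n2) / 2.0, rec.record_id, "?"))
        cands = _select_candidates(scored, db, max_candidates, prescreen_margin, False)
    else:
        cands = [(rec.record_id, "?") for rec in db]
    hits1, hits2 = [], []
    for ref_id, _ in cands:
        for query, sink, mate in ((r1, hits1, "1"), (r2, hits2, "2")):
            hit = local_align(
                query, db[ref_id].sequence, scoring,
                read_id=f"{read_id}/{mate}" if read_id else "", ref_id=ref_id,
            )
            if hit is not None:
                sink.append(hit)
    return hits1, hits2


# ---------------------------------------------------------------------------
# filtering, scoring, assignment


def pair_filter(
    hits_r1: Iterable[AlignmentHit],
    hits_r2: Iterable[AlignmentHit],
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
) -> list[tuple[str, float]]:
    """The read-pair concordance filter.

    A reference survives only if both mates align to it with at least
    ``min_len`` columns each and identity strictly greater than
    ``min_identity``; its pair score is the sum of the two mates'
    length x identity scores. Output sorted by ref_id (order-invariant
    in the inputs).
    """

    def best_by_ref(hits):
        best: dict[str, AlignmentHit] = {}
        for h in hits:
            if h.length >= min_len and h.identity > min_identity:
                if h.ref_id not in best or hit_score(h) > hit_score(best[h.ref_id]):
                    best[h.ref_id] = h
        return best

    b1 = best_by_ref(hits_r1)
    b2 = best_by_ref(hits_r2)
    out = []
    for ref_id in sorted(set(b1) & set(b2)):
        out.append((ref_id, hit_score(b1[ref_id]) + hit_score(b2[ref_id])))
    return out


def assign_read(
    candidates: Sequence[tuple[str, float]],
    db: ReferenceDatabase,
    tiebreak_priority: Sequence[str] = (),
    read_id: str = "",
    mode: str = "paired",
) -> ScoredAssignment:
    """Top-scoring reference wins; score ties across genera resolved
    by the priority list, then lexicographically, and flagged."""
    if not candidates:
        return unassigned(read_id, mode)
    for ref_id, _ in candidates:
        if ref_id not in db:
            raise KeyError(f"candidate reference {ref_id!r} not in database")
    top = max(score for _, score in candidates)
    tied_refs = sorted(ref_id for ref_id, score in candidates if score == top)
    genera = sorted({db[r].genus for r in tied_refs})
    if len(genera) == 1:
        genus = genera[0]
    else:
        genus = next((g for g in tiebreak_priority if g in genera), genera[0])
    species = min(db[r].species for r in tied_refs if db[r].genus == genus)
    return ScoredAssignment(
        read_id=read_id,
        genus=genus,
        species=species,
        score=float(top),
        tied=len(genera) > 1,
        mode=mode,
    )


def assign_single(
    hits: Iterable[AlignmentHit],
    db: ReferenceDatabase,
    min_len: int = DEFAULT_MIN_LEN,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    tiebreak_priority: Sequence[str] = (),
    read_id: str = "",
    mode: str = "single",
) -> ScoredAssignment:
    """Single-read analogue of the paired rule: same thresholds, one hit."""
    best: dict[str, float] = {}
    for h in hits:
        if h.length >= min_len and h.identity > min_identity:
            s = hit_score(h)
            if h.ref_id not in best or s > best[h.ref_id]:
                best[h.ref_id] = s
    candidates = sorted(best.items())
    return assign_read(candidates, db, tiebreak_priority, read_id=read_id, mode=mode)


def profile_sample(
    assignments: Iterable[ScoredAssignment], sample_id: str = ""
) -> "SampleProfile":
    """Collapse per-read assignments into a genus count table."""
    counts: Counter[str] = Counter()
    n_unassigned = 0
    n_tied = 0
    for a in assignments:
        if a.assigned:
            counts[a.genus] += 1
            if a.tied:
                n_tied += 1
        else:
            n_unassigned += 1
    return SampleProfile(
        sample_id=sample_id,
        counts=dict(sorted(counts.items())),
        n_unassigned=n_unassigned,
        n_tied=n_tied,
    )


@dataclass
class SampleProfile:
    """Genus -> read-count table for one sample."""

    sample_id: str
    counts: dict[str, int]
    n_unassigned: int = 0
    n_tied: int = 0

    def __post_init__(self):
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be non-negative")

    @property
    def n_assigned(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# 12-column tabular interchange (BLAST outfmt-6 style)

TABULAR_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_tabular_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Export hits in 12-column tabular format (1-based inclusive
    coordinates; minus-strand hits have sstart > send)."""
    lines = []
    for h in hits:
        qs, qe = h.query_interval[0] + 1, h.query_interval[1]
        ss, se = h.ref_interval[0] + 1, h.ref_interval[1]
        if h.strand == "-":
            ss, se = se, ss
        lines.append(
            "\t".join(
                [
                    h.read_id, h.ref_id, f"{100.0 * h.identity:.3f}", str(h.length),
                    str(h.mismatches), str(h.gap_opens), str(qs), str(qe),
                    str(ss), str(se), "0.0", str(h.score),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_tabular_hits(path: str | Path) -> list[AlignmentHit]:
    """Import 12-column tabular hits (e.g. from an external aligner).

    Column counts not represented in the format (matches, gap columns)
    are reconstructed from pident and length; query intervals become
    0-based half-open, minus strand inferred from sstart > send.
    """
    hits = []
    for line in Path(path).read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        f = line.split("\t")
        pident, length = float(f[2]), int(f[3])
        mism, gapopen = int(f[4]), int(f[5])
        qs, qe, ss, se = int(f[6]), int(f[7]), int(f[8]), int(f[9])
        strand = "+" if ss <= se else "-"
        if strand == "-":
            ss, se = se, ss
        matches = int(round(pident / 100.0 * length))
        hits.append(
            AlignmentHit(
                read_id=f[0], ref_id=f[1], score=int(float(f[11])), length=length,
                identity=pident / 100.0, matches=matches, mismatches=mism,
                gap_columns=max(length - matches - mism, 0), gap_opens=gapopen,
                query_interval=(qs - 1, qe), ref_interval=(ss - 1, se),
                strand=strand,
            )
        )
    return hits


def write_assignments(
    assignments: Iterable[ScoredAssignment], path: str | Path
) -> None:
    lines = ["read_id\tgenus\tspecies\tscore\ttied\tmode"]
    for a in assignments:
        lines.append(
            "\t".join(
                [
                    a.read_id,
                    a.genus or "NA",
                    a.species or "NA",
                    f"{a.score:.4f}",
                    str(a.tied).lower(),
                    a.mode,
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
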