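"""Read preparation: quality stats, flank trimming, concatemer splitting,
demultiplexing and mate-pair joining.

Long amplicon reads arrive wrapped in a barcoded adapter flank at each
end, are error-prone (the printed primer flanks carried up to ~30%
single-nucleotide mismatches, which sets the default match tolerance),
and occasionally contain two ligated amplicons in one read. Short
paired-end reads are joined into full amplicons only when the amplicon
is short enough for the mates to overlap.

All motif searches are mismatch- and indel-tolerant semi-global
alignments (edlib, unit costs): the match fraction compared against
``max_mismatch_frac`` is edit distance / motif length.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import revcomp

MAX_PHRED = 93


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read: bases plus per-base Phred qualities."""

    read_id: str
    bases: str
    quals: tuple[int, ...]
    platform: str = ""

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.read_id!r}: {len(self.bases)} bases vs "
                f"{len(self.quals)} quality values"
            )
        if self.quals and not (0 <= min(self.quals) and max(self.quals) <= MAX_PHRED):
            raise ValueError(f"read {self.read_id!r}: Phred values outside [0, {MAX_PHRED}]")

    def __len__(self) -> int:
        return len(self.bases)

    def slice(self, start: int, end: int) -> "ReadRecord":
        """Sub-read over [start, end); bases and qualities in lockstep."""
        return replace(self, bases=self.bases[start:end], quals=self.quals[start:end])


def read_fastq(path: str | Path, platform: str = "") -> list[ReadRecord]:
    reads = []
    for rec in SeqIO.parse(str(path), "fastq"):
        reads.append(
            ReadRecord(
                read_id=rec.id,
                bases=str(rec.seq).upper(),
                quals=tuple(rec.letter_annotations["phred_quality"]),
                platform=platform,
            )
        )
    return reads


def write_fastq(reads: Iterable[ReadRecord], path: str | Path) -> None:
    recs = []
    for r in reads:
        rec = SeqRecord(Seq(r.bases), id=r.read_id, description="")
        rec.letter_annotations["phred_quality"] = list(r.quals)
        recs.append(rec)
    SeqIO.write(recs, str(path), "fastq")


# ---------------------------------------------------------------------------
# quality statistics


def mean_read_q(read: ReadRecord, method: str = "error_prob") -> float:
    """Mean quality of one read.

    The default is the Phred of the mean error probability,
    ``-10*log10(mean(10^(-q/10)))`` — the convention of long-read QC
    tooling, and the one under which a handful of very bad bases
    dominates. ``method="arithmetic"`` gives the plain mean of the
    Q values for comparison.
    """
    if not read.quals:
        raise ValueError(f"read {read.read_id!r} is empty; mean quality undefined")
    q = np.asarray(read.quals, dtype=float)
    if method == "arithmetic":
        return float(q.mean())
    if method != "error_prob":
        raise ValueError(f"unknown method {method!r}")
    return float(-10.0 * math.log10(np.power(10.0, -q / 10.0).mean()))


@dataclass
class ReadSetSummary:
    """Count, length and quality statistics of a read collection."""

    n_reads: int
    length_min: float
    length_median: float
    length_mean: float
    length_max: float
    mean_q_median: float
    mean_q_mean: float


def summarize_reads(reads: Sequence[ReadRecord], q_method: str = "error_prob") -> ReadSetSummary:
    if not reads:
        nan = float("nan")
        return ReadSetSummary(0, nan, nan, nan, nan, nan, nan)
    lengths = np.array([len(r) for r in reads], dtype=float)
    qs = np.array([mean_read_q(r, q_method) for r in reads if len(r)], dtype=float)
    return ReadSetSummary(
        n_reads=len(reads),
        length_min=float(lengths.min()),
        length_median=float(np.median(lengths)),
        length_mean=float(lengths.mean()),
        length_max=float(lengths.max()),
        mean_q_median=float(np.median(qs)) if qs.size else float("nan"),
        mean_q_mean=float(qs.mean()) if qs.size else float("nan"),
    )


# ---------------------------------------------------------------------------
# motif search primitives


def _best_motif_match(window: str, motifs: Sequence[str]) -> tuple[float, int, int]:
    """Best semi-global match of any motif (or its revcomp) in ``window``.

    Returns (mismatch+indel fraction, start, end) of the best match;
    fraction is inf when the window is empty.
    """
    best = (float("inf"), 0, 0)
    if not window:
        return best
    seen = set()
    for motif in motifs:
        for m in (motif, revcomp(motif)):
            if m in seen or not m:
                continue
            seen.add(m)
            res = edlib.align(m, window, mode="HW", task="locations")
            dist = res["editDistance"]
            if dist < 0:
                continue
            frac = dist / len(m)
            if frac < best[0]:
                start, end = res["locations"][0]
                best = (frac, start, end + 1)
    return best


@dataclass
class FlankTrim:
    """Where a read was cut: retained span and per-end match flags."""

    start: int
    end: int
    matched_5p: bool
    matched_3p: bool


def find_and_trim_flanks(
    read: ReadRecord,
    motifs: Sequence[str],
    max_mismatch_frac: float = 0.30,
    end_window: int = 150,
) -> tuple[ReadRecord, FlankTrim]:
    """Remove adapter/barcode/primer flanks from both read ends.

    Each end's terminal ``end_window`` bases are scanned for the best
    semi-global match of any motif or its reverse complement; if the
    match's mismatch+indel fraction is at or under ``max_mismatch_frac``
    everything up to (resp. from) the match boundary is removed.
    Unmatched ends pass through unmodified with the flag unset.
    """
    if not motifs:
        raise ValueError("motifs must be non-empty")
    if not 0 <= max_mismatch_frac < 0.5:
        raise ValueError(f"max_mismatch_frac must be in [0, 0.5), got {max_mismatch_frac}")
    n = len(read)
    start, end = 0, n
    frac5, _, m_end = _best_motif_match(read.bases[:end_window], motifs)
    matched_5p = frac5 <= max_mismatch_frac
    if matched_5p:
        start = m_end
    tail_off = max(start, n - end_window)
    frac3, m_start, _ = _best_motif_match(read.bases[tail_off:], motifs)
    matched_3p = frac3 <= max_mismatch_frac
    if matched_3p:
        end = max(start, tail_off + m_start)
    return read.slice(start, end), FlankTrim(start, end, matched_5p, matched_3p)


def split_concatemers(
    read: ReadRecord,
    adapters: Sequence[str],
    max_mismatch_frac: float = 0.30,
    min_fragment: int = 50,
) -> list[ReadRecord]:
    """Split a read at internal adapter copies (ligation concatemers).

    Repeatedly locates the best adapter match anywhere in the read,
    removes the matched span and recurses on both sides; fragments
    shorter than ``min_fragment`` are dropped. Reads without an internal
    adapter come back unchanged (as a single-element list).
    """
    frags: list[tuple[str, tuple[int, ...]]] = []

    def recurse(bases: str, quals: tuple[int, ...]) -> None:
        frac, m_start, m_end = _best_motif_match(bases, adapters)
        if frac <= max_mismatch_frac:
            recurse(bases[:m_start], quals[:m_start])
            recurse(bases[m_end:], quals[m_end:])
        elif len(bases) >= min_fragment or (len(bases) == len(read) and bases):
            frags.append((bases, quals))

    recurse(read.bases, read.quals)
    if len(frags) == 1 and frags[0][0] == read.bases:
        return [read]
    return [
        replace(read, read_id=f"{read.read_id}/{i + 1}", bases=b, quals=q)
        for i, (b, q) in enumerate(frags)
    ]


def extract_amplicon(
    read: ReadRecord,
    fwd_primer: str,
    rev_primer: str,
    max_mismatch_frac: float = 0.30,
) -> ReadRecord | None:
    """Strict amplicon extraction: keep only the span between the primers.

    Both primer sites must be found (forward primer near one end, the
    reverse primer's complement near the other, in either read
    orientation) at or under the mismatch tolerance; reads failing
    either primer are discarded (returns None). The primers themselves
    are removed, leaving the ITS2 insert.
    """
    n = len(read)
    window = min(n, 120)

    def locate(orient_fwd: bool):
        # forward orientation: fwd primer at 5', revcomp(rev primer) at 3'
        if orient_fwd:
            head_motif, tail_motif = fwd_primer, revcomp(rev_primer)
        else:
            head_motif, tail_motif = rev_primer, revcomp(fwd_primer)
        f5, _, e5 = _best_motif_match_exact(read.bases[:window], head_motif)
        off = n - window
        f3, s3, _ = _best_motif_match_exact(read.bases[off:], tail_motif)
        return f5, e5, f3, off + s3

    best = None
    for orient_fwd in (True, False):
        f5, e5, f3, s3 = locate(orient_fwd)
        if f5 <= max_mismatch_frac and f3 <= max_mismatch_frac and e5 < s3:
            score = f5 + f3
            if best is None or score < best[0]:
                best = (score, e5, s3, orient_fwd)
    if best is None:
        return None
    _, e5, s3, orient_fwd = best
    insert = read.slice(e5, s3)
    if not orient_fwd:
        insert = replace(
            insert, bases=revcomp(insert.bases), quals=insert.quals[::-1]
        )
    return insert


def _best_motif_match_exact(window: str, motif: str) -> tuple[float, int, int]:
    """Like _best_motif_match but for a single motif, no revcomp."""
    if not window or not motif:
        return (float("inf"), 0, 0)
    res = edlib.align(motif, window, mode="HW", task="locations")
    dist = res["editDistance"]
    if dist < 0:
        return (float("inf"), 0, 0)
    start, end = res["locations"][0]
    return (dist / len(motif), start, end + 1)


# ---------------------------------------------------------------------------
# demultiplexing


def validate_barcodes(barcodes: dict[str, str], max_mismatch_frac: float) -> None:
    """Barcode sets must be same-length and pairwise well separated.

    Requires pairwise Hamming distance > 2 * allowed mismatches, so a
    read within tolerance of one barcode cannot also be within
    tolerance of another.
    """
    seqs = list(barcodes.values())
    if not seqs:
        raise ValueError("no barcodes supplied")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("barcodes must all have equal length")
    allowed = int(max_mismatch_frac * length)
    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            ham = sum(a != b for a, b in zip(seqs[i], seqs[j]))
            if ham <= 2 * allowed:
                raise ValueError(
                    f"barcodes {seqs[i]} and {seqs[j]} are only {ham} apart; "
                    f"need > {2 * allowed} at tolerance {max_mismatch_frac}"
                )


def demultiplex(
    reads: Iterable[ReadRecord],
    barcode_map: dict[str, str],
    max_mismatch_frac: float = 0.25,
    end_window: int = 120,
) -> tuple[dict[str, list[ReadRecord]], list[ReadRecord]]:
    """Bin reads by best-matching barcode; ambiguous/unmatched -> unassigned.

    Each barcode (and its reverse complement, for flipped reads) is
    searched in both terminal windows; a read is assigned to the unique
    barcode with the lowest edit fraction at or under tolerance. Bins
    are disjoint and together with the unassigned list partition the
    input exactly.
    """
    validate_barcodes(barcode_map, max_mismatch_frac)
    bins: dict[str, list[ReadRecord]] = {s: [] for s in barcode_map}
    unassigned: list[ReadRecord] = []
    for read in reads:
        head = read.bases[:end_window]
        tail = read.bases[-end_window:]
        best_frac, best_samples = float("inf"), []
        for sample, bc in barcode_map.items():
            frac = min(
                _best_motif_match_exact(head, bc)[0],
                _best_motif_match_exact(head, revcomp(bc))[0],
                _best_motif_match_exact(tail, bc)[0],
                _best_motif_match_exact(tail, revcomp(bc))[0],
            )
            if frac < best_frac:
                best_frac, best_samples = frac, [sample]
            elif frac == best_frac:
                best_samples.append(sample)
        if best_frac <= max_mismatch_frac and len(best_samples) == 1:
            bins[best_samples[0]].append(read)
        else:
            unassigned.append(read)
    return bins, unassigned


# ---------------------------------------------------------------------------
# mate-pair joining


def join_pairs(
    r1: ReadRecord,
    r2: ReadRecord,
    min_overlap: int = 10,
    max_mismatch_frac: float = 0.08,
) -> ReadRecord | None:
    """Merge a mate pair into one amplicon read via 3' overlap.

    R2 is reverse-complemented; the overlap between R1's 3' end and
    reverse-complemented R2's 5' end is scanned over all lengths >=
    ``min_overlap``. The overlap with the lowest mismatch fraction
    (ties -> longest) wins if it is at or under ``max_mismatch_frac``;
    conflicting overlap bases take the higher-quality call. Returns
    None when no acceptable overlap exists — for 2x150 chemistry this
    is every amplicon longer than 300 - min_overlap nt.
    """
    if len(r1.bases) != len(r1.quals) or len(r2.bases) != len(r2.quals):
        raise ValueError("bases/quality length mismatch")
    b2 = revcomp(r2.bases)
    q2 = r2.quals[::-1]
    a1 = np.frombuffer(r1.bases.encode(), dtype=np.uint8)
    a2 = np.frombuffer(b2.encode(), dtype=np.uint8)
    max_ov = min(len(a1), len(a2))
    best = None  # (frac, overlap)
    for ov in range(min_overlap, max_ov + 1):
        mism = int((a1[len(a1) - ov:] != a2[:ov]).sum())
        frac = mism / ov
        if frac <= max_mismatch_frac and (
            best is None or frac < best[0] or (frac == best[0] and ov > best[1])
        ):
            best = (frac, ov)
    if best is None:
        return None
    ov = best[1]
    head = r1.bases[: len(a1) - ov]
    head_q = r1.quals[: len(a1) - ov]
    tail = b2[ov:]
    tail_q = q2[ov:]
    mid = []
    mid_q = []
    for k in range(ov):
        c1, c2 = r1.bases[len(a1) - ov + k], b2[k]
        p1, p2 = r1.quals[len(a1) - ov + k], q2[k]
        if c1 == c2:
            mid.append(c1)
            mid_q.append(max(p1, p2))
        elif p1 >= p2:
            mid.append(c1)
            mid_q.append(p1)
        else:
            mid.append(c2)
            mid_q.append(p2)
    return ReadRecord(
        read_id=r1.read_id,
        bases=head + "".join(mid) + tail,
        quals=tuple(head_q) + tuple(mid_q) + tuple(tail_q),
        platform=r1.platform,
    )


# ---------------------------------------------------------------------------
# pipeline-level preparation of long reads


@dataclass
class TrimReport:
    """Aggregate effect of flank trimming / concatemer splitting."""

    n_reads_in: int = 0
    n_reads_out: int = 0
    mean_len_before: float = 0.0
    mean_len_after: float = 0.0
    mean_q_before: float = 0.0
    mean_q_after: float = 0.0
    n_split_concatemers: int = 0
    n_unmatched_flanks: int = 0
    n_discarded: int = 0
    trim_coords: list[tuple[str, int, int]] = field(default_factory=list)


def prep_long_reads(
    reads: Sequence[ReadRecord],
    flank_motifs: Sequence[str],
    mode: str = "trim",
    fwd_primer: str | None = None,
    rev_primer: str | None = None,
    max_mismatch_frac: float = 0.30,
    min_fragment: int = 50,
    end_window: int = 150,
) -> tuple[list[ReadRecord], TrimReport]:
    """End-trim (and split) long reads, or strictly extract amplicons.

    ``mode="trim"`` mirrors read-end adapter trimming with default
    parameters (the least-removal baseline): flanks off, internal
    adapters split. ``mode="extract"`` additionally requires both
    primers on every fragment and keeps only the insert between them,
    discarding everything else — stricter, hence fewer surviving reads.
    """
    if mode not in ("trim", "extract"):
        raise ValueError(f"mode must be 'trim' or 'extract', got {mode!r}")
    if mode == "extract" and not (fwd_primer and rev_primer):
        raise ValueError("extract mode requires fwd_primer and rev_primer")
    report = TrimReport(n_reads_in=len(reads))
    before = summarize_reads(reads)
    out: list[ReadRecord] = []
    for read in reads:
        trimmed, info = find_and_trim_flanks(
            read, flank_motifs, max_mismatch_frac, end_window
        )
        if not (info.matched_5p or info.matched_3p):
            report.n_unmatched_flanks += 1
        report.trim_coords.append((read.read_id, info.start, info.end))
        if not trimmed.bases:
            report.n_discarded += 1
            continue
        frags = split_concatemers(
            trimmed, flank_motifs, max_mismatch_frac, min_fragment
        )
        if len(frags) > 1:
            report.n_split_concatemers += 1
        for frag in frags:
            if mode == "extract":
                frag = extract_amplicon(frag, fwd_primer, rev_primer, max_mismatch_frac)
                if frag is None or not frag.bases:
                    report.n_discarded += 1
                    continue
            if frag.bases:
                out.append(frag)
    report.n_reads_out = len(out)
    after = summarize_reads(out)
    report.mean_len_before = before.length_mean
    report.mean_len_after = after.length_mean
    report.mean_q_before = before.mean_q_mean
    report.mean_q_after = after.mean_q_mean
    return out, report
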