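"""Summary statistics: pollen richness, rank abundance, concordance,
trimming effects, and the per-variant richness table.

Pollen richness is the number of plant genera detected in a sample
(configurable minimum count, default 1 read — single-read genera
inflate richness under high error rates, so a higher threshold is
available). Concordance mirrors the cross-platform comparison: do the
ten most abundant genera agree in membership even where their order
differs?
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .align_assign import SampleProfile
from .read_prep import ReadSetSummary


def pollen_richness(profile: SampleProfile, min_count: int = 1) -> int:
    """Number of genera with at least ``min_count`` assigned reads."""
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    return sum(1 for c in profile.counts.values() if c >= min_count)


def rank_abundance(profile: SampleProfile, top_n: int = 10) -> list[str]:
    """Genera by count descending (ties lexicographic), top ``top_n``."""
    if top_n < 1:
        raise ValueError("top_n must be >= 1")
    ranked = sorted(profile.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [g for g, _ in ranked[:top_n]]


@dataclass
class ConcordanceReport:
    """Agreement of two profiles' most-abundant genera."""

    top_n: int
    set_overlap: int
    identical_membership: bool
    rank_displacements: dict[str, int | None]  # None: absent from one profile


def _full_ranks(profile: SampleProfile) -> dict[str, int]:
    return {g: i for i, g in enumerate(rank_abundance(profile, top_n=max(len(profile.counts), 1)))}


def concordance(
    profile_x: SampleProfile, profile_y: SampleProfile, top_n: int = 10
) -> ConcordanceReport:
    """Top-n membership overlap and per-genus rank displacement.

    Displacement is |rank in x - rank in y| over the union of the two
    top-n lists, using each profile's full ranking; genera missing
    entirely from one profile get displacement None.
    """
    top_x = rank_abundance(profile_x, top_n)
    top_y = rank_abundance(profile_y, top_n)
    rx, ry = _full_ranks(profile_x), _full_ranks(profile_y)
    displacements: dict[str, int | None] = {}
    for g in sorted(set(top_x) | set(top_y)):
        if g in rx and g in ry:
            displacements[g] = abs(rx[g] - ry[g])
        else:
            displacements[g] = None
    return ConcordanceReport(
        top_n=top_n,
        set_overlap=len(set(top_x) & set(top_y)),
        identical_membership=set(top_x) == set(top_y),
        rank_displacements=displacements,
    )


def trimming_effect(
    summary_before: ReadSetSummary, summary_after: ReadSetSummary
) -> tuple[float, float]:
    """Percent change in mean length and mean read-mean-Q from trimming.

    Returns (100*(after-before)/before) for both quantities; a -25%
    length change with a positive quality change is the signature of
    removing long, low-quality adapter flanks.
    """
    if not summary_before.length_mean or not summary_before.mean_q_mean:
        raise ValueError("before-summary has zero mean length or quality")
    d_len = 100.0 * (summary_after.length_mean - summary_before.length_mean) / summary_before.length_mean
    d_q = 100.0 * (summary_after.mean_q_mean - summary_before.mean_q_mean) / summary_before.mean_q_mean
    return d_len, d_q


def richness_table(
    profiles_by_variant: Mapping[str, Sequence[SampleProfile]],
    min_count: int = 1,
) -> pd.DataFrame:
    """Mean/min/max pollen richness per pipeline variant."""
    rows = []
    for variant, profiles in profiles_by_variant.items():
        if not profiles:
            raise ValueError(f"variant {variant!r} has no profiles")
        values = [pollen_richness(p, min_count) for p in profiles]
        rows.append(
            dict(
                variant=variant,
                n_samples=len(values),
                mean_richness=sum(values) / len(values),
                min_richness=min(values),
                max_richness=max(values),
            )
        )
    return pd.DataFrame(rows).set_index("variant")


# ---------------------------------------------------------------------------
# TSV I/O


def write_profile(profile: SampleProfile, path: str | Path) -> None:
    lines = ["sample_id\tgenus\tcount"]
    for genus in sorted(profile.counts):
        lines.append(f"{profile.sample_id}\t{genus}\t{profile.counts[genus]}")
    lines.append(f"{profile.sample_id}\t__unassigned__\t{profile.n_unassigned}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_profile(path: str | Path) -> SampleProfile:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "genus": str, "count": int})
    sample_id = str(df["sample_id"].iloc[0]) if len(df) else ""
    counts = {}
    n_unassigned = 0
    for _, row in df.iterrows():
        if row["genus"] == "__unassigned__":
            n_unassigned = int(row["count"])
        else:
            counts[row["genus"]] = int(row["count"])
    return SampleProfile(sample_id=sample_id, counts=counts, n_unassigned=n_unassigned)


def render_concordance(report: ConcordanceReport) -> str:
    lines = [
        f"top_n\t{report.top_n}",
        f"set_overlap\t{report.set_overlap}",
        f"identical_membership\t{str(report.identical_membership).lower()}",
        "genus\trank_displacement",
    ]
    for genus, disp in sorted(report.rank_displacements.items()):
        lines.append(f"{genus}\t{'NA' if disp is None else disp}")
    return "\n".join(lines) + "\n"
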