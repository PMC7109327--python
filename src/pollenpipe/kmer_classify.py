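"""Miniature exact-k-mer LCA classifier over the project reference database.

The second assignment paradigm: instead of alignment, each read k-mer
is looked up in an index mapping canonical k-mers to the lowest common
ancestor (LCA) of every reference taxon containing it, and the read is
classified to the leaf of the highest-weighted root-to-leaf path
through the hit taxa (ties collapse to the LCA of the tied leaves).

The taxonomy is the three-level tree (root / genus / species) induced
by the reference database itself; no external taxonomy is consulted —
this keeps the alignment-vs-k-mer comparison self-contained and
desk-scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from ._dna import revcomp
from .align_assign import SampleProfile
from .reference_db import ReferenceDatabase

ROOT = "root"
DEFAULT_K = 21


@dataclass(frozen=True)
class TaxNode:
    taxon_id: str
    name: str
    rank: str  # 'root' | 'genus' | 'species'
    parent: str | None


class TaxTree:
    """Three-level taxonomy: root -> genera -> species."""

    def __init__(self, nodes: dict[str, TaxNode]):
        self.nodes = nodes
        roots = [t for t, n in nodes.items() if n.parent is None]
        if roots != [ROOT]:
            raise ValueError(f"tree must have the single root {ROOT!r}")
        for node in nodes.values():
            if node.parent is not None and node.parent not in nodes:
                raise ValueError(f"dangling parent {node.parent!r} of {node.taxon_id!r}")

    @classmethod
    def from_reference(cls, db: ReferenceDatabase | Iterable) -> "TaxTree":
        nodes = {ROOT: TaxNode(ROOT, ROOT, "root", None)}
        for rec in db:
            gid = f"g:{rec.genus}"
            sid = f"s:{rec.species}"
            nodes.setdefault(gid, TaxNode(gid, rec.genus, "genus", ROOT))
            nodes.setdefault(sid, TaxNode(sid, rec.species, "species", gid))
        return cls(nodes)

    def __contains__(self, taxon_id: str) -> bool:
        return taxon_id in self.nodes

    def path_to_root(self, taxon_id: str) -> list[str]:
        """[taxon, ..., root]."""
        if taxon_id not in self.nodes:
            raise KeyError(f"unknown taxon {taxon_id!r}")
        path = [taxon_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def lca(self, taxon_a: str, taxon_b: str) -> str:
        """Lowest common ancestor (commutative; lca(x, x) = x)."""
        anc_a = self.path_to_root(taxon_a)
        in_a = set(anc_a)
        for t in self.path_to_root(taxon_b):
            if t in in_a:
                return t
        return ROOT

    def genus_of(self, taxon_id: str) -> str | None:
        """Genus name for a genus/species taxon, None at root."""
        for t in self.path_to_root(taxon_id):
            if self.nodes[t].rank == "genus":
                return self.nodes[t].name
        return None

    def species_leaves(self) -> list[str]:
        return sorted(t for t, n in self.nodes.items() if n.rank == "species")

    def species_taxon(self, species: str) -> str:
        return f"s:{species}"


def canonical_kmer(kmer: str) -> str:
    """Lexicographic min of a k-mer and its reverse complement."""
    rc = revcomp(kmer)
    return kmer if kmer <= rc else rc


def _kmers(seq: str, k: int):
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" not in kmer:
            yield canonical_kmer(kmer)


@dataclass
class KmerIndex:
    """Canonical k-mer -> LCA taxon id over the reference database."""

    k: int
    map: dict[str, str]

    def __len__(self) -> int:
        return len(self.map)


def build_index(db: ReferenceDatabase | Sequence, tree: TaxTree, k: int = DEFAULT_K) -> KmerIndex:
    """Index every canonical reference k-mer at the LCA of its sources."""
    if k % 2 == 0 or not 11 <= k <= 31:
        raise ValueError(f"k must be odd and in [11, 31], got {k}")
    index: dict[str, str] = {}
    for rec in db:
        taxon = tree.species_taxon(rec.species)
        if taxon not in tree:
            raise KeyError(f"reference species {rec.species!r} missing from taxonomy")
        for kmer in set(_kmers(rec.sequence, k)):
            prev = index.get(kmer)
            index[kmer] = taxon if prev is None else tree.lca(prev, taxon)
    return KmerIndex(k=k, map=index)


@dataclass
class Classification:
    """Outcome of classifying one read."""

    read_id: str
    taxon: str | None  # None = unclassified
    n_kmers: int
    n_hit: int
    too_short: bool = False

    @property
    def classified(self) -> bool:
        return self.taxon is not None


def classify_read(
    seq: str, index: KmerIndex, tree: TaxTree, read_id: str = ""
) -> tuple[Classification, dict[str, int]]:
    """Classify one read by weighted root-to-leaf path maximisation.

    Each read k-mer that hits the index adds one count at its taxon;
    each root-to-leaf path is scored by the summed counts on its nodes;
    the read is labelled with the leaf of the maximal path, or the LCA
    of tied leaves. Returns the classification and the per-taxon hit
    counts.
    """
    if len(seq) < index.k:
        return Classification(read_id, None, 0, 0, too_short=True), {}
    hits: Counter[str] = Counter()
    n_kmers = 0
    for kmer in _kmers(seq, index.k):
        n_kmers += 1
        taxon = index.map.get(kmer)
        if taxon is not None:
            hits[taxon] += 1
    if not hits:
        return Classification(read_id, None, n_kmers, 0), {}
    n_hit = sum(hits.values())
    # hits only at root tie every leaf -> collapse straight to root
    if set(hits) == {ROOT}:
        return Classification(read_id, ROOT, n_kmers, n_hit), dict(hits)
    leaves = set()
    for taxon in hits:
        node = tree.nodes[taxon]
        if node.rank == "species":
            leaves.add(taxon)
        elif node.rank == "genus":
            leaves.update(
                t for t, n in tree.nodes.items()
                if n.rank == "species" and n.parent == taxon
            )
    best_score = -1
    best_leaves: list[str] = []
    for leaf in sorted(leaves):
        score = sum(hits.get(t, 0) for t in tree.path_to_root(leaf))
        if score > best_score:
            best_score, best_leaves = score, [leaf]
        elif score == best_score:
            best_leaves.append(leaf)
    label = best_leaves[0]
    for other in best_leaves[1:]:
        label = tree.lca(label, other)
    return Classification(read_id, label, n_kmers, n_hit), dict(hits)


def classify_reads(
    reads, index: KmerIndex, tree: TaxTree
) -> list[Classification]:
    """Classify a read collection (ReadRecord or (id, seq) pairs)."""
    out = []
    for read in reads:
        rid, seq = (read.read_id, read.bases) if hasattr(read, "bases") else read
        out.append(classify_read(seq, index, tree, read_id=rid)[0])
    return out


def kmer_profile(
    classifications: Iterable[Classification], tree: TaxTree, sample_id: str = ""
) -> SampleProfile:
    """Genus-level profile of k-mer classifications.

    Reads classified at root (genus-indeterminate) count as unassigned
    in the genus profile, as do unclassified reads.
    """
    counts: Counter[str] = Counter()
    n_unassigned = 0
    for c in classifications:
        genus = tree.genus_of(c.taxon) if c.classified else None
        if genus is None:
            n_unassigned += 1
        else:
            counts[genus] += 1
    return SampleProfile(
        sample_id=sample_id, counts=dict(sorted(counts.items())), n_unassigned=n_unassigned
    )


# ---------------------------------------------------------------------------
# paradigm comparison


@dataclass
class ParadigmComparison:
    """Alignment-based vs k-mer-based profile divergence for one sample."""

    genera_alignment: set[str]
    genera_kmer: set[str]
    jaccard_top: float
    top_n: int
    count_ratios: dict[str, float]  # kmer count / alignment count, shared genera
    genus_count_ratio: float  # |kmer genera| / |alignment genera|


def compare_paradigms(
    alignment_profile: SampleProfile,
    kmer_prof: SampleProfile,
    top_n: int = 10,
) -> ParadigmComparison:
    """Quantify how the two assignment paradigms diverge on one sample."""
    from .report import rank_abundance

    ga = set(alignment_profile.counts)
    gk = set(kmer_prof.counts)
    top_a = set(rank_abundance(alignment_profile, top_n))
    top_k = set(rank_abundance(kmer_prof, top_n))
    union = top_a | top_k
    jac = len(top_a & top_k) / len(union) if union else 1.0
    ratios = {
        g: kmer_prof.counts[g] / alignment_profile.counts[g]
        for g in sorted(ga & gk)
        if alignment_profile.counts[g] > 0
    }
    return ParadigmComparison(
        genera_alignment=ga,
        genera_kmer=gk,
        jaccard_top=jac,
        top_n=top_n,
        count_ratios=ratios,
        genus_count_ratio=(len(gk) / len(ga)) if ga else float("nan"),
    )


# ---------------------------------------------------------------------------
# serialization


def write_index(index: KmerIndex, path: str | Path) -> None:
    """Sorted TSV dump: header line with k, then kmer<TAB>taxon."""
    lines = [f"#k\t{index.k}"]
    for kmer in sorted(index.map):
        lines.append(f"{kmer}\t{index.map[kmer]}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_index(path: str | Path) -> KmerIndex:
    lines = Path(path).read_text().splitlines()
    if not lines or not lines[0].startswith("#k\t"):
        raise ValueError(f"{path}: missing '#k' header line")
    k = int(lines[0].split("\t")[1])
    mapping = {}
    for line in lines[1:]:
        if line:
            kmer, taxon = line.split("\t")
            mapping[kmer] = taxon
    return KmerIndex(k=k, map=mapping)


def write_classifications(
    classifications: Iterable[Classification], path: str | Path
) -> None:
    lines = ["read_id\tstatus\ttaxon\tn_kmers\tn_hit"]
    for c in classifications:
        status = "U" if not c.classified else "C"
        lines.append(
            f"{c.read_id}\t{status}\t{c.taxon or 'NA'}\t{c.n_kmers}\t{c.n_hit}"
        )
    Path(path).write_text("\n".join(lines) + "\n")
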