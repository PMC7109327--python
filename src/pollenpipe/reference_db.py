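"""ITS2 reference database: records, taxon filtering, dereplication, FASTA I/O.

The searchable unit is a :class:`ReferenceRecord` — one ITS2 sequence
carrying a binomial species label, of which the genus is the first
whitespace-delimited token. Databases are built from a global ITS2 set,
restricted to a regional allowlist of taxa, and made non-redundant by
collapsing *exactly identical* sequences (no similarity clustering).

FASTA dialect: ``>record_id|Genus species`` (pipe-delimited). A reader
hook for plain ``>record_id Genus species`` headers is available via
``header_style="space"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._dna import DNA_ALPHABET


class ReferenceFormatError(ValueError):
    """Malformed reference FASTA (bad header or non-IUPAC characters)."""


@dataclass(frozen=True)
class ReferenceRecord:
    """One reference ITS2 sequence with its taxonomic labels.

    ``also_species`` holds additional species labels merged onto this
    representative during dereplication with ``label_policy="merge"``.
    """

    record_id: str
    sequence: str
    species: str
    also_species: tuple[str, ...] = ()

    def __post_init__(self):
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError(f"record {self.record_id!r}: empty sequence")
        bad = set(seq) - set(DNA_ALPHABET)
        if bad:
            raise ValueError(
                f"record {self.record_id!r}: non-IUPAC characters {sorted(bad)}"
            )
        if not self.species.strip():
            raise ValueError(f"record {self.record_id!r}: empty species label")

    @property
    def genus(self) -> str:
        """First whitespace token of the species binomial.

        Hybrid markers ("x Genus ...") are kept verbatim: the first
        token is whatever the label starts with.
        """
        return self.species.split()[0]


@dataclass
class ReferenceDatabase:
    """An ordered collection of unique-id reference records.

    ``derep`` records whether :func:`dereplicate` has been applied, i.e.
    whether sequences are guaranteed pairwise distinct.
    """

    records: list[ReferenceRecord]
    derep: bool = False
    genus_index: dict[str, list[str]] = field(init=False)
    _by_id: dict[str, ReferenceRecord] = field(init=False, repr=False)

    def __post_init__(self):
        self._by_id = {}
        self.genus_index = {}
        for rec in self.records:
            if rec.record_id in self._by_id:
                raise ValueError(f"duplicate record_id {rec.record_id!r}")
            self._by_id[rec.record_id] = rec
            self.genus_index.setdefault(rec.genus, []).append(rec.record_id)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, record_id: str) -> ReferenceRecord:
        return self._by_id[record_id]

    def __contains__(self, record_id: str) -> bool:
        return record_id in self._by_id

    @property
    def genera(self) -> list[str]:
        return sorted(self.genus_index)


def filter_by_taxa(
    records: Iterable[ReferenceRecord],
    allowlist: Iterable[str],
    level: str = "genus",
) -> list[ReferenceRecord]:
    """Keep records whose genus (or full species name) is in the allowlist.

    Emulates restricting a global ITS2 set to the taxa known from one
    region. Input order is preserved; the input is not modified.
    """
    if level not in ("genus", "species"):
        raise ValueError(f"level must be 'genus' or 'species', got {level!r}")
    allowed = set(allowlist)
    if level == "genus":
        return [r for r in records if r.genus in allowed]
    return [r for r in records if r.species in allowed]


def dereplicate(
    records: Sequence[ReferenceRecord], label_policy: str = "first"
) -> list[ReferenceRecord]:
    """Collapse records with exactly identical sequences (case-insensitive).

    One representative per distinct sequence string, in order of first
    appearance. ``label_policy="first"`` keeps the earliest record's
    labels; ``"merge"`` additionally annotates the representative with
    every other distinct species label in the cluster.
    """
    if label_policy not in ("first", "merge"):
        raise ValueError(f"label_policy must be 'first' or 'merge', got {label_policy!r}")
    reps: dict[str, ReferenceRecord] = {}
    extra: dict[str, list[str]] = {}
    for rec in records:
        key = rec.sequence  # already uppercased on construction
        if key not in reps:
            reps[key] = rec
            extra[key] = []
        elif label_policy == "merge":
            rep = reps[key]
            if rec.species != rep.species and rec.species not in extra[key]:
                extra[key].append(rec.species)
    out = []
    for key, rec in reps.items():
        if extra[key]:
            rec = replace(rec, also_species=rec.also_species + tuple(extra[key]))
        out.append(rec)
    return out


def read_taxon_list(path: str | Path) -> set[str]:
    """Read an allowlist: one taxon name per line, '#' comments allowed."""
    names = set()
    for line in Path(path).read_text().splitlines():
        name = line.split("#", 1)[0].strip()
        if name:
            names.add(name)
    return names


def read_reference_fasta(
    path: str | Path, header_style: str = "pipe"
) -> list[ReferenceRecord]:
    """Parse a reference FASTA into records.

    ``header_style="pipe"`` expects ``>record_id|Genus species``;
    ``"space"`` expects ``>record_id Genus species``. Wrapped and
    unwrapped sequence lines are both accepted (standard FASTA).
    """
    if header_style not in ("pipe", "space"):
        raise ValueError(f"header_style must be 'pipe' or 'space', got {header_style!r}")
    records = []
    for idx, rec in enumerate(SeqIO.parse(str(path), "fasta"), start=1):
        header = rec.description
        if header_style == "pipe":
            if "|" not in header:
                raise ReferenceFormatError(
                    f"{path}: record {idx} header {header!r} has no '|' separator"
                )
            record_id, species = header.split("|", 1)
        else:
            parts = header.split(None, 1)
            if len(parts) != 2:
                raise ReferenceFormatError(
                    f"{path}: record {idx} header {header!r} has no species field"
                )
            record_id, species = parts
        species = species.strip()
        if not species:
            raise ReferenceFormatError(
                f"{path}: record {idx} header {header!r} has an empty species field"
            )
        try:
            records.append(
                ReferenceRecord(record_id=record_id.strip(), sequence=str(rec.seq), species=species)
            )
        except ValueError as exc:
            raise ReferenceFormatError(f"{path}: record {idx}: {exc}") from exc
    return records


def write_reference_fasta(
    records: Iterable[ReferenceRecord], path: str | Path
) -> None:
    """Write records in the ``>record_id|Genus species`` dialect."""
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=f"{r.record_id}|{r.species}", description="")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_manifest(db: ReferenceDatabase, path: str | Path) -> None:
    """Small key-value metadata file: derep flag and counts."""
    lines = [
        f"n_records\t{len(db)}",
        f"n_genera\t{len(db.genus_index)}",
        f"derep\t{str(db.derep).lower()}",
    ]
    Path(path).write_text("\n".join(lines) + "\n")
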