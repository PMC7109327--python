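"""Build a regional, dereplicated ITS2 reference database.

Generates a small synthetic global ITS2 set, restricts it to an
allowlist of regional genera, collapses identical sequences, and
round-trips it through FASTA.
"""

from pollenpipe import (
    ReferenceDatabase,
    dereplicate,
    filter_by_taxa,
    generate_reference_set,
)

# a "global" set: 12 genera x 3 species of genus-structured ITS2 spacers
global_set = generate_reference_set(n_genera=12, species_per_genus=3, seed=42)
print(f"global set: {len(global_set)} records, "
      f"{len({r.genus for r in global_set})} genera")

# restrict to the genera known from the study region
regional_allowlist = {"Genus001", "Genus004", "Genus007", "Genus010"}
regional = filter_by_taxa(global_set, regional_allowlist, level="genus")
print(f"regional subset: {len(regional)} records")

# collapse exactly identical sequences (none here, but real ITS2 sets
# carry many duplicates across congeneric species)
unique = dereplicate(regional, label_policy="merge")
db = ReferenceDatabase(unique, derep=True)
print(f"dereplicated database: {len(db)} records, genera: {db.genera}")
# the genus index maps each genus to its record ids
print("records of Genus004:", db.genus_index["Genus004"])
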