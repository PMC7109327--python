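# pollenpipe

**ITS2 pollen metabarcoding at desk scale: reference databases, read
simulation, alignment- and k-mer-based genus assignment, and richness
reporting.**

Pollinator diets can be read from the pollen they carry: PCR-amplify
the ITS2 nuclear ribosomal spacer from mixed-pollen DNA, sequence the
amplicons, and assign each read to a plant genus against a regional
ITS2 reference database. Short polymerase reads (2 × 150 nt, ~Q30)
rarely span a full amplicon (~354 nt on average, some > 600 nt), while
long nanopore-style single reads cover it whole but at ~Q8.5 with
indels — so the two platforms need different read preparation and
different assignment tolerances, and a natural question is whether they
recover the same genus profile. `pollenpipe` implements the whole
comparison as a reusable, fully tested Python library with a thin CLI,
including a ground-truthed simulator for both platforms so every claim
is checkable without external data.

## The core procedure

For each read (or read pair) aligned locally against reference entries
$r$ with alignment length $L$ (columns, gaps included) and identity
$I = \text{matches}/L$:

* alignment quality score $S = L \times I$;
* a **pair** survives only if both mates hit the *same* entry with
  $L \ge 50$ and $I > 0.98$, scoring $S_1 + S_2$;
* the top-scoring entry wins; exact cross-genus ties resolve by an
  explicit priority list (flagged `tied`), and counts collapse from
  species to genus;
* **pollen richness** of a sample = number of genera with ≥ 1 assigned
  read.

A second, alignment-free arm classifies reads by exact canonical
k-mer matches (k = 21) against an LCA-labelled index of the same
reference, scoring root-to-leaf taxonomy paths — the two paradigms can
then be compared profile against profile.

## A worked example

```python
from pollenpipe import (ReferenceDatabase, generate_reference_set,
                        SampleTruth, simulate_sample, simulate_long_reads,
                        prep_long_reads, align_to_db, assign_single,
                        profile_sample, pollen_richness)
from pollenpipe.synthetic_data import (DEFAULT_ADAPTER_LEADER, DEFAULT_BARCODES,
                                       ErrorModel)

records = generate_reference_set(n_genera=8, species_per_genus=3, seed=21)
db = ReferenceDatabase(records, derep=True)
truth = SampleTruth("demo", {"Genus003": 1.0}, n_amplicons=200, seed=4)
mols = simulate_sample(records, truth)
noisy = ErrorModel.long_single(sub_rate=0.03, ins_rate=0.03, del_rate=0.03)
reads, _ = simulate_long_reads(mols, DEFAULT_BARCODES[0], error=noisy, seed=6)
prepped, _ = prep_long_reads(reads, [DEFAULT_ADAPTER_LEADER + DEFAULT_BARCODES[0]])
assignments = [assign_single(align_to_db(r.bases, db, per_genus=True), db,
                             min_identity=0.80, read_id=r.read_id)
               for r in prepped]
prof = profile_sample(assignments, "demo")
print(prof.counts, "richness:", pollen_richness(prof))
```

prints

```
{'Genus003': 200} richness: 1
```

— all 200 noisy long reads (3% substitutions, insertions and deletions
each) trimmed, aligned and assigned back to their true genus; richness
1 because the sample contained one genus. The scripts in `examples/`
walk through every capability the same way (database construction,
platform simulation, demultiplexing/trimming/joining, the paired rule,
the k-mer comparison, and the end-to-end pipeline); each prints the
numbers it computes and what they mean.

## Command line

```bash
pollenpipe simulate --out-dir sim --n-samples 2 --seed 3     # ground-truthed data
pollenpipe makedb --fasta global.fasta --allowlist taxa.txt --out regional.fasta
pollenpipe prep trim --reads raw.fastq --motif <adapter> --out trimmed.fastq
pollenpipe prep join --r1 R1.fastq --r2 R2.fastq --out joined.fastq
pollenpipe assign --reads trimmed.fastq --reference regional.fasta --out calls.tsv
pollenpipe classify --reads trimmed.fastq --reference regional.fasta --out kmer.tsv
pollenpipe run --config pipeline.yaml                        # full variant run
```

Reference FASTA headers follow `>record_id|Genus species`. Exit codes:
0 ok, 2 configuration error, 3 input error, 4 internal error.

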