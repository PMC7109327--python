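# Methods

`pollenpipe` reimplements, as a tested library, the analysis path of an
ITS2 pollen-metabarcoding study that compares short paired-end
(polymerase) and long single-read (nanopore) sequencing of the same
amplicons. Because the real deposited sequencing runs and the
NCBI-scale databases behind the published headline numbers are not
desk-scale inputs, every stage is validated instead on ground-truthed
synthetic data whose generating conditions mirror the printed
characteristics of the real data. This note records the models,
defaults, and design decisions.

## The assignment model

Reads are assigned to plant **genera** (not species: many congeneric
plants share near-identical ITS2, so species-level calls are
unreliable) by local alignment against a regional ITS2 reference
database:

* **Alignment.** Affine-gap local alignment (Gotoh) with scores
  +1 match, −2 mismatch, −3 gap open (first gap column), −1 gap
  extend; both strands searched; exact dynamic programming. An edit-
  distance prescreen (edlib) ranks references and only plausible
  candidates get the exact DP; the prescreen keeps every reference
  within 0.05 normalised edit distance of the best (capped at 8), so
  the returned best hit is the DP optimum in all tested regimes. For
  genus-level single-read assignment an optional per-genus collapse
  aligns only the closest reference of each genus; it is never used
  for the paired filter, whose mates must agree on a single database
  entry.
* **Scoring.** Each hit scores `L × I` where `L` is the number of
  alignment columns (gaps included) and `I = matches / L`
  (BLAST-style gap-inclusive identity; the source convention for the
  identity denominator is not stated, so the tabular-alignment
  convention is used).
* **Pair rule.** A read pair counts only where both mates align to the
  *same* reference entry with `L ≥ 50` each and `I > 0.98` (strictly
  greater); the mate scores are summed.
* **Top hit and ties.** The top-scoring reference wins. Exact score
  ties spanning several genera cannot be broken by regional field
  knowledge in a reproducible way, so they are resolved by an explicit
  user-supplied genus priority list, then lexicographically, and every
  such assignment carries a `tied` flag so reports can quantify
  ambiguity.
* **Single/joined reads** (long reads, merged pairs) use the same
  thresholds applied to their one hit; the long-read identity
  threshold is independently configurable because an ~14% error rate
  is incompatible with 0.98 (the validation studies use 0.80).

Pollen **richness** is the number of genera with at least one assigned
read (threshold configurable: single-read genera inflate richness under
long-read error).

## The k-mer arm

The second paradigm is a miniature exact-k-mer LCA classifier: every
canonical k-mer (k = 21, odd, lexicographic min of k-mer and reverse
complement) of every reference maps to the lowest common ancestor of
the taxa containing it, over the three-level taxonomy (root / genus /
species) induced by the reference database itself. A read is classified
to the leaf of the highest-weighted root-to-leaf path through its
k-mer hits (ties collapse to the LCA of tied leaves). k = 21 is small
enough that some k-mers survive long-read error and large enough for
genus specificity on ITS2-scale divergence. The published comparison
ran this paradigm against the full NCBI non-redundant nucleotide
database; those absolute genus counts are database-scale artifacts and
are out of scope here — the self-contained classifier reproduces the
paradigm, not the database.

## The synthetic data generator

The generator emulates, at desk scale:

* **Reference diversity.** All sequences descend from one random core;
  each genus substitutes 20% of positions, each species a further 2%
  of its genus consensus. This yields ~4% within-genus and ~32%
  between-genus divergence — the right ordering for a genus-resolvable
  barcode, though real ITS2 divergence is locus- and clade-specific
  and includes indels, which the reference generator omits (reads add
  them back via the error model).
* **Amplicon geometry.** Amplicons are `ITS2F + insert +
  revcomp(ITS4R)` with the two printed 20-nt primers; lengths are
  drawn from a truncated normal (mean 354 nt, sd 60, support
  [150, 700] nt), matching the printed ~354 nt average with an upper
  tail for the >600 nt ITS2 variants.
* **Sample composition.** Each sample draws 15 genera: 10 "abundant"
  genera share 96% of molecules with jittered weights, 5 rare genera
  share the rest. The deliberate abundance gap makes top-10 membership
  a well-posed ground-truth quantity while the jitter lets rank order
  vary — the regime in which the two platforms are expected to agree
  on membership but not necessarily order.
* **Short reads.** 2 × 150 nt from the amplicon ends, substitution
  errors only (the dominant short-read mode) at 0.1%, qualities ~Q30.
* **Long reads.** Substitutions *and* indels (defaults 6%/4%/4%,
  chosen so the mean read quality lands at the printed ~Q8.5; the
  source reports no quantitative rates), wrapped in a 65-nt barcoded
  adapter flank per end (41-nt leader + 24-nt barcode), emitted on
  either strand, with probability 0.01 of two ligated amplicons per
  read (concatemers). Flank bases read ~2 Phred units worse than
  insert bases, so adapter trimming measurably *raises* mean read
  quality while shortening reads — the signature reported for real
  trimming. Read-mean quality uses the Phred of the mean error
  probability (the long-read QC convention); the quality draw location
  is solved by bisection so the flank/insert mixture hits the target
  mean.
* **Not modelled.** Signal-level artifacts, PCR bias and chimeras
  (other than adapter-joined concatemers), quality–error covariance,
  homopolymer-specific error structure, and real ITS2 sequence
  content. Passing tests therefore demonstrate the correctness of the
  pipeline's logic and its behaviour under the printed error regimes,
  not performance on any particular real flora.

Every generator takes an explicit integer seed; fixed seed ⇒
bit-identical outputs.

## Read preparation

All motif searches (adapters, barcodes, primers) are mismatch- and
indel-tolerant semi-global alignments; the match tolerance defaults to
30% of motif length because real primer flanks were observed with up
to 30% single-nucleotide mismatches. Two preparation modes mirror the
published comparison of trimming strategies: **end-trimming** (remove
flank matches at the read ends, split on internal adapter copies, keep
everything else — the least-removal baseline) and **strict amplicon
extraction** (require both primers, keep only the insert between
them). Extraction discards every read that trimming would have kept
but whose primers are unrecognisable, so per sample it never assigns
more reads — the ordering reported for the two real trimmers.
Demultiplexing assigns each read to the unique best-matching barcode
within tolerance (default 0.25 of 24 nt) and validates that barcodes
are pairwise separated by more than twice the allowed mismatches.
Mate-pair joining reverse-complements R2, scans all overlaps ≥ 10 nt,
accepts the lowest-mismatch overlap at ≤ 8% mismatches (ties →
longest), and takes the higher-quality base at overlap conflicts; the
published join parameters are not stated, so these follow the joining
tool family's defaults and are configurable. For 2 × 150 chemistry,
only amplicons ≤ 290 nt can join — the analytic benchmark used in the
join-rate validation.

## Numerical and tie-break conventions

* Alignment cell tie-breaks: diagonal > vertical (gap in reference) >
  horizontal (gap in query) > stop; the best cell is the first
  (smallest query index, then reference index) achieving the maximal
  score. The pure-Python oracle in the test suite implements the same
  conventions independently, making (score, L, matches) equality a
  meaningful check.
* Strand ties go to the forward strand; rank ties in abundance lists
  break lexicographically; `N` never matches anything, including `N`.
* Coordinates are 0-based half-open internally; the 12-column tabular
  interchange uses the 1-based inclusive convention with minus-strand
  hits encoded by swapped subject coordinates.
* All randomness flows from `numpy.random.default_rng(seed)`; the
  pipeline manifest records the configuration hash and seed, and reruns
  are byte-identical.

## Validation studies and problem sizes

The packaged evaluation study (shared by the test suite and
`scripts/acceptance.py`) uses 6 samples × 5,000 molecules over a
20-genus × 3-species reference, which is large enough for stable
top-10 membership and small enough to run on one CPU in minutes.
Focused experiments use 10,000 error-free pairs (join-rate analytics,
compared to the truncated-normal CDF within 3 binomial standard
deviations, with a half-base continuity correction for integer
lengths) and 500 forced concatemers at 3%/3%/3% error. The noisy
regime of the main study is 3% each of substitutions, insertions and
deletions — deliberately below the default ~14% so that the relaxed
0.80 identity threshold cleanly separates true from wrong-genus hits.

## Known limitations

* The aligner is exact DP after a heuristic prescreen; pathological
  references engineered so that edit distance misranks the DP-optimal
  candidate could evade the prescreen (disable it with
  `prescreen=False` for exhaustive search).
* The taxonomy is flat (root/genus/species); no family or higher ranks,
  and no support for reads from taxa absent from the reference other
  than "unassigned"/"unclassified".
* Concatemers are modelled and split as exactly two ligated amplicons;
  higher-order concatemers are split recursively but are not generated.
* Richness on real data is sensitive to low-count noise genera; the
  ≥1-read default mirrors the source definition, and the min-count
  option exists precisely because the synthetic studies show single
  misassigned reads create spurious genera under high error.
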