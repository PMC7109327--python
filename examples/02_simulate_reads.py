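"""Simulate both sequencing platforms for one ground-truthed sample.

Draws 500 amplicon molecules from a known genus composition, then
sequences them as 2x150 ~Q30 paired-end reads and as ~Q8.5 long single
reads with indels, adapter/barcode flanks and occasional concatemers.
"""

from pollenpipe import (
    SampleTruth,
    generate_reference_set,
    simulate_long_reads,
    simulate_sample,
    simulate_short_pairs,
    summarize_reads,
)
from pollenpipe.synthetic_data import DEFAULT_BARCODES

records = generate_reference_set(n_genera=5, species_per_genus=2, seed=7)
truth = SampleTruth(
    sample_id="demo",
    genus_proportions={"Genus001": 0.6, "Genus002": 0.3, "Genus003": 0.1},
    n_amplicons=500,
    seed=11,
)
molecules = simulate_sample(records, truth)
print(f"{len(molecules)} molecules; first molecule's genus: {molecules[0].genus}")

r1, r2, short_truth = simulate_short_pairs(molecules, seed=12)
s = summarize_reads(r1)
print(f"short R1: n={s.n_reads} len={s.length_mean:.0f} "
      f"median mean-Q={s.mean_q_median:.1f}  (fixed 150 nt, ~Q30)")

long_reads, long_truth = simulate_long_reads(molecules, DEFAULT_BARCODES[0], seed=13)
s = summarize_reads(long_reads)
print(f"long reads: n={s.n_reads} mean len={s.length_mean:.0f} "
      f"median mean-Q={s.mean_q_median:.1f}  (amplicon + 2x65 nt flanks, ~Q8.5)")
print(f"concatemer reads in truth table: {int(long_truth.is_concatemer.sum()) // 2}")
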