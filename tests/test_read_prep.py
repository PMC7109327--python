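"""Read preparation: quality stats, trimming, splitting, demux, joining."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pollenpipe._dna import revcomp
from pollenpipe.read_prep import (
    ReadRecord,
    demultiplex,
    extract_amplicon,
    find_and_trim_flanks,
    join_pairs,
    mean_read_q,
    prep_long_reads,
    read_fastq,
    split_concatemers,
    summarize_reads,
    validate_barcodes,
    write_fastq,
)
from pollenpipe.synthetic_data import (
    DEFAULT_ADAPTER_LEADER,
    DEFAULT_BARCODES,
    ErrorModel,
    SampleTruth,
    default_barcode_map,
    generate_reference_set,
    generate_sample_truths,
    simulate_long_reads,
    simulate_sample,
)


def read_of(bases, q=30, read_id="r"):
    quals = (q,) * len(bases) if isinstance(q, int) else tuple(q)
    return ReadRecord(read_id=read_id, bases=bases, quals=quals)


class TestReadRecord:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="quality"):
            ReadRecord("r", "ACGT", (30, 30))

    def test_phred_range_enforced(self):
        with pytest.raises(ValueError, match="Phred"):
            ReadRecord("r", "AC", (30, 94))

    def test_fastq_round_trip(self, tmp_path):
        reads = [read_of("ACGTACGT", q=[2, 10, 20, 30, 40, 41, 5, 7], read_id="a")]
        write_fastq(reads, tmp_path / "x.fastq")
        assert read_fastq(tmp_path / "x.fastq") == reads


class TestMeanReadQ:
    def test_constant_quality_is_identity(self):
        assert mean_read_q(read_of("ACGT", 20)) == pytest.approx(20.0)
        assert mean_read_q(read_of("AC", 10)) == pytest.approx(10.0)

    def test_matches_direct_formula(self):
        # Phred of the mean error probability, worked by hand
        expected = -10 * math.log10((0.1 + 0.01 + 0.001) / 3)
        got = mean_read_q(read_of("ACG", [10, 20, 30]))
        assert got == pytest.approx(expected)
        assert got == pytest.approx(14.31, abs=0.01)

    def test_arithmetic_variant_differs(self):
        r = read_of("ACG", [10, 20, 30])
        assert mean_read_q(r, method="arithmetic") == pytest.approx(20.0)
        assert mean_read_q(r) < 20.0  # error-prob mean is dominated by bad bases

    def test_empty_read_raises(self):
        with pytest.raises(ValueError, match="empty"):
            mean_read_q(ReadRecord("r", "", ()))


MOTIF = "ATGCGATACTTGGTGTGAAT"


class TestFindAndTrimFlanks:
    def test_exact_flank_removed(self):
        insert = "CCCTTTGGGAAACCCTTTGGGAAATTTCCCGGGAAATTTCCCGGG"
        r = read_of(MOTIF + insert)
        out, info = find_and_trim_flanks(r, [MOTIF])
        assert out.bases == insert
        assert info.matched_5p and not info.matched_3p

    def test_noisy_flank_within_tolerance_removed(self, rng):
        insert = "".join(rng.choice(list("ACGT"), 80))
        noisy = list(MOTIF)
        for pos in rng.choice(len(MOTIF), size=5, replace=False):  # 25% subs
            noisy[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[noisy[pos]]
        noisy = "".join(noisy)
        r = read_of(noisy + insert)
        out, info = find_and_trim_flanks(r, [MOTIF], max_mismatch_frac=0.30)
        assert info.matched_5p
        # exhaustive sliding edit-distance scan confirms a <=30% match exists
        assert oracles.best_infix_edit(MOTIF, noisy) <= 6
        assert out.bases == insert or len(out.bases) <= len(insert) + 2

    def test_no_motif_passes_through_flagged(self, rng):
        bases = "".join(rng.choice(list("ACGT"), 100))
        r = read_of(bases)
        out, info = find_and_trim_flanks(r, ["GGGGGGGGGGGGGGGGGGGG"], max_mismatch_frac=0.1)
        assert out.bases == bases
        assert not info.matched_5p and not info.matched_3p

    def test_never_increases_length_and_keeps_substring(self, rng):
        for _ in range(20):
            bases = "".join(rng.choice(list("ACGT"), rng.integers(30, 200)))
            r = read_of(bases)
            out, _ = find_and_trim_flanks(r, [MOTIF])
            assert len(out) <= len(r)
            assert out.bases in bases  # only removal, never new bases

    def test_trimming_bad_flank_raises_mean_q(self):
        r = ReadRecord("r", MOTIF + "A" * 50, (3,) * 20 + (35,) * 50)
        out, _ = find_and_trim_flanks(r, [MOTIF])
        assert mean_read_q(out) > mean_read_q(r)


class TestSplitConcatemers:
    ADAPTER = DEFAULT_ADAPTER_LEADER + DEFAULT_BARCODES[0]

    def test_exact_internal_adapter_splits(self, rng):
        a = "".join(rng.choice(list("ACGT"), 120))
        b = "".join(rng.choice(list("ACGT"), 90))
        r = read_of(a + self.ADAPTER + b)
        frags = split_concatemers(r, [self.ADAPTER])
        assert [f.bases for f in frags] == [a, b]
        assert [f.read_id for f in frags] == ["r/1", "r/2"]

    def test_no_internal_adapter_identity(self, rng):
        bases = "".join(rng.choice(list("ACGT"), 150))
        r = read_of(bases)
        assert split_concatemers(r, [self.ADAPTER]) == [r]

    def test_short_fragments_dropped(self, rng):
        a = "ACGTACGT"  # below min_fragment
        b = "".join(rng.choice(list("ACGT"), 100))
        r = read_of(a + self.ADAPTER + b)
        frags = split_concatemers(r, [self.ADAPTER], min_fragment=50)
        assert [f.bases for f in frags] == [b]

    def test_simulated_concatemers_split_to_truth(self, small_records):
        truth = SampleTruth("s", {small_records[0].genus: 1.0}, 200, seed=30)
        mols = simulate_sample(small_records, truth)
        err = ErrorModel.long_single(
            sub_rate=0.05 / 3, ins_rate=0.05 / 3, del_rate=0.05 / 3, concatemer_prob=1.0
        )
        bc = DEFAULT_BARCODES[0]
        reads, tt = simulate_long_reads(mols, bc, error=err, seed=31)
        assert len(reads) == 100
        flank = DEFAULT_ADAPTER_LEADER + bc
        amp_of = {m.molecule_id: m.amplicon for m in mols}
        rec_amp = {m.record_id: m.amplicon for m in mols}
        sources = tt.groupby("read_id").record_id.apply(list).to_dict()
        n_ok = 0
        for read in reads:
            trimmed, _ = find_and_trim_flanks(read, [flank])
            frags = split_concatemers(trimmed, [flank])
            if len(frags) != 2:
                continue
            # each fragment's closest source amplicon must match the truth
            import edlib

            got = []
            for f in frags:
                dists = {
                    rid: min(
                        edlib.align(f.bases, a, mode="NW", task="distance")["editDistance"],
                        edlib.align(revcomp(f.bases), a, mode="NW", task="distance")["editDistance"],
                    )
                    for rid, a in rec_amp.items()
                }
                got.append(min(dists, key=dists.get))
            if sorted(got) == sorted(sources[read.read_id]):
                n_ok += 1
        assert n_ok >= 95


class TestDemultiplex:
    def test_exact_barcode_assigned(self, rng):
        bc_map = default_barcode_map(["s1", "s2"])
        insert = "".join(rng.choice(list("ACGT"), 200))
        r = read_of(DEFAULT_ADAPTER_LEADER + bc_map["s2"] + insert)
        bins, unassigned = demultiplex([r], bc_map)
        assert bins["s2"] == [r] and bins["s1"] == [] and unassigned == []

    def test_unmatched_read_unassigned(self, rng):
        bc_map = default_barcode_map(["s1", "s2"])
        r = read_of("".join(rng.choice(list("ACGT"), 200)))
        bins, unassigned = demultiplex([r], bc_map)
        assert unassigned == [r]

    def test_ambiguous_barcode_set_rejected(self):
        with pytest.raises(ValueError, match="apart"):
            validate_barcodes({"a": "A" * 24, "b": "A" * 23 + "C"}, 0.25)

    def test_bins_partition_input(self, small_records):
        truths = generate_sample_truths(
            sorted({r.genus for r in small_records}), 3, 80, seed=32,
            n_genera_per_sample=4, n_abundant=3,
        )
        bc_map = default_barcode_map([t.sample_id for t in truths])
        err = ErrorModel.long_single(sub_rate=0.03, ins_rate=0.03, del_rate=0.03)
        all_reads = []
        for t in truths:
            mols = simulate_sample(small_records, t)
            reads, _ = simulate_long_reads(mols, bc_map[t.sample_id], error=err, seed=t.seed)
            all_reads.extend(reads)
        bins, unassigned = demultiplex(all_reads, bc_map)
        binned = [r for rs in bins.values() for r in rs] + unassigned
        assert sorted(r.read_id for r in binned) == sorted(r.read_id for r in all_reads)

    def test_noisy_reads_assigned_to_truth_sample(self, small_records):
        genera = sorted({r.genus for r in small_records})
        truths = generate_sample_truths(
            genera, 6, 350, seed=33, n_genera_per_sample=4, n_abundant=3
        )
        bc_map = default_barcode_map([t.sample_id for t in truths])
        err = ErrorModel.long_single(sub_rate=0.03, ins_rate=0.03, del_rate=0.03,
                                     concatemer_prob=0.0)
        all_reads, truth_sample = [], {}
        for t in truths:
            mols = simulate_sample(small_records, t)
            reads, _ = simulate_long_reads(mols, bc_map[t.sample_id], error=err, seed=t.seed)
            all_reads.extend(reads)
            truth_sample.update({r.read_id: t.sample_id for r in reads})
        bins, unassigned = demultiplex(all_reads, bc_map)
        n_correct = sum(
            truth_sample[r.read_id] == sample for sample, rs in bins.items() for r in rs
        )
        assert n_correct / len(all_reads) >= 0.99


class TestExtractAmplicon:
    def test_strict_extraction_recovers_insert(self, small_records):
        from pollenpipe.synthetic_data import ITS2F, ITS4R, locus_for

        rec = small_records[0]
        amp = locus_for(rec).amplicon
        r = read_of("TTTTTGGGGG" + amp + "CCCCCAAAAA")
        out = extract_amplicon(r, ITS2F, ITS4R)
        assert out is not None and out.bases == rec.sequence

    def test_reverse_oriented_read_handled(self, small_records):
        from pollenpipe.synthetic_data import ITS2F, ITS4R, locus_for

        rec = small_records[1]
        amp = locus_for(rec).amplicon
        r = read_of(revcomp("GGGGG" + amp + "CCCCC"))
        out = extract_amplicon(r, ITS2F, ITS4R)
        assert out is not None and out.bases == rec.sequence

    def test_missing_primer_discards(self, rng):
        from pollenpipe.synthetic_data import ITS2F, ITS4R

        r = read_of("".join(rng.choice(list("ACGT"), 300)))
        assert extract_amplicon(r, ITS2F, ITS4R, max_mismatch_frac=0.15) is None


class TestJoinPairs:
    @staticmethod
    def mates_from(amplicon):
        r1 = read_of(amplicon[:150], read_id="p/1")
        r2 = read_of(revcomp(amplicon)[:150], read_id="p/2")
        return r1, r2

    def test_perfect_overlap_reconstructs_amplicon(self, rng):
        amp = "".join(rng.choice(list("ACGT"), 200))
        r1, r2 = self.mates_from(amp)
        joined = join_pairs(r1, r2)
        assert joined is not None and joined.bases == amp

    def test_long_amplicon_unjoinable(self, rng):
        amp = "".join(rng.choice(list("ACGT"), 400))
        assert join_pairs(*self.mates_from(amp)) is None

    def test_conflicting_base_takes_higher_quality(self, rng):
        amp = "".join(rng.choice(list("ACGT"), 200))
        r1 = ReadRecord("p/1", amp[:150], (40,) * 150)
        bad = list(revcomp(amp)[:150])
        # index 120 sits inside the 100-base overlap once reverse-complemented
        bad[120] = {"A": "C", "C": "G", "G": "T", "T": "A"}[bad[120]]
        r2 = ReadRecord("p/2", "".join(bad), (5,) * 150)
        joined = join_pairs(r1, r2)
        assert joined is not None and joined.bases == amp  # R1's call wins

    def test_joined_fraction_matches_length_threshold(self, rng):
        # error-free: joinable iff amplicon length <= 300 - min_overlap
        from pollenpipe.synthetic_data import amplicon_length_distribution

        lengths = np.round(
            amplicon_length_distribution().rvs(size=400, random_state=rng)
        ).astype(int)
        n_joined = 0
        for L in lengths:
            amp = "".join(rng.choice(list("ACGT"), int(L)))
            n_joined += join_pairs(*self.mates_from(amp)) is not None
        expected = (lengths <= 290).sum()
        # random-sequence overlap false positives are possible but rare
        assert abs(n_joined - expected) <= 3


class TestSummarize:
    def test_known_lengths(self):
        reads = [read_of("A" * n) for n in (5, 350, 11519)]
        s = summarize_reads(reads)
        assert (s.length_min, s.length_median, s.length_max) == (5, 350, 11519)

    def test_empty_collection_typed(self):
        s = summarize_reads([])
        assert s.n_reads == 0 and math.isnan(s.length_mean)

    def test_matches_brute_force_recomputation(self, rng):
        reads = [
            read_of(
                "".join(rng.choice(list("ACGT"), rng.integers(10, 400))),
                q=int(rng.integers(5, 40)),
            )
            for _ in range(500)
        ]
        s = summarize_reads(reads)
        lens = sorted(len(r) for r in reads)
        qs = sorted(mean_read_q(r) for r in reads)
        assert s.length_mean == pytest.approx(sum(lens) / len(lens))
        assert s.length_median == pytest.approx(np.median(lens))
        assert s.mean_q_median == pytest.approx(np.median(qs))


class TestErrorFreeRoundTrip:
    def test_trim_then_split_recovers_source_amplicons(self, small_records):
        truth = SampleTruth("s", {small_records[0].genus: 1.0}, 60, seed=34)
        mols = simulate_sample(small_records, truth)
        err = ErrorModel.long_single(
            sub_rate=0.0, ins_rate=0.0, del_rate=0.0, concatemer_prob=0.2,
            flank_q_penalty=0.0,
        )
        bc = DEFAULT_BARCODES[3]
        reads, tt = simulate_long_reads(mols, bc, error=err, seed=35)
        flank = DEFAULT_ADAPTER_LEADER + bc
        prepped, report = prep_long_reads(reads, [flank], mode="trim")
        amps = {m.amplicon for m in mols}
        for frag in prepped:
            assert frag.bases in amps or revcomp(frag.bases) in amps
        assert len(prepped) == len(tt)  # one fragment per source molecule
        assert report.n_split_concatemers == int(tt.is_concatemer.sum()) / 2
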