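"""Local alignment, the pair filter, scoring and genus assignment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import oracles
from pollenpipe._dna import revcomp
from pollenpipe.align_assign import (
    AlignmentHit,
    align_pair_to_db,
    align_to_db,
    assign_read,
    assign_single,
    hit_score,
    local_align,
    pair_filter,
    profile_sample,
    read_tabular_hits,
    write_tabular_hits,
)
from pollenpipe.reference_db import ReferenceDatabase, ReferenceRecord


def make_hit(ref_id="x", length=100, identity=1.0, read_id="r"):
    matches = int(round(length * identity))
    return AlignmentHit(
        read_id=read_id, ref_id=ref_id, score=matches, length=length,
        identity=identity, matches=matches, mismatches=length - matches,
        gap_columns=0, gap_opens=0, query_interval=(0, length),
        ref_interval=(0, length), strand="+",
    )


class TestLocalAlign:
    def test_self_alignment_full_identity(self, rng):
        seq = "".join(rng.choice(list("ACGT"), 100))
        hit = local_align(seq, seq)
        assert (hit.length, hit.identity, hit.strand) == (100, 1.0, "+")

    def test_strand_symmetry(self, rng):
        ref = "".join(rng.choice(list("ACGT"), 200))
        frag = ref[40:160]
        fwd = local_align(frag, ref)
        rev = local_align(revcomp(frag), ref)
        assert (fwd.length, fwd.identity) == (rev.length, rev.identity)
        assert fwd.strand == "+" and rev.strand == "-"

    def test_no_positive_alignment_returns_none(self):
        # forward-only: every column mismatches (note revcomp would match)
        assert local_align("AAAA", "TTTT", strands="+") is None

    def test_empty_sequences_rejected(self):
        with pytest.raises(ValueError):
            local_align("", "ACGT")

    def test_matches_plain_dp_oracle_on_random_pairs(self, rng):
        for _ in range(25):
            n1, n2 = rng.integers(20, 180, size=2)
            if rng.random() < 0.5:
                q = "".join(rng.choice(list("ACGT"), n1))
                r = "".join(rng.choice(list("ACGT"), n2))
            else:  # related pair: mutated fragment
                r = "".join(rng.choice(list("ACGT"), n2))
                codes = list(r[: max(20, n2 // 2)])
                for pos in rng.choice(len(codes), size=len(codes) // 10, replace=False):
                    codes[pos] = rng.choice(list("ACGT"))
                q = "".join(codes)
            hit = local_align(q, r, strands="+")
            got = None if hit is None else (hit.score, hit.length, hit.matches)
            assert got == oracles.sw_oracle(q, r)

    def test_gap_costs_affine(self):
        # bridging a 3-column gap scores 20 - (3+1+1) = 15, beating the
        # best gapless local alignment (10), so the gap must be opened once
        q = "AAAAAAAAAACCCCCCCCCC"
        r = "AAAAAAAAAAGGGCCCCCCCCCC"
        hit = local_align(q, r, strands="+")
        assert hit.score == 15
        assert hit.gap_columns == 3 and hit.gap_opens == 1
        assert hit.length == 23 and hit.matches == 20


class TestHitScore:
    def test_direct_arithmetic(self):
        assert hit_score(make_hit(length=100, identity=1.0)) == pytest.approx(100.0)
        assert hit_score(make_hit(length=150, identity=0.98)) == pytest.approx(147.0)

    def test_degenerate_length_rejected_at_construction(self):
        with pytest.raises(ValueError):
            make_hit(length=0)

    @given(
        st.integers(min_value=1, max_value=500),
        st.integers(min_value=1, max_value=500),
        st.floats(min_value=0.0, max_value=1.0),
        st.floats(min_value=0.0, max_value=1.0),
    )
    @settings(deadline=None, derandomize=True)
    def test_monotone_in_length_and_identity(self, l1, l2, i1, i2):
        if l1 <= l2:
            assert hit_score(make_hit(length=l1, identity=i1)) <= hit_score(
                make_hit(length=l2, identity=i1)
            )
        if i1 <= i2:
            assert hit_score(make_hit(length=l1, identity=i1)) <= hit_score(
                make_hit(length=l1, identity=i2)
            )


class TestPairFilter:
    def test_kept_pair_scores_sum(self):
        h1 = [make_hit("ref1", 120, 0.99)]
        h2 = [make_hit("ref1", 110, 0.99)]
        out = pair_filter(h1, h2)
        assert len(out) == 1
        assert out[0][0] == "ref1"
        assert out[0][1] == pytest.approx(120 * 0.99 + 110 * 0.99)

    def test_identity_boundary_strict(self):
        # exactly 0.98 fails the strictly-greater rule; 0.981 passes
        assert pair_filter([make_hit(identity=0.98)], [make_hit(identity=0.99)]) == []
        assert len(pair_filter([make_hit(identity=0.981)], [make_hit(identity=0.99)])) == 1

    def test_length_boundary_inclusive(self):
        # "at least 50 bp" -> 50 passes, 49 fails
        assert pair_filter([make_hit(length=49)], [make_hit(length=100)]) == []
        assert len(pair_filter([make_hit(length=50)], [make_hit(length=100)])) == 1

    def test_different_refs_never_pair(self):
        assert pair_filter([make_hit("a")], [make_hit("b")]) == []

    def test_order_invariance(self, rng):
        hits1 = [make_hit(f"r{i}", int(rng.integers(40, 200)), float(rng.uniform(0.9, 1)))
                 for i in range(6)]
        hits2 = [make_hit(f"r{i}", int(rng.integers(40, 200)), float(rng.uniform(0.9, 1)))
                 for i in range(6)]
        a = pair_filter(hits1, hits2)
        b = pair_filter(list(reversed(hits1)), list(reversed(hits2)))
        assert a == b

    def test_matches_brute_force_on_randomized_sets(self, rng):
        for _ in range(150):
            refs = [f"ref{i}" for i in range(4)]
            mk = lambda: [
                make_hit(
                    rng.choice(refs),
                    int(rng.choice([49, 50, 51, 120])),
                    float(rng.choice([0.97, 0.98, 0.981, 1.0])),
                )
                for _ in range(rng.integers(0, 6))
            ]
            h1, h2 = mk(), mk()
            got = pair_filter(h1, h2)
            want = oracles.pair_filter_oracle(h1, h2)
            assert [(r, pytest.approx(s)) for r, s in want] == got

    def test_raising_thresholds_never_adds_survivors(self, rng):
        h1 = [make_hit(f"r{i}", int(rng.integers(30, 200)), float(rng.uniform(0.9, 1)))
              for i in range(8)]
        h2 = [make_hit(f"r{i}", int(rng.integers(30, 200)), float(rng.uniform(0.9, 1)))
              for i in range(8)]
        base = len(pair_filter(h1, h2, min_len=40, min_identity=0.92))
        assert len(pair_filter(h1, h2, min_len=60, min_identity=0.92)) <= base
        assert len(pair_filter(h1, h2, min_len=40, min_identity=0.97)) <= base


@pytest.fixture(scope="module")
def tiny_db():
    return ReferenceDatabase(
        [
            ReferenceRecord("a1", "ACGTACGTACGTACGTACGTACGT", "Alpha one"),
            ReferenceRecord("a2", "ACGTACGTACGTACGTACGTACGA", "Alpha two"),
            ReferenceRecord("b1", "TTTTGGGGCCCCAAAATTTTGGGG", "Beta one"),
            ReferenceRecord("c1", "GGGGCCCCTTTTAAAAGGGGCCCC", "Gamma one"),
        ]
    )


class TestAssignRead:
    def test_single_candidate(self, tiny_db):
        a = assign_read([("a1", 140.0)], tiny_db, read_id="r")
        assert (a.genus, a.species, a.tied) == ("Alpha", "Alpha one", False)

    def test_top_score_wins(self, tiny_db):
        a = assign_read([("a1", 147.0), ("b1", 140.0)], tiny_db)
        assert a.genus == "Alpha" and a.score == 147.0

    def test_cross_genus_tie_lexicographic_and_flagged(self, tiny_db):
        a = assign_read([("c1", 99.0), ("a1", 99.0), ("b1", 99.0)], tiny_db)
        assert (a.genus, a.tied) == ("Alpha", True)

    def test_priority_list_overrides_lexicographic(self, tiny_db):
        a = assign_read(
            [("c1", 99.0), ("a1", 99.0)], tiny_db, tiebreak_priority=["Gamma"]
        )
        assert a.genus == "Gamma" and a.tied

    def test_same_genus_tie_not_flagged(self, tiny_db):
        a = assign_read([("a1", 99.0), ("a2", 99.0)], tiny_db)
        assert a.genus == "Alpha" and not a.tied
        assert a.species == "Alpha one"  # lexicographically smallest

    def test_empty_candidates_unassigned(self, tiny_db):
        a = assign_read([], tiny_db, read_id="r")
        assert not a.assigned and a.genus is None

    def test_unknown_ref_is_integrity_error(self, tiny_db):
        with pytest.raises(KeyError):
            assign_read([("nope", 1.0)], tiny_db)

    def test_matches_sort_oracle_on_random_sets(self, tiny_db, rng):
        genus_of = {r.record_id: r.genus for r in tiny_db}
        ids = list(genus_of)
        for _ in range(1000):
            cands = [
                (rng.choice(ids), float(rng.choice([50.0, 99.0, 147.0])))
                for _ in range(rng.integers(0, 5))
            ]
            # deduplicate ref ids keeping max score (the filter's contract)
            dedup = {}
            for ref, s in cands:
                dedup[ref] = max(s, dedup.get(ref, 0.0))
            cands = sorted(dedup.items())
            got = assign_read(cands, tiny_db)
            want = oracles.assign_oracle(cands, genus_of)
            if want is None:
                assert not got.assigned
            else:
                assert (got.genus, got.score, got.tied) == want


class TestAssignSingleAndProfile:
    def test_error_free_amplicon_assigned_true_genus(self, small_db):
        rec = small_db.records[4]
        hits = align_to_db(rec.sequence, small_db)
        a = assign_single(hits, small_db, read_id="r")
        assert a.assigned and a.genus == rec.genus and a.score == pytest.approx(
            len(rec.sequence)
        )

    def test_empty_hits_unassigned(self, small_db):
        assert not assign_single([], small_db).assigned

    def test_profile_counts_and_conservation(self, tiny_db):
        assignments = [
            assign_read([("a1", 9.0)], tiny_db, read_id="1"),
            assign_read([("a2", 9.0)], tiny_db, read_id="2"),
            assign_read([("b1", 9.0)], tiny_db, read_id="3"),
            assign_read([], tiny_db, read_id="4"),
        ]
        prof = profile_sample(assignments, "s")
        assert prof.counts == {"Alpha": 2, "Beta": 1}
        assert prof.n_unassigned == 1
        assert prof.n_assigned + prof.n_unassigned == 4

    def test_all_unassigned_empty_profile(self, tiny_db):
        prof = profile_sample([assign_read([], tiny_db) for _ in range(5)])
        assert prof.counts == {} and prof.n_unassigned == 5


class TestAlignToDb:
    def test_exhaustive_and_prescreened_agree_on_best(self, small_db, rng):
        rec = small_db.records[2]
        noisy = list(rec.sequence)
        for pos in rng.choice(len(noisy), size=len(noisy) // 20, replace=False):
            noisy[pos] = rng.choice(list("ACGT"))
        query = "".join(noisy)
        full = align_to_db(query, small_db, prescreen=False)
        fast = align_to_db(query, small_db)
        best_full = max(full, key=hit_score)
        best_fast = max(fast, key=hit_score)
        assert (best_full.ref_id, hit_score(best_full)) == (
            best_fast.ref_id, hit_score(best_fast),
        )

    def test_pair_prescreen_aligns_both_mates_to_same_refs(self, small_db):
        rec = small_db.records[0]
        amp = "AAAA" + rec.sequence + "TTTT"
        r1, r2 = amp[:150], revcomp(amp)[:150]
        h1, h2 = align_pair_to_db(r1, r2, small_db)
        assert {h.ref_id for h in h1} == {h.ref_id for h in h2}
        cands = pair_filter(h1, h2, min_len=50, min_identity=0.98)
        a = assign_read(cands, small_db)
        assert a.genus == rec.genus


class TestTabularInterchange:
    def test_round_trip(self, tmp_path, small_db, rng):
        rec = small_db.records[1]
        hits = align_to_db(rec.sequence[10:200], small_db, read_id="q0")
        path = tmp_path / "hits.tsv"
        write_tabular_hits(hits, path)
        back = read_tabular_hits(path)
        assert len(back) == len(hits)
        for h, b in zip(sorted(hits, key=lambda x: x.ref_id),
                        sorted(back, key=lambda x: x.ref_id)):
            assert (b.read_id, b.ref_id, b.length, b.strand) == (
                h.read_id, h.ref_id, h.length, h.strand,
            )
            assert b.identity == pytest.approx(h.identity, abs=1e-3)
            assert b.query_interval == h.query_interval

    def test_minus_strand_encoded_by_coordinate_swap(self, tmp_path, small_db):
        rec = small_db.records[0]
        hit = local_align(revcomp(rec.sequence), rec.sequence, read_id="q", ref_id="r")
        assert hit.strand == "-"
        path = tmp_path / "m.tsv"
        write_tabular_hits([hit], path)
        fields = path.read_text().split("\t")
        assert int(fields[8]) > int(fields[9])  # sstart > send
        assert read_tabular_hits(path)[0].strand == "-"
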