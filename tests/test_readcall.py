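"""Alignment, parsing, outcome calling and UID collapsing."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tripcas.readcall import (
    AlignmentError,
    AlignmentParams,
    GuideTarget,
    MutationCall,
    align_semi_global,
    call_mutation,
    call_reads,
    collapse_uids,
    deletion_window,
    insertion_window,
    parse_amplicon,
    parse_batch,
    revcomp,
)

MATCH, MIS, OPEN, EXT, INIT = 2.0, -2.0, -5.0, -0.5, 30.0


def naive_affine_score(q: str, r: str) -> float:
    """Independent exhaustive affine DP oracle (memoized recursion)."""
    import sys
    from functools import lru_cache

    sys.setrecursionlimit(20000)
    NEG = float("-inf")

    @lru_cache(maxsize=None)
    def best(i, j, state):
        if i == 0:
            return 0.0 if state == "M" else NEG  # free leading reference skip
        if state == "M":
            if j == 0:
                return NEG
            s = MATCH if q[i - 1] == r[j - 1] else MIS
            prev = max(best(i - 1, j - 1, t) for t in "MXY")
            return prev + s if prev > NEG / 2 else NEG
        if state == "X":  # extra query base
            return max(best(i - 1, j, "M") + OPEN, best(i - 1, j, "X") + EXT)
        if j == 0:  # Y consumes reference
            return NEG
        return max(best(i, j - 1, "M") + OPEN, best(i, j - 1, "Y") + EXT)

    return INIT + max(best(len(q), j, s) for j in range(len(r) + 1) for s in "MXY")


class TestAlignment:
    def test_identical_sequences_score(self):
        seq = "ACGTACGTACGTACGTACGT"
        assert align_semi_global(seq, seq).score == INIT + 20 * MATCH

    def test_internal_three_nt_deletion_score(self):
        ref = "ACGTACGTACGTACGTACGT"
        query = ref[:8] + ref[11:]
        res = align_semi_global(query, ref)
        assert res.score == INIT + 17 * MATCH + OPEN + 2 * EXT
        assert res.ops == (("del", 8, "ACG"),)

    def test_free_reference_end_gaps(self):
        core = "ACGTACGTACGTACGTACGT"
        res = align_semi_global(core, "TTTT" + core + "GGGG")
        assert res.score == INIT + 20 * MATCH
        assert (res.ref_start, res.ref_end) == (4, 24)

    def test_n_scores_as_mismatch_even_against_n(self):
        assert align_semi_global("ACGN", "ACGT").score == INIT + 3 * MATCH + MIS
        # N never matches, not even another N: mismatch beats a gap here
        assert align_semi_global("N", "N").score == INIT + MIS

    @pytest.mark.parametrize("q,r", [("", "ACGT"), ("ACGT", ""), ("ACXG", "ACGT")])
    def test_invalid_inputs_rejected(self, q, r):
        with pytest.raises(AlignmentError):
            align_semi_global(q, r)

    def test_matches_exhaustive_dp_oracle(self):
        rnd = random.Random(20240917)
        for _ in range(500):
            q = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 15)))
            r = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(1, 15)))
            assert align_semi_global(q, r).score == pytest.approx(naive_affine_score(q, r))

    def test_indels_reported_at_three_prime_most_placement(self):
        # inserting A into the run of CA|AT contexts: reported downstream
        res = align_semi_global("GGCAATGG", "GGCATGG")
        assert res.ops == (("ins", 4, "A"),)
        # deletion in a homopolymer run reports the 3'-most copy; flanks are
        # long enough that a gap beats re-aligning them as mismatches
        ref = "GGCC" + "AAAA" + "TTCCGGTTCC"
        query = "GGCC" + "AAA" + "TTCCGGTTCC"
        res = align_semi_global(query, ref)
        assert res.ops == (("del", 7, "A"),)

    def test_initial_score_is_additive_offset_only(self):
        ref = "ACGTACGTAC"
        query = ref[:3] + ref[5:]
        base = align_semi_global(query, ref)
        shifted = align_semi_global(query, ref, AlignmentParams(initial_score=0.0))
        assert base.score - shifted.score == INIT
        assert base.ops == shifted.ops


class TestWindows:
    @given(st.text(alphabet="ACGT", min_size=5, max_size=25), st.data())
    @settings(max_examples=200, deadline=None)
    def test_window_members_reconstruct_identical_sequences(self, ref, data):
        start = data.draw(st.integers(0, len(ref) - 2))
        length = data.draw(st.integers(1, len(ref) - start - 1))
        mutated = ref[:start] + ref[start + length :]
        for p in deletion_window(ref, start, length):
            assert ref[:p] + ref[p + length :] == mutated
        bond = data.draw(st.integers(0, len(ref)))
        seq = data.draw(st.text(alphabet="ACGT", min_size=1, max_size=3))
        target = ref[:bond] + seq + ref[bond:]
        for p in insertion_window(ref, bond, seq):
            assert target[:p] == ref[:p] and target[p + len(seq) :] == ref[p:]


class TestParsing:
    def test_generator_round_trip(self, clean_assay):
        lib, reads, truth = clean_assay
        library = {c.barcode: c.target_region for c in lib}
        parsed, summary = parse_batch([s for _, s in reads], library)
        assert summary["parse_rate"] == 1.0
        truth_uids = dict(zip(truth["read"], truth["uid"]))
        for (name, _), rec in zip(reads, parsed):
            assert rec.uid == truth_uids[name]
            assert name.split(":")[1] == rec.barcode

    def test_one_mismatch_barcode_rejected_at_zero_tolerance(self, clean_assay):
        lib, reads, _ = clean_assay
        library = {c.barcode: c.target_region for c in lib}
        name, seq = reads[0]
        bc = name.split(":")[1]
        pos = 16 + 8  # barcode offset in the layout
        flip = "A" if seq[pos] != "A" else "C"
        bad = seq[:pos] + flip + seq[pos + 1 :]
        rec, reason = parse_amplicon(bad, library)
        assert rec is None and reason == "aberrant_barcode"
        rec, reason = parse_amplicon(bad, library, barcode_mismatch_tolerance=1)
        assert rec is not None and rec.barcode == bc

    def test_truncated_read_rejected(self, clean_assay):
        lib, reads, _ = clean_assay
        library = {c.barcode: c.target_region for c in lib}
        rec, reason = parse_amplicon(reads[0][1][:30], library)
        assert rec is None and reason == "truncated"

    def test_parse_rate_reported_as_parsed_over_total(self, clean_assay):
        lib, reads, _ = clean_assay
        library = {c.barcode: c.target_region for c in lib}
        seqs = [s for _, s in reads[:10]] + ["ACGT"]
        _, summary = parse_batch(seqs, library)
        assert summary["parse_rate"] == pytest.approx(10 / 11)
        assert summary["rejections"] == {"truncated": 1}


class TestCallMutation:
    def test_perfect_read_is_wild_type(self, guides):
        g = guides["sgG3"]
        ref = "ACGATCCTGAT" + g.ntdna + "TGACCTGAGT"
        frame = g.frame(ref)
        call = call_mutation(align_semi_global(ref, ref), frame)
        assert call.outcome == "wild_type" and not call.indels

    def test_single_t_insertion_at_4_5_in_t_free_context(self, guides):
        g = guides["sgG3"]  # position 4 is the only local T: window is {3|4, 4|5}
        ref = "ACGATCCTGAT" + g.ntdna + "TGACCTGAGT"
        frame = g.frame(ref)
        bond = frame.junction_to_bond(4)
        read = ref[:bond] + "T" + ref[bond:]
        call = call_mutation(align_semi_global(read, ref), frame)
        assert call.outcome == "insertion"
        ins = call.insertions[0]
        assert ins.sequence == "T"
        junctions = {frame.bond_to_junction(b) for b in ins.window}
        assert junctions == {3, 4}

    def test_deletion_plus_insertion_is_complex(self, guides):
        g = guides["sgG3"]
        ref = "ACGATCCTGAT" + g.ntdna + "TGACCTGAGT"
        frame = g.frame(ref)
        cut = frame.cut_bond
        read = ref[: cut - 8] + ref[cut - 6 : cut + 2] + "G" + ref[cut + 2 :]
        call = call_mutation(align_semi_global(read, ref), frame)
        assert call.outcome == "complex"
        assert len(call.indels) == 2

    def test_substitutions_alone_stay_wild_type(self, guides):
        g = guides["sgG3"]
        ref = "ACGATCCTGAT" + g.ntdna + "TGACCTGAGT"
        frame = g.frame(ref)
        read = ref[:5] + ("A" if ref[5] != "A" else "C") + ref[6:]
        call = call_mutation(align_semi_global(read, ref), frame)
        assert call.outcome == "wild_type"

    def test_fragment_missing_target_region_rejected(self, guides):
        g = guides["sgG3"]
        ref = "ACGATCCTGAT" + g.ntdna + "TGACCTGAGT"
        frame = g.frame(ref)
        call = call_mutation(align_semi_global(ref[:12], ref), frame)
        assert call.rejected == "off_target_fragment"

    def test_antisense_guide_coordinates(self, guides):
        g = guides["sgG3"]
        anti = GuideTarget(
            protospacer=g.protospacer, pam=g.pam, name="anti", orientation="antisense"
        )
        ref = "ACGATCCTGAT" + revcomp(g.ntdna) + "TGACCTGAGT"
        frame = anti.frame(ref)
        assert frame.ntref == revcomp(ref)
        assert frame.position_base(4) == g.nucleotide4


class TestRoundTrip:
    def test_calls_recover_truth_outcomes(self, clean_assay, guides):
        """On error-free synthetic reads the caller recovers the generating
        outcome class for essentially every read."""
        lib, reads, truth = clean_assay
        library = {c.barcode: c.target_region for c in lib}
        calls, _ = call_reads([s for _, s in reads], library, guides["sgG3"])
        assert len(calls) == len(truth)
        agree = sum(
            c.outcome == t for c, t in zip(calls, truth["outcome"])
        )
        assert agree / len(calls) >= 0.999


class TestCollapseUids:
    def _call(self, uid, outcome):
        return MutationCall(barcode="BC", uid=uid, outcome=outcome)

    def test_majority_outcome_wins(self):
        calls = [self._call("u1", "deletion"), self._call("u1", "deletion"),
                 self._call("u1", "wild_type")]
        molecules, stats = collapse_uids(calls)
        assert len(molecules) == 1 and molecules[0].outcome == "deletion"
        assert stats["max_family_size"] == 3

    def test_ties_break_toward_wild_type(self):
        calls = [self._call("u1", "deletion"), self._call("u1", "wild_type")]
        molecules, stats = collapse_uids(calls)
        assert molecules[0].outcome == "wild_type" and stats["ties"] == 1

    def test_unique_uids_pass_through(self):
        calls = [self._call(f"u{i}", "insertion") for i in range(5)]
        molecules, stats = collapse_uids(calls)
        assert len(molecules) == 5 and stats["molecules"] == 5
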