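"""Per-IR profile aggregation, spectra, boundary weights, expression."""

import numpy as np
import pandas as pd
import pytest

from tripcas.profiles import (
    compute_ir_expression,
    compute_profiles,
    deletion_boundary_frequencies,
    insertion_base_distribution,
    size_spectra,
)
from tripcas.readcall import (
    Indel,
    MutationCall,
    align_semi_global,
    call_mutation,
    deletion_window,
)
from tripcas.synthetic import DEFAULT_GUIDES, TARGET_REGION


def _call(bc, uid, outcome, indels=(), knockin=False):
    return MutationCall(barcode=bc, uid=uid, outcome=outcome, indels=tuple(indels),
                       knockin=knockin)


def _mix(bc, n_wt, n_del, n_ins, n_complex, n_ki=0):
    calls = []
    i = 0
    for outcome, n in (("wild_type", n_wt), ("deletion", n_del),
                       ("insertion", n_ins), ("complex", n_complex)):
        for _ in range(n):
            ki = outcome == "insertion" and i < n_ki
            calls.append(_call(bc, f"u{i}", outcome, knockin=ki))
            i += 1
    return calls


class TestComputeProfiles:
    def test_frequency_arithmetic(self):
        calls = {"assay": _mix("BC1", 50, 30, 15, 5)}
        prof = compute_profiles(calls, min_coverage=30)
        row = prof.iloc[0]
        assert (row.wild_type, row.deletion, row.insertion, row.complex) == (
            0.50, 0.30, 0.15, 0.05)
        assert row.total_mut_freq == 0.50
        assert row.coverage == 100

    def test_low_coverage_ir_excluded_everywhere(self):
        calls = {
            "a1": _mix("BC1", 20, 10, 0, 0) + _mix("BC2", 25, 10, 0, 0),
            "a2": _mix("BC1", 10, 9, 5, 5) + _mix("BC2", 40, 0, 0, 0),
        }
        prof = compute_profiles(calls, min_coverage=30)
        # BC1 has 29 molecules in a2 -> dropped from both assays
        assert set(prof["barcode"]) == {"BC2"}
        assert len(prof) == 2

    def test_all_wild_type_gives_zero_mutation_frequency(self):
        prof = compute_profiles({"a": _mix("BC1", 40, 0, 0, 0)}, min_coverage=30)
        assert prof.iloc[0].total_mut_freq == 0.0

    def test_knockin_plus_error_insertions_sum_to_insertion_fraction(self):
        prof = compute_profiles(
            {"a": _mix("BC1", 50, 20, 20, 10, n_ki=8)}, min_coverage=30
        )
        row = prof.iloc[0]
        assert row.knockin_freq + row.error_insertion_freq == pytest.approx(row.insertion)

    def test_replicate_pooling_is_order_invariant(self):
        r1 = _mix("BC1", 30, 10, 0, 0)
        r2 = _mix("BC1", 10, 30, 0, 0)
        p_ab = compute_profiles({"a": [r1, r2]}, min_coverage=30)
        p_ba = compute_profiles({"a": [r2, r1]}, min_coverage=30)
        pd.testing.assert_frame_equal(p_ab, p_ba)
        assert p_ab.iloc[0].coverage == 80

    def test_empty_call_set_returns_empty_table(self):
        prof = compute_profiles({}, min_coverage=30)
        assert prof.empty


class TestSizeSpectra:
    def _indel(self, kind, size):
        return Indel(kind=kind, position=0, sequence="A" * size, window=(0,))

    def test_deletion_fraction_below_10bp(self):
        calls = [
            _call("b", f"u{i}", "deletion", [self._indel("del", s)])
            for i, s in enumerate((3, 3, 7, 12))
        ]
        spec = size_spectra(calls)
        assert spec["fraction_deletions_lt10"] == 0.75
        assert spec["deletion"]["frequency"].sum() == pytest.approx(1.0)

    def test_all_one_bp_insertions(self):
        calls = [
            _call("b", f"u{i}", "insertion", [self._indel("ins", 1)]) for i in range(5)
        ]
        assert size_spectra(calls)["fraction_insertions_1bp"] == 1.0

    def test_generated_geometric_sizes_match_generator_within_3_sigma(self, guides):
        from tripcas.synthetic import SimulationConfig, generate_reporter_library, simulate_cas9_reads
        from tripcas.readcall import call_reads

        cfg = SimulationConfig(
            seed=21, n_irs=6, insertion_prob=0.0, complex_prob=0.0,
            seq_error_rate=0.0, coverage_mean=300.0, guide_efficiency=1.8,
            uid_dup_mean=0.0, deletion_geom_p=0.15,
        )
        lib = generate_reporter_library(cfg)
        reads, truth = simulate_cas9_reads(lib, guides["sgG3"], cfg)
        calls, _ = call_reads(
            [s for _, s in reads], {c.barcode: c.target_region for c in lib},
            guides["sgG3"],
        )
        spec = size_spectra(calls)
        truth_sizes = (
            truth.loc[truth["outcome"] == "deletion", "detail"]
            .str.extract(r"del:(\d+)@")[0].astype(int)
        )
        p_obs = spec["fraction_deletions_lt10"]
        p_true = (truth_sizes < 10).mean()
        n = len(truth_sizes)
        assert abs(p_obs - p_true) < 3 * np.sqrt(p_true * (1 - p_true) / n) + 0.01


class TestDeletionBoundaries:
    def _frame(self, guides):
        return guides["sgG1"].frame(TARGET_REGION)

    def _deletion_call(self, frame, start, size, uid="u0"):
        ref = frame.ntref
        window = deletion_window(ref, start, size)
        ind = Indel(kind="del", position=start, sequence=ref[start : start + size],
                    window=window)
        return _call("b", uid, "deletion", [ind])

    def test_unambiguous_deletion_abutting_3_4(self, guides):
        frame = self._frame(guides)
        # deletion ending exactly at the 3|4 bond, in a context with a
        # single placement
        start = frame.junction_to_bond(3) - 2
        c = self._deletion_call(frame, start, 2)
        if len(c.deletions[0].window) != 1:
            pytest.skip("context produced an ambiguous placement")
        table, overall = deletion_boundary_frequencies([c], frame)
        assert overall["freq_neighbor_3|4"] == 1.0
        assert overall["freq_neighbor_4|5"] == 0.0

    def test_ambiguous_placement_weights_are_fractional(self, guides):
        frame = self._frame(guides)
        # CGG loss in the CGG.CGG context: 4 equivalent placements, two of
        # which touch junction 3|4 (the positions 1-3 and 4-6 readings)
        start = frame.ntref.find("CGGCGG", frame.pam_index - 12) + 3
        c = self._deletion_call(frame, start, 3)
        assert len(c.deletions[0].window) == 4
        table, overall = deletion_boundary_frequencies([c], frame)
        assert overall["freq_neighbor_3|4"] == pytest.approx(2 / 4)

    def test_boundary_weight_never_exceeds_total(self, guides):
        frame = self._frame(guides)
        calls = [
            self._deletion_call(frame, frame.cut_bond - k, k, uid=f"u{k}")
            for k in (1, 2, 3)
        ]
        _, overall = deletion_boundary_frequencies(calls, frame)
        for j in (3, 4):
            assert 0.0 <= overall[f"freq_neighbor_{j}|{j+1}"] <= 1.0

    def test_junction_outside_protospacer_rejected(self, guides):
        frame = self._frame(guides)
        with pytest.raises(ValueError):
            deletion_boundary_frequencies([], frame, junctions=(3, 25))


class TestInsertionBaseDistribution:
    def _ins_call(self, bc, uid, base):
        ind = Indel(kind="ins", position=5, sequence=base, window=(5,))
        return _call(bc, uid, "insertion", [ind])

    def test_pure_t_distribution(self):
        calls = {"BC1": [self._ins_call("BC1", f"u{i}", "T") for i in range(4)]}
        per_ir, summary = insertion_base_distribution(calls)
        assert per_ir.loc["BC1"].tolist() == [0.0, 0.0, 0.0, 1.0]
        assert summary["T"] == 1.0

    def test_ir_without_insertions_omitted(self):
        calls = {"BC1": [self._ins_call("BC1", "u0", "G")],
                 "BC2": [_call("BC2", "u0", "wild_type")]}
        per_ir, _ = insertion_base_distribution(calls)
        assert list(per_ir.index) == ["BC1"]

    def test_mixture_expectation_half_staggered(self, guides):
        """50/50 blunt:staggered with template base T gives an asymptotic T
        fraction of 0.5 + 0.5/4 = 0.625."""
        from tripcas.readcall import call_reads
        from tripcas.synthetic import SimulationConfig, generate_reporter_library, simulate_cas9_reads

        cfg = SimulationConfig(
            seed=31, n_irs=6, f_staggered=0.5, insertion_prob=1.0, ins1_prob=1.0,
            complex_prob=0.0, seq_error_rate=0.0, coverage_mean=500.0,
            guide_efficiency=1.9, uid_dup_mean=0.0,
        )
        lib = generate_reporter_library(cfg)
        reads, _ = simulate_cas9_reads(lib, guides["sgG3"], cfg)
        calls, _ = call_reads(
            [s for _, s in reads], {c.barcode: c.target_region for c in lib},
            guides["sgG3"],
        )
        by_bc = {}
        for c in calls:
            by_bc.setdefault(c.barcode, []).append(c)
        _, summary = insertion_base_distribution(by_bc)
        n = sum(1 for c in calls if c.outcome == "insertion")
        assert abs(summary["T"] - 0.625) < 3 * np.sqrt(0.625 * 0.375 / n)


class TestExpression:
    def test_identity_ratio_is_zero(self):
        expr = compute_ir_expression({"b": 100}, {"b": 100})
        assert expr["b"] == 0.0

    def test_zero_cdna_stays_finite(self):
        expr = compute_ir_expression({}, {"b": 50})
        assert np.isfinite(expr["b"])

    def test_scale_invariance(self):
        e1 = compute_ir_expression({"b": 100}, {"b": 25})
        e2 = compute_ir_expression({"b": 200}, {"b": 50})
        assert e1["b"] == pytest.approx(e2["b"], abs=0.06)

    def test_zero_gdna_excluded(self):
        expr = compute_ir_expression({"a": 10, "b": 10}, {"a": 0, "b": 5})
        assert list(expr.index) == ["b"]
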