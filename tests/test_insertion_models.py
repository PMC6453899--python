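"""Ambiguity windows and model-based redistribution of insertion counts."""

import random

import numpy as np
import pandas as pd
import pytest

from tripcas.insertion_models import (
    AmbiguityWindow,
    CleavageModel,
    InsertionCountTable,
    expected_profile,
    find_ambiguity_windows,
    model_concordance,
    redistribute_counts,
    string_insertion_groups,
    window_for,
)
from tripcas.synthetic import DEFAULT_GUIDES, simulate_insertion_events


def brute_force_groups(seq: str):
    """Oracle: enumerate every (junction, base) insertion and group string
    indices by the literal mutated sequence."""
    out = {}
    for b in "ACGT":
        seen = {}
        for i in range(len(seq) + 1):
            seen.setdefault(seq[:i] + b + seq[i:], []).append(i)
        out[b] = sorted(tuple(v) for v in seen.values())
    return out


class TestAmbiguityWindows:
    def test_cat_context_two_junction_window(self):
        # C.A.T: inserting A at C|A or A|T both give CAAT
        groups = string_insertion_groups("CAT")["A"]
        assert (1, 2) in groups

    def test_run_of_three_gives_window_of_four_junctions(self):
        groups = string_insertion_groups("GAAAG")["A"]
        assert (1, 2, 3, 4) in groups

    def test_base_absent_from_neighborhood_is_everywhere_unambiguous(self):
        groups = string_insertion_groups("ACTCT")["G"]
        assert all(len(g) == 1 for g in groups)

    def test_window_construction_matches_brute_force_on_random_20mers(self):
        rnd = random.Random(17)
        for _ in range(200):
            seq = "".join(rnd.choice("ACGT") for _ in range(20))
            assert string_insertion_groups(seq) == brute_force_groups(seq)

    def test_pam_relative_windows_cover_each_junction_once(self, guides):
        g = guides["sgG3"]
        windows, unamb = find_ambiguity_windows(g.ntdna, 20)
        for b in "ACGT":
            claimed = [j for w in windows if w.base == b for j in w.junctions]
            claimed += list(unamb[b])
            assert sorted(claimed) == list(range(0, 9))

    def test_template_base_window_for_guide3(self, guides):
        g = guides["sgG3"]  # lone T at position 4
        w = window_for(g.ntdna, 20, "T", 4)
        assert w.junctions == (3, 4)


class TestRedistribution:
    def _table(self, guide, unambiguous, windows):
        t = InsertionCountTable(guide=guide.name, ntref=guide.ntdna, pam_index=20)
        t.unambiguous.update(unambiguous)
        t.windows.update(windows)
        return t

    def test_blunt_split_follows_unambiguous_proportions(self, guides):
        g = guides["sgG3"]
        t = self._table(
            g, {(4, "A"): 8, (3, "G"): 2},
            {AmbiguityWindow(base="T", junctions=(3, 4)): 10},
        )
        counts, diag = redistribute_counts(t, CleavageModel(kind="blunt"))
        assert counts.loc[4, "T"] == pytest.approx(8.0)
        assert counts.loc[3, "T"] == pytest.approx(2.0)
        assert diag["output_total"] == pytest.approx(t.total)

    def test_staggered_unlikely_site_gets_other_base_mean(self, guides):
        g = guides["sgG3"]
        t = self._table(
            g, {(3, "A"): 3, (3, "C"): 5, (3, "G"): 1},
            {AmbiguityWindow(base="T", junctions=(3, 4)): 10},
        )
        counts, diag = redistribute_counts(t, CleavageModel(kind="staggered"))
        assert counts.loc[3, "T"] == pytest.approx(3.0)  # mean of (3, 5, 1)
        assert counts.loc[4, "T"] == pytest.approx(7.0)  # remainder
        assert not diag["clamped_windows"]

    def test_no_windows_identity(self, guides):
        g = guides["sgG3"]
        t = self._table(g, {(3, "A"): 4, (5, "C"): 2}, {})
        for kind in ("blunt", "staggered", "combined"):
            counts, _ = redistribute_counts(t, CleavageModel(kind=kind))
            assert counts.loc[3, "A"] == 4 and counts.loc[5, "C"] == 2
            assert counts.to_numpy().sum() == 6

    def test_all_zero_weights_fall_back_to_uniform(self, guides):
        g = guides["sgG3"]
        t = self._table(g, {}, {AmbiguityWindow(base="T", junctions=(3, 4)): 8})
        counts, _ = redistribute_counts(t, CleavageModel(kind="blunt"))
        assert counts.loc[3, "T"] == counts.loc[4, "T"] == pytest.approx(4.0)

    def test_negative_remainder_clamped_and_reported(self, guides):
        g = guides["sgG3"]
        t = self._table(
            g, {(3, "A"): 50, (3, "C"): 50, (3, "G"): 50},
            {AmbiguityWindow(base="T", junctions=(3, 4)): 10},
        )
        counts, diag = redistribute_counts(t, CleavageModel(kind="staggered"))
        assert diag["clamped_windows"]
        assert counts.loc[4, "T"] == 0.0
        assert counts.loc[3, "T"] == pytest.approx(50.0)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            CleavageModel(kind="bent")

    def test_conservation_on_random_tables(self, guides):
        g = guides["sgG1"]
        rnd = np.random.default_rng(3)
        windows, _ = find_ambiguity_windows(g.ntdna, 20)
        for kind in ("blunt", "staggered", "combined"):
            t = InsertionCountTable(guide=g.name, ntref=g.ntdna, pam_index=20)
            for j in range(0, 9):
                for b in "ACGT":
                    t.unambiguous[(j, b)] = int(rnd.integers(0, 20))
            for w in windows:
                t.windows[w] = int(rnd.integers(50, 200))  # large: no clamping
            counts, diag = redistribute_counts(t, CleavageModel(kind=kind))
            if not diag["clamped_windows"]:
                assert counts.to_numpy().sum() == pytest.approx(t.total)

    def test_caller_convention_independence(self, guides):
        """Identical results whether ambiguous insertions are reported at
        the 5'-most or 3'-most junction of their window."""
        g = guides["sgG1"]
        rnd = np.random.default_rng(5)
        bases = [rnd.choice(list("ACGT")) for _ in range(500)]
        junctions = [int(rnd.integers(0, 9)) for _ in range(500)]
        ev_low, ev_high = [], []
        for b, j in zip(bases, junctions):
            w = window_for(g.ntdna, 20, b, j)
            ev_low.append((b, min(w.junctions)))
            ev_high.append((b, max(w.junctions)))
        t_low = InsertionCountTable.from_events(g.name, g.ntdna, 20, ev_low)
        t_high = InsertionCountTable.from_events(g.name, g.ntdna, 20, ev_high)
        for kind in ("blunt", "staggered", "combined"):
            c1, _ = redistribute_counts(t_low, CleavageModel(kind=kind))
            c2, _ = redistribute_counts(t_high, CleavageModel(kind=kind))
            pd.testing.assert_frame_equal(c1, c2)


class TestExpectedProfileAndConcordance:
    def test_staggered_expectation_is_template_base_at_4_5(self, guides):
        g = guides["sgG3"]
        prof = expected_profile(CleavageModel(kind="staggered"), g.ntdna, 20)
        assert prof.loc[4, "T"] == 1.0
        assert prof.drop(index=4).to_numpy().sum() == 0.0

    def test_blunt_expectation_uniform_at_3_4(self, guides):
        g = guides["sgG3"]
        prof = expected_profile(CleavageModel(kind="blunt"), g.ntdna, 20)
        assert (prof.loc[3] == 0.25).all()

    def test_combined_expectation_has_both_signatures(self, guides):
        g = guides["sgG3"]
        prof = expected_profile(CleavageModel(kind="combined"), g.ntdna, 20)
        assert (prof.loc[3] == 0.25).all() and prof.loc[4, "T"] == 1.0

    def test_concordance_flags(self, guides):
        g = guides["sgG3"]
        counts = pd.DataFrame(0.0, index=range(0, 9), columns=list("ACGT"))
        counts.loc[3] = [10.0, 10.0, 10.0, 10.0]
        counts.loc[4, "T"] = 100.0
        table = model_concordance(counts, CleavageModel(kind="combined"), g.ntdna, 20)
        by_junction = table.set_index("junction")
        assert bool(by_junction.loc["3|4", "concordant_blunt"])
        assert bool(by_junction.loc["4|5", "concordant_staggered"])
        assert by_junction.loc["4|5", "modal_share"] == 1.0

    def test_generator_round_trip_combined_concordant(self, guides):
        g = guides["sgG3"]
        rng = np.random.default_rng(11)
        events = simulate_insertion_events(g, 4000, 0.6, rng)
        t = InsertionCountTable.from_events(g.name, g.ntdna, 20, events)
        counts, _ = redistribute_counts(t, CleavageModel(kind="combined"))
        table = model_concordance(counts, CleavageModel(kind="combined"), g.ntdna, 20)
        by_junction = table.set_index("junction")
        assert bool(by_junction.loc["4|5", "concordant_staggered"])


class TestRecovery:
    @pytest.mark.parametrize("f", [0.0, 0.25, 0.5, 0.75, 1.0])
    def test_combined_model_recovers_staggered_fraction(self, guides, f):
        """Base-4 share over the 3|4 + 4|5 cut region after combined-model
        redistribution equals f + (1 - f)/4 within 3 points at n = 10,000."""
        g = guides["sgG3"]
        rng = np.random.default_rng(np.random.SeedSequence([1234, int(f * 100)]))
        events = simulate_insertion_events(g, 10_000, f, rng)
        t = InsertionCountTable.from_events(g.name, g.ntdna, 20, events)
        counts, _ = redistribute_counts(t, CleavageModel(kind="combined"))
        cut = counts.loc[[3, 4]]
        share = cut["T"].sum() / cut.to_numpy().sum()
        assert share == pytest.approx(f + (1 - f) / 4, abs=0.03)
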