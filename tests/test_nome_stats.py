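"""Accessibility statistics: per-site percentages, windowed profiles,
condition comparisons, footprints/open runs and bubble structures."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

import nomeamp as na
from nomeamp.calls import Call
from nomeamp.nome_stats import (NUCLEOSOME_SIZED, SUBTHRESHOLD,
                                bubble_round_trip, footprints_to_frame)
from nomeamp.pipeline import call_clones

from conftest import A, I, N, gch_registry, matrix_from_calls


class TestPercentInaccessible:
    @pytest.mark.parametrize("n_inacc, expected", [
        (6, 40.0), (0, 0.0), (15, 100.0),
    ])
    def test_formula(self, n_inacc, expected):
        rows = [[I] if k < n_inacc else [A] for k in range(15)]
        matrix = matrix_from_calls(rows, [10], gch_registry([10]))
        stat = na.percent_inaccessible(matrix, 10)
        assert stat.percent_inaccessible == pytest.approx(expected)
        assert stat.n_inaccessible == n_inacc
        assert stat.n_accessible == 15 - n_inacc

    def test_ambiguous_excluded_from_denominator(self):
        matrix = matrix_from_calls([[I], [I], [A], [N], [N]], [10],
                                   gch_registry([10]))
        stat = na.percent_inaccessible(matrix, 10)
        assert stat.percent_inaccessible == pytest.approx(100 * 2 / 3)
        assert stat.n_ambiguous == 2

    def test_all_ambiguous_is_undefined_not_zero(self):
        matrix = matrix_from_calls([[N], [N]], [10], gch_registry([10]))
        stat = na.percent_inaccessible(matrix, 10)
        assert not stat.defined
        assert np.isnan(stat.percent_inaccessible)

    def test_non_gch_site_rejected(self, simulated_matrix):
        matrix, _ = simulated_matrix
        ch = matrix.registry.ch_sites[0]
        with pytest.raises(ValueError, match="not a GCH"):
            na.percent_inaccessible(matrix, ch)

    def test_conservation_at_every_site(self, simulated_matrix):
        matrix, _ = simulated_matrix
        for site in matrix.registry.gch_sites:
            stat = na.percent_inaccessible(matrix, site)
            assert (stat.n_inaccessible + stat.n_accessible
                    + stat.n_ambiguous) == matrix.n_clones

    def test_invariant_under_clone_reordering(self, simulated_matrix):
        matrix, _ = simulated_matrix
        rng = np.random.default_rng(0)
        order = rng.permutation(matrix.clone_ids)
        shuffled = matrix.subset(list(order))
        for site in matrix.registry.gch_sites:
            assert (na.percent_inaccessible(shuffled, site)
                    == na.percent_inaccessible(matrix, site))


class TestWindowProfile:
    def test_two_sites_one_window(self):
        stats = pd.DataFrame({"site": [10, 50],
                              "percent_inaccessible": [40.0, 60.0]})
        prof = na.window_profile(stats, window=100, length=100)
        assert len(prof) == 1
        assert prof["mean_percent_inaccessible"].iloc[0] == 50.0
        assert prof["n_sites"].iloc[0] == 2

    def test_single_site_identity(self):
        stats = pd.DataFrame({"site": [30],
                              "percent_inaccessible": [73.0]})
        prof = na.window_profile(stats, window=100, length=100)
        assert prof["mean_percent_inaccessible"].iloc[0] == 73.0

    def test_zero_conservation_and_empty_flag(self):
        stats = pd.DataFrame({"site": [10, 150],
                              "percent_inaccessible": [0.0, 0.0]})
        prof = na.window_profile(stats, window=100, length=300)
        assert (prof.loc[~prof["empty"],
                         "mean_percent_inaccessible"] == 0.0).all()
        assert prof["empty"].tolist() == [False, False, True]
        assert np.isnan(
            prof.loc[prof["empty"], "mean_percent_inaccessible"]).all()


class TestSelectTestSites:
    def test_nearest_to_window_center(self):
        reg = gch_registry([20, 60, 140])
        assert na.select_test_sites(reg, stride=100) == [60, 140]

    def test_one_site_per_window_identity(self):
        reg = gch_registry([50, 150, 250])
        assert na.select_test_sites(reg, stride=100) == [50, 150, 250]

    def test_empty_registry(self):
        assert na.select_test_sites(gch_registry([]), stride=100) == []

    def test_tie_broken_toward_smaller_coordinate(self):
        reg = gch_registry([40, 60])
        assert na.select_test_sites(reg, stride=100) == [40]


class TestChiSquare:
    def test_hand_computed_example(self):
        """A=(12 acc, 3 inacc) vs B=(4, 11): expected counts (8,7,8,7),
        Pearson chi-square 8.571, p 0.0034."""
        stat, p = na.chi_square_2x2(np.array([[12, 3], [4, 11]]))
        assert stat == pytest.approx(8.571, abs=5e-4)
        assert p == pytest.approx(0.0034, abs=2e-4)

    def test_identical_counts_give_zero(self):
        stat, p = na.chi_square_2x2(np.array([[8, 7], [8, 7]]))
        assert stat == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_zero_margin_undefined(self):
        stat, p = na.chi_square_2x2(np.array([[0, 15], [0, 12]]))
        assert np.isnan(stat) and np.isnan(p)

    def test_matches_direct_formula_on_sweep(self):
        """Pearson statistic equals N(ad-bc)^2/(r1 r2 c1 c2) on a grid."""
        rng = np.random.default_rng(1)
        tables = rng.integers(0, 15, size=(500, 2, 2))
        stat, _ = na.chi_square_2x2(tables)
        a, b = tables[:, 0, 0], tables[:, 0, 1]
        c, d = tables[:, 1, 0], tables[:, 1, 1]
        n = a + b + c + d
        with np.errstate(divide="ignore", invalid="ignore"):
            direct = (n * (a * d - b * c) ** 2
                      / ((a + b) * (c + d) * (a + c) * (b + d)))
        both = ~np.isnan(stat) & ~np.isnan(direct)
        assert np.allclose(stat[both], direct[both])
        assert np.array_equal(np.isnan(stat), np.isnan(direct))


class TestExactTest:
    @staticmethod
    def _enumeration_midp(a, b, c, d):
        """Independent mid-p oracle via math.comb enumeration."""
        from math import comb
        n1, n2, m, n = a + b, c + d, a + c, a + b + c + d
        denom = comb(n, m)
        lo, hi = max(0, m - n2), min(m, n1)
        probs = [comb(n1, k) * comb(n2, m - k) / denom
                 for k in range(lo, hi + 1)]
        p_obs = comb(n1, a) * comb(n2, m - a) / denom
        eps = 1e-9 * p_obs
        smaller = sum(p for p in probs if p < p_obs - eps)
        equal = sum(p for p in probs if abs(p - p_obs) <= eps)
        return smaller + 0.5 * equal

    def test_midp_matches_enumeration(self):
        for a in range(5):
            for b in range(5):
                for c in range(5):
                    for d in range(5):
                        if a + b + c + d == 0:
                            continue
                        table = np.array([[a, b], [c, d]])
                        assert na.exact_test_2x2(table) == pytest.approx(
                            self._enumeration_midp(a, b, c, d), abs=1e-10)

    def test_fisher_option_matches_scipy(self):
        table = np.array([[12, 3], [4, 11]])
        assert na.exact_test_2x2(table, method="fisher") == pytest.approx(
            sstats.fisher_exact(table)[1])


class TestCompareConditions:
    def _two_matrices(self, counts_a, counts_b):
        site, reg = 10, gch_registry([10])
        rows_a = [[A]] * counts_a[0] + [[I]] * counts_a[1]
        rows_b = [[A]] * counts_b[0] + [[I]] * counts_b[1]
        return (matrix_from_calls(rows_a, [site], reg),
                matrix_from_calls(rows_b, [site], reg))

    def test_example_counts(self):
        ma, mb = self._two_matrices((12, 3), (4, 11))
        result = na.compare_conditions(ma, mb, test_sites=[10])
        assert result["statistic"].iloc[0] == pytest.approx(8.571, abs=5e-4)
        assert result["pvalue"].iloc[0] == pytest.approx(0.0034, abs=2e-4)

    def test_identical_conditions_symmetric(self):
        ma, mb = self._two_matrices((8, 7), (8, 7))
        result = na.compare_conditions(ma, mb, test_sites=[10])
        assert result["statistic"].iloc[0] == pytest.approx(0.0)
        assert result["pvalue"].iloc[0] == pytest.approx(1.0)

    def test_zero_margin_reported_undefined(self):
        ma, mb = self._two_matrices((0, 15), (0, 12))
        result = na.compare_conditions(ma, mb, test_sites=[10])
        assert result["undefined"].iloc[0]

    def test_bh_adjustment_option(self, gpc_only_reference):
        open_m = na.ChromatinStateModel(states=(
            na.CellState(weight=1.0, linker_accessibility=0.9),))
        closed = na.ChromatinStateModel(states=(
            na.CellState(weight=1.0, linker_accessibility=0.1),))
        sim_a = na.simulate_clones(gpc_only_reference, open_m,
                                   noise=na.NoiseModel(seed=1), n_clones=30)
        sim_b = na.simulate_clones(gpc_only_reference, closed,
                                   noise=na.NoiseModel(seed=2), n_clones=30)
        ma, _ = call_clones(gpc_only_reference, sim_a.clones)
        mb, _ = call_clones(gpc_only_reference, sim_b.clones)
        result = na.compare_conditions(ma, mb, adjust="bh")
        assert "qvalue" in result.columns
        ok = ~result["pvalue"].isna()
        assert (result.loc[ok, "qvalue"] >= result.loc[ok, "pvalue"]).all()


class TestFootprints:
    # GCH sites every 20 bp plus flanking context sites
    POSITIONS = [60, 100, 120, 140, 160, 180, 200, 220, 240, 260, 290]

    def _clone(self, inaccessible):
        return [I if p in inaccessible else A for p in self.POSITIONS]

    def test_nucleosome_sized_span(self):
        inacc = set(range(100, 261, 20))
        matrix = matrix_from_calls([self._clone(inacc)], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        fps = na.call_footprints(matrix, min_span=150)
        assert len(fps) == 1
        fp = fps[0]
        assert (fp.start, fp.end, fp.span) == (100, 260, 161)
        assert fp.classification == NUCLEOSOME_SIZED

    def test_subthreshold_span(self):
        inacc = set(range(100, 241, 20))
        matrix = matrix_from_calls([self._clone(inacc)], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        fps = na.call_footprints(matrix, min_span=150)
        assert len(fps) == 1
        assert fps[0].span == 141
        assert fps[0].classification == SUBTHRESHOLD

    def test_fully_accessible_clone_empty(self):
        matrix = matrix_from_calls([self._clone(set())], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        assert na.call_footprints(matrix) == []

    def test_ambiguous_does_not_break_run_or_extend_ends(self):
        calls = [A, I, I, N, I, I, A, A, A, A, A]
        matrix = matrix_from_calls([calls], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        fps = na.call_footprints(matrix, min_span=150)
        assert len(fps) == 1
        assert (fps[0].start, fps[0].end) == (100, 180)
        # trailing ambiguity must not extend the footprint
        calls2 = [A, I, I, I, N, A, A, A, A, A, A]
        matrix2 = matrix_from_calls([calls2], self.POSITIONS,
                                    gch_registry(self.POSITIONS))
        assert na.call_footprints(matrix2)[0].end == 140

    def test_midpoint_extension_widens_span(self):
        """The optional midpoint convention extends each boundary
        halfway toward the flanking accessible site."""
        inacc = set(range(100, 241, 20))
        matrix = matrix_from_calls([self._clone(inacc)], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        fp = na.call_footprints(matrix, min_span=150,
                                extend_to_midpoints=True)[0]
        assert (fp.start, fp.end) == (80, 250)   # midpoints of 60/100, 240/260
        assert fp.classification == NUCLEOSOME_SIZED

    def test_open_runs_mirror_footprints(self):
        acc = set(range(100, 261, 20))
        calls = [A if p in acc else I for p in self.POSITIONS]
        matrix = matrix_from_calls([calls], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        runs = na.call_open_runs(matrix, min_span=150)
        assert len(runs) == 1
        assert (runs[0].start, runs[0].end, runs[0].span) == (100, 260, 161)
        assert runs[0].classification == NUCLEOSOME_SIZED

    def test_min_span_larger_than_amplicon(self):
        matrix = matrix_from_calls([self._clone(set())], self.POSITIONS,
                                   gch_registry(self.POSITIONS))
        runs = na.call_open_runs(matrix, min_span=10_000)
        assert all(r.classification == SUBTHRESHOLD for r in runs)

    def test_duality_on_unambiguous_matrix(self, simulated_matrix):
        """Footprints of the polarity-flipped matrix equal open runs."""
        matrix, _ = simulated_matrix
        flipped_calls = matrix.calls.copy()
        ret = matrix.calls == int(Call.RETAINED)
        conv = matrix.calls == int(Call.CONVERTED)
        flipped_calls[ret] = int(Call.CONVERTED)
        flipped_calls[conv] = int(Call.RETAINED)
        flipped = na.CloneCallMatrix(calls=flipped_calls,
                                     registry=matrix.registry,
                                     clone_qc=matrix.clone_qc)
        assert (na.call_footprints(flipped, min_span=150)
                == na.call_open_runs(matrix, min_span=150))

    def test_simulated_ndr_detected_in_every_clone(self):
        """A 200-bp NDR flanked by nucleosomes is recovered per clone
        with >= 80% overlap."""
        ref = na.make_reference(700, 20, seed=4)
        ndr = (250, 450)
        model = na.ChromatinStateModel(states=(
            na.CellState(weight=1.0,
                         protected_intervals=((0, 250), (450, 700)),
                         linker_accessibility=1.0),))
        sim = na.simulate_clones(ref, model, noise=na.NoiseModel(seed=8),
                                 n_clones=50)
        matrix, _ = call_clones(ref, sim.clones)
        runs = footprints_to_frame(na.call_open_runs(matrix, min_span=147))
        for clone_id in matrix.clone_ids:
            mine = runs[runs["clone_id"] == clone_id]
            overlaps = (mine["end"].clip(upper=ndr[1] - 1)
                        - mine["start"].clip(lower=ndr[0]) + 1)
            assert (overlaps / (ndr[1] - ndr[0])).max() >= 0.8


class TestBubbleMatrix:
    def test_all_accessible_structure(self):
        positions = [10, 30, 50]
        matrix = matrix_from_calls([[A, A, A], [A, A, A]], positions,
                                   gch_registry(positions))
        structure = na.bubble_matrix(matrix)
        assert structure["sites"] == positions
        states = [s for m in structure["molecules"] for s in m["states"]]
        assert states == ["accessible"] * 6
        assert all(m["bars"] == [] for m in structure["molecules"])

    def test_nucleosome_bar_spans_footprint(self):
        positions = list(range(100, 261, 20)) + [290]
        calls = [[I] * 9 + [A]]
        matrix = matrix_from_calls(calls, positions,
                                   gch_registry(positions))
        structure = na.bubble_matrix(matrix)
        assert structure["molecules"][0]["bars"] == [[100, 260]]

    def test_serialisation_round_trip(self, simulated_matrix):
        matrix, _ = simulated_matrix
        structure = na.bubble_matrix(matrix)
        assert bubble_round_trip(structure) == structure
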