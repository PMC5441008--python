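import itertools
import math

import numpy as np
import pandas as pd
import pytest

from ptxmap.io import DHMatrix, MISSING
from ptxmap import binning, linkage
from ptxmap.linkage import (
    kosambi,
    kosambi_inverse,
    lod_from_counts,
    rf_lod,
    group_markers,
    order_regression,
    order_ml,
    detect_double_crossovers,
    phase_align,
    iterative_clean,
    spearman_order,
    RemovalCriteria,
    _fit_positions,
    _distance_weight,
)
from ptxmap.simulate import SimScenario, simulate_family


class TestKosambi:
    def test_identities(self):
        assert kosambi(0.0) == 0.0
        assert kosambi(0.03) == pytest.approx(3.0036, abs=1e-3)
        assert round(kosambi(0.03)) == 3
        assert kosambi_inverse(10.0) == pytest.approx(0.5 * math.tanh(0.2), abs=1e-12)

    def test_round_trip(self):
        for r in (0.01, 0.1, 0.25, 0.45):
            assert kosambi_inverse(kosambi(r)) == pytest.approx(r, abs=1e-10)

    def test_domain(self):
        with pytest.raises(ValueError):
            kosambi(0.5)
        with pytest.raises(ValueError):
            kosambi(-0.01)


class TestLod:
    def test_closed_forms(self):
        assert float(lod_from_counts(0, 100)) == pytest.approx(100 * math.log10(2), abs=1e-9)
        assert float(lod_from_counts(50, 100)) == pytest.approx(0.0, abs=1e-9)
        assert float(lod_from_counts(10, 100)) == pytest.approx(15.9849, abs=1e-3)

    def test_monotone_decreasing_in_r(self):
        lods = [float(lod_from_counts(r, 100)) for r in range(0, 51)]
        assert all(a >= b - 1e-12 for a, b in zip(lods, lods[1:]))

    def test_rf_lod_wrapper(self):
        a = np.zeros(100, dtype=np.int8)
        b = a.copy()
        b[:10] = 1
        pl = rf_lod(a, b, ids=("x", "y"))
        assert pl.r_hat == pytest.approx(0.1)
        assert pl.n == 100


class TestGrouping:
    def test_two_chromosomes_two_groups(self, two_chrom_scenario):
        fam = simulate_family(two_chrom_scenario, 300, "F", seed=2)
        mat = fam.dh["P1"]
        R, N = binning.pairwise_counts(mat)
        lod = lod_from_counts(R, N)
        rf = R / np.maximum(N, 1)
        groups, unplaced = group_markers(mat.marker_ids, lod, 3.0, rf_matrix=rf)
        assert len(groups) == 2
        for g in groups:
            chroms = {str(m)[1:3] for m in g}
            assert len(chroms) == 1

    def test_infinite_lod_all_unplaced(self, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        R, N = binning.pairwise_counts(mat)
        lod = lod_from_counts(R, N)
        groups, unplaced = group_markers(mat.marker_ids, lod, np.inf)
        assert groups == [] and len(unplaced) == mat.n_markers


def _counts_from_rf(rf_pairs, n, ids):
    """Exact (R, N) matrices from prescribed pairwise rfs."""
    m = len(ids)
    R = np.zeros((m, m))
    N = np.full((m, m), float(n))
    for (i, j), r in rf_pairs.items():
        R[i, j] = R[j, i] = r * n
    return R, N


class TestOrdering:
    def test_three_marker_chain(self):
        ids = ["A", "B", "C"]
        R, N = _counts_from_rf({(0, 1): 0.05, (1, 2): 0.05, (0, 2): 0.10}, 1000, ids)
        order, pos, obj, unplaced = order_regression(ids, R, N)
        assert list(order) in (["A", "B", "C"], ["C", "B", "A"])
        assert pos.max() == pytest.approx(kosambi(0.05) * 2, abs=0.15)
        assert not unplaced

    def test_two_markers_single_interval(self):
        ids = ["A", "B"]
        R, N = _counts_from_rf({(0, 1): 0.1}, 500, ids)
        order, pos, obj, _ = order_regression(ids, R, N)
        assert pos.max() == pytest.approx(kosambi(0.1), abs=1e-6)

    def test_single_marker_ml(self):
        order, pos, cost = order_ml(["only"], np.zeros((1, 1)), np.ones((1, 1)))
        assert list(order) == ["only"] and pos.tolist() == [0.0]

    def test_brute_force_oracle_small_groups(self):
        """Both algorithms reach the exhaustive optimum of their objectives
        on simulated groups of <= 8 markers."""
        sc = SimScenario(
            n_chromosomes=1, chrom_lengths_bp=(30_000_000,), chrom_lengths_cM=(60.0,),
            n_markers=7, seg_mix={"testcross_P1": 1.0}, error_rate=0.0,
            missing_rate=0.0, seed=23,
        )
        fam = simulate_family(sc, 150, "F", seed=31)
        mat = fam.dh["P1"]
        R, N = binning.pairwise_counts(mat)
        m = mat.n_markers
        D, W = _distance_weight(R, N)
        best_obj = min(
            _fit_positions(list(p), D, W)[1]
            for p in itertools.permutations(range(m)) if p[0] < p[-1]
        )
        _, _, obj, _ = order_regression(mat.marker_ids, R, N)
        assert obj <= best_obj + 1e-6
        cost_best = min(
            sum(R[a, b] for a, b in zip(p, p[1:]))
            for p in itertools.permutations(range(m)) if p[0] < p[-1]
        )
        _, _, cost = order_ml(mat.marker_ids, R, N)
        assert cost == pytest.approx(cost_best, abs=1e-9)

    def test_error_free_group_recovers_truth(self, one_chrom_scenario, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        R, N = binning.pairwise_counts(mat)
        lay = one_chrom_scenario.layout().set_index("marker")
        for fn in (order_regression, order_ml):
            out = fn(mat.marker_ids, R, N)
            order = out[0]
            truth = lay.loc[[str(m) for m in order], "cM"].to_numpy()
            # correct up to reversal and swaps of near-coincident markers
            rho = abs(pd.Series(truth).corr(pd.Series(range(len(truth))), method="spearman"))
            assert rho > 0.999

    def test_map_length_reversal_invariant(self, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        R, N = binning.pairwise_counts(mat)
        order, pos, _, _ = order_regression(mat.marker_ids, R, N)
        idx = {m: i for i, m in enumerate(mat.marker_ids)}
        rev = [idx[m] for m in order[::-1]]
        D, W = _distance_weight(R, N)
        pos_rev, _ = _fit_positions(rev, D, W)
        assert pos.max() == pytest.approx(pos_rev.max(), rel=1e-6)
        assert pos.min() == 0.0


class TestDoubleCrossovers:
    def test_clean_data_zero(self, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        lay_order = np.argsort([str(m) for m in mat.marker_ids])  # ids follow cM order
        counts = detect_double_crossovers(phase_align(mat.calls[lay_order]))
        assert counts.max() <= 1  # genuine doubles only, interference-suppressed

    def test_injected_miscall_detected(self, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        calls = phase_align(mat.calls.copy())
        base = detect_double_crossovers(calls)
        # flip a call whose flanking calls agree with it, so the miscall
        # becomes a fresh singleton
        j = int(np.flatnonzero((calls[9] == calls[11]) & (calls[10] == calls[9]))[0])
        calls[10, j] ^= 1
        counts = detect_double_crossovers(calls)
        assert counts[10] == base[10] + 1
        others = np.delete(counts - base, 10)
        assert np.all(others == 0)

    def test_error_rate_expectation(self, one_chrom_family):
        """Miscalls at rate e produce ~ n*e singletons per marker (small-r
        limit, flanks agreeing)."""
        rng = np.random.default_rng(12)
        e = 0.01
        calls = phase_align(one_chrom_family.dh["P1"].calls.copy())
        flips = rng.random(calls.shape) < e
        calls = np.where(flips, calls ^ 1, calls).astype(np.int8)
        counts = detect_double_crossovers(calls)[1:-1]  # terminal markers see fewer
        n = calls.shape[1]
        expected = n * e
        se = math.sqrt(expected / len(counts))
        assert abs(counts.mean() - expected) < 4 * se + 0.5


class TestIterativeClean:
    def test_clean_group_no_removals(self, one_chrom_family):
        mat = one_chrom_family.dh["P1"]
        order, pos, log = iterative_clean(mat, [str(m) for m in mat.marker_ids])
        assert len(order) == mat.n_markers
        assert len(log) == 0

    def test_planted_bad_markers_removed(self, one_chrom_family):
        rng = np.random.default_rng(77)
        mat = one_chrom_family.dh["P1"]
        calls = mat.calls.copy()
        bad = [3, 12, 21]
        for b in bad:
            flip = rng.random(calls.shape[1]) < 0.05
            calls[b] = np.where(flip, calls[b] ^ 1, calls[b])
        noisy = DHMatrix(mat.marker_ids, mat.offspring_ids, calls)
        order, pos, log = iterative_clean(noisy, [str(m) for m in mat.marker_ids])
        removed = set(log["marker"])
        assert {str(mat.marker_ids[b]) for b in bad} <= removed
        assert log["iteration"].astype(str).str.extract(r"(\d+)")[0].astype(float).max() <= 5

    def test_degenerate_group_aborts(self):
        row = np.zeros(40, dtype=np.int8)
        mat = DHMatrix(np.array(["a"], object), np.array([f"o{i}" for i in range(40)]),
                       row[None, :])
        with pytest.raises(RuntimeError):
            iterative_clean(mat, ["a"])

    def test_criteria_validation(self):
        with pytest.raises(ValueError):
            RemovalCriteria(chisq_contrib_max=0.0)


class TestSpearmanOrder:
    def test_identical_and_reversed(self):
        a = pd.Series([0.0, 1, 2, 3, 4], index=list("abcde"))
        rho, p, n = spearman_order(a, a)
        assert rho == pytest.approx(1.0) and n == 5
        rho_rev, _, _ = spearman_order(a, a.iloc[::-1].rank())
        assert rho_rev == pytest.approx(1.0)  # orientation-normalised

    def test_single_swap(self):
        a = pd.Series([1.0, 2, 3, 4, 5], index=list("abcde"))
        b = pd.Series([1.0, 3, 2, 4, 5], index=list("abcde"))
        rho, p, n = spearman_order(a, b)
        assert rho == pytest.approx(0.9)

    def test_too_few_shared(self):
        a = pd.Series([0.0, 1], index=["x", "y"])
        rho, p, n = spearman_order(a, a)
        assert math.isnan(rho) and n == 2
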