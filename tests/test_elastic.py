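"""Elastic shape analysis: SRSF closed forms, metric axioms, DP vs exhaustive
lattice enumeration, Karcher mean behavior, warp validity, mode plumbing."""

import itertools

import numpy as np
import pytest

from conftest import unit_train
from lickshape.elastic import (
    WarpFn,
    align_pair,
    align_population,
    candidate_steps,
    fr_distance,
    interlick_esa,
    karcher_mean,
    random_breakpoints,
    random_interval_esa,
    srsf_transform,
    warp_function,
)
from lickshape.elastic import _dp_warp  # white-box: DP entry point for oracle test
from lickshape.rate_phase import InterlickPartition
from lickshape.spike_io import SmoothedTrain


def bump(centre, width=0.05, n=200, lo=0.0, hi=1.0):
    g = np.linspace(lo, hi, n)
    return SmoothedTrain(g, np.exp(-0.5 * ((g - centre) / width) ** 2), 1.0)


def enumerate_lattice_paths(q1, q2, steps):
    """Exhaustive minimum over all monotone lattice paths built from `steps`.

    Recomputes each edge cost independently with the same trapezoid rule the
    DP uses, but explores paths by explicit recursion.
    """
    n = len(q1)
    h = 1.0 / (n - 1)

    def edge_cost(i0, j0, i1, j1):
        p, q = i1 - i0, j1 - j0
        slope = q / p
        c = 0.0
        for k in range(p + 1):
            y = j0 + slope * k
            yi = min(int(np.floor(y)), n - 2)
            fy = y - yi
            q2v = q2[yi] * (1 - fy) + q2[yi + 1] * fy
            d = q1[i0 + k] - q2v * np.sqrt(slope)
            c += (0.5 if k in (0, p) else 1.0) * d * d
        return c * h

    best = [np.inf]

    def recurse(i, j, acc):
        if acc >= best[0]:
            return
        if i == n - 1 and j == n - 1:
            best[0] = acc
            return
        for p, q in steps:
            if i + p <= n - 1 and j + q <= n - 1:
                recurse(i + p, j + q, acc + edge_cost(i, j, i + p, j + q))

    recurse(0, 0, 0.0)
    return best[0]


class TestSRSF:
    def test_constant_function_zero_srsf(self):
        # tolerance is √(float roundoff): the SRSF takes a square root of
        # the finite-difference derivative
        q = srsf_transform(unit_train(np.full(100, 3.0))).q_values
        np.testing.assert_allclose(q, 0.0, atol=1e-6)

    def test_identity_function_unit_srsf(self):
        g = np.linspace(0, 1, 500)
        q = srsf_transform(SmoothedTrain(g, g.copy(), 1.0)).q_values
        np.testing.assert_allclose(q, 1.0, atol=1e-9)

    def test_quadratic_closed_form(self):
        g = np.linspace(0, 1, 1000)
        q = srsf_transform(SmoothedTrain(g, g**2, 1.0)).q_values
        np.testing.assert_allclose(q[1:-1], np.sqrt(2 * g[1:-1]), atol=1e-3)


class TestFisherRaoDistance:
    def test_identity_of_indiscernibles(self):
        f = bump(0.4)
        assert fr_distance(f, f) == 0.0

    def test_linear_vs_quadratic_closed_form(self):
        g = np.linspace(0, 1, 1000)
        f = SmoothedTrain(g, g.copy(), 1.0)
        h = SmoothedTrain(g, g**2, 1.0)
        expected = np.sqrt(2 - 4 * np.sqrt(2) / 3)
        assert fr_distance(f, h) == pytest.approx(expected, abs=1e-3)

    def test_warp_invariance(self):
        # dist(f∘γ, g∘γ) = dist(f, g) for boundary-fixed γ
        g = np.linspace(0, 1, 1000)
        f = SmoothedTrain(g, np.sin(2 * np.pi * g) + 1.5, 1.0)
        h = SmoothedTrain(g, np.cos(2 * np.pi * g) + 1.5, 1.0)
        d0 = fr_distance(f, h)
        rng = np.random.default_rng(0)
        for _ in range(20):
            knots = np.sort(rng.uniform(0.1, 0.9, 3))
            vals = np.sort(rng.uniform(0.1, 0.9, 3))
            gamma = WarpFn(
                np.concatenate([[0], knots, [1]]), np.concatenate([[0], vals, [1]])
            )
            dw = fr_distance(warp_function(f, gamma), warp_function(h, gamma))
            assert dw == pytest.approx(d0, abs=1e-2)

    def test_metric_axioms_on_random_triples(self):
        rng = np.random.default_rng(1)
        g = np.linspace(0, 1, 300)
        trains = [
            SmoothedTrain(g, np.abs(np.convolve(rng.normal(size=300),
                                                np.ones(30) / 30, "same")), 1.0)
            for _ in range(3)
        ]
        d01 = fr_distance(trains[0], trains[1])
        d12 = fr_distance(trains[1], trains[2])
        d02 = fr_distance(trains[0], trains[2])
        assert d01 == pytest.approx(fr_distance(trains[1], trains[0]), abs=1e-8)
        assert d02 <= d01 + d12 + 1e-8

    def test_mismatched_domains_rejected(self):
        with pytest.raises(ValueError, match="domain"):
            fr_distance(bump(0.4, hi=1.0), bump(0.4, hi=2.0))


class TestDPAlignment:
    def test_self_alignment_is_identity(self):
        f = bump(0.5)
        res = align_pair(f, f)
        grid = res.warp.grid
        assert np.max(np.abs(res.warp.values - grid)) < 1.5 / (grid.size - 1)
        assert res.distance <= 1e-6

    def test_shifted_bumps_reconcile(self):
        f, g = bump(0.35), bump(0.6)
        res = align_pair(f, g)
        assert res.distance < 0.05 * res.distance_unaligned
        assert np.max(np.abs(res.aligned.values - f.values)) < 0.05
        # warp far from identity: the timing difference moved into γ
        assert np.max(np.abs(res.warp.values - res.warp.grid)) > 0.1

    def test_two_peaks_are_preserved(self):
        from scipy.signal import find_peaks

        g = np.linspace(0, 1, 200)
        one = SmoothedTrain(g, np.exp(-0.5 * ((g - 0.5) / 0.08) ** 2), 1.0)
        two_v = (
            np.exp(-0.5 * ((g - 0.3) / 0.05) ** 2)
            + np.exp(-0.5 * ((g - 0.7) / 0.05) ** 2)
        ) / 2
        two = SmoothedTrain(g, two_v, 1.0)
        res = align_pair(one, two)
        peaks, _ = find_peaks(res.aligned.values, height=0.1)
        assert len(peaks) == 2

    def test_alignment_never_increases_distance(self):
        rng = np.random.default_rng(2)
        g = np.linspace(0, 1, 150)
        for k in range(5):
            f = SmoothedTrain(g, np.abs(np.convolve(rng.normal(size=150),
                                                    np.ones(20) / 20, "same")), 1.0)
            h = SmoothedTrain(g, np.abs(np.convolve(rng.normal(size=150),
                                                    np.ones(20) / 20, "same")), 1.0)
            res = align_pair(f, h)
            assert res.distance <= res.distance_unaligned + 1e-9

    @pytest.mark.parametrize("n", [8, 10])
    def test_dp_matches_exhaustive_enumeration(self, n):
        # with steps up to n−1 the DP searches all monotone lattice paths;
        # the oracle enumerates them explicitly
        rng = np.random.default_rng(7)
        steps = candidate_steps(n - 1)
        for k in range(3):
            q1 = rng.normal(size=n)
            q2 = rng.normal(size=n)
            _, dp_cost = _dp_warp(q1, q2, steps)
            oracle = enumerate_lattice_paths(q1, q2, [tuple(s) for s in steps])
            assert dp_cost == pytest.approx(oracle, abs=1e-12)

    def test_warp_validity_and_inverse(self):
        res = align_pair(bump(0.35), bump(0.6))
        w = res.warp
        assert np.all(np.diff(w.values) > 0)
        assert w.values[0] == pytest.approx(0.0) and w.values[-1] == pytest.approx(1.0)
        round_trip = w.compose(w.inverse())
        assert np.max(np.abs(round_trip.values - w.grid)) < 0.02


class TestKarcherMean:
    def test_identical_trains_fixed_point(self):
        f = bump(0.4)
        res = karcher_mean([f, f, f])
        assert np.max(np.abs(res.mean.values - f.values)) < 0.01

    def test_shifted_bumps_give_unimodal_mean(self):
        from scipy.signal import find_peaks

        trains = [bump(0.35), bump(0.6)]
        res = karcher_mean(trains)
        pk, _ = find_peaks(res.mean.values, height=0.1 * res.mean.values.max())
        assert len(pk) == 1
        cross = np.mean([t.values for t in trains], axis=0)
        pk2, _ = find_peaks(cross, height=0.1 * cross.max())
        assert len(pk2) == 2

    def test_objective_trace_nonincreasing(self):
        rng = np.random.default_rng(3)
        g = np.linspace(0, 1, 150)
        trains = [
            SmoothedTrain(g, np.abs(np.convolve(rng.normal(size=150),
                                                np.ones(25) / 25, "same")), 1.0)
            for _ in range(5)
        ]
        res = karcher_mean(trains, max_iter=10)
        assert all(b <= a + 1e-12 for a, b in zip(res.objective_trace,
                                                  res.objective_trace[1:]))

    def test_mean_beats_cross_sectional_mean(self):
        trains = [bump(0.3), bump(0.5), bump(0.7)]
        res = karcher_mean(trains)
        g = trains[0].grid
        cross = SmoothedTrain(g, np.mean([t.values for t in trains], axis=0), 1.0)
        obj_karcher = sum(align_pair(res.mean, t).distance ** 2 for t in trains)
        obj_cross = sum(align_pair(cross, t).distance ** 2 for t in trains)
        assert obj_karcher <= obj_cross + 1e-9


class TestPopulationModes:
    def test_identical_population_gives_identity_warps(self):
        f = bump(0.5)
        res = align_population([f] * 4, n_grid=100)
        for w in res.warp_fns:
            assert np.max(np.abs(w.values - w.grid)) < 0.02

    def test_interlick_concatenation_structure(self):
        g = np.arange(0, 650, 1.0)
        rng = np.random.default_rng(5)
        trains = [
            SmoothedTrain(g, np.abs(np.convolve(rng.normal(size=g.size),
                                                np.ones(40) / 40, "same")), 1.0)
            for _ in range(3)
        ]
        part = InterlickPartition(np.array([0.0, 130, 260, 390, 520, 650]))
        res = interlick_esa(trains, [part] * 3, seg_grid=30, karcher_iters=2)
        assert len(res.aligned_trains) == 3 and len(res.warp_fns) == 3
        for w in res.warp_fns:
            # concatenated warp is continuous, increasing, boundary-fixed
            assert np.all(np.diff(w.values) > 0)
            assert w.values[0] == pytest.approx(0.0)
            assert w.values[-1] == pytest.approx(1.0)
            # passes through the segment joins at multiples of 1/5
            for i in range(1, 5):
                assert w(np.array([i / 5]))[0] == pytest.approx(i / 5, abs=1e-9)

    def test_random_breakpoints_determinism_and_min_gap(self):
        rng1 = np.random.default_rng(9)
        rng2 = np.random.default_rng(9)
        b1 = random_breakpoints(650.0, rng1)
        b2 = random_breakpoints(650.0, rng2)
        np.testing.assert_array_equal(b1, b2)
        edges = np.concatenate([[0], b1, [650.0]])
        assert np.diff(edges).min() >= 20.0
        with pytest.raises(ValueError):
            random_breakpoints(80.0, rng1)

    def test_random_interval_results_paired_and_seeded(self):
        g = np.arange(0, 650, 1.0)
        rng = np.random.default_rng(6)
        trains = [
            SmoothedTrain(g, np.abs(np.convolve(rng.normal(size=g.size),
                                                np.ones(40) / 40, "same")), 1.0)
            for _ in range(3)
        ]
        spans = [650.0, 660.0, 640.0]
        r1 = random_interval_esa(trains, spans, n_repeats=2, seed=4,
                                 seg_grid=25, karcher_iters=1)
        r2 = random_interval_esa(trains, spans, n_repeats=2, seed=4,
                                 seg_grid=25, karcher_iters=1)
        assert len(r1) == 2
        for a, b in zip(r1, r2):
            for wa, wb in zip(a.warp_fns, b.warp_fns):
                np.testing.assert_array_equal(wa.values, wb.values)
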