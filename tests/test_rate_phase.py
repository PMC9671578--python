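"""RP codes and separation scores, checked against brute-force enumeration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_trial
from lickshape.rate_phase import (
    Exclusion,
    InterlickPartition,
    dataset_rp_codes,
    interlick_partition,
    rp_code,
    separation_scores,
)
from lickshape.synthetic import GeneratorConfig, TasteCodeSpec, generate_neuron

LICKS6 = [0, 130, 260, 390, 520, 650]
PRE = [-780, -650, -520, -390, -260, -130]


def brute_force_combination(A, B, n_angles=1000):
    """Dense-angle grid oracle for the best separating line of any slope."""
    pts = np.vstack([A, B])
    best = 0.0
    for th in np.linspace(0, np.pi, n_angles, endpoint=False):
        u = np.array([np.cos(th), np.sin(th)])
        pa, pb = A @ u, B @ u
        allv = np.unique(np.concatenate([pa, pb]))
        cands = np.concatenate(
            [[-np.inf], (allv[1:] + allv[:-1]) / 2, allv, [np.inf]]
        )
        for c in cands:
            s1 = (pa < c).sum() + (pb >= c).sum()
            s2 = (pb < c).sum() + (pa >= c).sum()
            best = max(best, max(s1, s2) / len(pts))
    return best


class TestInterlickPartition:
    def test_direct_construction(self):
        part = interlick_partition(make_trial([50.0], PRE + LICKS6))
        assert isinstance(part, InterlickPartition)
        assert part.intervals == [(0, 130), (130, 260), (260, 390), (390, 520), (520, 650)]

    def test_too_few_post_licks_excluded(self):
        trial = make_trial([50.0], PRE + [0, 130, 260, 390, 520])
        part = interlick_partition(trial)
        assert isinstance(part, Exclusion) and part.reason == "too_few_licks"

    def test_no_spikes_in_intervals_excluded(self):
        trial = make_trial([-500.0, 1500.0], PRE + LICKS6)
        part = interlick_partition(trial)
        assert isinstance(part, Exclusion) and part.reason == "no_spikes"


class TestRPCode:
    def test_midpoint_spikes(self):
        licks = [0, 100, 200, 300, 400, 500]
        trial = make_trial([50.0, 150.0, 250.0], PRE + licks)
        part = interlick_partition(trial)
        code = rp_code(trial, part)
        assert code.R == pytest.approx(3 / 5)
        assert code.P == pytest.approx(0.5)

    def test_spike_on_starting_lick_has_phase_zero(self):
        trial = make_trial([130.0], PRE + LICKS6)
        code = rp_code(trial, interlick_partition(trial))
        assert code.P == pytest.approx(0.0)

    def test_unequal_intervals_printed_formula(self):
        # intervals [0,100), [100,300), then padding; spikes at 10, 150, 250
        licks = [0, 100, 300, 400, 500, 600]
        trial = make_trial([10.0, 150.0, 250.0], PRE + licks)
        part = interlick_partition(trial)
        code = rp_code(trial, part)
        # phases 0.10, 0.25, 0.75 → P = 11/30; R over the 5 declared intervals
        assert code.P == pytest.approx((0.10 + 0.25 + 0.75) / 3)
        assert code.R == pytest.approx(3 / 5)

    def test_per_interval_mean_variant(self):
        licks = [0, 100, 200, 300, 400, 500]
        trial = make_trial([10.0, 90.0, 150.0], PRE + licks)
        part = interlick_partition(trial)
        spike_mean = rp_code(trial, part).P
        interval_mean = rp_code(trial, part, per_interval_mean=True).P
        assert spike_mean == pytest.approx((0.1 + 0.9 + 0.5) / 3)
        assert interval_mean == pytest.approx((0.5 + 0.5) / 2)

    def test_dataset_codes_and_exclusions(self, rate_neuron):
        codes, exclusions = dataset_rp_codes(rate_neuron)
        n_codes = sum(len(v) for v in codes.values())
        assert n_codes + len(exclusions) == len(rate_neuron.trials)
        for lst in codes.values():
            for c in lst:
                assert c.R > 0 and 0 <= c.P < 1


class TestSeparationScores:
    def test_fully_separated_clouds(self):
        res = separation_scores([(1, 0.2), (2, 0.3)], [(5, 0.8), (6, 0.9)])
        assert res.rate_score == res.phase_score == res.combination_score == 1.0

    def test_collinear_alternating_points(self):
        res = separation_scores([(1, 0.5), (3, 0.5)], [(2, 0.5), (4, 0.5)])
        assert res.rate_score == pytest.approx(0.75)
        assert res.phase_score == pytest.approx(0.5)
        assert res.combination_score == pytest.approx(0.75)

    def test_diagonal_structure_needs_combination(self):
        # separable only by an oblique line
        A = [(1, 0.1), (2, 0.35), (3, 0.6)]
        B = [(1, 0.35), (2, 0.6), (3, 0.85)]
        res = separation_scores(A, B)
        assert res.combination_score == 1.0
        assert res.rate_score < 1.0 and res.phase_score < 1.0

    @given(st.data())
    @settings(max_examples=25, deadline=None)
    def test_exact_search_matches_brute_force(self, data):
        n_a = data.draw(st.integers(2, 6))
        n_b = data.draw(st.integers(2, 6))
        coords = st.tuples(
            st.floats(0, 10, allow_nan=False), st.floats(0, 1, exclude_max=True)
        )
        A = np.array(data.draw(st.lists(coords, min_size=n_a, max_size=n_a)))
        B = np.array(data.draw(st.lists(coords, min_size=n_b, max_size=n_b)))
        res = separation_scores(A, B)
        oracle = brute_force_combination(A, B)
        # exact search can only beat a finite angle grid
        assert res.combination_score >= oracle - 1e-12
        assert res.combination_score >= max(res.rate_score, res.phase_score)
        assert res.rate_score >= 0.5 and res.phase_score >= 0.5

    def test_invariances(self):
        rng = np.random.default_rng(4)
        A = np.column_stack([rng.uniform(0, 5, 6), rng.uniform(0, 1, 6)])
        B = np.column_stack([rng.uniform(2, 8, 6), rng.uniform(0, 1, 6)])
        res = separation_scores(A, B)
        swapped = separation_scores(B, A)
        assert res.rate_score == swapped.rate_score
        assert res.combination_score == swapped.combination_score
        shift = np.array([3.0, 0.2])
        shifted = separation_scores(A + shift, B + shift)
        assert res.combination_score == pytest.approx(shifted.combination_score)
        # rate score ignores any monotone transform of P
        warped = separation_scores(
            np.column_stack([A[:, 0], A[:, 1] ** 3]),
            np.column_stack([B[:, 0], B[:, 1] ** 3]),
        )
        assert res.rate_score == warped.rate_score

    def test_code_recovery_rate_vs_phase_neurons(self):
        rate_res, phase_res = [], []
        for seed, spec, out in (
            (31, TasteCodeSpec.rate_code(), rate_res),
            (32, TasteCodeSpec.phase_code(), phase_res),
        ):
            ds = generate_neuron(GeneratorConfig(seed=seed, n_trials_per_taste=20,
                                                 code_spec=spec))
            codes, _ = dataset_rp_codes(ds)
            # the most distinct pair under each spec
            res = separation_scores(codes["sucrose"], codes["water"])
            out.append(res)
        r, p = rate_res[0], phase_res[0]
        assert r.rate_score > r.phase_score
        assert r.combination_score >= r.rate_score
        assert p.phase_score > p.rate_score
        assert p.combination_score >= p.phase_score

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            separation_scores([(1, 0.5)], [(2, 0.5), (3, 0.5)])
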