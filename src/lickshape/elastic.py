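"""Elastic shape analysis of smoothed spike trains.

Functions are compared with the extended Fisher–Rao metric, computed through
the square-root slope function (SRSF) q(t) = sgn(f'(t))·√|f'(t)|, under which
the metric becomes the ordinary L² distance and is invariant to simultaneous
time warping of both functions.  Optimal pairwise alignment — the monotone,
boundary-fixed warp γ minimizing ‖q_f − (q_g∘γ)√γ'‖ — is found by dynamic
programming over a lattice of piecewise-linear warps.  A population of spike
trains is summarized by its Karcher mean (the function minimizing the sum of
squared Fisher–Rao distances) and each train is aligned to it: the aligned
trains retain rate information while the warp functions carry the timing
information removed by alignment.

Three alignment modes mirror the decoding analyses: the whole post-taste
window, the first five interlick intervals (each rescaled to [0,1], aligned
separately, and concatenated — warps then read directly as lick-phase maps),
and five randomized intervals of the same five-lick span, which serve as the
lick-agnostic control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import gcd
from typing import Optional, Sequence

import numpy as np
from numba import njit

from .spike_io import SmoothedTrain

log = logging.getLogger(__name__)

DEFAULT_GRID = 200       # DP samples for whole-window alignment
DEFAULT_SEGMENT_GRID = 50  # DP samples per interlick segment
DEFAULT_MAX_SLOPE = 7
MIN_RANDOM_SEGMENT_MS = 20.0


# ---------------------------------------------------------------------------
# SRSF transform and Fisher–Rao distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SRSF:
    """Square-root slope function on a uniform grid."""

    grid: np.ndarray
    q_values: np.ndarray


def _uniform_grid(f: SmoothedTrain) -> np.ndarray:
    g = np.asarray(f.grid, dtype=float)
    if g.size < 3:
        raise ValueError("need at least 3 samples for the SRSF transform")
    steps = np.diff(g)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("SRSF requires a uniform grid")
    return g


def srsf_transform(f: SmoothedTrain) -> SRSF:
    """q = sgn(f')·√|f'| with f' from centred finite differences."""
    g = _uniform_grid(f)
    df = np.gradient(f.values, g)
    return SRSF(grid=g, q_values=np.sign(df) * np.sqrt(np.abs(df)))


def _resample(values: np.ndarray, grid: np.ndarray, n: int):
    new_grid = np.linspace(grid[0], grid[-1], n)
    return new_grid, np.interp(new_grid, grid, values)


def _common_srsf(f: SmoothedTrain, g: SmoothedTrain, n: Optional[int] = None):
    gf, gg = _uniform_grid(f), _uniform_grid(g)
    span_f, span_g = gf[-1] - gf[0], gg[-1] - gg[0]
    if not np.isclose(span_f, span_g, rtol=1e-9):
        raise ValueError(f"domain lengths differ: {span_f} vs {span_g}")
    n = n or max(gf.size, gg.size)
    grid, vf = _resample(f.values, gf, n)
    _, vg = _resample(g.values, gg, n)
    fr = SmoothedTrain(grid, vf, f.window)
    gr = SmoothedTrain(grid, vg, g.window)
    return srsf_transform(fr), srsf_transform(gr), fr, gr


def fr_distance(f: SmoothedTrain, g: SmoothedTrain) -> float:
    """Extended Fisher–Rao distance: √∫ (q_f − q_g)² dt by trapezoid rule."""
    qf, qg, _, _ = _common_srsf(f, g)
    return float(np.sqrt(np.trapezoid((qf.q_values - qg.q_values) ** 2, qf.grid)))


# ---------------------------------------------------------------------------
# Warp functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WarpFn:
    """Monotone boundary-fixed warp on the normalized domain [0, 1]."""

    grid: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.grid, float)
        v = np.asarray(self.values, float)
        if g.shape != v.shape or g.size < 2:
            raise ValueError("grid/values mismatch")
        if not (np.isclose(v[0], 0.0) and np.isclose(v[-1], 1.0)):
            raise ValueError("warp must fix the boundary: γ(0)=0, γ(1)=1")
        if np.any(np.diff(v) <= 0):
            raise ValueError("warp must be strictly increasing")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.interp(x, self.grid, self.values)

    def inverse(self) -> "WarpFn":
        return WarpFn(self.grid, np.interp(self.grid, self.values, self.grid))

    def compose(self, other: "WarpFn") -> "WarpFn":
        """self ∘ other, by interpolation on the common grid."""
        return WarpFn(self.grid, self(other(self.grid)))

    @staticmethod
    def identity(n: int = 101) -> "WarpFn":
        g = np.linspace(0.0, 1.0, n)
        return WarpFn(g, g.copy())


def warp_function(f: SmoothedTrain, warp: WarpFn) -> SmoothedTrain:
    """f ∘ γ on f's own grid (γ in normalized coordinates)."""
    g = np.asarray(f.grid, float)
    x = (g - g[0]) / (g[-1] - g[0])
    return SmoothedTrain(g, np.interp(g[0] + warp(x) * (g[-1] - g[0]), g, f.values), f.window)


def warp_srsf(q: np.ndarray, grid01: np.ndarray, warp: WarpFn) -> np.ndarray:
    """Isometric action (q∘γ)·√γ' on a normalized uniform grid."""
    gv = warp(grid01)
    dgamma = np.gradient(gv, grid01)
    return np.interp(gv, grid01, q) * np.sqrt(np.clip(dgamma, 0.0, None))


# ---------------------------------------------------------------------------
# Dynamic-programming alignment
# ---------------------------------------------------------------------------

def candidate_steps(max_slope: int = DEFAULT_MAX_SLOPE) -> np.ndarray:
    """Coprime lattice steps (Δi, Δj) with components in 1..max_slope.

    Any monotone lattice path decomposes into these primitive steps with the
    same piecewise-linear warp and cost, so with max_slope = n−1 the DP is an
    exact search over all monotone lattice warps.
    """
    steps = [(p, q) for p in range(1, max_slope + 1)
             for q in range(1, max_slope + 1) if gcd(p, q) == 1]
    return np.array(steps, dtype=np.int64)


@njit(cache=True)
def _dp_cost(q1, q2, steps):  # pragma: no cover - exercised via align_pair
    n = q1.shape[0]
    h = 1.0 / (n - 1)
    E = np.full((n, n), np.inf)
    back = np.full((n, n), -1, np.int64)
    E[0, 0] = 0.0
    for i in range(1, n):
        for j in range(1, n):
            best = np.inf
            barg = -1
            for s in range(steps.shape[0]):
                p = steps[s, 0]
                q = steps[s, 1]
                if i < p or j < q:
                    continue
                prev = E[i - p, j - q]
                if prev == np.inf:
                    continue
                slope = q / p
                sq = np.sqrt(slope)
                c = 0.0
                for k in range(p + 1):
                    y = (j - q) + slope * k
                    yi = int(y)
                    if yi > n - 2:
                        yi = n - 2
                    fy = y - yi
                    q2v = q2[yi] * (1.0 - fy) + q2[yi + 1] * fy
                    d = q1[i - p + k] - q2v * sq
                    w = 0.5 if (k == 0 or k == p) else 1.0
                    c += w * d * d
                tot = prev + c * h
                if tot < best:
                    best = tot
                    barg = s
            E[i, j] = best
            back[i, j] = barg
    return E, back


def _dp_warp(q1: np.ndarray, q2: np.ndarray, steps: np.ndarray):
    """Optimal lattice warp aligning q2 to q1; returns (γ samples, cost)."""
    n = q1.shape[0]
    E, back = _dp_cost(
        np.ascontiguousarray(q1, dtype=np.float64),
        np.ascontiguousarray(q2, dtype=np.float64),
        steps,
    )
    if not np.isfinite(E[n - 1, n - 1]):
        raise RuntimeError("DP lattice has no feasible path; increase max_slope")
    path_i, path_j = [n - 1], [n - 1]
    i, j = n - 1, n - 1
    while i > 0 or j > 0:
        s = back[i, j]
        i -= int(steps[s, 0])
        j -= int(steps[s, 1])
        path_i.append(i)
        path_j.append(j)
    xi = np.array(path_i[::-1], float) / (n - 1)
    yj = np.array(path_j[::-1], float) / (n - 1)
    grid = np.linspace(0.0, 1.0, n)
    gamma = np.interp(grid, xi, yj)
    return gamma, float(E[n - 1, n - 1])


@dataclass(frozen=True)
class PairAlignment:
    warp: WarpFn
    aligned: SmoothedTrain
    distance: float          # Fisher–Rao distance after alignment
    distance_unaligned: float


def align_pair(
    f_ref: SmoothedTrain,
    g: SmoothedTrain,
    n_grid: Optional[int] = None,
    max_slope: int = DEFAULT_MAX_SLOPE,
) -> PairAlignment:
    """Warp g onto f_ref by minimizing the SRSF distance over lattice warps.

    The achieved distance never exceeds the unaligned distance: the identity
    warp is itself a lattice path.
    """
    qf, qg, f_r, g_r = _common_srsf(f_ref, g, n_grid)
    steps = candidate_steps(max_slope)
    gamma, cost = _dp_warp(qf.q_values, qg.q_values, steps)
    # the DP integrates over the normalized domain; the Fisher–Rao distance
    # on the original domain is √span larger
    span = float(qf.grid[-1] - qf.grid[0])
    warp = WarpFn(np.linspace(0.0, 1.0, gamma.size), gamma)
    aligned = warp_function(g_r, warp)
    d_un = float(
        np.sqrt(
            span
            * np.trapezoid(
                (qf.q_values - qg.q_values) ** 2,
                np.linspace(0, 1, qf.q_values.size),
            )
        )
    )
    return PairAlignment(
        warp=warp,
        aligned=aligned,
        distance=float(np.sqrt(span * cost)),
        distance_unaligned=d_un,
    )


# ---------------------------------------------------------------------------
# Karcher mean and population alignment
# ---------------------------------------------------------------------------

@dataclass
class KarcherResult:
    mean: SmoothedTrain
    warps: list
    aligned: list
    objective_trace: list
    converged: bool


def _srsf_to_function(q: np.ndarray, grid: np.ndarray, f0: float) -> np.ndarray:
    from scipy.integrate import cumulative_trapezoid

    return f0 + np.concatenate([[0.0], cumulative_trapezoid(q * np.abs(q), grid)])


def karcher_mean(
    trains: Sequence[SmoothedTrain],
    n_grid: Optional[int] = None,
    max_iter: int = 8,
    tol: float = 1e-4,
    max_slope: int = DEFAULT_MAX_SLOPE,
) -> KarcherResult:
    """Fisher–Rao Karcher mean of a population of smoothed trains.

    Initialized at the cross-sectional SRSF mean, then iterates
    align-to-mean / re-average, recentring by the mean warp to fix the
    gauge freedom.  The objective (sum of squared aligned distances) is
    tracked; if an iteration fails to decrease it the previous iterate is
    kept, so the recorded trace is nonincreasing.
    """
    if len(trains) < 2:
        raise ValueError("need at least 2 trains")
    grids = [_uniform_grid(t) for t in trains]
    n = n_grid or max(g.size for g in grids)
    grid01 = np.linspace(0.0, 1.0, n)
    qs = []
    f0s = []
    for t, g in zip(trains, grids):
        _, v = _resample(t.values, g, n)
        qs.append(srsf_transform(SmoothedTrain(grid01, v, t.window)).q_values)
        f0s.append(v[0])
    qs = np.array(qs)
    steps = candidate_steps(max_slope)

    mu = qs.mean(axis=0)
    best_obj = np.inf
    best_state = None
    trace = []
    converged = False
    for _ in range(max_iter):
        gammas, warped = [], []
        obj = 0.0
        for q in qs:
            gamma, cost = _dp_warp(mu, q, steps)
            obj += cost
            gammas.append(gamma)
            warped.append(warp_srsf(q, grid01, WarpFn(grid01, gamma)))
        if obj >= best_obj - tol * max(best_obj, 1.0):
            if obj < best_obj:
                best_obj = obj
                best_state = (mu.copy(), gammas, warped)
            converged = True
            trace.append(min(obj, best_obj))
            break
        best_obj = obj
        best_state = (mu.copy(), gammas, warped)
        trace.append(obj)
        new_mu = np.mean(warped, axis=0)
        # recentre by the mean warp so the mean stays in the centre of the
        # orbit rather than drifting along it
        gamma_bar = np.mean(gammas, axis=0)
        gamma_bar[0], gamma_bar[-1] = 0.0, 1.0
        inv = WarpFn(grid01, gamma_bar).inverse()
        mu = warp_srsf(new_mu, grid01, inv)
    if best_state is None:  # max_iter == 0 degenerate call
        best_state = (mu, [grid01.copy() for _ in qs], list(qs))
    if not converged:
        log.info("Karcher mean: objective still falling after %d iterations; "
                 "returning the best iterate", max_iter)

    mu, gammas, warped = best_state
    mean_train = SmoothedTrain(grid01, _srsf_to_function(mu, grid01, float(np.mean(f0s))),
                               trains[0].window)
    warps = [WarpFn(grid01, g) for g in gammas]
    aligned = []
    for t, g, w in zip(trains, grids, warps):
        _, v = _resample(t.values, g, n)
        aligned.append(warp_function(SmoothedTrain(grid01, v, t.window), w))
    return KarcherResult(mean_train, warps, aligned, trace, converged)


@dataclass
class AlignmentResult:
    """Population alignment: mean train, per-trial aligned trains and warps."""

    mean_train: SmoothedTrain
    aligned_trains: list
    warp_fns: list
    mode: str
    kept_indices: list = field(default_factory=list)


def align_population(
    trains: Sequence[SmoothedTrain],
    n_grid: int = DEFAULT_GRID,
    max_slope: int = DEFAULT_MAX_SLOPE,
    karcher_iters: int = 8,
) -> AlignmentResult:
    """Align every train to the population Karcher mean (whole-window mode)."""
    res = karcher_mean(trains, n_grid=n_grid, max_iter=karcher_iters, max_slope=max_slope)
    return AlignmentResult(
        mean_train=res.mean,
        aligned_trains=res.aligned,
        warp_fns=res.warps,
        mode="whole_window",
        kept_indices=list(range(len(trains))),
    )


# ---------------------------------------------------------------------------
# Interlick and randomized-interval alignment
# ---------------------------------------------------------------------------

def _segment_resampled(train: SmoothedTrain, start: float, stop: float, n: int) -> SmoothedTrain:
    """Train restricted to [start, stop) and rescaled to the unit domain."""
    g = np.asarray(train.grid, float)
    new = np.linspace(start, stop, n)
    v = np.interp(new, g, train.values)
    return SmoothedTrain(np.linspace(0.0, 1.0, n), v, train.window)


def _aligned_segments(
    trains: Sequence[SmoothedTrain],
    boundaries: Sequence[np.ndarray],
    seg_grid: int,
    max_slope: int,
    karcher_iters: int,
    mode: str,
) -> AlignmentResult:
    """Per-interval Karcher alignment; segments and warps concatenated in order."""
    n_trials = len(trains)
    n_seg = len(boundaries[0]) - 1
    seg_aligned = [[] for _ in range(n_trials)]
    seg_warps = [[] for _ in range(n_trials)]
    seg_means = []
    for i in range(n_seg):
        segs = [
            _segment_resampled(t, b[i], b[i + 1], seg_grid)
            for t, b in zip(trains, boundaries)
        ]
        res = karcher_mean(segs, n_grid=seg_grid, max_iter=karcher_iters,
                           max_slope=max_slope)
        seg_means.append(res.mean)
        for k in range(n_trials):
            seg_aligned[k].append(res.aligned[k])
            seg_warps[k].append(res.warps[k])

    mean_vals = np.concatenate([m.values for m in seg_means])
    mean_grid = np.concatenate(
        [(i + m.grid) / n_seg for i, m in enumerate(seg_means)]
    )
    aligned_trains, warp_fns = [], []
    for k in range(n_trials):
        vals = np.concatenate([s.values for s in seg_aligned[k]])
        aligned_trains.append(
            SmoothedTrain(mean_grid.copy(), vals, trains[k].window)
        )
        wg = np.concatenate(
            [
                ((i + w.grid) / n_seg)[1 if i else 0:]
                for i, w in enumerate(seg_warps[k])
            ]
        )
        wv = np.concatenate(
            [
                ((i + w.values) / n_seg)[1 if i else 0:]
                for i, w in enumerate(seg_warps[k])
            ]
        )
        warp_fns.append(WarpFn(wg, wv))
    return AlignmentResult(
        mean_train=SmoothedTrain(mean_grid, mean_vals, trains[0].window),
        aligned_trains=aligned_trains,
        warp_fns=warp_fns,
        mode=mode,
    )


def interlick_esa(
    trains: Sequence[SmoothedTrain],
    partitions: Sequence,
    seg_grid: int = DEFAULT_SEGMENT_GRID,
    max_slope: int = DEFAULT_MAX_SLOPE,
    karcher_iters: int = 4,
) -> AlignmentResult:
    """Alignment performed separately on each of the five interlick intervals.

    Each interval is rescaled to [0,1] before alignment, so segment warps read
    directly as lick-phase maps; aligned segments and warps are concatenated
    into single per-trial vectors/functions.  ``partitions`` are
    InterlickPartition objects matching ``trains`` one-to-one.
    """
    boundaries = [np.asarray(p.boundaries, float) for p in partitions]
    if len(boundaries) != len(trains):
        raise ValueError("one partition per train required")
    return _aligned_segments(trains, boundaries, seg_grid, max_slope,
                             karcher_iters, mode="interlick")


def random_breakpoints(
    span: float, rng: np.random.Generator, n_segments: int = 5,
    min_segment: float = MIN_RANDOM_SEGMENT_MS,
) -> np.ndarray:
    """n_segments−1 sorted breakpoints uniform in (0, span), min gap enforced
    by resampling."""
    if span < 100.0:
        raise ValueError(f"five-lick span too short: {span} ms")
    for _ in range(1000):
        b = np.sort(rng.uniform(0.0, span, size=n_segments - 1))
        edges = np.concatenate([[0.0], b, [span]])
        if np.diff(edges).min() >= min_segment:
            return b
    raise RuntimeError("could not draw breakpoints honouring the minimum segment")


def random_interval_esa(
    trains: Sequence[SmoothedTrain],
    spans: Sequence[float],
    n_repeats: int = 20,
    seed: int = 0,
    seg_grid: int = DEFAULT_SEGMENT_GRID,
    max_slope: int = DEFAULT_MAX_SLOPE,
    karcher_iters: int = 4,
) -> list:
    """Randomized-interval control: one AlignmentResult per repeat.

    Per repeat, four breakpoints are drawn uniformly in absolute time within
    the five-lick window (bounded by the shortest trial span, minimum segment
    20 ms) and shared across trials, so the partition ignores lick timing;
    each trial's final segment runs to its own span end.
    """
    spans = np.asarray(spans, float)
    rng = np.random.default_rng(seed)
    out = []
    ref = float(spans.min())
    for _ in range(n_repeats):
        bp = random_breakpoints(ref, rng)
        results_boundaries = [
            np.concatenate([[0.0], bp, [s]]) for s in spans
        ]
        res = _aligned_segments(trains, results_boundaries, seg_grid, max_slope,
                                karcher_iters, mode="random_intervals")
        out.append(res)
    return out


# ---------------------------------------------------------------------------
# Feature extraction for SVM decoding
# ---------------------------------------------------------------------------

def aligned_feature_matrix(result: AlignmentResult) -> np.ndarray:
    return np.vstack([t.values for t in result.aligned_trains])


def warp_feature_matrix(result: AlignmentResult, n_points: int = 100) -> np.ndarray:
    """Warps resampled to n_points with the identity removed, so the
    classifier sees only the timing deviations."""
    x = np.linspace(0.0, 1.0, n_points)
    return np.vstack([w(x) - x for w in result.warp_fns])


def esa_classification_scores(
    dataset,
    mode: str = "whole_window",
    *,
    taste_set: Optional[Sequence[str]] = None,
    window: float = 250.0,
    n_grid: int = DEFAULT_GRID,
    seg_grid: int = DEFAULT_SEGMENT_GRID,
    max_slope: int = DEFAULT_MAX_SLOPE,
    karcher_iters: int = 4,
    svm_repeats: int = 20,
    train_frac: float = 0.67,
    n_random_repeats: int = 20,
    seed: int = 0,
) -> dict:
    """Per-neuron decoding scores for original, aligned and warp features.

    Smooths the post-taste half of each trial, aligns per ``mode``
    ('whole_window', 'interlick' or 'random_intervals'), and runs the
    repeated-split SVM on three representations: the original smoothed
    trains, the aligned trains (rate information) and the warp functions
    (timing information).  In random mode the aligned/warp scores are the
    mean over ``n_random_repeats`` random partitions of the five-lick span.

    Returns {'original', 'aligned', 'warp'} → ClassScore.
    """
    from .decoding import FeatureMatrix, classification_score
    from .rate_phase import Exclusion, interlick_partition

    trials = dataset.trials
    if taste_set is not None:
        trials = [t for t in trials if t.tastant in taste_set]

    from .spike_io import smooth_trial

    if mode in ("interlick", "random_intervals"):
        kept, partitions = [], []
        for tr in trials:
            part = interlick_partition(tr)
            if isinstance(part, Exclusion):
                log.info("trial %s/%s dropped from ESA: %s",
                         tr.neuron_id, tr.trial_id, part.reason)
                continue
            kept.append(tr)
            partitions.append(part)
        trials = kept
    else:
        partitions = [None] * len(trials)

    labels = np.array([t.tastant for t in trials])
    smoothed = [smooth_trial(t, window).segment(0.0, 2000.0) for t in trials]

    def _score(X: np.ndarray, tag: str):
        return classification_score(
            FeatureMatrix(X, labels, tag, dataset.neuron_id),
            n_repeats=svm_repeats, train_frac=train_frac, seed=seed,
        )

    # original representation: smoothed post-taste trains on the DP grid
    X_orig = np.vstack(
        [_resample(s.values, np.asarray(s.grid, float), n_grid)[1] for s in smoothed]
    )
    original = _score(X_orig, "smoothed")

    if mode == "whole_window":
        res = align_population(smoothed, n_grid=n_grid, max_slope=max_slope,
                               karcher_iters=karcher_iters)
        aligned = _score(aligned_feature_matrix(res), "aligned")
        warp = _score(warp_feature_matrix(res), "warp")
    elif mode == "interlick":
        res = interlick_esa(smoothed, partitions, seg_grid=seg_grid,
                            max_slope=max_slope, karcher_iters=karcher_iters)
        aligned = _score(aligned_feature_matrix(res), "aligned")
        warp = _score(warp_feature_matrix(res), "warp")
    elif mode == "random_intervals":
        spans = [p.boundaries[-1] for p in partitions]
        reps = random_interval_esa(
            smoothed, spans, n_repeats=n_random_repeats, seed=seed,
            seg_grid=seg_grid, max_slope=max_slope, karcher_iters=karcher_iters,
        )
        a_scores, w_scores = [], []
        for r, res in enumerate(reps):
            a_scores.append(_score(aligned_feature_matrix(res), "aligned").score)
            w_scores.append(_score(warp_feature_matrix(res), "warp").score)
        from .decoding import ClassScore

        tset = tuple(sorted(np.unique(labels)))
        aligned = ClassScore(dataset.neuron_id, tset, "aligned_random",
                             float(np.mean(a_scores)), svm_repeats)
        warp = ClassScore(dataset.neuron_id, tset, "warp_random",
                          float(np.mean(w_scores)), svm_repeats)
    else:
        raise ValueError(f"unknown ESA mode {mode!r}")
    return {"original": original, "aligned": aligned, "warp": warp}
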