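"""Rate–Phase (RP) codes over the first five post-delivery interlick intervals,
and the line-scan separation scores that quantify how well a neuron splits two
tastants in the RP-plane.

The RP code collapses a trial to two numbers: R, the mean number of spikes
per interlick interval (denominator fixed at the five declared intervals),
and P, the mean relative spike position in [0, 1) within its interval
(0 = concurrent with the starting lick).  Trials without five post-delivery
licks, or with no spikes in any of the five intervals, are excluded.

Separation scores scan separating lines in the RP-plane: vertical lines see
only R (rate score), horizontal lines only P (phase score), and arbitrary
lines both (combination score).  The search over arbitrary lines is exact:
the score as a function of line angle is piecewise constant, changing only
at angles perpendicular to some inter-point difference, so enumerating those
critical angles, the midpoints between them and the two axis directions —
then scanning thresholds at projection midpoints — attains the global
maximum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .spike_io import TrialRecord

N_INTERVALS = 5


@dataclass(frozen=True)
class InterlickPartition:
    """Boundaries t_0=0 < t_1 < ... < t_5 of the five post-delivery intervals."""

    boundaries: np.ndarray

    def __post_init__(self):
        b = np.asarray(self.boundaries, dtype=float)
        if b.shape != (N_INTERVALS + 1,) or b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValueError("need 6 strictly increasing boundaries starting at 0")
        object.__setattr__(self, "boundaries", b)

    @property
    def intervals(self) -> list:
        b = self.boundaries
        return [(b[i], b[i + 1]) for i in range(N_INTERVALS)]


@dataclass(frozen=True)
class Exclusion:
    """A trial removed from the RP analysis, with the reason."""

    reason: str  # 'too_few_licks' | 'no_spikes'


@dataclass(frozen=True)
class RPCode:
    R: float  # mean spikes per interlick interval
    P: float  # mean spike phase in [0, 1)

    def __post_init__(self):
        if self.R <= 0:
            raise ValueError("R must be positive (zero-spike trials are excluded)")
        if not (0 <= self.P < 1):
            raise ValueError("P must lie in [0, 1)")


def interlick_partition(trial: TrialRecord):
    """First five post-delivery interlick intervals, or an Exclusion.

    Exclusion reasons: 'too_few_licks' when fewer than five licks follow
    delivery; 'no_spikes' when the neuron fires in none of the intervals.
    """
    post = trial.post_delivery_licks
    if post.size < N_INTERVALS:
        return Exclusion("too_few_licks")
    boundaries = np.concatenate([[0.0], post[:N_INTERVALS]])
    part = InterlickPartition(boundaries)
    t5 = boundaries[-1]
    n_spikes = np.count_nonzero(
        (trial.spike_times >= 0.0) & (trial.spike_times < t5)
    )
    if n_spikes == 0:
        return Exclusion("no_spikes")
    return part


def spike_phases(trial: TrialRecord, partition: InterlickPartition) -> np.ndarray:
    """Relative position in [0, 1) of each in-window spike within its interval."""
    b = partition.boundaries
    s = trial.spike_times
    s = s[(s >= b[0]) & (s < b[-1])]
    idx = np.searchsorted(b, s, side="right") - 1
    lo, hi = b[idx], b[idx + 1]
    return (s - lo) / (hi - lo)


def rp_code(
    trial: TrialRecord,
    partition: InterlickPartition,
    per_interval_mean: bool = False,
) -> RPCode:
    """RP code of one trial.

    R is the total spike count over the five intervals divided by five.  P is
    by default the unweighted mean phase over all spikes; with
    ``per_interval_mean`` it is instead the mean over intervals of the
    per-interval mean phases (the two readings coincide when every interval
    holds the same number of spikes).
    """
    phases = spike_phases(trial, partition)
    if phases.size == 0:
        raise ValueError("trial has no spikes in the five intervals; exclude it first")
    R = phases.size / N_INTERVALS
    if per_interval_mean:
        b = partition.boundaries
        s = trial.spike_times
        s = s[(s >= b[0]) & (s < b[-1])]
        idx = np.searchsorted(b, s, side="right") - 1
        means = [phases[idx == i].mean() for i in range(N_INTERVALS) if (idx == i).any()]
        P = float(np.mean(means))
    else:
        P = float(phases.mean())
    return RPCode(R=float(R), P=min(P, np.nextafter(1.0, 0.0)))


# ---------------------------------------------------------------------------
# Separation scores
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeparationLine:
    """A separating line: points project onto direction (cos θ, sin θ); the
    line is the set {p : p·u = offset}."""

    theta: float
    offset: float


@dataclass(frozen=True)
class SeparationResult:
    rate_score: float
    phase_score: float
    combination_score: float
    rate_line: SeparationLine
    phase_line: SeparationLine
    combination_line: SeparationLine


def _best_threshold(proj_a: np.ndarray, proj_b: np.ndarray):
    """Best split of two projected samples over all thresholds and both label
    assignments.  A point with projection ≥ threshold counts as 'right of'
    the line.  Returns (score, threshold)."""
    n = proj_a.size + proj_b.size
    allv = np.unique(np.concatenate([proj_a, proj_b]))
    mids = (allv[1:] + allv[:-1]) / 2.0 if allv.size > 1 else np.empty(0)
    thresholds = np.concatenate([[-np.inf], mids, allv, [np.inf]])
    a_left = np.searchsorted(np.sort(proj_a), thresholds, side="left")
    b_left = np.searchsorted(np.sort(proj_b), thresholds, side="left")
    # assignment 1: A left / B right; assignment 2: the reverse
    s1 = a_left + (proj_b.size - b_left)
    s2 = b_left + (proj_a.size - a_left)
    scores = np.maximum(s1, s2) / n
    k = int(np.argmax(scores))
    return float(scores[k]), float(thresholds[k])


def _candidate_angles(points: np.ndarray) -> np.ndarray:
    """Angles (mod π) at which the projection ordering can change, plus the
    midpoints of the gaps between them and the two axis directions."""
    diffs = points[:, None, :] - points[None, :, :]
    iu = np.triu_indices(len(points), k=1)
    d = diffs[iu]
    d = d[np.any(d != 0, axis=1)]
    crit = np.mod(np.arctan2(d[:, 0], -d[:, 1]), np.pi)  # u ⟂ difference
    crit = np.unique(np.concatenate([crit, [0.0, np.pi / 2]]))
    ext = np.concatenate([crit, [crit[0] + np.pi]])
    mids = np.mod((ext[1:] + ext[:-1]) / 2.0, np.pi)
    return np.unique(np.concatenate([crit, mids]))


def separation_scores(
    points_a: Sequence, points_b: Sequence, angles: Optional[np.ndarray] = None
) -> SeparationResult:
    """Rate, phase and combination separation scores for two RP point clouds.

    Each score is the maximal fraction of points correctly split by a line
    of the given family (vertical / horizontal / arbitrary), maximized over
    both tastant-to-side assignments.  All scores lie in [0.5, 1] and the
    combination score is ≥ max(rate, phase) since vertical and horizontal
    lines are members of the arbitrary family.

    ``angles`` overrides the candidate angle set (used by grid-search
    cross-checks); by default the exact critical-angle enumeration is used.
    """
    A = np.array([(p.R, p.P) if isinstance(p, RPCode) else tuple(p) for p in points_a])
    B = np.array([(p.R, p.P) if isinstance(p, RPCode) else tuple(p) for p in points_b])
    if len(A) < 2 or len(B) < 2:
        raise ValueError("need at least 2 points per tastant")

    rate_score, rate_c = _best_threshold(A[:, 0], B[:, 0])
    phase_score, phase_c = _best_threshold(A[:, 1], B[:, 1])

    if angles is None:
        angles = _candidate_angles(np.vstack([A, B]))
    best = (0.0, 0.0, 0.0)
    for th in angles:
        u = np.array([np.cos(th), np.sin(th)])
        s, c = _best_threshold(A @ u, B @ u)
        if s > best[0]:
            best = (s, th, c)
    comb_score = max(best[0], rate_score, phase_score)
    comb_line = (
        SeparationLine(best[1], best[2])
        if best[0] >= max(rate_score, phase_score)
        else (
            SeparationLine(0.0, rate_c)
            if rate_score >= phase_score
            else SeparationLine(np.pi / 2, phase_c)
        )
    )
    return SeparationResult(
        rate_score=rate_score,
        phase_score=phase_score,
        combination_score=comb_score,
        rate_line=SeparationLine(0.0, rate_c),
        phase_line=SeparationLine(np.pi / 2, phase_c),
        combination_line=comb_line,
    )


def dataset_rp_codes(dataset, per_interval_mean: bool = False):
    """RP codes for every trial of a neuron; returns (codes, exclusions).

    ``codes`` maps tastant → list of RPCode; ``exclusions`` is a list of
    (trial_id, reason).
    """
    codes: dict = {}
    exclusions = []
    for tr in dataset.trials:
        part = interlick_partition(tr)
        if isinstance(part, Exclusion):
            exclusions.append((tr.trial_id, part.reason))
            continue
        codes.setdefault(tr.tastant, []).append(
            rp_code(tr, part, per_interval_mean=per_interval_mean)
        )
    return codes, exclusions
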