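"""Trial-aligned spike/lick data model, event-table I/O, binning and smoothing.

A trial is a 4 s window centred on taste delivery: the lick that triggers
delivery defines t = 0, and spike/lick event times are real-valued
milliseconds in [-2000, 2000).  The raw representation of a trial's spiking
is a 4000-dimensional {0,1} vector at 1 ms resolution; binning and Gaussian
smoothing produce the coarse-grained and continuous representations used by
the downstream classifiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

WINDOW_START_MS = -2000.0
WINDOW_END_MS = 2000.0
WINDOW_LEN_MS = 4000
T0_INDEX = 2000

TASTANTS = ("sucrose", "nacl", "citric_acid", "quinine", "water")


class ValidationError(ValueError):
    """A trial or dataset violates a structural invariant."""


class ParseError(ValueError):
    """An event table row could not be interpreted."""


def _as_sorted_times(times: Iterable[float], name: str, trial: str) -> np.ndarray:
    arr = np.asarray(list(times), dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{trial}: {name} must be a 1-d sequence")
    if arr.size and np.any(np.diff(arr) <= 0):
        raise ValidationError(f"{trial}: {name} must be strictly increasing")
    if arr.size and (arr[0] < WINDOW_START_MS or arr[-1] >= WINDOW_END_MS):
        raise ValidationError(
            f"{trial}: {name} outside window [{WINDOW_START_MS}, {WINDOW_END_MS})"
        )
    return arr


@dataclass(frozen=True)
class TrialRecord:
    """One trial: spike and lick event times (ms) plus the tastant label.

    Exactly one lick sits at ``delivery_time`` = 0 (the lick that triggered
    taste delivery).  Event times are strictly increasing and confined to
    the [-2000, 2000) ms window.
    """

    neuron_id: str
    trial_id: str
    tastant: str
    spike_times: np.ndarray
    lick_times: np.ndarray
    delivery_time: float = 0.0

    def __post_init__(self):
        tag = f"trial {self.neuron_id}/{self.trial_id}"
        if self.tastant not in TASTANTS:
            raise ValidationError(f"{tag}: unknown tastant {self.tastant!r}")
        object.__setattr__(
            self, "spike_times", _as_sorted_times(self.spike_times, "spike_times", tag)
        )
        object.__setattr__(
            self, "lick_times", _as_sorted_times(self.lick_times, "lick_times", tag)
        )
        if self.delivery_time != 0.0:
            raise ValidationError(f"{tag}: delivery_time must be 0")
        if np.count_nonzero(self.lick_times == 0.0) != 1:
            raise ValidationError(f"{tag}: exactly one lick must sit at t=0")

    @property
    def post_delivery_licks(self) -> np.ndarray:
        return self.lick_times[self.lick_times > 0.0]


@dataclass(frozen=True)
class BinaryTrain:
    """{0,1}-valued spike vector at 1 ms resolution over the 4 s window."""

    values: np.ndarray
    t0_index: int = T0_INDEX

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.int8)
        if v.shape != (WINDOW_LEN_MS,):
            raise ValidationError(f"binary train must have length {WINDOW_LEN_MS}")
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("binary train entries must be 0 or 1")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class BinnedTrain:
    """Spike counts per bin; the last bin may be partial if bin_width ∤ 4000."""

    counts: np.ndarray
    bin_width: int


@dataclass(frozen=True)
class SmoothedTrain:
    """Nonnegative smoothed firing profile on a uniform ms grid.

    The smoothing kernel has unit area, so the integral of ``values`` over
    the grid approximates the spike count.
    """

    grid: np.ndarray
    values: np.ndarray
    window: float

    def __post_init__(self):
        g = np.asarray(self.grid, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if g.shape != v.shape:
            raise ValidationError("grid and values must match in shape")
        object.__setattr__(self, "grid", g)
        object.__setattr__(self, "values", v)

    def segment(self, start: float, stop: float) -> "SmoothedTrain":
        """Restrict to grid points in [start, stop)."""
        m = (self.grid >= start) & (self.grid < stop)
        return SmoothedTrain(self.grid[m], self.values[m], self.window)


@dataclass
class NeuronDataset:
    """All trials for one neuron, with a configurable per-tastant trial floor."""

    neuron_id: str
    trials: list = field(default_factory=list)

    def validate(self, min_trials_per_taste: int = 15) -> None:
        counts = self.trial_counts()
        for taste in TASTANTS:
            if counts.get(taste, 0) < min_trials_per_taste:
                raise ValidationError(
                    f"neuron {self.neuron_id}: tastant {taste!r} has "
                    f"{counts.get(taste, 0)} trials, needs ≥ {min_trials_per_taste}"
                )

    def trial_counts(self) -> dict:
        out: dict = {}
        for tr in self.trials:
            out[tr.tastant] = out.get(tr.tastant, 0) + 1
        return out

    def by_tastant(self, tastant: str) -> list:
        return [t for t in self.trials if t.tastant == tastant]


# ---------------------------------------------------------------------------
# Event-table I/O
# ---------------------------------------------------------------------------

_COLUMNS = ["neuron_id", "trial_id", "tastant", "event_type", "time_ms"]


def write_trials(datasets: Sequence[NeuronDataset], path) -> None:
    """Write datasets as a CSV event table.

    Times are written at full float precision (never rounded: rounding could
    push an event just inside the window boundary onto it), so the round
    trip through read_trials is lossless.
    """
    rows = []
    for ds in datasets:
        for tr in ds.trials:
            for t in tr.spike_times:
                rows.append((ds.neuron_id, tr.trial_id, tr.tastant, "spike", t))
            for t in tr.lick_times:
                rows.append((ds.neuron_id, tr.trial_id, tr.tastant, "lick", t))
    df = pd.DataFrame(rows, columns=_COLUMNS)
    df.to_csv(path, index=False)


def read_trials(path) -> list:
    """Read an event-table CSV into a list of validated NeuronDatasets.

    Raises ParseError naming the offending line for malformed rows and
    ValidationError naming the trial for invariant violations.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"neuron_id": str, "trial_id": str})
    except Exception as exc:  # noqa: BLE001 - surface pandas' message
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    bad = ~df["event_type"].isin(["spike", "lick"])
    if bad.any():
        line = int(df.index[bad][0]) + 2  # header is line 1
        raise ParseError(f"{path}: line {line}: bad event_type {df.loc[bad, 'event_type'].iloc[0]!r}")
    if df["time_ms"].isna().any():
        line = int(df.index[df["time_ms"].isna()][0]) + 2
        raise ParseError(f"{path}: line {line}: unparseable time_ms")

    datasets = []
    for nid, g_neuron in df.groupby("neuron_id", sort=True):
        ds = NeuronDataset(neuron_id=str(nid))
        for tid, g in g_neuron.groupby("trial_id", sort=True):
            tastants = g["tastant"].unique()
            if len(tastants) != 1:
                raise ValidationError(
                    f"trial {nid}/{tid}: conflicting tastant labels {sorted(tastants)}"
                )
            spikes = np.sort(g.loc[g.event_type == "spike", "time_ms"].to_numpy(float))
            licks = np.sort(g.loc[g.event_type == "lick", "time_ms"].to_numpy(float))
            ds.trials.append(
                TrialRecord(
                    neuron_id=str(nid),
                    trial_id=str(tid),
                    tastant=str(tastants[0]),
                    spike_times=spikes,
                    lick_times=licks,
                )
            )
        datasets.append(ds)
    return datasets


# ---------------------------------------------------------------------------
# Preprocessing: binary vector, binning, smoothing
# ---------------------------------------------------------------------------

def to_binary_train(trial: TrialRecord) -> BinaryTrain:
    """Rasterize spike times into the 4000-dim {0,1} vector.

    Entry k covers millisecond [-2000 + k, -2000 + k + 1).  Two spikes
    falling in the same millisecond collapse to a single 1 (with a warning);
    the full-precision times remain available on the TrialRecord.
    """
    v = np.zeros(WINDOW_LEN_MS, dtype=np.int8)
    idx = np.floor(trial.spike_times - WINDOW_START_MS).astype(int)
    if idx.size != np.unique(idx).size:
        # constant message so the default warning filter collapses repeats
        warnings.warn(
            "sub-millisecond spike pair collapsed in binary representation",
            stacklevel=2,
        )
    v[idx] = 1
    return BinaryTrain(values=v)


def bin_train(train: BinaryTrain, bin_width: int) -> BinnedTrain:
    """Count spikes in consecutive bins of bin_width ms (last bin may be partial)."""
    if not (1 <= bin_width <= WINDOW_LEN_MS):
        raise ValueError(f"bin_width must be in [1, {WINDOW_LEN_MS}], got {bin_width}")
    bin_width = int(bin_width)
    n_bins = -(-WINDOW_LEN_MS // bin_width)
    counts = np.zeros(n_bins, dtype=int)
    np.add.at(counts, np.arange(WINDOW_LEN_MS) // bin_width, train.values)
    return BinnedTrain(counts=counts, bin_width=bin_width)


def gaussian_kernel(window: float) -> np.ndarray:
    """Unit-area Gaussian kernel, σ = window ms, truncated at ±3σ, on a 1 ms grid."""
    if window <= 0:
        raise ValueError(f"smoothing window must be positive, got {window}")
    half = int(np.ceil(3 * window))
    x = np.arange(-half, half + 1, dtype=float)
    k = np.exp(-0.5 * (x / window) ** 2)
    return k / k.sum()


def smooth_train(train: BinaryTrain, window: float) -> SmoothedTrain:
    """Convolve the binary vector with a unit-area Gaussian (σ = window ms).

    Zero-padding applies outside the window, so spikes near the edges lose
    mass symmetrically.  Grid points sit at bin centres (-1999.5 … 1999.5).
    """
    kernel = gaussian_kernel(window)
    values = fftconvolve(train.values.astype(float), kernel, mode="same")
    np.clip(values, 0.0, None, out=values)
    grid = np.arange(WINDOW_LEN_MS, dtype=float) + WINDOW_START_MS + 0.5
    return SmoothedTrain(grid=grid, values=values, window=float(window))


def smooth_trial(trial: TrialRecord, window: float) -> SmoothedTrain:
    """Shorthand: rasterize then smooth a trial."""
    return smooth_train(to_binary_train(trial), window)
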