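"""Repeated-split SVM decoding of single-neuron feature vectors.

Each trial is a feature vector (binned counts, smoothed values, aligned-train
values or warp-function values); a neuron's decoding ability is the test-set
accuracy of a linear SVM averaged over 20 random stratified 67/33 splits.
Scores are computed for the full five-tastant problem and for every tastant
pair; a neuron is flagged as *coding* for a taste set when its score exceeds
the population mean by more than one standard deviation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .spike_io import TASTANTS, NeuronDataset, bin_train, smooth_trial, to_binary_train

log = logging.getLogger(__name__)

MIN_TRIALS_PER_CLASS = 3


@dataclass
class FeatureMatrix:
    """Per-trial feature vectors with tastant labels for one neuron."""

    X: np.ndarray
    labels: np.ndarray
    representation_tag: str = "smoothed"
    neuron_id: str = ""

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or len(self.labels) != self.X.shape[0]:
            raise ValueError("X must be 2-d with one label per row")

    def restrict(self, tastes: Sequence[str]) -> "FeatureMatrix":
        m = np.isin(self.labels, list(tastes))
        return FeatureMatrix(
            self.X[m], self.labels[m], self.representation_tag, self.neuron_id
        )


@dataclass(frozen=True)
class ClassScore:
    neuron_id: str
    taste_set: tuple
    representation_tag: str
    score: float
    n_repeats: int


class InsufficientTrialsError(ValueError):
    """A class has too few trials for the repeated-split protocol."""


class _LinearOvRSVM:
    """Linear SVM, C = 1, one-vs-rest.

    Features are standardized per column with statistics from the training
    split only.  Multiclass prediction takes the highest one-vs-rest decision
    value; exact ties resolve to the lexicographically first class.  The
    solver tolerance is relaxed to 1e-2: the classifier is used only for
    test-set predictions, which are insensitive to the final KKT digits,
    and the looser tolerance cuts solver iterations several-fold on
    label-uninformative features.
    """

    _params = dict(kernel="linear", C=1.0, tol=1e-2)

    def fit(self, X, y):
        self.scaler_ = StandardScaler().fit(X)
        Xs = self.scaler_.transform(X)
        self.classes_ = np.unique(y)
        if len(self.classes_) == 2:
            self.models_ = [SVC(**self._params).fit(Xs, y == self.classes_[1])]
        else:
            self.models_ = [
                SVC(**self._params).fit(Xs, y == c) for c in self.classes_
            ]
        return self

    def predict(self, X):
        Xs = self.scaler_.transform(X)
        if len(self.classes_) == 2:
            return self.classes_[(self.models_[0].decision_function(Xs) > 0).astype(int)]
        d = np.column_stack([m.decision_function(Xs) for m in self.models_])
        return self.classes_[np.argmax(d, axis=1)]


def classification_score(
    features: FeatureMatrix,
    n_repeats: int = 20,
    train_frac: float = 0.67,
    seed: int = 0,
) -> ClassScore:
    """Mean test accuracy over repeated stratified 67/33 train/test splits."""
    labels = features.labels
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise InsufficientTrialsError("need at least 2 classes")
    if counts.min() < MIN_TRIALS_PER_CLASS:
        raise InsufficientTrialsError(
            f"class {classes[counts.argmin()]!r} has {counts.min()} trials "
            f"(need ≥ {MIN_TRIALS_PER_CLASS})"
        )
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=seed
    )
    accs = []
    for train_idx, test_idx in splitter.split(features.X, labels):
        clf = _LinearOvRSVM()
        clf.fit(features.X[train_idx], labels[train_idx])
        accs.append(float(np.mean(clf.predict(features.X[test_idx]) == labels[test_idx])))
    return ClassScore(
        neuron_id=features.neuron_id,
        taste_set=tuple(sorted(classes)),
        representation_tag=features.representation_tag,
        score=float(np.mean(accs)),
        n_repeats=n_repeats,
    )


# ---------------------------------------------------------------------------
# Feature extraction from datasets
# ---------------------------------------------------------------------------

def features_from_dataset(
    dataset: NeuronDataset,
    representation: str = "smoothed",
    *,
    window: float = 250.0,
    bin_width: int = 50,
    epoch: str = "post",
    sample_step: int = 10,
) -> FeatureMatrix:
    """Build per-trial feature vectors from a dataset.

    representation 'smoothed' uses the Gaussian-smoothed train sampled every
    ``sample_step`` ms (the smoothed signal is band-limited by the window, so
    10 ms sampling is lossless for windows ≥ ~50 ms and keeps the SVM fast);
    'binned' uses spike counts per bin.  ``epoch`` selects the pre-taste
    ([-2000, 0)) or post-taste ([0, 2000)) half, or 'full'.
    """
    rows, labels = [], []
    for tr in dataset.trials:
        if representation == "smoothed":
            st = smooth_trial(tr, window)
            if epoch == "pre":
                st = st.segment(-2000.0, 0.0)
            elif epoch == "post":
                st = st.segment(0.0, 2000.0)
            rows.append(st.values[::sample_step])
        elif representation == "binned":
            bt = bin_train(to_binary_train(tr), bin_width)
            counts = bt.counts
            n = len(counts)
            if epoch == "pre":
                counts = counts[: n // 2]
            elif epoch == "post":
                counts = counts[n // 2 :]
            rows.append(counts.astype(float))
        else:
            raise ValueError(f"unknown representation {representation!r}")
        labels.append(tr.tastant)
    return FeatureMatrix(
        np.vstack(rows), np.array(labels), representation, dataset.neuron_id
    )


# ---------------------------------------------------------------------------
# Score tables, pairwise decoding, coding neurons
# ---------------------------------------------------------------------------

def taste_pairs() -> list:
    return list(combinations(TASTANTS, 2))


def pairwise_scores(
    dataset: NeuronDataset,
    representation: str = "smoothed",
    *,
    window: float = 250.0,
    bin_width: int = 50,
    n_repeats: int = 20,
    seed: int = 0,
) -> list:
    """One ClassScore per unordered tastant pair (10 per neuron)."""
    feats = features_from_dataset(
        dataset, representation, window=window, bin_width=bin_width
    )
    scores = []
    for pair in taste_pairs():
        try:
            scores.append(
                classification_score(feats.restrict(pair), n_repeats=n_repeats, seed=seed)
            )
        except InsufficientTrialsError as exc:
            log.warning("neuron %s pair %s skipped: %s", dataset.neuron_id, pair, exc)
    return scores


def score_table(scores: Sequence[ClassScore]) -> pd.DataFrame:
    """Population score table with the mean+1SD coding flag per taste set."""
    df = pd.DataFrame(
        {
            "neuron_id": [s.neuron_id for s in scores],
            "taste_set": ["|".join(s.taste_set) for s in scores],
            "representation": [s.representation_tag for s in scores],
            "score": [s.score for s in scores],
            "n_repeats": [s.n_repeats for s in scores],
        }
    )
    if df.empty:
        raise ValueError("empty score table")
    grp = df.groupby(["taste_set", "representation"])["score"]
    df["pop_mean"] = grp.transform("mean")
    df["pop_sd"] = grp.transform("std").fillna(0.0)
    df["coding"] = df["score"] > df["pop_mean"] + df["pop_sd"]
    return df


def coding_pair_cumulative(table: pd.DataFrame) -> pd.DataFrame:
    """Fraction of neurons that are coding neurons for ≥ k taste pairs, k=1..10.

    Monotone nonincreasing in k by construction.
    """
    if table.empty:
        raise ValueError("empty score table")
    per_neuron = table.groupby("neuron_id")["coding"].sum()
    n = len(per_neuron)
    ks = np.arange(1, 11)
    frac = [(per_neuron >= k).sum() / n for k in ks]
    return pd.DataFrame({"k": ks, "fraction": frac})
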