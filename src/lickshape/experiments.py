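"""Self-contained calibration experiments for the decoding pipeline.

Two endpoints anchor the SVM protocol: a population of taste-blind neurons
must decode at chance (0.2 for five tastants), and a neuron with perfectly
separable per-tastant features must decode at exactly 1.  Both run the full
repeated-split protocol end to end (generation → smoothing → classification).
"""

from __future__ import annotations

import numpy as np

from .decoding import FeatureMatrix, classification_score, features_from_dataset
from .spike_io import TASTANTS
from .synthetic import TasteCodeSpec, generate_neuron, population_configs


def chance_calibration(
    n_neurons: int = 200,
    n_trials_per_taste: int = 15,
    seed: int = 0,
    window: float = 250.0,
    n_repeats: int = 20,
    train_frac: float = 0.67,
) -> dict:
    """Mean five-way SVM score over taste-blind synthetic neurons.

    Every tastant shares identical generative parameters, so the features
    carry no label information and the expected score is chance (0.2).
    """
    scores = []
    for cfg in population_configs(
        n_neurons, TasteCodeSpec.uniform(), seed=seed,
        n_trials_per_taste=n_trials_per_taste,
    ):
        ds = generate_neuron(cfg)
        feats = features_from_dataset(ds, "smoothed", window=window, epoch="post")
        scores.append(
            classification_score(
                feats, n_repeats=n_repeats, train_frac=train_frac, seed=cfg.seed
            ).score
        )
    scores = np.asarray(scores)
    return {
        "mean_score": float(scores.mean()),
        "sd": float(scores.std(ddof=1)),
        "n_neurons": n_neurons,
        "n_trials_per_taste": n_trials_per_taste,
    }


def separable_neuron_score(
    n_trials_per_taste: int = 15,
    seed: int = 0,
    n_repeats: int = 20,
    train_frac: float = 0.67,
) -> dict:
    """Five-way SVM score for constant, disjoint per-tastant feature vectors.

    Each tastant's trials share one one-hot block vector; any working
    classifier must label every test trial correctly, so the score is 1.
    """
    block = 4
    X, y = [], []
    for c, taste in enumerate(TASTANTS):
        row = np.zeros(len(TASTANTS) * block)
        row[c * block : (c + 1) * block] = 1.0
        X.extend([row] * n_trials_per_taste)
        y.extend([taste] * n_trials_per_taste)
    feats = FeatureMatrix(np.array(X), np.array(y), "one_hot", "separable")
    score = classification_score(
        feats, n_repeats=n_repeats, train_frac=train_frac, seed=seed
    )
    return {"score": score.score, "n_trials_per_taste": n_trials_per_taste}
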