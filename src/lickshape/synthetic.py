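"""Synthetic lick trains and taste-conditioned spike trains.

The generator emulates the structure of recordings from a freely licking
rodent: rhythmic licking at ~7–8 Hz (interlick interval ≈ 130 ms) with six
dry licks preceding taste delivery at t = 0, and per-tastant spiking whose
rate and lick-phase preference are independently controllable.  Post-taste
spikes follow an inhomogeneous Poisson process whose intensity is modulated
by a von-Mises-shaped bump over lick phase with *unit mean*, so the phase
concentration ``phase_kappa`` reshapes spike timing without changing the
expected spike count — the dissociation of rate and phase codes that real
data cannot guarantee.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import i0

from .spike_io import (
    TASTANTS,
    WINDOW_END_MS,
    WINDOW_START_MS,
    NeuronDataset,
    TrialRecord,
)

MIN_ILI_MS = 20.0  # intervals at or below this are resampled


@dataclass(frozen=True)
class LickModel:
    """Gaussian-jittered periodic licking.

    base_ili is the mean interlick interval in ms (130 ms ≈ 7.7 Hz licking);
    ili_jitter_sd is the SD of the additive Gaussian jitter.  The invariant
    base_ili > 3·ili_jitter_sd keeps resampling of non-positive intervals rare.
    """

    base_ili: float = 130.0
    ili_jitter_sd: float = 10.0
    n_dry_licks: int = 6

    def __post_init__(self):
        if self.base_ili <= 3 * self.ili_jitter_sd:
            raise ValueError("base_ili must exceed 3× ili_jitter_sd")
        if self.ili_jitter_sd < 0 or self.n_dry_licks < 1:
            raise ValueError("ili_jitter_sd must be ≥ 0 and n_dry_licks ≥ 1")


@dataclass(frozen=True)
class TasteParams:
    """Per-tastant spiking parameters.

    mean_rate: post-taste firing rate in spikes/s.
    phase_mu: preferred lick phase in [0, 1).
    phase_kappa: von-Mises concentration (0 ⇒ no phase locking).
    """

    mean_rate: float
    phase_mu: float = 0.0
    phase_kappa: float = 0.0

    def __post_init__(self):
        if self.mean_rate < 0 or self.phase_kappa < 0:
            raise ValueError("rates and concentrations must be nonnegative")
        if not (0 <= self.phase_mu < 1):
            raise ValueError("phase_mu must lie in [0, 1)")


@dataclass(frozen=True)
class TasteCodeSpec:
    """Map tastant → TasteParams, plus the pre-taste baseline rate (spikes/s)."""

    per_tastant: Mapping[str, TasteParams]
    baseline_rate: float = 5.0

    def __post_init__(self):
        missing = [t for t in TASTANTS if t not in self.per_tastant]
        if missing:
            raise ValueError(f"missing tastants in code spec: {missing}")
        if self.baseline_rate < 0:
            raise ValueError("baseline_rate must be nonnegative")

    @classmethod
    def uniform(cls, rate: float = 10.0, baseline_rate: float = 5.0) -> "TasteCodeSpec":
        """Identical parameters for every tastant: a taste-blind neuron."""
        return cls({t: TasteParams(mean_rate=rate) for t in TASTANTS}, baseline_rate)

    @classmethod
    def rate_code(
        cls,
        rates: Sequence[float] = (2, 4, 8, 16, 32),
        baseline_rate: float = 5.0,
    ) -> "TasteCodeSpec":
        """Tastants differ only in firing rate."""
        return cls(
            {t: TasteParams(mean_rate=r) for t, r in zip(TASTANTS, rates)},
            baseline_rate,
        )

    @classmethod
    def phase_code(
        cls,
        rate: float = 10.0,
        phase_mus: Sequence[float] = (0.1, 0.3, 0.5, 0.7, 0.9),
        kappa: float = 8.0,
        baseline_rate: float = 5.0,
    ) -> "TasteCodeSpec":
        """Tastants share one rate but prefer distinct lick phases."""
        return cls(
            {
                t: TasteParams(mean_rate=rate, phase_mu=m, phase_kappa=kappa)
                for t, m in zip(TASTANTS, phase_mus)
            },
            baseline_rate,
        )


@dataclass(frozen=True)
class GeneratorConfig:
    neuron_id: str = "synth-0"
    n_trials_per_taste: int = 15
    seed: int = 0
    lick_model: LickModel = field(default_factory=LickModel)
    code_spec: TasteCodeSpec = field(default_factory=TasteCodeSpec.uniform)

    def __post_init__(self):
        if self.n_trials_per_taste < 1:
            raise ValueError("n_trials_per_taste must be ≥ 1")


def _draw_ili(model: LickModel, rng: np.random.Generator) -> float:
    while True:
        ili = model.base_ili + rng.normal(0.0, model.ili_jitter_sd)
        if ili > MIN_ILI_MS:
            return ili


def generate_lick_train(model: LickModel, rng) -> np.ndarray:
    """Lick times (ms) covering the whole window, one lick exactly at t = 0.

    Licking is rhythmic throughout the 4 s window, which guarantees at least
    ``n_dry_licks`` dry licks before delivery and at least five complete
    post-delivery interlick intervals.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    pre = []
    t = 0.0
    while True:
        t -= _draw_ili(model, rng)
        if t < WINDOW_START_MS:
            break
        pre.append(t)
    post = []
    t = 0.0
    while True:
        t += _draw_ili(model, rng)
        if t >= WINDOW_END_MS:
            break
        post.append(t)
    licks = np.array(pre[::-1] + [0.0] + post)
    if (licks < 0).sum() < model.n_dry_licks or (licks > 0).sum() < 6:
        raise ValueError("lick model cannot cover the window rhythmically")
    return licks


def phase_modulation(phase: np.ndarray, params: TasteParams) -> np.ndarray:
    """Unit-mean von-Mises bump over lick phase ∈ [0, 1)."""
    if params.phase_kappa == 0:
        return np.ones_like(phase)
    return np.exp(
        params.phase_kappa * np.cos(2 * np.pi * (phase - params.phase_mu))
    ) / i0(params.phase_kappa)


def _lick_phase(t: np.ndarray, licks: np.ndarray) -> np.ndarray:
    """Relative position of each time within its enclosing interlick interval."""
    i = np.searchsorted(licks, t, side="right")
    i = np.clip(i, 1, len(licks) - 1)
    lo, hi = licks[i - 1], licks[i]
    return (t - lo) / (hi - lo)


def _homogeneous_poisson(rate_hz: float, t0: float, t1: float, rng) -> np.ndarray:
    n = rng.poisson(rate_hz * (t1 - t0) / 1000.0)
    return np.sort(rng.uniform(t0, t1, size=n))


def _post_taste_spikes(
    params: TasteParams, licks: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Inhomogeneous Poisson spikes on [0, 2000) by thinning.

    Intensity λ(t) = mean_rate · m(φ(t)) where φ(t) is the lick phase and m
    the unit-mean von-Mises modulation; λ_max = mean_rate · e^κ / I₀(κ).
    """
    if params.mean_rate == 0:
        return np.empty(0)
    lam_max = params.mean_rate * (
        np.exp(params.phase_kappa) / i0(params.phase_kappa)
        if params.phase_kappa > 0
        else 1.0
    )
    cand = _homogeneous_poisson(lam_max, 0.0, WINDOW_END_MS, rng)
    if cand.size == 0:
        return cand
    lam = params.mean_rate * phase_modulation(_lick_phase(cand, licks), params)
    keep = rng.uniform(0.0, 1.0, size=cand.size) < lam / lam_max
    return cand[keep]


def generate_trial(
    tastant: str,
    config: GeneratorConfig,
    rng: np.random.Generator,
    trial_id: str,
) -> TrialRecord:
    licks = generate_lick_train(config.lick_model, rng)
    params = config.code_spec.per_tastant[tastant]
    pre = _homogeneous_poisson(
        config.code_spec.baseline_rate, WINDOW_START_MS, 0.0, rng
    )
    post = _post_taste_spikes(params, licks, rng)
    spikes = np.concatenate([pre, post])
    # strict monotonicity: drop exact duplicates (prob. 0 events aside)
    spikes = np.unique(spikes)
    return TrialRecord(
        neuron_id=config.neuron_id,
        trial_id=trial_id,
        tastant=tastant,
        spike_times=spikes,
        lick_times=licks,
    )


def generate_neuron(config: GeneratorConfig) -> NeuronDataset:
    """Generate one neuron's full trial set; byte-identical under a fixed seed."""
    rng = np.random.default_rng(config.seed)
    ds = NeuronDataset(neuron_id=config.neuron_id)
    for tastant in TASTANTS:
        for k in range(config.n_trials_per_taste):
            ds.trials.append(
                generate_trial(tastant, config, rng, trial_id=f"{tastant}-{k:03d}")
            )
    return ds


def generate_population(configs: Sequence[GeneratorConfig]) -> list:
    """Independent neurons, one per config; neuron_ids must be unique."""
    ids = [c.neuron_id for c in configs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate neuron_ids in population configs")
    return [generate_neuron(c) for c in configs]


def population_configs(
    n_neurons: int,
    code_spec: TasteCodeSpec,
    seed: int,
    n_trials_per_taste: int = 15,
    lick_model: LickModel | None = None,
    id_prefix: str = "synth",
) -> list:
    """Configs for a homogeneous population with independent per-neuron seeds."""
    child = np.random.SeedSequence(seed).generate_state(n_neurons, dtype=np.uint32)
    return [
        GeneratorConfig(
            neuron_id=f"{id_prefix}-{i:04d}",
            n_trials_per_taste=n_trials_per_taste,
            seed=int(s) % (2**31),
            lick_model=lick_model or LickModel(),
            code_spec=code_spec,
        )
        for i, s in enumerate(child)
    ]


# -- JSON config round-trip (CLI surface) -----------------------------------

def config_to_dict(config: GeneratorConfig) -> dict:
    return {
        "neuron_id": config.neuron_id,
        "n_trials_per_taste": config.n_trials_per_taste,
        "seed": config.seed,
        "lick_model": vars(config.lick_model).copy(),
        "code_spec": {
            "baseline_rate": config.code_spec.baseline_rate,
            "per_tastant": {
                t: vars(p).copy() for t, p in config.code_spec.per_tastant.items()
            },
        },
    }


def config_from_dict(d: dict) -> GeneratorConfig:
    spec = d.get("code_spec", {})
    return GeneratorConfig(
        neuron_id=d.get("neuron_id", "synth-0"),
        n_trials_per_taste=d.get("n_trials_per_taste", 15),
        seed=d.get("seed", 0),
        lick_model=LickModel(**d.get("lick_model", {})),
        code_spec=TasteCodeSpec(
            per_tastant={
                t: TasteParams(**p) for t, p in spec.get("per_tastant", {}).items()
            },
            baseline_rate=spec.get("baseline_rate", 5.0),
        )
        if spec.get("per_tastant")
        else TasteCodeSpec.uniform(),
    )


def load_config(path) -> GeneratorConfig:
    with open(path) as fh:
        return config_from_dict(json.load(fh))
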