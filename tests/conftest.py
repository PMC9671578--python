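import warnings

import numpy as np
import pytest

from lickshape.spike_io import SmoothedTrain, TrialRecord
from lickshape.synthetic import GeneratorConfig, TasteCodeSpec, generate_neuron


@pytest.fixture(autouse=True)
def _quiet_collapse_warning():
    # sub-ms spike collisions are expected at realistic rates
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="sub-millisecond spike pair collapsed"
        )
        yield


@pytest.fixture(scope="session")
def null_neuron():
    """A taste-blind neuron: identical generative parameters for all tastants."""
    return generate_neuron(GeneratorConfig(seed=101, code_spec=TasteCodeSpec.uniform()))


@pytest.fixture(scope="session")
def rate_neuron():
    """A rate-coding neuron (2..32 spikes/s across tastants, no phase locking)."""
    return generate_neuron(GeneratorConfig(seed=102, code_spec=TasteCodeSpec.rate_code()))


@pytest.fixture(scope="session")
def phase_neuron():
    """A phase-coding neuron (shared rate, distinct preferred lick phases)."""
    return generate_neuron(GeneratorConfig(seed=103, code_spec=TasteCodeSpec.phase_code()))


def make_trial(spikes, licks, tastant="sucrose", neuron="n0", trial="t0"):
    return TrialRecord(
        neuron_id=neuron,
        trial_id=trial,
        tastant=tastant,
        spike_times=np.asarray(spikes, float),
        lick_times=np.asarray(licks, float),
    )


def unit_train(values, lo=0.0, hi=1.0):
    g = np.linspace(lo, hi, len(values))
    return SmoothedTrain(g, np.asarray(values, float), window=1.0)
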