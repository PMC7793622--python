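import numpy as np
import pytest

from windcompass import synthetic_ephys as se
from windcompass import closed_loop_sim as cl


@pytest.fixture
def airflow_trial():
    return se.TrialSpec(direction=90.0, condition="airflow")


@pytest.fixture
def default_neuron():
    return se.NeuronModel()


@pytest.fixture
def quiet_neuron():
    """No oscillation, no noise, no spikes: a flat membrane."""
    return se.NeuronModel(osc_amp=0.0, osc_freq=0.0, noise_sd=0.0,
                          baseline_rate=0.0, a_air=0.0, a_stripe=0.0)


@pytest.fixture
def default_arena():
    return cl.ArenaConfig()


@pytest.fixture
def still_agent():
    """Agent that never steers (zero gain, no noise, no pause bias)."""
    return cl.FlyAgent(k=0.0, noise_sd=0.0, pause_bias=0.0)
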