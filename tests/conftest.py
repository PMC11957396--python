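import numpy as np
import pandas as pd
import pytest

from gonogo import qlearning as ql
from gonogo import synth


@pytest.fixture(scope="session")
def small_behavior():
    """Two synthetic mice, 4 sessions x 80 trials, with lick times."""
    cfg = synth.SynthConfig(n_mice=2, n_sessions=4, trials_per_session=80)
    trials, traces, params = synth.gen_behavior(cfg, seed=42)
    return trials, traces, params


@pytest.fixture(scope="session")
def small_spikes(small_behavior):
    """Planted-structure spike table for one mouse of ``small_behavior``."""
    trials, traces, _ = small_behavior
    one = trials[trials["mouse"] == "mouse00"].reset_index(drop=True)
    cfg = synth.SynthConfig(n_neurons_per_session=8)
    spikes, factors, gains = synth.gen_spikes(
        cfg, one, {"mouse00": traces["mouse00"]}, seed=7
    )
    return spikes, factors, gains, one


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
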