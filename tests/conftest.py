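import numpy as np
import pytest

from degronmap import GeneratorConfig, gen_array_signals, rgs2_degron_profile


@pytest.fixture(scope="session")
def degron_profile():
    return rgs2_degron_profile()


@pytest.fixture(scope="session")
def noisy_degron_dataset(degron_profile):
    """One replicated array generated with the degron ground-truth pattern."""
    cfg = GeneratorConfig(seed=11, noise_model="lognormal", noise_scale=0.1, n_replicates=9)
    return gen_array_signals(degron_profile, parent_signal=1000.0, config=cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
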