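import numpy as np
import pytest

from vgaedti.synthgen import SynthConfig, generate


@pytest.fixture(scope="session")
def small_synth():
    """A small but structured bundle shared by fast pipeline tests."""
    return generate(
        SynthConfig(
            n_drugs=20,
            n_targets=25,
            n_diseases=8,
            latent_rank=4,
            edge_density=0.12,
            noise_flip_rate=0.0,
            seed=1234,
        )
    )


@pytest.fixture(scope="session")
def small_net(small_synth):
    return small_synth.network()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
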