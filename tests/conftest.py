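import numpy as np
import pytest

import bistream as bs


@pytest.fixture(scope="session")
def small_cfg():
    """Two short blocks (100 trials) at the native 600 Hz rate."""
    return bs.StimulusConfig(block_s=30.0, n_blocks=2)


@pytest.fixture(scope="session")
def small_effect():
    return bs.SourceEffect(
        positions=np.array([[54.0, -14.0, 11.0], [-49.0, -20.0, 5.0]]),
        effect_amplitude=0.55,
        effect_sources=(0,),
    )


@pytest.fixture(scope="session")
def small_process():
    return bs.PerceptProcess(mu_log=np.log(5.0), sigma_log=0.5, seed=0)


@pytest.fixture(scope="session")
def small_recording(small_cfg, small_process, small_effect):
    """A small but complete synthetic recording (32 sensors, 24 sources)."""
    return bs.generate_dataset(
        small_cfg,
        small_process,
        small_effect,
        seed=11,
        n_sensors=32,
        n_background_sources=22,
        noise_sd=1.0,
    )


@pytest.fixture(scope="session")
def small_epochs(small_recording):
    return bs.preprocess_recording(small_recording)
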