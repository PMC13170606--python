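import numpy as np
import pytest

from mpa_nfdk import (Montage, NoiseParams, ProtocolConfig,
                      build_session_timeline, preprocess_pipeline,
                      simulate_session)


@pytest.fixture(scope="session")
def config():
    return ProtocolConfig()


@pytest.fixture(scope="session")
def timeline(config):
    return build_session_timeline(config, 1)


@pytest.fixture(scope="session")
def small_montage():
    return Montage.default().subset(["S3-D2", "S5-D5", "S1-D1"])


@pytest.fixture(scope="session")
def noisy_recording(config, small_montage):
    return simulate_session(config, 1, small_montage, seed=11)


@pytest.fixture(scope="session")
def silent_recording(config, small_montage):
    return simulate_session(config, 1, small_montage,
                            noise=NoiseParams.silent(), seed=11)


@pytest.fixture(scope="session")
def noisy_hemo(noisy_recording):
    return preprocess_pipeline(noisy_recording)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
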