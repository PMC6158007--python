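import numpy as np
import pytest

from synphys import detect
from synphys.synthgen import (NoiseModel, SyntheticAmplitudeModel,
                              SyntheticPSPConfig, make_protocol,
                              synthesize_background_pool, synthesize_pair)

# tests run at 20 kHz to keep the suite fast; the default acquisition rate
# (50 kHz) is exercised where the check is about discretization
DT = 0.05


@pytest.fixture(scope="session")
def protocol50():
    return make_protocol(50.0, 250.0, n_trials=5)


@pytest.fixture(scope="session")
def psp_config():
    return SyntheticPSPConfig()


@pytest.fixture(scope="session")
def connected_pair(protocol50, psp_config):
    sweeps, truth = synthesize_pair(
        protocol50, psp_config,
        SyntheticAmplitudeModel(target_mean_amplitude=0.5),
        noise=NoiseModel(rms=0.15), seed=42, dt=DT)
    return sweeps, truth


@pytest.fixture(scope="session")
def background_pool(protocol50):
    return synthesize_background_pool(10, protocol50, seed=77, dt=DT)


@pytest.fixture(scope="session")
def trained_classifier(protocol50, psp_config):
    """Classifier trained on a small synthetic benchmark: connected pairs
    spanning 0.02-2 mV plus heterogeneous-noise backgrounds."""
    feats, labels = [], []
    for i, amp in enumerate(np.geomspace(0.02, 2.0, 40)):
        sweeps, _ = synthesize_pair(
            protocol50, psp_config,
            SyntheticAmplitudeModel(target_mean_amplitude=float(amp)),
            seed=11, dt=DT, pair_key=i)
        feats.append(detect.extract_features(sweeps))
        labels.append(True)
    for b in synthesize_background_pool(80, protocol50, seed=12, dt=DT):
        feats.append(detect.extract_features(b))
        labels.append(False)
    return detect.train_classifier(list(zip(feats, labels)), seed=0)
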