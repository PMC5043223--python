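import numpy as np
import pytest

from p300bench.speller_pipeline import SimulatorConfig, build_training_features
from p300bench.synthetic_eeg import ERPTemplate, get_profile


@pytest.fixture(scope="session")
def hydrogel_cfg():
    """Moderate-SNR hydrogel configuration (per-flash SNR ≈ 0.74)."""
    return SimulatorConfig(get_profile("hydrogel"),
                           ERPTemplate(peak_amplitude=5.0))


@pytest.fixture(scope="session")
def high_snr_cfg():
    """Near-noise-free configuration for ceiling-accuracy checks."""
    return SimulatorConfig(get_profile("hydrogel"),
                           ERPTemplate(peak_amplitude=20.0))


@pytest.fixture(scope="session")
def trained_features(hydrogel_cfg):
    """Feature matrix + targets from one 15-sequence "BRAIN" training run."""
    return build_training_features(hydrogel_cfg,
                                   seed=np.random.SeedSequence(11))
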