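import numpy as np
import pytest

from neuroindex.predictor import ModelParams
from neuroindex.spectral import PSDEstimate
from neuroindex.synth import SynthEEGConfig, generate_eeg_pair


def make_psd(power_per_channel: dict[str, np.ndarray], freqs: np.ndarray) -> PSDEstimate:
    """Assemble a PSDEstimate from per-channel power vectors on a grid."""
    labels = list(power_per_channel)
    power = np.vstack([power_per_channel[ch] for ch in labels])
    df = float(freqs[1] - freqs[0])
    return PSDEstimate(
        freqs_hz=freqs,
        power=power,
        resolution_hz=df,
        epoch_seconds=1.0 / df,
        labels=labels,
    )


@pytest.fixture(scope="session")
def welch_grid():
    """Frequency grid of a 4-s epoch at 128 Hz (0 .. 64 Hz, step 0.25)."""
    return np.arange(0.0, 64.25, 0.25)


@pytest.fixture(scope="session")
def single_peak_params():
    return ModelParams(k1=1.0, a2=50.0, k2=-1.2, a3=8.0, mu=10.0, sigma=1.0)


@pytest.fixture(scope="session")
def eeg_pair():
    """One strongly reactive synthetic EC/EO pair (alpha at 10.25 Hz)."""
    config = SynthEEGConfig(seed=7, alpha_bandwidth_hz=1.0)
    return generate_eeg_pair(config)
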