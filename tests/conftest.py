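import numpy as np
import pytest

from bcibench.core import EpochSet, Marker, Recording
from bcibench.synthgen import SynthConfig, generate_synchronous


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture
def small_recording(rng):
    """Plain white-noise recording with a few balanced markers."""
    fs = 100.0
    signals = rng.standard_normal((3, 4000))
    markers = [
        Marker(onset_sample=200 + 350 * i, label="left" if i % 2 == 0 else "right")
        for i in range(10)
    ]
    return Recording(
        signals=signals,
        sampling_rate=fs,
        channel_labels=["C3", "Cz", "C4"],
        markers=markers,
    )


@pytest.fixture
def random_epochs(rng):
    return EpochSet(
        epochs=rng.standard_normal((12, 4, 200)),
        labels=np.array(["a", "b"] * 6, dtype=object),
        sampling_rate=100.0,
        window=(0.0, 2.0),
    )


@pytest.fixture(scope="session")
def erd_config():
    """Small but strongly separable alpha-ERD study: 30 trials/class at 100 Hz."""
    return SynthConfig(
        n_channels=4,
        sampling_rate=100.0,
        trials_per_class=30,
        trial_length_s=3.0,
        inter_trial_s=0.5,
        modulation={"left": (1.0, 1.0), "right": (0.3, 1.0)},
        noise_sd=0.5,
        seed=7,
    )


@pytest.fixture(scope="session")
def erd_recording(erd_config):
    return generate_synchronous(erd_config)
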