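import numpy as np
import pandas as pd
import pytest

from beattag.epochs import EpochedEEG


@pytest.fixture(scope="session")
def rhythm_table():
    from beattag.rhythms import builtin_rhythm_table

    return builtin_rhythm_table()


def make_epochs(
    data: np.ndarray,
    sample_rate: float = 256.0,
    condition: str = "strong",
    session: str = "pre",
    rhythm_set: str = "trained",
) -> EpochedEEG:
    """Wrap a trials x channels x samples array with uniform labels."""
    n = data.shape[0]
    return EpochedEEG(
        data=data,
        sample_rate=sample_rate,
        trials=pd.DataFrame(
            {"condition": [condition] * n, "session": [session] * n,
             "rhythm_set": [rhythm_set] * n}
        ),
    )


def sinusoid_epochs(
    freq_hz: float,
    amplitude: float = 1.0,
    phase: float = 0.0,
    n_trials: int = 4,
    n_channels: int = 8,
    sample_rate: float = 256.0,
    duration_s: float = 8.0,
    **labels,
) -> EpochedEEG:
    """Noiseless epochs of one cosine, identical across trials and channels."""
    t = np.arange(int(sample_rate * duration_s)) / sample_rate
    wave = amplitude * np.cos(2 * np.pi * freq_hz * t + phase)
    return make_epochs(
        np.tile(wave, (n_trials, n_channels, 1)), sample_rate, **labels
    )
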