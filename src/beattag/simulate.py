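"""Synthetic epoched EEG with known ground truth.

The generator emulates the signal model the spectral pipeline assumes:
an aperiodic background whose expected amplitude spectrum decays as
``a * b**f`` (the exponential "1/f" form the analysis fits and subtracts),
plus phase-locked sinusoidal components at the frequencies of interest.
Each component's phase is drawn once per trial from a von Mises
distribution (mean ``mu``, concentration ``kappa``) and shared across
channels — a volume-conduction-like model that matches the pipeline's
channel averaging — with multiplicative per-channel sensor gains.
Optionally, a damped-oscillation kernel convolved with a tone-onset train
adds onset-evoked responses.

Ground truth is recorded alongside the data, so every analysis stage can
be checked against what was injected: the time-domain average of a
component with concentration ``kappa`` converges to its amplitude times
the population resultant length ``I1(kappa)/I0(kappa)``, which is also the
expected intertrial phase coherence.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import i0e, i1e

from .epochs import EpochedEEG

__all__ = [
    "Component",
    "SyntheticEEGConfig",
    "expected_itpc",
    "generate_trial",
    "generate_dataset",
    "damped_oscillation_kernel",
]

CONDITIONS = ("strong", "weak", "non")
SESSIONS = ("pre", "post")
RHYTHM_SETS = ("trained", "untrained")


@dataclass(frozen=True)
class Component:
    """One phase-locked sinusoid: frequency (Hz), amplitude (uV), von Mises
    phase concentration kappa (>= 0; 0 = uniform phase, inf-like values =
    fully phase-locked) and mean phase (radians, cosine convention)."""

    freq_hz: float
    amplitude_uv: float
    kappa: float
    mean_phase: float = 0.0

    def __post_init__(self) -> None:
        if self.amplitude_uv < 0:
            raise ValueError("component amplitude must be nonnegative")
        if self.kappa < 0:
            raise ValueError("kappa must be nonnegative")


def _default_components() -> dict[str, tuple[Component, ...]]:
    # Condition-specific ground truth mirroring the experimental ordering:
    # 1-Hz (beat) amplitude and phase concentration strong > weak > non,
    # plus a stimulus-rate component (4 Hz integer rhythms, 3.34 Hz non-beat).
    # Amplitudes sit well above the residual noise floor left after
    # trial averaging at the default trial counts (see docs/methods.md).
    return {
        "strong": (Component(1.0, 1.0, 15.0), Component(4.0, 0.8, 15.0)),
        "weak": (Component(1.0, 0.7, 8.0), Component(4.0, 0.9, 8.0)),
        "non": (Component(1.0, 0.4, 4.0), Component(3.34, 0.6, 4.0)),
    }


@dataclass
class SyntheticEEGConfig:
    """Study-shaped generator settings.

    Defaults mirror the recording parameters of the experiment the
    pipeline targets: 64 channels at 1024 Hz, ~18-s trials, and 24 trials
    per condition x session x rhythm-set cell (each of six blocks presented
    the four rhythms of a condition/set cell once per session).
    ``fast_profile`` gives a cheap variant for quick runs.
    """

    n_trials: int = 24
    n_channels: int = 64
    sample_rate: float = 1024.0
    trial_duration_s: float = 18.0
    aperiodic_a: float = 0.3
    aperiodic_b: float = 0.75
    components: Mapping[str, Sequence[Component]] | Sequence[Component] | None = None
    onset_kernel: np.ndarray | None = None
    onset_times_s: Mapping[str, Sequence[float]] | None = None
    channel_gain_sd: float = 0.1
    conditions: tuple[str, ...] = CONDITIONS
    sessions: tuple[str, ...] = SESSIONS
    rhythm_sets: tuple[str, ...] = RHYTHM_SETS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.trial_duration_s <= 0 or self.sample_rate <= 0:
            raise ValueError("trial duration and sample rate must be positive")
        if not 0 < self.aperiodic_b <= 1:
            raise ValueError("aperiodic decay factor b must be in (0, 1]")
        if self.aperiodic_a < 0:
            raise ValueError("aperiodic intercept a must be nonnegative")
        if self.components is None:
            self.components = _default_components()
        elif not isinstance(self.components, Mapping):
            self.components = {c: tuple(self.components) for c in self.conditions}
        else:
            self.components = {k: tuple(v) for k, v in self.components.items()}

    @classmethod
    def fast_profile(cls, **overrides) -> "SyntheticEEGConfig":
        """Reduced-size settings (16 channels, 256 Hz, 6-s trials)."""
        defaults = dict(n_channels=16, sample_rate=256.0, trial_duration_s=6.0)
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_s * self.sample_rate))

    def components_for(self, condition: str) -> tuple[Component, ...]:
        assert isinstance(self.components, Mapping)
        return tuple(self.components.get(condition, ()))


def expected_itpc(kappa: float) -> float:
    """Population resultant vector length of a von Mises distribution.

    ``I1(kappa) / I0(kappa)`` — 0 for uniform phases, approaching 1 as the
    distribution concentrates. This is both the expected intertrial phase
    coherence and the attenuation factor that time-domain trial averaging
    applies to a component's amplitude.
    """
    if kappa < 0:
        raise ValueError("kappa must be nonnegative")
    # exponentially scaled Bessel ratio is stable for large kappa
    return float(i1e(kappa) / i0e(kappa))


def _aperiodic_background(
    config: SyntheticEEGConfig, rng: np.random.Generator
) -> np.ndarray:
    """Channels x samples noise whose amplitude spectrum is a * b**f exactly.

    White noise shaped in the frequency domain: each positive-frequency bin
    gets magnitude ``(N/2) * a * b**f`` and an independent uniform random
    phase, so the analysis convention ``2/N * |FFT|`` reads back a * b**f
    bin for bin, while trial-to-trial phases are incoherent.
    """
    n = config.n_samples
    freqs = np.fft.rfftfreq(n, d=1.0 / config.sample_rate)
    profile = (n / 2.0) * config.aperiodic_a * config.aperiodic_b ** freqs
    profile[0] = 0.0  # no DC offset
    if n % 2 == 0:
        profile[-1] = 0.0  # drop the (real-valued) Nyquist bin
    phases = rng.uniform(0, 2 * np.pi, size=(config.n_channels, freqs.size))
    return np.fft.irfft(profile * np.exp(1j * phases), n=n, axis=-1)


def _channel_gains(config: SyntheticEEGConfig, rng: np.random.Generator) -> np.ndarray:
    gains = 1.0 + config.channel_gain_sd * rng.standard_normal(config.n_channels)
    return np.clip(gains, 0.1, None)


def generate_trial(
    config: SyntheticEEGConfig,
    rng: np.random.Generator,
    condition: str = "strong",
    gains: np.ndarray | None = None,
) -> np.ndarray:
    """One trial (channels x samples, uV): shaped background + phase-locked
    components (+ optional onset-evoked responses)."""
    x = _aperiodic_background(config, rng)
    gains = _channel_gains(config, rng) if gains is None else np.asarray(gains)
    t = np.arange(config.n_samples) / config.sample_rate

    for comp in config.components_for(condition):
        if comp.kappa == 0:
            phi = rng.uniform(-np.pi, np.pi)
        else:
            phi = rng.vonmises(comp.mean_phase, comp.kappa)
        wave = comp.amplitude_uv * np.cos(2 * np.pi * comp.freq_hz * t + phi)
        x += gains[:, None] * wave[None, :]

    if config.onset_kernel is not None and config.onset_times_s is not None:
        onsets = config.onset_times_s.get(condition, ())
        if len(onsets):
            train = np.zeros(config.n_samples)
            idx = np.round(np.asarray(onsets) * config.sample_rate).astype(int)
            train[idx[idx < config.n_samples]] = 1.0
            evoked = np.convolve(train, config.onset_kernel)[: config.n_samples]
            x += gains[:, None] * evoked[None, :]
    return x


def generate_dataset(config: SyntheticEEGConfig) -> EpochedEEG:
    """Assemble labeled trials for every condition x session x set cell.

    All randomness flows from ``config.seed``; channel gains are drawn once
    and shared across trials (fixed sensor array). Ground truth — injected
    components, their expected trial-averaged amplitude
    (amplitude x I1(kappa)/I0(kappa)) and expected ITPC — is recorded in
    the dataset metadata.
    """
    rng = np.random.default_rng(config.seed)
    gains = _channel_gains(config, rng)

    data, rows = [], []
    for condition in config.conditions:
        for session in config.sessions:
            for rhythm_set in config.rhythm_sets:
                for _ in range(config.n_trials):
                    data.append(generate_trial(config, rng, condition, gains))
                    rows.append(
                        {"condition": condition, "session": session, "rhythm_set": rhythm_set}
                    )

    truth = [
        {
            "condition": cond,
            "freq_hz": comp.freq_hz,
            "amplitude_uv": comp.amplitude_uv,
            "kappa": comp.kappa,
            "mean_phase": comp.mean_phase,
            "expected_itpc": expected_itpc(comp.kappa),
            "expected_averaged_amplitude_uv": comp.amplitude_uv * expected_itpc(comp.kappa),
        }
        for cond in config.conditions
        for comp in config.components_for(cond)
    ]
    meta = {
        "seed": config.seed,
        "sample_rate": config.sample_rate,
        "trial_duration_s": config.trial_duration_s,
        "aperiodic_a": config.aperiodic_a,
        "aperiodic_b": config.aperiodic_b,
        "channel_gain_sd": config.channel_gain_sd,
        "n_trials_per_cell": config.n_trials,
        "ground_truth": truth,
    }
    return EpochedEEG(
        data=np.stack(data),
        sample_rate=config.sample_rate,
        trials=pd.DataFrame(rows),
        meta=meta,
    )


def ground_truth_table(epochs: EpochedEEG) -> pd.DataFrame:
    """The generator's injected components as a tidy DataFrame."""
    return pd.DataFrame(epochs.meta.get("ground_truth", []))


def damped_oscillation_kernel(
    freq_hz: float = 10.0,
    decay_s: float = 0.1,
    sample_rate: float = 1024.0,
    duration_s: float = 0.6,
    amplitude_uv: float = 1.0,
) -> np.ndarray:
    """Exponentially damped sinusoid for onset-evoked responses."""
    t = np.arange(int(round(duration_s * sample_rate))) / sample_rate
    return amplitude_uv * np.exp(-t / decay_s) * np.sin(2 * np.pi * freq_hz * t)
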