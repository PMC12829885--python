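"""Intertrial phase coherence (ITPC) at a frequency of interest.

Phase-locked (entrained) activity shows up not only as spectral amplitude
but as phase consistency across trials. Per trial, a complex spectrum is
computed for every channel under the same zero-padded FFT convention as
the amplitude pipeline, the complex values are averaged across channels
(amplitude-weighted, so strong channels dominate and opposite-phase
channels cancel), and the phase angle at the bin nearest the frequency of
interest is extracted. ITPC is the resultant vector length of those
per-trial unit phasors: 1 when every trial has the same phase, near 0 for
uniformly scattered phases (with the usual ~1/sqrt(n) small-sample bias).

Phase convention: angle relative to a cosine at trial start; trials must
share a stimulus-locked time zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .epochs import EpochedEEG

__all__ = ["TrialPhases", "ITPCResult", "single_trial_phase", "itpc"]

#: complex-mean magnitudes below this fraction of the channel RMS magnitude
#: mark the trial's phase as undefined (opposite-phase cancellation)
UNDEFINED_PHASE_RTOL = 1e-12


@dataclass
class TrialPhases:
    """Per-trial phase angles at one frequency bin.

    ``n_undefined`` counts trials excluded because the channel-averaged
    complex value had near-zero magnitude (phase undefined).
    """

    phases: np.ndarray
    foi_hz: float
    bin_hz: float
    n_undefined: int = 0

    def __len__(self) -> int:
        return self.phases.size


@dataclass
class ITPCResult:
    """Resultant vector length and mean angle of per-trial phases."""

    r: float
    mean_angle: float
    n_trials: int
    foi_hz: float

    def __post_init__(self) -> None:
        if not -1e-9 <= self.r <= 1 + 1e-9:
            raise ValueError("resultant vector length must lie in [0, 1]")
        self.r = float(min(max(self.r, 0.0), 1.0))


def single_trial_phase(
    epochs: EpochedEEG,
    foi_hz: float,
    resolution: float = 0.0125,
) -> TrialPhases:
    """Channel-averaged complex spectral phase of each trial at ``foi_hz``.

    Uses the amplitude pipeline's FFT convention (mean removal, zero
    padding to the 1/resolution window); channel combination is complex
    averaging, not phase-angle averaging.
    """
    from .spectral import _fft_length  # local import avoids a module cycle

    if epochs.n_trials == 0:
        raise ValueError("no trials")
    if foi_hz >= epochs.sample_rate / 2:
        raise ValueError("frequency of interest must be below Nyquist")
    n_signal = epochs.n_samples
    n_fft = _fft_length(epochs.sample_rate, resolution)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / epochs.sample_rate)
    # nearest bin, ties toward lower — same rule as the amplitude readout
    pos = foi_hz / resolution
    lo = int(np.floor(pos))
    k = lo + 1 if (pos - lo) > (lo + 1 - pos) else lo

    centered = epochs.data - epochs.data.mean(axis=-1, keepdims=True)
    # rfft of the full padded array at one bin only: direct DTFT is cheaper
    t = np.arange(n_signal)
    phasor = np.exp(-2j * np.pi * k * t / n_fft)
    coef = (centered @ phasor) * (2.0 / n_signal)  # trials x channels, complex

    chan_mean = coef.mean(axis=1)
    rms = np.sqrt(np.mean(np.abs(coef) ** 2, axis=1))
    defined = np.abs(chan_mean) > UNDEFINED_PHASE_RTOL * np.maximum(rms, 1e-300)
    return TrialPhases(
        phases=np.angle(chan_mean[defined]),
        foi_hz=foi_hz,
        bin_hz=float(freqs[k]),
        n_undefined=int((~defined).sum()),
    )


def itpc(phases: TrialPhases | np.ndarray) -> ITPCResult:
    """Resultant vector length of per-trial phases.

    ``r = |mean(exp(i*phi))|``; the mean angle is the argument of that
    complex mean. Requires at least two trials.
    """
    if isinstance(phases, TrialPhases):
        foi = phases.foi_hz
        values = phases.phases
    else:
        foi = np.nan
        values = np.asarray(phases, dtype=np.float64)
    if values.size < 2:
        raise ValueError("ITPC needs at least two trial phases")
    mean_vec = np.exp(1j * values).mean()
    return ITPCResult(
        r=float(np.abs(mean_vec)),
        mean_angle=float(np.angle(mean_vec)),
        n_trials=int(values.size),
        foi_hz=float(foi),
    )
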