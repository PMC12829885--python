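"""The frequency-tagging spectral pipeline.

Stages, in the order the analysis applies them:

1. artifact rejection — drop any trial in which a channel's peak-to-peak
   range exceeds 300 uV;
2. time-domain averaging of trials within a condition x session x set
   cell, per channel, to isolate phase-locked (entrained) activity;
3. FFT of each channel's average on a fixed 0.0125-Hz grid (the mean-
   removed series is zero-padded to an 80-s effective window), with
   amplitude scaled as ``2/N * |FFT|`` so a sinusoid's amplitude is read
   directly in uV;
4. averaging of the amplitude (not complex) spectra across channels;
5. fitting the aperiodic background ``a * b**f`` over 0.5-6 Hz (bins near
   the frequencies of interest and their harmonics excluded) and
   subtracting it, flattening the spectrum so periodic peaks remain above
   zero (negative residuals are retained — the correction can overshoot);
6. reading amplitude at each frequency of interest from the nearest grid
   bin (1 and 4 Hz are exact bins; 3.34 Hz falls on the 3.3375-Hz bin).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .epochs import EpochedEEG
from . import phase as _phase

__all__ = [
    "AmplitudeSpectrum",
    "FOITable",
    "RejectionReport",
    "reject_trials",
    "average_trials",
    "amplitude_spectrum",
    "average_channels",
    "fit_aperiodic",
    "subtract_aperiodic",
    "foi_amplitude",
    "condition_table",
    "DEFAULT_RESOLUTION",
    "DEFAULT_FIT_BAND",
]

DEFAULT_RESOLUTION = 0.0125
DEFAULT_FIT_BAND = (0.5, 6.0)
DEFAULT_REJECT_UV = 300.0


@dataclass
class FOITable:
    """Frequencies of interest: the 1-Hz beat rate plus the per-condition
    peak of the stimulus envelope spectrum."""

    beat_hz: float = 1.0
    stimulus_hz: dict[str, float] | None = None

    def __post_init__(self) -> None:
        if self.stimulus_hz is None:
            self.stimulus_hz = {"strong": 4.0, "weak": 4.0, "non": 3.34}
        if self.beat_hz <= 0 or any(f <= 0 for f in self.stimulus_hz.values()):
            raise ValueError("frequencies of interest must be positive")

    def for_condition(self, condition: str) -> tuple[float, ...]:
        """FOIs evaluated for one condition: the beat rate and all stimulus rates."""
        return (self.beat_hz,) + tuple(sorted(set(self.stimulus_hz.values())))

    def all_frequencies(self) -> tuple[float, ...]:
        return (self.beat_hz,) + tuple(sorted(set(self.stimulus_hz.values())))


@dataclass
class AmplitudeSpectrum:
    """Amplitude spectrum on a fixed-resolution grid.

    ``amplitude`` is in uV per bin and must be nonnegative unless
    ``denoised`` (aperiodic-subtracted), in which case negative residuals
    are allowed and the fitted coefficients (a, b) are stored.
    """

    freqs: np.ndarray
    amplitude: np.ndarray
    resolution: float = DEFAULT_RESOLUTION
    denoised: bool = False
    aperiodic_a: float | None = None
    aperiodic_b: float | None = None
    #: the epoch's native (unpadded) bin spacing 1/T_signal, when known;
    #: lets the aperiodic fit avoid finite-epoch leakage skirts (see
    #: fit_aperiodic)
    native_resolution_hz: float | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.freqs.shape[-1] != self.amplitude.shape[-1]:
            raise ValueError("grid and amplitude length mismatch")
        spacing = np.diff(self.freqs)
        if not np.allclose(spacing, self.resolution, rtol=0, atol=1e-9):
            raise ValueError("grid spacing must equal the configured resolution")
        if not self.denoised and np.any(self.amplitude < 0):
            raise ValueError("raw amplitude spectra are nonnegative")

    def bin_index(self, freq_hz: float) -> int:
        """Nearest grid bin (ties toward the lower frequency)."""
        if freq_hz < self.freqs[0] or freq_hz > self.freqs[-1]:
            raise ValueError(f"{freq_hz} Hz is outside the grid")
        pos = (freq_hz - self.freqs[0]) / self.resolution
        lo = int(np.floor(pos))
        hi = min(lo + 1, self.freqs.size - 1)
        # strict inequality: a tie selects the lower bin
        return hi if (pos - lo) > (hi - pos) else lo


@dataclass
class RejectionReport:
    """Outcome of artifact rejection: the surviving epochs plus bookkeeping."""

    epochs: EpochedEEG
    kept: np.ndarray
    threshold_uv: float

    @property
    def n_total(self) -> int:
        return self.kept.size

    @property
    def n_retained(self) -> int:
        return int(self.kept.sum())

    @property
    def retained_fraction(self) -> float:
        return self.n_retained / self.n_total


def reject_trials(
    epochs: EpochedEEG, threshold_uv: float = DEFAULT_REJECT_UV
) -> RejectionReport:
    """Remove trials in which any channel fluctuates more than ``threshold_uv``.

    "Fluctuates" is the peak-to-peak range of the channel within the trial.
    An all-rejected outcome is returned explicitly (zero retained trials);
    downstream averaging refuses empty input.
    """
    if epochs.n_trials == 0:
        raise ValueError("no trials to screen")
    ptp = epochs.data.max(axis=2) - epochs.data.min(axis=2)  # trials x channels
    kept = (ptp <= threshold_uv).all(axis=1)
    return RejectionReport(
        epochs=epochs.take(np.flatnonzero(kept)),
        kept=kept,
        threshold_uv=threshold_uv,
    )


def average_trials(
    epochs: EpochedEEG,
    where: Callable[[pd.Series], bool] | None = None,
    **labels: str,
) -> np.ndarray:
    """Time-domain mean across trials (channels x samples).

    Averaging in the time domain retains only activity that is phase-locked
    across trials; non-phase-locked activity cancels toward zero. Trials
    may be restricted by label equality (``condition="strong"``) or an
    arbitrary row predicate ``where``.
    """
    sub = epochs.select(**labels) if labels else epochs
    if where is not None:
        mask = sub.trials.apply(where, axis=1).to_numpy(dtype=bool)
        sub = sub.take(np.flatnonzero(mask))
    if sub.n_trials == 0:
        raise ValueError("no trials match the grouping")
    return sub.data.mean(axis=0)


def _fft_length(sample_rate: float, resolution: float) -> int:
    n_fft = sample_rate / resolution
    if not math.isclose(n_fft, round(n_fft), rel_tol=0, abs_tol=1e-9):
        raise ValueError("sample_rate / resolution must be an integer FFT length")
    for foi in (1.0, 4.0):
        if not math.isclose(foi / resolution, round(foi / resolution), abs_tol=1e-9):
            raise ValueError("the grid must contain 1 and 4 Hz exactly")
    return int(round(n_fft))


def amplitude_spectrum(
    series: np.ndarray,
    sample_rate: float,
    resolution: float = DEFAULT_RESOLUTION,
    f_max: float | None = 30.0,
) -> AmplitudeSpectrum:
    """FFT amplitude of (channels x samples) series on a fixed-resolution grid.

    The mean-removed series is zero-padded to an effective window of
    ``1/resolution`` seconds (80 s at the default), yielding bins every
    ``resolution`` Hz. Amplitude is ``2/N_signal * |FFT|`` with N_signal
    the unpadded length, so a unit-amplitude sinusoid at a bin frequency
    that completes whole cycles in the epoch reads ~1. Frequencies above
    ``f_max`` are dropped (the analysis band ends well below Nyquist).
    """
    series = np.atleast_2d(np.asarray(series, dtype=np.float64))
    n_signal = series.shape[-1]
    if n_signal == 0:
        raise ValueError("empty series")
    n_fft = _fft_length(sample_rate, resolution)
    if n_fft < n_signal:
        raise ValueError("resolution window is shorter than the epoch")
    centered = series - series.mean(axis=-1, keepdims=True)
    spec = np.abs(np.fft.rfft(centered, n=n_fft, axis=-1)) * (2.0 / n_signal)
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / sample_rate)
    if f_max is not None:
        keep = freqs <= f_max + 1e-9
        freqs, spec = freqs[keep], spec[..., keep]
    return AmplitudeSpectrum(
        freqs=freqs,
        amplitude=np.squeeze(spec),
        resolution=resolution,
        native_resolution_hz=sample_rate / n_signal,
    )


def average_channels(spectra: AmplitudeSpectrum) -> AmplitudeSpectrum:
    """Pointwise mean of per-channel amplitude spectra.

    Amplitudes (not complex spectra) are averaged, so channel-wise phase
    differences do not cancel signal.
    """
    if spectra.amplitude.ndim == 1:
        return replace(spectra, amplitude=spectra.amplitude.copy())
    return replace(spectra, amplitude=spectra.amplitude.mean(axis=0))


def _exclusion_mask(
    freqs: np.ndarray,
    exclude_hz: Sequence[float],
    half_width_hz: float,
    band_max: float,
    harmonics: bool,
) -> np.ndarray:
    """True where bins are excluded from the aperiodic fit."""
    mask = np.zeros(freqs.size, dtype=bool)
    for foi in exclude_hz:
        multiples = [foi]
        if harmonics:
            k = 2
            while k * foi <= band_max + 1e-9:
                multiples.append(k * foi)
                k += 1
        for f in multiples:
            mask |= np.abs(freqs - f) <= half_width_hz + 1e-12
    return mask


def fit_aperiodic(
    spectrum: AmplitudeSpectrum,
    band: tuple[float, float] = DEFAULT_FIT_BAND,
    exclude_hz: Sequence[float] = (1.0, 3.34, 4.0),
    exclude_half_width_hz: float = 0.05,
    exclude_harmonics: bool = True,
) -> tuple[float, float]:
    """Least-squares fit of ``amplitude(f) ~ a * b**f`` over ``band``.

    Bins within ``exclude_half_width_hz`` of each frequency of interest
    (and, by default, its harmonics up to the band edge) are excluded so
    periodic peaks do not bias the background estimate.

    When the spectrum records its native (unpadded) bin spacing, the fit
    additionally restricts itself to the bins nearest multiples of that
    spacing. Zero-padding interpolates the finite-epoch Dirichlet kernel
    of any coherent sinusoid, whose slowly decaying skirts would otherwise
    lift the background estimate across much of the band; at the native
    bins the kernel of a component completing whole cycles in the epoch is
    exactly zero, so those samples see only the true background.

    The fit runs in linear amplitude space; a log-linear regression on the
    positive bins seeds the optimiser.
    """
    if spectrum.denoised:
        raise ValueError("spectrum is already denoised")
    if spectrum.amplitude.ndim != 1:
        raise ValueError("fit the channel-averaged spectrum")
    in_band = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1])
    use = in_band & ~_exclusion_mask(
        spectrum.freqs, exclude_hz, exclude_half_width_hz, band[1], exclude_harmonics
    )
    if spectrum.native_resolution_hz is not None:
        native = np.arange(
            np.ceil(band[0] / spectrum.native_resolution_hz),
            np.floor(band[1] / spectrum.native_resolution_hz) + 1,
        ) * spectrum.native_resolution_hz
        idx = np.unique([spectrum.bin_index(f) for f in native])
        on_native = np.zeros(spectrum.freqs.size, dtype=bool)
        on_native[idx] = True
        use &= on_native
    f = spectrum.freqs[use]
    y = spectrum.amplitude[use]
    if f.size < 2 or not np.any(y > 0):
        raise ValueError("not enough positive amplitude in band to fit a decay")

    pos = y > 0
    slope, intercept = np.polyfit(f[pos], np.log(y[pos]), 1)
    p0 = (float(np.exp(intercept)), float(np.clip(np.exp(slope), 1e-6, 1.0)))
    try:
        (a, b), _ = curve_fit(
            lambda x, a, b: a * b**x, f, y, p0=p0,
            bounds=([0.0, 1e-9], [np.inf, 2.0]), maxfev=10000,
        )
    except RuntimeError:
        a, b = p0
    return float(a), float(b)


def subtract_aperiodic(
    spectrum: AmplitudeSpectrum, a: float, b: float
) -> AmplitudeSpectrum:
    """Subtract the fitted background ``a * b**f`` bin by bin.

    Flattens the spectrum so periodic signals remain as peaks above 0 uV.
    Negative residuals (overcorrection) are retained.
    """
    return replace(
        spectrum,
        amplitude=spectrum.amplitude - a * b**spectrum.freqs,
        denoised=True,
        aperiodic_a=a,
        aperiodic_b=b,
    )


def foi_amplitude(spectrum: AmplitudeSpectrum, foi_hz: float) -> float:
    """Amplitude at the grid bin nearest the frequency of interest.

    1 and 4 Hz are exact bins of the 0.0125-Hz grid; 3.34 Hz is off-grid
    and resolves to the 3.3375-Hz bin.
    """
    if spectrum.amplitude.ndim != 1:
        raise ValueError("foi_amplitude expects a channel-averaged spectrum")
    return float(spectrum.amplitude[spectrum.bin_index(foi_hz)])


def _analyze_cell(
    cell: EpochedEEG,
    fois: Sequence[float],
    resolution: float,
    band: tuple[float, float],
    exclude_hz: Sequence[float],
) -> tuple[AmplitudeSpectrum, tuple[float, float], dict[float, float]]:
    """Average -> spectrum -> channel average -> fit/subtract -> FOI readout."""
    mean_ts = cell.data.mean(axis=0)
    spec = average_channels(amplitude_spectrum(mean_ts, cell.sample_rate, resolution))
    a, b = fit_aperiodic(spec, band=band, exclude_hz=exclude_hz)
    denoised = subtract_aperiodic(spec, a, b)
    return denoised, (a, b), {f: foi_amplitude(denoised, f) for f in fois}


def condition_table(
    epochs: EpochedEEG,
    foi_table: FOITable | None = None,
    resolution: float = DEFAULT_RESOLUTION,
    band: tuple[float, float] = DEFAULT_FIT_BAND,
    reject_uv: float | None = DEFAULT_REJECT_UV,
    itpc_foi_hz: float | None = None,
) -> pd.DataFrame:
    """Run the full pipeline per condition x session x set cell.

    Returns one tidy record per cell and frequency of interest: labels,
    FOI, de-noised amplitude, intertrial phase coherence at the beat
    frequency (or ``itpc_foi_hz``), trial counts, and the fitted aperiodic
    coefficients. Cells whose trials were all rejected appear explicitly
    with NaN results rather than being silently dropped.
    """
    foi_table = FOITable() if foi_table is None else foi_table
    itpc_foi = foi_table.beat_hz if itpc_foi_hz is None else itpc_foi_hz
    exclude = foi_table.all_frequencies()

    records = []
    for labels, cell in epochs.iter_cells():
        n_total = cell.n_trials
        if reject_uv is not None:
            cell = reject_trials(cell, reject_uv).epochs
        base = {**labels, "n_trials": n_total, "n_retained": cell.n_trials}
        fois = foi_table.for_condition(labels["condition"])
        if cell.n_trials == 0:
            for f in fois:
                records.append(
                    {**base, "foi_hz": f, "amplitude_uv": np.nan, "itpc": np.nan,
                     "aperiodic_a": np.nan, "aperiodic_b": np.nan}
                )
            continue
        _, (a, b), amps = _analyze_cell(cell, fois, resolution, band, exclude)
        if cell.n_trials >= 2:
            phases = _phase.single_trial_phase(cell, itpc_foi, resolution)
            r = _phase.itpc(phases).r
        else:
            r = np.nan
        for f in fois:
            records.append(
                {**base, "foi_hz": f, "amplitude_uv": amps[f], "itpc": r,
                 "aperiodic_a": a, "aperiodic_b": b}
            )
    return pd.DataFrame.from_records(records)
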