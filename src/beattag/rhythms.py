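"""Rhythmic stimulus set, audio synthesis, and stimulus-driven frequencies of interest.

The stimulus set comprises 24 unique auditory rhythms in three beat-strength
conditions (strong-beat, weak-beat, non-beat), organised into four
counterbalanced sets of 12 rhythms (4 per condition). Each rhythm is an
ordered list of interval multipliers of a 250-ms base unit: strong- and
weak-beat rhythms use integer ratios (1:2:3:4) and always sum to 12 units
(3 s); non-beat rhythms replace the 2 and 3 multipliers with non-integer
ratios (1:1.4:3.6:4), abolishing the regularity that affords a beat.

Rhythms are rendered as trains of 500-Hz sine tones. Each tone fills its
interonset interval except for a 40-ms silent gap that demarcates the next
onset, with 8-ms linear on/off ramps. A closing tone the length of the
rhythm's shortest interval marks the end of the final interval. Long
(~18 s) versions loop the 3-s pattern six times, appending the closing
downbeat only after the final loop.

The stimulus-driven frequency of interest for a condition is the largest
non-DC peak of the condition-averaged amplitude spectrum of the Hilbert
envelope of the long stimuli (4 Hz for strong and weak beat, 3.34 Hz for
non-beat).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import hilbert

__all__ = [
    "RhythmSpec",
    "AudioStimulus",
    "StimulusSpectrum",
    "CONDITIONS",
    "UNIT_MS",
    "builtin_rhythm_table",
    "synthesize",
    "make_long",
    "add_am_targets",
    "envelope_spectrum",
    "average_spectra",
    "peak_frequency",
    "default_spectrum_grid",
    "write_wav",
    "write_stimulus_table",
    "read_stimulus_table",
]

CONDITIONS = ("strong", "weak", "non")

#: base unit duration ("1" interval) in milliseconds
UNIT_MS = 250.0

_INTEGER_MULTIPLIERS = frozenset({1.0, 2.0, 3.0, 4.0})
_NONBEAT_MULTIPLIERS = frozenset({1.0, 1.4, 3.6, 4.0})


@dataclass(frozen=True)
class RhythmSpec:
    """One rhythm: ordered interval multipliers plus condition and set membership.

    Parameters
    ----------
    intervals
        Interonset-interval duration multipliers of the base unit. Integer
        ratios {1, 2, 3, 4} for strong/weak-beat rhythms, {1, 1.4, 3.6, 4}
        for non-beat rhythms. Six or seven intervals per rhythm.
    condition
        Beat-strength condition: ``"strong"``, ``"weak"`` or ``"non"``.
    set_ids
        Which of the four counterbalanced stimulus sets contain this rhythm.
    unit_ms
        Duration of the "1" multiplier in milliseconds.
    """

    intervals: tuple[float, ...]
    condition: str
    set_ids: frozenset[int] = field(default_factory=frozenset)
    unit_ms: float = UNIT_MS

    def __post_init__(self) -> None:
        object.__setattr__(self, "intervals", tuple(float(i) for i in self.intervals))
        object.__setattr__(self, "set_ids", frozenset(int(s) for s in self.set_ids))
        if self.condition not in CONDITIONS:
            raise ValueError(f"unknown condition {self.condition!r}")
        if len(self.intervals) not in (6, 7):
            raise ValueError("rhythms have six or seven intervals")
        allowed = _NONBEAT_MULTIPLIERS if self.condition == "non" else _INTEGER_MULTIPLIERS
        if not all(any(math.isclose(i, a) for a in allowed) for i in self.intervals):
            raise ValueError(
                f"{self.condition} rhythm uses multipliers outside {sorted(allowed)}"
            )
        if self.condition in ("strong", "weak") and not math.isclose(self.total_units, 12.0):
            raise ValueError("strong/weak rhythms must sum to 12 units")

    @property
    def total_units(self) -> float:
        """Sum of interval multipliers (12 for strong/weak rhythms)."""
        return float(sum(self.intervals))

    @property
    def duration_ms(self) -> float:
        """Total rhythm duration (excluding the appended closing tone)."""
        return self.total_units * self.unit_ms

    @property
    def interval_durations_ms(self) -> tuple[float, ...]:
        return tuple(i * self.unit_ms for i in self.intervals)

    def label(self) -> str:
        """Compact interval string, e.g. ``'1 1 2 3 1 4'``."""
        return " ".join(f"{i:g}" for i in self.intervals)


@dataclass
class AudioStimulus:
    """A synthesized rhythm waveform with tone-onset bookkeeping.

    ``samples`` is a mono waveform with peak magnitude <= 1;
    ``onset_times_ms`` are the tone onsets (first at 0 ms) and
    ``target_tone_indices`` flags tones carrying 40-Hz amplitude modulation
    for the target-detection task.
    """

    samples: np.ndarray
    sample_rate: float
    onset_times_ms: np.ndarray
    duration_ms: float
    target_tone_indices: tuple[int, ...] = ()
    source: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        self.onset_times_ms = np.asarray(self.onset_times_ms, dtype=np.float64)
        if self.onset_times_ms.size:
            if self.onset_times_ms[0] != 0.0:
                raise ValueError("first tone onset must be at 0 ms")
            if np.any(np.diff(self.onset_times_ms) <= 0):
                raise ValueError("onset times must be strictly increasing")
        if self.samples.size and np.max(np.abs(self.samples)) > 1.0 + 1e-12:
            raise ValueError("waveform peak magnitude must not exceed 1")

    @property
    def n_tones(self) -> int:
        return int(self.onset_times_ms.size)


@dataclass
class StimulusSpectrum:
    """Amplitude spectrum of a stimulus envelope on a strictly increasing grid."""

    freqs: np.ndarray
    amplitude: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.amplitude = np.asarray(self.amplitude, dtype=np.float64)
        if self.freqs.shape != self.amplitude.shape:
            raise ValueError("frequency grid and amplitude must have equal length")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if np.any(self.amplitude < 0):
            raise ValueError("envelope-spectrum amplitude must be nonnegative")


# The printed stimulus table: 24 unique rhythms; rhythms shared between two
# counterbalanced sets appear once with both set ids.
_TABLE: tuple[tuple[tuple[float, ...], str, tuple[int, ...]], ...] = (
    # strong beat
    ((1, 1, 1, 1, 4, 3, 1), "strong", (1, 3)),
    ((2, 1, 1, 2, 2, 3, 1), "strong", (1, 4)),
    ((1, 1, 2, 3, 1, 4), "strong", (1, 3)),
    ((2, 2, 1, 3, 3, 1), "strong", (1, 4)),
    ((2, 1, 1, 3, 1, 1, 3), "strong", (2, 3)),
    ((3, 1, 4, 1, 1, 1, 1), "strong", (2, 4)),
    ((3, 1, 2, 2, 1, 3), "strong", (2, 4)),
    ((3, 1, 1, 3, 2, 2), "strong", (2, 3)),
    # weak beat
    ((1, 4, 1, 1, 3, 1, 1), "weak", (1, 4)),
    ((1, 1, 3, 2, 2, 1, 2), "weak", (1, 3)),
    ((1, 2, 2, 1, 4, 2), "weak", (1, 3)),
    ((2, 3, 1, 1, 2, 3), "weak", (1, 4)),
    ((2, 3, 3, 1, 1, 1, 1), "weak", (2, 4)),
    ((2, 1, 4, 1, 2, 1, 1), "weak", (2, 3)),
    ((3, 2, 3, 2, 1, 1), "weak", (2, 3)),
    ((4, 1, 2, 2, 1, 2), "weak", (2, 4)),
    # non-beat
    ((1, 3.6, 1, 4, 1, 1, 1), "non", (1, 3)),
    ((1.4, 1, 1.4, 3.6, 1.4, 1, 1), "non", (1, 4)),
    ((1.4, 1, 4, 1.4, 1.4, 1), "non", (1, 4)),
    ((1, 3.6, 1.4, 3.6, 1.4, 1), "non", (1, 3)),
    ((3.6, 1, 1, 3.6, 1, 1.4, 1), "non", (2, 3)),
    ((3.6, 1.4, 1.4, 1, 1, 1, 1.4), "non", (2, 4)),
    ((1.4, 1.4, 1, 1.4, 4, 1), "non", (2, 3)),
    ((4, 1.4, 1, 3.6, 1, 1), "non", (2, 4)),
)


def builtin_rhythm_table(unit_ms: float = UNIT_MS) -> list[RhythmSpec]:
    """Return the 24 unique rhythms of the built-in stimulus set.

    Eight rhythms per beat-strength condition; each rhythm belongs to two
    of the four counterbalanced sets, so every set holds four rhythms per
    condition (12 total).
    """
    return [
        RhythmSpec(intervals=iv, condition=cond, set_ids=frozenset(sets), unit_ms=unit_ms)
        for iv, cond, sets in _TABLE
    ]


def _tone(duration_s: float, tone_hz: float, ramp_s: float, sample_rate: float) -> np.ndarray:
    """A ramped sine tone; linear amplitude ramps at both ends."""
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    x = np.sin(2 * np.pi * tone_hz * t)
    n_ramp = int(round(ramp_s * sample_rate))
    if n_ramp > 0 and n >= 2 * n_ramp:
        ramp = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
        x[:n_ramp] *= ramp
        x[-n_ramp:] *= ramp[::-1]
    return x


def _render(
    durs_ms: Sequence[float],
    final_ms: float | None,
    tone_hz: float,
    ramp_ms: float,
    gap_ms: float,
    sample_rate: float,
    source: str,
) -> AudioStimulus:
    """Render a train of ramped tones from raw interonset intervals (ms)."""
    if sample_rate < 2 * tone_hz:
        raise ValueError("sample_rate must be at least twice the tone frequency")
    if any(d <= gap_ms for d in durs_ms):
        raise ValueError("every interval must be longer than the silent gap")

    onsets_ms = [0.0]
    for d in durs_ms[:-1]:
        onsets_ms.append(onsets_ms[-1] + d)
    tone_durs_ms = [d - gap_ms for d in durs_ms]

    total_ms = sum(durs_ms)
    if final_ms is not None:
        onsets_ms.append(total_ms)
        tone_durs_ms.append(final_ms - gap_ms)
        total_ms += final_ms

    n_total = int(round(total_ms / 1000.0 * sample_rate))
    samples = np.zeros(n_total)
    for onset_ms, dur_ms in zip(onsets_ms, tone_durs_ms):
        i0 = int(round(onset_ms / 1000.0 * sample_rate))
        tone = _tone(dur_ms / 1000.0, tone_hz, ramp_ms / 1000.0, sample_rate)
        samples[i0 : i0 + tone.size] = tone[: max(0, n_total - i0)]

    return AudioStimulus(
        samples=samples,
        sample_rate=sample_rate,
        onset_times_ms=np.asarray(onsets_ms),
        duration_ms=total_ms,
        source=source,
    )


def synthesize(
    spec: RhythmSpec,
    tone_hz: float = 500.0,
    ramp_ms: float = 8.0,
    gap_ms: float = 40.0,
    sample_rate: float = 44100.0,
    append_final_tone: bool = True,
) -> AudioStimulus:
    """Render a rhythm as a train of ramped sine tones.

    Tone *k* starts at the cumulative onset of interval *k* and fills the
    interval except for the closing ``gap_ms`` of silence. With
    ``append_final_tone``, a closing tone the length of the shortest
    interval starts at the end of the last interval, demarcating it.
    """
    durs_ms = list(spec.interval_durations_ms)
    final_ms = min(durs_ms) if append_final_tone else None
    return _render(
        durs_ms, final_ms, tone_hz, ramp_ms, gap_ms, sample_rate,
        source=f"{spec.condition}:{spec.label()}",
    )


def make_long(
    spec: RhythmSpec,
    n_loops: int = 6,
    tone_hz: float = 500.0,
    ramp_ms: float = 8.0,
    gap_ms: float = 40.0,
    sample_rate: float = 44100.0,
) -> AudioStimulus:
    """Loop a rhythm seamlessly ``n_loops`` times for the long (~18 s) stimuli.

    The closing downbeat tone is omitted between loops — each loop's first
    tone serves as the previous loop's closing downbeat — and appended only
    after the final loop. So the interval pattern of (3,1,2,2,1,3) looped
    reads 3 1 2 2 1 3 3 1 2 2 1 3 ... 3 1 2 2 1 3 1.
    """
    if n_loops < 1:
        raise ValueError("n_loops must be at least 1")
    durs_ms = list(spec.interval_durations_ms) * n_loops
    return _render(
        durs_ms, min(spec.interval_durations_ms), tone_hz, ramp_ms, gap_ms,
        sample_rate, source=f"{spec.condition}:{spec.label()} x{n_loops}",
    )


def add_am_targets(
    stim: AudioStimulus,
    n_targets: int,
    am_hz: float = 40.0,
    depth: float = 1.0,
    rng: np.random.Generator | None = None,
) -> AudioStimulus:
    """Amplitude-modulate ``n_targets`` randomly chosen tones at ``am_hz``.

    Target tones for the detection task are modulated by
    ``(1 - depth/2) + (depth/2) * cos(2*pi*am_hz*t)``, i.e. full-depth
    modulation at ``depth=1``. Modulation applies over the tone's interval
    support only; gaps stay silent. Selection is reproducible from ``rng``.
    """
    if not 1 <= n_targets <= 4:
        raise ValueError("n_targets must be between 1 and 4")
    if stim.n_tones < n_targets:
        raise ValueError("stimulus has fewer tones than requested targets")
    rng = np.random.default_rng() if rng is None else rng

    targets = sorted(rng.choice(stim.n_tones, size=n_targets, replace=False).tolist())
    samples = stim.samples.copy()
    sr = stim.sample_rate
    bounds_ms = np.append(stim.onset_times_ms, stim.duration_ms)
    for k in targets:
        i0 = int(round(bounds_ms[k] / 1000.0 * sr))
        i1 = min(int(round(bounds_ms[k + 1] / 1000.0 * sr)), samples.size)
        t = np.arange(i1 - i0) / sr
        samples[i0:i1] *= (1 - depth / 2) + (depth / 2) * np.cos(2 * np.pi * am_hz * t)

    return AudioStimulus(
        samples=samples,
        sample_rate=sr,
        onset_times_ms=stim.onset_times_ms.copy(),
        duration_ms=stim.duration_ms,
        target_tone_indices=tuple(targets),
        source=stim.source,
    )


def envelope_spectrum(stim: AudioStimulus) -> StimulusSpectrum:
    """Amplitude spectrum of the waveform's Hilbert envelope.

    The envelope is the magnitude of the analytic signal; its one-sided
    FFT amplitude spectrum (arbitrary units, normalised by sample count)
    carries the slow tone-onset structure that defines the stimulus-driven
    frequencies of interest. The DC bin is returned but excluded from peak
    picking downstream.
    """
    if stim.samples.size == 0:
        raise ValueError("empty stimulus")
    env = np.abs(hilbert(stim.samples))
    amp = np.abs(np.fft.rfft(env)) / env.size
    freqs = np.fft.rfftfreq(env.size, d=1.0 / stim.sample_rate)
    return StimulusSpectrum(freqs=freqs, amplitude=amp, source=stim.source)


def default_spectrum_grid(f_max: float = 10.0, df: float = 0.0125) -> np.ndarray:
    """Common frequency grid for condition-averaged stimulus spectra.

    Matches the EEG analysis resolution (0.0125 Hz) so stimulus peak
    frequencies land on the same grid as the EEG frequencies of interest.
    """
    return np.arange(0.0, f_max + df / 2, df)


def average_spectra(
    spectra: Sequence[StimulusSpectrum], grid: np.ndarray | None = None
) -> StimulusSpectrum:
    """Pointwise mean of amplitude spectra after interpolation onto a common grid.

    Looped rhythms differ in duration and hence in native frequency grids;
    each spectrum is linearly interpolated onto ``grid`` before averaging.
    """
    if not spectra:
        raise ValueError("no spectra to average")
    grid = default_spectrum_grid() if grid is None else np.asarray(grid, dtype=np.float64)
    for s in spectra:
        if grid[0] < s.freqs[0] or grid[-1] > s.freqs[-1]:
            raise ValueError("grid extends outside a spectrum's support")
    stack = np.stack([np.interp(grid, s.freqs, s.amplitude) for s in spectra])
    return StimulusSpectrum(
        freqs=grid,
        amplitude=stack.mean(axis=0),
        source=f"mean of {len(spectra)} spectra",
    )


def peak_frequency(
    spectrum: StimulusSpectrum, band: tuple[float, float] = (0.5, 8.0)
) -> float:
    """Frequency of the largest amplitude within ``band`` (ties toward lower).

    The lower band edge excludes the DC bin and the slow loop-repetition
    harmonics below the rhythmically meaningful range.
    """
    mask = (spectrum.freqs >= band[0]) & (spectrum.freqs <= band[1])
    if not np.any(mask):
        raise ValueError("band contains no grid frequencies")
    idx = int(np.argmax(spectrum.amplitude[mask]))
    return float(spectrum.freqs[mask][idx])


def write_wav(stim: AudioStimulus, path: str | Path, peak: float = 0.9) -> None:
    """Write 16-bit PCM WAV plus a CSV sidecar of onsets and target flags."""
    path = Path(path)
    x = stim.samples
    scale = peak / max(np.max(np.abs(x)), 1e-12)
    wavfile.write(path, int(stim.sample_rate), np.round(x * scale * 32767).astype(np.int16))
    with open(path.with_suffix(".onsets.csv"), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tone_index", "onset_ms", "is_target"])
        for k, onset in enumerate(stim.onset_times_ms):
            w.writerow([k, f"{onset:.3f}", int(k in stim.target_tone_indices)])


def write_stimulus_table(rhythms: Iterable[RhythmSpec], path: str | Path) -> None:
    """Export rhythm definitions as delimited text (one row per set membership)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["set", "condition", "intervals"])
        for r in rhythms:
            for set_id in sorted(r.set_ids):
                w.writerow([set_id, r.condition, r.label()])


def read_stimulus_table(path: str | Path, unit_ms: float = UNIT_MS) -> list[RhythmSpec]:
    """Read a stimulus table written by :func:`write_stimulus_table`.

    Rows sharing condition and intervals are merged back into one
    :class:`RhythmSpec` with multiple set ids.
    """
    merged: dict[tuple[str, tuple[float, ...]], set[int]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            intervals = tuple(float(x) for x in row["intervals"].split())
            merged.setdefault((row["condition"], intervals), set()).add(int(row["set"]))
    return [
        RhythmSpec(intervals=iv, condition=cond, set_ids=frozenset(sets), unit_ms=unit_ms)
        for (cond, iv), sets in merged.items()
    ]
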