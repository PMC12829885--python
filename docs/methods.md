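# Methods

## Signal model and analysis logic

The analysis treats the trial-averaged EEG amplitude spectrum as the sum
of two parts: an aperiodic background whose amplitude decays smoothly with
frequency, modeled in exponential form

    amplitude(f) = a · bᶠ,      a ≥ 0 (μV intercept), 0 < b ≤ 1 (decay per Hz),

and periodic components phase-locked to the stimulus, which survive
time-domain averaging and appear as narrow peaks. Averaging n trials
attenuates a component whose per-trial phase φ_t is von Mises distributed
with concentration κ by the population resultant length

    R(κ) = I₁(κ)/I₀(κ),

so the expected averaged amplitude of a component of amplitude A is A·R(κ),
and R(κ) is likewise the expected intertrial phase coherence (ITPC) at
that frequency. These identities are the analytic oracles the test suite
checks the pipeline against.

## Stimuli

The 24-rhythm set is stored as interval-multiplier sequences over a 250-ms
unit. Synthesis follows fixed rules: each 500-Hz tone fills its interval
except a 40-ms closing gap; 8-ms linear on/off ramps; a closing tone the
length of the rhythm's shortest interval demarcates the final interval.
Long versions loop the 3-s pattern six times seamlessly — the first tone
of each loop serves as the previous loop's closing downbeat, and the
closing tone is appended only once, after the last loop.

Choices where the synthesis rules left freedom:

- **Audio sample rate** defaults to 44.1 kHz; the envelope analysis lives
  below 10 Hz and is insensitive to the rate (a test verifies identical
  FOIs at 8 kHz).
- **Ramp shape** is linear — the simplest monotone ramp; at FOI scale the
  ramp contributes nothing distinguishable from any other 8-ms taper.
- **Condition-average envelope spectra** are linearly interpolated onto a
  common 0.0125-Hz grid (0–10 Hz) before averaging, because looped
  rhythms differ in duration and hence in native FFT grids; the grid
  matches the EEG resolution so stimulus peaks and EEG frequencies of
  interest land on the same bins. Peak picking takes the maximal bin in
  0.5–8 Hz, ties toward the lower frequency.

Derived this way, the condition-averaged envelope spectra peak at 4 Hz
(strong and weak beat) and at the 3.3375-Hz bin (non-beat), reported to
two decimals as 3.34 Hz.

## Spectral pipeline

- **Artifact rejection**: "fluctuated more than 300 μV" is implemented as
  the peak-to-peak range of any channel within a trial — the standard
  threshold convention.
- **FFT convention**: the mean-removed average is zero-padded to a
  1/resolution window (80 s at 0.0125 Hz); amplitude is 2/N_signal·|FFT|
  with N_signal the unpadded length, so a sinusoid completing whole cycles
  in the epoch reads its amplitude in μV directly. The resolution must
  place 1 and 4 Hz exactly on the grid; 3.34 Hz resolves to the nearest
  bin (3.3375 Hz = 267 × 0.0125).
- **Aperiodic fit**: nonlinear least squares of a·bᶠ over 0.5–6 Hz in
  linear amplitude space (log-linear regression seeds the optimiser),
  excluding bins within ±0.05 Hz of each frequency of interest and its
  harmonics up to the band edge. Two further numerical choices matter:
  - *Native-bin restriction.* Zero-padding interpolates the finite-epoch
    Dirichlet kernel of any coherent sinusoid; its slowly decaying skirts
    would lift the background estimate across much of the band and cause
    systematic over-subtraction (~13% amplitude loss in simulation). When
    the spectrum records its native bin spacing 1/T, the fit therefore
    uses only bins nearest multiples of 1/T — there the leakage kernel of
    a component completing whole cycles in the epoch is exactly zero.
    Spectra constructed directly on a grid (no epoch behind them) are fit
    on all non-excluded bins.
  - *Subtraction* is pointwise and unclipped: negative residuals are
    retained, making any overcorrection visible rather than hidden.
- **Unequal epochs** are not silently handled: the container enforces
  equal trial lengths, and datasets of mixed duration must be truncated to
  the shortest common length before construction.

## Synthetic EEG generator

The generator emulates exactly the features the pipeline measures, and no
more:

- **Background**: white noise shaped in the frequency domain — each
  positive-frequency bin receives deterministic magnitude (N/2)·a·bᶠ and
  an independent uniform phase, per channel. A single trial's amplitude
  spectrum is then a·bᶠ *exactly* under the pipeline's convention, which
  makes the expected-spectrum property testable without Monte-Carlo slack.
- **Components**: one phase draw per trial from von Mises(μ, κ), shared
  across channels (volume-conduction-like), scaled by per-channel gains
  g_c ~ 1 + N(0, 0.1) drawn once per dataset. Optionally a damped
  oscillation kernel convolved with a tone-onset train adds evoked
  responses; its shape is a free parameter, not calibrated to data.
- **Defaults** mirror the recording conditions the pipeline targets:
  64 channels, 1024 Hz, 18-s trials, 24 trials per condition × session ×
  set cell. A fast profile (16 channels, 256 Hz, 6-s trials) keeps
  simulations cheap; trials still hold whole cycles of every FOI.
- **Condition parameters** (1-Hz amplitude 1.0/0.7/0.4 μV, κ = 15/8/4 for
  strong/weak/non, plus a stimulus-rate component per condition over an
  a = 0.3, b = 0.75 background) encode the qualitative ordering the
  experiment manipulates. Their scale is set analytically: after averaging
  n trials the residual background floor at 1 Hz is ≈ a·b·√(π/4n), and
  amplitudes were chosen so this floor stays below a tenth of the weakest
  component's expected averaged amplitude at the default trial counts —
  i.e., recoverability is a design property, not a tuned outcome.

What the generator does **not** emulate: real scalp topographies, eye or
muscle artifacts, non-stationary backgrounds, evoked-response variability,
or any familiarity/training effect. Passing tests therefore show that the
pipeline measures what it claims on data obeying its own signal model —
they do not validate preprocessing choices on real recordings.

## Phase coherence

Channel combination is complex (amplitude-weighted) averaging of per-trial
spectra, not averaging of phase angles; opposite-phase channels cancel,
and a trial whose channel-averaged magnitude falls below 10⁻¹² of the
channel RMS magnitude is flagged phase-undefined and excluded with a
count. Phases are measured against a cosine at trial start, so trials must
share a stimulus-locked time zero (the generator guarantees this; real
data must be epoch-locked the same way).

## Behavioral scoring

Reproduced intervals are consecutive tap-time differences; the first tap's
absolute time is ignored (no external anchor exists in the response
window). A rhythm of n intervals requires exactly n+1 taps — the final tap
marks the last interval's end, mirroring the appended closing tone; any
other tap count excludes the trial from error averaging and scores it
incorrect. The tap-count convention is explicit in the API rather than
configurable magic. Learning slopes require all four session means and
refuse gaps explicitly.

## Problem sizes and determinism

Simulated checks use the fast profile: 72 trials/cell for parameter
recovery, 20 simulated subjects × 10 replicates for the null-training
check, chosen as the smallest sizes at which the analytic tolerances
(10% amplitude, Monte-Carlo ITPC error, sign-test calibration) are
comfortably resolvable. All randomness descends from a single integer
seed per run (subject seeds spawn from a seed sequence); identical
configuration and seed reproduce every output file byte for byte.

## Known limitations

- The aperiodic model is a two-parameter exponential; real EEG backgrounds
  with knees or multiple regimes will fit poorly, and the fit band
  (0.5–6 Hz) is assumed to bracket the FOIs.
- The 3.34-Hz frequency of interest is off the 0.0125-Hz grid; the
  nearest-bin readout (3.3375 Hz) is the documented convention, and
  two-decimal agreement is the reproduction contract for the non-beat
  stimulus peak.
- Amplitude recovery carries a small negative bias (~ the residual noise
  floor at the FOI bin) that shrinks as 1/√(n_trials); at the default
  trial counts it stays within the stated tolerances but is visible in
  the demo's recovered-versus-expected table.
- The pipeline accepts already-cleaned epochs; filtering, ICA, channel
  interpolation and re-referencing are upstream concerns it does not
  implement.
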