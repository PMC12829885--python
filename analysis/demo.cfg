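# End-to-end demo configuration (key = value, one section per stage).
# Identical config + seed reproduces every output byte for byte.

[run]
seed = 1
out_dir = results/demo

[stimuli]
audio_sample_rate = 44100
n_loops = 6
tone_hz = 500
ramp_ms = 8
gap_ms = 40

[eeg]
# "fast" = 16 channels, 256 Hz, 6-s trials; "full" = 64 channels, 1024 Hz, 18 s
eeg_profile = fast
n_trials = 24
aperiodic_a = 0.3
aperiodic_b = 0.75
channel_gain_sd = 0.1

[analysis]
resolution_hz = 0.0125
fit_band = 0.5:6
reject_uv = 300
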