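"""Stimulus set integrity, synthesis timing rules, and envelope spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from beattag import rhythms as R


class TestRhythmTable:
    def test_24_unique_rhythms_8_per_condition(self, rhythm_table):
        assert len(rhythm_table) == 24
        assert len({(r.condition, r.intervals) for r in rhythm_table}) == 24
        for cond in R.CONDITIONS:
            assert sum(r.condition == cond for r in rhythm_table) == 8

    def test_each_set_has_4_rhythms_per_condition(self, rhythm_table):
        for set_id in (1, 2, 3, 4):
            members = [r for r in rhythm_table if set_id in r.set_ids]
            assert len(members) == 12
            for cond in R.CONDITIONS:
                assert sum(r.condition == cond for r in members) == 4

    def test_shared_rhythm_membership(self, rhythm_table):
        # the strong rhythm 1 1 1 1 4 3 1 appears in sets 1 and 3
        match = [
            r for r in rhythm_table
            if r.condition == "strong" and r.intervals == (1, 1, 1, 1, 4, 3, 1)
        ]
        assert len(match) == 1
        assert match[0].set_ids == frozenset({1, 3})

    def test_integer_rhythms_sum_to_12_units(self, rhythm_table):
        for r in rhythm_table:
            if r.condition in ("strong", "weak"):
                assert math.isclose(r.total_units, 12.0)
                assert math.isclose(r.duration_ms, 3000.0)

    def test_multiplier_vocabulary(self, rhythm_table):
        for r in rhythm_table:
            allowed = {1, 1.4, 3.6, 4} if r.condition == "non" else {1, 2, 3, 4}
            assert all(any(math.isclose(i, a) for a in allowed) for i in r.intervals)
            assert len(r.intervals) in (6, 7)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            R.RhythmSpec(intervals=(1, 1, 1, 1, 4, 3), condition="strong")  # sums to 11
        with pytest.raises(ValueError):
            R.RhythmSpec(intervals=(1, 1.4, 1, 1, 4, 3, 1), condition="strong")
        with pytest.raises(ValueError):
            R.RhythmSpec(intervals=(1, 2, 3, 4, 1, 1), condition="nope")

    def test_table_roundtrips_through_csv(self, rhythm_table, tmp_path):
        path = tmp_path / "table.csv"
        R.write_stimulus_table(rhythm_table, path)
        back = R.read_stimulus_table(path)
        key = lambda r: (r.condition, r.intervals)
        assert sorted(
            (r.condition, r.intervals, r.set_ids) for r in back
        ) == sorted((r.condition, r.intervals, r.set_ids) for r in rhythm_table)


class TestSynthesize:
    SR = 8000.0

    def test_appended_tone_onset_at_3000ms(self):
        spec = R.RhythmSpec(intervals=(1, 1, 2, 3, 1, 4), condition="strong")
        stim = R.synthesize(spec, sample_rate=self.SR)
        assert stim.onset_times_ms[-1] == pytest.approx(3000.0)
        assert stim.n_tones == 7  # six intervals + closing tone

    def test_onsets_are_cumulative_interval_starts(self):
        spec = R.RhythmSpec(intervals=(2, 2, 1, 3, 3, 1), condition="strong")
        stim = R.synthesize(spec, sample_rate=self.SR)
        np.testing.assert_allclose(
            stim.onset_times_ms[:-1], [0, 500, 1000, 1250, 2000, 2750]
        )
        assert stim.onset_times_ms[0] == 0.0

    def test_tone_fills_interval_minus_gap(self):
        # single-interval rhythm is not in the stimulus vocabulary, so build
        # the check from a legal rhythm's first tone: multiplier 4 -> 960 ms
        spec = R.RhythmSpec(intervals=(4, 1, 2, 2, 1, 2), condition="weak")
        stim = R.synthesize(spec, sample_rate=self.SR, append_final_tone=False)
        i0, i1 = 0, int(round(0.960 * self.SR))
        assert np.any(stim.samples[i0:i1] != 0)
        gap = stim.samples[i1 : int(round(1.000 * self.SR))]
        np.testing.assert_array_equal(gap, 0)

    def test_closing_tone_length_is_shortest_interval(self):
        # shortest interval 250 ms -> closing tone 210 ms of sound
        spec = R.RhythmSpec(intervals=(4, 1, 2, 2, 1, 2), condition="weak")
        stim = R.synthesize(spec, sample_rate=self.SR)
        assert stim.duration_ms == pytest.approx(3000 + 250)
        start = int(round(3.0 * self.SR))
        sound = np.flatnonzero(stim.samples[start:])
        assert sound.size > 0
        assert sound[-1] / self.SR == pytest.approx(0.210, abs=2e-3)

    def test_silent_during_every_gap(self):
        spec = R.RhythmSpec(intervals=(3, 1, 2, 2, 1, 3), condition="strong")
        stim = R.synthesize(spec, sample_rate=self.SR)
        bounds = np.append(stim.onset_times_ms, stim.duration_ms)
        for end in bounds[1:]:
            g0 = int(round((end - 40) / 1000 * self.SR)) + 1
            g1 = int(round(end / 1000 * self.SR))
            np.testing.assert_array_equal(stim.samples[g0:g1], 0)

    def test_peak_magnitude_at_most_one(self, rhythm_table):
        for spec in rhythm_table[:6]:
            stim = R.synthesize(spec, sample_rate=self.SR)
            assert np.max(np.abs(stim.samples)) <= 1.0

    def test_gap_longer_than_interval_rejected(self):
        spec = R.RhythmSpec(intervals=(1, 1, 2, 3, 1, 4), condition="strong")
        with pytest.raises(ValueError):
            R.synthesize(spec, gap_ms=260.0, sample_rate=self.SR)
        with pytest.raises(ValueError):
            R.synthesize(spec, sample_rate=600.0)  # below 2 x 500 Hz


class TestMakeLong:
    SR = 8000.0

    def test_six_loops_last_about_18s(self):
        spec = R.RhythmSpec(intervals=(3, 1, 2, 2, 1, 3), condition="strong")
        stim = R.make_long(spec, n_loops=6, sample_rate=self.SR)
        assert stim.duration_ms == pytest.approx(6 * 3000 + 250)
        assert stim.n_tones == 6 * 6 + 1

    def test_single_loop_equals_short_version(self):
        spec = R.RhythmSpec(intervals=(1, 1, 2, 3, 1, 4), condition="strong")
        short = R.synthesize(spec, sample_rate=self.SR)
        looped = R.make_long(spec, n_loops=1, sample_rate=self.SR)
        np.testing.assert_array_equal(short.samples, looped.samples)
        np.testing.assert_array_equal(short.onset_times_ms, looped.onset_times_ms)

    def test_nonbeat_loop_duration_follows_unit_sum(self):
        spec = R.RhythmSpec(
            intervals=(1.4, 1, 4, 1.4, 1.4, 1), condition="non"
        )  # 10.2 units
        stim = R.make_long(spec, n_loops=6, sample_rate=self.SR)
        assert stim.duration_ms == pytest.approx(6 * 10.2 * 250 + 250)

    def test_loop_boundary_carries_no_closing_tone(self):
        # onsets of loop 2 start exactly one pattern-duration after loop 1
        spec = R.RhythmSpec(intervals=(3, 1, 2, 2, 1, 3), condition="strong")
        stim = R.make_long(spec, n_loops=2, sample_rate=self.SR)
        n = len(spec.intervals)
        np.testing.assert_allclose(
            stim.onset_times_ms[n : 2 * n], stim.onset_times_ms[:n] + 3000.0
        )


class TestAmTargets:
    SR = 8000.0

    def _stim(self):
        spec = R.RhythmSpec(intervals=(1, 1, 2, 3, 1, 4), condition="strong")
        return R.synthesize(spec, sample_rate=self.SR)

    def test_flags_requested_number_of_tones(self):
        out = R.add_am_targets(self._stim(), n_targets=2, rng=np.random.default_rng(0))
        assert len(out.target_tone_indices) == 2
        assert len(set(out.target_tone_indices)) == 2

    def test_zero_depth_leaves_waveform_unchanged(self):
        stim = self._stim()
        out = R.add_am_targets(stim, 3, depth=0.0, rng=np.random.default_rng(0))
        np.testing.assert_array_equal(out.samples, stim.samples)

    def test_target_selection_is_reproducible(self):
        a = R.add_am_targets(self._stim(), 4, rng=np.random.default_rng(7))
        b = R.add_am_targets(self._stim(), 4, rng=np.random.default_rng(7))
        assert a.target_tone_indices == b.target_tone_indices
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_target_count_bounds(self):
        with pytest.raises(ValueError):
            R.add_am_targets(self._stim(), 0)
        with pytest.raises(ValueError):
            R.add_am_targets(self._stim(), 5)

    def test_full_depth_modulation_reaches_zero(self):
        out = R.add_am_targets(self._stim(), 1, depth=1.0, rng=np.random.default_rng(1))
        k = out.target_tone_indices[0]
        bounds = np.append(out.onset_times_ms, out.duration_ms)
        i0 = int(round(bounds[k] / 1000 * self.SR))
        # at 40 Hz the modulator hits zero every 25 ms within the tone
        seg = out.samples[i0 : i0 + int(0.2 * self.SR)]
        orig = self._stim().samples[i0 : i0 + int(0.2 * self.SR)]
        assert np.max(np.abs(seg)) <= np.max(np.abs(orig)) + 1e-12
        assert np.min(np.abs(seg[np.abs(orig) > 0.5])) < 1e-2


class TestEnvelopeSpectrum:
    SR = 4000.0

    def test_isochronous_envelope_peak(self):
        # an isochronous 250-ms tone train has its envelope peak at 4 Hz
        t = np.arange(int(12 * self.SR)) / self.SR  # 12 s of 250-ms cycles
        gate = ((t % 0.25) < 0.21).astype(float)
        stim = R.AudioStimulus(
            samples=gate * np.sin(2 * np.pi * 500 * t),
            sample_rate=self.SR,
            onset_times_ms=np.arange(0, 12000, 250.0),
            duration_ms=12000.0,
        )
        spec = R.envelope_spectrum(stim)
        assert R.peak_frequency(spec, band=(0.5, 8.0)) == pytest.approx(4.0, abs=0.05)

    def test_silence_gives_zero_spectrum(self):
        stim = R.AudioStimulus(
            samples=np.zeros(1000), sample_rate=self.SR,
            onset_times_ms=np.array([0.0]), duration_ms=250.0,
        )
        spec = R.envelope_spectrum(stim)
        np.testing.assert_array_equal(spec.amplitude, 0)

    def test_amplitude_nonnegative(self, rhythm_table):
        stim = R.synthesize(rhythm_table[0], sample_rate=self.SR)
        spec = R.envelope_spectrum(stim)
        assert np.all(spec.amplitude >= 0)

    @given(scale=st.floats(min_value=0.05, max_value=1.0))
    @settings(max_examples=10, deadline=None)
    def test_scaling_waveform_scales_spectrum(self, scale):
        spec0 = R.builtin_rhythm_table()[0]
        stim = R.synthesize(spec0, sample_rate=2000.0)
        scaled = R.AudioStimulus(
            samples=stim.samples * scale, sample_rate=stim.sample_rate,
            onset_times_ms=stim.onset_times_ms, duration_ms=stim.duration_ms,
        )
        s0 = R.envelope_spectrum(stim)
        s1 = R.envelope_spectrum(scaled)
        np.testing.assert_allclose(s1.amplitude, scale * s0.amplitude, atol=1e-12)


class TestAverageAndPeak:
    def _spec(self, amp):
        return R.StimulusSpectrum(freqs=np.arange(0, 10, 0.01), amplitude=amp)

    def test_average_of_identical_spectra_is_identity(self):
        amp = np.random.default_rng(0).random(1000)
        grid = np.arange(0, 10, 0.01)
        out = R.average_spectra([self._spec(amp)] * 3, grid=grid)
        np.testing.assert_allclose(out.amplitude, amp)

    def test_average_is_linear(self):
        amp = np.random.default_rng(1).random(1000)
        grid = np.arange(0, 10, 0.01)
        out = R.average_spectra([self._spec(amp), self._spec(np.zeros(1000))], grid=grid)
        np.testing.assert_allclose(out.amplitude, amp / 2)

    def test_grid_outside_support_rejected(self):
        with pytest.raises(ValueError):
            R.average_spectra([self._spec(np.ones(1000))], grid=np.arange(0, 20, 0.5))

    def test_peak_of_single_component(self):
        freqs = np.arange(0, 10, 0.01)
        amp = np.exp(-0.5 * ((freqs - 3.2) / 0.05) ** 2)
        assert R.peak_frequency(R.StimulusSpectrum(freqs=freqs, amplitude=amp)) == pytest.approx(3.2)

    def test_empty_band_rejected(self):
        spec = self._spec(np.ones(1000))
        with pytest.raises(ValueError):
            R.peak_frequency(spec, band=(11.0, 12.0))
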