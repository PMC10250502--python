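import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from amdt import (
    AMToneSpec,
    AudioTrack,
    CalibrationProfile,
    MixEntry,
    apply_level,
    calibrate_level,
    downmix_to_mono,
    mix,
    normalize_rms,
    read_wav,
    resample,
    synthesize_am_tone,
    write_wav,
)
from amdt.stimulus import StimulusError


def sine(freq=100.0, amp=1.0, dur=1.0, rate=44100.0):
    t = np.arange(int(dur * rate)) / rate
    return AudioTrack(amp * np.sin(2 * np.pi * freq * t), rate)


class TestAMToneSynthesis:
    @pytest.mark.parametrize("depth_db, m", [(0.0, 1.0), (-20.0, 0.1), (-6.0206, 0.5)])
    def test_depth_to_modulation_index(self, depth_db, m):
        spec = AMToneSpec(400.0, 5.0, depth_db)
        assert spec.modulation_index == pytest.approx(m, abs=1e-4)

    def test_overmodulation_clamped_for_synthesis_only(self):
        spec = AMToneSpec(400.0, 5.0, depth_db=6.0)
        assert spec.modulation_index == 1.0
        assert spec.depth_db == 6.0  # tracked value untouched
        full = synthesize_am_tone(AMToneSpec(400.0, 5.0, 0.0))
        over = synthesize_am_tone(spec)
        np.testing.assert_allclose(over.samples, full.samples)

    def test_unit_rms_and_length(self):
        track = synthesize_am_tone(AMToneSpec(400.0, 5.0, -6.0206, 1.0, 44100.0))
        assert track.rms == pytest.approx(1.0, abs=1e-9)
        assert len(track.samples) == 44100
        assert track.rate == 44100.0

    def test_zero_modulation_rate_is_pure_carrier(self):
        unmod = synthesize_am_tone(AMToneSpec(400.0, 0.0, 0.0, 0.5))
        carrier = normalize_rms(sine(400.0, dur=0.5))
        np.testing.assert_allclose(unmod.samples, carrier.samples, atol=1e-12)

    def test_deep_depth_approaches_pure_carrier(self):
        nearly_flat = synthesize_am_tone(AMToneSpec(400.0, 5.0, -120.0, 0.5))
        carrier = synthesize_am_tone(AMToneSpec(400.0, 0.0, 0.0, 0.5))
        np.testing.assert_allclose(nearly_flat.samples, carrier.samples, atol=1e-4)

    @pytest.mark.parametrize("bad", [
        dict(carrier_hz=0.0, mod_hz=5.0, depth_db=0.0),
        dict(carrier_hz=400.0, mod_hz=-1.0, depth_db=0.0),
        dict(carrier_hz=400.0, mod_hz=5.0, depth_db=0.0, duration_s=0.0),
        dict(carrier_hz=400.0, mod_hz=5.0, depth_db=0.0, rate=0.0),
    ])
    def test_invalid_specification_rejected(self, bad):
        with pytest.raises(StimulusError):
            AMToneSpec(**bad)


class TestNormalizeRMS:
    def test_sine_gains_sqrt2_amplitude(self):
        out = normalize_rms(sine(amp=0.3))
        assert np.max(np.abs(out.samples)) == pytest.approx(np.sqrt(2), rel=1e-4)
        assert out.rms == pytest.approx(1.0, abs=1e-9)

    def test_unit_rms_input_unchanged(self):
        track = normalize_rms(sine())
        again = normalize_rms(track)
        np.testing.assert_allclose(again.samples, track.samples, rtol=1e-12)

    def test_random_track(self, rng):
        track = AudioTrack(rng.normal(size=1000), 44100.0)
        assert normalize_rms(track).rms == pytest.approx(1.0, abs=1e-9)

    def test_all_zero_rejected(self):
        with pytest.raises(StimulusError):
            normalize_rms(AudioTrack(np.zeros(100), 44100.0))

    @settings(max_examples=50, derandomize=True)
    @given(arrays(np.float64, st.integers(2, 200),
                  elements=st.floats(-1e6, 1e6, allow_nan=False),
                  ).filter(lambda a: np.sqrt(np.mean(a * a)) > 1e-12))
    def test_unit_rms_postcondition_property(self, samples):
        out = normalize_rms(AudioTrack(samples, 48000.0))
        assert out.rms == pytest.approx(1.0, abs=1e-9)
        # shape preserved: output is a positive multiple of the input
        scale = np.sqrt(np.mean(samples**2))
        np.testing.assert_allclose(out.samples * scale, samples, rtol=1e-9, atol=1e-12)


class TestDownmix:
    def test_identical_channels_sum(self):
        left = np.sin(np.linspace(0, 1, 100))
        out = downmix_to_mono([left, left], 44100.0)
        np.testing.assert_allclose(out.samples, 2 * left)

    def test_single_channel_identity(self):
        left = np.sin(np.linspace(0, 1, 100))
        np.testing.assert_allclose(downmix_to_mono([left], 44100.0).samples, left)

    def test_antiphase_cancels(self):
        left = np.sin(np.linspace(0, 1, 100))
        out = downmix_to_mono([left, -left], 44100.0)
        np.testing.assert_allclose(out.samples, 0.0, atol=1e-15)

    def test_ragged_channels_rejected(self):
        with pytest.raises(StimulusError):
            downmix_to_mono([np.zeros(10), np.zeros(11)], 44100.0)


class TestResample:
    def test_same_rate_is_bitwise_passthrough(self):
        track = sine()
        assert resample(track, track.rate) is track

    def test_duration_conserved(self):
        out = resample(sine(dur=1.0, rate=44100.0), 48000.0)
        assert len(out.samples) == 48000
        assert out.rate == 48000.0

    def test_downsampled_sine_matches_analytic(self):
        out = resample(sine(freq=100.0, rate=44100.0), 22050.0)
        t = np.arange(len(out.samples)) / 22050.0
        ref = np.sin(2 * np.pi * 100.0 * t)
        # ignore filter edge effects
        sl = slice(200, -200)
        corr = np.corrcoef(out.samples[sl], ref[sl])[0, 1]
        assert corr > 0.999

    def test_sub_nyquist_energy_preserved(self):
        track = sine(freq=100.0, rate=44100.0)
        out = resample(track, 22050.0)
        assert out.rms == pytest.approx(track.rms, rel=0.01)

    def test_invalid_rate_rejected(self):
        with pytest.raises(StimulusError):
            resample(sine(), 0.0)


class TestApplyLevel:
    @pytest.mark.parametrize("level_db, factor, tol", [
        (0.0, 1.0, 1e-12), (-20.0, 0.1, 1e-12), (6.0206, 2.0, 1e-6),
    ])
    def test_db_scaling(self, level_db, factor, tol):
        track = sine()
        out = apply_level(track, level_db)
        np.testing.assert_allclose(out.samples, track.samples * factor,
                                   rtol=tol, atol=tol)


class TestMix:
    def test_empty_schedule_is_silence(self):
        buf = mix([], n_channels=2, rate=44100.0, duration_s=1.0)
        assert buf.shape == (2, 44100)
        assert not buf.any()

    def test_onset_quantization(self):
        dc = AudioTrack(np.ones(11025), 44100.0)  # nonzero from its first sample
        entry = MixEntry(dc, onset_s=0.5)
        buf = mix([entry], 1, 44100.0, 1.0)
        nonzero = np.flatnonzero(buf[0])
        assert nonzero[0] == 22050
        assert not buf[0, :22050].any()

    def test_superposition_of_identical_entries(self):
        entry = MixEntry(sine(dur=0.25), onset_s=0.1)
        one = mix([entry], 1, 44100.0, 1.0)
        two = mix([entry, entry], 1, 44100.0, 1.0)
        np.testing.assert_allclose(two, 2 * one)

    def test_mix_is_linear_in_the_schedule(self, rng):
        a = [MixEntry(sine(200.0, dur=0.2), level_db=-3.0, channel=0, onset_s=0.0),
             MixEntry(sine(300.0, dur=0.3), level_db=2.0, channel=1, onset_s=0.4)]
        b = [MixEntry(AudioTrack(rng.normal(size=4410), 44100.0),
                      level_db=-6.0, channel=0, onset_s=0.55)]
        combined = mix(a + b, 2, 44100.0, 1.0)
        np.testing.assert_allclose(
            combined, mix(a, 2, 44100.0, 1.0) + mix(b, 2, 44100.0, 1.0),
            atol=1e-15)

    def test_entry_rms_over_support_matches_level(self):
        track = normalize_rms(sine(dur=0.5))
        buf = mix([MixEntry(track, level_db=-12.0, onset_s=0.25)], 1, 44100.0, 1.0)
        support = buf[0, 11025:11025 + 22050]
        assert np.sqrt(np.mean(support**2)) == pytest.approx(10 ** (-12 / 20), abs=1e-6)

    def test_channel_out_of_range_rejected(self):
        with pytest.raises(StimulusError, match="channel"):
            mix([MixEntry(sine(dur=0.1), channel=2)], 2, 44100.0, 1.0)

    def test_overrunning_entry_rejected(self):
        with pytest.raises(StimulusError, match="overrun"):
            mix([MixEntry(sine(dur=0.6), onset_s=0.5)], 1, 44100.0, 1.0)


class TestCalibration:
    def test_offset_subtracted(self):
        profile = CalibrationProfile({0: 5.0}, reference="1 kHz warble, ch0")
        assert calibrate_level(70.0, 0, profile) == 65.0

    def test_zero_offset_identity(self):
        assert calibrate_level(60.0, 0, CalibrationProfile({0: 0.0})) == 60.0

    @pytest.mark.parametrize("target, offset", [(70.0, 5.0), (62.5, -3.25), (0.0, 11.0)])
    def test_round_trip(self, target, offset):
        profile = CalibrationProfile({0: offset})
        assert calibrate_level(target, 0, profile) + offset == target

    def test_unknown_channel_rejected(self):
        with pytest.raises(StimulusError, match="channel 3"):
            calibrate_level(70.0, 3, CalibrationProfile({0: 0.0}))

    def test_profile_json_round_trip(self, tmp_path):
        profile = CalibrationProfile({0: 5.0, 1: -2.5}, reference="pink noise")
        path = tmp_path / "cal.json"
        profile.to_json(path)
        assert CalibrationProfile.from_json(path) == profile
        assert json.loads(path.read_text())["offset_db"] == {"0": 5.0, "1": -2.5}


class TestWavIO:
    def test_round_trip(self, tmp_path):
        track = synthesize_am_tone(AMToneSpec(400.0, 5.0, -6.0, 0.2))
        path = tmp_path / "tone.wav"
        write_wav(path, track)
        back = read_wav(path)
        assert back.rate == track.rate
        np.testing.assert_allclose(back.samples, track.samples, atol=1e-6)
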