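"""Envelope extraction, onset signal, peak counting, stimulus preparation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocktailtrf.audio import (
    AudioTrack,
    EnvelopeSeries,
    build_mixture,
    count_envelope_peaks,
    extract_envelope,
    onset_signal,
    percent_excess,
    read_wav,
    shorten_pauses,
    write_wav,
)

FS = 44100


def tone(freq=1000.0, dur=5.0, amp=1.0):
    t = np.arange(0, dur, 1 / FS)
    return AudioTrack(amp * np.sin(2 * np.pi * freq * t), FS)


class TestExtractEnvelope:
    def test_constant_tone_has_flat_envelope(self):
        env = extract_envelope(tone())
        inner = env.values[64:-64]  # half a second away from the edges
        assert inner.std() / inner.mean() < 0.05

    def test_silence_gives_zero_envelope(self):
        env = extract_envelope(AudioTrack(np.zeros(FS * 2), FS))
        assert np.allclose(env.values, 0.0)

    def test_am_modulation_frequency_survives(self):
        # 100% sinusoidal AM at 4 Hz: the analytic-signal magnitude is
        # (1 + sin 2*pi*4t)/2, so the envelope's dominant non-DC spectral
        # component must sit at 4 Hz
        t = np.arange(0, 5, 1 / FS)
        am = AudioTrack(np.sin(2 * np.pi * 1000 * t) * (1 + np.sin(2 * np.pi * 4 * t)) / 2, FS)
        env = extract_envelope(am)
        x = env.values - env.values.mean()
        freqs = np.fft.rfftfreq(len(x), 1 / env.rate)
        assert freqs[np.argmax(np.abs(np.fft.rfft(x)))] == pytest.approx(4.0, abs=0.1)

    def test_output_length_is_rounded_duration(self):
        env = extract_envelope(tone(dur=3.3))
        assert len(env.values) == round(3.3 * 128)

    def test_amplitude_homogeneous(self):
        e1 = extract_envelope(tone(amp=1.0))
        e2 = extract_envelope(tone(amp=3.5))
        assert np.allclose(e2.values, 3.5 * e1.values, rtol=1e-9, atol=1e-12)

    def test_rejects_low_rate_and_stereo(self):
        with pytest.raises(ValueError):
            extract_envelope(AudioTrack(np.zeros(1000), 8000))
        with pytest.raises(ValueError):
            AudioTrack(np.zeros((2, 100)), FS)

    def test_too_short_audio_raises(self):
        with pytest.raises(ValueError, match="too short"):
            extract_envelope(AudioTrack(np.ones(5), FS))


class TestOnsetSignal:
    def test_decreasing_envelope_gives_zero(self):
        env = EnvelopeSeries(np.linspace(1, 0, 100), 128.0)
        assert np.allclose(onset_signal(env).values, 0.0)

    def test_linear_ramp_gives_constant_slope(self):
        k = 2.5
        rate = 128.0
        env = EnvelopeSeries(k * np.arange(200) / rate, rate)
        out = onset_signal(env)
        assert out.values[0] == 0.0
        assert np.allclose(out.values[1:], k)

    def test_am_envelope_onset_burst_rate(self):
        # each 4-Hz AM cycle has exactly one rising phase -> 4 bursts/s
        rate = 128.0
        t = np.arange(0, 5, 1 / rate)
        env = EnvelopeSeries((1 + np.sin(2 * np.pi * 4 * t)) / 2, rate)
        out = onset_signal(env)
        active = out.values > 0
        n_bursts = int(np.sum(np.diff(active.astype(int)) == 1))
        assert n_bursts == pytest.approx(4 * 5, abs=1)

    @given(st.lists(st.floats(0, 10), min_size=2, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_everywhere_nonnegative(self, values):
        out = onset_signal(EnvelopeSeries(np.array(values), 128.0))
        assert np.all(out.values >= 0)

    def test_empty_is_an_error(self):
        with pytest.raises(ValueError):
            onset_signal(EnvelopeSeries(np.array([]), 128.0))


def pulse_train(times_s, rate=128.0, dur=5.0, width=1.5):
    x = np.zeros(int(dur * rate))
    base = np.exp(-0.5 * (np.arange(-4, 5) / width) ** 2)
    for t in times_s:
        i = int(round(t * rate))
        x[i - 4 : i + 5] += base
    return EnvelopeSeries(x, rate)


class TestCountEnvelopePeaks:
    def test_all_zero_has_zero_count(self):
        stats = count_envelope_peaks(EnvelopeSeries(np.zeros(640), 128.0))
        assert stats.count == 0 and stats.rate_per_s == 0.0

    def test_isolated_pulse_train_counted_exactly(self):
        times = np.linspace(0.2, 4.8, 33)
        stats = count_envelope_peaks(pulse_train(times))
        assert stats.count == 33
        assert stats.rate_per_s == pytest.approx(6.6)

    def test_near_coincident_pulses_merge(self):
        # two pulses closer than the pulse width fuse into a single ridge
        merged = count_envelope_peaks(pulse_train([1.0, 1.008], dur=2.0))
        apart = count_envelope_peaks(pulse_train([1.0, 1.5], dur=2.0))
        assert merged.count == 1
        assert apart.count == 2

    def test_invariant_to_amplitude_scaling(self):
        times = np.linspace(0.3, 4.5, 20)
        env = pulse_train(times)
        scaled = EnvelopeSeries(env.values * 37.0, env.rate)
        assert count_envelope_peaks(env).count == count_envelope_peaks(scaled).count


class TestPercentExcess:
    def test_published_count_pair(self):
        assert percent_excess(11169, 10199) == 9.5

    def test_identity_and_forced_arithmetic(self):
        assert percent_excess(123, 123) == 0.0
        assert percent_excess(110, 100) == 10.0

    def test_zero_reference_is_an_error(self):
        with pytest.raises(ValueError):
            percent_excess(10, 0)


def speech_like(rng, dur=1.0):
    return rng.normal(size=int(dur * FS))


class TestShortenPauses:
    def test_single_long_gap_truncated_to_300ms(self, rng):
        sp = speech_like(rng)
        a = AudioTrack(np.concatenate([sp, np.zeros(FS), sp]), FS)
        b = shorten_pauses(a)
        assert a.duration - b.duration == pytest.approx(0.7, abs=1e-3)

    def test_short_gaps_left_bit_identical(self, rng):
        sp = speech_like(rng)
        a = AudioTrack(np.concatenate([sp, np.zeros(int(0.2 * FS)), sp]), FS)
        assert np.array_equal(shorten_pauses(a).samples, a.samples)

    def test_two_gaps_truncated_independently(self, rng):
        sp = speech_like(rng)
        a = AudioTrack(
            np.concatenate(
                [sp, np.zeros(int(0.5 * FS)), sp, np.zeros(int(0.4 * FS)), sp]
            ),
            FS,
        )
        b = shorten_pauses(a)
        assert a.duration - b.duration == pytest.approx(0.3, abs=1e-3)

    def test_never_lengthens_and_idempotent(self, rng):
        sp = speech_like(rng)
        a = AudioTrack(np.concatenate([sp, np.zeros(2 * FS), sp]), FS)
        b = shorten_pauses(a)
        c = shorten_pauses(b)
        assert len(b.samples) <= len(a.samples)
        assert np.array_equal(b.samples, c.samples)


class TestBuildMixture:
    def make_pair(self, rng, masker_scale=3.0):
        t = AudioTrack(rng.normal(size=7 * FS), FS)
        m = AudioTrack(masker_scale * rng.normal(size=6 * FS), FS)
        return t, m

    def test_silent_masker_returns_ramped_target(self, rng):
        t, _ = self.make_pair(rng)
        silent = AudioTrack(np.zeros(6 * FS), FS)
        mix = build_mixture(t, silent)
        n_ramp = int(round(0.017 * FS))
        assert np.allclose(mix.samples[n_ramp:-n_ramp], t.samples[n_ramp:-n_ramp])

    def test_rms_normalization(self, rng):
        t, m = self.make_pair(rng, masker_scale=5.0)
        mix = build_mixture(t, m)
        ref = np.sqrt(np.mean(t.samples**2))
        # reconstruct the masker contribution from the mixture tail region
        masker_part = mix.samples[FS : 7 * FS] - t.samples[FS : 7 * FS] * 1.0
        # inner portion away from ramps has the normalized masker
        inner = masker_part[FS : 4 * FS]
        assert np.sqrt(np.mean(inner**2)) == pytest.approx(ref, rel=1e-2)

    def test_no_masker_energy_before_offset(self, rng):
        t, m = self.make_pair(rng)
        mix = build_mixture(t, m)
        pre = mix.samples[: FS - 1]
        assert np.allclose(pre, t.samples[: FS - 1] * _ramp_weights(len(t.samples))[: FS - 1])

    def test_rate_mismatch_is_an_error(self, rng):
        t = AudioTrack(rng.normal(size=7 * FS), FS)
        m = AudioTrack(rng.normal(size=6 * 22050), 22050)
        with pytest.raises(ValueError):
            build_mixture(t, m)


def _ramp_weights(n, ramp=0.017, fs=FS):
    from cocktailtrf.audio import _cosine_ramp

    return _cosine_ramp(n, int(round(ramp * fs)))


class TestWavRoundTrip:
    def test_float_wav_round_trip(self, tmp_path, rng):
        a = AudioTrack(rng.normal(size=1000).astype(np.float32).astype(float), FS)
        path = tmp_path / "t.wav"
        write_wav(path, a)
        b = read_wav(path)
        assert b.rate == FS
        assert np.allclose(a.samples, b.samples, atol=1e-6)
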