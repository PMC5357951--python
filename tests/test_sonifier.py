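"""Voltage-to-sound mapping: normalization, pitch/amplitude laws, rendering."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ecgsonify import sonifier
from ecgsonify.sonifier import (
    AudioSignal,
    ControlSignal,
    SonificationConfig,
    amplitude_gain,
    instantaneous_frequency,
    mix,
    normalize_channel,
    render_channel,
    resample_control,
    sonify,
)

# exclude magnitudes tiny enough to underflow to 0 under max-abs division
finite_voltages = st.lists(
    st.floats(-10, 10, allow_nan=False).filter(lambda x: x == 0 or abs(x) > 1e-9),
    min_size=2, max_size=50,
)


class TestNormalize:
    def test_zero_input_stays_zero(self):
        np.testing.assert_array_equal(normalize_channel(np.zeros(3)), np.zeros(3))

    def test_max_abs_scaling(self):
        np.testing.assert_allclose(
            normalize_channel(np.array([-2.0, 1.0])), [-1.0, 0.5]
        )

    @settings(deadline=None)
    @given(finite_voltages)
    def test_nonzero_input_has_unit_peak(self, values):
        v = np.asarray(values)
        out = normalize_channel(v)
        if np.max(np.abs(v)) > 0:
            assert np.max(np.abs(out)) == pytest.approx(1.0)
            # sign- and order-preserving
            assert np.all(np.sign(out) == np.sign(v))

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_channel(np.array([1.0, np.inf]))


class TestResample:
    def test_constant_stays_constant(self):
        ctrl = resample_control(np.array([0.5, 0.5]), 1.0, 100.0)
        assert ctrl.values.size == 200
        np.testing.assert_allclose(ctrl.values, 0.5)

    def test_linear_ramp_midpoint(self):
        ctrl = resample_control(np.array([0.0, 1.0]), 2.0, 1000.0)
        assert ctrl.values[0] == 0.0
        # value at t=0.25 s is halfway up the 0..0.5 s ramp
        assert ctrl.values[250] == pytest.approx(0.5, abs=1e-3)

    @settings(deadline=None)
    @given(finite_voltages)
    def test_extrema_bounded_by_input(self, values):
        v = normalize_channel(np.asarray(values)) if np.any(values) else np.asarray(values)
        ctrl = resample_control(v, 257.0, 8000.0)
        assert ctrl.values.min() >= v.min() - 1e-12
        assert ctrl.values.max() <= v.max() + 1e-12

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            resample_control(np.array([1.0]), 257.0, 44100.0)


class TestMappingLaws:
    def test_no_modulation_at_baseline(self):
        assert instantaneous_frequency(146.83, 0.0, 0.5) == pytest.approx(146.83)

    def test_full_scale_is_half_semitone_about_3_percent(self):
        ratio = instantaneous_frequency(200.0, 1.0, 0.5) / 200.0
        assert ratio == pytest.approx(2 ** (1 / 24))
        assert ratio == pytest.approx(1.03, abs=0.001)

    def test_geometric_symmetry(self):
        up = instantaneous_frequency(100.0, 1.0, 0.5) / 100.0
        down = instantaneous_frequency(100.0, -1.0, 0.5) / 100.0
        assert up * down == pytest.approx(1.0)

    @pytest.mark.parametrize("v,expected", [(-1.0, 0.0), (0.0, 0.5), (1.0, 1.0)])
    def test_amplitude_transfer_endpoints(self, v, expected):
        assert amplitude_gain(v) == pytest.approx(expected)

    def test_amplitude_transfer_monotone(self):
        v = np.linspace(-1, 1, 101)
        assert np.all(np.diff(amplitude_gain(v)) > 0)


def naive_render_oracle(v, config, channel_index):
    """Independent per-sample re-synthesis: explicit Python loop over the
    phase recursion phi[n] = phi[n-1] + 2*pi*f(v[n])/rate, phi[0] = 0."""
    f0 = config.fundamentals_hz[channel_index]
    w = config.loudness_weights[channel_index]
    rate = config.audio_sample_rate_hz
    headroom = 1.0 + sum(config.harmonic_rel_amplitudes)
    out = []
    phi = 0.0
    for n, vn in enumerate(v):
        f = f0 * 2.0 ** (config.pitch_mod_semitones * vn / 12.0)
        if n > 0:
            phi += 2.0 * math.pi * f / rate
        sample = math.sin(phi)
        for k, a in zip(config.harmonic_multipliers, config.harmonic_rel_amplitudes):
            sample += a * math.sin(k * phi)
        out.append(w * (1.0 + vn) / 2.0 * sample / headroom)
    return np.array(out)


class TestRenderChannel:
    def test_matches_naive_oracle_on_ramped_control(self, default_config):
        rate = default_config.audio_sample_rate_hz
        v = np.linspace(-0.8, 0.8, rate)  # 1 s slow ramp
        ctrl = ControlSignal(values=v, sample_rate_hz=rate)
        fast = render_channel(ctrl, default_config, 2)
        slow = naive_render_oracle(v, default_config, 2)
        assert np.max(np.abs(fast.samples - slow)) <= 1e-9

    def test_full_negative_control_is_silent(self, default_config):
        ctrl = ControlSignal(values=-np.ones(4410), sample_rate_hz=44100)
        audio = render_channel(ctrl, default_config, 0)
        np.testing.assert_array_equal(audio.samples, 0.0)

    def test_phase_continuity_across_control_jumps(self, default_config):
        # square-wave control: pitch jumps, but successive samples never
        # differ by more than the largest possible phase step allows
        rate = default_config.audio_sample_rate_hz
        v = np.where(np.arange(rate) % 1000 < 500, 1.0, -1.0)
        audio = render_channel(ControlSignal(v, rate), default_config, 5)
        f_max = default_config.fundamentals_hz[-1] * 2 ** (0.5 / 12)
        k_max = max(default_config.harmonic_multipliers)
        max_step = 2 * np.pi * f_max * k_max / rate * (
            1 + sum(default_config.harmonic_rel_amplitudes)
        )
        assert np.max(np.abs(np.diff(audio.samples))) <= max_step

    def test_rms_follows_loudness_ramp(self, default_config, zero_control_10s):
        rms = []
        for i in range(6):
            a = render_channel(zero_control_10s, default_config, i)
            rms.append(np.sqrt(np.mean(a.samples**2)))
        ratios = np.array(rms) / rms[0]
        # finite-window RMS of a sine is not exactly amplitude/sqrt(2);
        # partial-period remainders perturb the ratio at the 1e-5 level
        np.testing.assert_allclose(
            ratios, np.linspace(1.0, 0.30, 6), atol=1e-4
        )

    def test_out_of_range_channel(self, default_config, zero_control_10s):
        with pytest.raises(IndexError):
            render_channel(zero_control_10s, default_config, 6)


class TestMix:
    def _tone(self, f, n=4410, rate=44100, amp=0.3):
        t = np.arange(n) / rate
        return AudioSignal(amp * np.sin(2 * np.pi * f * t), rate)

    def test_single_channel_scaled_to_peak(self, default_config):
        audio = mix([self._tone(220.0)], default_config)
        assert np.max(np.abs(audio.samples)) == pytest.approx(
            default_config.output_peak, abs=1e-9
        )

    def test_silence_in_silence_out(self, default_config):
        silent = AudioSignal(np.zeros(4410), 44100)
        out = mix([silent, silent], default_config)
        np.testing.assert_array_equal(out.samples, 0.0)

    def test_peak_equals_target_for_many_channels(self, default_config):
        rng = np.random.default_rng(7)
        chans = [
            AudioSignal(0.4 * np.sin(2 * np.pi * f * np.arange(44100) / 44100
                                     + rng.uniform(0, 6)), 44100)
            for f in (150, 220, 330, 440, 550, 660)
        ]
        out = mix(chans, default_config)
        assert np.max(np.abs(out.samples)) == pytest.approx(0.9, abs=1e-9)

    def test_mix_is_linear_up_to_scale(self, default_config):
        a, b = self._tone(220.0), self._tone(330.0)
        out = mix([a, b], default_config)
        total = a.samples + b.samples
        scale = default_config.output_peak / np.max(np.abs(total))
        n_fade = round(default_config.fade_s * 44100)
        np.testing.assert_allclose(
            out.samples[n_fade:-n_fade], (total * scale)[n_fade:-n_fade], atol=1e-12
        )

    def test_mismatched_inputs_rejected(self, default_config):
        with pytest.raises(ValueError):
            mix([self._tone(220, n=100), self._tone(220, n=200)], default_config)


class TestSonify:
    def test_duration_maps_to_audio_samples(self, make_record, default_config):
        rec = make_record(n_samples=2570)
        audio = sonify(rec, default_config)
        assert audio.samples.size == 441000
        assert audio.sample_rate_hz == 44100

    def test_deterministic_bit_identical(self, make_record, default_config):
        rec = make_record(seed=3)
        a = sonify(rec, default_config)
        b = sonify(rec, default_config)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_lead_count_mismatch_names_both_counts(self, make_record):
        rec = make_record(n_leads=2)
        with pytest.raises(ValueError, match="2 leads.*6 pitches"):
            sonify(rec, SonificationConfig())

    def test_config_invariants(self):
        with pytest.raises(ValueError):
            SonificationConfig(fundamentals_hz=(220.0, 146.83))  # not increasing
        with pytest.raises(ValueError):
            SonificationConfig(harmonic_multipliers=(3, 4),
                               harmonic_rel_amplitudes=(0.15,))
        with pytest.raises(ValueError):
            SonificationConfig(fundamentals_hz=(5000.0, 9000.0))  # over Nyquist
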