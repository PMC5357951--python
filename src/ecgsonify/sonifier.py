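"""Polyphonic parameter-mapping sonification of multi-lead ECG.

Each ECG lead drives one time-variant oscillator. The lead voltage,
normalized to [-1, 1], controls both the oscillator's amplitude (louder for
higher voltage, silent at full negative deflection) and its pitch (up to
half a semitone of deviation, i.e. ~3 %, at full scale). Each oscillator
carries a fixed harmonic set — multiples 3, 4 and 5 of the fundamental at
15 %, 5 % and 5 % of its amplitude; the 2nd harmonic is deliberately absent
because the upper three fundamentals are octave shifts of the lower three
and an octave harmonic would blur which channel is sounding. Per-channel
gains fall linearly from 100 % for the lowest pitch to 30 % for the highest,
a rough loudness compensation. The six defaults are the D-minor pitches
D3, F3, A3, D4, F4, A4 over two octaves.

The rendering path is ``normalize_channel`` → ``resample_control`` →
``render_channel`` per lead, then ``mix``; :func:`sonify` composes them.
Everything is deterministic: same record and config, bit-identical audio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .io import ECGRecord

__all__ = [
    "SonificationConfig",
    "ControlSignal",
    "AudioSignal",
    "normalize_channel",
    "resample_control",
    "instantaneous_frequency",
    "amplitude_gain",
    "render_channel",
    "mix",
    "sonify",
    "write_wav",
]

#: D-minor scale over two octaves (D3 F3 A3 D4 F4 A4), one pitch per lead.
D_MINOR_FUNDAMENTALS = (146.83, 174.61, 220.00, 293.67, 349.23, 440.00)


def loudness_ramp(n_channels: int, low: float = 1.0, high: float = 0.30) -> list[float]:
    """Linear per-channel gain ramp from ``low`` (lowest pitch) to ``high``
    (highest pitch); a coarse stand-in for an equal-loudness contour."""
    if n_channels == 1:
        return [low]
    return list(np.linspace(low, high, n_channels))


@dataclass
class SonificationConfig:
    """All mapping parameters of the sonification.

    Attributes
    ----------
    fundamentals_hz
        One oscillator fundamental per sonified channel, strictly increasing.
    harmonic_multipliers, harmonic_rel_amplitudes
        Parallel lists: integer frequency multiples added to each channel and
        their amplitudes as fractions of the fundamental's amplitude.
    pitch_mod_semitones
        Peak pitch deviation, in semitones, reached at control value ±1.
    loudness_weights
        Per-channel gain; defaults to the linear 1.00 → 0.30 ramp.
    audio_sample_rate_hz
        Output audio rate (Hz).
    fade_s
        Raised-cosine fade length applied to both ends of the mix (s).
    output_peak
        Peak amplitude the mixed signal is normalized to.
    """

    fundamentals_hz: tuple[float, ...] = D_MINOR_FUNDAMENTALS
    harmonic_multipliers: tuple[int, ...] = (3, 4, 5)
    harmonic_rel_amplitudes: tuple[float, ...] = (0.15, 0.05, 0.05)
    pitch_mod_semitones: float = 0.5
    loudness_weights: tuple[float, ...] | None = None
    audio_sample_rate_hz: int = 44100
    fade_s: float = 0.005
    output_peak: float = 0.9

    def __post_init__(self) -> None:
        f = np.asarray(self.fundamentals_hz, dtype=float)
        if f.size == 0 or np.any(f <= 0) or np.any(np.diff(f) <= 0):
            raise ValueError("fundamentals_hz must be positive and strictly increasing")
        if len(self.harmonic_multipliers) != len(self.harmonic_rel_amplitudes):
            raise ValueError("harmonic multiplier and amplitude lists differ in length")
        if self.loudness_weights is None:
            self.loudness_weights = tuple(loudness_ramp(f.size))
        if len(self.loudness_weights) != f.size:
            raise ValueError("one loudness weight per fundamental is required")
        if not all(0 < w <= 1 for w in self.loudness_weights):
            raise ValueError("loudness weights must lie in (0, 1]")
        k_max = max(self.harmonic_multipliers, default=1)
        mod = 2 ** (abs(self.pitch_mod_semitones) / 12)
        if f.max() * k_max * mod >= self.audio_sample_rate_hz / 2:
            raise ValueError(
                "highest harmonic exceeds Nyquist even before modulation headroom"
            )
        if self.fade_s < 0 or not 0 < self.output_peak <= 1:
            raise ValueError("fade_s must be >= 0 and output_peak in (0, 1]")

    @property
    def n_channels(self) -> int:
        return len(self.fundamentals_hz)


@dataclass
class ControlSignal:
    """A normalized voltage trace resampled to audio rate; values in [-1, 1]."""

    values: np.ndarray
    sample_rate_hz: float
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("control signal contains non-finite values")
        if self.values.size and np.max(np.abs(self.values)) > 1 + 1e-12:
            raise ValueError("control signal exceeds [-1, 1]")


@dataclass
class AudioSignal:
    """Rendered audio: finite samples bounded by ±1 at a fixed rate."""

    samples: np.ndarray
    sample_rate_hz: int

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")
        if self.samples.size and np.max(np.abs(self.samples)) > 1 + 1e-9:
            raise ValueError("audio exceeds the [-1, 1] range")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sample_rate_hz


def normalize_channel(voltages: np.ndarray) -> np.ndarray:
    """Scale a voltage trace by its max absolute value into [-1, 1].

    Sign- and order-preserving; an all-zero trace stays all-zero. The scope
    is the whole trace of one channel, so relative deflections within a
    channel are preserved while channels of different absolute amplitude
    all become audible.
    """
    v = np.asarray(voltages, dtype=float)
    if v.size == 0:
        raise ValueError("empty voltage sequence")
    if not np.all(np.isfinite(v)):
        raise ValueError("voltages contain non-finite values")
    peak = np.max(np.abs(v))
    return v / peak if peak > 0 else np.zeros_like(v)


def resample_control(
    values: np.ndarray, ecg_rate_hz: float, audio_rate_hz: float, label: str = ""
) -> ControlSignal:
    """Linearly interpolate a normalized trace from ECG rate to audio rate.

    Output length is ``round(duration * audio_rate)`` with duration =
    n/ecg_rate; endpoints are preserved and, linear interpolation being
    convex, the output never leaves [min(input), max(input)].
    """
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 samples to resample")
    if not ecg_rate_hz < audio_rate_hz:
        raise ValueError("audio rate must exceed the ECG rate")
    n_out = int(round(v.size / ecg_rate_hz * audio_rate_hz))
    t_out = np.arange(n_out) / audio_rate_hz
    t_in = np.arange(v.size) / ecg_rate_hz
    out = np.interp(t_out, t_in, v)
    return ControlSignal(values=out, sample_rate_hz=audio_rate_hz, label=label)


def instantaneous_frequency(
    f0: float | np.ndarray, v: float | np.ndarray, pitch_mod_semitones: float
) -> float | np.ndarray:
    """Voltage-controlled pitch: f = f0 * 2**(s*v/12).

    At the default half-semitone depth, v=+1 raises the pitch by a factor
    2**(1/24) ≈ 1.0293, i.e. about +3 %; v=-1 lowers it symmetrically on the
    log-frequency axis. f(0) = f0 exactly.
    """
    return f0 * 2.0 ** (pitch_mod_semitones * np.asarray(v, dtype=float) / 12.0)


def amplitude_gain(v: float | np.ndarray) -> float | np.ndarray:
    """Voltage-to-amplitude transfer g(v) = (1+v)/2.

    The isoelectric baseline (v=0) sounds at half gain, so the sonification
    is a continuous stream of notes; full negative deflection is silent.
    """
    return (1.0 + np.asarray(v, dtype=float)) / 2.0


def render_channel(
    control: ControlSignal, config: SonificationConfig, channel_index: int
) -> AudioSignal:
    """Render one channel as a time-variant oscillator with its harmonic set.

    The phase accumulates sample by sample, phi[0] = 0 and
    phi[n] = phi[n-1] + 2*pi*f(v[n])/rate, so pitch changes never reset the
    phase (no clicks). Harmonics are phase-locked at k*phi and share the
    channel's gain envelope; the per-channel loudness weight scales the whole
    channel.
    """
    if not 0 <= channel_index < config.n_channels:
        raise IndexError(
            f"channel_index {channel_index} out of range for "
            f"{config.n_channels} configured channels"
        )
    v = control.values
    f = instantaneous_frequency(
        config.fundamentals_hz[channel_index], v, config.pitch_mod_semitones
    )
    inc = 2.0 * math.pi * np.asarray(f) / config.audio_sample_rate_hz
    phi = np.empty_like(inc)
    if phi.size:
        phi[0] = 0.0
        np.cumsum(inc[1:], out=phi[1:])
    wave = np.sin(phi)
    for k, a in zip(config.harmonic_multipliers, config.harmonic_rel_amplitudes):
        wave += a * np.sin(k * phi)
    gain = config.loudness_weights[channel_index] * amplitude_gain(v)
    samples = gain * wave
    # headroom: |wave| <= 1 + sum(a_k) may exceed 1 transiently; bound it so
    # AudioSignal's invariant holds for any legal config
    scale = 1.0 + float(np.sum(config.harmonic_rel_amplitudes))
    if scale > 1:
        samples = samples / scale
    return AudioSignal(samples=samples, sample_rate_hz=config.audio_sample_rate_hz)


def _raised_cosine_fades(samples: np.ndarray, fade_s: float, rate: int) -> np.ndarray:
    n_fade = int(round(fade_s * rate))
    if n_fade <= 0 or samples.size == 0:
        return samples
    n_fade = min(n_fade, samples.size // 2)
    ramp = 0.5 * (1 - np.cos(np.pi * np.arange(n_fade) / n_fade)) if n_fade else None
    out = samples.copy()
    if n_fade:
        out[:n_fade] *= ramp
        out[-n_fade:] *= ramp[::-1]
    return out


def mix(channels: list[AudioSignal], config: SonificationConfig) -> AudioSignal:
    """Sum channels, normalize the peak to ``config.output_peak`` and apply
    raised-cosine edge fades. Silent input stays silent (no 0/0)."""
    if not channels:
        raise ValueError("no channels to mix")
    rate = channels[0].sample_rate_hz
    n = channels[0].samples.size
    for ch in channels[1:]:
        if ch.sample_rate_hz != rate or ch.samples.size != n:
            raise ValueError("all channels must share length and sample rate")
    total = np.sum([ch.samples for ch in channels], axis=0)
    peak = np.max(np.abs(total)) if total.size else 0.0
    if peak > 0:
        total = total * (config.output_peak / peak)
    total = _raised_cosine_fades(total, config.fade_s, rate)
    return AudioSignal(samples=total, sample_rate_hz=rate)


def sonify(record: ECGRecord, config: SonificationConfig | None = None) -> AudioSignal:
    """Sonify a multi-lead record: one oscillator per lead, lead order maps
    to ascending pitch order, mixed to a single normalized mono signal whose
    duration matches the record's within one audio sample."""
    if config is None:
        config = SonificationConfig()
    if record.n_leads != config.n_channels:
        raise ValueError(
            f"record has {record.n_leads} leads but the config defines "
            f"{config.n_channels} pitches; select leads or adjust fundamentals"
        )
    rendered = []
    for i, name in enumerate(record.lead_names):
        norm = normalize_channel(record.voltages[:, i])
        ctrl = resample_control(
            norm, record.sample_rate_hz, config.audio_sample_rate_hz, label=name
        )
        rendered.append(render_channel(ctrl, config, i))
    return mix(rendered, config)


def write_wav(audio: AudioSignal, path: str | Path, float32: bool = False) -> None:
    """Write mono WAV: 16-bit PCM by default, IEEE float32 on request."""
    if float32:
        data = audio.samples.astype(np.float32)
    else:
        data = np.clip(np.rint(audio.samples * 32767), -32768, 32767).astype(np.int16)
    wavfile.write(str(path), int(audio.sample_rate_hz), data)
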