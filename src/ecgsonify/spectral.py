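"""Spectral measurement utilities: the test surface for the sonifier.

Turns rendered audio into checkable numbers — banded spectral peaks with
sub-bin accuracy (Hann window + parabolic interpolation on log magnitude),
harmonic amplitude ratios, and framewise pitch tracks. Magnitudes are linear
amplitude, scaled so a full-scale sine reports ~1.0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sonifier import AudioSignal

__all__ = ["SpectrumPeak", "fft_peak", "harmonic_ratio", "pitch_track"]

_SILENCE = 1e-10  # linear amplitude below which a band counts as silent


@dataclass(frozen=True)
class SpectrumPeak:
    frequency_hz: float
    magnitude: float  # linear amplitude units


def fft_peak(audio: AudioSignal, band_hz: tuple[float, float]) -> SpectrumPeak | None:
    """Locate the strongest spectral peak inside a frequency band.

    Hann-windowed rFFT; the peak bin is refined by fitting a parabola to the
    log magnitude of the bin and its two neighbours, giving sub-bin frequency
    and amplitude estimates. Returns ``None`` (an explicit "no peak") when
    the band is empty or effectively silent, instead of raising.
    """
    lo, hi = band_hz
    fs = audio.sample_rate_hz
    if not (0 <= lo < hi <= fs / 2):
        raise ValueError(f"band {band_hz} outside [0, Nyquist={fs / 2}]")
    x = audio.samples
    n = x.size
    if n == 0:
        return None
    win = np.hanning(n)
    spec = np.abs(np.fft.rfft(x * win)) * 2.0 / win.sum()
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    in_band = np.nonzero((freqs >= lo) & (freqs <= hi))[0]
    if in_band.size == 0:
        return None
    k = in_band[np.argmax(spec[in_band])]
    if spec[k] < _SILENCE:
        return None
    df = fs / n
    if 0 < k < spec.size - 1 and spec[k - 1] > 0 and spec[k + 1] > 0:
        la, lb, lc = np.log(spec[k - 1 : k + 2])
        denom = la - 2 * lb + lc
        delta = 0.5 * (la - lc) / denom if denom != 0 else 0.0
        delta = float(np.clip(delta, -0.5, 0.5))
        freq = (k + delta) * df
    else:
        freq = k * df
    # amplitude by direct projection at the interpolated frequency: exact for
    # a windowed sinusoid, unlike the parabolic amplitude estimate
    t = np.arange(n) / fs
    mag = 2.0 * np.abs(np.sum(x * win * np.exp(-2j * np.pi * freq * t))) / win.sum()
    return SpectrumPeak(frequency_hz=float(freq), magnitude=float(mag))


def harmonic_ratio(audio: AudioSignal, f0_hz: float, k: int) -> float:
    """Linear amplitude of the k-th harmonic relative to the fundamental.

    Both components are measured with :func:`fft_peak` in ±3 % bands. A
    silent harmonic band reports 0.0; a silent fundamental is an error
    (the ratio is undefined).
    """
    if k * f0_hz >= audio.sample_rate_hz / 2:
        raise ValueError(f"harmonic {k} x {f0_hz} Hz is above Nyquist")
    base = fft_peak(audio, (f0_hz * 0.97, f0_hz * 1.03))
    if base is None:
        raise ValueError(f"no fundamental near {f0_hz} Hz: undefined ratio")
    harm = fft_peak(audio, (k * f0_hz * 0.97, k * f0_hz * 1.03))
    if harm is None:
        return 0.0
    return harm.magnitude / base.magnitude


def pitch_track(audio: AudioSignal, f0_hz: float, frame_s: float) -> np.ndarray:
    """Framewise pitch: per non-overlapping frame, the peak frequency in a
    ±6 % band around ``f0_hz``. Frames without a peak are NaN. Frame length
    must span at least four periods of ``f0_hz``."""
    if frame_s < 4.0 / f0_hz:
        raise ValueError(f"frame_s must be >= 4/f0 = {4.0 / f0_hz:.4f} s")
    fs = audio.sample_rate_hz
    n_frame = int(round(frame_s * fs))
    n_frames = audio.samples.size // n_frame
    band = (f0_hz * 0.94, f0_hz * 1.06)
    track = np.full(n_frames, np.nan)
    for i in range(n_frames):
        frame = AudioSignal(
            samples=audio.samples[i * n_frame : (i + 1) * n_frame],
            sample_rate_hz=fs,
        )
        peak = fft_peak(frame, band)
        if peak is not None:
            track[i] = peak.frequency_hz
    return track
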