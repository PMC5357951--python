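"""Synthetic six-lead ECG generator for five rhythm/morphology classes.

The model is deliberately simple and fully parameterized:

* a beat is a sum of Gaussian bumps for the P, Q, R, S and T waves
  (:class:`BeatTemplate`), with an optional flat ST-segment offset between
  the S and T waves (the STEMI signature);
* a rhythm is a sequence of RR intervals plus a parallel beat-type sequence
  (:class:`RhythmModel`): regular with slight jitter for normal/STEMI,
  isolated premature wide-QRS beats with a full compensatory pause for PVC,
  strict normal/PVC alternation for bigeminy, and independent log-normal RR
  with absent P waves plus 4–9 Hz fibrillatory baseline noise for atrial
  fibrillation;
* a scalar cardiac source ("dipole") is rendered from rhythm + template and
  projected onto the six frontal leads by the cosine of the angle between
  each lead's Cabrera-circle direction and the mean electrical axis.

Every random draw flows from ``spec.seed`` through one Generator, so equal
specs produce bit-identical records.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .io import ECGRecord, FRONTAL_LEADS

__all__ = [
    "PATHOLOGIES",
    "BeatTemplate",
    "SyntheticECGSpec",
    "RhythmModel",
    "make_rhythm",
    "render_dipole",
    "project_leads",
    "generate",
]

PATHOLOGIES = ("normal", "stemi", "pvc", "bigeminy", "afib")

#: Frontal-lead directions on the Cabrera circle, degrees.
LEAD_ANGLES_DEG = {"I": 0.0, "II": 60.0, "III": 120.0,
                   "aVR": -150.0, "aVL": -30.0, "aVF": 90.0}


@dataclass(frozen=True)
class _Wave:
    center_s: float   # offset from the R peak
    width_s: float    # Gaussian sigma
    amplitude_mv: float


@dataclass(frozen=True)
class BeatTemplate:
    """PQRST morphology: five Gaussians relative to the R peak at t=0,
    plus a flat ST-segment baseline shift between the S and T waves."""

    p: _Wave = _Wave(-0.20, 0.025, 0.15)
    q: _Wave = _Wave(-0.035, 0.010, -0.10)
    r: _Wave = _Wave(0.0, 0.012, 1.00)
    s: _Wave = _Wave(0.035, 0.010, -0.20)
    t: _Wave = _Wave(0.30, 0.060, 0.30)
    st_offset_mv: float = 0.0

    def __post_init__(self) -> None:
        waves = [self.p, self.q, self.r, self.s, self.t]
        if any(w.width_s <= 0 for w in waves):
            raise ValueError("wave widths must be positive")
        centers = [w.center_s for w in waves]
        if sorted(centers) != centers or len(set(centers)) != 5:
            raise ValueError("wave centers must be strictly ordered P<Q<R<S<T")

    # ST window: clear of the S and T Gaussian cores
    @property
    def st_window_s(self) -> tuple[float, float]:
        return (self.s.center_s + 3 * self.s.width_s,
                self.t.center_s - 2 * self.t.width_s)

    def pvc_variant(self) -> "BeatTemplate":
        """Ventricular ectopic morphology: QRS widened x3 and scaled x1.5,
        no P wave."""
        def wide(w: _Wave) -> _Wave:
            return _Wave(w.center_s, w.width_s * 3, w.amplitude_mv * 1.5)
        return replace(self, p=_Wave(self.p.center_s, self.p.width_s, 0.0),
                       q=wide(self.q), r=wide(self.r), s=wide(self.s))


@dataclass(frozen=True)
class SyntheticECGSpec:
    """Full description of one synthetic record; the seed makes it a fixture."""

    pathology: Literal["normal", "stemi", "pvc", "bigeminy", "afib"] = "normal"
    heart_rate_bpm: float = 75.0
    duration_s: float = 10.0
    sample_rate_hz: float = 257.0
    noise_sd_mv: float = 0.02
    seed: int = 0
    lead_angles_deg: tuple[float, ...] = tuple(LEAD_ANGLES_DEG[n] for n in FRONTAL_LEADS)
    axis_deg: float = 60.0
    template: BeatTemplate = field(default_factory=BeatTemplate)
    st_elevation_mv: float = 0.3        # applied when pathology == "stemi"
    pvc_fraction: float = 0.10          # share of PVC beats in the pvc class
    pvc_coupling: float = 0.6           # coupling interval as a fraction of RR
    afib_rr_cv: float = 0.25            # log-normal RR coefficient of variation
    rr_jitter: float = 0.02             # max relative jitter of regular RR

    def __post_init__(self) -> None:
        if self.pathology not in PATHOLOGIES:
            raise ValueError(
                f"unknown pathology {self.pathology!r}; choose from {PATHOLOGIES}"
            )
        if self.heart_rate_bpm <= 0 or self.duration_s <= 0 or self.sample_rate_hz <= 0:
            raise ValueError("rate and duration parameters must be positive")
        if self.duration_s * self.sample_rate_hz < 2:
            raise ValueError("spec yields fewer than 2 samples")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be >= 0")
        if len(self.lead_angles_deg) != 6:
            raise ValueError("six frontal lead angles are required")
        if any(not (-180 < a <= 180) for a in self.lead_angles_deg):
            raise ValueError("lead angles must lie in (-180, 180]")


@dataclass
class RhythmModel:
    """RR intervals (s) and parallel beat types covering the record."""

    rr_intervals_s: np.ndarray
    beat_types: list[str]

    def __post_init__(self) -> None:
        self.rr_intervals_s = np.asarray(self.rr_intervals_s, dtype=float)
        if np.any(self.rr_intervals_s <= 0):
            raise ValueError("RR intervals must be positive")
        if len(self.beat_types) != self.rr_intervals_s.size:
            raise ValueError("beat_types must parallel rr_intervals_s")
        if any(t not in ("normal", "pvc") for t in self.beat_types):
            raise ValueError("beat types must be 'normal' or 'pvc'")

    @property
    def onsets_s(self) -> np.ndarray:
        """R-peak times: cumulative RR starting at the first interval."""
        return np.cumsum(self.rr_intervals_s)


def _rng(spec: SyntheticECGSpec, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([spec.seed, salt]))


def make_rhythm(spec: SyntheticECGSpec) -> RhythmModel:
    """Build the class-defining RR structure.

    normal / stemi: constant RR = 60/HR with uniform jitter within ±2 %.
    pvc: regular rhythm with isolated premature beats (~10 % of beats, at
        least one) at a 0.6·RR coupling interval, each followed by a full
        compensatory pause so coupling + pause = 2·RR.
    bigeminy: strict normal/PVC alternation with the same coupling/pause pair.
    afib: independent log-normal RR (mean 60/HR, CV 0.25); continuous draws
        make consecutive equal intervals impossible.
    """
    rng = _rng(spec, 1)
    rr_nominal = 60.0 / spec.heart_rate_bpm
    horizon = spec.duration_s + 2 * rr_nominal

    def jittered() -> float:
        return rr_nominal * (1 + spec.rr_jitter * rng.uniform(-1, 1))

    rr: list[float] = []
    types: list[str] = []

    if spec.pathology in ("normal", "stemi"):
        while sum(rr) < horizon:
            rr.append(jittered())
            types.append("normal")

    elif spec.pathology == "pvc":
        n_expected = int(np.ceil(horizon / rr_nominal))
        # choose isolated PVC slots up front; at least one per record
        n_pvc = max(1, int(round(spec.pvc_fraction * n_expected)))
        slots: list[int] = []
        candidates = list(range(1, n_expected - 1))
        rng.shuffle(candidates)
        for c in candidates:
            if len(slots) == n_pvc:
                break
            if all(abs(c - s) > 1 for s in slots):
                slots.append(c)
        i = 0
        while sum(rr) < horizon:
            if i in slots:
                rr.append(spec.pvc_coupling * rr_nominal)     # premature
                types.append("pvc")
                rr.append((2 - spec.pvc_coupling) * rr_nominal)  # compensatory
                types.append("normal")
                i += 2
            else:
                rr.append(jittered())
                types.append("normal")
                i += 1

    elif spec.pathology == "bigeminy":
        while sum(rr) < horizon:
            rr.append((2 - spec.pvc_coupling) * rr_nominal)   # pause before normal
            types.append("normal")
            rr.append(spec.pvc_coupling * rr_nominal)         # premature couplet
            types.append("pvc")

    else:  # afib
        sigma = np.sqrt(np.log(1 + spec.afib_rr_cv**2))
        mu = np.log(rr_nominal) - sigma**2 / 2
        while sum(rr) < horizon:
            rr.append(float(rng.lognormal(mu, sigma)))
            types.append("normal")

    return RhythmModel(rr_intervals_s=np.array(rr), beat_types=types)


def _gauss(t: np.ndarray, wave: _Wave) -> np.ndarray:
    return wave.amplitude_mv * np.exp(-0.5 * ((t - wave.center_s) / wave.width_s) ** 2)


def render_dipole(
    rhythm: RhythmModel, template: BeatTemplate, spec: SyntheticECGSpec
) -> np.ndarray:
    """Render the scalar cardiac source (mV) on the spec's time grid.

    Beats are placed at the rhythm's cumulative onsets; PVC beats use the
    wide-QRS no-P variant. For STEMI the template's ST offset (default set
    from ``spec.st_elevation_mv``) is added as a flat shift between the S
    and T waves of every beat. For AFib the P wave is dropped everywhere and
    band-limited 4–9 Hz fibrillatory noise (sd 0.05 mV) replaces it.
    Measurement noise of ``noise_sd_mv`` is added last.
    """
    n = int(round(spec.duration_s * spec.sample_rate_hz))
    t = np.arange(n) / spec.sample_rate_hz
    x = np.zeros(n)

    tmpl = template
    if spec.pathology == "stemi" and tmpl.st_offset_mv == 0:
        tmpl = replace(tmpl, st_offset_mv=spec.st_elevation_mv)
    drop_p = spec.pathology == "afib"

    pvc_tmpl = tmpl.pvc_variant()
    for onset, btype in zip(rhythm.onsets_s, rhythm.beat_types):
        b = pvc_tmpl if btype == "pvc" else tmpl
        tb = t - onset
        # skip beats entirely outside the record (±1 s template support)
        if onset < -1 or onset > spec.duration_s + 1:
            continue
        for w in (b.p, b.q, b.r, b.s, b.t):
            if w.amplitude_mv != 0 and not (drop_p and w is b.p):
                x += _gauss(tb, w)
        if b.st_offset_mv != 0 and btype != "pvc":
            lo, hi = b.st_window_s
            x += b.st_offset_mv * ((tb >= lo) & (tb <= hi))

    if drop_p:
        rng = _rng(spec, 2)
        white = rng.standard_normal(n)
        sos = butter(4, [4.0, 9.0], btype="bandpass", fs=spec.sample_rate_hz,
                     output="sos")
        fib = sosfiltfilt(sos, white)
        sd = fib.std()
        if sd > 0:
            x += 0.05 * fib / sd

    if spec.noise_sd_mv > 0:
        x += spec.noise_sd_mv * _rng(spec, 3).standard_normal(n)
    return x


def project_leads(dipole: np.ndarray, spec: SyntheticECGSpec) -> ECGRecord:
    """Project the scalar source onto the six frontal leads:
    lead_i(t) = dipole(t) * cos(angle_i - axis). Every lead is therefore an
    exact scalar multiple of the source."""
    angles = np.radians(np.asarray(spec.lead_angles_deg) - spec.axis_deg)
    volt = np.outer(np.asarray(dipole, dtype=float), np.cos(angles))
    return ECGRecord(
        sample_rate_hz=spec.sample_rate_hz,
        lead_names=list(FRONTAL_LEADS),
        voltages=volt,
    )


def generate(spec: SyntheticECGSpec) -> ECGRecord:
    """Rhythm → dipole → lead projection; reproducible for a given seed."""
    rhythm = make_rhythm(spec)
    dipole = render_dipole(rhythm, spec.template, spec)
    return project_leads(dipole, spec)
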