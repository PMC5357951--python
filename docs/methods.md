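# Methods

## Sonification model

The sonifier is a bank of per-channel time-variant oscillators driven by the
normalized lead voltage *v(t)* ∈ [−1, 1]:

    output_i(t) = w_i · g(v_i(t)) · [ sin φ_i(t) + Σ_k a_k sin(k·φ_i(t)) ]
    φ_i(n)      = φ_i(n−1) + 2π · f_i(v_i(n)) / rate,   φ_i(0) = 0
    f_i(v)      = f0_i · 2^(s·v/12)
    g(v)        = (1 + v) / 2

with defaults f0 = (146.83, 174.61, 220.00, 293.67, 349.23, 440.00) Hz (the
D-minor triad over two octaves, one pitch per lead in ascending order),
harmonic multipliers k = (3, 4, 5) at relative amplitudes a = (0.15, 0.05,
0.05), pitch-modulation depth s = 0.5 semitones, loudness weights w a linear
ramp from 1.00 to 0.30 across channels, audio rate 44.1 kHz.

Design choices where the mapping was genuinely open:

* **Voltage → amplitude transfer.** g(v) = (1+v)/2 on the max-abs-normalized
  voltage: the isoelectric baseline is audible at half gain, so the result
  is a continuous six-note stream rather than isolated blips; full negative
  deflection is silent. Normalization scope is per channel over the whole
  record — a fixed mV scale would mute low-amplitude leads entirely, and a
  global scale would let one dominant lead drown the rest.
* **Pitch law exponential in semitones** rather than linear in Hz. "Half a
  semitone" and "3 %" coincide to within 0.05 % at this depth; the semitone
  reading is exact on the musical-pitch axis and symmetric in log frequency.
* **Harmonics phase-locked** at k·φ(t) and sharing the channel's gain
  envelope, preserving a single coherent timbre per channel under
  modulation.
* **Headroom.** The defined waveform sin φ + Σ a_k sin kφ can transiently
  exceed 1, so each channel is scaled by 1/(1+Σa_k); this cancels in every
  ratio measurement and in the mix normalization, and keeps single-channel
  renderings within [−1, 1].
* **Phase starts at 0** for every channel: determinism matters, relative
  phase of steady tones is perceptually irrelevant.
* **Mixing**: sample-wise sum, peak-normalized to 0.9, 5 ms raised-cosine
  fades at both ends against onset clicks. Control signals are linearly
  interpolated from the ECG rate (257 Hz) to audio rate; at these rates
  linear interpolation tracks the envelope far above perceptual needs and
  cannot overshoot.
* **Lead-to-pitch assignment** defaults to record order I, II, III, aVR,
  aVL, aVF on ascending pitch. Other orderings (e.g. by Cabrera angle) are a
  matter of passing a different `--leads` order or fundamentals list; the
  default is a convention, not a claim.
* **No preprocessing**: no baseline-wander or mains-hum filtering is applied
  before mapping; what is in the record is what sounds.

## Synthetic ECG generator

The generator emulates the *study conditions*: six frontal-plane leads,
10-second segments at 257 Hz, five classes. It is a deliberately minimal
physiological model:

* **Morphology**: each beat is five Gaussians (P, Q, R, S, T) placed
  relative to the R peak (defaults: centers −0.20, −0.035, 0, 0.035, 0.30 s;
  widths 25, 10, 12, 10, 60 ms; amplitudes 0.15, −0.10, 1.00, −0.20,
  0.30 mV — textbook shapes at 75 bpm). STEMI adds a flat +0.3 mV shift on
  the ST window between the S and T cores. PVC beats widen the QRS ×3,
  scale it ×1.5 and drop the P wave.
* **Rhythm**: normal/STEMI use RR = 60/HR with ≤2 % uniform jitter; PVC
  inserts isolated premature beats (10 % of beats, ≥1 per record) at a
  0.6·RR coupling interval with a full compensatory pause (coupling + pause
  = 2·RR exactly); bigeminy strictly alternates the same couplet; atrial
  fibrillation draws RR i.i.d. log-normal with mean 60/HR and CV 0.25 and
  replaces P waves with 4–9 Hz band-limited noise (sd 0.05 mV).
* **Leads**: a single scalar source projected as cos(lead angle − axis)
  onto the Cabrera-circle directions (I=0°, II=60°, III=120°, aVR=−150°,
  aVL=−30°, aVF=90°; axis 60°), so every lead is an exact scalar multiple
  of the source and closed-form amplitude ratios are testable.
* **Noise**: additive white Gaussian, sd 0.02 mV by default.
* **Randomness**: one seeded generator per call, split by stage; equal
  specs give bit-identical records.

What this model does *not* capture: vectorcardiographic loop rotation (all
leads share one waveform up to scale), heart-rate-variability spectra,
restitution, electrode artifacts, and the morphology diversity of real
database records. Tests passing on these fixtures demonstrate that the
pipeline is correct and the class signatures are separable — not that real
pathological ECGs are equally separable by ear.

## Spectral validation

Peaks are measured on Hann-windowed rFFTs; the peak bin is refined by a
parabolic fit to the log magnitude of three bins, and the amplitude is then
re-measured by direct complex projection at the interpolated frequency,
which is exact for a windowed sinusoid (the parabolic amplitude estimate
alone biases ratios by ~1 %). Magnitudes are linear amplitude (the
percentage targets are linear fractions, not dB). Bands: ±3 % around each
harmonic for ratios, ±6 % around the fundamental for pitch tracks. Silence
returns an explicit "no peak" (None / NaN frames) rather than raising.
Measurement budgets used by the tests: ≤0.1 Hz frequency error on 10 s
windows, ≤0.01 absolute error on harmonic ratios.

## Study statistics

Accuracy is correct/total per observer; group summaries are mean ± sample
SD (n−1), reported in percent. "Student's t-test" is implemented as the
classic pooled-variance two-sample test (df = nA+nB−2) with a one-tailed
p for mean(A) > mean(B); Welch's form is available behind a flag. A
summary-statistic variant accepts published (n, mean, SD) triples. Zero
pooled variance pins p to 0/1/0.5 by the sign of the mean difference and
flags the result as degenerate. "Above threshold" uses strict inequality:
with 12 samples, over 90 % means ≥11 correct. Display rounding is integer
percent; all computation runs on fractions.

## Problem sizes and numerical choices

Tests and the acceptance script render 1–10 s of audio at 44.1 kHz and
generate 10 s records at 257 Hz — the natural scale of this method, where
every spectral check resolves well under 0.1 Hz. The vectorized renderer is
checked against a per-sample Python re-synthesis of the identical phase
recursion to 1e-9. WFDB storage quantizes at 1000 ADC units/mV (0.5 µV
round-trip error bound); CSV storage round-trips exactly at 17 significant
digits.

## Known limitations

* The WFDB support is a minimal subset (single signal file, format 16,
  explicit physical units); annotation files and multi-segment records are
  out of scope.
* No real-time or streaming synthesis; records are rendered whole.
* The amplitude transfer and normalization scope are design choices — other
  mappings (raw-mV scaling, compressive transfers) would change loudness
  relations between leads and are not explored here.
* Human classification performance cannot be reproduced computationally;
  the study module scores response sheets but does not model listeners.
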