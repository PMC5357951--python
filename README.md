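# ecgsonify

Polyphonic parameter-mapping sonification of six-lead ECG signals — a
toolkit for turning the frontal-plane leads of an electrocardiogram (I, II,
III, aVR, aVL, aVF) into sound, so that clinically relevant rhythm and
morphology abnormalities (ST elevation, premature ventricular contractions,
bigeminy, atrial fibrillation) become audible patterns. It is aimed at
auditory-display researchers and at anyone who wants to build or evaluate
listening studies on sonified ECGs without access to clinical recordings.

## The method

Each lead drives one time-variant oscillator. With *v(t)* the lead voltage
normalized to [−1, 1]:

* **Pitch.** Each channel gets a fixed fundamental from the D-minor scale
  over two octaves — 146.83, 174.61, 220.00, 293.67, 349.23, 440.00 Hz —
  and the voltage continuously bends it by up to half a semitone:
  *f(t) = f₀ · 2^(s·v(t)/12)* with *s* = 0.5, i.e. ≈ ±3 % at full scale.
* **Loudness.** The voltage controls the amplitude, *g(v) = (1+v)/2*: the
  isoelectric baseline sounds at half gain (a continuous stream of six
  notes), full negative deflection is silent.
* **Timbre.** Harmonics *k* = 3, 4, 5 are added at 15 %, 5 % and 5 % of the
  fundamental's amplitude, phase-locked at *k·φ(t)*. The 2nd harmonic is
  deliberately omitted: channels 4–6 are octave shifts of channels 1–3, and
  an octave harmonic would blur which channel is sounding.
* **Balance.** Per-channel gains fall linearly from 100 % (lowest pitch) to
  30 % (highest pitch) as a rough loudness compensation.

The oscillator phase accumulates sample by sample
(*φₙ = φₙ₋₁ + 2π·f(vₙ)/rate*), so pitch changes never click. Channels are
summed, peak-normalized and faded at the edges.

The package also contains:

* `ecgsonify.synthetic` — a seeded generator of six-lead records (10 s at
  257 Hz by default) for five classes: normal, STEMI, PVC, bigeminy and
  atrial fibrillation, built from a Gaussian P-Q-R-S-T beat template, a
  per-class RR-interval rhythm model, and a cosine projection of a scalar
  cardiac source onto the Cabrera-circle lead directions;
* `ecgsonify.spectral` — spectral peaks, harmonic amplitude ratios and
  pitch tracks for validating rendered audio;
* `ecgsonify.study` — scoring for blinded four-class listening studies:
  per-observer accuracy, group mean ± SD, confusion matrices, the share of
  observers above an accuracy threshold, and one-tailed two-sample
  Student/Welch t-tests (also from published summary statistics).

## Worked example

Generate a synthetic bigeminy record, sonify it, and verify the rendering:

```sh
$ ecgsonify synth --pathology bigeminy --seed 7 --out bigeminy.csv
bigeminy.csv
$ ecgsonify sonify bigeminy.csv --out bigeminy.wav
INFO lead I -> 146.83 Hz
INFO lead II -> 174.61 Hz
INFO lead III -> 220.00 Hz
INFO lead aVR -> 293.67 Hz
INFO lead aVL -> 349.23 Hz
INFO lead aVF -> 440.00 Hz
INFO wrote bigeminy.wav: 10.00 s at 44100 Hz
bigeminy.wav
$ ecgsonify validate bigeminy.csv
lead    f0_hz   peak_hz h3_ratio        h4_ratio        h5_ratio
I       146.83  146.83  0.1500  0.0500  0.0500
II      174.61  174.61  0.1500  0.0500  0.0500
III     220.00  220.00  0.1500  0.0500  0.0500
aVR     293.67  293.67  0.1500  0.0500  0.0500
aVL     349.23  349.23  0.1500  0.0500  0.0500
aVF     440.00  440.00  0.1500  0.0500  0.0500
```

The CSV holds 2570 rows (10 s × 257 Hz) of six-lead voltages; the WAV is
the 10-second polyphonic mix. The `validate` report renders each channel
separately with a zero control signal and measures it: the spectral peak
recovers each configured fundamental, and the harmonic amplitude ratios
recover the configured 15 %/5 %/5 % timbre. In the WAV itself you hear six
simultaneous notes whose loudness pulses with each beat; in bigeminy every
other pulse arrives early, giving the characteristic long-short gallop.

Response sheets from a listening study (CSV with columns `observer_id,
group, sample_id, true_class, assigned_class`) are scored with
`ecgsonify eval responses.csv`, which prints per-observer accuracies, group
summaries, the 4×4 confusion matrix and the fraction of observers above
90 % accuracy.

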