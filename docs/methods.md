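# Methods

## Signal model and assumptions

The detector treats one ECG lead at a time as a uniformly sampled sequence
in mV. It assumes QRS complexes are the highest-slope events in the record,
with most of their spectral energy between roughly 5 and 16 Hz, while the
main contaminants live elsewhere: baseline wander well below 1 Hz,
powerline interference at 48–60 Hz, muscle (EMG) noise concentrated at
38–45 Hz, plus broadband white noise. P and T waves overlap the low end of
the QRS band but are smoother and lower-amplitude. No assumption is made
about QRS polarity or absolute amplitude: the normalization step and the
evenness of the Shannon transform make the pipeline exactly invariant to
positive rescaling and insensitive to sign.

All processing is batch (whole record at once). Zero-phase filtering is
inherently non-causal, so the detector is not a streaming algorithm.

## Pipeline parameters

| parameter | default | units | role |
|---|---|---|---|
| `band_low`, `band_high` | 5, 16 | Hz | Butterworth passband corners |
| `filter_order` | 2 | — | design order of the prototype (squared by the forward–backward pass) |
| `L` | 0.10 | s (float) or samples (int) | boxcar length of each envelope pass |
| `kappa` | 0.5 | — | threshold scale |
| `refractory_s` | 0.250 | s | minimum inter-beat spacing (240 bpm ceiling) |
| `search_window_s` | 0.100 | s | half-width of the R localization window |
| `match_tolerance_s` | 0.150 | s | beat-matching tolerance for evaluation |
| `log_base` | e | — | Shannon-energy logarithm base (pure rescale) |

Rationale for the values that are genuinely free:

* **`L` = 100 ms at 1 kHz** spans a full QRS complex, so the several energy
  spikes inside one QRS merge into a single envelope lobe, while beats at
  physiological spacing (≥ 250 ms) remain separate lobes.
* **`kappa` = 0.5** was fixed by a grid search over the synthetic scenario
  suite at its default noise amplitudes, maximizing beat-level F1; the
  optimum is a broad plateau (any value in roughly 0.3–1.5 gives identical
  results on the suite), so the choice is not delicate. On the z-scored
  envelope the operative branch is `κ·σ·(1 − μ²) ≈ κ·σ`, i.e. the threshold
  is a noise-floor multiple.
* **Refractory 250 ms.** Besides suppressing double detections, the
  refractory comparison is the mechanism that rejects tall T waves: a T
  lobe peaks ~200 ms after its R lobe and is always the smaller of the
  pair, so it is pruned whenever the interval covers it. A 200 ms value —
  the other common convention — fails exactly at the typical 200 ms R–T
  spacing regardless of the threshold (the T lobe then survives as a false
  positive on sharp 0.8×R T waves), which is why the default here is
  250 ms. It remains configurable for genuinely fast rhythms.
* **±100 ms search window** is half the minimum beat spacing, so windows of
  neighbouring beats cannot both contain the same extremum.
* **±150 ms matching tolerance** follows the ANSI/AAMI EC57 convention.

## Thresholding and localization details

The threshold statistics μ and σ are computed over the final smoothed
envelope `m2` — the same signal whose local maxima are being gated — so
threshold and candidate heights share units. One global threshold is used
per lead; windowed re-estimation is deliberately not implemented.

R localization takes the argmax of the *absolute* filtered signal within
the window, so negative-polarity QRS localizes identically to positive.
After localization the refractory rule is re-applied to the refined
indices, guaranteeing the output spacing invariant even when two lobes
refine toward each other.

## Numerical choices

* The normalization denominator is `max|f|` (not the signed maximum), so
  `a² ∈ [0, 1]` and the Shannon energy is non-negative by construction.
* `0·log 0 := 0` is implemented by masking zero samples, not by adding an
  epsilon; this keeps `s(|a|=1) = 0` exact and the transform exactly even.
* Standardization uses the population (1/N) standard deviation; the choice
  is pinned by tests so it cannot drift silently.
* The envelope's group delay `L − 1` is compensated by an integer left
  shift with zero tail padding. The first boxcar pass is causal with zero
  initial state, so the first `2L` samples of the envelope are a startup
  transient; records must be longer than `2L`.
* Band-pass edge effects are handled by even-reflection padding inside the
  forward–backward pass; signals shorter than the padding requirement are
  rejected rather than silently filtered.
* Flat-topped envelope maxima resolve to the leftmost plateau sample;
  matching ties resolve to the earlier reference, then earlier detection.
  Both tie-breaks are deterministic so identical inputs give bit-identical
  outputs.
* Percentages are kept at full precision internally and rendered
  round-half-even to 3 decimals only in reports.

## Beat matching

Matching is one-to-one greedy nearest-first within the tolerance. When
consecutive reference beats are more than twice the tolerance apart — the
physiological regime for the default 150 ms tolerance — each detection can
match at most one reference, the match graph decomposes into independent
stars, and the greedy pairing is provably of maximum cardinality; the test
suite verifies equality with an optimal-assignment oracle on random
instances of up to 10 beats in that regime. With beats closer than twice
the tolerance the greedy result can in principle differ from the optimum;
such rhythms also violate the detector's refractory assumption.

## Synthetic generator

Each beat is the sum of five Gaussian bumps at fixed offsets from the R
center (amplitude mV, offset s, FWHM s): P (0.15, −0.200, 0.060),
Q (−0.10, −0.025, 0.025), R (1.00, 0, 0.030), S (−0.20, +0.025, 0.025),
T (0.30, +0.200, 0.080). R–R intervals are drawn from a normal with
configurable fractional jitter (default 2%), truncated at 250 ms. Noise
classes: a slow sinusoid for baseline wander (default 0.3 mV at 0.3 Hz), a
sinusoid in the 48–60 Hz band for line pickup (0.05 mV at 50 Hz), white
noise band-passed to 38–45 Hz for EMG (0.05 mV RMS), and broadband white
noise. All randomness flows from one seed through a single generator.

The eight named scenarios (clean, the three single-noise cases, tall-T at
0.8×R, negative QRS, irregular rhythm at 15% jitter, low-SNR composite)
are 60-second records at 60 bpm and 1 kHz — about 60 beats each. That
desk-scale corpus keeps the full test suite and the acceptance script in
the tens of seconds while still exercising every failure mode the detector
addresses.

What the generator does **not** emulate: beat-to-beat morphology
variability, pathological morphologies (bundle-branch block, atrial
fibrillation, ectopy), electrode motion artefacts with QRS-like slopes,
harmonic stacks of line interference, or the vectorial relationship
between leads (each synthetic record is one independent lead). Perfect
scores on the suite therefore show the pipeline is implemented correctly
and robust to the modelled contaminants — not that it attains any
particular performance on clinical recordings.

## Known limitations

* Single global threshold per lead: very large within-record amplitude
  shifts (e.g. intermittent lead detachment) would need the windowed
  re-estimation that is deliberately out of scope here.
* The WFDB reader supports format 16 single-`.dat` records (the PTB
  layout) only, and reads no binary annotation files.
* Extremely short records (under twice the envelope window plus filter
  padding, ~0.25 s at 1 kHz) are rejected rather than processed.
* DER is undefined at TP = 0 and reported as infinity.
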