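# Methods

This note documents the models, the numerical conventions, the synthetic
data generator and the design decisions behind `snorescreen`, in the
order the pipeline runs.

## Preprocessing

All audio is reduced to mono 16 kHz on read (channel mean, band-limited
polyphase resampling). The short-time chain is:

1. **Pre-emphasis** `y[n] = x[n] − α·x[n−1]` with α = 0.97, the common
   speech value (the first-order high-pass compensates the spectral
   tilt of voiced sound before spectral analysis).
2. **Framing** at 0.03 s length / 0.01 s shift (480 / 160 samples). The
   incomplete trailing frame is dropped:
   `n_frames = floor((n − 480)/160) + 1`, which yields exactly 298
   frames for a 3 s clip — the row count of every feature matrix. With
   padding conventions the count would differ, so dropping is load-bearing.
3. **Hamming window** `w[n] = 0.54 − 0.46·cos(2πn/(N−1))`.
4. **Power spectrum**: frames zero-padded to `n_fft = 512` (smallest
   power of two ≥ 480), squared-magnitude rFFT, 257 bins retained.

## Feature extractors

All three extractors produce `298 × 40` matrices with coefficients
indexed `n = 1..40`; the constant (n = 0) term is excluded, which makes
the features invariant to overall gain.

**MFCC.** Mel filterbank of M = 40 unit-peak triangles, centers equally
spaced on `mel(f) = 2595·log10(1 + f/700)` between 0 and 8000 Hz;
natural-log band energies floored at 1e−10 (the log is otherwise
undefined for silent bands); cosine transform
`C(n) = Σ_m s(m)·cos(πn(m+0.5)/M)`. Choosing M = L = 40 is the only
pair consistent with a non-degenerate cosine transform and the 40-wide
feature matrix. With L = M the last row of the transform is identically
zero (cos(π(m+½)) = 0); it is kept for shape consistency and carries no
information.

**LPCC.** Per frame, an order-12 all-pole model is fitted by the
autocorrelation method (Levinson–Durbin), which guarantees a stable,
minimum-phase filter; order 12 is the standard choice at 16 kHz. The
cepstrum follows the recursion `c(1) = a(1)`;
`c(n) = a(n) + Σ_{k<n}(1−k/n)·a_k·c(n−k)` for `n ≤ p`; the same sum
without the `a(n)` term for `n > p` (coefficients 13..40 come from this
branch). All-zero frames have no model and map to all-zero rows.

**LPMFCC.** The LPC coefficient vector `a_1..a_p` itself is zero-padded
to 512 points and Fourier-transformed; its squared magnitude is passed
through the same mel filterbank, log and cosine transform as MFCC. This
reading — transforming the coefficients, not the model's frequency
response `G/A(e^{jω})` — is taken literally; it also gives the sensible
degenerate behaviour that an all-zero coefficient vector produces a flat
zero spectrum and (after the floor) zero coefficients.

## Segmentation

Snore episodes are found by a dual-threshold detector on per-frame
energy and zero-crossing rate:

- noise floor = 10th percentile of frame energies (percentile rather
  than leading frames, since a recording may start mid-snore);
- candidate regions where energy > 8 × floor;
- regions grow outward while energy > 2 × floor **or** ZCR exceeds the
  median frame ZCR by 40 crossings. The ZCR test is relative to the
  median because broadband background noise crosses zero hundreds of
  times per 480-sample frame; an absolute threshold in that regime
  extends every region until the whole recording merges into one event;
- regions closer than 0.2 s merge; regions shorter than 0.3 s drop.

Each event becomes one 3 s clip centred on its peak-energy frame
(symmetric context helps the spectral features more than onset
alignment), shifted inward at the recording edges so clips always
contain real audio.

## Classifiers

Implemented directly in numpy (im2col convolution, backpropagation
through time, Adam); analytic gradients are verified against central
finite differences in the test suite.

| architecture | structure |
| --- | --- |
| `cnn3` | conv 20×8/64/s2 → 10×4/64/s2 → 5×2/64/s1, each + ReLU + 2×2 max-pool |
| `cnn5` | `cnn3` + two 2×2/64/s1 blocks |
| `lstm` | 1 recurrent layer, one step per frame (298 steps of 40-dim input) |

Both CNNs use "same" spatial padding and ceil-mode pooling — without
ceil pooling the fifth block's input would collapse to zero height on a
298 × 40 input. A single fully connected layer maps the flattened conv
output (or the final LSTM hidden state) to two logits; softmax +
cross-entropy is the training objective.

The LSTM cell is the standard gate form (forget/input/output gates and
a tanh candidate state). Two initialisation details matter:

- hidden size defaults to 128;
- the forget-gate bias is initialised at **3.0**. With the final-state
  readout, evidence from a burst ending ~70 frames before the sequence
  end must survive to step 298; at the conventional bias of 1.0 the
  initial per-step retention σ(1) ≈ 0.73 decays that evidence by ~1e−9
  and training degenerates into memorising per-clip noise (perfect
  training accuracy, chance validation accuracy). At σ(3) ≈ 0.95 the
  gradient path stays open and training converges in a few epochs.

Training: Adam (lr 1e−3, β = 0.9/0.999), batch 32, 10 epochs, gradient
clipping at global norm 5, 10 % validation split; these sizes hold the
full benchmark run to about a minute on one CPU. Inputs are
standardised per coefficient with training-split statistics stored in
the model and re-applied at inference. A fixed `TrainConfig.seed`
reproduces initialisation, shuffling and therefore the final weights.

## Screening arithmetic

- confusion-matrix metrics: accuracy, precision, sensitivity,
  specificity = TN/(TN+FP), F1. A metric whose denominator is zero is
  reported as *missing* (None), never silently as 0. (Definitions that
  divide specificity by TP+FP circulate as a transcription error; the
  conventional form is used.)
- `AHI = (AB/2)/SH`: AB abnormal-labelled clips, SH hours of sleep
  (recording duration when not supplied). The divisor 2 encodes the
  two-abnormal-snores-per-event assumption and is an exposed constant.
- severity: degree 0 (normal) for AHI ≤ 5, 1 (slight) ≤ 15,
  2 (moderate) ≤ 30, 3 (serious) above; boundaries belong to the lower
  grade.
- `ahi_discrepancy` returns the quarter-scaled difference |Δ|/4 used in
  published subject comparisons alongside the plain absolute
  difference; the plain difference is the recommended quantity for new
  work.

## Synthetic data

The generator produces the two inputs the pipeline needs — labelled 3 s
clips and whole sessions — as pure functions of their seeds.

A snore is a harmonic series at fundamental f0 with a −12 dB/octave
roll-off, gated by a raised-cosine envelope; a gasp is a broadband
noise burst (sharp attack, slow decay) mixed with jittered harmonics.
Class parameters:

| kind | f0 (Hz) | peak amplitude | burst length (s) |
| --- | --- | --- | --- |
| normal | U(90, 140) | U(0.4, 0.7) | U(1.2, 2.2) |
| faint (in-apnea) | U(60, 100) | U(0.05, 0.15) | U(1.2, 1.8) |
| gasp (post-apnea) | U(70, 120) | U(0.8, 1.0) | U(1.0, 1.5) |

Background noise RMS is 0.003 everywhere. A generated clip is one burst
approximately centred in the 3 s window — the same thing endpoint
detection extracts from a long recording — so models trained on
`gen_clip_dataset` transfer to session screening by construction.
Because coefficients n ≥ 1 are gain-invariant, class amplitude reaches
the features only through each burst's signal-to-noise ratio (how far
its harmonics stay above the noise floor), alongside the overlapping f0
ranges; the classes are separable but not trivially so.

Sessions: background noise; normal snores at 4/min outside events;
apnea events of 9–11 s at the requested events/hour rate
(exponential gaps with a 30 s hard minimum; rates above 120/h are
infeasible and rejected). Each event is a quiet interval with one faint
snore at its middle and one gasp 0.5–1 s after its end — exactly two
abnormal snores, matching the AHI divisor. The generator returns exact
annotations and the planted AHI, so screening can be validated with an
oracle classifier that reads the planted labels: any AHI deviation then
isolates segmentation or bookkeeping errors from model errors.

What the generator does **not** model: real upper-airway acoustics,
inter-subject variability, room reverberation, bed-partner noise,
position-dependent snore changes, hypopneas (events with reduced rather
than absent airflow). Passing the synthetic benchmark therefore
demonstrates that the pipeline is internally correct and learnable, not
that it reaches the same accuracy on clinical recordings.

## Numerical and degenerate-input conventions

- log floor 1e−10 on all filterbank energies: every feature is finite
  for every finite input;
- all-zero frames: LPCC rows are zero; LPMFCC rows go through the
  flat-zero-spectrum path (≈ 0 after the cosine transform); MFCC rows
  hit the floor in every band and are ≈ 0 for n ≥ 1;
- Levinson–Durbin clamps a numerically non-positive prediction-error
  update to the smallest positive float rather than failing;
- zeros count as positive for zero-crossing purposes;
- `preemphasize` accepts α = 1.0 (exact differencing) even though
  operational use stays in [0, 1);
- severity boundaries are closed below (AHI = 5 is degree 0).

## Problem sizes used in the shipped checks

The packaged benchmark trains on 1600 clips (80 % of 1000 per class)
for 10 epochs and evaluates on the held-out 400; session validation
screens one generated hour at 20 events/hour. These sizes were chosen
so a complete run stays around two minutes on a single CPU while still
exercising every stage at full feature resolution (298 × 40, 298-step
recurrence).

## Known limitations

- The CNNs are functional and tested for gradient correctness and
  small-scale learning, but the shipped benchmark is the MFCC + LSTM
  combination; no claim is made about CNN-vs-LSTM ranking beyond the
  synthetic setting.
- Sleep time is taken as recording duration unless the caller supplies
  it; no sleep/wake detection is attempted.
- The detector's thresholds assume a roughly stationary noise floor; a
  recording with large slow noise-level drift would need the
  percentile floor computed per segment.
- Obstructive, central and mixed apneas are indistinguishable from
  audio alone; no hypopnea-specific handling exists.
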