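# Methods

## Signal model and assumptions

The luminosity trace of a skin ROI is modelled as

    x[t] = B + A · g(φ(t)) + d(t) + ε[t]

with base intensity `B` (8-bit units), pulse amplitude `A`, a periodic beat
shape `g` evaluated at the accumulated cardiac phase
`φ(t) = ∫ HR(τ)/60 dτ`, a slow illumination drift `d`, and white sensor
noise `ε`. The method assumes the subject's face is static within the ROI
(no tracking is performed; ROIs are fixed rectangles), that the pulse rate
stays within 50–190 BPM, and that the frame rate (nominally 15 fps)
exceeds twice the highest pulse frequency. Motion, occlusion and specular
reflections are out of scope.

ROI means are computed in floating point on the 8-bit values: the pulse
amplitude (order 1–2 intensity units) is far below one quantization step,
and only survives averaging over many pixels.

## Filtering and transient handling

The bandpass is a second-order Butterworth with cutoffs 50 and 190 BPM
(0.83 and 3.17 Hz), applied forward–backward (`sosfiltfilt`) so that beat
timing is not phase-shifted — peak-interval statistics would otherwise be
biased. Transients are handled by discarding the first 1 s of the raw
trace before filtering and excluding the next 3 s of filtered output from
every downstream estimate; all estimates therefore start 4 s into a
recording.

## HR estimation

Each HR value is the in-band maximum of the FFT magnitude of a 10 s
window, advanced every 0.5 s. A raw 10 s window at 15 fps has 0.1 Hz
(6 BPM) bins; the window is therefore zero-padded to a grid of ≤ 1 BPM and
the peak refined by quadratic interpolation over the three bins around the
maximum, giving sub-BPM effective resolution. The window is de-meaned
before transforming to avoid DC leakage.

Two estimator details matter in practice:

* **Subharmonic guard.** Near the low cutoff the filter attenuates the
  pulse fundamental; for slow pulses (~55 BPM) the second harmonic of the
  beat waveform can then narrowly exceed the fundamental in finely
  resolved spectra. If an in-band line near half the peak frequency
  carries ≥ 40% of the peak magnitude, that line is taken as the
  fundamental. A pure tone has no subharmonic energy, so the guard cannot
  fire on single-tone inputs.
* **Adaptive beat separation.** Beats are local maxima with prominence
  ≥ 0.5 × the retained-span SD. The minimum peak separation defaults to
  0.6 × the beat period at the spectrally estimated rate: the dicrotic
  shoulder of the beat template sits ~0.3 period after the systolic peak,
  so a fixed separation tied to the band's fastest rate (60/190 s) admits
  it as a spurious beat at low heart rates, double-counting beats. The
  adaptive rule rejects the dicrotic bump at every rate and still cannot
  merge true beats (0.6 < 1 period). Passing `min_separation_s` restores a
  fixed rule.

The piecewise correction (−15 BPM below 76, none in 76–90, +15 above 90)
is exposed with two banding modes: by the raw estimate (default) or by a
contact-device reference when one is available. The band edges close the
published gaps as low < 76 ≤ mid ≤ 90 < high, the only exhaustive
partition consistent with the stated interior.

## Features and normalization

Each region contributes means and sample (n−1) standard deviations of the
sliding HR series, the beat amplitudes, and the inter-beat intervals
(seconds; a configuration switch to 1/distance in Hz is deliberately not
provided — callers can invert the column). The sample SD is used because
per-video series are short. Region order is fixed (forehead, right cheek,
left cheek).

Variables are mapped linearly onto [−1, 1] by per-variable (min, max)
settings (`SymmetricMinMaxScaler`); the settings are stored with every
trained model so outputs can be denormalized to BPM/mmHg. For the
feedforward model the settings are fitted on the training partition only,
preventing leakage into validation/test. For the NARX model they are
fitted on the full series: rows are assigned to stages by random division
of the lagged design matrix, so a "training-rows-only" min/max has no
clean series-level meaning, and the map is a fixed affine rescaling either
way. Constant variables raise an error rather than silently collapsing.

The 70/15/15 division assigns `round(0.15 n)` samples to each of
validation and test and the remainder to training — the only rounding rule
consistent with both 45 → 31/7/7 and 10 984 → 7688/1648/1648 — using a
seeded random permutation.

## Networks and training

Both models are two-layer perceptrons (tanh hidden layer, linear output)
trained by Levenberg–Marquardt: damped Gauss–Newton steps
`(JᵀJ + λI) δ = −Jᵀr` on the full analytic Jacobian, with the classic
multiplicative schedule (λ ×10 on a rejected step, ÷10 on acceptance,
initial λ = 10⁻³). Accepted steps strictly decrease training MSE. Training
stops after 6 consecutive epochs without validation improvement or at 1000
epochs, returning the weights of the best-validation epoch. Weights are
initialized from a seeded fan-in-scaled uniform distribution; with a fixed
seed, training and prediction are bit-reproducible.

The feedforward model is 18 → 10 → 3 (hidden width 10 chosen by a manual
neuron sweep over {3, 5, 7, 10}, exposed as `neuron_grid`). The NARX model
is series-parallel (open loop): the regressor for second `t` concatenates
the exogenous input rows at `t−1, t−2` with the *measured* target rows at
`t−1, t−2` (delays apply to both, the conventional NARX default), giving a
22-wide input to a 5-neuron hidden layer and 2 outputs. Only open-loop
one-step-ahead prediction is supported; closed-loop multistep forecasting
is out of scope. The first prediction is emitted at `t = delays` (2 s at
1 s cadence). Fit reports carry per-stage MSE and Pearson R on the
normalized scale (the scale the optimizer sees) plus the overall R after
denormalization, since the two conventions differ.

## Synthetic data

The generators exist to make every stage testable with known ground truth.

* **Beat template**: two Gaussians — systolic peak (phase 0.25, sd 0.06)
  and dicrotic shoulder at 40% amplitude (phase 0.55, sd 0.09) —
  zero-meaned over the period. Richer than a sinusoid (harmonics, an
  asymmetric shoulder) so that peak detection is exercised realistically.
* **Channel amplitudes** default to G:R:B = 2.0 : 1.0 : 0.6 intensity
  units, reflecting hemoglobin's preferential green absorption.
* **Scenario defaults**: 120 s at 15 fps, constant 72 BPM, noise SD 0.1,
  illumination drift 0.5 units at a 30 s period (below the passband).
* **Validation study**: 15 subjects × 3 states (rest, post-exercise,
  recovery; HR ordering enforced), 90 s recordings (within a 1.5–3 min
  protocol), one trace per region × channel, white-noise SD 1.0, three
  cuff-style HR/BP triplets (start/middle/end) and a 1 Hz finger-style HR
  series per recording. At noise 1.0 the green channel operates at high
  SNR (per-study mean R² ≈ 0.99 against reference on the default seed)
  while red (≈ 0.7) and blue (≈ 0.2) degrade — the regime in which channel
  comparison is informative. Blood pressure follows the documented linear
  links SP = 0.6·HR + 70, DP = 0.4·HR + 45 (+ noise, mmHg); these
  constants are arbitrary but fixed, existing only to make model recovery
  testable, not to model physiology.
* **Pulse videos** default to 120×160 frames with proportionally scaled
  ROIs (full 1080p geometry is configurable). A static per-pixel dither
  field (uniform in [−0.5, 0.5], emulating sensor fixed-pattern noise)
  lets ROI averaging recover sub-integer modulation after 8-bit
  quantization.
* **NARX benchmark**: a randomly weighted teacher network of the same
  topology iterated on smooth AR(1) exogenous drivers plus observation
  noise — a recoverable process inside the student's hypothesis class.

What the generators do *not* emulate: head motion, face tracking error,
codec compression, specular highlights, ambient-light flicker,
subject-to-subject skin-tone differences, and any true physiological
HR–BP coupling. Passing tests therefore demonstrate correctness of the
signal chain and trainers under the stated signal model, not clinical
accuracy on human recordings.

## Numerical choices

* FFT length: the next power of two above max(window length, fs/Δf) with
  Δf = 1/60 Hz.
* Quadratic peak interpolation clamps the vertex offset to ±0.5 bin and
  falls back to the bin center at grid edges or degenerate curvature.
* `dominant_hr` clamps results to the band and raises a no-signal error
  when the in-band maximum is below a floor (default 10⁻¹²).
* LM solves with λI regularization; a singular system raises λ rather
  than failing. λ is capped at 10¹⁰; exhaustion ends training (local
  minimum).
* Zero-variance predictions yield NaN correlations (with a warning path
  in the statistics module) rather than exceptions.
* Correlation matrices use pairwise-complete rows; constant columns warn
  and yield NaN entries. Benjamini–Hochberg adjustment is available but
  off by default (the per-pair α = 0.05 convention).
* Slope p-values use the t statistic with n−2 degrees of freedom.

## Problem sizes

Default test and reproduction sizes are desk-scale by design: 45–90 s
recordings at 15 fps, a 45-recording study, 500-sample regression sets,
and 2000 s NARX series — large enough for the statistical contracts
(sub-BPM HR recovery, R ≥ 0.95–0.99 function recovery) to be
discriminating, small enough to run anywhere.

## Known limitations

* Fixed rectangular ROIs; no face detection or tracking.
* The correction rule is a coarse three-band offset inherited from the
  field's practice; the neural models are the principled replacement.
* The NARX model is open-loop only; it cannot forecast beyond one step
  without measured feedback.
* Real-video containers require an imageio codec plugin; the native
  formats are lossless frame stacks (PNG directory, TIFF, NPY).
* The BP links in the synthetic data are linear in HR by construction, so
  BP-prediction results on synthetic data say nothing about cuffless BP
  accuracy in people.
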