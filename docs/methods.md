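# Methods

This note documents the models, the synthetic study conditions, the
numerical choices, and the limits of what the test suite demonstrates.

## Synthetic data

The generators define the study conditions for every benchmark in the
package.

**EEG.** Records are channels × samples matrices at 256 Hz, 8 s per
segment, 22 channels by default (an 18-channel option exists; 22 matches
the canonical 252-dim feature contract).  Background (label 0) is pink
(1/f-amplitude) noise at 10 µV RMS per channel plus a low-amplitude 10 Hz
alpha component with per-channel phase — a spectral tilt realistic enough
for Welch-based features.  Seizure segments (label 1) add a rhythmic
oscillation with fundamental drawn uniformly from 3–7 Hz, second and third
harmonics at 0.4 and 0.2 relative amplitude, and a 0.5 s onset envelope
whose start is uniform in the first half of the segment, so the burst
covers at least half the record; its amplitude is ≥ 3× the background RMS.
The default cohort is 24 subjects, every subject contributing both
classes, so subject-independent splits are always well defined.  Datasets
serialize as `signal_samples.npy` / `is_sz.npy` plus a JSON sidecar.

**Brain phantoms.** Smooth ellipsoidal foregrounds (logistic edge, mild
sinusoidal texture) scaled to [0, 0.75], with an optional Gaussian
lesion blob (amplitude 0.3, width 0.12–0.2 in normalized coordinates)
whose support mask is recorded; intensities are clipped to [0, 1].  The
phantom cohort defaults to 52 subjects.  Phantoms are 32×32 in the
benchmarks — large enough for a 2-level descriptor pyramid and the 2-stage
embedder, small enough for single-CPU runs.

**Noise.** Gaussian (additive i.i.d.), impulse (salt-and-pepper at the
data range extremes, the classic motivation for median filtering), or
both.  Benchmark defaults: EEG sd 5 µV + 2 % impulses; images sd 0.08 +
3–5 % impulses.  These levels leave the classes separable after denoising
but visibly corrupt the raw data (raw-signal SNR ≈ 3 dB).

**What passing tests do not show.** The generator makes no claim of
physiological fidelity: no inter-channel propagation, no artifacts with
EEG-like morphology (blinks, EMG), no hemodynamics.  Perfect benchmark
accuracy means the pipeline recovers a constructed contrast through noise,
preprocessing and subject-disjoint evaluation — not that it would reach
such numbers on clinical recordings.

## Denoising

Both filters use symmetric (edge-duplicating) boundary padding; the
choice is arbitrary but applied consistently, and the naive oracles in the
tests use the same convention.

**G-MF.**  Stage 1 smooths each point with a truncated Gaussian kernel on
[-N, N] whose width is `sigma_i = max(phi * var_i, sigma_min)`; the local
variance is computed over the same 2N+1 window as the filter.  The kernel
is renormalized to sum 1 so constants pass unchanged.  Assigning a
variance directly to a kernel width is the filter's defining (if unusual)
choice; `sigma_from_sd=True` switches to `phi * sqrt(var_i)` for users who
prefer dimensional consistency.  Stage 2 is a 2N+1 median.  Defaults
N=3, phi=0.5, sigma_min=0.25 (samples).

**AW-WF.**  The Wiener gain `(s2 - v2)/s2` is clamped to [0, 1] and the
`s2 = 0` case returns the local mean; without the clamp the estimate
overshoots wherever local variance drops below the noise floor.  The
global noise variance defaults to the mean of the local variances (classic
Wiener practice) and is logged.  The weight `beta = v2/(s2 + lam*alpha +
eps)` is clamped to [0, 1] because the raw ratio exceeds 1 in flat regions
quieter than the noise floor, and convex mixing requires the clamp.
Defaults: 3×3 window, lam=0.5, eps=1e-6.  The PSD-via-autocorrelation
diagnostic and the mean-assignment pass are recorded but do not enter the
filtering equation, which consumes only the local median, mean, variance
and gradient.

## EEG features

Welch PSD uses 2-s Hann segments with 50 % overlap; band powers integrate
the PSD over [low, high) with the rectangle rule, so a flat spectrum
yields powers exactly proportional to bandwidth.  Band edges: delta
0.5–4, theta 4–8, alpha 8–13, beta 13–30, gamma 30–80 Hz (capped at
Nyquist; a band entirely above Nyquist is reported as zero with a
warning).  Spectral roll-off defaults to the 85th power percentile and is
exposed separately from the canonical vector.  Hjorth ratios guard
constant channels by reporting 0.

**E-CSP.**  The activation chain standardizes a trial against
resting-state statistics (mean/sd of the background reference), applies
softsign (bounding to (−1, 1)) and then swish; on that interval the chain
is monotone and bounded in ≈ (−0.27, 1).  Covariances are per-trial
`Z Zᵀ / T` averaged per class.  Frequency weighting has two modes:
`spectral` (default) band-limits each trial to [fc − Δf, fc + Δf] and
scales the amplitude spectrum by √w(f) so the PSD is weighted by w;
`scalar` weights each trial's covariance by w evaluated at the trial's
dominant frequency.  Defaults fc = 5 Hz, Δf = 4 Hz (the ictal band of the
generator), γ1 = γ2 = 0.1.  Filters solve `G1' w = λ G2' w` with a
symmetric generalized eigensolver — the form that extremizes the
between-class variance ratio; a singular rest covariance is ridged with
1e-8·I and a warning.  The bank takes ⌈n/2⌉ eigenvectors from the top of
the spectrum and ⌊n/2⌋ from the bottom; for the canonical 32-filter bank
over 22 channels the two halves overlap mid-spectrum and those
eigenvectors appear twice.  The default feature is the mean squared
projected sample (`mean_power`): the arithmetic mean of a spatially
filtered zero-mean signal is ≈ 0 and carries no class information, so the
literal mean is retained only as an option (`literal_mean`).  The
H2 Rayleigh objective is exposed as a diagnostic (`ecsp_objective`).

Feature layout is electrode-major: channel 0's five band powers, channel
1's, …, then the five temporal descriptors per channel, then the filter
bank block — 10·C + n_filters values.  Band powers, Hjorth activity and
line length scale with amplitude; zero-crossing rate and roll-off are
scale-free; the activation chain makes E-CSP features approximately
scale-free in the task signal.

## Image features

**S-PHOG.**  Gradients are centered differences ([-1, 0, 1] and its
vertical counterpart, applied by convolution) of the Gaussian-smoothed
image (σ = 1 px default).  The vote weight is the magnitude normalized by
its summed 3×3-neighborhood magnitude plus a guard (1e-12; small enough
that the descriptor is stable under global intensity scaling to ~1e-7).
The vote angle is the circular mean of the neighborhood's unit gradient
vectors; a vanishing mean vector is flagged and reported as angle 0.
Orientations are unsigned by default (wrapped into [0, 180)) with Z = 9
bins; levels {0, 1} give a 45-dim descriptor, L1-normalized to sum 1
(uniform if the image has no gradients).  The unsmoothed, unnormalized
pyramid-HOG baseline ships for ablation; over 20 noise seeds the smoothed
descriptor moves less between clean and noisy phantoms than the baseline,
which is the design goal of the smoothing.

**Embedder.**  A two-stage 3-D convolutional encoder (widths 32 and 64,
kernel 3 per axis, ReLU, max pooling) with He-initialized weights frozen
at a seed — a random-projection encoder, deliberately untrained so the
embedding is a pure deterministic function of (seed, image).  Readout:
per-channel mean/std statistics globally pooled and projected to 256
dimensions, and the same statistics pooled over a fixed left-half lateral
region projected to 128.  The 128-dim block is a synthetic stand-in for
regional connectivity descriptors and is labelled as such; it encodes
lateralized intensity structure, not connectivity.  2-D images are lifted
to single-slice volumes.

In the end-to-end pipeline the 45-dim S-PHOG descriptor overwrites the
tail of the 384-dim embedding so the per-volume feature stays at the
384-dim contract while carrying both representations.

## Classifier

**Blocks.**  The chaotic map `x → x/q (x<q); (1−x)/(1−q) (x≥q)` supplies
the fixed scaling factors ϖ, ϑ of the composite activation at
initialization (consecutive iterates, skipping boundary values); they are
not learned because no update rule is defined for them.  The composite
activation is `x·tanh(softplus(x))` for x ≥ 0 (the Mish form) and
`ϖ·ELU(x) + ϑ·GELU(x)` for x < 0 (standard ELU, α = 1), continuous at 0.
Updated batch normalization standardizes per channel with batch (training)
or stored (inference) statistics, then multiplies by a gate:
the composite activation times a channel-axis attention normalization
`std(z)·(1 + softmax(w1·z + b))`, mixed-pooled (`χ·max + (1−χ)·mean`,
χ = 0.5) over each sample's spatial extent — a per-(sample, channel)
scalar, the only shape-consistent reading of a pooled multiplier on a
normalized map.  With the gate forced to 1 the layer is exactly standard
batch normalization.  Spatial attention aggregates the map along each
axis with mean and max, passes the 2-channel summary through a seeded 3×3
convolution (max(C/4, 4) filters), instance norm + ReLU, a mean+max
aggregation over filters, a kernel-3 cross-interaction 1-D convolution
and a sigmoid, yielding per-axis profiles in (0, 1) that re-weight the
input; biases are zero so a zero map gets 0.5 profiles.  For 1-D branch
maps only the length-axis half of the module applies.  Ghost modules
produce out/ratio intrinsic maps with a dense convolution and the rest
with cheap depthwise transforms; parameter count is strictly below the
equivalent dense convolution for more than one input channel.

**Training scheme.**  The convolutional stages are seed-initialized and
frozen; only the dense softmax heads (128-64-2 with dropout 0.3 for the
dual-branch model; 64-2 for the ghost network) are trained — random
convolutional features with a trained readout.  This keeps the whole
model in NumPy, exactly reproducible, and fast on one CPU, at the cost of
not adapting the convolutional filters to the data; on the synthetic
benchmark the heads are more than sufficient.  Optimization is mini-batch
Adam (lr 0.001, batch 32), binary cross-entropy, ≤ 100 epochs with early
stopping on validation loss (patience 10, best weights restored).
Normalization statistics and feature standardization are fitted on the
training encode pass only.  The 384-dim image vector is reshaped to a
16×24 map for the 2-D branch; the fused vector is zero-padded to a
16-row map for the ghost network — row-major reshapes, fixed and
documented rather than meaningful.

**Fusion.**  Soft voting averages the two probability matrices with
nonnegative weights renormalized to sum 1 (default equal, since no
principled weighting is available a priori); the label is the fused
argmax with ties resolved to class 0 (deterministic).  EEG features feed
the 1-D branch and image features the 2-D branch by default; both
routings are configurable.

## Evaluation

Nine metrics (accuracy, precision, sensitivity, specificity, FNR, FPR,
F1, MCC, NPV) with the seizure class positive; zero-denominator metrics
are reported as 0 with a warning.  PSNR uses `10·log10(peak²/MSE)` with a
+∞ sentinel at zero error; SSIM uses the standard 7-pixel window with
K1 = 0.01, K2 = 0.03; SNR is the clean-signal power over the residual
power in dB.  Cross-validation is subject-independent: unique subjects
are shuffled with the seed and partitioned into k test folds; within each
iteration the remaining subjects split into train and validation
(~15 % of subjects, rotated per fold); every fold must contain both
classes in every partition.

## Benchmark sizes

The default end-to-end benchmark uses 240 records across 24 subjects with
five-fold CV, 32×32 phantoms, and 20 seeds for the noise-comparison
studies.  These sizes were chosen as the package's desk-scale study
conditions; all headline quantities in `scripts/acceptance.py` are
computed at these sizes.

## Known limitations

- The E-CSP activation treats the whole record as "task" and background
  records as the resting reference; in the feature vector each record
  self-references by default, which is convenient but differs from a
  paradigm with explicit rest periods.
- The embedder's "connectivity" block is a labelled stand-in (see above).
- The frozen-feature training scheme cannot express improvements that
  require adapting convolutional filters; ablations that remove attention
  or the normalization gate therefore shift the representation rather
  than an optimized model.
- The ghost network sees the concatenated feature vector as an arbitrary
  2-D map; no spatial meaning is intended.
- Perfect synthetic accuracies reflect the constructed class contrast,
  not expected clinical performance.
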