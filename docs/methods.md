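# Methods

This note documents the models, conventions and design choices behind
`arslab`, in the spirit of a methods appendix: what is computed, under what
assumptions, and what the synthetic experiments do and do not show.

## Event duration models

Event durations are modelled with the Burr Type XII distribution with scale
α and shapes c, k:

    f(x) = (k·c/α) · (x/α)^(c−1) · (1 + (x/α)^c)^(−k−1),   x > 0
    F(x) = 1 − (1 + (x/α)^c)^(−k)

Two parameter sets are built in: the fit to annotated crackle durations
(α = 0.199 s, c = 7.6698, k = 0.3146) truncated at 100 ms, and the fit to
annotated wheeze durations (α = 0.2266 s, c = 4.1906, k = 0.3029) truncated
to (0.1 s, 2 s].  The lower bound of 0.1 s on the wheeze-like model follows
from its definition as the "longer than 100 ms" negative class.  Sampling
uses the closed-form inverse CDF restricted to the truncation interval —
distribution-identical to rejecting out-of-range draws, but using exactly
one uniform per sample.  This matters for the crackle-like model, whose
truncation keeps only ≈0.16 % of the untruncated mass; literal rejection
would need ≈600 draws per accepted sample.  A configuration whose
truncation window keeps less than 1e−6 of the mass is rejected as
unsatisfiable.

The same two models are used (a) for the variable-duration negative class
and (b) as the default duration models of the synthetic generator's
crackles and wheezes.  Consequence: in variable mode, negatives are
duration-matched to positives *by construction*, which is precisely the
control the duration-confound experiments need.

## Negative-event generation

Fixed mode draws events of exactly 50 ms and 150 ms with uniformly random
start times; variable mode draws durations from the truncated Burr models.
Per-file random streams are derived by stable (CRC-based) hashing of a
master seed with the recording identifier, so corpora are reproducible
file-by-file while varying across files.  By default generated negatives
may not overlap annotated adventitious events (negative-class purity); a
flag disables the constraint.  Negatives may overlap each other — with
matched counts in a 21.5 s recording the collision probability is small
and ground truth remains exact.

Per recording, the default number of generated negatives *matches* the
adventitious counts (short negatives = number of crackles, long negatives =
number of wheezes).  Published corpus-level tallies use a smaller,
unmatched negative class; the matched design is chosen deliberately: it
equalizes class balance across fixed/variable modes and makes the
duration-only control sharp — with matched counts, duration carries no
class information in variable mode beyond the short/long split, so a
duration-only classifier's optimum equals the majority-class rate.

## Excerpting and time–frequency analysis

Events are cut to fixed 2 s excerpts (the median-plus-two-standard-
deviations of annotated wheeze durations): shorter events are centered and
zero-padded (extra sample on the right when the pad is odd; padding adds no
energy), longer events keep their first 2 s.  Event intervals are half-open
`[start, end)` seconds; sample conversion rounds the start down and the end
up so no annotated sample is dropped.

The STFT uses no edge padding and hop = window·(1 − overlap); frames =
⌊(L − W)/H⌋ + 1.  This is the only frame convention that reproduces the
canonical 247 × 257 image for a 2 s excerpt at 4 kHz with a 32 ms window,
75 % overlap and a 512-point transform, which pins it down.  Windows
shorter than the transform are zero-padded to it; windows longer than
512 samples (the 256 and 512 ms analysis scales at 4 kHz) get the next
power-of-two transform length.  The spectrogram is magnitude, not power;
logarithmic compression enters only inside the MFCC computation.  The mel
filterbank is triangular, area-unnormalized, with 64 centers uniform on
m = 2595·log₁₀(1 + f/700) between 0 Hz and Nyquist; bands that would cover
no bin at coarse resolutions are given their nearest bin so no filter is
empty.  Images are min–max normalized per image to [0, 1]; constant images
map to zeros.

## Features

Each analysis window length yields 81 per-frame channels; five statistics
(mean, sample standard deviation with n−1, median, min, max) over frames ×
six window lengths (16, 32, 64, 128, 256, 512 ms; Hamming window for
feature extraction) give the 2430-dimensional descriptor with names
`{stat}_{channel}_{window_ms}`.

Conventions for quantities the literature names but does not define:

* **Entropy** — Shannon entropy of the magnitude-normalized spectrum
  divided by log(bins), in [0, 1].
* **Flatness** — geometric over arithmetic mean of the magnitude spectrum.
* **Roughness** — summed Sethares sensory dissonance over pairs of spectral
  peaks (at most 12 peaks per frame, ≥5 % of the frame maximum).
* **Irregularity** — Σ(aᵢ − aᵢ₊₁)² / Σaᵢ² over successive peak amplitudes.
* **Flux family** — flux is the Euclidean distance between successive
  magnitude spectra (first frame 0); "inc" sums only positive bin
  differences; "halfwave" is the Euclidean norm of the half-wave-rectified
  difference; "median" applies a 5-point median filter to the flux curve.
* **Brightness** — fraction of spectral energy above the cutoff (100, 200,
  400, 800 Hz), plus the 400/100 and 800/100 ratios.
* **Rolloff** — lowest frequency containing the given fraction (95, 75, 25,
  5 %) of spectral energy, plus the 5/95 (outlier) and 25/75
  (interquartile) ratios.
* **ZCR** — sign-change rate per second counted on the time-domain frames
  aligned with the spectrogram; when only a spectrogram is available the
  estimate 2·centroid is used (exact for a sinusoid).

Ratios with denominators below 1e−12 are defined as 0 so silent frames
cannot poison event statistics; every channel is finite for any input,
including pure silence (verified by fuzzing with silent, impulsive and
clipped excerpts).

**Melodic channels.** Pitch is estimated per frame from the product of the
real cepstrum and the (non-negative) autocorrelation over the candidate lag
range — a cepstral-autocorrelation detector — then refined on the
quadratically interpolated spectral peak nearest the candidate.  The
ceiling is 1600 Hz (the highest fundamental reported for wheezes); the
nominal 60 Hz floor is raised to 2·rate/W when the analysis window cannot
hold a full period, so the 16 ms scale remains usable.  Voicing is the
fraction of spectral energy captured by a ±1-bin harmonic comb at the
estimated pitch; frames below a 0.25 voicing threshold (and silent frames)
are unvoiced, with pitch encoded as 0 and included in the statistics
(statistics must be total; the encoding is documented so selected channels
remain interpretable).  Inharmonicity is the energy-weighted deviation of
spectral peaks from integer multiples of the pitch, scaled to [0, 1]; it is
0 for unvoiced frames.  Smoothing uses centered moving averages over the
frame-count equivalents of 100/250/500/1000 ms, count-normalized at the
edges.  The same 15 channels are recomputed on a 400 Hz high-passed signal
(4th-order Butterworth, zero-phase), where normal breathing energy is
negligible.  MFCC deltas are plain first differences (first frame 0), and
the 13 MFCCs are orthonormal DCT-II coefficients 1–13 of the log mel
energies.

## Feature selection and classical models

MRMR ranks channels by the greedy mutual-information quotient: the first
pick maximizes I(f; y); later picks maximize I(f; y) / mean I(f; s) over
the selected set.  Continuous features are discretized into 10
equal-frequency bins before MI estimation; ties break toward the lower
channel index.  With `top_k` set, the greedy pass stops after k picks and
the tail is appended in current-quotient order; only the prefix is then the
exact greedy ranking (the study subsets use the best 10 or 100, so this is
what experiments need).  Selection is always fitted on the training split
only — anything else would leak test data.

Classifiers: LDA with lsqr shrinkage (the shrinkage coefficient in [0, 1]
plays the role of the usual "delta" regularizer), SVC with RBF kernel
(γ = 1/(2·kernel_scale²)), and RUSBoost — SAMME boosting over decision
trees where each round's training subset undersamples every class to the
minority count, drawn according to the current boosting weights; the
per-round class counts are recorded on the fitted model as an
instrumentation hook.  Hyperparameters are tuned by sequential model-based
search: 8 random configurations, then expected-improvement maximization
under a Matérn-5/2 Gaussian-process surrogate over a seeded candidate pool,
with validation accuracy on a stratified 25 % split as the objective
(default budget 30 evaluations); the chosen configuration is refit on the
full training split.  Default ranges: shrinkage 1e−6–1 (log); SVM box
constraint and kernel scale 1e−3–1e3 (log); RUSBoost learning rate 1e−3–1
(log), 10–500 rounds, minimum leaf 1–50, maximum leaf nodes 2–1024 (log),
feature-sampling fraction 0.1–1.  Everything is reproducible from the seed.

## Convolutional models

The CNNs are a compact self-contained numpy implementation: per input
branch, convolution blocks (3×3 kernels, rectifier, 2×2 max-pool; default
16/32/64 filters), flattened and concatenated across branches, a 64-unit
dense layer and a softmax head.  The dual-input configuration takes the
spectrogram and mel-spectrogram images together; single-input variants take
either alone.  Training uses Adam at 0.001 with batch 16 for at most 30
epochs, stopping after 10 consecutive epochs without a new best validation
loss (stratified 25 % validation split) and restoring the best-validation
parameters.  The layer parameters are package defaults, configurable per
experiment; all experimental conclusions are behavioral, not tied to one
architecture.  Prediction ties break toward the lowest class index.

## Metrics and experiments

Accuracy, precision, sensitivity, F1 and MCC are computed from binary
counts, with multiclass matrices collapsed one-vs-all.  Zero-denominator
conventions: precision/sensitivity/F1 are 0 when undefined and MCC is 0
when any marginal is zero, so degenerate all-one-class predictors score 0
rather than NaN (variable-duration experiments do reach such regimes).
AUC is the Mann–Whitney probability with half credit for ties, reported for
binary tasks only.  Reports give mean ± standard deviation over seeds as
percentages to one decimal, plus confusion matrices and per-split event
tallies.

The experiment grid crosses the negative-class mode of the training and
test sides (fixed/fixed, fixed/variable, variable/variable) with three
tasks (crackle vs wheeze vs other, crackle vs other, wheeze vs other).
The fixed/variable cell — train on fixed-duration negatives, evaluate on
duration-matched ones — is the diagnostic: a classifier that learned
duration collapses there.  A duration-only control (a depth-6 decision tree
on the annotated duration alone) quantifies the leakage ceiling.

## Synthetic corpus

The generator emulates the statistical structure the analysis needs, not
lung acoustics: ~21.5 s recordings at 4 kHz; crackles as exponentially
damped, slightly chirped oscillations with center frequency 200–1500 Hz
(≥90 % of energy in the 60–2000 Hz crackle band, peak in the first third);
wheezes as amplitude-modulated harmonic tones (fundamental 100–1000 Hz,
1/k harmonic rolloff); background as ~1/f noise low-passed at 2 kHz and
amplitude-modulated by a raised-cosine breathing cycle (4 s period).
Events never overlap one another and each is scaled to the configured
signal-to-noise ratio against the local background; annotations are exact.
Per-recording streams derive from stable hashing of (seed, participant,
recording).

The default SNR is −12 dB (event RMS against local background RMS over the
event interval).  This is deliberate: with clearly audible events the
acoustic task is trivially separable and every experiment cell saturates,
which no real auscultation corpus resembles.  At −12 dB the acoustic task
is hard but learnable, reproducing the difficulty regime reported for real
corpora, where duration-controlled three-class accuracy sits near 80 %
rather than near ceiling.  Note that for a damped crackle transient the
interval-RMS understates the onset peak, so −12 dB events are still locally
prominent.

What passing synthetic tests shows: the pipeline's machinery is correct and
the duration-confound mechanism behaves as theory predicts (fixed-duration
negatives are identifiable from duration alone; Burr-matched negatives are
not).  What it does not show: absolute performance on clinical recordings —
real corpora contain sensor noise, intermittent disturbances, fine/coarse
crackle substructure and annotation imprecision that the generator does not
model.

## Problem sizes used in the checks

The packaged acceptance checks run on a 50-recording corpus (10
participants × 5 recordings, 4 crackles and 2 wheezes per recording), with
the SVM-RBF classifier on the best-100 MRMR channels, 10 seeds and a
12-evaluation tuning budget; the dual-vs-single CNN comparison uses reduced
images (0.5 s excerpts, 128-point transform, 16 mel bands) and 8 epochs.
These sizes are the package's choice of a desk-scale experiment; the same
code paths scale to larger corpora unchanged.

## Known limitations

* The melodic pitch detector targets strong harmonic structure; for
  polyphonic wheezes it reports the dominant fundamental only.
* MRMR's mutual-information estimates inherit the bias of 10-bin
  discretization; rankings on very small sample sizes are noisy.
* The numpy CNN is CPU-bound and intended for desk-scale experiments, not
  large-image training at scale.
* The annotation importer covers per-event annotation files; per-cycle
  annotations must be converted upstream.
* Whether the original spectrogram pipeline used magnitude or power is
  unknowable from its description; magnitude is the default and the choice
  is a documented knob.
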