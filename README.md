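# arslab

Adventitious respiratory sound classification with duration-controlled
negative classes.

## The problem

Patients with respiratory conditions exhibit adventitious respiratory
sounds (ARS) on top of normal breathing: **crackles** — explosive,
nonmusical transients, typically shorter than 20 ms with energy between
60 Hz and 2 kHz — and **wheezes** — musical, harmonic sounds longer than
100 ms with fundamentals between 100 and 1000 Hz.  Automatic classifiers
for these events are usually evaluated against a negative ("other") class
cut from the recordings at *fixed* durations (e.g. 50 ms and 150 ms).  That
design leaks the label through event duration alone: a model can score in
the high nineties without learning anything acoustic.  This package
implements a full classification pipeline together with the experimental
design needed to expose and control that confound, and a synthetic corpus
generator so every stage is testable without access to clinical data.

## What it implements

* **I/O** (`arslab.io_rsd`) — PCM WAV reading with anti-aliased polyphase
  resampling to 4 kHz, a canonical per-event TSV annotation dialect, YAML
  corpus manifests, and strictly participant-disjoint train/test splitting.
* **Duration models and negatives** (`arslab.events`) — truncated Burr
  Type XII duration models

  $$f(x\mid\alpha,c,k)=\frac{kc}{\alpha}\Big(\frac{x}{\alpha}\Big)^{c-1}
    \Big(1+\big(\tfrac{x}{\alpha}\big)^{c}\Big)^{-(k+1)},$$

  with the crackle-duration fit (α=0.199, c=7.6698, k=0.3146, ceiling
  100 ms) and the wheeze-duration fit (α=0.2266, c=4.1906, k=0.3029,
  ceiling 2 s); negative-event generation in fixed (50/150 ms) and
  Burr variable-duration modes; fixed-length 2 s event excerpting
  (center-and-zero-pad short events, truncate long ones).
* **Time–frequency images** (`arslab.tf`) — magnitude spectrograms
  (Blackman–Harris 32 ms window, 75 % overlap, 512-point transform: a 2 s
  excerpt gives a 1 × 247 × 257 image) and 64-band mel spectrograms
  (1 × 247 × 64) using m = 2595·log₁₀(1 + f/700), min–max normalized.
* **Features** (`arslab.features`) — 81 per-frame channels (25 spectral,
  13 MFCC + 13 deltas, 30 melodic pitch/inharmonicity/voicing channels)
  at six window lengths (16–512 ms), summarized by five statistics into a
  2430-dimensional named event descriptor.
* **Selection and classifiers** (`arslab.selection`) — greedy MRMR ranking
  by mutual-information quotient; regularized LDA, RBF-kernel SVM, and
  RUSBoost (boosting with per-round random undersampling), each tuned by a
  seeded Gaussian-process hyperparameter search.
* **CNNs** (`arslab.cnn`) — compact single- and dual-input convolutional
  networks over the spectrogram/mel images (Adam, batch 16, learning rate
  0.001, ≤30 epochs, early stopping with patience 10 on validation loss).
* **Evaluation and experiments** (`arslab.evaluate`, `arslab.experiments`)
  — accuracy, precision, sensitivity, F1 and the Matthews correlation
  coefficient

  $$\mathrm{MCC}=\frac{TP\cdot TN-FP\cdot FN}
    {\sqrt{(TP{+}FP)(TP{+}FN)(TN{+}FP)(TN{+}FN)}}$$

  under one-vs-all reduction, Mann–Whitney AUC for binary tasks, and the
  experiment grid (train/test negatives fixed or variable × three tasks),
  including a duration-only control classifier.
* **Synthetic corpora** (`arslab.synth`) — multi-participant recordings of
  breathing-modulated noise with injected crackle transients and harmonic
  wheezes whose durations follow the Burr models, with exact annotations.

## Worked example

`examples/06_duration_confound.py` builds a small synthetic corpus and runs
a classifier that sees *only* each event's duration:

```
fixed     negatives: duration-only 3-class accuracy = 1.000  (test events: {'crackle': 16, 'wheeze': 8, 'other50': 16, 'other150': 8})
variable  negatives: duration-only 3-class accuracy = 0.417  (test events: {'crackle': 16, 'wheeze': 8, 'otherCrackle': 16, 'otherWheeze': 8})
```

With fixed 50/150 ms negatives, duration alone solves the three-class task
perfectly — the task is confounded.  With Burr duration-matched negatives
the same classifier drops to the majority-class level: whatever a model
then achieves must come from acoustics.  The other scripts in `examples/`
walk through corpus generation, negative-event modes, the time–frequency
images, the 2430-feature descriptor, and MRMR + tuned-classifier training,
each printing the quantities it computes.

## Scope notes

The package does not download or redistribute any clinical recordings; the
I/O layer reads the same WAV + annotation layout used by public
respiratory-sound corpora, and an importer maps per-event annotation files
onto the canonical TSV dialect.  Wavelet/scalogram representations and
statistical significance testing between classifiers are out of scope.
See `docs/methods.md` for modelling assumptions, parameter defaults and
known limitations.
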