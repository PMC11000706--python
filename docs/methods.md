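# Methods

## Pipeline

Input records are single-channel EEG signals in the five-set Bonn layout
(100 records per set, 4,097 samples, 173.61 Hz, integer ADC units, one
sample per text line). The pipeline is: record loading and task labelling →
optional zero-phase band-pass filtering → non-overlapping segmentation →
stratified five-fold cross-validated training of a unit-stack network →
confusion-matrix metrics, fold-averaged.

Class indices follow the task name left to right (healthy lowest, seizure
highest), which fixes the confusion-matrix orientation; the seizure set E is
always the positive class of binary tasks.

## Preprocessing

* **Filter.** Order-2 Butterworth band-pass, 0.5–50 Hz, applied forward and
  backward (`scipy.signal.sosfiltfilt`, odd-reflection edge padding of the
  scipy default length). Zero-phase filtering means the effective magnitude
  response is the *squared* one-pass response, so the cutoffs sit at −6 dB
  of the effective response. Filtering applies in studies 2, 4 and 6 only.
* **Segmentation.** Windows anchor at sample 0, no overlap, trailing
  remainder discarded. Segment lengths per study: full record (studies
  1–2), 2,048 samples (3–4), 178 samples (5–6). A 1 s window at 173.61 Hz
  is ~174 samples; the published figure of 178 is kept as-is, so each
  4,097-sample record yields floor(4097/178) = 23 one-second segments with
  3 samples discarded. No amplitude normalization is applied by default
  (the source protocol mentions none); `build_study_dataset(...,
  zscore=True)` offers per-segment standardization, off by default.

## Architecture

Each unit is Conv1D (stride 1, valid padding, ReLU) → bidirectional
LSTM/GRU (full sequence output, the two directions concatenated along the
feature axis) → average pooling. Choices the source description leaves
open, fixed here:

* pool size/stride = 2/2 (smallest non-trivial downsampling);
* conv activation ReLU; recurrent gates use the conventional
  sigmoid/tanh activations (GRU in the classic reset-before-candidate
  form);
* bidirectional merge by concatenation (doubles the channel count);
* one dropout stage after each unit except the last;
* final stage: Flatten → ReLU dense stack → K-way softmax (forced by the
  categorical cross-entropy loss);
* Adam learning rate 0.001 (unstated in the source), batch size 64,
  epsilon 1e-7.

The registry (`src/seizurenet/data/registry.yaml`) holds all 30 study×task
hyperparameter sets; BiLSTM and BiGRU variants share them. Kernel size is
2 everywhere except Study 2's four-/five-class tasks (4) and Study 5's
AB–C–D–E (4) and A–B–C–D–E (8). Entries whose published description omits
a value carry a `missing` flag and resolve with documented fallbacks
(dense width 100; epochs 150; Study 1 dropout 0.1, matching studies 2–4);
`get_config` warns when it fills one in, and any field can be overridden.

Ablation (`ablate`) removes every conv stage or every Bi-RNN stage while
leaving pooling, dropout, the dense stack and the training protocol
untouched. Removing convolutions always reduces the parameter count;
removing Bi-RNNs can *increase* it when the conv channel width exceeds
twice the RNN width, because the flattened feature vector grows — the
protocol is layer removal, not parameter matching.

## Training engine

The networks are trained by an in-package engine built on numpy with
numba-compiled recurrent kernels: float32 arithmetic, full
backpropagation through time, softmax cross-entropy fused with the output
layer, Adam. Initialization is Glorot-uniform for input/dense kernels,
orthogonal for recurrent kernels, zero biases except the LSTM forget-gate
bias (1.0). Input projections are hoisted out of the time loop as one
matrix product per layer; sigmoid/tanh inside the kernels are written via
`exp` for speed. Raw ADC-scale inputs are fed directly to the first conv
layer, matching the no-normalization default.

Numerical and policy details:

* prediction = argmax of the softmax vector, ties broken toward the lowest
  class index;
* a fold whose loss turns non-finite is marked failed, excluded from the
  averages, and the report is flagged partial — never silently averaged;
* per-class metrics with a zero denominator are defined as 0 with a
  recorded warning;
* fold splits and weight initialization are fully determined by the run
  seed (per-fold streams derived via `numpy.random.SeedSequence`); two runs
  with equal seeds use identical splits and initial weights. Bitwise
  identity of *trained* weights is best-effort: it holds in practice on a
  fixed single-threaded BLAS but is not asserted.

## Evaluation

Folds are stratified at the segment level (per-class fold sizes differ by
at most one), matching the published 800/200, 160/40 and 400/100 per-fold
arithmetic. Segment-level splitting lets segments of one source record
fall in both train and test folds; a `group_aware` option provides
leakage-free record-grouped splits and is flagged as a deviation from that
arithmetic. Accuracy is the overall fraction correct (trace over total —
identical to the TP/TN formula for two classes); sensitivity, specificity
and F1 for K > 2 are unweighted one-vs-rest macro averages, a symmetric
default the source description does not pin down. All metrics are percent;
fold averages are arithmetic means. Wall-clock training/inference seconds
are recorded per fold for information only — they are hardware-dependent
and never an acceptance surface.

## Surrogate EEG generator

`seizurenet.synthetic` produces seeded surrogate records so every stage is
exercisable without the clinical download. Per class: a 1/f^α colored
Gaussian background (α = 1–1.2, amplitude flattened below 2 Hz), plus

* **A** (eyes open): weak 10 Hz component (relative power 0.3);
* **B** (eyes closed): prominent 8–13 Hz alpha peak (relative power 4);
* **C**/**D** (interictal): Poisson-timed biphasic spikes
  (derivative-of-Gaussian template, width 60 ms, amplitude 200 ADC units)
  at 0.7/s and 1.5/s respectively;
* **E** (ictal): a high-amplitude rhythm wandering in 3–12 Hz with gain 5
  relative to the background (background SD 60 vs. 40–50 ADC units
  elsewhere), slow amplitude modulation;

plus white noise (SD 5). Defaults were chosen so the classes carry the
qualitative structure of the real sets — the ictal class dominated by
3–12 Hz power and by far the largest amplitude (a plain variance threshold
separates E from the rest at ≥95%), the eyes-closed class alpha-peaked —
at a scale where integer rounding in the Bonn text dialect loses nothing.
The generator makes no claim of physiological realism: no neural-mass
dynamics, no EMG/EOG artifacts, no inter-subject variability, no temporal
nonstationarity beyond the burst envelope. Passing synthetic end-to-end
checks therefore demonstrates that the architecture, training loop and
evaluation plumbing work and can exploit amplitude/spectral class
structure; it does not certify clinical performance, and the published
real-data accuracies are reproducible only against the actual corpus
(`reproduce-study --data <bonn-dir>`).

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` verify arithmetic on the
full-size surrogate corpus (500 records × 4,097 samples) but train only
the smallest published architecture (Study 1, A–E) for 10 epochs on 200
records — the package's chosen desk-scale demonstration, which already
saturates at 100% on the strongly separated surrogate classes. Published
epoch counts (50–150) apply unchanged when reproducing real-data runs.

## Known limitations

* Subject identity of the 100 records per set is not published, so
  subject-aware splitting cannot be replicated and is not attempted.
* The 178-sample "1 s" window is numerically inconsistent with the
  173.61 Hz sampling rate; the printed value wins and the inconsistency is
  documented, not resolved.
* Several published hyperparameters are missing (see registry `missing`
  flags); fold-averaged results for those combinations depend on the
  documented fallbacks.
* The engine targets CPU; no GPU path, no early stopping, no checkpoint
  selection, no significance testing across models.
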