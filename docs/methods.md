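# Methods

## The problem

Automatic sleep staging assigns one of the five AASM stages — Wake (W),
N1, N2, N3, REM — to each 30-second epoch of an overnight
polysomnography (PSG) recording. Models trained on a fixed pool of
subjects degrade on new ones, because EEG/EOG/EMG/ECG signals differ
systematically between individuals (electrode placement, skull
conductivity, muscle tone, age). This package implements a
domain-generalization approach: every training subject is treated as a
*source domain*, the held-out subject as an unseen *target domain*, and
an adversarial branch pushes the feature extractor toward
subject-invariant representations without ever seeing target data.

## Model

The classifier has three parts.

**Feature extractor (Res-CA-FE).** Each 30-s epoch is represented as a
10-channel stack of STFT magnitude spectrograms, a tensor
`(128, 128, 10)` in the reference configuration. The encoder is a stack
of residual channel-attention blocks (Res_CAB): a 3×3 convolution
produces a feature map `o`, a squeeze-and-excitation (SE) module pools
each channel to a scalar `z_c = mean_{i,j} o_c(i,j)`, passes the vector
through a bottleneck `s = σ(W₂ δ(W₁ z))` (reduction `r = max(C/16, 1)`),
rescales `õ_c = s_c · o_c`, and the block output is
`relu(õ + shortcut(x))` — identity shortcut when channel counts match,
1×1 projection otherwise. Four stride-2 stages (widths 64, 128, 256,
256; one projection block plus one standard block each) bring
`(128, 128, 10)` to `(8, 8, 256)`. A U-shaped decoder upsamples twice
(nearest-neighbour ×2), concatenates the encoder feature map of equal
resolution, and fuses with a 1×1 convolution; the result is averaged
over the frequency axis to a 32-step sequence and passed through a
bidirectional GRU (hidden 128 per direction), giving feature sequences
`(32, 256)`.

**Label predictor.** The flattened (step-major) feature sequence passes
through three fully connected layers ending in a 5-way softmax. The
stage loss is the mean cross-entropy
`L_cla = −(1/M) Σᵢ Σⱼ y_ij log ŷ_ij`.

**Domain discriminator.** The same FC shape ends in an `n_domains`-way
softmax (9 for a 10-subject cohort) with domain cross-entropy `L_d`.
A gradient reversal layer (GRL) sits between the extractor and the
discriminator: identity in the forward pass, gradient × (−λ) in the
backward pass. One backward pass through `L_cla + L_d` therefore moves
the discriminator down `L_d` while the extractor ascends it, realizing
the adversarial total loss

    L_all = L_cla − λ · L_d.

Both loss terms are multiclass cross-entropies; the domain term's inner
sum runs over the domain classes, the only reading consistent with a
softmax over domains.

Reference training hyperparameters: Adam (β₁ = 0.9, β₂ = 0.999),
learning rate 2e-5, batch size 16, 150 epochs, λ = 1.0 constant. An
optional DANN-style ramp λ(p) = 2/(1+e^(−10p)) − 1 over training
progress p is exposed (`lambda_schedule: dann`); it was measured on the
synthetic benchmark and did not outperform the constant schedule, so the
constant default stands.

## Preprocessing

Per recording: polyphase resampling to 128 Hz (anti-aliased;
upsampling is refused), segmentation into contiguous non-overlapping
30-s epochs (3840 samples; trailing remainder dropped), per-channel STFT
with a Hamming window of 128 samples and 50 % overlap, **no boundary
padding**, giving a 65 × 59 one-sided magnitude spectrogram (the padded
library default would give 61 frames; the unpadded count is pinned so
the shape is dialect-independent). The 65 × 59 map is bilinearly resized
to the square model input (the mapping from STFT output to the network's
input grid is not uniquely determined by the architecture contract;
bilinear interpolation was chosen over cropping/padding because it
neither discards frames nor injects zeros), then compressed with
log(1 + x) — spectrogram magnitudes span orders of magnitude — and
finally z-scored per channel with statistics computed **on the training
tensors only** (std floor 1e-8), so no target-subject information leaks
into the transform under LOSO.

Stage labels are encoded W=0, N1=1, N2=2, N3=3, REM=4 everywhere.

## Evaluation protocol

Leave-one-subject-out cross-validation: n subjects give n folds; each
fold trains on n−1 subjects (re-based domain labels 0..n−2) and tests on
the held-out subject. Reported metrics: accuracy, per-class
precision/recall/F1 from the 5×5 confusion matrix, macro-F1 (unweighted
mean of the five per-class F1s), Cohen's κ = (p_o − p_e)/(1 − p_e), and
a percentile bootstrap confidence interval (B = 1000, level 0.95,
resampling epoch-level prediction pairs — the resampling unit and B are
package choices, recorded in every report). Headline numbers are
unweighted means over folds; the pooled confusion matrix and its
per-class metrics are reported alongside. Zero-denominator
precision/recall cases return 0 with a logged flag instead of NaN.

## Synthetic cohort generator

Real PSG cohorts are large, access-controlled downloads, so the package
ships a generator that emulates the two properties the method needs:
separable stage-specific spectra and per-subject domain shift.

Channel layout: 6 EEG + 2 EOG + 1 EMG + 1 ECG = 10 channels at 128 Hz.
Stage recipes follow textbook physiology: W = 8–12 Hz alpha with high
EMG tone; N1 = low-amplitude 4–7 Hz theta; N2 = theta plus ~13 Hz
spindle bursts (Poisson rate 2 per epoch, 1 s, raised-sine envelope);
N3 = high-amplitude 0.5–2 Hz delta; REM = mixed theta, slow (~0.3 Hz)
EOG deflections, near-atonic EMG. Oscillations are rendered as sums of
three random-phase sinusoids inside each band on a 1/f broadband floor;
ECG carries a ~1.1 Hz beat train. Hypnogram labels are drawn i.i.d.
from the configured stage distribution — the model classifies one epoch
at a time, so stage-transition structure is deliberately absent.

Domain shift per subject (all derived deterministically from the cohort
master seed): lognormal per-channel gains (σ = 0.6 × magnitude),
Gaussian oscillation-center jitter (sd = 1.5 Hz × magnitude), lognormal
noise-floor scale (σ = 0.5 × magnitude). The default magnitude 1.0 was
calibrated once so that a classifier trained *without* the adversarial
branch visibly degrades on a held-out subject (in-domain hold-out
accuracy ≈ 0.9 vs held-out-subject accuracy 0.25–0.75 on 6-subject
cohorts); at magnitude 0 all subjects share identical domain parameters.

**What passing tests on this generator do and do not show.** They show
the pipeline is correct end to end, the staging problem is solvable
(a learning-free band-power nearest-centroid oracle exceeds 0.6
accuracy), the domain shift is real (channel-variance ratios ≥ 1.2
between subjects), and the adversarial branch buys held-out
generalization under subject shift. They do not show clinical-grade
performance: real PSG has artifacts, non-stationarity, stage-transition
structure, annotator noise and far richer inter-subject variability
than three shift parameters.

## Numerical choices

* All network arithmetic is float32; gradients are reverse-mode
  automatic differentiation on numpy arrays (tape-based; convolutions
  via im2col, strided scatter-add backward).
* Softmax is computed shift-invariantly; the logistic function is
  evaluated in its overflow-free branch form.
* Cross-entropy clamps probabilities at ε = 1e-12 (gradient zero where
  the clamp engages) and logs a warning when a true class is clamped.
* Weight initialization is Glorot-uniform from the run seed; batches
  are shuffled draws from a generator seeded per run, so identical
  configurations reproduce bit-identical training histories.
* Batches with fewer than 2 samples are skipped (batch statistics are
  meaningless there); batch composition pools all source domains
  without per-domain balancing.
* Fine-tuning freezes the encoder/decoder convolution and SE parameters
  bit-exactly (they are excluded from the optimizer) and re-initializes
  the domain head if the new cohort's subject count differs.

## Desk-scale problem sizes

Full-size training (128×128 inputs, ~15 M parameters, 150 epochs) is a
GPU-scale undertaking. The shipped `configs/desk.yaml` preset and the
directional experiments use a reduced model: 32×32 input tensors
(configurable resize target), encoder widths 8/16/32, decoder width 32,
GRU hidden 16, heads 32/16, learning rate 1e-3, with 3–6 subjects and
40–100 epochs per subject. The domain-generalization comparison runs a
6-subject cohort (100 epochs per subject, generator defaults), a reduced
model, 30 training epochs and 5 replicate seeds, and compares held-out
accuracy with and without the discriminator branch — a directional
check that the adversarial branch buys generalization, not an
absolute-performance claim.

## Known limitations

* The encoder/decoder internals (block counts, widths, FC sizes) are
  constrained only by the end-shape contract ((128,128,10) → (8,8,256)
  → (32,256)); many architectures satisfy it.
* The synthetic generator cannot validate absolute staging accuracy on
  real PSG; reading real EDF recordings is supported (optional `mne`
  dependency) but untested against any specific sleep cohort's channel
  and annotation conventions.
* Bootstrap intervals resample epochs, not subjects; subject-level
  uncertainty across folds is reported only as the per-fold accuracy
  vector.
* Training is single-threaded CPU numpy; the reference configuration is
  provided for contract checking, not for practical training speed.
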