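# Methods

This note documents the models, conventions and numerical choices behind
`ecgssl`, and what the synthetic benchmark does and does not demonstrate.

## Data model and conventions

An ECG record is a `leads × samples` float matrix in **millivolts** with a
sampling rate and ordered lead names. The canonical 12-lead order is
I, II, III, AVR, AVL, AVF, V1–V6; all internal code indexes leads 0–11 in
this order. Sample indices are 0-based; windows are half-open `[a, b)`.
WFDB gain fields are honoured on read and no per-record rescaling is applied
(low-voltage diagnostic classes are amplitude-dependent). The CSV dialect is
a header row of lead names and one row per sample; annotations are binary
vectors against an ordered label catalog that accepts an arbitrary two-level
(parent/child) hierarchy. Dataset splits are **subject-disjoint**: every
record of a subject belongs to one split, and manifests re-verify this on
load.

## Synthetic generator

Records are synthesised from **electrode potentials**, not leads: the nine
measurement electrodes (RA, LA, LL, RL, V1–V6 positions) each carry a
Gaussian-wave beat train (P, Q, R, S, T; per-electrode amplitudes, shared
timing), and the 12 leads are formed by the standard algebra
(I = LA−RA, …, Vi = vi − Wilson central terminal). Consequences:

* Einthoven (I+III = II) and Goldberger (aVR+aVL+aVF = 0) identities hold
  exactly on every clean record;
* electrode misplacement is a literal permutation of potentials followed by
  the same algebra, so the six *wearing situations* (normal, left/right arm
  swap, upper/lower swap, left- and right-sided swaps, chest reversal) have
  algebraically exact ground truth. The chest "reversal" convention is the
  full V1↔V6 order flip (configurable); limb swaps involving the ground
  electrode route the near-indifferent RL potential into a limb input, as a
  physical cable swap does.

Seven surrogate classes with long-tail prevalences (NORM 0.40, TACHY 0.20,
BRADY 0.15, IRREG_RR 0.15, WIDE_BEAT 0.12, ST_SHIFT 0.10, LOW_VOLT 0.06)
encode rate, rhythm-regularity, QRS-width, ST-segment and voltage
abnormalities. IRREG_RR uses i.i.d. lognormal RR jitter (σ = 0.25) with a
suppressed P wave — an AF-like *simulation device*, not a physiological
model. ST_SHIFT is an **anterior-localised** elevation (plateau on the
V2–V4 electrodes): lead-localised signatures are the reason additional
leads carry additional information in real ECG, and the lead-subset
comparison below measures exactly that property. Labels are multilabel
(e.g. TACHY ∧ IRREG_RR); TACHY ∧ BRADY is rejected as contradictory.

Three artifact families emulate wearable-ECG corruption: *myoelectric*
noise (zero-mean, band-limited 30–150 Hz — capped at 0.45·fs below 330 Hz
sampling), *baseline wander* (random-phase sinusoids on exact Fourier bins
below 0.5 Hz, hence strictly band-limited), and *electrode shedding* (one
lead held constant over a 20–60% span). Each family has an apply
probability and magnitude; all-zero levels are the identity, and an
injection log records what went where.

**What the generator does not emulate:** real arrhythmia morphology
(ectopy, conduction patterns), inter-subject anatomy, electrode impedance
drift, or the 60-term diagnostic hierarchy. Passing the directional tests
therefore demonstrates that the *pipeline mechanics* (losses, transfer,
augmentation, lead handling) behave correctly on learnable surrogates — not
that clinical performance numbers transfer to real ECGs.

## Preprocessing

5th-order Butterworth high-pass, cutoff 0.5 Hz, applied per lead as a
second-order-section cascade. Filtering is **zero-phase**
(forward–backward) by default so ST/T morphology is not phase-distorted;
this squares the magnitude response, and the analytic oracle used in tests
is accordingly |H(f)|² with |H(f)| = (f/fc)⁵/√(1+(f/fc)¹⁰). A causal
single-pass mode is available by flag. Records are reflect-padded by 2 s to
suppress the startup transient. DC is removed exactly; on finite noisy
records the *segment mean* of the output is only ~10⁻² of the signal RMS,
because components between ~0.05 and 0.5 Hz are attenuated, not
annihilated — an unavoidable property of any finite-order high-pass on
finite records.

## Augmentation

Default magnitudes (all configurable): dropped DCT bins ~ U{1..50},
crop fraction ~ U(0.5, 1.0), cycle-mask window offset −40 ms and width
~ U(40, 120) ms relative to each R peak (masking **all leads**, so the model
cannot read the masked interval from a sibling lead), channel-mask count
~ U{1..3}; each operator fires independently with probability 0.5.
Composition order is frequency dropout → crop resize → cycle mask → channel
mask — masks last, so zeroed regions survive resampling. The R-peak
detector is Pan–Tompkins-style (5–25 Hz band-pass, derivative, squaring,
150 ms moving-window integration, adaptive threshold at a quantile of the
integrated energy, 200 ms refractory period, refinement to the band-passed
extremum), run on lead II with a first-channel fallback for reduced-lead
records.

## Network

The MSConv block holds four parallel 1-D convolutions (kernels 3/5/9/17,
'same'-style padding, each producing out/4 channels, concatenated). It
carries exactly half the weights of the width-17 convolution it replaces:
(3+5+9+17)/4 = 8.5 vs 17 taps per channel pair. The backbone stacks a
stride-2 MSConv stem and `residual_units` units with channels
`base + growth·k` (production: 64+16k, k = 0..7; ≈2.2 M parameters at 60
classes). Each unit: MSConv(stride 2) → BN → ReLU → dropout 0.2 →
MSConv(stride 1) → BN → SE gate, added to a stride-2 1×1-conv shortcut,
then ReLU. SE reduction ratio defaults to 16 (4 at desk scale); dropout
sits between the two MSConv blocks. CAM for a class is the head-weighted
sum of the final feature maps, linearly upsampled to the input length and
min-max normalised (constant maps return zeros).

All layers live in `ecgssl.nn`, a deliberately small explicit-backprop
NumPy engine (im2col convolutions, batch-norm with running statistics,
inverted dropout, SGD-momentum and Adam). There is no autograd graph: each
composite module wires its own backward pass, and the test suite checks
every gradient path against central finite differences (≤1e-3 relative on
sampled coordinates).

## Pretraining objective

Embeddings are L2-normalised before all dot products. The (K+1)-way softmax
at τ = 0.07 over [positive key, queue] defines the contrastive loss
L_C = −log P₀; the distribution-divergence loss is the sum over the N = 3
extra views of KL(anchor distribution ‖ view distribution), weighted by
β = 0.15. Two conventions that the objective's terse algebra leaves open
are resolved as follows: the positive key k⁺ is the **momentum encoder's**
embedding of an independently augmented view (not the anchor itself), and
L_D compares the full (K+1)-way distributions of anchor and views — the
only reading that makes it a distribution divergence. Gradients flow
through anchor and view embeddings; the queue and k⁺ are detached, the key
encoder is updated only by the momentum moving average
θ_k ← m·θ_k + (1−m)·θ_q (m = 0.9), and the queue is FIFO with a wrapping
pointer. Batch-norm runs without cross-device shuffling (single-process
desk scale); the queue is 512 at desk scale (batch 32) and configurable to
corpus scale (72 000 / 360). The optimizer is Adam at 1e-3.

## Supervised training

BCE class weights are 1/positive-count, rescaled to mean 1; zero-count
classes receive the largest finite weight and are flagged. Weights apply to
the BCE term only — the LSEP ranking term log(1+Σ exp(logit_neg−logit_pos))
is pairwise and unweighted to avoid double-counting prevalence; its mixing
weight λ defaults to 1. The one-cycle schedule interpolates linearly
between anchors at 0/45/90/100% of the epoch budget (1e-3, 1e-2, 1e-3,
1e-6); pretrained initialisation starts at the peak anchor and runs only
the decaying half. Model selection keeps the state with the lowest loss on
the held-out validation split (selecting on the evaluation set itself is
deliberately not done).

## Evaluation

AUROC is rank-based with half credit for ties; AUPRC is step-wise average
precision (no trapezoidal interpolation). Undefined values — no positives,
single-class labels, zero denominators — are NaN flags, excluded from macro
averages with a reported skip count, never silently zeroed. Binarisation
uses score ≥ threshold. Example-based metrics average per-recording values
over recordings, skipping recordings where a denominator is zero.
Operating-point selection works on a table of (threshold, confusion counts):
break-even minimises |precision−recall| (ties to higher F1), optimal-F1
maximises F1, sensitivity-floor maximises precision subject to Sen ≥ s_min
(default 0.9) and flags infeasibility while returning the
highest-sensitivity row. Model comparisons use a paired t-test on per-class
AUPRC vectors; zero-variance differences are flagged degenerate (identical
inputs: t = 0, p = 1 by convention).

## Desk-scale study conditions

The synthetic benchmark is 600 records at 100 Hz / 6 s (12 leads), a
two-unit MSDNN (base 8, growth 8, SE ratio 4, projection dim 16), batch 16,
10 supervised epochs and 4 pretraining epochs — sizes chosen so the full
study (four designs × five seeds) completes in CPU minutes while every
stage runs end to end. Directional claims (pretraining helps at small
label budgets; augmentation shrinks the clean-vs-corrupted AUPRC gap; more
leads never hurt; wearing-situation detection ≥ 0.9 accuracy) are evaluated
as **medians over five seeds**, never single runs, and as orderings rather
than absolute values: absolute clinical metrics depend on the real corpus
and are out of reach of any synthetic surrogate.

## Known limitations

* The NumPy engine is CPU-only and unoptimised for large batches; the
  production-size configuration builds and runs but is not meant for
  full-corpus training.
* The baseline single-scale ("plain width-17") architecture is available
  via `ms_kernels=(17,)` behind the same interface, but no attempt is made
  to reproduce any specific published baseline's exact parameter count.
* The wearing-situation simulator covers electrode *permutations* only;
  partial misplacement (displaced but not swapped electrodes) is not
  modelled.
* R-peak detection is tuned for the generator's morphology families and
  typical adult rates (refractory 200 ms); pathological morphologies beyond
  the surrogate classes are untested.
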