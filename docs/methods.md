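# Methods

## Problem and data model

Four-class motor imagery (left hand, right hand, feet, tongue) is decoded from
22-electrode scalp EEG laid out on the international 10–20 system. The unit of
analysis is the cue-aligned epoch: the 1.25 s window after the visual cue,
which at the assumed 250 Hz sampling rate is exactly
`floor(1.25 * 250) = 312` samples under the half-open convention
`[cue, cue + N)`. Signals are held in microvolts; labels are one-hot vectors
of length 4. Ingested recordings are assumed to carry the acquisition
pipeline's own preprocessing (0.5–100 Hz band-pass, 50 Hz notch); the package
does not re-apply it. Channels whose name marks them as EOG are dropped on
read; exactly 22 EEG channels must remain.

The on-disk exchange format is a `signals.npy` array (trial × electrode ×
sample) plus a JSON sidecar with sampling rate, electrode order, labels and
provenance. The round trip is bit-exact and inspectable from any language.
EDF is supported for interchange but is 16-bit quantised by construction
(step ≈ 0.024 µV at the ±800 µV physical range used by the writer).

## 3D representation

Each epoch is mapped onto a 6×7 grid whose cells follow scalp anatomy (rows
frontal→posterior); the 22 placed cells carry their electrode's time course,
unplaced cells are identically zero. The grid is data (a JSON montage file),
not code: alternative layouts need no code change. The exact grid of the
backbone's original description is not recoverable, so the 6×7 anatomical
layout is a documented assumption. Inputs are z-scored per electrode with
statistics taken from the training fold only; unplaced cells stay zero.

## Backbone network

Three branches (SRF, MRF, LRF) process copies of the input through three
strided 3D convolutions each:

| layer | kernel (h×w×t) | strides | filters |
| --- | --- | --- | --- |
| conv1 (all branches) | 3×3×5 | 2,2,4 | 16 |
| conv2/conv3 SRF | 2×2×1 | 2,2,1 | 32 / 64 |
| conv2/conv3 MRF | 2×2×3 | 2,2,2 | 32 / 64 |
| conv2/conv3 LRF | 2×2×5 | 2,2,4 | 32 / 64 |

The three conv1 layers share their specification but not their weights, so
each branch owns a complete gradient path for attribution. Padding is "same"
everywhere (each dimension maps to `ceil(dim/stride)`); with valid padding
the 6×7 grid would collapse below the kernel size by conv3. On a 312-sample
input the final maps are 1×1 spatially and 78/20/5 time cells ×64 filters for
SRF/MRF/LRF.

Each branch flattens its final map into a dense(32)–ELU–dense(4)–softmax
head (the reduced head width is an assumption; the source only states the
dense layer was reduced). The fused prediction is the softmax of the
elementwise **sum of the three branch softmax vectors**; ties in the argmax
break toward the lower class id. The training loss is the negative
log-likelihood of the fused output plus the three per-branch NLLs with equal
weights, optimised by Adam (learning rate 1e-3, batch 32, 30 epochs by
default; all config keys). No regularisation by default; dropout on the
hidden dense layer is available.

The network is implemented directly on NumPy: convolution as stride-tricks
patch extraction + GEMM with hand-written backward passes. Arithmetic
defaults to float32; a float64 switch exists and is what the
finite-difference gradient checks use. Two consequences worth knowing:
training is deterministic per seed on one device (bitwise-equal histories),
and the final-conv activations together with the exact gradient of any
pre-softmax class score with respect to them are ordinary return values
(`MultiBranchModel.conv_tap`), which is precisely what Grad-CAM needs. The
first conv layer skips its input-gradient computation (nothing below
consumes it) and evaluation runs in minibatches; both are pure optimisations.

## Signed Grad-CAM and interval segmentation

For trial $x$, branch $b$ and target class $c$ (the trial's **true** label by
default — attribution measures contribution to the *correct* decision; a
predicted-class mode exists), the per-filter weight is the global average of
$\partial y^c / \partial A^k$ over the final conv map, and the saliency map is
the **signed** weighted sum $\sum_k \alpha_k A^k$ — the classic ReLU is
deliberately omitted because negatively contributing (useless) regions are
the object of interest. The conv-resolution map is linearly interpolated to
grid-and-time resolution, read out at each placed electrode, and normalised
to unit peak magnitude per trial and branch. Attribution uses the pre-softmax
branch score (softmax saturates gradients).

Because the final conv maps are 1×1 spatially, the upsampled saliency is
constant across electrodes: at this architecture's resolution Grad-CAM
localises *time*, not scalp position. This is a property of the backbone, not
of the implementation.

Maximal runs with value > +θ become useful intervals; runs < −θ useless ones;
runs shorter than a minimum length are discarded. Defaults: **θ = 0.35,
minimum run 64 samples (256 ms)**. These were calibrated deliberately:
integer-Hz peak attribution needs roughly a quarter second of signal (the
main lobe of a 32 ms segment is ~8 Hz wide, so shorter runs produce
essentially random peak bins), and saliency values near zero are dominated by
attribution noise. Both are config keys.

A class-stratified tenth of the training trials is sampled for attribution
(proportional allocation, largest remainder, deterministic per seed); all
three branches are attributed and their intervals pooled.

## Frequency tallies and the selection rule

Each interval's electrode segment is mean-removed, zero-padded to 512 samples
and Fourier transformed; the in-band (0.5–100 Hz) frequency of maximal
magnitude, rounded to the nearest integer Hz (ties toward lower Hz), is its
peak frequency. No taper is applied by default (a Hann option exists).
Degenerate segments (shorter than 8 samples, or spectrally empty) are skipped
and counted.

Peaks pool into one *good* (useful) and one *bad* (useless) tally across
trials, electrodes and branches (a per-branch mode exists behind a flag).
The filtering set is `top-20(bad) \ top-100(good)`, both rankings by
descending count with ties toward lower Hz, result sorted ascending. The
1/f background places low frequencies at the top of both tallies, so they
cancel in the difference; the set can never exceed 20 frequencies, and
enlarging the good cutoff can only shrink it. Selected frequencies closer
than 1 Hz are merged to the higher-count member before filtering.

Note one structural property of integer binning: the band holds at most 100
integer bins, so the top-100 good cutoff admits *every* frequency that occurs
in the good tally even once. A nuisance frequency is therefore selected only
if it *never* peaks a useful interval in the attribution sample — a stringent
condition discussed under Limitations.

## Notch filtering

Each selected frequency gets a second-order IIR notch (quality factor 30,
about 1.7 Hz of −3 dB bandwidth at 50 Hz) applied forward and backward
(zero net phase) to the cropped per-trial signal, with 64 samples of reflect
padding against edge transients. Measured on steady-state probe tones the
notch attenuates its centre frequency by well over 26 dB and changes probes
≥5 Hz away by under 3% RMS. The filter family, order and Q are config keys
(an FIR band-stop alternative is included); the family and bandwidth are
design choices — the source method does not specify its filter.

## Evaluation protocol

All trials are pooled, shuffled once with a seeded permutation and split into
k = 10 contiguous folds whose sizes differ by at most one (576 trials → six
folds of 58 and four of 57); each fold validates a model trained on the rest.
Stratification is optional and off by default (the protocol statement is
"randomly"). Reported per stage: per-fold accuracy and kappa, their mean and
standard deviation, and kappa of the pooled confusion matrix (the literature
is ambiguous about which kappa is meant, so both are computed). Kappa is
$(p_o - p_e)/(1 - p_e)$; for balanced four-class folds this reduces to
$(\text{acc} - 0.25)/0.75$. Stages are compared with a classical two-tailed
paired t-test on matched scores (fold-level within a run). Degenerate cases:
identical scores give t = 0, p = 1; constant non-zero differences are flagged
and reported as p < 1e-12.

Within each fold, frequency selection sees only that fold's training trials
(stage-1 model of that fold); the filter is then applied to both the fold's
training and held-out trials for stage 2. The leaky variant (select once on
all data) exists only behind an explicit flag. Stage-2 networks reuse the
stage-1 per-fold seeds, so the two stages share initialisation and batch
order and differ only in their training data — without this the stage
comparison at desk scale is dominated by training noise.

The pipeline writes stage reports, per-fold filter sets, a comparison t-test
and a manifest (config digest + completed stages) under the output directory;
re-running with `resume` skips completed stages byte-identically and
recomputes only what is missing. More than two stages (iterative refinement)
are supported via `stages=N`; iteration risks removing genuine signal and is
not part of the validated surface.

## Synthetic data generator

The generator emulates the features of cue-aligned MI data that this method
actually consumes, with known ground truth:

* **1/f background** — white noise spectrally shaped to power ∝ 1/f
  (exponent 1.0), std 1 µV per electrode, independent across electrodes.
  This reproduces the low-frequency dominance that motivates the set
  difference rule.
* **Cue-locked class bursts** — one Hann-windowed sinusoid per trial at the
  class band (10 Hz on C3 for left hand, 10 Hz on C4 for right hand, 22 Hz on
  Cz for feet, 7 Hz on Fz for tongue), onset 0.45–0.6 s after the cue,
  duration 300–500 ms, 10 µV at the focal electrode and 0.6 of that on every
  other electrode (volume conduction). Cue-locked latency is what makes the
  response *event-related*; it also gives the network a stable temporal
  target.
* **Interference episodes** — class-irrelevant 50 and 35 Hz tones, 6 µV ± 20%
  on all electrodes, one episode per trial of 300–450 ms starting within
  80 ms of the cue — the timing of cue-evoked artifacts (reflexive blink,
  startle muscle tension) that precede the imagery response. Timing and
  amplitude distributions are identical across classes. A continuous-tone
  mode exists.

Everything is deterministic per seed. A trivial linear classifier on
ground-truth band powers exceeds 90% accuracy on the default configuration,
so the network has real signal to find; artifact-band energy passes a KS test
for class-independence.

What the generator does **not** model: volume conduction with realistic head
geometry (the spread factor is uniform), non-stationary rhythms, inter-trial
and inter-subject variability beyond amplitude jitter, ocular/muscle
artifacts with their true spectra, or electrode drift. Passing tests on this
generator therefore demonstrate the pipeline's mechanics and its behaviour
under the method's stated assumptions — not performance on real recordings.

## Numerical and degenerate-input choices

* Peak extraction ties break toward the lower frequency at every ranking
  step; constant (DC-only) segments raise a no-peak error because the band
  excludes 0 Hz.
* An all-zero gradient map yields an all-zero saliency map with a warning
  rather than an error.
* Fold, sampling and per-fold training seeds all derive deterministically
  from one master seed and stay below 2³¹.
* Conv output dims use ceil division, so only a zero-sized input dimension
  can make a layer degenerate; this is rejected at spec time.
* Training aborts with the epoch number if the loss becomes non-finite.

## Limitations

* **Exact-bin nuisance recovery is fragile.** With integer bins the set
  difference demands zero leakage of a planted frequency into the good
  tally across roughly a thousand intervals per run. The attribution maps of
  this small backbone (final conv 1×1 spatially; 5 time cells on LRF) have
  limited temporal precision — their correlation with the true burst window
  is roughly 0.2–0.5 per branch at desk-scale training — so a planted tone
  peaks at least one nominally useful interval in most runs and is then
  excluded from the filter set, or survives only via a ±1 Hz neighbour bin.
  In repeated-seed measurements both planted tones land in the filter set
  (±1 Hz) in a minority of runs, while class-informative band centers are
  *never* selected for filtering. The end-to-end effect — stage 2 at least
  as accurate as stage 1 — is nonetheless the majority outcome across seeds,
  because the selected sets are dominated by interference neighbourhoods and
  narrow notches at spurious bins are nearly harmless.
* **The method presupposes temporal disjointness.** Interference that
  co-occurs with the informative response lands in the good tally and is
  protected from filtering; the generator's artifact timing makes this
  assumption explicit rather than hiding it.
* **Short-window peak attribution is information-limited below ~3 Hz**: a
  0.5 s window holds less than two cycles at 2 Hz, and a sub-cycle (sine
  phase) segment can shift the mean-removed FFT peak by one bin.
* Desk-scale accuracy figures (3-fold, 10 training epochs, 160 trials) are
  far below what full training on real recordings achieves and are meant
  only for direction and mechanism checks.
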