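# Methods

This note documents the models, the synthetic data, and the numerical and
design choices behind `ethoseg`, in the spirit of a methods appendix: what
is computed, under which assumptions, and what the desk-scale results do and
do not demonstrate.

## Problem setting

Bio-loggers on marine animals record tri-axial acceleration (g) and angular
velocity (deg s⁻¹) at 20 Hz and pressure at 1 Hz. Given video-annotated
deployments, the task is *per-timestep behavior segmentation*: assign one of
seven ethogram classes (Breathing, Feeding, Gliding, Resting, Scratching,
Swimming, Other) to every 20 Hz sample. The scientific question the package
operationalizes is whether a model pre-trained on a data-rich source species
can be fine-tuned to a data-poor target species (cross-species transfer
learning), and which layers must be fine-tuned for the transfer to work.

## Segmentation networks

Two 1-D fully convolutional encoder–decoder families are implemented from
scratch in numpy (forward pass, backpropagation, Adam), with named parameter
groups so transfer surgery is explicit:

* **V-Net** (3 pooling levels): 3 encoder blocks of two kernel-3 convs,
  a two-conv bottleneck, 3 decoder blocks of two convs, and a kernel-1
  segmentation head — 15 convolutional layers. Downsampling is max-pooling
  by 2; upsampling is non-learned nearest-neighbour repetition, so neither
  enters the conv census.
* **U-Net** (4 levels): 4 encoder blocks of two convs, a two-conv
  bottleneck, 4 decoder blocks of (learned kernel-2 stride-2 up-conv + two
  convs), and a kernel-1 head — 23 convolutional layers.

Shared conventions: stride 1, same-padding, ReLU; feature counts double per
level from the base `depth`; skip connections concatenate encoder features
onto the upsampled decoder path; the head emits `nb_behaviors` logits per
timestep, softmaxed into a probability distribution. Output length always
equals the input window length. Batch normalization is deliberately absent:
its running statistics would blur the freeze audit (a "frozen" group would
still change state during fine-tuning).

Weight init is fan-in-scaled uniform, seeded. A fixed per-channel
standardization (mean/s.d. estimated on the training split) is stored as a
buffer in the model and applied before the first convolution; it travels
with the weights, so a transferred model standardizes target data with its
source statistics, exactly as a practitioner shipping a pre-trained model
would. Without it the raw channel scales (±1 g acceleration vs ±40 deg s⁻¹
gyroscope) leave the small desk-scale networks effectively untrainable.

## Losses and training

**Generalized Dice loss** (V-Net family): with one-hot targets `r` and
probabilities `p` over all timesteps in a batch,

    GDL = 1 − 2 · Σ_l w_l Σ_n r_ln p_ln / Σ_l w_l Σ_n (r_ln + p_ln),
    w_l = 1 / (Σ_n r_ln + ε)²,  ε = 1e−6.

The inverse-square class weights keep gradient pressure on rare behaviors.
One numerical caveat matters in practice: a class absent from a batch would
receive weight 1/ε² ≈ 10¹², the denominator is then dominated by that
class's predicted mass, the loss pins at 1 and every gradient vanishes
(observed at ~10⁻¹⁹). Absent classes therefore get weight 0 — the loss
stays in [0, 1], is 0 at perfect prediction, and remains finite for
degenerate targets. The U-Net family trains with per-timestep categorical
cross-entropy. Gradients of both losses are propagated through the softmax
analytically and were verified against central finite differences.

Training regenerates a fresh class-balanced window batch every epoch from an
epoch-derived seed; validation windows are generated once with a fixed seed
so per-epoch checkpoint comparisons see identical data. The checkpoint
metric is macro F1 over validation windows (the headline metric of the
analysis); the best-epoch weights are restored at the end. Optimizer state
is reset (not transferred) when fine-tuning. Everything is reproducible from
`(model seed, config seed)`; repeated runs derive their seeds from one
master seed.

Full-scale printed configurations are kept as constants
(`PAPER_PRETRAIN_VNET`: 30 epochs, lr 1e−4, GDL; `PAPER_PRETRAIN_UNET`: 50
epochs, lr 1e−3, cross-entropy; `PAPER_FINETUNE`: 20 epochs, lr 1e−4,
batch 32; 6000 training / 3000 validation windows per epoch; V-Net on
7×800 windows, U-Net on 6×224).

## Windowing

*Balanced training windows*: the generator cycles round-robin over the
behavior classes; each turn picks a uniformly random onset (run start) of
that class anywhere in the training recordings and places the window
uniformly among positions containing that onset, within one contiguous
segment (windows never span an excision cut). Minority classes are thereby
over-sampled relative to their time share; classes that cannot host a
window anywhere are dropped with a logged warning and their quota
redistributed.

*Test windows*: each full recording is cut into consecutive windows with
10% overlap (stride = round(0.9·WS)); a final window is right-aligned to
the segment end so every sample is covered without zero-padding.
Per-window probabilities are reassembled by per-sample averaging over all
covering windows — symmetric and order-independent, and means of
distributions remain distributions. Decoding is argmax with ties (counted)
broken toward the lowest class index.

## Preprocessing

Pressure is first-differenced at 1 Hz and linearly upsampled to 20 Hz.
Each difference `d[i] = p[i+1] − p[i]` is anchored at the end of its
interval; the first/last differences are held constant over the boundary
seconds so the output has exactly 20 samples per pressure sample and stays
aligned with the other channels. Acceleration and gyroscope channels are
used raw. Label intervals are half-open `[start, end)` with boundary ties
going to the later interval, which preserves duration conservation when
intervals abut. Unlabeled stretches (night gaps) are excised; the cut
positions are retained and respected by all windowing.

## Evaluation

All test metrics are computed on reassembled full-length tracks, never on
isolated windows. From the pooled confusion matrix over test individuals:
global accuracy (correct/total; the one-vs-rest aggregate
(ΣTP+ΣTN)/(ΣTP+ΣTN+ΣFP+ΣFN) is also reported as `ovr_accuracy`), per-class
precision, recall and F1, macro F1 (unweighted over classes with any true
or predicted instance — the imbalance-robust headline score; a
support-weighted F1 is emitted for comparison), and per-individual time
budgets (share of labeled time per predicted class). Zero-denominator
precision/recall is defined as 0.

## Synthetic two-species data

The generator emulates the statistical structure the pipeline assumes,
not turtle biomechanics:

* **Bout scripting** — a semi-Markov process: no immediate
  self-transitions, log-normal bout durations (Breathing median 8 s …
  Resting median 80 s), and class-selection weights solved by fixed-point
  iteration so stationary *duration shares* match the prescribed prevalence
  weights. Prevalence defaults mirror the two real deployments
  proportionally: the source species is resting-dominant, the target
  feeding-dominant with "Other" at 0.1% of time.
* **Signal rendering** — gravity projection (pitched per behavior) plus a
  sinusoidal carrier on behavior-specific axes gated by a duty-cycle burst
  envelope (swimming: continuous 0.8 Hz strokes; scratching: faster and
  burstier), AR(1) posture drift, white measurement noise; feeding
  alternates motion bursts with quiet chewing oscillation; breathing ramps
  the 1 Hz pressure channel to the surface and back.
* **Species divergence** — the target species shares the carrier structure
  with carrier frequencies ×1.2, amplitudes ×0.8 and a ~7° posture shift.
  This was calibrated once so that zero-shot transfer is clearly degraded
  (seed-dependent, from near chance up to ~37% macro F1) while the shared
  structure still gives fine-tuning something to transfer, matching the
  premise of two closely related species; with much harsher divergence the
  transfer question becomes vacuous.
* **Individuals** — per-individual log-normal frequency/amplitude jitter
  (10%), one contiguous unlabeled "night" gap (10% of samples), and
  hierarchical seeding (one child seed stream per individual) so any
  recording regenerates in isolation.

A sanity floor guarantees the task is solvable: a trivial periodogram
peak-ratio classifier separates 10 s swimming clips from resting clips with
100% accuracy on default profiles.

What the generator does **not** emulate: hydrodynamics, device-attachment
artifacts, annotation noise, within-bout non-stationarity, or realistic
inter-individual behavioral repertoires. Passing results on synthetic data
demonstrate that the pipeline's machinery (balancing, training, transfer
surgery, reassembly, metrics) behaves as designed — they are not evidence
about real turtle data, and the published real-data F1 values are not
reproduction targets here.

## Desk-scale experiment conditions

The experiment grid runs on one CPU by shrinking the *scale*, never the
*design*: 13 source / 6 target individuals (3/1/2 target split by
individual), balanced windows, 10% overlap evaluation, best-on-validation
checkpointing, 10 seeded repeats per arm. Sizes: 1200 s per source and
600 s per target individual; V-Net analogue with WS=64 (3.2 s), depth 8;
pre-training 30 epochs × 1500 windows, best of 3 candidate initializations
selected by source-validation macro F1 (a pre-trained model stands for a
vetted published artifact, so it is selected on its own species' data);
fine-tuning/scratch 20 epochs × 600 windows with 300 validation windows;
batch 32; Adam, lr 1e−3; Generalized Dice. The cross-taxon arm uses a 6-channel, 6-class U-Net analogue (WS=32,
depth 4, cross-entropy) adapted to the 7-class target by head replacement.

Under these conditions (canonical master seed, 10 repeats per arm) the
three qualitative findings of the study design reproduce: fine-tuning the
pre-trained model beats training from scratch on mean test macro F1;
transfer learning shrinks the run-to-run spread caused by weight
initialization; and zero-shot application of the source model trails the
fine-tuned pipeline. At desk scale these orderings are not universal across
synthetic dataset draws: the target training set is large enough, relative
to the shrunken model, that a lucky scratch initialization occasionally
matches or beats fine-tuning on other draws. The full-scale regime the
study describes (much more source data, far larger models, a vetted source
model) makes the ordering sharper than this desk-scale analogue can.

## Known limitations

* The numpy networks are CPU-bound; the full published scale (depth 32,
  WS 800, 6000 windows × 20–30 epochs × 20 repeats) is supported by the
  code but impractical without an accelerator backend.
* GDL batch-level weighting means the effective class weights vary with the
  batch composition produced by the balancing generator.
* The semi-Markov sampler treats bout durations as independent of the
  preceding behavior; real ethograms have structured transition kernels.
* Argmax decoding ignores temporal smoothness; no post-hoc smoothing (e.g.
  HMM decoding) is applied.
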