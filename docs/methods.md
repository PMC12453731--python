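# Methods

## Problem and pipeline

The package classifies one cardiac cycle at a time as normal or
abnormal from a pair of synchronized waveforms: an ECG channel
(electrical activity) and a PCG channel (heart sounds). Records are
z-scored per channel over their whole duration, then cut at consecutive
S1 onsets — S1 marks mitral/tricuspid valve closure at the start of
systole, shortly after the ECG R peak, so the S1-to-S1 interval frames
one complete cycle — and each cycle is linearly resampled on the time
axis to a fixed length (1 s, 2,000 samples at 2,000 Hz). Segmentation
consumes S1 annotations; it does not perform heart-sound detection.

Slices are half-open `[s_i, s_{i+1})` with 0-based sample indices, so
adjacent beats share no samples. Normalization precedes segmentation
(per-record statistics). Intervals outside 0.1–3 s are skipped with a
log message: such intervals are annotation glitches, and a hard failure
would discard an otherwise usable record. Per-beat resampling is linear
interpolation — shape-preserving at the sub-3× ratios involved, and
cheap; endpoints are preserved exactly.

Cross-validation folds are assigned at the segment level (stratified by
label, shuffled under a pinned seed) because the source data do not
identify subjects, making subject-level splitting infeasible. A
record-grouped mode (`group_by_record=True`) is provided for stricter,
leakage-free evaluation; it is off by default to match the evaluation
protocol the experiments use. Note that segment-level splitting lets
beats of one record appear on both sides of a split, so its accuracies
are optimistic relative to record-level generalization.

## Network

Three branches: two architecturally identical but weight-independent
modality encoders and a progressive fusion branch.

**Encoder.** Four levels; each is one CBR block (conv k=7 → batch norm
→ ReLU) followed by two SE-ResNet blocks. Each level downsamples
exactly once, in the CBR convolution (stride 5 at levels 2–4), with the
ResNet convolutions at stride 1 — repeating the stride in every
convolution of a level would collapse a 2,000-sample input to under
one sample, and the single-downsample chain is the one under which the
raw-signal pooling windows (5, 25) land exactly on the level-3/4 input
lengths (400, 80). Channels are 64/128/192/256, lengths
2000/400/80/16. The SE gate uses reduction ratio r=16 (the standard
default).
At levels 3 and 4 the raw 1-channel input, average-pooled by a window
equal to the product of the preceding strides (5 and 25), is added to
the level *input*, broadcast across feature channels by replication — a
parameter-free addition; a learned 1×1 projection was considered and
rejected to keep the injection parameter-free. Biases are disabled on convolutions followed by BN.

**Fusion (SACMF).** Per level: concatenate the two modality features
(2C channels); spatial attention = 1×1 conv to `max(2C/4, 8)` channels
→ ReLU → k=16 conv (asymmetric same padding 8/7, since 16 is even) →
ReLU → 1×1 conv to 2 channels → sigmoid, giving one weight map per
modality; each modality's features are rescaled by its map and
re-concatenated (`V_s`). Channel attention is SE-style with bottleneck
ratio 16. Fusion with the previous level pools the previous fused map
by 5 (matching the encoder stride) to the current length, concatenates
it with `V_c`, and applies BN → conv(k=7) → ReLU, in that order by
default (a conv-first alternative is available via
`fuse_bn_first=False`). Level 1
has no history input. Fused channel counts equal the encoder channel
counts per level, so the final fused map is (16, 256).

**Head.** conv(k=3, s=2) → GAP → dense 128/64/32, each with ReLU and
dropout 0.5 → dense 2 → softmax. Dropout is identity at inference.

**Variants.** `full`; `single_ecg`/`single_pcg` (one encoder → head);
`early_fusion` (both signals stacked as a 2-channel input to one
encoder; the raw-injection signal is the channel mean); `late_fusion`
(level-4 concat → BN → conv → ReLU → head); `only_last_sacmf` (one
SACMF at level 4, no history); `concat_only`, `sa_only`, `ca_only`
(attention branches replaced by identity). `concat_only` is exactly the
full model with both attention branches forced to identity — asserted
at activation level under shared weights in the tests.

## Training protocol

Adam from lr 0.01; lr ×0.1 when the training loss has not strictly
decreased (tolerance 0, configurable) for 5 consecutive epochs, with
the stall counter reset after each decay (no cooldown); stop after 20 consecutive non-improving epochs
or 100 epochs. Batch 32 train / 128 eval. Cross-entropy with class
weights `w_c = N_total / (K·N_c)` — normalized so balanced data gives
unit weights; among the many "inversely proportional" scalings only the
ratio affects gradients. He initialization on conv and dense weights
(undefined for BN, which keeps γ=1, β=0). The L2 coefficient defaults
to 1e-4 (configurable), applied as a classic ridge gradient
on conv/dense weights only, and the monitored training loss is the data
term. The decision threshold for confusion metrics is 0.5 on the
positive-class softmax probability.

All computation is float32 numpy through a small reverse-mode autodiff
engine (`cardiofuse.nn`); convolution is im2col + matmul. Gradients of
every layer type are verified against float64 central finite
differences. Training is bit-reproducible under a fixed seed (single
thread; BLAS reductions are deterministic for these shapes).

## Synthetic data

The generator emulates the target regime — synchronized two-channel
stethoscope recordings at 2,000 Hz — not cardiac physiology:

* ECG beat: five Gaussian deflections (P, Q, R, S, T) at fixed phases
  of the RR interval, R the global maximum. The beat spans one RR
  interval starting just before R, so S1 (R + 50 ms electromechanical
  delay) falls near the beat start and S2 near 40 % of the interval.
* PCG beat: Gaussian-enveloped cosine packets for S1 (50 Hz) and S2
  (60 Hz); the S1 envelope peaks exactly at the annotated onset sample.
* Class structure: abnormal records get a raised-cosine ST-segment
  offset on the ECG (`ecg_effect`) and/or a 100–300 Hz band-passed
  noise murmur filling the systolic interval on the PCG (`pcg_effect`).
  Random draws are consumed identically for both classes, so zeroing an
  effect reproduces the normal record bit for bit, and systolic energy
  is monotone in `pcg_effect` under paired seeds.
* Beat-to-beat variability: multiplicative lognormal RR jitter
  (σ = `hr_jitter`, strictly positive intervals); i.i.d. Gaussian
  sample noise per channel (`noise_sd`).

Defaults: 75 bpm, jitter 0.05, 10 beats/record, noise 0.05, effects
0.3. Presets: `easy` (effects 0.8, noise 0.02) for learnability checks;
`ecg_only`/`pcg_only` for single-modality-informative data; and a
*complementary* builder where half the abnormal records are abnormal
only in the ECG and half only in the PCG, so each single-modality
classifier tops out near 75 % while a fused model can reach 100 %.

What the generator does **not** emulate: real murmur taxonomy,
baseline wander, respiration, electrode/stethoscope artifacts,
inter-patient morphology variation. Passing tests therefore demonstrate
that the architecture, optimization and protocol work as specified and
that fusion exploits complementary structure — not clinical-grade
performance on real recordings.

## Problem sizes for the desk-scale experiments

Training-based checks run the same architecture at reduced width —
channels 8/16/24/32, SE and channel-attention ratios 4, head 32/16/8,
inputs resampled to 500 samples (the stride chain needs a multiple of
125) — chosen as the package's standard single-CPU experiment scale:

* Learning capacity: 40 records × 10 beats (`easy` preset), stratified
  75/25 split, ≤30 epochs; the fused model is expected to reach ≥95 %
  held-out accuracy (majority of 3 seeds). Typical runs reach 100 %
  within ~5 epochs.
* Fusion ordering: 48 complementary records × 8 beats, stratified 50/50
  split, ≤40 epochs, 3 seeds; mean accuracies are compared
  directionally (full ≥ each single modality; one-modality-zeroed
  inference stays above chance and within 5 points of the retained
  single-modality model). Single-seed missing-modality accuracy is
  volatile — a run occasionally sits at chance — which is why the
  comparison is made on seed means.
* Structural checks (shape contract, closed-form attention limits,
  concat/identity equivalence) run the full-scale model
  (2,000-sample input, channels 64/128/192/256).

## Known limitations

* The numpy engine is single-threaded and orders of magnitude slower
  than a GPU framework; full-scale training (≈14k segments, width-256
  model, 100 epochs) is out of reach here, so the package validates
  directional and structural properties at desk scale rather than
  clinical-scale accuracies.
* WFDB support covers format 16 with gain/baseline and named channels —
  the subset the pipeline reads and writes — not the full spec.
* Missing-modality inference uses zero inputs exactly as specified;
  batch-norm statistics are not re-estimated for the zeroed branch,
  which is a known source of the volatility noted above.
* Noisy-record exclusion is configuration: `build_dataset`
  accepts an exclusion list and defaults to empty, so real-data segment
  counts depend on the list supplied.
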