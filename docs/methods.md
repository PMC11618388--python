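# Methods

## The detection model

The baseline is the standard small single-stage detector family: a CSP
(cross-stage-partial) backbone with a 6×6/stride-2 stem, four
stride-halving stages each followed by a C3 block (repeats 1/2/3/1 after
the 0.33 depth multiplier; widths 32/64/128/256/512 after the 0.50 width
multiplier), an SPPF pyramid pool, an FPN+PAN neck, and a three-scale
anchor head (three anchors per scale at strides 8/16/32, one output
channel group of x, y, w, h, objectness and per-class scores per anchor).
With one class this graph holds 7,022,326 learnable scalars; folding each
conv+BN pair into a biased convolution for deployment removes exactly one
scalar per BN channel (9,504 in total), giving 7,012,822. Both counts are
computed by `count_parameters`, the second by actually performing the
fusion on a copy and counting what remains.

### The C3f-RN block

The improved backbone replaces all four C3 stages with C3f-RN, a
dual-branch block whose internal widths were fixed by exact parameter
reconstruction (below). For a stage of width `c` with `n` repeats:

* both branches open with a 1×1 conv+BN+SiLU keeping width `c`, then
  split into halves of `c/2`;
* branch one: one half bypasses, the other passes `n` bottlenecks (two
  3×3 conv+BN+SiLU each, identity shortcut, SimAM tail); concat, 1×1
  conv back to `c`;
* branch two: one half passes `2n` bottlenecks whose shortcut alternates
  (residual, plain, …), the other passes a 3×3 conv and the attention
  stage; concat (`c/2 + 64` channels), 1×1 conv back to `c`;
* the attention stage: patch partition of size 1 (a reshape), linear
  embedding as a 1×1 conv+BN onto a fixed 64-channel space shared by all
  four insertion points, then an even stack (depth 2) of pre-norm
  windowed multi-head self-attention blocks alternating plain and
  shifted windows (shift ws//2, cyclic roll with masked attention at the
  seams), each with qkv/projection linears with bias, a 4× MLP with
  GELU, and a per-head relative position bias table of (2·ws−1)²
  entries. Non-divisible maps are zero-padded on the right/bottom to a
  multiple of the window and cropped after the inverse tiling;
* merge: both branch outputs are projected by 1×1 convs and summed, then
  pass a switchable atrous convolution (one weight-standardised 3×3
  kernel evaluated at dilations 1 and 3 — the second branch adds a
  learned weight delta — blended per pixel by a switch head of 5×5
  average pool + 1×1 conv + sigmoid, with global-context 1×1 convs
  applied before and after) wrapped in BN+SiLU, and finally coordinate
  attention (directional average pooling along H and along W, a joint
  1×1 reduction to `max(8, c/32)` channels with BN and hard-swish, and
  two sigmoid-gated 1×1 expansions producing the height and width
  gates).

Every sub-path preserves the spatial extent, so the block is a drop-in
replacement for any same-width stage; the neck and head are untouched
(asserted by diffing the two graphs).

### How the wiring was fixed

The original system's description of the block specifies its topology
but not its widths. We treated its reported parameter-count grid as an
exact oracle: the counts across window sizes and head counts satisfy
`count = 21,990,898 + 8·n_heads·(2·ws−1)²` (eleven of twelve grid points
are consistent; the remaining one is arithmetically incompatible with
every neighbour and was discarded as a misprint). An exhaustive search
over structural variants — hidden-width ratio, bottleneck conv kinds,
branch-two repeat count, embedding width, attention-block internals, and
the SAC/coordinate-attention sub-structures — has exactly one solution
that both reproduces the full grid and keeps every component in its
reference form (standard attention block, reference SAC with weight
standardisation and both context convs, reference coordinate attention at
reduction 32): the wiring described above, with full-width branch hidden
channels, a fixed 64-channel embedding, and `2n` interleaved bottlenecks
on branch two. The package asserts all twelve usable grid points exactly.

The same accounting explains an apparent inconsistency in the baseline
counts reported for the original system: 7,022,326 and 7,012,822 are the train-time and
deploy-time (BN-folded) counts of one identical graph, 9,504 = ΣBN
channels apart; the same identity holds for the 20-class variant
(7,073,569 vs 7,064,065).

### FLOPs convention

`count_flops` reports 2 × multiply-accumulates of convolution and linear
layers only, measured by instrumented forward at a small probe resolution
and scaled quadratically (exact for convolutional graphs). The baseline
at 640 gives 15.75 GFLOPs. Attention matrix products, normalisations and
activations are excluded — the convention of the common profilers — so
FLOP figures for attention-bearing variants are comparable only under
the same convention.

## Training

Composite loss: CIoU on matched boxes, BCE objectness against the
clipped CIoU of the assigned target (balance 4.0/1.0/0.4 over the three
scales), BCE classification only when nc > 1. Targets are assigned to
anchors by the shape-ratio filter (max ratio < 4) with 0.5-cell
neighbour expansion. Optimiser: SGD, momentum 0.937, weight decay 5e-4,
cosine decay from lr0 with a 50-step linear warmup; best checkpoint by
validation AP is retained. There is no EMA and no mixed precision; the
generator pre-builds augmentations instead of applying them on the fly.

## Channel pruning

Sparsity is an explicit subgradient step — `grad(γ) += λ·sign(γ)` for
every prunable BN scale, applied between backward and the optimiser step
— so λ (default 0.002; preset grid 0.001–0.005) is exactly the L1
coefficient. The pruning threshold is the global r-quantile (default
r = 0.8; preset grid 0.1–0.9) of |γ| pooled over prunable channels.
Surgery operates on explicit producer/consumer *prune groups*; the
prunable set covers bottleneck hidden channels, the C3 partial paths,
SPPF's pooled width, the attention-stage entry convs and the
coordinate-attention reduction. Channels that feed residual additions,
channel splits or the branch sum are structurally coupled and are
protected instead of jointly masked — a deliberately conservative
policy; at least 8 channels (configurable) are kept per layer. The
cumulative removal census reported for the original system depends on
weights trained on an unreleased dataset and is not a reproduction
target; what
the package reproduces is the pipeline's behavioural signature
(γ-shrinkage under sparsity, removal fraction ≈ r, masked-equivalence on
shortcut-free paths, parameters dropping only at the prune stage, AP dip
and recovery).

## The synthetic generator

`generate_scene` renders: a green canopy base with soil patches and leaf
ellipses; per plant a stem and an umbel of 15–40 overlapping red
ellipses (radius 2–6 px at 640², floored at ~1.2 px at small sizes);
leaf occluders drawn over the fruit until a per-umbel target fraction
(Gaussian around the spec's occlusion level) is covered; a global
illumination gain drawn from [0.5, 1.5]. Boxes are fitted to the visible
fruit pixels (largest connected clump, greedily trimmed until at least
half the box is fruit), and clusters with less than 10% of their pixels
visible are left unlabelled — the annotation rule for heavily occluded
fruit. Generation is a pure function of the spec (including its seed).

What the generator emulates: dense red-on-green clusters, partial
occlusion, scale and illumination variation, negative samples, the exact
label geometry. What it does not: photorealistic texture, camera noise
and blur, wind motion, immature (green) fruit, background red
distractors. Desk-scale training results on these scenes therefore
demonstrate that the architecture, loss, assignment and evaluation
machinery learn and measure correctly — not that field-level accuracy
transfers.

## Problem sizes in the test suite

The original system trained for 200 epochs at 640² on GPU hardware; the
test suite exercises the same code paths at sizes chosen for a single
CPU. The end-to-end check trains the width-0.125 attention variant at
96² on 200 generated scenes (160/40 split) for at most 30 epochs with
early stopping once held-out AP@0.5 exceeds 0.55; under the fixed seeds
it passes 0.9 within ~12 epochs. The compression check uses a four-conv
single-scale toy detector at 64² (110 scenes), where the full
sparse→prune(r=0.5)→fine-tune cycle recovers the unpruned AP exactly.
Numerical notes: batch-norm eps 1e-3 / momentum 0.03; layer-norm eps
1e-5; SimAM stabiliser 1e-4; NMS ties broken by (confidence, then box
area) for order-independence; AP integrated exactly over the monotone
envelope ("all points" scheme) rather than any sampled approximation;
headline P/R reported at the F1-maximising confidence.

## Known limitations

* The compute core is single-threaded numpy; wall-clock scale is desk
  scale by design. Real-data training at 640² is out of reach here.
* Pruning protects coupled channels rather than masking them jointly, so
  the achievable compression on the full detector is lower than a
  coupled-mask implementation would give.
* The inference-time, fps and model-size-on-disk figures of the original
  system are hardware- and serialisation-bound and are not modelled.
* The generator's occluders are shared across the scene, so an umbel can
  be occluded by a neighbour's foliage; per-scene fruit counts track the
  plant count only as occlusion approaches zero.
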