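# ginsengdet

Detection of mature ginseng berries in field scenes. A ginseng fruit is a
dense, umbrella-shaped cluster (umbel) of small red berries sitting on a
stem above green canopy; detecting these clusters reliably under heavy
occlusion, scale variation and changing illumination is the visual front
end of mechanised berry harvesting. This package is a self-contained
reimplementation of a single-class detector built for that task, together
with the compression pipeline that makes it deployable, written for
researchers who want to study the architecture and its accounting at desk
scale rather than run a GPU production system.

Four components:

* **C3f-RN**, a plug-and-play dual-branch feature-extraction block that
  replaces the four cross-stage-partial (C3) stages of a small CSP
  detector backbone (width 0.50, depth 0.33). Each branch splits its
  channels; one half runs through bottlenecks of two 3×3 convolutions
  (with parameter-free SimAM attention at each tail, residual on branch
  one, alternating residual/plain on branch two), while branch two's
  second half passes through a windowed multi-head self-attention stage
  (patch partition + linear embedding onto a shared 64-channel space +
  W-MSA/SW-MSA block pair with per-head relative position bias of size
  (2·ws−1)²). The merged branches are refined by switchable atrous
  convolution (two dilation rates blended per pixel by a learned switch)
  and coordinate attention.
* **Channel pruning** in three stages: L1-sparse training of the
  batch-norm scale factors γ (subgradient λ·sign γ), removal of all
  channels whose |γ| falls below the network-wide r-quantile (with graph
  surgery on producers and consumers), and fine-tuning from the pruned
  weights.
* **Evaluation**: P = TP/(TP+FP), R = TP/(TP+FN) with IoU-0.5 greedy
  matching, and AP@0.5 as the exact area under the monotone envelope of
  the precision/recall curve.
* **A synthetic berry-scene generator** that renders red umbels on
  green/brown canopy with controllable occlusion, scale and illumination,
  emits pixel-accurate YOLO labels (clusters more than 90% occluded are
  left unlabelled), and implements the augmentation set (rotation,
  translation, brightness, simulated occlusion, 4-image mosaic) and the
  7:2:1 dataset split.

Everything runs on a small numpy compute core (reverse-mode autodiff,
convolution/attention layers, SGD) included in the package, so the full
stack — assembly, training, pruning, inference — needs only the
scientific Python base.

## Worked example: exact architecture accounting

```bash
python examples/architecture_accounting.py
```

prints

```
baseline (train form):   7,022,326 parameters
baseline (deploy form):  7,012,822 parameters  (conv+BN folded)
baseline GFLOPs @640:   15.75

attention variant (depth 2) parameter counts:
  heads= 8  window=4x4:  21,994,034
  heads=16  window=4x4:  21,997,170
  heads= 8  window=1x1:  21,990,962
  heads= 1  window=4x4:  21,991,290
  heads= 1  window=7x7:  21,992,250
```

The two baseline figures differ by exactly 9,504 — one scalar per
conv+BN pair, lost when the batch norm is folded into the convolution for
deployment. The attention-variant counts obey the closed law
`count = 21,990,898 + 8·n_heads·(2·ws−1)²`: eight attention blocks
network-wide (four insertion points × depth 2), each holding one
relative-position-bias table per head. These identities pin the entire
block wiring and are asserted exactly in the test suite.

Other examples: `examples/synthetic_scenes.py` (generation, augmentation,
split, YOLO round-trip), `examples/train_and_evaluate.py` (a sub-minute
toy training run; it prints the loss/AP trajectory and the held-out
P/R/AP@0.5), and `examples/compression_pipeline.py` (the four-stage
sparse→prune→fine-tune summary, showing parameters dropping only at the
prune stage and accuracy recovering after fine-tuning).

A thin CLI mirrors the workflow:

```bash
ginsengdet count-params --nc 1 --c3f-rn --n-heads 8 --win-size 4
ginsengdet synth --n 200 --seed 0 --imgsz 256 --out data/
ginsengdet train --data data/ --c3f-rn --width 0.125 --imgsz 96 --epochs 30
ginsengdet eval --weights model.npz --data data/
ginsengdet compress --weights model.npz --data data/ --lambda 0.002 --ratio 0.8
```

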