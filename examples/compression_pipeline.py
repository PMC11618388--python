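"""Three-stage channel pruning on a toy detector: sparse training of BN
scale factors, global-threshold pruning (coefficient r), fine-tuning.

Prints the four-stage summary (AP@0.5, parameters, size, per-image
inference time): parameters drop only at the prune stage, accuracy dips
there and is restored by fine-tuning.
"""

import warnings

from ginsengdet.compress import PruneConfig, ToyDetector, compress_pipeline
from ginsengdet.synthetic import SceneSpec, generate_scene
from ginsengdet.train import train

warnings.simplefilter("ignore", UserWarning)

spec = lambda i: SceneSpec(img_size=64, n_plants=2, occlusion_fraction=0.0,
                           berry_radius=(25, 45), cluster_radius=50,
                           seed=1000 + i)
items = [generate_scene(spec(i)) for i in range(110)]
tr, va = items[:90], items[90:]

hyp = dict(epochs=40, batch_size=8, seed=0, lr0=0.05)
model = ToyDetector(widths=(16, 32, 32, 32), seed=0)
model, _ = train(model, tr, va, hyp=hyp)

model, report, summary = compress_pipeline(
    model, tr, va,
    PruneConfig(lam=0.002, r=0.5, min_channels=4),
    hyp_sparse=dict(hyp, epochs=30),
    hyp_finetune=dict(hyp, epochs=40))

print(f"{'stage':<10} {'AP@0.5':>7} {'params':>8} {'size MB':>8} "
      f"{'ms/img':>7}")
for stage, row in summary.items():
    print(f"{stage:<10} {row['ap']:>7.3f} {row['parameters']:>8} "
          f"{row['size_mb']:>8.2f} {row['inference_ms']:>7.1f}")
print(f"\nremoved {report.channels_removed} of {report.channels_before} "
      f"prunable channels at sparsity 0.002 / coefficient 0.5;")
print("the dip at 'prune' and full recovery after 'finetune' is the "
      "expected signature of magnitude-based channel pruning.")
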