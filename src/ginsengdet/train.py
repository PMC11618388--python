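"""Training loop: SGD on the composite detection loss, per-epoch validation
AP@0.5, best-checkpoint retention.  Deliberately small: no EMA, no mixed
precision, no mosaic-on-the-fly — the generator pre-builds augmentations."""

from __future__ import annotations

import json
import math

import numpy as np

from .loss import DetectionLoss
from .metrics import evaluate
from .model import ModelConfig, YoloModel
from .nn import SGD
from .nn.tensor import Tensor

__all__ = ["train", "default_hyp", "save_checkpoint", "load_checkpoint",
           "make_batches"]


def default_hyp(**over):
    hyp = dict(epochs=30, batch_size=8, lr0=0.01, lrf=0.1, momentum=0.937,
               weight_decay=5e-4, box=0.05, obj=1.0, cls=0.5, anchor_t=4.0,
               seed=0, conf_thr=0.01, warmup_steps=50, early_stop_ap=None)
    hyp.update(over)
    return hyp


def _resize(img: np.ndarray, size: int) -> np.ndarray:
    if img.shape[0] == size and img.shape[1] == size:
        return img
    from .model import letterbox
    return letterbox(img, size)[0]


def make_batches(items, batch_size: int, img_size: int, rng=None):
    """Yield (x, targets) with x (B,3,S,S) in [0,1] and targets rows
    (img_idx, cls, cx, cy, w, h)."""
    idx = np.arange(len(items))
    if rng is not None:
        rng.shuffle(idx)
    for start in range(0, len(items), batch_size):
        sel = idx[start:start + batch_size]
        imgs, rows = [], []
        for bi, i in enumerate(sel):
            it = items[i]
            imgs.append(_resize(it.image, img_size).astype(np.float32)
                        .transpose(2, 0, 1) / 255.0)
            for lab in it.labels:
                rows.append([bi, *lab])
        x = np.stack(imgs)
        t = (np.asarray(rows, dtype=np.float32).reshape(-1, 6)
             if rows else np.zeros((0, 6), dtype=np.float32))
        yield x, t


def _validate_labels(items, name):
    if len(items) == 0:
        raise ValueError(f"{name} dataset is empty")
    for it in items:
        lab = np.asarray(it.labels, dtype=float).reshape(-1, 5)
        if len(lab) and ((lab[:, 3:] <= 0).any() or (lab[:, 1:] < 0).any()
                         or (lab[:, 1:] > 1).any()):
            raise ValueError(f"degenerate label in {name} item {it.name!r}")


def train(model: YoloModel, train_set, val_set, hyp=None, on_step=None,
          ckpt_path=None, quiet=True):
    """Train the detector; returns (model-with-best-weights, log rows).

    ``on_step(model)`` runs after each backward pass and before the
    optimiser step (used by sparse training to add the L1 subgradient on
    BN scale factors).
    """
    hyp = default_hyp() if hyp is None else dict(default_hyp(), **hyp)
    _validate_labels(train_set, "train")
    _validate_labels(val_set, "val")
    size = model.cfg.img_size
    rng = np.random.default_rng(hyp["seed"])
    crit = DetectionLoss(model, box=hyp["box"], obj=hyp["obj"],
                         cls=hyp["cls"], anchor_t=hyp["anchor_t"])
    opt = SGD(model.parameters(), lr=hyp["lr0"], momentum=hyp["momentum"],
              weight_decay=hyp["weight_decay"])
    nb = math.ceil(len(train_set) / hyp["batch_size"])
    log, best_ap, best_state = [], -1.0, None
    step = 0
    for epoch in range(hyp["epochs"]):
        # cosine decay with a short linear warmup
        frac = epoch / max(hyp["epochs"] - 1, 1)
        lr_epoch = hyp["lr0"] * (hyp["lrf"] + 0.5 * (1 - hyp["lrf"])
                                 * (1 + math.cos(math.pi * frac)))
        model.train()
        tot = 0.0
        for x, t in make_batches(train_set, hyp["batch_size"], size, rng):
            step += 1
            opt.lr = lr_epoch * min(1.0, step / max(hyp["warmup_steps"], 1))
            preds = model(Tensor(x))
            loss, parts = crit(preds, t)
            opt.zero_grad()
            loss.backward()
            if on_step is not None:
                on_step(model)
            opt.step()
            tot += float(loss.data)
        res = evaluate(model, val_set, conf_thr=hyp["conf_thr"])
        row = dict(epoch=epoch, loss=tot / max(nb, 1), ap=res.ap,
                   precision=res.precision, recall=res.recall, lr=opt.lr)
        log.append(row)
        if not quiet:
            print(f"epoch {epoch:3d}  loss {row['loss']:8.4f}  "
                  f"AP50 {res.ap:.3f}")
        if res.ap >= best_ap:
            best_ap = res.ap
            best_state = model.state_dict()
        if (hyp["early_stop_ap"] is not None
                and best_ap >= hyp["early_stop_ap"]):
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    if ckpt_path is not None:
        save_checkpoint(model, ckpt_path)
    return model, log


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(model: YoloModel, path):
    """Weights + config + BN state in one npz archive."""
    from dataclasses import asdict

    cfg = asdict(model.cfg)
    cfg["anchors"] = [[list(a) for a in s] for s in cfg["anchors"]]
    state = {f"w::{k}": v for k, v in model.state_dict().items()}
    state["config"] = np.frombuffer(
        json.dumps(cfg).encode(), dtype=np.uint8).copy()
    np.savez_compressed(path, **state)


def load_checkpoint(path) -> YoloModel:
    with np.load(path) as z:
        cfg_d = json.loads(bytes(z["config"]).decode())
        cfg_d["anchors"] = tuple(tuple(tuple(a) for a in s)
                                 for s in cfg_d["anchors"])
        cfg = ModelConfig(**cfg_d)
        model = YoloModel(cfg)
        model.load_state_dict(
            {k[3:]: z[k] for k in z.files if k.startswith("w::")})
    return model
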