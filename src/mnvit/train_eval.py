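"""Training, transfer learning and evaluation of the classifier.

The training recipe follows the study setup: Adam from an initial learning
rate of 1e-3 with cosine decay, batch size 64, 50 epochs, 224x224 inputs —
all exposed through :class:`TrainConfig` so desk-scale runs can shrink the
problem.  Evaluation reports the metric set used throughout the ablations:

* ``Avg_Acc`` — balanced accuracy, the mean of per-class recalls.  A
  constant (collapsed) classifier scores exactly 0.5 on any two-class set,
  which is why this metric is the headline under heavy class imbalance.
* ``F1`` — per-class F1 with a macro average.
* ``ROC`` — area under the ROC curve of the positive-class score.

Metric computation delegates to scikit-learn; checkpoints are ``.npz``
arrays of named parameters with a JSON sidecar carrying the model config.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skm

from . import nn
from .model_zoo import MobileViTMN, ModelVariantConfig, build_model
from .pipeline import load_split_arrays
from .tensor import Tensor, cross_entropy

__all__ = [
    "TrainConfig", "MetricsReport", "TransferReport", "TrainingHistory",
    "balanced_accuracy", "f1_scores", "roc_auc", "evaluate", "train",
    "predict_scores", "save_checkpoint", "load_checkpoint", "load_pretrained",
    "Adam",
]


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 64
    initial_lr: float = 0.001
    epochs: int = 50
    input_side: int = 224
    optimizer: str = "adam"
    lr_schedule: str = "cosine"
    weight_decay: float = 0.0
    seed: int = 0
    freeze_trunk: bool = False
    augment_flips: bool = True   # on-the-fly random h/v flips on train batches

    def __post_init__(self):
        if min(self.batch_size, self.epochs, self.input_side) < 1 or self.initial_lr <= 0:
            raise ValueError("batch size, epochs, input side and lr must be positive")


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def _check_both_classes(labels: np.ndarray):
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined: labels contain a single class")


def balanced_accuracy(labels: np.ndarray, predictions: np.ndarray) -> float:
    """Mean of per-class recalls (Avg_Acc)."""
    labels = np.asarray(labels)
    _check_both_classes(labels)
    return float(skm.balanced_accuracy_score(labels, np.asarray(predictions)))


def f1_scores(labels: np.ndarray, predictions: np.ndarray,
              ) -> tuple[float, np.ndarray]:
    """(macro F1, per-class F1).  An unpredicted class scores 0 with a warning."""
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    _check_both_classes(labels)
    if len(np.unique(predictions)) < 2:
        warnings.warn("degenerate predictions: one class never predicted; "
                      "its F1 is reported as 0", stacklevel=2)
    per_class = skm.f1_score(labels, predictions, average=None, zero_division=0)
    return float(per_class.mean()), per_class


def roc_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Area under the ROC curve of positive-class scores (midrank ties)."""
    labels = np.asarray(labels)
    _check_both_classes(labels)
    return float(skm.roc_auc_score(labels, np.asarray(scores, dtype=float)))


@dataclass
class MetricsReport:
    avg_acc: float
    per_class_recall: list[float]
    f1: float
    per_class_f1: list[float]
    roc_auc: float
    confusion: list[list[int]]
    n: int

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def report_from_outputs(labels: np.ndarray, predictions: np.ndarray,
                        scores: np.ndarray) -> MetricsReport:
    labels = np.asarray(labels)
    cm = skm.confusion_matrix(labels, predictions, labels=[0, 1])
    recalls = [cm[i, i] / max(cm[i].sum(), 1) for i in range(2)]
    macro, per_class = f1_scores(labels, predictions)
    return MetricsReport(
        avg_acc=balanced_accuracy(labels, predictions),
        per_class_recall=[float(r) for r in recalls],
        f1=macro, per_class_f1=[float(v) for v in per_class],
        roc_auc=roc_auc(labels, scores),
        confusion=cm.tolist(), n=int(cm.sum()))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    def __init__(self, params: list[nn.Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps, self.weight_decay = lr, betas, eps, weight_decay
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        bias1 = 1 - b1 ** self.t
        bias2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)


def cosine_lr(initial_lr: float, epoch: int, total_epochs: int) -> float:
    return 0.5 * initial_lr * (1 + np.cos(np.pi * epoch / max(total_epochs, 1)))


# ---------------------------------------------------------------------------
# Inference and evaluation
# ---------------------------------------------------------------------------

def predict_scores(model: MobileViTMN, images: np.ndarray,
                   batch_size: int = 32) -> np.ndarray:
    """Positive-class probabilities for an (N, 3, H, W) array."""
    was_training = model.training
    model.eval()
    out = []
    for i in range(0, len(images), batch_size):
        logits = model(Tensor(images[i:i + batch_size])).data
        shifted = logits - logits.max(axis=1, keepdims=True)
        probs = np.exp(shifted)
        probs /= probs.sum(axis=1, keepdims=True)
        out.append(probs[:, 1])
    model.train(was_training)
    return np.concatenate(out)


def evaluate(model: MobileViTMN, manifest: pd.DataFrame, split: str = "test",
             input_side: int | None = None) -> MetricsReport:
    """Single forward pass over one manifest split -> MetricsReport."""
    side = input_side or model.cfg.input_size
    images, labels = load_split_arrays(manifest, split, side)
    scores = predict_scores(model, images)
    return report_from_outputs(labels, (scores >= 0.5).astype(int), scores)


# ---------------------------------------------------------------------------
# Checkpoints and transfer learning
# ---------------------------------------------------------------------------

def save_checkpoint(model: MobileViTMN, path: str | Path):
    """Write parameters+buffers as .npz with a JSON config sidecar."""
    path = Path(path)
    np.savez(path, **model.state_dict())
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(asdict(model.cfg), indent=2))


def load_checkpoint(path: str | Path, seed: int = 0) -> MobileViTMN:
    path = Path(path)
    cfg_raw = json.loads(path.with_suffix(".json").read_text())
    cfg_raw["transformer_depths"] = tuple(cfg_raw["transformer_depths"])
    cfg = ModelVariantConfig(**cfg_raw)
    model = build_model(cfg, seed=seed)
    npz = path if path.suffix == ".npz" else path.with_suffix(".npz")
    with np.load(npz) as data:
        model.load_state_dict({k: data[k] for k in data.files})
    return model


@dataclass
class TransferReport:
    matched: int
    skipped: list[str]
    reinitialized: list[str]


def load_pretrained(model: MobileViTMN, checkpoint: str | Path,
                    exclude_head: bool = False) -> TransferReport:
    """Copy every checkpoint array whose name and shape match the model.

    Mismatching names or shapes are skipped and reported; with
    ``exclude_head`` the classification head keeps its fresh initialization
    even when the checkpoint's head would fit.
    """
    path = Path(checkpoint)
    if not path.exists():
        raise IOError(f"checkpoint not found: {path}")
    try:
        with np.load(path) as data:
            state = {k: data[k] for k in data.files}
    except Exception as exc:  # corrupt archive
        raise IOError(f"unreadable checkpoint {path}: {exc}") from exc
    own = dict(model.named_parameters())
    own.update({n: None for n, _ in model.named_buffers()})
    matched, skipped, reinit = 0, [], []
    buffer_slots = dict(model._iter_buffer_slots())
    for name in sorted(set(state) | set(own)):
        is_head = name.startswith("fc.")
        if name not in state or name not in own:
            skipped.append(name)
            continue
        if exclude_head and is_head:
            reinit.append(name)
            continue
        src = state[name]
        if name in buffer_slots:
            mod, attr = buffer_slots[name]
            dst = getattr(mod, attr)
            if dst.shape != src.shape:
                skipped.append(name)
                continue
            dst[...] = src
        else:
            p = own[name]
            if p.data.shape != src.shape:
                skipped.append(name)
                continue
            p.data[...] = src
        matched += 1
    return TransferReport(matched=matched, skipped=skipped, reinitialized=reinit)


# ---------------------------------------------------------------------------
# Training loop
# ---------------------------------------------------------------------------

@dataclass
class TrainingHistory:
    epochs: list[dict] = field(default_factory=list)
    best_epoch: int = -1
    best_val_avg_acc: float = -1.0
    checkpoint_path: str | None = None

    def to_jsonl(self, path: str | Path):
        with open(path, "w") as fh:
            for row in self.epochs:
                fh.write(json.dumps(row) + "\n")


def _iter_batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield order[i:i + batch_size]


def train(model: MobileViTMN, manifest: pd.DataFrame, cfg: TrainConfig,
          out_dir: str | Path | None = None,
          eval_val: bool = True) -> TrainingHistory:
    """Fine-tune ``model`` on the manifest's train split.

    Per epoch: shuffled mini-batches, cross-entropy loss, Adam with cosine
    learning-rate decay.  When a val split exists (and ``eval_val``), a
    validation MetricsReport is recorded each epoch and the best-val-Avg_Acc
    checkpoint is saved to ``out_dir``.
    """
    images, labels = load_split_arrays(manifest, "train", cfg.input_side)
    if len(np.unique(labels)) < 2:
        raise ValueError("training data must contain both classes")
    has_val = eval_val and (manifest["split"] == "val").any()
    rng = np.random.default_rng(cfg.seed)
    if cfg.freeze_trunk:
        params = [p for n, p in model.named_parameters() if n.startswith("fc.")]
    else:
        params = list(model.parameters())
    opt = Adam(params, lr=cfg.initial_lr, weight_decay=cfg.weight_decay)
    history = TrainingHistory()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    for epoch in range(cfg.epochs):
        opt.lr = cosine_lr(cfg.initial_lr, epoch, cfg.epochs)
        model.train()
        losses = []
        for batch in _iter_batches(len(images), cfg.batch_size, rng):
            xb = images[batch]
            if cfg.augment_flips:
                xb = xb.copy()
                flips = rng.random((len(batch), 2)) < 0.5
                for k in range(len(batch)):
                    if flips[k, 0]:
                        xb[k] = xb[k][:, :, ::-1]
                    if flips[k, 1]:
                        xb[k] = xb[k][:, ::-1, :]
                xb = np.ascontiguousarray(xb)
            model.zero_grad()
            logits = model(Tensor(xb))
            loss = cross_entropy(logits, labels[batch])
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        row = {"epoch": epoch, "lr": opt.lr, "train_loss": float(np.mean(losses))}
        if has_val:
            rep = evaluate(model, manifest, "val", input_side=cfg.input_side)
            row["val"] = asdict(rep)
            if rep.avg_acc > history.best_val_avg_acc:
                history.best_val_avg_acc = rep.avg_acc
                history.best_epoch = epoch
                if out is not None:
                    ckpt = out / "best.npz"
                    save_checkpoint(model, ckpt)
                    history.checkpoint_path = str(ckpt)
        history.epochs.append(row)
    if out is not None and history.checkpoint_path is None:
        ckpt = out / "last.npz"
        save_checkpoint(model, ckpt)
        history.checkpoint_path = str(ckpt)
    return history
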