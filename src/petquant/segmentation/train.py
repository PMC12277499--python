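"""Training and evaluation for the segmentation backends.

The Swin-UNETR feature stack is frozen at its seeded initialization and the
per-voxel linear readout (the final 1x1x1 convolution) is optimized with
Adam on a combined soft-dice + cross-entropy loss.  Gradients of the loss
with respect to the readout are exact (closed form through the softmax), so
training is deterministic per seed and runs comfortably on a single CPU.
Because the encoder is frozen, per-sample features are computed once and
cached, and each iteration is a pair of matrix products.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..grids import BinaryMask
from ..spatial import dice as mask_dice
from .config import SegmentationConfig
from .swin import SwinUnetr, _softmax

__all__ = [
    "TrainingHistory",
    "train",
    "evaluate",
    "evaluate_label_volumes",
    "IntensityAtlasBaseline",
]


@dataclass
class TrainingHistory:
    loss: list[float] = field(default_factory=list)
    ce_loss: list[float] = field(default_factory=list)
    dice_loss: list[float] = field(default_factory=list)
    dice_iterations: list[int] = field(default_factory=list)
    dice: list[float] = field(default_factory=list)  # mean foreground dice on the dataset


def _one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    return np.eye(n_classes)[labels.reshape(-1)]


def _losses_and_grad(logits: np.ndarray, y: np.ndarray, cfg: SegmentationConfig):
    """CE and soft-dice losses plus d(total)/d(logits); logits/y: (N, K)."""
    n, k = logits.shape
    p = _softmax(logits, axis=-1)
    eps = 1e-7
    ce = float(-(y * np.log(p + eps)).sum() / n)
    d_ce = (p - y) / n

    num = 2.0 * (p * y).sum(axis=0) + eps
    den = p.sum(axis=0) + y.sum(axis=0) + eps
    dice_loss = float(1.0 - (num / den).mean())
    g = -(2.0 * y * den - num) / den**2 / k  # d(dice_loss)/dp
    d_dice = p * (g - (g * p).sum(axis=-1, keepdims=True))  # chain through softmax

    total = cfg.ce_weight * ce + cfg.dice_weight * dice_loss
    grad = cfg.ce_weight * d_ce + cfg.dice_weight * d_dice
    return total, ce, dice_loss, grad


def _foreground_dice(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    scores = []
    for c in range(1, n_classes):
        a, b = pred == c, truth == c
        if not a.any() and not b.any():
            continue
        scores.append(2.0 * np.count_nonzero(a & b) / (np.count_nonzero(a) + np.count_nonzero(b)))
    return float(np.mean(scores)) if scores else 1.0


def train(
    model: SwinUnetr,
    dataset: list[tuple[np.ndarray, np.ndarray]],
    config: SegmentationConfig | None = None,
) -> TrainingHistory:
    """Optimize the readout head on (normalized volume, integer labels) pairs.

    Records the loss at every iteration and the mean foreground dice over the
    dataset every ``eval_every`` iterations.  Zero iterations leave the model
    untouched.  Deterministic for a fixed config seed.
    """
    cfg = config or model.config
    if not dataset:
        raise ValueError("empty training dataset")
    history = TrainingHistory()
    if cfg.iterations == 0:
        return history

    cached = []
    for vol, lab in dataset:
        feats = model.forward_features(np.asarray(vol, dtype=float))
        cached.append(
            (feats.reshape(-1, model.n_features), _one_hot(np.asarray(lab, dtype=int), cfg.n_classes))
        )
    # frozen features: the whole (desk-scale) dataset fits in one batch
    feats = np.vstack([c[0] for c in cached])
    y = np.vstack([c[1] for c in cached])

    W, b = model.head_W, model.head_b
    mW, vW = np.zeros_like(W), np.zeros_like(W)
    mb, vb = np.zeros_like(b), np.zeros_like(b)
    beta1, beta2, adam_eps = 0.9, 0.999, 1e-8

    for it in range(1, cfg.iterations + 1):
        logits = feats @ W + b
        total, ce, dl, grad = _losses_and_grad(logits, y, cfg)
        history.loss.append(total)
        history.ce_loss.append(ce)
        history.dice_loss.append(dl)

        gW = feats.T @ grad
        gb = grad.sum(axis=0)
        for g_, m_, v_, theta in ((gW, mW, vW, W), (gb, mb, vb, b)):
            m_ *= beta1
            m_ += (1 - beta1) * g_
            v_ *= beta2
            v_ += (1 - beta2) * g_**2
            mhat = m_ / (1 - beta1**it)
            vhat = v_ / (1 - beta2**it)
            theta -= cfg.learning_rate * mhat / (np.sqrt(vhat) + adam_eps)

        if it % cfg.eval_every == 0 or it == cfg.iterations:
            scores = []
            for feats_i, y_i in cached:
                pred = np.argmax(feats_i @ W + b, axis=-1)
                scores.append(_foreground_dice(pred, np.argmax(y_i, axis=-1), cfg.n_classes))
            history.dice_iterations.append(it)
            history.dice.append(float(np.mean(scores)))
    return history


def evaluate(pred_masks: dict[str, BinaryMask], label_masks: dict[str, BinaryMask]) -> float:
    """Unweighted mean dice over organs, matching masks by label name."""
    if set(pred_masks) != set(label_masks):
        raise ValueError(
            f"prediction and label organ sets differ: {sorted(pred_masks)} vs {sorted(label_masks)}"
        )
    if not label_masks:
        raise ValueError("no organs to evaluate")
    return float(np.mean([mask_dice(pred_masks[k], label_masks[k]) for k in label_masks]))


def evaluate_label_volumes(pred: np.ndarray, truth: np.ndarray, n_classes: int) -> float:
    """Mean foreground dice between two integer label volumes."""
    if pred.shape != truth.shape:
        raise ValueError("label volumes must share a shape")
    return _foreground_dice(np.asarray(pred), np.asarray(truth), n_classes)


class IntensityAtlasBaseline:
    """Nearest-mean-intensity voxel classifier: the trivial baseline backend.

    ``fit`` records each class's mean normalized intensity over the training
    set; ``predict_labels`` assigns every voxel the class with the closest
    mean.  Useful wherever a fast, transparent segmenter is enough (phantom
    organs have distinct attenuation by construction).
    """

    def __init__(self, n_classes: int):
        self.n_classes = n_classes
        self.class_means: np.ndarray | None = None

    def fit(self, dataset: list[tuple[np.ndarray, np.ndarray]]) -> "IntensityAtlasBaseline":
        if not dataset:
            raise ValueError("empty training dataset")
        sums = np.zeros(self.n_classes)
        counts = np.zeros(self.n_classes)
        for vol, lab in dataset:
            for c in range(self.n_classes):
                sel = lab == c
                sums[c] += vol[sel].sum()
                counts[c] += sel.sum()
        if (counts == 0).any():
            missing = np.flatnonzero(counts == 0)
            raise ValueError(f"classes {missing.tolist()} absent from the training set")
        self.class_means = sums / counts
        return self

    def predict_labels(self, volume: np.ndarray) -> np.ndarray:
        if self.class_means is None:
            raise RuntimeError("baseline is not fitted")
        dist = np.abs(volume[..., None] - self.class_means)
        return np.argmin(dist, axis=-1)
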