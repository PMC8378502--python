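"""Seeded training harness for the dense recurrent segmenter.

Optimisation is plain Adam on the analytic gradients from
:func:`cineseg.dense_rnn.loss_and_grads`.  Every source of randomness —
parameter initialisation, batch order, start-frame rotations — is drawn
from generators derived from one seed, so a run is fully reproducible.

Start-frame augmentation cyclically rotates each training sequence to a
random start frame; this is valid because phantom sequences span whole
cardiac cycles, so a rotated sequence is another plausible acquisition
of the same heart.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dense_rnn import DenseRNNModel, forward, loss_and_grads
from .evaluation import evaluate_sequence
from .phantom import LabeledSequence

__all__ = [
    "TrainConfig",
    "MetricTrace",
    "rotate_start",
    "train",
    "train_ablation_pair",
]


@dataclass(frozen=True)
class TrainConfig:
    iterations: int = 300
    learning_rate: float = 1e-2
    batch_size: int = 4
    seed: int = 0
    augment_start_frames: bool = True
    eval_every: int = 10
    hidden_channels: int = 16
    kernel_size: int = 3
    loss_reduction: str = "mean_pixels_sum_frames"
    holdout_fraction: float = 0.05
    dense: bool = True

    def validate(self) -> None:
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be > 0, got {self.learning_rate}")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.loss_reduction != "mean_pixels_sum_frames":
            raise ValueError(f"unknown loss_reduction {self.loss_reduction!r}")


@dataclass
class MetricTrace:
    """Per-evaluation rows of (iteration, split, mean IoU, first-frame IoU, loss)."""

    rows: list[dict] = field(default_factory=list)

    def append(self, iteration: int, split: str, mean_iou: float,
               first_frame_iou: float, loss: float) -> None:
        self.rows.append({
            "iteration": iteration, "split": split, "mean_iou": mean_iou,
            "first_frame_iou": first_frame_iou, "loss": loss,
        })

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows,
                            columns=["iteration", "split", "mean_iou",
                                     "first_frame_iou", "loss"])

    def split(self, name: str) -> pd.DataFrame:
        df = self.to_frame()
        return df[df["split"] == name].reset_index(drop=True)


def rotate_start(sequence: LabeledSequence, start_index: int) -> LabeledSequence:
    """Cyclically rotate frames, masks and labels to begin at ``start_index``."""
    t_len = len(sequence.images)
    if not 0 <= start_index < t_len:
        raise ValueError(f"start_index {start_index} out of range [0, {t_len})")
    if start_index == 0:
        return sequence
    order = np.roll(np.arange(t_len), -start_index)
    return LabeledSequence(
        images=sequence.images[order],
        masks=sequence.masks[order],
        state_labels=[sequence.state_labels[i] for i in order],
        params=sequence.params,
    )


class Adam:
    """Adam over a flat name -> array parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        self.t += 1
        out = {}
        for k, p in params.items():
            g = grads[k]
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            mhat = self.m[k] / (1 - self.b1 ** self.t)
            vhat = self.v[k] / (1 - self.b2 ** self.t)
            out[k] = p - self.lr * mhat / (np.sqrt(vhat) + self.eps)
        return out


def _split_dataset(
    dataset: list[LabeledSequence], rng: np.random.Generator, holdout_fraction: float
) -> tuple[list[int], list[int]]:
    n = len(dataset)
    n_hold = max(1, round(holdout_fraction * n)) if n > 1 else 0
    order = rng.permutation(n)
    return list(order[n_hold:]), list(order[:n_hold])


def _eval_split(model: DenseRNNModel, seqs: list[LabeledSequence]) -> tuple[float, float]:
    mean_ious, first_ious = [], []
    for seq in seqs:
        report = evaluate_sequence(forward(seq.images, model), seq)
        mean_ious.append(report.mean_sequence)
        first_ious.append(report.first_frame)
    return float(np.mean(mean_ious)), float(np.mean(first_ious))


def train(
    dataset: list[LabeledSequence], config: TrainConfig
) -> tuple[DenseRNNModel, MetricTrace]:
    """Train on labelled sequences; returns the best-held-out checkpoint.

    The dataset is split into train/held-out parts (held-out size
    ``max(1, round(holdout_fraction * n))``); every ``eval_every``
    iterations both splits are scored and appended to the trace, and the
    parameters with the best held-out mean IoU are kept.  Aborts with a
    diagnostic if the loss becomes non-finite.
    """
    config.validate()
    if not dataset:
        raise ValueError("dataset must be non-empty")
    t_len = len(dataset[0].images)
    for i, seq in enumerate(dataset):
        if len(seq.images) != t_len:
            raise ValueError(f"sequence {i} has {len(seq.images)} frames, expected {t_len}")

    rng = np.random.default_rng(config.seed)
    train_idx, hold_idx = _split_dataset(dataset, rng, config.holdout_fraction)
    if not train_idx:  # single-sequence corner: train and evaluate on it
        train_idx, hold_idx = hold_idx, hold_idx
    train_seqs = [dataset[i] for i in train_idx]
    hold_seqs = [dataset[i] for i in hold_idx] or train_seqs

    model = DenseRNNModel.init(
        rng, n_frames=t_len, hidden_channels=config.hidden_channels,
        kernel_size=config.kernel_size, dense=config.dense,
    )
    params = model.to_dict()
    opt = Adam(params, lr=config.learning_rate)
    trace = MetricTrace()
    best_iou = -1.0
    best_params = {k: v.copy() for k, v in params.items()}

    for it in range(1, config.iterations + 1):
        picks = rng.choice(len(train_seqs), size=min(config.batch_size, len(train_seqs)),
                           replace=False)
        batch = []
        for idx in picks:
            seq = train_seqs[idx]
            if config.augment_start_frames:
                seq = rotate_start(seq, int(rng.integers(0, t_len)))
            batch.append(seq)
        x = np.stack([s.images[:, None] for s in batch])        # (B, T, 1, H, W)
        y = np.stack([s.masks.astype(float) for s in batch])    # (B, T, H, W)

        model = DenseRNNModel.from_dict(params)
        loss, grads = loss_and_grads(model, x, y)
        if not np.isfinite(loss):
            raise RuntimeError(f"non-finite loss at iteration {it}; aborting")
        params = opt.step(params, grads)

        if it % config.eval_every == 0 or it == config.iterations or it == 1:
            model = DenseRNNModel.from_dict(params)
            tr_mean, tr_first = _eval_split(model, train_seqs[: len(hold_seqs) * 2 or 2])
            ho_mean, ho_first = _eval_split(model, hold_seqs)
            trace.append(it, "train", tr_mean, tr_first, float(loss))
            trace.append(it, "heldout", ho_mean, ho_first, float(loss))
            if ho_mean > best_iou:
                best_iou = ho_mean
                best_params = {k: v.copy() for k, v in params.items()}

    return DenseRNNModel.from_dict(best_params), trace


def train_ablation_pair(
    dataset: list[LabeledSequence], config: TrainConfig
) -> tuple[MetricTrace, MetricTrace]:
    """Train the dense model and the plain single-chain baseline with
    matched seed and configuration; returns (dense trace, no-dense trace)
    for first-frame-vs-mean IoU comparisons."""
    _, trace_dense = train(dataset, replace(config, dense=True))
    _, trace_nodense = train(dataset, replace(config, dense=False))
    return trace_dense, trace_nodense
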