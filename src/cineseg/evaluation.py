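"""Segmentation and state-decoding metrics.

The segmentation metric is Intersection over Union, IoU = |S ∩ G| / |S ∪ G|
between a predicted mask S and ground truth G.  Sequences are scored both
by the mean IoU over frames and by the IoU of the first frame alone: a
plain recurrent segmenter has no temporal context at frame one, so the
first-frame score isolates exactly the weakness the dense compensation
targets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dense_rnn import PredictionSequence
from .phantom import LabeledSequence
from .state_estimation import estimate_states

__all__ = ["IoUReport", "iou", "evaluate_sequence"]


@dataclass
class IoUReport:
    per_frame: np.ndarray        # (T,) IoU per frame
    mean_sequence: float         # arithmetic mean of per_frame
    first_frame: float           # per_frame[0]
    state_accuracy: float | None # fraction of correctly decoded pair labels


def iou(pred: np.ndarray, truth: np.ndarray) -> float:
    """|S ∩ G| / |S ∪ G| for two binary masks of identical shape.

    Two empty masks agree perfectly on the absence of structure, so the
    empty/empty case returns 1.0.
    """
    p = np.asarray(pred)
    g = np.asarray(truth)
    if p.shape != g.shape:
        raise ValueError(f"pred shape {p.shape} != truth shape {g.shape}")
    for name, m in (("pred", p), ("truth", g)):
        if not np.isin(m, (0, 1)).all():
            raise ValueError(f"{name} mask must be binary (0/1)")
    pb = p.astype(bool)
    gb = g.astype(bool)
    union = np.logical_or(pb, gb).sum()
    if union == 0:
        return 1.0
    return float(np.logical_and(pb, gb).sum() / union)


def evaluate_sequence(
    pred: PredictionSequence | np.ndarray,
    truth: LabeledSequence,
    N: int = 4,
    threshold: float = 0.5,
    convention: str = "consistent",
) -> IoUReport:
    """Score one predicted sequence against its labelled ground truth.

    Probabilities are binarised at ``threshold``; the decoded cardiac
    states of the *predicted* masks are compared with the phantom's
    per-frame labels over adjacent pairs (pair k vs frame label k).
    """
    if isinstance(pred, PredictionSequence):
        binary = pred.binarized if threshold == pred.threshold else (
            (pred.probs >= threshold).astype(np.uint8))
    else:
        arr = np.asarray(pred)
        binary = arr.astype(np.uint8) if np.isin(arr, (0, 1)).all() \
            else (arr >= threshold).astype(np.uint8)
    t_len = len(truth.masks)
    if len(binary) != t_len:
        raise ValueError(f"prediction has {len(binary)} frames, truth has {t_len}")
    per_frame = np.array([iou(binary[t], truth.masks[t]) for t in range(t_len)])

    state_accuracy = None
    if truth.state_labels is not None and t_len >= 2:
        decoded = estimate_states(binary, N=N, convention=convention)
        ref = truth.state_labels[: t_len - 1]
        hits = sum(a == b for a, b in zip(decoded.labels, ref))
        state_accuracy = hits / (t_len - 1)

    return IoUReport(
        per_frame=per_frame,
        mean_sequence=float(per_frame.mean()),
        first_frame=float(per_frame[0]),
        state_accuracy=state_accuracy,
    )
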