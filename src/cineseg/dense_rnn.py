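"""Dense two-chain recurrent segmentation network.

A plain single-chain recurrent segmenter starts its first frame from a
zero hidden state, so the first frame is segmented with no temporal
context and its (poor) hidden output pollutes every later frame.  The
dense topology fixes this with two chained conv-LSTM RNNs over the same
frame sequence:

* the *compensation* chain (RNN 1) runs from the zero state and exposes
  its hidden outputs h'_1 .. h'_n;
* a learned weighted sum  h_0 = sum_i omega_i h'_i  initialises the hidden
  state of the *main* chain (RNN 2), whose per-frame hidden outputs feed a
  1x1-convolution + sigmoid segmentation head.

The omegas are unconstrained scalars trained end-to-end; omega == 0
recovers the plain single-chain baseline exactly, which is the ablation
axis used throughout the tests.  The main chain's initial memory c_0
stays zero — only the hidden layer is compensated.

Training minimises a per-frame binary cross-entropy summed over frames
and averaged over pixels (so the loss magnitude is independent of image
size).  Gradients are computed analytically by backpropagation through
time in :func:`loss_and_grads`; a finite-difference check in the test
suite pins the derivation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._ops import sigmoid
from .recurrent_core import (
    ConvLSTMParams,
    LSTMState,
    _cell_backward,
    _cell_forward,
    _StepCache,
)

__all__ = [
    "CompensationWeights",
    "DenseRNNModel",
    "PredictionSequence",
    "dense_compensation",
    "forward",
    "sequence_loss",
    "loss_and_grads",
]

_EPS = 1e-7


@dataclass
class CompensationWeights:
    """Learned scalars weighting the compensation chain's hidden outputs,
    one per frame.  Unconstrained (no softmax): the compensated state is a
    bare weighted sum."""

    omega: np.ndarray

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        if self.omega.ndim != 1:
            raise ValueError("omega must be a 1-D vector of per-frame scalars")
        if not np.all(np.isfinite(self.omega)):
            raise ValueError("omega must be finite")

    def __len__(self) -> int:
        return len(self.omega)


def dense_compensation(
    hidden_list: list[np.ndarray] | np.ndarray,
    omega: CompensationWeights | np.ndarray,
) -> np.ndarray:
    """Weighted sum  sum_i omega_i * h'_i  of the compensation chain's outputs."""
    w = omega.omega if isinstance(omega, CompensationWeights) else np.asarray(omega, float)
    hs = list(hidden_list)
    if len(hs) == 0:
        raise ValueError("hidden_list must be non-empty")
    if len(w) != len(hs):
        raise ValueError(
            f"omega has {len(w)} entries but hidden_list has {len(hs)} tensors"
        )
    shape = hs[0].shape
    for i, h in enumerate(hs):
        if h.shape != shape:
            raise ValueError(f"hidden_list[{i}] shape {h.shape} != {shape}")
    out = np.zeros(shape, dtype=float)
    for wi, h in zip(w, hs):
        out += wi * h
    return out


@dataclass
class PredictionSequence:
    """Per-frame per-pixel wall probabilities and their binarisation."""

    probs: np.ndarray            # (T, H, W) in (0, 1)
    threshold: float = 0.5

    @property
    def binarized(self) -> np.ndarray:
        return (self.probs >= self.threshold).astype(np.uint8)


@dataclass
class DenseRNNModel:
    """Compensation chain + main chain + omegas + 1x1 segmentation head.

    ``rnn1`` / ``omega`` may be ``None``, giving the plain single-chain
    baseline (main chain from the zero state) used in the ablation.
    """

    rnn1: ConvLSTMParams | None
    rnn2: ConvLSTMParams
    omega: np.ndarray | None     # (n_frames,)
    head_w: np.ndarray           # (hidden_channels,) — a 1x1 conv kernel
    head_b: np.ndarray           # scalar, shape ()

    def __post_init__(self) -> None:
        if (self.rnn1 is None) != (self.omega is None):
            raise ValueError("rnn1 and omega must both be set (dense) or both None (plain)")
        if self.rnn1 is not None:
            if self.rnn1.hidden_channels != self.rnn2.hidden_channels:
                raise ValueError("rnn1 and rnn2 hidden channels must match for compensation")
        if self.head_w.shape != (self.rnn2.hidden_channels,):
            raise ValueError(
                f"head_w must have shape ({self.rnn2.hidden_channels},), got {self.head_w.shape}"
            )

    @property
    def dense(self) -> bool:
        return self.rnn1 is not None

    @property
    def n_frames(self) -> int | None:
        return None if self.omega is None else len(self.omega)

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        n_frames: int,
        hidden_channels: int = 16,
        input_channels: int = 1,
        kernel_size: int = 3,
        dense: bool = True,
        head_bias: float = -2.0,
    ) -> "DenseRNNModel":
        """Seeded initialisation.  Omegas start at 1/n so the compensated
        state begins as the average of the compensation chain's outputs;
        the head bias starts negative because the wall occupies a small
        fraction of the frame."""
        rnn1 = ConvLSTMParams.init(rng, hidden_channels, input_channels, kernel_size) \
            if dense else None
        rnn2 = ConvLSTMParams.init(rng, hidden_channels, input_channels, kernel_size)
        omega = np.full(n_frames, 1.0 / n_frames) if dense else None
        head_w = rng.normal(0.0, 1.0 / np.sqrt(hidden_channels), hidden_channels)
        return cls(rnn1=rnn1, rnn2=rnn2, omega=omega,
                   head_w=head_w, head_b=np.asarray(float(head_bias)))

    # -- flat parameter dict (shared by the optimizer and checkpoints) --

    def to_dict(self) -> dict[str, np.ndarray]:
        d: dict[str, np.ndarray] = {}
        if self.dense:
            d.update(self.rnn1.as_dict("rnn1."))
            d["omega"] = self.omega
        d.update(self.rnn2.as_dict("rnn2."))
        d["head_w"] = self.head_w
        d["head_b"] = np.asarray(self.head_b)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, np.ndarray]) -> "DenseRNNModel":
        dense = "omega" in d
        return cls(
            rnn1=ConvLSTMParams.from_dict(d, "rnn1.") if dense else None,
            rnn2=ConvLSTMParams.from_dict(d, "rnn2."),
            omega=np.asarray(d["omega"], float) if dense else None,
            head_w=np.asarray(d["head_w"], float),
            head_b=np.asarray(d["head_b"], float),
        )

    def copy(self) -> "DenseRNNModel":
        return DenseRNNModel.from_dict({k: v.copy() for k, v in self.to_dict().items()})


def _as_batch(sequence: np.ndarray) -> tuple[np.ndarray, bool]:
    """Normalise (T,H,W) / (T,C,H,W) / (B,T,C,H,W) to (B,T,C,H,W)."""
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim == 3:
        return seq[None, :, None], True
    if seq.ndim == 4:
        return seq[None], True
    if seq.ndim == 5:
        return seq, False
    raise ValueError(f"sequence must have 3-5 dims, got shape {seq.shape}")


def _run_chain_cached(
    x: np.ndarray, h0: np.ndarray, c0: np.ndarray, params: ConvLSTMParams
) -> tuple[list[np.ndarray], list[_StepCache]]:
    """Batched chain run keeping per-step caches; x is (B, T, C, H, W)."""
    h, c = h0, c0
    hs: list[np.ndarray] = []
    caches: list[_StepCache] = []
    for t in range(x.shape[1]):
        _, h, c, cache = _cell_forward(x[:, t], h, c, params)
        hs.append(h)
        caches.append(cache)
    return hs, caches


def _forward_internal(x: np.ndarray, model: DenseRNNModel) -> dict:
    """Full forward pass on a batch (B,T,C,H,W); returns all intermediates."""
    b, t_len, _, hh, ww = x.shape
    nh = model.rnn2.hidden_channels
    zero = np.zeros((b, nh, hh, ww))
    out: dict = {}
    if model.dense:
        if len(model.omega) != t_len:
            raise ValueError(
                f"model has {len(model.omega)} omegas but sequence has {t_len} frames"
            )
        hs1, caches1 = _run_chain_cached(x, zero, zero, model.rnn1)
        h0 = np.zeros_like(zero)
        for wi, h in zip(model.omega, hs1):
            h0 += wi * h
        out.update(hs1=hs1, caches1=caches1)
    else:
        h0 = zero
    hs2, caches2 = _run_chain_cached(x, h0, zero.copy(), model.rnn2)
    logits = np.stack(
        [np.einsum("bchw,c->bhw", h, model.head_w) + float(model.head_b) for h in hs2],
        axis=1,
    )  # (B, T, H, W)
    probs = sigmoid(logits)
    out.update(h0=h0, hs2=hs2, caches2=caches2, logits=logits, probs=probs)
    return out


def forward(sequence: np.ndarray, model: DenseRNNModel,
            threshold: float = 0.5) -> PredictionSequence:
    """Segment a single sequence (T, H, W) or (T, C, H, W).

    Runs the compensation chain (when present) over the full sequence,
    forms the compensated initial hidden state, runs the main chain, and
    maps each hidden output through the 1x1-conv head + sigmoid.
    Deterministic: identical inputs give bit-identical probabilities.
    """
    xb, single = _as_batch(sequence)
    res = _forward_internal(xb, model)
    probs = np.clip(res["probs"], _EPS, 1.0 - _EPS)
    if not single:
        raise ValueError("forward segments one sequence; use loss_and_grads for batches")
    return PredictionSequence(probs=probs[0], threshold=threshold)


def sequence_loss(
    pred: PredictionSequence | np.ndarray, truth: np.ndarray
) -> float:
    """Binary cross-entropy, mean over pixels and summed over frames.

    ``truth`` must be binary masks of the same (T, H, W) shape; predicted
    probabilities are clipped to [eps, 1-eps] for numerical stability.
    """
    p = pred.probs if isinstance(pred, PredictionSequence) else np.asarray(pred, float)
    y = np.asarray(truth, dtype=float)
    if p.shape != y.shape:
        raise ValueError(f"prediction shape {p.shape} != truth shape {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("truth masks must be binary (0/1)")
    p = np.clip(p, _EPS, 1.0 - _EPS)
    per_pixel = -(y * np.log(p) + (1.0 - y) * np.log(1.0 - p))
    t_axis = per_pixel.reshape(per_pixel.shape[0], -1)
    return float(t_axis.mean(axis=1).sum())


def loss_and_grads(
    model: DenseRNNModel, x: np.ndarray, y: np.ndarray
) -> tuple[float, dict[str, np.ndarray]]:
    """Loss and analytic gradients on a batch.

    ``x`` is (B, T, C, H, W), ``y`` is (B, T, H, W) binary.  The loss is
    the per-sequence value of :func:`sequence_loss` averaged over the
    batch.  Gradients flow backwards through the head, the main chain,
    the compensated initial state, the omegas, and the compensation
    chain (backpropagation through time).
    """
    xb = np.asarray(x, dtype=float)
    yb = np.asarray(y, dtype=float)
    if xb.ndim != 5:
        raise ValueError(f"x must be (B, T, C, H, W), got shape {xb.shape}")
    b, t_len, _, hh, ww = xb.shape
    npix = hh * ww
    res = _forward_internal(xb, model)
    probs = res["probs"]

    pc = np.clip(probs, _EPS, 1.0 - _EPS)
    per_pixel = -(yb * np.log(pc) + (1.0 - yb) * np.log(1.0 - pc))
    loss = float(per_pixel.reshape(b, t_len, -1).mean(axis=2).sum(axis=1).mean())

    # d loss / d logits for BCE-with-logits: (p - y), with the mean-over-
    # pixels, sum-over-frames, mean-over-batch reduction baked in.
    dlogits = (probs - yb) / (npix * b)                       # (B, T, H, W)

    nh = model.rnn2.hidden_channels
    grads: dict[str, np.ndarray] = {
        "head_w": np.zeros_like(model.head_w),
        "head_b": np.zeros(()),
    }

    # main chain BPTT
    g2 = {k: np.zeros_like(v) for k, v in model.rnn2.as_dict().items()}
    dh = np.zeros((b, nh, hh, ww))
    dc = np.zeros_like(dh)
    cin = model.rnn2.input_channels
    for t in range(t_len - 1, -1, -1):
        h_t = res["hs2"][t]
        grads["head_w"] += np.einsum("bhw,bchw->c", dlogits[:, t], h_t)
        grads["head_b"] += dlogits[:, t].sum()
        dh = dh + dlogits[:, t][:, None] * model.head_w[None, :, None, None]
        dh, dc, _, step_g = _cell_backward(dh, dc, res["caches2"][t], model.rnn2, cin)
        for k in g2:
            g2[k] += step_g[k]
    for k, v in g2.items():
        grads["rnn2." + k] = v
    dh0 = dh  # gradient w.r.t. the compensated initial hidden state

    if model.dense:
        domega = np.array([float(np.sum(dh0 * h)) for h in res["hs1"]])
        g1 = {k: np.zeros_like(v) for k, v in model.rnn1.as_dict().items()}
        dh = np.zeros_like(dh0)
        dc = np.zeros_like(dh0)
        cin1 = model.rnn1.input_channels
        for t in range(t_len - 1, -1, -1):
            dh = dh + model.omega[t] * dh0
            dh, dc, _, step_g = _cell_backward(dh, dc, res["caches1"][t], model.rnn1, cin1)
            for k in g1:
                g1[k] += step_g[k]
        for k, v in g1.items():
            grads["rnn1." + k] = v
        grads["omega"] = domega

    return loss, grads
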