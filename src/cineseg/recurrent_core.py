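"""Convolutional LSTM cell and single-chain runner.

The cell follows the standard LSTM gate structure with convolutional gate
maps: every gate is a same-padded convolution of the channel concatenation
``[h_{t-1}, x_t]``.  For an input frame x_t and previous state (h, c):

    f_t = sigma(W_f * [h_{t-1}, x_t] + b_f)          forget gate
    i_t = sigma(W_i * [h_{t-1}, x_t] + b_i)          input gate
    c~_t = tanh(W_c * [h_{t-1}, x_t] + b_c)          candidate memory
    c_t = f_t . c_{t-1} + i_t . c~_t                 memory update
    o_t = sigma(W_o * [h_{t-1}, x_t] + b_o)          output gate
    h_t = o_t . tanh(c_t)                            hidden output

where ``*`` is convolution and ``.`` the elementwise product.  Because
h_t is a product of a sigmoid and a tanh, |h_t| <= 1 entrywise after any
number of steps.

Internally the four gates are computed with one fused im2col + matmul per
step (gate order f, i, c, o); the public parameter container keeps the
four kernels separate so checkpoints stay self-describing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._ops import im2col, sigmoid

__all__ = [
    "ConvLSTMParams",
    "LSTMState",
    "GateActivations",
    "lstm_step",
    "run_chain",
]


@dataclass
class ConvLSTMParams:
    """Gate kernels and biases of one convolutional LSTM cell.

    Each kernel has shape ``(hidden_channels, hidden_channels + input_channels,
    k, k)`` and maps the channel concatenation ``[h, x]`` to hidden channels.
    ``kernel_size`` must be odd so same-padding preserves spatial dims.
    """

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    def __post_init__(self) -> None:
        shape = self.W_f.shape
        for name in ("W_i", "W_c", "W_o"):
            if getattr(self, name).shape != shape:
                raise ValueError(
                    f"gate kernel {name} has shape {getattr(self, name).shape}, "
                    f"expected {shape} (all four kernels must match)"
                )
        if len(shape) != 4 or shape[2] != shape[3]:
            raise ValueError(f"gate kernels must be (out, in, k, k), got {shape}")
        if shape[2] % 2 != 1:
            raise ValueError(f"kernel_size must be odd, got {shape[2]}")
        if shape[1] <= shape[0]:
            raise ValueError(
                f"kernel input channels ({shape[1]}) must exceed hidden channels "
                f"({shape[0]}): gates consume [h, x]"
            )
        for name in ("b_f", "b_i", "b_c", "b_o"):
            if getattr(self, name).shape != (shape[0],):
                raise ValueError(f"bias {name} must have shape ({shape[0]},)")

    @property
    def hidden_channels(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_channels(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    @property
    def kernel_size(self) -> int:
        return self.W_f.shape[2]

    @classmethod
    def init(
        cls,
        rng: np.random.Generator,
        hidden_channels: int = 16,
        input_channels: int = 1,
        kernel_size: int = 3,
        forget_bias: float = 1.0,
    ) -> "ConvLSTMParams":
        """Glorot-scaled random kernels; forget bias starts positive so early
        training retains memory across frames (standard LSTM practice)."""
        cin = hidden_channels + input_channels
        fan = cin * kernel_size * kernel_size
        scale = 1.0 / np.sqrt(fan)

        def w() -> np.ndarray:
            return rng.normal(0.0, scale, (hidden_channels, cin, kernel_size, kernel_size))

        zeros = np.zeros(hidden_channels)
        return cls(
            W_f=w(), W_i=w(), W_c=w(), W_o=w(),
            b_f=zeros + forget_bias, b_i=zeros.copy(), b_c=zeros.copy(), b_o=zeros.copy(),
        )

    def fused(self) -> tuple[np.ndarray, np.ndarray]:
        """Kernels stacked along the output axis in gate order (f, i, c, o),
        flattened for the im2col matmul: returns (4h, cin*k*k) and (4h,)."""
        w = np.concatenate([self.W_f, self.W_i, self.W_c, self.W_o], axis=0)
        b = np.concatenate([self.b_f, self.b_i, self.b_c, self.b_o])
        return w.reshape(w.shape[0], -1), b

    def as_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        return {prefix + n: getattr(self, n)
                for n in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o")}

    @classmethod
    def from_dict(cls, d: dict[str, np.ndarray], prefix: str = "") -> "ConvLSTMParams":
        return cls(**{n: np.asarray(d[prefix + n])
                      for n in ("W_f", "W_i", "W_c", "W_o", "b_f", "b_i", "b_c", "b_o")})

    def copy(self) -> "ConvLSTMParams":
        return ConvLSTMParams.from_dict(self.as_dict())


@dataclass
class LSTMState:
    """The (h, c) pair flowing between cells; both (..., hidden, H, W)."""

    h: np.ndarray
    c: np.ndarray

    def __post_init__(self) -> None:
        if self.h.shape != self.c.shape:
            raise ValueError(f"h shape {self.h.shape} != c shape {self.c.shape}")

    @classmethod
    def zeros(cls, hidden_channels: int, height: int, width: int,
              batch: int | None = None) -> "LSTMState":
        shape = (hidden_channels, height, width)
        if batch is not None:
            shape = (batch,) + shape
        return cls(h=np.zeros(shape), c=np.zeros(shape))


@dataclass
class GateActivations:
    """Per-step gate values: f, i, o in (0,1); c_tilde in (-1,1)."""

    f: np.ndarray
    i: np.ndarray
    c_tilde: np.ndarray
    o: np.ndarray


@dataclass
class _StepCache:
    """Intermediates kept for backpropagation through one cell step."""

    cols: np.ndarray      # im2col of [h_prev, x]
    gates: GateActivations
    c_prev: np.ndarray
    c: np.ndarray


def _as_batched(t: np.ndarray, name: str) -> tuple[np.ndarray, bool]:
    if t.ndim == 3:
        return t[None], True
    if t.ndim == 4:
        return t, False
    raise ValueError(f"{name} must be (C,H,W) or (B,C,H,W), got shape {t.shape}")


def _cell_forward(
    x: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray, params: ConvLSTMParams
) -> tuple[GateActivations, np.ndarray, np.ndarray, _StepCache]:
    """One fused LSTM step on batched tensors (B, C, H, W)."""
    b, _, hh, ww = x.shape
    nh = params.hidden_channels
    cat = np.concatenate([h_prev, x], axis=1)
    cols = im2col(cat, params.kernel_size)          # (B, HW, Ctot*k*k)
    wmat, bias = params.fused()
    z = cols @ wmat.T + bias                        # (B, HW, 4h)
    z = z.transpose(0, 2, 1).reshape(b, 4 * nh, hh, ww)
    zf, zi, zc, zo = np.split(z, 4, axis=1)
    gates = GateActivations(
        f=sigmoid(zf), i=sigmoid(zi), c_tilde=np.tanh(zc), o=sigmoid(zo)
    )
    c = gates.f * c_prev + gates.i * gates.c_tilde
    h = gates.o * np.tanh(c)
    return gates, h, c, _StepCache(cols=cols, gates=gates, c_prev=c_prev, c=c)


def _cell_backward(
    dh: np.ndarray,
    dc_in: np.ndarray,
    cache: _StepCache,
    params: ConvLSTMParams,
    input_channels: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, dict[str, np.ndarray]]:
    """Gradients of one step.  Returns (dh_prev, dc_prev, dx, param grads)."""
    from ._ops import col2im

    g = cache.gates
    b, nh, hh, ww = dh.shape
    tc = np.tanh(cache.c)
    do = dh * tc
    dc = dc_in + dh * g.o * (1.0 - tc * tc)
    df = dc * cache.c_prev
    di = dc * g.c_tilde
    dg = dc * g.i
    dc_prev = dc * g.f
    dzf = df * g.f * (1.0 - g.f)
    dzi = di * g.i * (1.0 - g.i)
    dzg = dg * (1.0 - g.c_tilde * g.c_tilde)
    dzo = do * g.o * (1.0 - g.o)
    dz = np.concatenate([dzf, dzi, dzg, dzo], axis=1)       # (B, 4h, H, W)
    dz_flat = dz.reshape(b, 4 * nh, hh * ww).transpose(0, 2, 1)  # (B, HW, 4h)

    wmat, _ = params.fused()
    dwmat = np.einsum("bpo,bpi->oi", dz_flat, cache.cols)
    dbias = dz_flat.sum(axis=(0, 1))
    dcols = dz_flat @ wmat                                   # (B, HW, Ctot*k*k)
    k = params.kernel_size
    ctot = nh + input_channels
    dcat = col2im(dcols, (b, ctot, hh, ww), k)
    dh_prev = dcat[:, :nh]
    dx = dcat[:, nh:]

    kshape = (nh, ctot, k, k)
    dwf, dwi, dwc, dwo = np.split(dwmat.reshape(4 * nh, ctot, k, k), 4, axis=0)
    grads = {
        "W_f": dwf.reshape(kshape), "W_i": dwi.reshape(kshape),
        "W_c": dwc.reshape(kshape), "W_o": dwo.reshape(kshape),
        "b_f": dbias[:nh], "b_i": dbias[nh:2 * nh],
        "b_c": dbias[2 * nh:3 * nh], "b_o": dbias[3 * nh:],
    }
    return dh_prev, dc_prev, dx, grads


def lstm_step(
    x: np.ndarray, prev: LSTMState, params: ConvLSTMParams
) -> tuple[GateActivations, LSTMState]:
    """Apply one convolutional LSTM step to frame ``x`` given state ``prev``."""
    xb, squeeze = _as_batched(x, "x")
    hb, hsq = _as_batched(prev.h, "prev.h")
    cb, _ = _as_batched(prev.c, "prev.c")
    if squeeze != hsq:
        raise ValueError("x and prev state must be consistently batched or unbatched")
    if xb.shape[0] != hb.shape[0] or xb.shape[2:] != hb.shape[2:]:
        raise ValueError(
            f"x spatial/batch shape {xb.shape} incompatible with prev.h {hb.shape}"
        )
    if xb.shape[1] != params.input_channels:
        raise ValueError(
            f"x has {xb.shape[1]} channels but params expect {params.input_channels}"
        )
    if hb.shape[1] != params.hidden_channels:
        raise ValueError(
            f"prev.h has {hb.shape[1]} channels but params expect {params.hidden_channels}"
        )
    gates, h, c, _ = _cell_forward(xb, hb, cb, params)
    if squeeze:
        gates = GateActivations(
            f=gates.f[0], i=gates.i[0], c_tilde=gates.c_tilde[0], o=gates.o[0]
        )
        return gates, LSTMState(h=h[0], c=c[0])
    return gates, LSTMState(h=h, c=c)


def run_chain(
    sequence: np.ndarray,
    init: LSTMState | None,
    params: ConvLSTMParams,
) -> tuple[list[LSTMState], list[np.ndarray]]:
    """Run the cell left-to-right over ``sequence`` of shape (T, C, H, W).

    ``init=None`` starts from the all-zero state (a first frame that
    acquires no hidden information).  Returns the per-frame states and,
    for convenience, the list of hidden tensors.
    """
    seq = np.asarray(sequence, dtype=float)
    if seq.ndim == 3:  # (T, H, W) single-channel shorthand
        seq = seq[:, None]
    if seq.ndim != 4:
        raise ValueError(f"sequence must be (T, C, H, W), got shape {seq.shape}")
    if seq.shape[0] == 0:
        raise ValueError("sequence must contain at least one frame")
    t_len, _, hh, ww = seq.shape
    if init is None:
        init = LSTMState.zeros(params.hidden_channels, hh, ww)
    state = init
    states: list[LSTMState] = []
    for t in range(t_len):
        _, state = lstm_step(seq[t], state, params)
        states.append(state)
    return states, [s.h for s in states]
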