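"""Cardiac-state decoding from wall-mask areas.

The LV wall thickens during contraction (systole) and thins during
diastole, but the change between adjacent frames is small, so a raw
pairwise comparison is noisy.  The estimator therefore works in three
steps on a sequence of binary wall masks:

1. per-frame wall areas  Area(f_k)  (pixel counts);
2. a binary indicator per adjacent pair,
       d'_k = 1  if Area(f_k) > Area(f_{k+1}) else 0
   (strict inequality; d' = 1 flags an area *decrease*, i.e. thinning);
3. an N-frame running mean  s_k = (1/N) * sum_{i=k-N/2}^{k+N/2-1} d'_i
   which suppresses isolated misestimates, followed by thresholding at
   0.5 to decode the state of each pair.

Two decoding conventions are provided because the raw indicator (1 =
thinning) and the published decoding rule (s < 0.5 -> diastole) point in
opposite directions.  The default, "consistent", follows the indicator's
own semantics: sustained thinning (s > 0.5) decodes as diastole and
sustained thickening as contraction; ties (s == 0.5) decode as
contraction.  The "literal" convention applies the opposite rule
(s < 0.5 -> diastole) unchanged.

Near the sequence ends the window is clamped to the valid index range
and the divisor is the actual number of in-range terms, so s stays an
exact arithmetic mean in [0, 1] for every pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import CONTRACTION, DIASTOLE

__all__ = [
    "AreaSeries",
    "StateSeries",
    "mask_areas",
    "adjacent_diff",
    "smooth_states",
    "decode_state",
    "estimate_states",
]


@dataclass
class AreaSeries:
    """Per-frame wall pixel counts."""

    areas: np.ndarray

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas)
        if (self.areas < 0).any():
            raise ValueError("areas must be non-negative")


@dataclass
class StateSeries:
    """Adjacent-pair indicators, their windowed means, and decoded labels."""

    d_prime: np.ndarray      # (T-1,) in {0, 1}
    s: np.ndarray            # (T-1,) in [0, 1]
    window_N: int
    labels: list[str]        # per pair, CONTRACTION or DIASTOLE


def mask_areas(masks: np.ndarray) -> AreaSeries:
    """Count wall pixels per frame; masks must be binary (T, H, W)."""
    m = np.asarray(masks)
    if not np.isin(m, (0, 1)).all():
        raise ValueError("masks must be binary (0/1)")
    return AreaSeries(areas=m.reshape(m.shape[0], -1).sum(axis=1))


def adjacent_diff(areas: AreaSeries | np.ndarray) -> np.ndarray:
    """d'_k = 1 iff Area(f_k) > Area(f_{k+1}) (strict; ties give 0)."""
    a = areas.areas if isinstance(areas, AreaSeries) else np.asarray(areas)
    if len(a) < 2:
        raise ValueError(f"need at least 2 frames to compare, got {len(a)}")
    return (a[:-1] > a[1:]).astype(np.int64)


def decode_state(s: float, threshold: float = 0.5, convention: str = "consistent") -> str:
    """Decode one smoothed value into a cardiac-state label (see module docs)."""
    if not 0.0 <= s <= 1.0:
        raise ValueError(f"s must be in [0, 1], got {s}")
    if convention == "consistent":
        # d'=1 flags thinning, so a majority of 1s means diastole
        return DIASTOLE if s > threshold else CONTRACTION
    if convention == "literal":
        return DIASTOLE if s < threshold else CONTRACTION
    raise ValueError(f"unknown convention {convention!r}")


def smooth_states(
    d_prime: np.ndarray, N: int = 4, convention: str = "consistent"
) -> StateSeries:
    """Windowed mean of the pair indicators with end-clamping.

    For pair index k the window covers indices k-N/2 .. k+N/2-1; indices
    outside the valid range are dropped and the mean is taken over the
    terms actually present, keeping s an exact mean in [0, 1].
    """
    if N % 2 != 0 or N < 2:
        raise ValueError(f"window N must be even and >= 2, got {N}")
    d = np.asarray(d_prime)
    if not np.isin(d, (0, 1)).all():
        raise ValueError("d_prime must be binary (0/1)")
    n = len(d)
    s = np.empty(n, dtype=float)
    half = N // 2
    for k in range(n):
        lo = max(0, k - half)
        hi = min(n, k + half)       # exclusive; covers k-N/2 .. k+N/2-1
        s[k] = d[lo:hi].mean()
    labels = [decode_state(v, convention=convention) for v in s]
    return StateSeries(d_prime=d.astype(np.int64), s=s, window_N=N, labels=labels)


def estimate_states(
    masks: np.ndarray, N: int = 4, convention: str = "consistent"
) -> StateSeries:
    """End-to-end decoding: mask areas -> pair indicators -> windowed
    means -> labels.  ``masks`` is a binary (T, H, W) stack with T >= 2."""
    areas = mask_areas(masks)
    d = adjacent_diff(areas)
    return smooth_states(d, N=N, convention=convention)
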