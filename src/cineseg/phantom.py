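"""Synthetic beating-heart phantom sequences.

Emulates the structure of a four-chamber cine view: the left-ventricle
(LV) wall appears as a bright annulus whose thickness oscillates over the
cardiac cycle (thick at end-systole, thin at end-diastole), surrounded by
confusable static structures — a thin crescent standing in for the
right-ventricle (RV) free wall and two elliptical blobs standing in for
the atria — at the *same* intensity as the LV wall, which is precisely
what makes the real segmentation problem hard.  Additive Gaussian noise
completes the image model.

Every sequence carries per-frame ground-truth wall masks and per-frame
cardiac-state labels ("contraction" while the noise-free wall area is
increasing, "diastole" otherwise), so the segmentation network and the
downstream state estimator are both testable without any external data.

Geometry conventions: row-major 0-based pixel indices; distances are
measured at pixel centres; masks use 1 = wall.  The wall thickens inward
(fixed outer radius, shrinking lumen), as the myocardium does.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONTRACTION",
    "DIASTOLE",
    "Distractor",
    "PhantomParams",
    "PhantomRanges",
    "LabeledSequence",
    "default_distractors",
    "distractor_mask",
    "wall_thickness",
    "annulus_mask",
    "generate_sequence",
    "generate_dataset",
]

CONTRACTION = "contraction"
DIASTOLE = "diastole"


class PhantomParameterError(ValueError):
    """A phantom parameter violates its documented constraint."""


@dataclass(frozen=True)
class Distractor:
    """One static confusable structure.

    ``shape`` is "crescent" (a thin partial annulus, the RV free wall) or
    "blob" (a filled ellipse, an atrium).  ``center`` is (row, col);
    ``size`` holds shape-specific geometry: for a crescent
    (radius, thickness, opening_deg), for a blob (semi_row, semi_col).
    """

    shape: str
    center: tuple[float, float]
    size: tuple[float, ...]
    intensity: float


@dataclass(frozen=True)
class PhantomParams:
    image_size: int = 64
    n_frames: int = 18
    center: tuple[float, float] | None = None     # default: image centre
    outer_radius_base: float = 14.0
    wall_thickness_base: float = 4.0
    thickness_amplitude: float = 2.0
    cycle_phase_offset: float = -np.pi / 2        # start at the thinnest wall
    n_cycles: int = 1
    distractor_spec: tuple[Distractor, ...] | None = None  # None -> defaults
    noise_sigma: float = 0.05
    wall_intensity: float = 0.9
    background_intensity: float = 0.1
    distractor_intensity: float = 0.9
    seed: int = 0

    def resolved_center(self) -> tuple[float, float]:
        if self.center is not None:
            return self.center
        mid = (self.image_size - 1) / 2.0
        return (mid, mid)

    def validate(self) -> None:
        if not (self.outer_radius_base > self.wall_thickness_base
                + self.thickness_amplitude > 0):
            raise PhantomParameterError(
                "require outer_radius_base > wall_thickness_base + "
                f"thickness_amplitude > 0, got {self.outer_radius_base} vs "
                f"{self.wall_thickness_base} + {self.thickness_amplitude}"
            )
        if self.image_size < 2 * (self.outer_radius_base + 2):
            raise PhantomParameterError(
                f"image_size {self.image_size} < 2*(outer_radius_base + 2) "
                f"= {2 * (self.outer_radius_base + 2)}"
            )
        if self.noise_sigma < 0:
            raise PhantomParameterError(f"noise_sigma must be >= 0, got {self.noise_sigma}")
        for name in ("wall_intensity", "background_intensity", "distractor_intensity"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise PhantomParameterError(f"{name} must be in [0, 1], got {v}")
        if self.n_frames < 1 or self.n_cycles < 1:
            raise PhantomParameterError("n_frames and n_cycles must be >= 1")


@dataclass
class LabeledSequence:
    """Images, ground-truth wall masks and cardiac-state labels for one run."""

    images: np.ndarray        # (T, H, W) float in [0, 1]
    masks: np.ndarray         # (T, H, W) uint8, 1 = LV wall
    state_labels: list[str]   # per frame, CONTRACTION or DIASTOLE
    params: PhantomParams

    def __post_init__(self) -> None:
        t = self.params.n_frames
        if not (len(self.images) == len(self.masks) == len(self.state_labels) == t):
            raise ValueError("images, masks and state_labels must all have n_frames entries")


def wall_thickness(params: PhantomParams, t: int | np.ndarray) -> np.ndarray:
    """Noise-free wall thickness at frame t (pixels):
    base + amplitude * sin(2*pi*n_cycles*t/n_frames + phase)."""
    phase = 2.0 * np.pi * params.n_cycles * np.asarray(t) / params.n_frames
    return (params.wall_thickness_base
            + params.thickness_amplitude * np.sin(phase + params.cycle_phase_offset))


def _radial_grid(params: PhantomParams) -> np.ndarray:
    n = params.image_size
    cr, cc = params.resolved_center()
    rows, cols = np.mgrid[0:n, 0:n]
    return np.hypot(rows - cr, cols - cc)


def annulus_mask(params: PhantomParams, t: int) -> np.ndarray:
    """Binary wall mask at frame t: pixels between the inner and outer radius."""
    dist = _radial_grid(params)
    outer = params.outer_radius_base
    inner = outer - wall_thickness(params, t)
    return ((dist <= outer) & (dist > inner)).astype(np.uint8)


def default_distractors(params: PhantomParams) -> tuple[Distractor, ...]:
    """One RV-wall crescent beside the LV and two atrial blobs below it,
    all at the distractor intensity (by default equal to the wall's)."""
    cr, cc = params.resolved_center()
    r = params.outer_radius_base
    return (
        Distractor(
            shape="crescent",
            center=(cr, cc - 1.65 * r),
            size=(0.85 * r, max(1.2, 0.45 * params.wall_thickness_base), 140.0),
            intensity=params.distractor_intensity,
        ),
        Distractor(
            shape="blob",
            center=(cr + 1.55 * r, cc - 0.55 * r),
            size=(0.32 * r, 0.42 * r),
            intensity=params.distractor_intensity,
        ),
        Distractor(
            shape="blob",
            center=(cr + 1.55 * r, cc + 0.55 * r),
            size=(0.30 * r, 0.38 * r),
            intensity=params.distractor_intensity,
        ),
    )


def _draw_distractor(d: Distractor, n: int) -> np.ndarray:
    rows, cols = np.mgrid[0:n, 0:n]
    dr = rows - d.center[0]
    dc = cols - d.center[1]
    if d.shape == "crescent":
        radius, thickness, opening = d.size
        dist = np.hypot(dr, dc)
        ring = (dist <= radius) & (dist > radius - thickness)
        # keep the arc facing the LV (opening towards +col)
        ang = np.degrees(np.arctan2(dr, dc))
        return ring & (np.abs(ang) <= opening / 2.0)
    if d.shape == "blob":
        a, b = d.size
        return (dr / a) ** 2 + (dc / b) ** 2 <= 1.0
    raise PhantomParameterError(f"unknown distractor shape {d.shape!r}")


def distractor_mask(params: PhantomParams) -> np.ndarray:
    """Union of all distractor pixels (static across frames), excluding the
    LV disk so distractors never touch the wall or its lumen."""
    n = params.image_size
    spec = params.distractor_spec
    if spec is None:
        spec = default_distractors(params)
    mask = np.zeros((n, n), dtype=bool)
    for d in spec:
        mask |= _draw_distractor(d, n)
    lv_disk = _radial_grid(params) <= params.outer_radius_base + 1.0
    mask &= ~lv_disk
    return mask


def analytic_wall_area(params: PhantomParams, t: int | np.ndarray) -> np.ndarray:
    """Continuous (sub-pixel) wall area at frame t: pi*(R^2 - r^2) with
    r = R - thickness(t).  Pixel-counted mask areas track this to within
    discretisation error."""
    r_out = params.outer_radius_base
    th = wall_thickness(params, t)
    return np.pi * th * (2.0 * r_out - th)


def _state_labels_from_areas(areas: np.ndarray) -> list[str]:
    """Contraction iff the noise-free wall area grows to the next frame;
    ties label as diastole; the last frame inherits its predecessor.

    Uses the continuous-model area, so labels follow the phantom's true
    motion rather than pixel-grid plateaus near the cycle extrema."""
    labels = [
        CONTRACTION if areas[t + 1] > areas[t] else DIASTOLE
        for t in range(len(areas) - 1)
    ]
    labels.append(labels[-1] if labels else DIASTOLE)
    return labels


def generate_sequence(params: PhantomParams) -> LabeledSequence:
    """Render one seeded phantom sequence with masks and state labels.

    Deterministic given ``params.seed``; the noise field is the only
    stochastic element, so mask geometry is identical across seeds.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    n, t_len = params.image_size, params.n_frames
    spec = params.distractor_spec
    if spec is None:
        spec = default_distractors(params)
    dmask = distractor_mask(replace(params, distractor_spec=spec))

    masks = np.stack([annulus_mask(params, t) for t in range(t_len)])
    images = np.empty((t_len, n, n), dtype=float)
    for t in range(t_len):
        img = np.full((n, n), params.background_intensity)
        for d in spec:
            shape_px = _draw_distractor(d, n) & dmask
            img[shape_px] = d.intensity
        img[masks[t].astype(bool)] = params.wall_intensity
        if params.noise_sigma > 0:
            img = img + rng.normal(0.0, params.noise_sigma, (n, n))
        images[t] = np.clip(img, 0.0, 1.0)

    areas = analytic_wall_area(params, np.arange(t_len))
    return LabeledSequence(
        images=images,
        masks=masks,
        state_labels=_state_labels_from_areas(areas),
        params=params,
    )


def scaled_params(image_size: int, n_frames: int = 18, **overrides) -> PhantomParams:
    """Phantom geometry scaled proportionally to the image size.

    The default 64-pixel geometry (outer radius 14, wall 4, amplitude 2)
    corresponds to ratios 0.22 / 0.0625 / 0.031 of the image side; this
    keeps smaller phantoms (e.g. 32x32 for fast training runs) visually
    and statistically comparable to the full-size ones.
    """
    params = PhantomParams(
        image_size=image_size,
        n_frames=n_frames,
        outer_radius_base=round(0.22 * image_size, 1),
        wall_thickness_base=round(0.0625 * image_size, 1),
        thickness_amplitude=round(0.031 * image_size, 1),
        **overrides,
    )
    params.validate()
    return params


@dataclass(frozen=True)
class PhantomRanges:
    """Uniform sampling ranges over phantom geometry for dataset generation.

    Fields not listed here are taken from ``base``.  Each range is an
    inclusive (low, high) pair; degenerate ranges (low == high) pin the
    value.  ``center_jitter`` shifts the LV centre by up to that many
    pixels in each axis.
    """

    base: PhantomParams = field(default_factory=PhantomParams)
    outer_radius: tuple[float, float] | None = None
    wall_thickness: tuple[float, float] | None = None
    thickness_amplitude: tuple[float, float] | None = None
    cycle_phase_offset: tuple[float, float] | None = None
    noise_sigma: tuple[float, float] | None = None
    center_jitter: float = 0.0

    def _check(self) -> None:
        for name in ("outer_radius", "wall_thickness", "thickness_amplitude",
                     "cycle_phase_offset", "noise_sigma"):
            rng = getattr(self, name)
            if rng is not None and rng[1] < rng[0]:
                raise PhantomParameterError(f"empty range for {name}: {rng}")


def _draw(rng: np.random.Generator, bounds: tuple[float, float] | None,
          default: float) -> float:
    if bounds is None:
        return default
    return float(rng.uniform(bounds[0], bounds[1]))


def generate_dataset(
    n_sequences: int,
    params_distribution: PhantomRanges | None = None,
    seed: int = 0,
) -> list[LabeledSequence]:
    """Draw ``n_sequences`` phantoms with per-sequence parameters sampled
    from the given ranges, each rendered from an independent seed-derived
    substream.  Fully reproducible: same arguments, same dataset."""
    if n_sequences < 1:
        raise PhantomParameterError(f"n_sequences must be >= 1, got {n_sequences}")
    ranges = params_distribution or PhantomRanges()
    ranges._check()
    base = ranges.base
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sequences)
    out: list[LabeledSequence] = []
    for child in children:
        rng = np.random.default_rng(child)
        cr, cc = base.resolved_center()
        if ranges.center_jitter > 0:
            cr += float(rng.uniform(-ranges.center_jitter, ranges.center_jitter))
            cc += float(rng.uniform(-ranges.center_jitter, ranges.center_jitter))
        params = replace(
            base,
            center=(cr, cc),
            outer_radius_base=_draw(rng, ranges.outer_radius, base.outer_radius_base),
            wall_thickness_base=_draw(rng, ranges.wall_thickness, base.wall_thickness_base),
            thickness_amplitude=_draw(
                rng, ranges.thickness_amplitude, base.thickness_amplitude),
            cycle_phase_offset=_draw(
                rng, ranges.cycle_phase_offset, base.cycle_phase_offset),
            noise_sigma=_draw(rng, ranges.noise_sigma, base.noise_sigma),
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        out.append(generate_sequence(params))
    return out
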