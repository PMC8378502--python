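"""Shared fixtures: small seeded phantom datasets and reference builders."""

import numpy as np
import pytest

from cineseg.phantom import PhantomParams, PhantomRanges, generate_dataset, scaled_params


def training_ranges(image_size: int, n_frames: int, noise_sigma: float = 0.03) -> PhantomRanges:
    """The standard study conditions for training runs: geometry scaled to
    the image size, sub-pixel centre jitter, uniformly varied cycle phase."""
    base = scaled_params(image_size, n_frames=n_frames, noise_sigma=noise_sigma)
    return PhantomRanges(
        base=base,
        outer_radius=(0.9 * base.outer_radius_base, 1.05 * base.outer_radius_base),
        cycle_phase_offset=(-np.pi, np.pi),
        center_jitter=1.0,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """20 seeded 32x32, 8-frame phantoms used by the training checks."""
    return generate_dataset(20, training_ranges(32, 8), seed=11)


@pytest.fixture()
def default_sequence():
    """One deterministic full-size phantom sequence."""
    from cineseg.phantom import generate_sequence

    return generate_sequence(PhantomParams(seed=7))


@pytest.fixture()
def noise_free_params():
    return PhantomParams(seed=3, noise_sigma=0.0)
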