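"""Area-difference state decoding: exact window means, tie rules,
flip suppression, and recovery of phantom labels."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cineseg.phantom import CONTRACTION, DIASTOLE, PhantomParams, generate_sequence
from cineseg.state_estimation import (
    adjacent_diff,
    decode_state,
    estimate_states,
    mask_areas,
    smooth_states,
)


def brute_force_window_mean(d, N):
    """Independent oracle: literal mean of d'[k-N/2 .. k+N/2-1] over the
    indices that exist."""
    out = []
    for k in range(len(d)):
        terms = [d[i] for i in range(k - N // 2, k + N // 2) if 0 <= i < len(d)]
        out.append(sum(terms) / len(terms))
    return np.array(out)


def test_mask_areas_counts_pixels():
    masks = np.zeros((2, 4, 4), dtype=np.uint8)
    masks[1, :3, :3] = 1
    np.testing.assert_array_equal(mask_areas(masks).areas, [0, 9])
    with pytest.raises(ValueError, match="binary"):
        mask_areas(np.full((1, 2, 2), 0.4))


@pytest.mark.parametrize(
    "areas,expected",
    [
        ((10, 8), [1]),
        ((5, 5), [0]),          # ties are "not a decrease"
        ((1, 2, 3, 2, 1), [0, 0, 1, 1]),
    ],
)
def test_adjacent_diff(areas, expected):
    np.testing.assert_array_equal(adjacent_diff(np.array(areas)), expected)


def test_adjacent_diff_needs_two_frames():
    with pytest.raises(ValueError, match="2"):
        adjacent_diff(np.array([5]))


@pytest.mark.parametrize("N", [2, 4])
def test_window_mean_matches_brute_force_exhaustively(N):
    """Exhaustive check over every binary indicator vector of length <= 10."""
    for length in range(2, 11):
        for bits in itertools.product((0, 1), repeat=length):
            d = np.array(bits)
            s = smooth_states(d, N=N).s
            np.testing.assert_allclose(s, brute_force_window_mean(d, N))


@settings(max_examples=200, derandomize=True)
@given(
    d=st.lists(st.integers(0, 1), min_size=2, max_size=40),
    N=st.sampled_from([2, 4, 6]),
)
def test_window_mean_is_exact_in_window_average(d, N):
    """For arbitrary indicator vectors and window sizes, every smoothed
    value is the exact arithmetic mean of the in-range window terms."""
    s = smooth_states(np.array(d), N=N).s
    np.testing.assert_allclose(s, brute_force_window_mean(d, N))
    assert (s >= 0).all() and (s <= 1).all()


def test_constant_inputs_map_to_constant_means():
    assert (smooth_states(np.zeros(8, dtype=int), N=4).s == 0).all()
    assert (smooth_states(np.ones(8, dtype=int), N=4).s == 1).all()


def test_odd_window_rejected():
    with pytest.raises(ValueError, match="even"):
        smooth_states(np.zeros(6, dtype=int), N=3)


def test_isolated_flips_are_corrected():
    """Up to two isolated spurious indicators inside a uniform run vanish
    after windowed decoding (the smoother's purpose)."""
    d = np.array([0, 0, 1, 0, 0, 1, 0, 0])
    series = smooth_states(d, N=4)
    assert all(lbl == CONTRACTION for lbl in series.labels)
    assert (series.s <= 0.5).all()
    # raw decoding would have flipped four times; smoothing flips zero times
    raw_flips = np.sum(d[:-1] != d[1:])
    smooth_flips = sum(a != b for a, b in zip(series.labels[:-1], series.labels[1:]))
    assert smooth_flips <= raw_flips


def test_smoothing_never_adds_transitions():
    rng = np.random.default_rng(0)
    for _ in range(50):
        d = rng.integers(0, 2, size=12)
        raw_labels = [decode_state(float(v)) for v in d]
        smooth_labels = smooth_states(d, N=4).labels
        raw_flips = sum(a != b for a, b in zip(raw_labels[:-1], raw_labels[1:]))
        sm_flips = sum(a != b for a, b in zip(smooth_labels[:-1], smooth_labels[1:]))
        assert sm_flips <= raw_flips


def test_decode_conventions():
    # consistent: the indicator flags thinning, so high s = diastole
    assert decode_state(0.0, convention="consistent") == CONTRACTION
    assert decode_state(1.0, convention="consistent") == DIASTOLE
    assert decode_state(0.5, convention="consistent") == CONTRACTION  # tie rule
    # literal: published threshold direction, s < 0.5 = diastole
    assert decode_state(0.0, convention="literal") == DIASTOLE
    assert decode_state(1.0, convention="literal") == CONTRACTION
    with pytest.raises(ValueError, match="convention"):
        decode_state(0.2, convention="bogus")


def test_constant_masks_decode_as_contraction():
    masks = np.ones((6, 5, 5), dtype=np.uint8)
    series = estimate_states(masks, N=4)
    assert (series.d_prime == 0).all()
    assert all(lbl == CONTRACTION for lbl in series.labels)


def test_noise_free_phantom_labels_flip_twice():
    """On a one-cycle noise-free phantom the decoded labels flip at the
    two turning points and nowhere else."""
    params = PhantomParams(seed=0, noise_sigma=0.0, center=(31.6, 31.2),
                           cycle_phase_offset=0.3)
    seq = generate_sequence(params)
    series = estimate_states(seq.masks, N=4)
    flips = sum(a != b for a, b in zip(series.labels[:-1], series.labels[1:]))
    assert flips <= 2


def test_phantom_state_recovery_interior():
    """Decoded states from ground-truth masks match the phantom's labels
    away from the cycle turning points."""
    params = PhantomParams(seed=5, noise_sigma=0.0, center=(31.7, 31.4))
    seq = generate_sequence(params)
    series = estimate_states(seq.masks, N=4)
    ref = seq.state_labels[: len(series.labels)]
    acc = np.mean([a == b for a, b in zip(series.labels, ref)])
    assert acc >= 0.85
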