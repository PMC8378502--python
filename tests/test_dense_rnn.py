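"""Dense two-chain model: compensation algebra, reduction to the plain
baseline, loss closed forms, and the analytic-gradient correctness check."""

import numpy as np
import pytest

from cineseg.dense_rnn import (
    CompensationWeights,
    DenseRNNModel,
    PredictionSequence,
    dense_compensation,
    forward,
    loss_and_grads,
    sequence_loss,
)


@pytest.fixture()
def tiny_model():
    rng = np.random.default_rng(0)
    return DenseRNNModel.init(rng, n_frames=4, hidden_channels=2, kernel_size=3)


def test_one_hot_omega_selects_single_hidden():
    rng = np.random.default_rng(1)
    hs = [rng.random((2, 4, 4)) for _ in range(5)]
    omega = np.zeros(5)
    omega[3] = 1.0
    np.testing.assert_array_equal(dense_compensation(hs, omega), hs[3])


def test_zero_omega_gives_zero_state():
    hs = [np.ones((2, 3, 3))] * 4
    out = dense_compensation(hs, np.zeros(4))
    np.testing.assert_array_equal(out, np.zeros((2, 3, 3)))


def test_uniform_omega_averages_constants():
    hs = [np.full((1, 2, 2), v) for v in (1.0, 2.0, 3.0, 4.0)]
    out = dense_compensation(hs, CompensationWeights(np.full(4, 0.25)))
    np.testing.assert_allclose(out, 2.5)


def test_compensation_length_mismatch_raises():
    with pytest.raises(ValueError, match="omega"):
        dense_compensation([np.zeros((1, 2, 2))] * 3, np.zeros(4))


def test_zero_omega_forward_equals_plain_chain(tiny_model):
    """With omega == 0 the dense model must reproduce the single-chain
    baseline (main chain from the zero state) to 1e-6 — the ablation axis."""
    rng = np.random.default_rng(2)
    seq = rng.random((4, 6, 6))
    dense = tiny_model.copy()
    dense.omega = np.zeros(4)
    plain = DenseRNNModel(rnn1=None, rnn2=tiny_model.rnn2, omega=None,
                          head_w=tiny_model.head_w, head_b=tiny_model.head_b)
    np.testing.assert_allclose(
        forward(seq, dense).probs, forward(seq, plain).probs, atol=1e-6)


def test_forward_is_deterministic(tiny_model):
    rng = np.random.default_rng(3)
    seq = rng.random((4, 6, 6))
    a = forward(seq, tiny_model).probs
    b = forward(seq, tiny_model).probs
    np.testing.assert_array_equal(a, b)


def test_single_frame_compensation(tiny_model):
    """For T=1 the compensated initial state is omega_1 * h'_1."""
    from cineseg.recurrent_core import run_chain

    rng = np.random.default_rng(4)
    seq = rng.random((1, 6, 6))
    model = tiny_model.copy()
    model.omega = np.array([0.7])
    _, hs1 = run_chain(seq, None, model.rnn1)
    h0 = dense_compensation(hs1, model.omega)
    np.testing.assert_allclose(h0, 0.7 * hs1[0])


def test_permuting_frames_changes_predictions(tiny_model):
    """The model is genuinely sequential: frame order matters."""
    rng = np.random.default_rng(5)
    seq = rng.random((4, 6, 6))
    p_fwd = forward(seq, tiny_model).probs
    p_rev = forward(seq[::-1], tiny_model).probs
    assert not np.allclose(p_fwd[0], p_rev[-1], atol=1e-6)


def test_loss_closed_forms():
    t_len, h, w = 3, 4, 4
    y = np.zeros((t_len, h, w))
    y[:, 1:3, 1:3] = 1.0
    # uniform 0.5 prediction: ln 2 per pixel, mean over pixels, summed over frames
    half = np.full((t_len, h, w), 0.5)
    assert sequence_loss(half, y) == pytest.approx(t_len * np.log(2), abs=1e-6)
    # perfect prediction: only the clipping epsilon remains
    assert sequence_loss(y.copy(), y) == pytest.approx(0.0, abs=1e-5)
    # single pixel, y=1, p=0.25: -log 0.25
    assert sequence_loss(np.array([[[0.25]]]), np.array([[[1.0]]])) == pytest.approx(
        -np.log(0.25), abs=1e-6)


def test_loss_rejects_non_binary_truth():
    with pytest.raises(ValueError, match="binary"):
        sequence_loss(np.full((1, 2, 2), 0.5), np.full((1, 2, 2), 0.3))


def test_analytic_gradients_match_finite_differences():
    """The hand-derived BPTT gradients must agree with central finite
    differences for every parameter tensor of a small dense model."""
    rng = np.random.default_rng(6)
    model = DenseRNNModel.init(rng, n_frames=3, hidden_channels=2, kernel_size=3)
    x = rng.random((2, 3, 1, 5, 5))
    y = (rng.random((2, 3, 5, 5)) > 0.7).astype(float)
    _, grads = loss_and_grads(model, x, y)

    params = model.to_dict()
    eps = 1e-6
    check_rng = np.random.default_rng(7)
    for key, p in params.items():
        flat = p.reshape(-1) if p.ndim else p.reshape(1)
        g = grads[key].reshape(-1) if grads[key].ndim else grads[key].reshape(1)
        n_checks = min(len(flat), 10)
        for i in check_rng.choice(len(flat), n_checks, replace=False):
            orig = flat[i]
            flat[i] = orig + eps
            lp, _ = loss_and_grads(DenseRNNModel.from_dict(params), x, y)
            flat[i] = orig - eps
            lm, _ = loss_and_grads(DenseRNNModel.from_dict(params), x, y)
            flat[i] = orig
            fd = (lp - lm) / (2 * eps)
            assert g[i] == pytest.approx(fd, rel=1e-3, abs=1e-7), key


def test_omega_gradient_is_nonzero_for_generic_input(tiny_model):
    rng = np.random.default_rng(8)
    x = rng.random((1, 4, 1, 6, 6))
    y = (rng.random((1, 4, 6, 6)) > 0.6).astype(float)
    _, grads = loss_and_grads(tiny_model, x, y)
    assert np.abs(grads["omega"]).max() > 0


def test_prediction_binarization_threshold():
    probs = np.array([[[0.2, 0.6], [0.5, 0.9]]])
    pred = PredictionSequence(probs=probs)
    np.testing.assert_array_equal(pred.binarized, [[[0, 1], [1, 1]]])


def test_model_dict_roundtrip(tiny_model):
    rng = np.random.default_rng(9)
    seq = rng.random((4, 6, 6))
    clone = DenseRNNModel.from_dict(tiny_model.to_dict())
    np.testing.assert_array_equal(forward(seq, tiny_model).probs,
                                  forward(seq, clone).probs)
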