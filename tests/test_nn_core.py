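"""Layer library: fold/unfold bijection, dilated convolutions, recurrent
cells, gradients against finite differences, and the optimiser."""

import numpy as np
import pytest

import eitgest.nn.core as core
from eitgest.nn.core import (
    Adam,
    AvgPool2d,
    BilinearUpsample2x,
    Conv2d,
    GRU,
    LSTM,
    Linear,
    ReLU,
    fold2x2,
    softmax,
    softmax_cross_entropy,
    unfold2x2,
)


@pytest.fixture
def float64_layers(monkeypatch):
    """Run gradient checks in float64 so finite differences are exact."""
    monkeypatch.setattr(core, "DTYPE", np.float64)


# --- fold / unfold -----------------------------------------------------------


def test_fold_unfold_are_mutually_inverse_on_100_random_tensors():
    rng = np.random.default_rng(0)
    for _ in range(100):
        B, C = rng.integers(1, 4), rng.integers(1, 5)
        H = 2 * rng.integers(1, 9)
        W = 2 * rng.integers(1, 9)
        x = rng.normal(size=(B, C, H, W))
        f = fold2x2(x)
        assert f.shape == (B, 4 * C, H // 2, W // 2)
        assert np.array_equal(unfold2x2(f), x)
        y = rng.normal(size=(B, 4 * C, H // 2, W // 2))
        assert np.array_equal(fold2x2(unfold2x2(y)), y)


def test_fold_preserves_value_multiset_and_constants():
    rng = np.random.default_rng(1)
    x = rng.normal(size=(2, 8, 32, 32))
    f = fold2x2(x)
    assert np.array_equal(np.sort(f.ravel()), np.sort(x.ravel()))
    const = np.full((1, 3, 8, 8), 2.5)
    assert np.all(fold2x2(const) == 2.5)


def test_fold_2x2_block_positions_are_preserved():
    # a delta at (r, c) must land at spatial (r//2, c//2) in channel 2*(r%2)+(c%2)
    x = np.zeros((1, 1, 6, 6))
    x[0, 0, 3, 4] = 1.0
    f = fold2x2(x)
    assert f[0, 2 * (3 % 2) + (4 % 2), 3 // 2, 4 // 2] == 1.0
    assert f.sum() == 1.0


def test_fold_requires_even_dimensions_and_unfold_divisible_channels():
    with pytest.raises(ValueError):
        fold2x2(np.zeros((1, 1, 5, 6)))
    with pytest.raises(ValueError):
        unfold2x2(np.zeros((1, 6, 4, 4)))


# --- convolution -------------------------------------------------------------


@pytest.mark.parametrize("dilation", [1, 2, 4])
def test_dilated_conv_preserves_spatial_size(dilation):
    rng = np.random.default_rng(2)
    conv = Conv2d(4, 8, 3, rng, dilation=dilation)
    x = rng.normal(size=(2, 4, 16, 16)).astype(np.float32)
    assert conv.forward(x).shape == (2, 8, 16, 16)


@pytest.mark.parametrize("dilation", [1, 2, 4])
def test_conv_receptive_field_by_impulse_probe(dilation):
    """Gradient-support probe: the output at the centre depends on exactly
    the 9 taps of the dilated kernel, spanning a (2d+1)^2 bounding box."""
    rng = np.random.default_rng(3)
    conv = Conv2d(1, 1, 3, rng, dilation=dilation)
    conv.W.value[:] = 1.0
    x = np.zeros((1, 1, 17, 17), dtype=np.float32)
    conv.forward(x)
    g = np.zeros((1, 1, 17, 17), dtype=np.float32)
    g[0, 0, 8, 8] = 1.0
    gx = conv.backward(g)[0, 0]
    support = np.argwhere(gx != 0)
    assert len(support) == 9
    offsets = support - 8
    assert set(map(tuple, offsets)) == {
        (i * dilation, j * dilation) for i in (-1, 0, 1) for j in (-1, 0, 1)
    }
    assert np.ptp(support, axis=0).max() == 2 * dilation  # (2d+1)^2 box


def test_zero_input_zero_bias_gives_zero_output():
    rng = np.random.default_rng(4)
    conv = Conv2d(3, 5, 3, rng, dilation=2)
    out = conv.forward(np.zeros((2, 3, 8, 8), dtype=np.float32))
    assert np.all(out == 0.0)


def test_conv_gradients_match_finite_differences(float64_layers):
    rng = np.random.default_rng(5)
    conv = Conv2d(3, 4, 3, rng, dilation=2)
    x = rng.normal(size=(2, 3, 8, 8))
    W = rng.normal(size=(2, 4, 8, 8))

    def loss():
        return (conv.forward(x, True) * W).sum()

    loss()
    for p in conv.params():
        p.grad[:] = 0
    gx = conv.backward(W.copy())
    for arr, grad in [(conv.W.value, conv.W.grad), (conv.b.value, conv.b.grad), (x, gx)]:
        flat, gflat = arr.ravel(), grad.ravel()
        idx = rng.integers(0, flat.size, 12)
        for i in idx:
            eps, old = 1e-6, flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - gflat[i]) < 1e-6 * max(1.0, abs(fd))


# --- recurrent cells ---------------------------------------------------------


@pytest.mark.parametrize("cell_cls,n_gates", [(GRU, 3), (LSTM, 4)])
def test_recurrent_cell_gradients_match_finite_differences(
    float64_layers, cell_cls, n_gates
):
    rng = np.random.default_rng(6)
    cell = cell_cls(4, 5, rng)
    assert sum(p.size for p in cell.params()) == n_gates * 5 * (4 + 5 + 1)
    x = rng.normal(size=(2, 6, 4))
    W = rng.normal(size=(2, 5))

    def loss():
        return (cell.forward(x, True) * W).sum()

    loss()
    for p in cell.params():
        p.grad[:] = 0
    gx = cell.backward(W.copy())
    for arr, grad in [(p.value, p.grad) for p in cell.params()] + [(x, gx)]:
        flat, gflat = arr.ravel(), grad.ravel()
        idx = rng.integers(0, flat.size, 10)
        for i in idx:
            eps, old = 1e-6, flat[i]
            flat[i] = old + eps
            lp = loss()
            flat[i] = old - eps
            lm = loss()
            flat[i] = old
            fd = (lp - lm) / (2 * eps)
            assert abs(fd - gflat[i]) < 1e-6 * max(1.0, abs(fd))


def test_gru_final_state_depends_on_frame_order(float64_layers):
    rng = np.random.default_rng(7)
    cell = GRU(3, 4, rng)
    x = rng.normal(size=(1, 5, 3))
    h1 = cell.forward(x)
    h2 = cell.forward(x[:, ::-1])
    assert not np.allclose(h1, h2)


# --- pooling / upsampling adjoints ------------------------------------------


def test_upsample_and_pool_backward_are_exact_adjoints():
    rng = np.random.default_rng(8)
    up = BilinearUpsample2x(8)
    x = rng.normal(size=(2, 3, 8, 8))
    y = rng.normal(size=(2, 3, 16, 16))
    assert np.isclose((up.forward(x) * y).sum(), (x * up.backward(y)).sum())
    pool = AvgPool2d(4)
    fx = pool.forward(x)
    z = rng.normal(size=fx.shape)
    assert np.isclose((fx * z).sum(), (x * pool.backward(z)).sum())


def test_upsample_doubles_size_and_preserves_constants():
    up = BilinearUpsample2x(16)
    x = np.full((1, 1, 16, 16), 3.0)
    y = up.forward(x)
    assert y.shape == (1, 1, 32, 32)
    assert np.allclose(y, 3.0)


# --- loss & optimiser --------------------------------------------------------


def test_cross_entropy_closed_forms():
    logits = np.log(np.full((4, 9), 1.0 / 9))
    loss, _ = softmax_cross_entropy(logits, np.array([0, 3, 5, 8]))
    assert np.isclose(loss, np.log(9.0), atol=1e-6)
    confident = np.full((1, 9), -100.0)
    confident[0, 2] = 100.0
    loss, _ = softmax_cross_entropy(confident, np.array([2]))
    assert loss < 1e-6
    p = softmax(np.random.default_rng(9).normal(size=(5, 9)))
    assert np.allclose(p.sum(axis=1), 1.0)
    assert np.all(p >= 0)


def test_adam_reduces_loss_on_fixed_batch(float64_layers):
    rng = np.random.default_rng(10)
    lin = Linear(6, 16, rng)
    relu = ReLU()
    head = Linear(16, 3, rng)
    X = rng.normal(size=(32, 6))
    y = rng.integers(0, 3, 32)
    opt = Adam(lin.params() + head.params(), lr=1e-2)
    losses = []
    for _ in range(50):
        logits = head.forward(relu.forward(lin.forward(X, True), True), True)
        loss, d = softmax_cross_entropy(logits, y)
        losses.append(loss)
        opt.zero_grad()
        lin.backward(relu.backward(head.backward(d)))
        opt.step()
    assert losses[-1] < 0.5 * losses[0]
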