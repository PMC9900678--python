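"""Layer-level checks of the numpy NN toolkit: oracle comparisons against
scipy correlation, finite-difference gradients, and optimizer behavior."""

import numpy as np
import pytest
from scipy.signal import correlate2d

from dotrecon import nn


@pytest.fixture()
def nprng():
    return np.random.default_rng(0)


class TestConv2d:
    @pytest.mark.parametrize("k,stride,padding", [(3, 1, "same"), (5, 1, "same"), (2, 2, "valid")])
    def test_matches_scipy_correlation(self, nprng, k, stride, padding):
        cin, cout = 3, 4
        conv = nn.Conv2d(cin, cout, k, nprng, stride=stride, padding=padding)
        x = nprng.normal(size=(2, 9, 8, cin)).astype(np.float32)
        y = conv(x)
        pad = k // 2 if padding == "same" else 0
        for n in (0, 1):
            for o in range(cout):
                acc = np.zeros((x.shape[1] + 2 * pad - k + 1, x.shape[2] + 2 * pad - k + 1))
                for c in range(cin):
                    xi = np.pad(x[n, :, :, c], pad)
                    acc += correlate2d(xi, conv.w.value[:, :, c, o], mode="valid")
                acc = acc[::stride, ::stride] + conv.b.value[o]
                assert np.allclose(y[n, :, :, o], acc, atol=1e-4)

    def test_same_padding_preserves_shape(self, nprng):
        conv = nn.Conv2d(2, 5, 3, nprng)
        assert conv(np.zeros((1, 16, 15, 2), np.float32)).shape == (1, 16, 15, 5)

    def test_strided_valid_shape(self, nprng):
        conv = nn.Conv2d(4, 6, 2, nprng, stride=2, padding="valid")
        assert conv(np.zeros((1, 16, 15, 4), np.float32)).shape == (1, 8, 7, 6)


class TestPoolingAndUpsample:
    def test_maxpool_values(self):
        pool = nn.MaxPool2x2()
        x = np.arange(16, dtype=np.float32).reshape(1, 4, 4, 1)
        y = pool(x)
        assert y.ravel().tolist() == [5, 7, 13, 15]

    def test_maxpool_drops_odd_edge(self):
        pool = nn.MaxPool2x2()
        assert pool(np.zeros((1, 5, 7, 3), np.float32)).shape == (1, 2, 3, 3)

    def test_upsample_roundtrip_with_pool(self, nprng):
        x = nprng.normal(size=(2, 6, 5, 3)).astype(np.float32)
        up = nn.Upsample2x()
        pool = nn.MaxPool2x2()
        assert np.allclose(pool(up(x)), x)  # nearest blocks are constant


def _numeric_grad(layer, x, g_out, param, idx, eps=1e-4):
    flat = param.value.ravel()
    old = flat[idx]
    flat[idx] = old + eps
    lp = float((layer.forward(x, False) * g_out).sum())
    flat[idx] = old - eps
    lm = float((layer.forward(x, False) * g_out).sum())
    flat[idx] = old
    return (lp - lm) / (2 * eps)


class TestGradients:
    """Finite-difference validation (float64) of every layer's backward."""

    def setup_method(self):
        self._dtype = nn.DTYPE
        nn.DTYPE = np.float64

    def teardown_method(self):
        nn.DTYPE = self._dtype

    @pytest.mark.parametrize(
        "make",
        [
            lambda r: nn.Conv2d(3, 4, 3, r),
            lambda r: nn.Conv2d(3, 4, 2, r, stride=2, padding="valid"),
            lambda r: nn.Dense(10, 7, r),
        ],
        ids=["conv3x3", "conv2x2s2", "dense"],
    )
    def test_parameter_gradients(self, nprng, make):
        layer = make(nprng)
        x = (
            nprng.normal(size=(4, 6, 6, 3))
            if isinstance(layer, nn.Conv2d)
            else nprng.normal(size=(4, 10))
        )
        y = layer.forward(x, True)
        g_out = nprng.normal(size=y.shape)
        layer.backward(g_out)
        for p in layer.params():
            for idx in [0, p.value.size // 2, p.value.size - 1]:
                num = _numeric_grad(layer, x, g_out, p, idx)
                ana = p.grad.ravel()[idx]
                assert ana == pytest.approx(num, rel=1e-5, abs=1e-8)

    @pytest.mark.parametrize(
        "make,shape",
        [
            (lambda r: nn.Conv2d(2, 3, 3, r), (3, 5, 5, 2)),
            (lambda r: nn.BatchNorm(4, spatial=True), (3, 5, 5, 4)),
            (lambda r: nn.BatchNorm(6, spatial=False), (5, 6)),
            (lambda r: nn.ReLU(), (3, 5, 5, 2)),
            (lambda r: nn.MaxPool2x2(), (3, 6, 6, 2)),
            (lambda r: nn.Upsample2x(), (3, 4, 4, 2)),
        ],
        ids=["conv", "bn2d", "bn1d", "relu", "maxpool", "upsample"],
    )
    def test_input_gradients(self, nprng, make, shape):
        layer = make(nprng)
        x = nprng.normal(size=shape)
        y = layer.forward(x, True)
        g_out = nprng.normal(size=y.shape)
        gx = layer.backward(g_out)
        assert gx.shape == x.shape
        bufs = [b.copy() for b in layer.buffers()]

        def scalar(xv):
            for b, b0 in zip(layer.buffers(), bufs):
                b[...] = b0
            out = layer.forward(xv, True)
            if hasattr(layer, "_cache"):
                layer._cache.clear()
            return float((out * g_out).sum())

        rng2 = np.random.default_rng(5)
        for _ in range(6):
            idx = rng2.integers(x.size)
            eps = 1e-5
            xp = x.copy().ravel()
            xp[idx] += eps
            lp = scalar(xp.reshape(shape))
            xm = x.copy().ravel()
            xm[idx] -= eps
            lm = scalar(xm.reshape(shape))
            num = (lp - lm) / (2 * eps)
            assert gx.ravel()[idx] == pytest.approx(num, rel=1e-4, abs=1e-7)


class TestBatchNorm:
    def test_train_normalizes_batch(self, nprng):
        bn = nn.BatchNorm(3, spatial=True)
        x = nprng.normal(2.0, 3.0, size=(8, 4, 4, 3)).astype(np.float32)
        y = bn.forward(x, True)
        assert np.allclose(y.reshape(-1, 3).mean(axis=0), 0.0, atol=1e-5)
        assert np.allclose(y.reshape(-1, 3).std(axis=0), 1.0, atol=1e-2)

    def test_eval_uses_running_stats(self, nprng):
        bn = nn.BatchNorm(2, spatial=False)
        x = nprng.normal(1.0, 2.0, size=(64, 2)).astype(np.float32)
        for _ in range(200):
            bn.forward(x, True)
            bn._cache.clear()
        y = bn.forward(x, False)
        assert np.allclose(y.mean(axis=0), 0.0, atol=0.05)


class TestAdam:
    def test_minimizes_quadratic(self):
        p = nn.Parameter(np.array([5.0, -3.0]))
        opt = nn.Adam([p], lr=0.1, weight_decay=0.0)
        for _ in range(300):
            opt.zero_grad()
            p.grad[...] = 2 * p.value
            opt.step()
        assert np.abs(p.value).max() < 1e-3

    def test_decoupled_weight_decay_shrinks_params(self):
        p = nn.Parameter(np.array([1.0]))
        opt = nn.Adam([p], lr=0.01, weight_decay=0.5)
        opt.zero_grad()  # zero gradient: only decay acts
        opt.step()
        assert p.value[0] < 1.0
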