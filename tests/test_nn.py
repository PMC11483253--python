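"""Gradient and determinism checks for the autodiff engine and layers.

Gradients are verified against central finite differences on float64
inputs, which makes agreement to ~1e-6 relative error achievable.
"""

import numpy as np
import pytest

from temporalmatch import nn
from temporalmatch.nn import autodiff as ad
from temporalmatch.nn.autodiff import Tensor


def numgrad(f, x, eps=1e-5):
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        i = it.multi_index
        orig = x[i]
        x[i] = orig + eps
        fp = f()
        x[i] = orig - eps
        fm = f()
        x[i] = orig
        g[i] = (fp - fm) / (2 * eps)
        it.iternext()
    return g


def assert_grads_match(build, params, tol=1e-6):
    out = build()
    out.backward()
    for name, p in params.items():
        ng = numgrad(lambda: build().item(), p.data)
        # floor the denominator: some true gradients are ~0 (e.g. the key
        # bias, to which softmax attention is invariant) and finite-difference
        # noise would dominate a pure relative error there
        err = np.abs(p.grad - ng).max() / max(np.abs(ng).max(), 1e-3)
        assert err < tol, f"{name}: relative gradient error {err:.2e}"
        p.grad = None


@pytest.fixture
def rng():
    return np.random.default_rng(0)


class TestOpGradients:
    def test_matmul_softmax_cross_entropy(self, rng):
        w = Tensor(rng.normal(0, 1, (5, 7)), requires_grad=True)
        x = Tensor(rng.normal(0, 1, (4, 5)))
        t = np.array([1, 3, 6, 0])
        assert_grads_match(
            lambda: ad.softmax_cross_entropy(ad.matmul(x, w), t), {"w": w})

    def test_layer_norm(self, rng):
        g = Tensor(rng.normal(0, 1, (3, 6)))
        w = Tensor(rng.normal(1, 0.1, 6), requires_grad=True)
        b = Tensor(rng.normal(0, 0.1, 6), requires_grad=True)
        x = Tensor(rng.normal(0, 1, (3, 6)), requires_grad=True)
        assert_grads_match(lambda: ad.tsum(ad.layer_norm(x, w, b) * g),
                           {"w": w, "b": b, "x": x})

    def test_pointwise_nonlinearities(self, rng):
        a = Tensor(rng.normal(0, 1, (4, 4)), requires_grad=True)
        assert_grads_match(
            lambda: ad.tsum(ad.gelu(a) * ad.sigmoid(a) + ad.tanh(a) + ad.relu(a + 0.1)),
            {"a": a}, tol=1e-5)

    def test_batched_attention_pattern(self, rng):
        q = Tensor(rng.normal(0, 1, (2, 3, 4, 5)), requires_grad=True)
        k = Tensor(rng.normal(0, 1, (2, 3, 4, 5)), requires_grad=True)
        g = Tensor(rng.normal(0, 1, (2, 3, 4, 5)))
        assert_grads_match(
            lambda: ad.tsum(ad.matmul(
                ad.softmax(ad.matmul(q, ad.swapaxes(k, -1, -2))), k) * g),
            {"q": q, "k": k})

    def test_fused_linear(self, rng):
        x = Tensor(rng.normal(0, 1, (2, 4, 5)), requires_grad=True)
        w = Tensor(rng.normal(0, 1, (5, 3)), requires_grad=True)
        b = Tensor(rng.normal(0, 1, 3), requires_grad=True)
        g = Tensor(rng.normal(0, 1, (2, 4, 3)))
        assert_grads_match(lambda: ad.tsum(ad.linear(x, w, b) * g),
                           {"x": x, "w": w, "b": b})

    def test_fused_attention_matches_composed_ops(self, rng):
        q = Tensor(rng.normal(0, 1, (2, 2, 5, 4)), requires_grad=True)
        k = Tensor(rng.normal(0, 1, (2, 2, 5, 4)), requires_grad=True)
        v = Tensor(rng.normal(0, 1, (2, 2, 5, 4)), requires_grad=True)
        mask = np.ones((2, 5), dtype=bool)
        mask[1, 3:] = False
        g = Tensor(rng.normal(0, 1, (2, 2, 5, 4)))
        assert_grads_match(
            lambda: ad.tsum(ad.scaled_dot_attention(q, k, v, mask) * g),
            {"q": q, "k": k, "v": v}, tol=1e-5)
        # forward agrees with the primitive-op composition
        scale = 1.0 / np.sqrt(4)
        scores = ad.matmul(q, ad.swapaxes(k, -1, -2)) * Tensor(np.float64(scale))
        scores = scores + Tensor(
            np.where(mask[:, None, None, :], 0.0, -1e9))
        composed = ad.matmul(ad.softmax(scores), v)
        fused = ad.scaled_dot_attention(q, k, v, mask)
        np.testing.assert_allclose(fused.data, composed.data, rtol=1e-9)

    def test_bce_with_logits(self, rng):
        z = Tensor(rng.normal(0, 1, (6, 1)), requires_grad=True)
        y = (rng.random(6) > 0.5).astype(float)
        w = np.full(6, 1.3)
        assert_grads_match(lambda: ad.bce_with_logits(z, y, w), {"z": z})

    def test_gather_power_chain(self, rng):
        t = Tensor(rng.normal(0, 1, (5, 3)), requires_grad=True)
        idx = np.array([[0, 2], [4, 4]])
        assert_grads_match(
            lambda: ad.tmean(ad.power(
                ad.tsum(ad.gather_rows(t, idx) * ad.gather_rows(t, idx), axis=2)
                + Tensor(np.float64(1e-9)), 0.5)),
            {"t": t})

    def test_concat_and_reductions(self, rng):
        a = Tensor(rng.normal(0, 1, (2, 3)), requires_grad=True)
        b = Tensor(rng.normal(0, 1, (4, 3)), requires_grad=True)
        g = Tensor(rng.normal(0, 1, (6, 1)))
        assert_grads_match(
            lambda: ad.tsum(ad.tmean(ad.concat([a, b], axis=0),
                                     axis=1, keepdims=True) * g),
            {"a": a, "b": b})


def _float64(module):
    for p in module.parameters():
        p.data = p.data.astype(np.float64)
    return module


class TestModuleGradients:
    def test_transformer_layer_end_to_end(self, rng):
        layer = _float64(nn.TransformerLayer(8, 2, 16, rng))
        x = Tensor(rng.normal(0, 1, (2, 5, 8)))
        mask = np.ones((2, 5), dtype=bool)
        mask[1, 3:] = False
        g = Tensor(rng.normal(0, 1, (2, 5, 8)))
        params = {f"p{i}": p for i, p in enumerate(layer.parameters())}
        assert_grads_match(lambda: ad.tsum(layer(x, mask) * g), params, tol=1e-4)

    def test_lstm_end_to_end(self, rng):
        lstm = _float64(nn.LSTM(6, 4, rng))
        x = Tensor(rng.normal(0, 1, (3, 4, 6)))
        mask = np.array([[1, 1, 1, 1], [1, 1, 0, 0], [1, 0, 0, 0]], dtype=bool)
        g = Tensor(rng.normal(0, 1, (3, 4)))
        params = {f"p{i}": p for i, p in enumerate(lstm.parameters())}
        assert_grads_match(lambda: ad.tsum(lstm(x, mask) * g), params, tol=1e-4)

    def test_lstm_last_real_state_respects_mask(self, rng):
        # an item masked after step 1 must equal a length-1 sequence
        lstm = nn.LSTM(3, 5, rng)
        x_full = rng.normal(0, 1, (1, 4, 3)).astype(np.float32)
        mask_full = np.array([[True, False, False, False]])
        out_masked = lstm(Tensor(x_full), mask_full).data
        out_short = lstm(Tensor(x_full[:, :1]), np.array([[True]])).data
        np.testing.assert_allclose(out_masked, out_short, rtol=1e-6)


class TestAdam:
    def test_converges_on_quadratic(self):
        p = Tensor(np.array([5.0, -3.0]), requires_grad=True)
        opt = nn.Adam([p], lr=0.1)
        for _ in range(500):
            loss = ad.tsum(p * p)
            opt.zero_grad()
            loss.backward()
            opt.step()
        assert np.abs(p.data).max() < 1e-3

    def test_update_is_deterministic(self, rng):
        def run():
            r = np.random.default_rng(3)
            lin = nn.Linear(4, 2, r)
            opt = nn.Adam(lin.parameters(), lr=1e-3)
            x = Tensor(np.ones((3, 4), dtype=np.float32))
            for _ in range(5):
                loss = ad.tsum(lin(x) * lin(x))
                opt.zero_grad()
                loss.backward()
                opt.step()
            return [p.data.copy() for p in lin.parameters()]

        a, b = run(), run()
        for pa, pb in zip(a, b):
            assert np.array_equal(pa, pb)


class TestNoGrad:
    def test_no_graph_built_in_inference_mode(self, rng):
        w = Tensor(rng.normal(0, 1, (3, 3)), requires_grad=True)
        with ad.no_grad():
            out = ad.matmul(Tensor(np.eye(3)), w)
        assert not out.requires_grad and out._parents == ()
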