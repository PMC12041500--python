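import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from endosfm import autodiff as ad
from endosfm.autodiff import Adam, Conv2d, Module, Parameter, Tensor, \
    as_tensor, clip_grad_norm

from oracles import numeric_gradient


def check_grad(fn, x0, atol=1e-5):
    """Compare autodiff and central-difference gradients of a scalar-valued
    function of one array."""
    t = Tensor(np.asarray(x0, dtype=np.float64).copy(), requires_grad=True)
    fn(t).backward()
    num = numeric_gradient(lambda x: fn(Tensor(x)).item(),
                           np.asarray(x0, dtype=np.float64).copy())
    assert np.allclose(t.grad, num, atol=atol), \
        f"max err {np.abs(t.grad - num).max():.2e}"


class TestElementwise:
    def test_arithmetic_chain(self, rng):
        x = rng.normal(size=(3, 4))
        check_grad(lambda t: ((t * 2.0 - 1.0) / (t * t + 2.0)).sum(), x)

    def test_unary_functions(self, rng):
        x = 0.5 + rng.random((3, 3))
        for fn in (ad.exp, ad.log, ad.sqrt, ad.sin, ad.cos, ad.sigmoid,
                   ad.softplus):
            check_grad(lambda t, f=fn: f(t).sum(), x)

    def test_abs_and_pow(self, rng):
        x = rng.normal(size=(4, 4)) + 3.0   # keep away from |x| kink
        check_grad(lambda t: t.abs().sum(), x)
        check_grad(lambda t: (t ** 3).sum(), x)

    def test_relu_elu(self, rng):
        x = rng.normal(size=(5, 5)) + 0.3
        x[np.abs(x) < 1e-3] = 0.5           # avoid the kink
        check_grad(lambda t: ad.relu(t).sum(), x)
        check_grad(lambda t: ad.elu(t).sum(), x)

    def test_broadcasting_gradients(self, rng):
        a0 = rng.normal(size=(3, 1, 4))
        b0 = rng.normal(size=(2, 4))
        a = Tensor(a0, requires_grad=True)
        b = Tensor(b0, requires_grad=True)
        (a * b).sum().backward()
        assert a.grad.shape == a0.shape
        assert b.grad.shape == b0.shape
        assert np.allclose(a.grad, np.broadcast_to(b0, (3, 2, 4))
                           .sum(axis=1, keepdims=True))

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_sum_mean_axes_property(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=(2, 3, 4))
        axis = int(rng.integers(0, 3))
        keep = bool(rng.integers(0, 2))
        t = Tensor(x, requires_grad=True)
        t.mean(axis=axis, keepdims=keep).sum().backward()
        expected = np.full_like(x, 1.0 / x.shape[axis])
        assert np.allclose(t.grad, expected)


class TestStructural:
    def test_reshape_transpose_getitem(self, rng):
        x = rng.normal(size=(2, 3, 4))
        check_grad(lambda t: t.reshape(6, 4).transpose(1, 0)[1:3].sum(), x)

    def test_concatenate(self, rng):
        a = Tensor(rng.normal(size=(2, 3)), requires_grad=True)
        b = Tensor(rng.normal(size=(2, 2)), requires_grad=True)
        (ad.concatenate([a, b], axis=1) ** 2).sum().backward()
        assert np.allclose(a.grad, 2 * a.data)
        assert np.allclose(b.grad, 2 * b.data)

    def test_broadcast_to(self, rng):
        x = rng.normal(size=(1, 3, 1))
        check_grad(lambda t: (ad.broadcast_to(t, (2, 3, 4)) ** 2).sum(), x)

    def test_where_maximum(self, rng):
        x = rng.normal(size=(4, 4))
        mask = x > 0
        check_grad(lambda t: ad.where(mask, t * 2.0, t * 3.0).sum(), x)
        y = x + 10.0
        check_grad(lambda t: ad.maximum(t, 0.5).sum(), y)

    def test_upsample_nearest(self, rng):
        x = rng.normal(size=(1, 2, 3, 4))
        out = ad.upsample_nearest(Tensor(x), 2)
        assert out.shape == (1, 2, 6, 8)
        assert np.allclose(out.data[0, 0, ::2, ::2], x[0, 0])
        check_grad(lambda t: (ad.upsample_nearest(t, 2) ** 2).sum(), x)

    def test_take_pixels(self, rng):
        f = rng.normal(size=(2, 3, 5, 6))
        iy = rng.integers(0, 5, size=(2, 4, 4))
        ix = rng.integers(0, 6, size=(2, 4, 4))
        out = ad.take_pixels(Tensor(f), iy, ix)
        for n in range(2):
            assert np.allclose(out.data[n], f[n][:, iy[n], ix[n]])
        check_grad(lambda t: (ad.take_pixels(t, iy, ix) ** 2).sum(), f)


class TestConvAndFilters:
    @pytest.mark.parametrize("stride,padding", [(1, 1), (2, 1), (1, 0)])
    def test_conv2d_gradients(self, rng, stride, padding):
        x0 = rng.normal(size=(2, 3, 6, 7))
        w0 = rng.normal(size=(4, 3, 3, 3)) * 0.3
        b0 = rng.normal(size=(4,))
        mix = None

        def forward(x, w, b):
            out = ad.conv2d(x, w, b, stride=stride, padding=padding)
            nonlocal mix
            if mix is None:
                mix = np.random.default_rng(0).normal(size=out.shape)
            return (out * mix).sum()

        xt = Tensor(x0.copy(), requires_grad=True)
        wt = Tensor(w0.copy(), requires_grad=True)
        bt = Tensor(b0.copy(), requires_grad=True)
        forward(xt, wt, bt).backward()
        num_x = numeric_gradient(
            lambda x: forward(Tensor(x), Tensor(w0), Tensor(b0)).item(),
            x0.copy())
        num_w = numeric_gradient(
            lambda w: forward(Tensor(x0), Tensor(w), Tensor(b0)).item(),
            w0.copy())
        assert np.allclose(xt.grad, num_x, atol=1e-5)
        assert np.allclose(wt.grad, num_w, atol=1e-5)
        assert np.allclose(bt.grad,
                           mix.sum(axis=(0, 2, 3)), atol=1e-9)

    def test_conv2d_matches_direct_convolution(self, rng):
        """Cross-check against an explicit loop implementation."""
        x = rng.normal(size=(1, 2, 5, 5))
        w = rng.normal(size=(3, 2, 3, 3))
        out = ad.conv2d(Tensor(x), Tensor(w), None, stride=1, padding=1).data
        xp = np.pad(x, ((0, 0), (0, 0), (1, 1), (1, 1)))
        ref = np.zeros((1, 3, 5, 5))
        for co in range(3):
            for i in range(5):
                for j in range(5):
                    ref[0, co, i, j] = np.sum(
                        xp[0, :, i:i + 3, j:j + 3] * w[co])
        assert np.allclose(out, ref, atol=1e-12)

    def test_box3_mean_matches_scalar(self, rng):
        from oracles import box3_mean_scalar
        x = rng.normal(size=(7, 6))
        out = ad.box3_mean(Tensor(x[None, None])).data[0, 0]
        assert np.allclose(out, box3_mean_scalar(x), atol=1e-12)

    def test_box3_mean_gradient(self, rng):
        x = rng.normal(size=(1, 1, 5, 5))
        mix = rng.normal(size=(1, 1, 5, 5))
        check_grad(lambda t: (ad.box3_mean(t) * mix).sum(), x)


class TestOptimizer:
    def test_adam_matches_reference(self, rng):
        """Two steps of Adam against a hand-written reference."""
        p0 = rng.normal(size=(3,))
        param = Parameter(p0.copy())
        opt = Adam([param], lr=0.1, betas=(0.9, 0.99))
        ref = p0.copy()
        m = np.zeros(3)
        v = np.zeros(3)
        for t in range(1, 3):
            grad = 2.0 * param.data
            param.grad = grad.copy()
            opt.step()
            m = 0.9 * m + 0.1 * grad
            v = 0.99 * v + 0.01 * grad ** 2
            mh = m / (1 - 0.9 ** t)
            vh = v / (1 - 0.99 ** t)
            ref = ref - 0.1 * mh / (np.sqrt(vh) + 1e-8)
            assert np.allclose(param.data, ref, atol=1e-12)

    def test_adam_state_roundtrip(self, rng):
        params = [Parameter(rng.normal(size=(2, 2)))]
        opt = Adam(params, lr=0.05)
        params[0].grad = np.ones((2, 2))
        opt.step()
        state = opt.state_dict()
        params2 = [Parameter(params[0].data.copy())]
        opt2 = Adam(params2, lr=0.05)
        opt2.load_state_dict(state)
        params[0].grad = np.full((2, 2), 0.5)
        params2[0].grad = np.full((2, 2), 0.5)
        opt.step()
        opt2.step()
        assert np.allclose(params[0].data, params2[0].data, atol=1e-15)

    def test_clip_grad_norm(self):
        a = Parameter(np.zeros(3))
        a.grad = np.array([3.0, 4.0, 0.0])
        norm = clip_grad_norm([a], 1.0)
        assert norm == pytest.approx(5.0)
        assert np.allclose(a.grad, np.array([0.6, 0.8, 0.0]))
        # below the cap: untouched
        a.grad = np.array([0.3, 0.4, 0.0])
        clip_grad_norm([a], 1.0)
        assert np.allclose(a.grad, np.array([0.3, 0.4, 0.0]))


class TestModule:
    def test_state_dict_roundtrip(self, rng):
        conv = Conv2d(2, 3, 3, rng)
        state = conv.state_dict()
        conv2 = Conv2d(2, 3, 3, np.random.default_rng(999))
        conv2.load_state_dict(state)
        x = Tensor(rng.normal(size=(1, 2, 4, 4)))
        assert np.allclose(conv(x).data, conv2(x).data, atol=1e-15)

    def test_load_rejects_shape_mismatch(self, rng):
        conv = Conv2d(2, 3, 3, rng)
        other = Conv2d(2, 4, 3, rng)
        with pytest.raises((ValueError, KeyError)):
            conv.load_state_dict(other.state_dict())
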