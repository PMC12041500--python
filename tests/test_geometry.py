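import numpy as np
import pytest
from scipy.ndimage import map_coordinates
from scipy.spatial.transform import Rotation

from endosfm import autodiff as ad
from endosfm.autodiff import Tensor
from endosfm.geometry import (Intrinsics, RigidMotion, grid_sample,
                              pixel_grid, project_warp, rotate_points,
                              warp_features_at_plane, warp_to_source)

from conftest import random_scene
from oracles import brute_force_warp, numeric_gradient


class TestIntrinsics:
    def test_matrix_roundtrip(self):
        intr = Intrinsics(0.82, 1.02, 0.5, 0.5)
        k = intr.to_matrix(64, 48)
        assert k[0, 0] == pytest.approx(0.82 * 64)
        assert k[1, 2] == pytest.approx(0.5 * 48)
        back = Intrinsics.from_matrix(k, 64, 48)
        assert back == intr

    @pytest.mark.parametrize("bad", [dict(fx=-1.0), dict(fy=0.0),
                                     dict(cx=1.5), dict(cy=0.0)])
    def test_validation(self, bad):
        kwargs = dict(fx=0.8, fy=1.0, cx=0.5, cy=0.5)
        kwargs.update(bad)
        with pytest.raises(ValueError):
            Intrinsics(**kwargs)


class TestRigidMotion:
    def test_inverse_composes_to_identity(self, rng):
        m = RigidMotion(tuple(rng.normal(size=3) * 0.3),
                        tuple(rng.normal(size=3)))
        ident = m.compose(m.inverse()).to_matrix()
        assert np.allclose(ident, np.eye(4), atol=1e-12)

    def test_matrix_roundtrip(self, rng):
        m = RigidMotion((0.1, -0.2, 0.05), (1.0, 2.0, -0.5))
        back = RigidMotion.from_matrix(m.to_matrix())
        assert np.allclose(back.rotation, m.rotation)
        assert np.allclose(back.translation, m.translation)

    def test_rejects_bad_shapes(self):
        with pytest.raises(ValueError):
            RigidMotion((0.0, 0.0), (0.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            RigidMotion((np.nan, 0.0, 0.0), (0.0, 0.0, 0.0))


class TestRotatePoints:
    def test_matches_scipy_rotation(self, rng):
        rotvec = rng.normal(scale=0.5, size=(2, 3))
        pts = rng.normal(size=(2, 4, 5, 3))
        x, y, z = (Tensor(pts[..., i]) for i in range(3))
        xo, yo, zo = rotate_points(Tensor(rotvec), x, y, z)
        for n in range(2):
            expected = Rotation.from_rotvec(rotvec[n]).apply(
                pts[n].reshape(-1, 3)).reshape(4, 5, 3)
            got = np.stack([xo.data[n], yo.data[n], zo.data[n]], axis=-1)
            assert np.allclose(got, expected, atol=1e-12)

    def test_zero_rotation_is_identity(self, rng):
        pts = rng.normal(size=(1, 3, 3, 3))
        x, y, z = (Tensor(pts[..., i]) for i in range(3))
        xo, yo, zo = rotate_points(Tensor(np.zeros((1, 3))), x, y, z)
        assert np.allclose(xo.data, pts[..., 0], atol=1e-12)
        assert np.allclose(zo.data, pts[..., 2], atol=1e-12)

    def test_gradient_through_zero(self, rng):
        """The epsilon guard must leave the rotation gradient finite and
        correct near the zero-rotation limit."""
        pts = rng.normal(size=(1, 2, 2, 3))
        x, y, z = (Tensor(pts[..., i]) for i in range(3))

        def loss_of(rv):
            xo, yo, zo = rotate_points(Tensor(rv.reshape(1, 3)), x, y, z)
            return (xo.sum() + 2.0 * yo.sum() - zo.sum()).item()

        rv = np.zeros(3)
        rv_t = Tensor(rv.reshape(1, 3), requires_grad=True)
        xo, yo, zo = rotate_points(rv_t, x, y, z)
        (xo.sum() + 2.0 * yo.sum() - zo.sum()).backward()
        num = numeric_gradient(loss_of, rv, eps=1e-7)
        assert np.allclose(rv_t.grad.ravel(), num, atol=1e-6)


class TestGridSample:
    def test_interior_matches_map_coordinates(self, rng):
        img = rng.random((1, 2, 9, 11))
        u = 1.0 + 8.0 * rng.random((1, 5, 6))
        v = 1.0 + 6.0 * rng.random((1, 5, 6))
        out = grid_sample(Tensor(img), Tensor(u), Tensor(v)).data
        for c in range(2):
            ref = map_coordinates(img[0, c], [v[0].ravel(), u[0].ravel()],
                                  order=1).reshape(5, 6)
            assert np.allclose(out[0, c], ref, atol=1e-12)

    def test_integer_coordinates_reproduce_pixels(self, rng):
        img = rng.random((1, 1, 4, 5))
        u, v = pixel_grid(5, 4)
        out = grid_sample(Tensor(img), Tensor(u[None]), Tensor(v[None])).data
        assert np.allclose(out[0, 0], img[0, 0], atol=1e-15)


class TestWarp:
    def test_identity_motion_is_identity(self, rng):
        img, depth, _, intr = random_scene(rng)
        res = warp_to_source(img, depth, RigidMotion((0, 0, 0), (0, 0, 0)),
                             intr)
        assert np.allclose(res.image, img, atol=1e-9)
        assert res.valid_mask.all()

    def test_matches_brute_force_oracle(self, rng):
        img, depth, motion, intr = random_scene(rng)
        res = warp_to_source(img, depth, motion, intr)
        ref, valid = brute_force_warp(img, depth, motion.rotation,
                                      motion.translation, intr.fx, intr.fy,
                                      intr.cx, intr.cy)
        assert (res.valid_mask.astype(bool) == valid).all()
        assert np.abs(res.image - ref).max() <= 1e-6

    def test_pure_x_translation_shifts_fronto_plane(self):
        """A fronto-parallel plane at depth Z seen under camera translation
        tx moves by exactly fx_px * tx / Z pixels."""
        h, w, z, tx = 12, 16, 2.0, 0.25
        intr = Intrinsics(0.8, 0.9, 0.5, 0.5)
        img = np.zeros((h, w))
        img[:, 8] = 1.0
        depth = np.full((h, w), z)
        res = warp_to_source(img, depth, RigidMotion((0, 0, 0), (tx, 0, 0)),
                             intr)
        shift = intr.fx * w * tx / z
        u = np.arange(w, dtype=float)
        expected_col = np.clip(1.0 - np.abs(u + shift - 8.0), 0.0, 1.0)
        inside = u + shift <= w - 1
        assert np.allclose(res.image[:, inside],
                           np.broadcast_to(expected_col[inside],
                                           (h, inside.sum())), atol=1e-9)

    def test_behind_camera_marked_invalid(self):
        intr = Intrinsics(0.8, 0.8, 0.5, 0.5)
        img = np.ones((8, 8))
        depth = np.full((8, 8), 1.0)
        res = warp_to_source(img, depth,
                             RigidMotion((0, 0, 0), (0, 0, -5.0)), intr)
        assert not res.valid_mask.any()

    def test_rejects_nonpositive_depth(self):
        intr = Intrinsics(0.8, 0.8, 0.5, 0.5)
        with pytest.raises(ValueError):
            warp_to_source(np.ones((4, 4)), np.zeros((4, 4)),
                           RigidMotion((0, 0, 0), (0, 0, 0)), intr)

    def test_plane_warp_equals_constant_depth_warp(self, rng):
        feats = rng.random((6, 7, 4))
        motion = RigidMotion((0.01, -0.02, 0.005), (0.02, 0.0, 0.01))
        intr = Intrinsics(0.7, 0.7, 0.5, 0.5)
        a = warp_features_at_plane(feats, 1.5, motion, intr)
        b = warp_to_source(feats, np.full((6, 7), 1.5), motion, intr)
        assert np.allclose(a.image, b.image)
        assert (a.valid_mask == b.valid_mask).all()


class TestWarpGradients:
    def test_gradient_wrt_depth_and_motion(self, rng):
        """Autodiff gradients through the full warp match central
        differences."""
        img = rng.random((1, 1, 6, 8))
        depth0 = 1.0 + rng.random((1, 6, 8))
        rot0 = np.array([[0.02, -0.01, 0.015]])
        tr0 = np.array([[0.03, 0.01, -0.02]])
        weights = rng.random((1, 1, 6, 8))

        def run(depth, rot, tr, fx):
            w_, _ = project_warp(Tensor(img), Tensor(depth), Tensor(rot),
                                 Tensor(tr), Tensor(fx), Tensor(0.9),
                                 Tensor(0.5), Tensor(0.5))
            return (w_ * weights).sum()

        d_t = Tensor(depth0.copy(), requires_grad=True)
        r_t = Tensor(rot0.copy(), requires_grad=True)
        t_t = Tensor(tr0.copy(), requires_grad=True)
        f_t = Tensor(0.8, requires_grad=True)
        w_, _ = project_warp(Tensor(img), d_t, r_t, t_t,
                             f_t, Tensor(0.9), Tensor(0.5), Tensor(0.5))
        (w_ * weights).sum().backward()

        num_r = numeric_gradient(
            lambda r: run(depth0, r, tr0, 0.8).item(), rot0.copy())
        num_t = numeric_gradient(
            lambda t: run(depth0, rot0, t, 0.8).item(), tr0.copy())
        num_f = numeric_gradient(
            lambda f: run(depth0, rot0, tr0, float(f)).item(),
            np.array(0.8))
        assert np.allclose(r_t.grad, num_r, atol=1e-5)
        assert np.allclose(t_t.grad, num_t, atol=1e-5)
        assert np.allclose(f_t.grad, num_f, atol=1e-5)
        # depth gradient: bilinear sampling is piecewise linear, so check
        # only pixels whose sample point is far from cell boundaries
        num_d = numeric_gradient(
            lambda d: run(d, rot0, tr0, 0.8).item(), depth0.copy())
        close = np.abs(d_t.grad - num_d)
        assert np.median(close) < 1e-5
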