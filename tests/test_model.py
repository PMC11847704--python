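"""Model components: equivariance, Euler encoding, spatial transform."""

import math

import numpy as np
import pytest

from codae.model import (
    CODAE,
    ModelConfig,
    euler_encode,
    group_conv,
    group_max_pool,
    lift_conv,
    rotation_resampling_matrix,
    spatial_transform,
)


def rotate_shift(feat, rotdir=1, shift=3):
    """The group action on an oriented feature map for a 90-deg input
    rotation (N=4): spatial rot90 plus a cyclic orientation shift."""
    return np.roll(np.rot90(feat, rotdir, axes=(-2, -1)), shift, axis=2)


@pytest.fixture()
def oriented_input(rng):
    img = np.zeros((1, 1, 16, 16), dtype=np.float32)
    img[0, 0, 4:12, 5:10] = rng.random((8, 5)).astype(np.float32)
    return img


class TestKernelRotation:
    def test_90_degree_rotation_is_exact_permutation(self, rng):
        M = rotation_resampling_matrix(5, math.pi / 2)
        assert np.allclose(np.sort(M.sum(axis=1)), 1.0)  # rows sum to 1
        k = rng.standard_normal((5, 5)).astype(np.float32)
        kr = (M @ k.ravel()).reshape(5, 5)
        assert np.allclose(kr, np.rot90(k, 3), atol=1e-6)

    def test_identity_rotation(self, rng):
        M = rotation_resampling_matrix(7, 0.0)
        assert np.allclose(M, np.eye(49), atol=1e-12)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            rotation_resampling_matrix(4, 0.3)


class TestLiftConv:
    def test_orientation_zero_matches_plain_correlation(self, oriented_input, rng):
        from scipy.signal import correlate2d
        k = rng.standard_normal((2, 1, 5, 5)).astype(np.float32)
        out = lift_conv(oriented_input, k, 4)
        for f in range(2):
            ref = correlate2d(oriented_input[0, 0], k[f, 0], mode="same")
            assert np.abs(out[0, f, 0] - ref).max() < 1e-4

    def test_zero_input_gives_zero_map(self):
        out = lift_conv(np.zeros((1, 1, 8, 8), np.float32),
                        np.ones((1, 1, 3, 3), np.float32), 4)
        assert np.abs(out).max() == 0.0

    def test_rotate_by_90_shifts_orientation_axis(self, oriented_input, rng):
        k = rng.standard_normal((2, 1, 5, 5)).astype(np.float32)
        out = lift_conv(oriented_input, k, 4)
        rot = np.rot90(oriented_input, 1, axes=(2, 3)).copy()
        out_rot = lift_conv(rot, k, 4)
        assert np.abs(rotate_shift(out) - out_rot).max() < 1e-5


class TestGroupConv:
    def test_equivariance_through_composition(self, oriented_input, rng):
        k1 = rng.standard_normal((2, 1, 5, 5)).astype(np.float32) * 0.5
        k2 = rng.standard_normal((3, 2, 4, 3, 3)).astype(np.float32) * 0.5
        a = group_conv(lift_conv(oriented_input, k1, 4), k2)
        rot = np.rot90(oriented_input, 1, axes=(2, 3)).copy()
        b = group_conv(lift_conv(rot, k1, 4), k2)
        assert np.abs(rotate_shift(a) - b).max() < 1e-5

    def test_zero_kernels_zero_output(self, oriented_input):
        feat = lift_conv(oriented_input, np.ones((1, 1, 3, 3), np.float32), 4)
        out = group_conv(feat, np.zeros((2, 1, 4, 3, 3), np.float32))
        assert np.abs(out).max() == 0.0

    def test_single_orientation_reduces_to_plain_conv(self, oriented_input, rng):
        from scipy.signal import correlate2d
        feat = oriented_input[:, :, None]  # (1, 1, 1, 16, 16)
        k = rng.standard_normal((2, 1, 1, 3, 3)).astype(np.float32)
        out = group_conv(feat, k)
        for f in range(2):
            ref = correlate2d(oriented_input[0, 0], k[f, 0, 0], mode="same")
            assert np.abs(out[0, f, 0] - ref).max() < 1e-4

    def test_orientation_axis_mismatch_rejected(self, oriented_input):
        feat = lift_conv(oriented_input, np.ones((1, 1, 3, 3), np.float32), 4)
        with pytest.raises(ValueError, match="orientation-axis"):
            group_conv(feat, np.zeros((2, 1, 8, 3, 3), np.float32))


class TestGroupMaxPool:
    def test_cyclic_permutation_invariance(self, rng):
        feat = rng.standard_normal((2, 3, 8, 5, 5)).astype(np.float32)
        base = group_max_pool(feat)
        for s in range(1, 8):
            assert np.array_equal(group_max_pool(np.roll(feat, s, axis=2)),
                                  base)

    def test_dominant_channel_wins(self, rng):
        feat = rng.standard_normal((1, 2, 4, 6, 6)).astype(np.float32)
        feat[:, :, 2] += 100.0
        assert np.allclose(group_max_pool(feat), feat[:, :, 2])


class TestEulerEncoding:
    def test_reference_axis_zero_angle(self):
        assert np.allclose(euler_encode(np.zeros(1)), [1.0, 0.0])

    def test_unit_norm_everywhere(self, rng):
        z = rng.standard_normal((200, 5)) * 3.0
        norms = np.linalg.norm(euler_encode(z), axis=1)
        assert np.abs(norms - 1.0).max() < 1e-12

    def test_jacobian_columns_orthogonal(self, rng):
        eps = 1e-5
        for _ in range(30):
            z0 = rng.standard_normal(3) * 2.0
            cols = []
            for i in range(3):
                e = np.zeros(3)
                e[i] = eps
                cols.append((euler_encode(z0 + e) - euler_encode(z0 - e))
                            / (2 * eps))
            J = np.stack(cols, axis=1)
            G = J.T @ J
            off = G - np.diag(np.diag(G))
            assert np.abs(off).max() < 1e-5


class TestSpatialTransform:
    def test_identity(self, oriented_input):
        out = spatial_transform(oriented_input, 0.0, 0.0, 0.0)
        assert np.abs(out - oriented_input).max() == 0.0

    def test_integer_translation_roundtrip(self, oriented_input):
        t = spatial_transform(oriented_input, 3.0, -2.0, 0.0)
        back = spatial_transform(t, -3.0, 2.0, 0.0)
        assert np.abs(back - oriented_input).max() == 0.0

    def test_90_degree_equals_index_rotation(self, oriented_input):
        out = spatial_transform(oriented_input, 0.0, 0.0, math.pi / 2)
        assert np.allclose(out, np.rot90(oriented_input, 3, axes=(2, 3)),
                           atol=1e-5)

    def test_rotation_inverse_near_identity(self):
        # a smooth blob: bilinear resampling error vanishes away from edges
        g = np.arange(32, dtype=np.float32)
        gx, gy = np.meshgrid(g, g, indexing="xy")
        img = np.exp(-((gx - 18) ** 2 + (gy - 13) ** 2) / 30.0)[None, None]
        t = spatial_transform(spatial_transform(img, 0, 0, 0.7), 0, 0, -0.7)
        inner = (slice(None), slice(None), slice(4, -4), slice(4, -4))
        assert np.abs(t[inner] - img[inner]).max() < 0.03  # bilinear tolerance


class TestCODAEModel:
    def test_encode_shape_contract(self, xyrcs_small):
        imgs, _ = xyrcs_small
        model = CODAE(ModelConfig(image_size=32, d=2, seed=0))
        z_equi, z_inv = model.encode(imgs.data[:8])
        assert z_equi.shape == (8, 3)
        assert z_inv.shape == (8, 2)
        assert np.isfinite(z_equi).all() and np.isfinite(z_inv).all()

    def test_encode_rejects_wrong_size(self):
        model = CODAE(ModelConfig(image_size=32, seed=0))
        from codae.autograd import Tensor
        with pytest.raises(ValueError, match="size"):
            model.forward(Tensor(np.zeros((1, 1, 16, 16), np.float32)))

    def test_decode_dimension_mismatch_rejected(self):
        model = CODAE(ModelConfig(image_size=32, d=2, seed=0))
        with pytest.raises(ValueError, match="dimension"):
            model.decode(np.zeros(5))

    def test_decoder_deterministic_for_identical_codes(self):
        model = CODAE(ModelConfig(image_size=32, d=2, seed=0))
        code = euler_encode(np.array([[0.3, -0.2], [0.3, -0.2]]))
        out = model.decode(code)
        assert np.array_equal(out[0], out[1])
        assert out.min() >= 0.0 and out.max() <= 1.0

    def test_checkpoint_roundtrip(self, tmp_path, xyrcs_small):
        imgs, _ = xyrcs_small
        model = CODAE(ModelConfig(image_size=32, seed=3))
        path = tmp_path / "m.npz"
        model.save(path)
        clone = CODAE.load(path)
        a = model.encode(imgs.data[:4])
        b = clone.encode(imgs.data[:4])
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_plain_conv_ablation_runs(self, xyrcs_small):
        imgs, _ = xyrcs_small
        model = CODAE(ModelConfig(image_size=32, equivariant=False, seed=0))
        z_equi, z_inv = model.encode(imgs.data[:4])
        assert z_equi.shape == (4, 3)

    def test_invalid_n_orient_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(n_orient=7)
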