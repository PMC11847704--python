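"""Losses, the beta schedule, and training-loop bookkeeping."""

import math

import numpy as np
import pytest

from codae.model import CODAE, ModelConfig, spatial_transform
from codae.moments import moment_targets
from codae.synth import SynthConfig, generate_xyrcs
from codae.train import (
    TrainConfig,
    beta_schedule,
    latent_traverse,
    moment_loss,
    reconstruct_views,
    reconstruction_loss,
    train_codae,
)


class TestReconstructionLoss:
    def test_identity_is_zero(self, rng):
        x = rng.random((2, 1, 8, 8))
        assert reconstruction_loss(x, x) == 0.0

    def test_constant_offset(self, rng):
        x = rng.random((2, 1, 8, 8)) * 0.3
        assert reconstruction_loss(x, x + 0.5) == pytest.approx(0.25)

    def test_matches_pixel_loop_oracle(self, rng):
        a = rng.random((3, 1, 5, 5))
        b = rng.random((3, 1, 5, 5))
        total = 0.0
        for i in range(3):
            for y in range(5):
                for x in range(5):
                    total += (a[i, 0, y, x] - b[i, 0, y, x]) ** 2
        assert reconstruction_loss(a, b) == pytest.approx(total / 75)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((1, 1, 4, 4)), np.zeros((1, 1, 5, 5)))

    def test_bce_mode_nonnegative(self, rng):
        a = (rng.random((2, 1, 6, 6)) > 0.5).astype(float)
        b = rng.random((2, 1, 6, 6))
        assert reconstruction_loss(a, b, kind="bce") > 0.0


class TestMomentLoss:
    def test_exact_match_is_zero(self):
        z = np.array([[1.0, -2.0, 0.4]])
        assert moment_loss(z, ([1.0], [-2.0], [0.4])) == 0.0

    def test_pi_periodic_orientation(self):
        z = np.array([[0.0, 0.0, 0.4 + math.pi]])
        assert moment_loss(z, ([0.0], [0.0], [0.4])) == pytest.approx(0.0, abs=1e-12)

    def test_quarter_turn_squared_distance(self):
        z = np.array([[0.0, 0.0, 0.4 + math.pi / 2]])
        assert moment_loss(z, ([0.0], [0.0], [0.4])) == pytest.approx(
            (math.pi / 2) ** 2)

    def test_learn_xy_off_skips_positions(self):
        z = np.array([[5.0, 5.0, 0.4]])
        assert moment_loss(z, ([0.0], [0.0], [0.4]), learn_xy=False) == 0.0

    def test_degenerate_samples_skipped(self):
        z = np.array([[0.0, 0.0, 1.0], [3.0, 0.0, 0.0]])
        targets = (np.zeros(2), np.zeros(2), np.array([1.0, 0.0]),
                   np.array([True, False]), np.array([True, False]))
        assert moment_loss(z, targets) == 0.0


class TestBetaSchedule:
    def _cfg(self, **kw):
        from dataclasses import replace
        return replace(TrainConfig(total_steps=100), **kw)

    def test_starts_at_beta0(self):
        assert beta_schedule(0, self._cfg()) == 10.0

    def test_zero_at_and_after_horizon(self):
        cfg = self._cfg()
        for step in (50, 51, 99, 100, 10_000):
            assert beta_schedule(step, cfg) == 0.0

    def test_non_increasing(self):
        cfg = self._cfg()
        vals = [beta_schedule(s, cfg) for s in range(100)]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_cosine_shape_also_decays_to_zero(self):
        cfg = self._cfg(beta_shape="cosine")
        assert beta_schedule(0, cfg) == pytest.approx(10.0)
        assert beta_schedule(70, cfg) == 0.0


@pytest.fixture(scope="module")
def tiny_run():
    imgs, tab = generate_xyrcs(SynthConfig(n=16, image_size=32, seed=2))
    cfg = TrainConfig(epochs=1, batch_size=8, seed=0,
                      model=ModelConfig(image_size=32, seed=0))
    model, log = train_codae(imgs, cfg)
    return imgs, tab, model, log


class TestTrainingLoop:
    def test_loss_log_bookkeeping(self, tiny_run):
        _, _, _, log = tiny_run
        assert len(log.epochs) == 1
        assert len(log.steps) == 2  # 16 images / batch 8
        for s in log.steps:
            assert s.total == pytest.approx(s.recon + s.beta * s.moment,
                                            rel=1e-6)

    def test_seed_reproducibility(self):
        imgs, _ = generate_xyrcs(SynthConfig(n=16, image_size=32, seed=2))
        cfg = TrainConfig(epochs=1, batch_size=8, seed=5,
                          model=ModelConfig(image_size=32, seed=5))
        m1, l1 = train_codae(imgs, cfg)
        m2, l2 = train_codae(imgs, cfg)
        for k in m1.params:
            assert np.array_equal(m1.params[k].data, m2.params[k].data)
        assert [s.total for s in l1.steps] == [s.total for s in l2.steps]

    def test_beta0_zero_total_is_pure_reconstruction(self):
        imgs, _ = generate_xyrcs(SynthConfig(n=16, image_size=32, seed=2))
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0, beta0=0.0,
                          model=ModelConfig(image_size=32, seed=0))
        _, log = train_codae(imgs, cfg)
        for s in log.steps:
            assert s.total == s.recon


class TestReconstructViews:
    def test_same_view_is_transform_of_aligned(self, tiny_run):
        imgs, _, model, _ = tiny_run
        aligned, same = reconstruct_views(model, imgs.data[:6])
        z_equi, _ = model.encode(imgs.data[:6])
        manual = spatial_transform(aligned, z_equi[:, 0], z_equi[:, 1],
                                   z_equi[:, 2])
        assert np.abs(manual - same).max() < 1e-6

    def test_zero_pose_means_identical_views(self, tiny_run):
        _, _, model, _ = tiny_run
        code_img = model.decode(
            np.array([1.0, 0.0, 0.0]))  # any aligned image
        stack = code_img[None]
        out = spatial_transform(stack, 0.0, 0.0, 0.0)
        assert np.array_equal(out, stack)


class TestLatentTraverse:
    def test_grid_shape(self, tiny_run):
        imgs, _, model, _ = tiny_run
        zq, zi = model.encode(imgs.data[:1])
        grid = latent_traverse(model, (zq[0], zi[0]), dim=3,
                               values=np.linspace(-1, 1, 5))
        assert grid.shape == (5, 1, 32, 32)

    def test_x_traversal_moves_centroid_monotonically(self, tiny_run):
        from codae.moments import compute_moments
        imgs, _, model, _ = tiny_run
        zq, zi = model.encode(imgs.data[:1])
        grid = latent_traverse(model, (zq[0], zi[0]), dim=0,
                               values=[-5.0, 0.0, 5.0])
        xs = [compute_moments(g[0]).xbar for g in grid]
        assert xs[0] < xs[1] < xs[2]

    def test_inv_traversal_keeps_pose_fixed(self, tiny_run):
        from codae.moments import compute_moments
        imgs, _, model, _ = tiny_run
        zq, zi = model.encode(imgs.data[:1])
        grid = latent_traverse(model, (zq[0], zi[0]), dim=3,
                               values=[-0.5, 0.0, 0.5])
        cents = [(compute_moments(g[0]).xbar, compute_moments(g[0]).ybar)
                 for g in grid]
        for cx, cy in cents[1:]:
            assert abs(cx - cents[0][0]) < 2.0
            assert abs(cy - cents[0][1]) < 2.0

    def test_out_of_range_dim_rejected(self, tiny_run):
        imgs, _, model, _ = tiny_run
        zq, zi = model.encode(imgs.data[:1])
        with pytest.raises(ValueError):
            latent_traverse(model, (zq[0], zi[0]), dim=9, values=[0.0])


class TestMomentSourceCom:
    def test_com_mode_trains_without_xy(self):
        imgs, _ = generate_xyrcs(SynthConfig(n=16, image_size=32, seed=4))
        cfg = TrainConfig(epochs=1, batch_size=8, seed=0, learn_xy=False,
                          moment_source="com",
                          model=ModelConfig(image_size=32, seed=0))
        model, log = train_codae(imgs, cfg)
        zq, _ = model.encode(imgs.data[:4])
        assert np.allclose(zq[:, :2], 0.0)  # translation frozen
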