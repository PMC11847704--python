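"""Losses, the beta decay schedule, and the optimization loop.

The objective is

    L = L_r(I, T_z(D(E(z_inv)))) + beta(t) * L_m({xbar, ybar, alpha}, z_equi)

where ``L_r`` is the pixelwise reconstruction error between the input
and the same-view reconstruction, and ``L_m`` ties the pose code to the
image-moment centroid and orientation of each input.  ``beta`` starts
large and decays to zero, so moments act as guidance early in training
and the reconstruction loss alone refines the pose afterwards.  The
moment orientation is only defined modulo pi, so the angular term of
``L_m`` uses the pi-periodic squared distance; the full-circle
orientation is resolved by the reconstruction loss once beta has
decayed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import autograd as ag
from .autograd import Tensor, Adam
from .model import CODAE, ModelConfig, _spatial_transform_t, TWO_PI
from .moments import moment_targets
from .synth import ImageBatch


@dataclass(frozen=True)
class TrainConfig:
    """Optimization settings.

    ``beta0`` is the initial moment-loss weight; the default schedule
    decays it linearly to zero at ``beta_end_frac`` of the total step
    count.  ``learn_xy=False`` freezes the translation part of the pose
    (the protocol for pre-centred stacks such as diffraction patterns),
    and ``moment_source="com"`` takes the orientation guidance from the
    centre-of-mass angle instead of the second-moment axis.
    """

    epochs: int = 10
    batch_size: int = 32
    lr: float = 1e-3
    beta0: float = 10.0
    beta_end_frac: float = 0.5
    beta_shape: str = "linear"   # or "cosine"
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)
    learn_xy: bool = True
    moment_source: str = "image_moments"
    recon_loss: str = "mse"      # or "bce" for silhouette data
    clip_norm: float = 5.0
    total_steps: int | None = None  # derived from data unless set

    def __post_init__(self):
        if self.beta0 < 0:
            raise ValueError("beta0 must be non-negative")
        if self.moment_source not in ("image_moments", "com"):
            raise ValueError("moment_source must be 'image_moments' or 'com'")


@dataclass
class LossState:
    """One logged optimization step: total = L_r + beta * L_m exactly."""

    step: int
    epoch: int
    recon: float
    moment: float
    beta: float
    total: float


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def reconstruction_loss(images: np.ndarray, recon: np.ndarray,
                        kind: str = "mse") -> float:
    """Mean reconstruction error over all pixels (MSE by default)."""
    a = np.asarray(images, dtype=np.float64)
    b = np.asarray(recon, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if kind == "mse":
        return float(np.mean((a - b) ** 2))
    if kind == "bce":
        eps = 1e-7
        bc = np.clip(b, eps, 1 - eps)
        return float(-np.mean(a * np.log(bc) + (1 - a) * np.log(1 - bc)))
    raise ValueError(f"unknown reconstruction loss {kind!r}")


def _recon_loss_t(x: Tensor, xh: Tensor, kind: str) -> Tensor:
    if kind == "mse":
        d = ag.add(x, ag.mul(xh, -1.0))
        return ag.tmean(ag.mul(d, d))
    eps = 1e-6
    # bce on sigmoid outputs; clamp via scaling into (eps, 1-eps)
    xc = ag.add(ag.mul(xh, 1.0 - 2 * eps), eps)
    return ag.mul(ag.tmean(ag.add(ag.mul(x, ag.log(xc)),
                                  ag.mul(ag.add(1.0, ag.mul(x, -1.0)),
                                         ag.log(ag.add(1.0, ag.mul(xc, -1.0)))))),
                  -1.0)


def wrapped_angle_sq(theta: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Squared pi-periodic distance min_k (theta - alpha + k*pi)^2."""
    d = np.asarray(theta, dtype=np.float64) - np.asarray(alpha, dtype=np.float64)
    w = (d + math.pi / 2) % math.pi - math.pi / 2
    return w ** 2


def moment_loss(z_equi: np.ndarray, targets, learn_xy: bool = True) -> float:
    """Guidance loss between the pose code and image-moment targets.

    ``z_equi``: (n, 3) array of (x, y, theta); ``targets``: the tuple
    returned by :func:`codae.moments.moment_targets` (or a (tx, ty,
    talpha) triple; all samples then count as valid).  Position terms are
    squared pixel errors and are skipped when ``learn_xy`` is off; the
    angle term is the squared pi-periodic distance.  Degenerate frames
    (invalid moments) are excluded from the average.
    """
    z = np.asarray(z_equi, dtype=np.float64)
    if len(targets) == 3:
        tx, ty, ta = (np.asarray(t, dtype=np.float64) for t in targets)
        valid = np.ones(len(tx), dtype=bool)
        angle_valid = valid
    elif len(targets) == 4:
        tx, ty, ta, valid = targets
        angle_valid = valid
    else:
        tx, ty, ta, valid, angle_valid = targets
    if not np.any(valid):
        return 0.0
    per = wrapped_angle_sq(z[:, 2], ta) * (valid & angle_valid)
    if learn_xy:
        per = per + ((z[:, 0] - tx) ** 2 + (z[:, 1] - ty) ** 2) * valid
    return float(per.sum() / valid.sum())


def _moment_loss_t(tx: Tensor, ty: Tensor, theta: Tensor,
                   targets: tuple, learn_xy: bool) -> Tensor:
    ttx, tty, tta, valid, angle_valid = targets
    n_valid = int(valid.sum())
    if n_valid == 0:
        return Tensor(np.float32(0.0))
    w = (valid.astype(np.float32) / n_valid)
    wa = ((valid & angle_valid).astype(np.float32) / n_valid)
    # pi-periodic wrap: subtract the nearest multiple of pi, computed from
    # the forward values and treated as a constant (piecewise identity).
    d = theta.data - tta
    k = np.round(d / math.pi)
    adiff = ag.add(theta, Tensor((-tta - k * math.pi).astype(np.float32)))
    loss = ag.tsum(ag.mul(ag.mul(adiff, adiff), Tensor(wa)))
    if learn_xy:
        dx = ag.add(tx, Tensor(-ttx.astype(np.float32)))
        dy = ag.add(ty, Tensor(-tty.astype(np.float32)))
        loss = ag.add(loss, ag.tsum(ag.mul(ag.add(ag.mul(dx, dx),
                                                  ag.mul(dy, dy)), Tensor(w))))
    return loss


def beta_schedule(step: int, config: TrainConfig) -> float:
    """Moment-loss weight at an optimization step: beta0 at step 0,
    non-increasing, exactly zero from the decay horizon onwards."""
    if step < 0:
        raise ValueError("step must be non-negative")
    total = config.total_steps
    if total is None:
        raise ValueError("total_steps must be resolved before scheduling")
    end = max(1, int(round(total * config.beta_end_frac)))
    if step >= end:
        return 0.0
    frac = 1.0 - step / end
    if config.beta_shape == "linear":
        return config.beta0 * frac
    if config.beta_shape == "cosine":
        return config.beta0 * 0.5 * (1.0 - math.cos(math.pi * frac))
    raise ValueError(f"unknown beta shape {config.beta_shape!r}")


# ---------------------------------------------------------------------------
# training loop
# ---------------------------------------------------------------------------

class TrainLog:
    """Per-step loss states plus per-epoch averages."""

    def __init__(self):
        self.steps: list[LossState] = []
        self.epochs: list[dict] = []

    def to_frame(self):
        import pandas as pd
        return pd.DataFrame([vars(s) for s in self.steps])


def train_codae(data, config: TrainConfig) -> tuple[CODAE, TrainLog]:
    """Train the autoencoder on an image stack.

    ``data`` is an :class:`ImageBatch`, a raw array, or an
    ``(ImageBatch, FactorTable)`` pair (the factor table is not used for
    training — the method is unsupervised — but accepting the pair keeps
    the generator's output plumbing-compatible).  Image moments of every
    input are computed once and cached as guidance targets.  Fully
    reproducible for a fixed seed on one device.
    """
    if isinstance(data, tuple):
        data = data[0]
    if isinstance(data, ImageBatch):
        arr = data.data
    else:
        arr = np.asarray(data, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
    n = arr.shape[0]
    cfg = config
    if arr.shape[2] != cfg.model.image_size:
        raise ValueError("data image size does not match model config")
    steps_per_epoch = max(1, math.ceil(n / cfg.batch_size))
    if cfg.total_steps is None:
        cfg = replace(cfg, total_steps=steps_per_epoch * cfg.epochs)

    model = CODAE(cfg.model)
    model.learn_xy = cfg.learn_xy
    opt = Adam(model.parameters(), lr=cfg.lr, clip_norm=cfg.clip_norm)
    rng = np.random.default_rng(cfg.seed)

    # moment guidance targets, computed once
    tx_all, ty_all, ta_all, valid_all, avalid_all = moment_targets(
        arr, source=cfg.moment_source)

    log = TrainLog()
    step = 0
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        ep_r = ep_m = ep_t = 0.0
        for lo in range(0, n, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            xb = Tensor(arr[idx])
            beta = beta_schedule(step, cfg)
            out = model.forward(xb, learn_xy=cfg.learn_xy)
            l_r = _recon_loss_t(xb, out["same_view"], cfg.recon_loss)
            targets = (tx_all[idx], ty_all[idx], ta_all[idx], valid_all[idx],
                       avalid_all[idx])
            l_m = _moment_loss_t(out["tx"], out["ty"], out["theta"],
                                 targets, cfg.learn_xy)
            total = ag.add(l_r, ag.mul(l_m, beta))
            if not np.isfinite(total.data):
                raise FloatingPointError(
                    f"non-finite loss at step {step} (recon={l_r.data}, "
                    f"moment={l_m.data}, beta={beta})")
            opt.zero_grad()
            total.backward()
            opt.step()
            state = LossState(step=step, epoch=epoch,
                              recon=float(l_r.data), moment=float(l_m.data),
                              beta=beta, total=float(total.data))
            log.steps.append(state)
            ep_r += state.recon
            ep_m += state.moment
            ep_t += state.total
            step += 1
        k = steps_per_epoch
        log.epochs.append({"epoch": epoch, "recon": ep_r / k,
                           "moment": ep_m / k, "total": ep_t / k,
                           "beta": beta_schedule(step - 1, cfg)})
    return model, log


# ---------------------------------------------------------------------------
# inference helpers
# ---------------------------------------------------------------------------

def reconstruct_views(model: CODAE, images, *, batch_size: int = 256
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Aligned (canonical-pose) and same-view reconstructions.

    ``same_view`` is, by construction, exactly the spatial transform of
    ``aligned`` by each image's pose code.
    """
    arr = images.data if isinstance(images, ImageBatch) else np.asarray(
        images, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    aligned_out, same_out = [], []
    for lo in range(0, arr.shape[0], batch_size):
        out = model.forward(Tensor(arr[lo:lo + batch_size]))
        aligned_out.append(out["aligned"].data)
        same_out.append(out["same_view"].data)
    return np.concatenate(aligned_out), np.concatenate(same_out)


def latent_traverse(model: CODAE, base: tuple[np.ndarray, np.ndarray],
                    dim: int, values) -> np.ndarray:
    """Decode a sweep along one latent dimension, all others fixed.

    ``base`` is a ``(z_equi, z_inv)`` pair for a single image (as
    returned by ``model.encode``).  Dimensions 0..2 index the pose code
    (x, y, theta): the base invariant code is decoded once and the
    varying pose is applied by the spatial transform.  Dimensions 3..
    index ``z_inv``: each value is decoded to its aligned image (pose is
    not applied, so content changes while the pose stays canonical).
    """
    z_equi = np.asarray(base[0], dtype=np.float32).reshape(-1)
    z_inv = np.asarray(base[1], dtype=np.float32).reshape(-1)
    d = model.config.d
    if not 0 <= dim < 3 + d:
        raise ValueError(f"dim must be in [0, {3 + d})")
    values = np.asarray(values, dtype=np.float32)
    k = len(values)
    from .model import euler_encode, spatial_transform
    if dim < 3:
        aligned = model.decode(euler_encode(z_inv))[None]
        pose = np.tile(z_equi, (k, 1))
        pose[:, dim] = values
        stack = np.repeat(aligned, k, axis=0)
        return spatial_transform(stack, pose[:, 0], pose[:, 1], pose[:, 2])
    zs = np.tile(z_inv, (k, 1))
    zs[:, dim - 3] = values
    return model.decode(euler_encode(zs))
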