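"""The centroid- and orientation-aware disentangling autoencoder.

The encoder is translation- and rotation-equivariant: its convolutions
correlate the input with stacks of the same base kernels resampled at
``n_orient`` equally spaced orientations, so a feature map carries an
explicit orientation axis.  Rotating the input by a group angle rotates
the feature maps spatially and cyclically shifts the orientation axis —
the property the pose branch ``B_equi`` exploits to read off (x, y)
position and in-plane angle.  Max-pooling over the orientation axis
(plus ordinary spatial processing) yields rotation-invariant features
for the semantic branch ``B_inv``.

The invariant code is passed through an Euler encoding (a hyperspherical
embedding whose tangent directions are mutually orthogonal, so latent
dimensions act orthogonally on the decoder), decoded to a canonical-pose
("aligned") image by a conventional convolutional decoder, and finally
rotated/translated back to the input view by a bilinear spatial
transform driven by the pose code.

Angles follow the package convention: measured from +x (columns) toward
+y (rows); kernel/feature rotations by multiples of 90 degrees are exact
index permutations, so equivariance at group angles holds to float32
round-off.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict

import numpy as np

from . import autograd as ag
from .autograd import Tensor, Parameter

TWO_PI = 2.0 * math.pi


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters.

    ``n_orient`` is the number of kernel orientations (must divide 360
    degrees evenly); ``channels`` are the per-stage widths of the
    equivariant trunk (each stage halves the spatial size); ``d`` is the
    invariant latent dimensionality; ``equivariant=False`` replaces the
    group-convolution trunk by plain convolutions of matched total width
    (the ablation model).
    """

    image_size: int = 32
    in_channels: int = 1
    n_orient: int = 8
    channels: tuple[int, ...] = (8, 16, 16)
    lift_kernel: int = 5
    group_kernel: int = 3
    d: int = 2
    hidden: int = 128
    equivariant: bool = True
    angle_mode: str = "axial"   # "axial": theta in [0, pi); "full": [0, 2*pi)
    seed: int = 0

    def __post_init__(self):
        if self.n_orient < 1 or 360 % self.n_orient != 0:
            raise ValueError("n_orient must divide 360 evenly in degrees")
        if self.n_orient < 4 and self.n_orient != 1:
            raise ValueError("n_orient must be >= 4 (or 1 for the "
                             "degenerate plain-convolution case)")
        if self.angle_mode not in ("axial", "full"):
            raise ValueError("angle_mode must be 'axial' or 'full'")
        down = 2 ** len(self.channels)
        if self.image_size % down != 0:
            raise ValueError(
                f"image_size must be divisible by {down} for "
                f"{len(self.channels)} pooling stages")


# ---------------------------------------------------------------------------
# rotated kernel stacks
# ---------------------------------------------------------------------------

def rotation_resampling_matrix(k: int, angle: float) -> np.ndarray:
    """(k*k, k*k) matrix mapping a flattened kernel to its rotation.

    The rotated kernel is the base kernel bilinearly resampled on the
    grid rotated by ``angle`` about the kernel centre; at multiples of
    90 degrees the matrix is an exact permutation.
    """
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    c = (k - 1) / 2.0
    ct, st = math.cos(angle), math.sin(angle)
    M = np.zeros((k * k, k * k), dtype=np.float32)
    for r in range(k):          # target row (y)
        for col in range(k):    # target column (x)
            tx, ty = col - c, r - c
            # source point: rotate target back by -angle
            sx = ct * tx + st * ty + c
            sy = -st * tx + ct * ty + c
            x0, y0 = math.floor(sx), math.floor(sy)
            fx, fy = sx - x0, sy - y0
            for dy, dx, w in ((0, 0, (1 - fx) * (1 - fy)),
                              (0, 1, fx * (1 - fy)),
                              (1, 0, (1 - fx) * fy),
                              (1, 1, fx * fy)):
                yy, xx = y0 + dy, x0 + dx
                if 0 <= yy < k and 0 <= xx < k and w > 1e-12:
                    M[r * k + col, yy * k + xx] += w
    return M


def _rotation_matrices(k: int, n_orient: int) -> list[np.ndarray]:
    step = TWO_PI / n_orient
    return [rotation_resampling_matrix(k, r * step) for r in range(n_orient)]


def _rotate_kernel_stack(w: Tensor, mats: list[np.ndarray]) -> list[Tensor]:
    """Rotate base kernels (..., k, k) by each group angle (autograd-aware)."""
    shp = w.shape
    k = shp[-1]
    flat = ag.reshape(w, (-1, k * k))
    out = []
    for M in mats:
        rot = ag.matmul(flat, Tensor(M.T))
        out.append(ag.reshape(rot, shp))
    return out


# ---------------------------------------------------------------------------
# functional equivariant ops (array in, array out; Tensor path used by CODAE)
# ---------------------------------------------------------------------------

def _lift_conv_t(x: Tensor, w: Tensor, n_orient: int,
                 mats: list[np.ndarray] | None = None) -> Tensor:
    """Lifting correlation: (B,C,H,W) -> (B,F,n_orient,H,W)."""
    F, C, k, _ = w.shape
    if mats is None:
        mats = _rotation_matrices(k, n_orient)
    rotated = _rotate_kernel_stack(w, mats)          # n_orient x (F,C,k,k)
    stacked = ag.concat([ag.reshape(r, (F, 1, C, k, k)) for r in rotated],
                        axis=1)                      # (F, n_orient, C, k, k)
    wbig = ag.reshape(stacked, (F * n_orient, C, k, k))
    out = ag.conv2d(x, wbig)                         # (B, F*n_orient, H, W)
    B, _, H, W = out.shape
    return ag.reshape(out, (B, F, n_orient, H, W))


def _group_conv_t(feat: Tensor, w: Tensor, n_orient: int,
                  mats: list[np.ndarray] | None = None,
                  bias: Tensor | None = None) -> Tensor:
    """Group correlation over space and the orientation axis.

    ``feat``: (B, C_in, n_orient, H, W); ``w``: (C_out, C_in, n_orient, k, k).
    Output orientation r correlates the input with the base kernel
    rotated spatially by the r-th group angle and cyclically shifted by
    r along its orientation axis, which preserves equivariance through
    composition.
    """
    C_out, C_in, N, k, _ = w.shape
    if N != n_orient or feat.shape[2] != n_orient:
        raise ValueError("orientation-axis size mismatch")
    if mats is None:
        mats = _rotation_matrices(k, n_orient)
    rotated = _rotate_kernel_stack(w, mats)          # per r: (C_out,C_in,N,k,k)
    blocks = []
    for r, wr in enumerate(rotated):
        if r:
            # roll by +r along the input-orientation axis:
            # rolled[..., s] = wr[..., (s - r) mod N]
            rolled = ag.concat([wr[:, :, N - r:], wr[:, :, :N - r]], axis=2)
        else:
            rolled = wr
        blocks.append(ag.reshape(rolled, (C_out, 1, C_in * N, k, k)))
    wbig = ag.reshape(ag.concat(blocks, axis=1), (C_out * N, C_in * N, k, k))
    B, _, _, H, W = feat.shape
    x2 = ag.reshape(feat, (B, C_in * N, H, W))
    if bias is not None:
        # one bias per output channel, shared across orientations
        b = ag.reshape(ag.mul(ag.reshape(bias, (C_out, 1)),
                              Tensor(np.ones((1, N), dtype=np.float32))),
                       (C_out * N,))
        out = ag.conv2d(x2, wbig, b)
    else:
        out = ag.conv2d(x2, wbig)
    return ag.reshape(out, (B, C_out, N, H, W))


def lift_conv(images: np.ndarray, kernels: np.ndarray, n_orient: int
              ) -> np.ndarray:
    """Correlate images with ``n_orient`` rotated copies of each kernel.

    images: (B, C, H, W); kernels: (F, C, k, k), odd k.
    Returns the group feature map (B, F, n_orient, H, W).
    """
    out = _lift_conv_t(Tensor(np.asarray(images, dtype=np.float32)),
                       Tensor(np.asarray(kernels, dtype=np.float32)), n_orient)
    return out.data


def group_conv(feat: np.ndarray, kernels: np.ndarray) -> np.ndarray:
    """Group-equivariant correlation on an oriented feature map.

    feat: (B, C_in, n_orient, H, W); kernels: (C_out, C_in, n_orient, k, k).
    """
    n_orient = np.asarray(feat).shape[2]
    out = _group_conv_t(Tensor(np.asarray(feat, dtype=np.float32)),
                        Tensor(np.asarray(kernels, dtype=np.float32)),
                        n_orient)
    return out.data


def group_max_pool(feat: np.ndarray) -> np.ndarray:
    """Elementwise maximum over the orientation axis: (B,C,N,H,W)->(B,C,H,W)."""
    arr = np.asarray(feat)
    if arr.ndim != 5:
        raise ValueError("expected (B, C, n_orient, H, W)")
    return arr.max(axis=2)


# ---------------------------------------------------------------------------
# Euler encoding
# ---------------------------------------------------------------------------

def _euler_encode_t(z: Tensor) -> Tensor:
    """Hyperspherical embedding R^d -> unit sphere in R^(d+1).

    E(z) = (cos z1, sin z1 cos z2, ..., sin z1 ... sin z_{d-1} cos z_d,
    sin z1 ... sin z_d): successive planar rotations applied to a fixed
    reference axis.  Unit norm everywhere; the tangent directions
    dE/dz_i are mutually orthogonal at every point.
    """
    B, d = z.shape
    comps = []
    running = None  # product of sines so far, (B, 1)
    for i in range(d):
        zi = z[:, i:i + 1]
        ci, si = ag.cos(zi), ag.sin(zi)
        comps.append(ci if running is None else ag.mul(running, ci))
        running = si if running is None else ag.mul(running, si)
    comps.append(running)
    return ag.concat(comps, axis=1)


def euler_encode(z_inv: np.ndarray) -> np.ndarray:
    """Euler encoding of invariant codes; accepts (d,) or (B, d).

    Computed in float64 (the training graph uses the float32 Tensor
    path); the output always has unit norm.
    """
    arr = np.asarray(z_inv, dtype=np.float64)
    single = arr.ndim == 1
    if single:
        arr = arr[None]
    B, d = arr.shape
    out = np.empty((B, d + 1), dtype=np.float64)
    running = np.ones(B, dtype=np.float64)
    for i in range(d):
        out[:, i] = running * np.cos(arr[:, i])
        running = running * np.sin(arr[:, i])
    out[:, d] = running
    return out[0] if single else out


# ---------------------------------------------------------------------------
# spatial transform (rotate about centre, then translate)
# ---------------------------------------------------------------------------

def _spatial_transform_t(images: Tensor, tx: Tensor, ty: Tensor,
                         theta: Tensor) -> Tensor:
    """Differentiable rotate-then-translate with bilinear resampling.

    ``tx, ty, theta``: (B,) tensors.  Output pixel (X, Y) samples the
    input at R(-theta) @ (X - c - t, Y - c - t) + c; regions mapped from
    outside the frame are zero.
    """
    B, C, H, W = images.shape
    cx, cy = (W - 1) / 2.0, (H - 1) / 2.0
    gx0, gy0 = np.meshgrid(np.arange(W, dtype=np.float32),
                           np.arange(H, dtype=np.float32), indexing="xy")
    X = Tensor(gx0[None])  # (1, H, W)
    Y = Tensor(gy0[None])
    ct = ag.reshape(ag.cos(theta), (B, 1, 1))
    st = ag.reshape(ag.sin(theta), (B, 1, 1))
    dx = ag.add(ag.add(X, -cx), ag.mul(ag.reshape(tx, (B, 1, 1)), -1.0))
    dy = ag.add(ag.add(Y, -cy), ag.mul(ag.reshape(ty, (B, 1, 1)), -1.0))
    sx = ag.add(ag.add(ag.mul(ct, dx), ag.mul(st, dy)), cx)
    sy = ag.add(ag.add(ag.mul(st, ag.mul(dx, -1.0)), ag.mul(ct, dy)), cy)
    return ag.sample_bilinear(images, sx, sy)


def spatial_transform(images: np.ndarray, x: np.ndarray | float,
                      y: np.ndarray | float, theta: np.ndarray | float
                      ) -> np.ndarray:
    """Rotate each image by ``theta`` about its centre, then translate by
    ``(x, y)`` pixels (bilinear; zero fill outside the frame).

    ``images``: (B, C, H, W); scalars broadcast over the batch.
    """
    arr = np.asarray(images, dtype=np.float32)
    B = arr.shape[0]
    tx = np.broadcast_to(np.asarray(x, dtype=np.float32), (B,)).copy()
    ty = np.broadcast_to(np.asarray(y, dtype=np.float32), (B,)).copy()
    th = np.broadcast_to(np.asarray(theta, dtype=np.float32), (B,)).copy()
    out = _spatial_transform_t(Tensor(arr), Tensor(tx), Tensor(ty), Tensor(th))
    return out.data


# ---------------------------------------------------------------------------
# the full model
# ---------------------------------------------------------------------------

def _he(rng, shape, fan_in):
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class CODAE:
    """Encoder/decoder pair with pose and invariant branches.

    Parameters are float32 numpy arrays on the autograd tape; the public
    ``encode``/``decode``/``reconstruct`` methods take and return plain
    arrays, while ``forward`` returns the Tensor graph used in training.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        #: pose-translation flag; set False by the training protocol for
        #: pre-centred stacks (translation then stays frozen at 0)
        self.learn_xy = True
        cfg = config
        rng = np.random.default_rng(cfg.seed)
        self.params: dict[str, Parameter] = {}
        N = cfg.n_orient if cfg.equivariant else 1
        self._mats = {
            cfg.lift_kernel: _rotation_matrices(cfg.lift_kernel, cfg.n_orient),
            cfg.group_kernel: _rotation_matrices(cfg.group_kernel, cfg.n_orient),
        } if cfg.equivariant else {}

        def P(name, arr):
            p = Parameter(arr)
            self.params[name] = p
            return p

        chans = cfg.channels
        kl, kg = cfg.lift_kernel, cfg.group_kernel
        if cfg.equivariant:
            # base kernels only; rotated stacks are rebuilt every forward
            P("lift_w", _he(rng, (chans[0], cfg.in_channels, kl, kl),
                            cfg.in_channels * kl * kl))
            for i in range(1, len(chans)):
                fan = chans[i - 1] * cfg.n_orient * kg * kg
                P(f"gc{i}_w", _he(rng, (chans[i], chans[i - 1], cfg.n_orient,
                                        kg, kg), fan))
                P(f"gc{i}_b", np.zeros(chans[i], dtype=np.float32))
            trunk_ch = chans[-1]
            equi_in = chans[-1] * cfg.n_orient
        else:
            # ablation: plain convolutions at width C*sqrt(N), which
            # matches both the parameter count and the compute of the
            # group-convolution trunk (group conv: N*C_out*C_in*k^2
            # parameters; plain conv at aC widths: a^2*C_out*C_in*k^2)
            a = math.sqrt(cfg.n_orient)
            wide = [max(1, round(c * a)) for c in chans]
            P("lift_w", _he(rng, (wide[0], cfg.in_channels, kl, kl),
                            cfg.in_channels * kl * kl))
            for i in range(1, len(chans)):
                P(f"gc{i}_w", _he(rng, (wide[i], wide[i - 1], kg, kg),
                                  wide[i - 1] * kg * kg))
                P(f"gc{i}_b", np.zeros(wide[i], dtype=np.float32))
            trunk_ch = wide[-1]
            equi_in = wide[-1]
        s_final = cfg.image_size // (2 ** len(chans))
        self._s_final = s_final
        flat_equi = equi_in * s_final * s_final
        flat_inv = trunk_ch * s_final * s_final

        P("equi_w1", _he(rng, (flat_equi, cfg.hidden), flat_equi))
        P("equi_b1", np.zeros(cfg.hidden, dtype=np.float32))
        P("equi_w2", (rng.standard_normal((cfg.hidden, 4)) * 0.01).astype(np.float32))
        P("equi_b2", np.zeros(4, dtype=np.float32))

        P("inv_w1", _he(rng, (flat_inv, cfg.hidden), flat_inv))
        P("inv_b1", np.zeros(cfg.hidden, dtype=np.float32))
        P("inv_w2", (rng.standard_normal((cfg.hidden, cfg.d)) * 0.1).astype(np.float32))
        P("inv_b2", np.zeros(cfg.d, dtype=np.float32))

        dc = chans[::-1]  # decoder widths mirror the encoder
        P("dec_w0", _he(rng, (cfg.d + 1, dc[0] * s_final * s_final), cfg.d + 1))
        P("dec_b0", np.zeros(dc[0] * s_final * s_final, dtype=np.float32))
        for i in range(1, len(dc)):
            P(f"dec_w{i}", _he(rng, (dc[i], dc[i - 1], 3, 3), dc[i - 1] * 9))
            P(f"dec_b{i}", np.zeros(dc[i], dtype=np.float32))
        P("dec_wout", _he(rng, (cfg.in_channels, dc[-1], 3, 3), dc[-1] * 9))
        P("dec_bout", np.zeros(cfg.in_channels, dtype=np.float32))

    # -- pieces -----------------------------------------------------------
    def _trunk(self, x: Tensor) -> tuple[Tensor, Tensor]:
        """Returns (equivariant features for B_equi, pooled map for B_inv).

        Equivariant mode: features (B, C, N, H', W'), pooled (B, C, H', W').
        Plain mode: both are the same (B, C_total, H', W') map.
        """
        cfg = self.config
        p = self.params
        if cfg.equivariant:
            h = _lift_conv_t(x, p["lift_w"], cfg.n_orient,
                             self._mats[cfg.lift_kernel])
            h = ag.relu(h)
            h = self._pool5(h)
            for i in range(1, len(cfg.channels)):
                h = _group_conv_t(h, p[f"gc{i}_w"], cfg.n_orient,
                                  self._mats[cfg.group_kernel],
                                  bias=p[f"gc{i}_b"])
                h = ag.relu(h)
                h = self._pool5(h)
            pooled = ag.tmax(h, axis=2)
            return h, pooled
        h = ag.conv2d(x, p["lift_w"])
        h = ag.relu(h)
        h = ag.avg_pool2(h)
        for i in range(1, len(cfg.channels)):
            h = ag.conv2d(h, p[f"gc{i}_w"], p[f"gc{i}_b"])
            h = ag.relu(h)
            h = ag.avg_pool2(h)
        return h, h

    @staticmethod
    def _pool5(h: Tensor) -> Tensor:
        """2x2 average pooling on a 5D oriented feature map."""
        B, C, N, H, W = h.shape
        h4 = ag.reshape(h, (B, C * N, H, W))
        h4 = ag.avg_pool2(h4)
        return ag.reshape(h4, (B, C, N, H // 2, W // 2))

    def _heads(self, equi_feat: Tensor, pooled: Tensor
               ) -> tuple[Tensor, Tensor, Tensor, Tensor]:
        cfg = self.config
        p = self.params
        B = equi_feat.shape[0]
        fe = ag.reshape(equi_feat, (B, -1))
        he = ag.relu(ag.add(ag.matmul(fe, p["equi_w1"]), p["equi_b1"]))
        eq = ag.add(ag.matmul(he, p["equi_w2"]), p["equi_b2"])  # (B, 4)
        half = cfg.image_size / 2.0
        tx = ag.mul(ag.tanh(eq[:, 0]), half)
        ty = ag.mul(ag.tanh(eq[:, 1]), half)
        # (a, b) -> atan2(b, a); the axial mode halves the angle so the
        # 2-vector winds once per half-turn, matching the pi-periodic
        # moment guidance with a single consistent target direction
        theta = ag.atan2(eq[:, 3], eq[:, 2])
        if cfg.angle_mode == "axial":
            theta = ag.mul(theta, 0.5)
        # canonical representative in [0, period): the same angle the
        # public encode() reports drives the spatial transform
        period = math.pi if cfg.angle_mode == "axial" else TWO_PI
        k = np.floor(theta.data / period)
        theta = ag.add(theta, Tensor((-k * period).astype(np.float32)))
        fi = ag.reshape(pooled, (B, -1))
        hi = ag.relu(ag.add(ag.matmul(fi, p["inv_w1"]), p["inv_b1"]))
        z_inv = ag.add(ag.matmul(hi, p["inv_w2"]), p["inv_b2"])
        return tx, ty, theta, z_inv

    def _decode_t(self, code: Tensor) -> Tensor:
        cfg = self.config
        p = self.params
        B = code.shape[0]
        dc = cfg.channels[::-1]
        s = self._s_final
        h = ag.relu(ag.add(ag.matmul(code, p["dec_w0"]), p["dec_b0"]))
        h = ag.reshape(h, (B, dc[0], s, s))
        for i in range(1, len(dc)):
            h = ag.upsample2(h)
            h = ag.relu(ag.conv2d(h, p[f"dec_w{i}"], p[f"dec_b{i}"]))
        h = ag.upsample2(h)
        return ag.sigmoid(ag.conv2d(h, p["dec_wout"], p["dec_bout"]))

    # -- training-graph forward -------------------------------------------
    def forward(self, images: Tensor, *, learn_xy: bool | None = None) -> dict:
        cfg = self.config
        if learn_xy is None:
            learn_xy = self.learn_xy
        if images.shape[2] != cfg.image_size or images.shape[3] != cfg.image_size:
            raise ValueError(
                f"input size {images.shape[2:]} does not match configured "
                f"image_size {cfg.image_size}")
        if images.shape[1] != cfg.in_channels:
            raise ValueError("channel count mismatch")
        equi_feat, pooled = self._trunk(images)
        tx, ty, theta, z_inv = self._heads(equi_feat, pooled)
        if not learn_xy:
            B = images.shape[0]
            zero = Tensor(np.zeros(B, dtype=np.float32))
            tx, ty = zero, zero
        code = _euler_encode_t(z_inv)
        aligned = self._decode_t(code)
        same_view = _spatial_transform_t(aligned, tx, ty, theta)
        return {"tx": tx, "ty": ty, "theta": theta, "z_inv": z_inv,
                "aligned": aligned, "same_view": same_view}

    # -- array-level public API -------------------------------------------
    def encode(self, images: np.ndarray, *, batch_size: int = 256
               ) -> tuple[np.ndarray, np.ndarray]:
        """Latent codes for an image stack.

        Returns ``(z_equi, z_inv)`` with ``z_equi`` of shape (n, 3)
        holding (x, y, theta) — centre offsets in pixels and the angle in
        [0, pi) for the axial mode, [0, 2*pi) otherwise — and ``z_inv``
        of shape (n, d).
        """
        arr = np.asarray(images, dtype=np.float32)
        if arr.ndim == 3:
            arr = arr[:, None]
        zs, zi = [], []
        for lo in range(0, arr.shape[0], batch_size):
            xb = Tensor(arr[lo:lo + batch_size])
            equi_feat, pooled = self._trunk(xb)
            tx, ty, theta, z_inv = self._heads(equi_feat, pooled)
            th = theta.data  # already wrapped to [0, period) by the head
            txd, tyd = tx.data, ty.data
            if not self.learn_xy:
                txd, tyd = np.zeros_like(txd), np.zeros_like(tyd)
            zs.append(np.stack([txd, tyd, th], axis=1))
            zi.append(z_inv.data)
        return np.concatenate(zs), np.concatenate(zi)

    def decode(self, code: np.ndarray) -> np.ndarray:
        """Decode Euler-encoded invariant vectors to aligned images."""
        arr = np.asarray(code, dtype=np.float32)
        single = arr.ndim == 1
        if single:
            arr = arr[None]
        if arr.shape[1] != self.config.d + 1:
            raise ValueError(
                f"decoder expects codes of dimension {self.config.d + 1} "
                "(Euler-encoded invariant vectors)")
        out = self._decode_t(Tensor(arr)).data
        return out[0] if single else out

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    # -- serialization -----------------------------------------------------
    def save(self, path) -> None:
        meta = json.dumps({**asdict(self.config), "learn_xy": self.learn_xy})
        np.savez(path, __config__=np.frombuffer(meta.encode(), dtype=np.uint8),
                 **{k: p.data for k, p in self.params.items()})

    @classmethod
    def load(cls, path) -> "CODAE":
        with np.load(path) as z:
            meta = json.loads(bytes(z["__config__"]).decode())
            meta["channels"] = tuple(meta["channels"])
            learn_xy = meta.pop("learn_xy", True)
            model = cls(ModelConfig(**meta))
            model.learn_xy = learn_xy
            for k in model.params:
                model.params[k].data = z[k].astype(np.float32)
        return model
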