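"""Synthetic benchmarks with exact ground-truth generative factors.

Two generators are provided.  ``generate_xyrcs`` renders the XYRCS
benchmark: one of three shapes (circle, isosceles triangle, rectangle)
per frame with independently sampled x/y position, in-plane orientation
and brightness.  ``generate_dsprites_like`` renders square/ellipse/heart
silhouettes with a scale factor instead of brightness, as a no-download
stand-in for the dSprites benchmark.  ``fixture_bank`` returns a handful
of deterministic images with analytically known image moments that the
test suites share.

Coordinate convention (used repository-wide): ``x`` is the column index,
``y`` is the row index, the origin is the centre of the top-left pixel,
and angles are measured from the +x axis toward +y (the row direction).
The silhouette centroid of every canonical shape is at its local origin,
so the recorded (x, y) factors coincide with the image-moment centroid
up to antialiasing error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

TWO_PI = 2.0 * math.pi

XYRCS_SHAPES = ("circle", "triangle", "rectangle")
DSPRITES_SHAPES = ("square", "ellipse", "heart")

#: relative half-height of the isosceles triangle (see docs/methods.md:
#: an equilateral triangle would have no defined moment orientation).
_TRI_ASPECT = 0.55


@dataclass(frozen=True)
class SynthConfig:
    """Sampling configuration for the synthetic generators.

    Positions are offsets from the image centre in pixels; orientation is
    in radians; brightness multiplies the silhouette intensity; scale
    multiplies the canonical shape size (dSprites-like mode only).
    """

    n: int = 1000
    image_size: int = 64
    seed: int = 0
    radius: float | None = None          # bounding radius; default size / 4
    x_range: tuple[float, float] | None = None   # default +/- size / 6
    y_range: tuple[float, float] | None = None
    orientation_range: tuple[float, float] = (0.0, TWO_PI)
    brightness_range: tuple[float, float] = (0.4, 1.0)
    scale_range: tuple[float, float] = (0.5, 1.0)
    shapes: tuple[str, ...] = XYRCS_SHAPES
    antialias: int = 4                   # supersampling factor per axis

    def resolved(self) -> "SynthConfig":
        """Fill derived defaults (radius, position ranges)."""
        r = self.radius if self.radius is not None else self.image_size / 4.0
        half = self.image_size / 6.0
        xr = self.x_range if self.x_range is not None else (-half, half)
        yr = self.y_range if self.y_range is not None else (-half, half)
        return replace(self, radius=r, x_range=xr, y_range=yr)

    def validate(self, max_bound_factor: float = 1.0) -> None:
        cfg = self.resolved()
        if cfg.n < 0:
            raise ValueError("n must be non-negative")
        if cfg.image_size < 16:
            raise ValueError("image_size must be at least 16")
        if cfg.antialias < 1:
            raise ValueError("antialias factor must be >= 1")
        # the object (bounding radius * factor) must stay inside the frame
        # for every admissible position, otherwise moments and alignment
        # are ill-defined.
        c = (cfg.image_size - 1) / 2.0
        bound = cfg.radius * max_bound_factor
        for lo, hi in (cfg.x_range, cfg.y_range):
            if lo > hi:
                raise ValueError("factor range must satisfy lo <= hi")
            if c + hi + bound > cfg.image_size - 0.5 or c + lo - bound < -0.5:
                raise ValueError(
                    "position range lets the object leave the frame: "
                    f"range ({lo}, {hi}) with bounding radius {bound:.2f} "
                    f"in a {cfg.image_size}px image"
                )


class ImageBatch:
    """A stack of square images, shape ``(n, channels, H, W)`` in [0, 1]."""

    def __init__(self, data: np.ndarray):
        data = np.asarray(data)
        if data.ndim == 3:  # (n, H, W) -> single channel
            data = data[:, None, :, :]
        if data.ndim != 4:
            raise ValueError("ImageBatch expects (n, channels, H, W)")
        if data.shape[2] != data.shape[3]:
            raise ValueError("images must be square")
        self.data = data.astype(np.float32, copy=False)

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def channels(self) -> int:
        return self.data.shape[1]

    @property
    def image_size(self) -> int:
        return self.data.shape[2]

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, idx) -> np.ndarray:
        return self.data[idx]


# ---------------------------------------------------------------------------
# silhouette membership tests (canonical frame, centroid at the origin)
# ---------------------------------------------------------------------------

def _membership(shape: str, px: np.ndarray, py: np.ndarray, r: float) -> np.ndarray:
    """Boolean mask of points (px, py) inside the canonical shape."""
    if shape == "circle":
        return px * px + py * py <= r * r
    if shape == "rectangle":
        # long axis along +x, half extents (r, r/2)
        return (np.abs(px) <= r) & (np.abs(py) <= r / 2.0)
    if shape == "triangle":
        # isosceles, apex toward +x: vertices (r, 0), (-r/2, +/- a r);
        # the vertex mean is the origin, and the density centroid of a
        # triangle is the vertex mean, so the centroid sits at the origin.
        a = _TRI_ASPECT
        v1 = (r, 0.0)
        v2 = (-r / 2.0, a * r)
        v3 = (-r / 2.0, -a * r)
        return _in_triangle(px, py, v1, v2, v3)
    if shape == "square":
        h = 0.7 * r
        return (np.abs(px) <= h) & (np.abs(py) <= h)
    if shape == "ellipse":
        return (px / r) ** 2 + (py / (r / 2.0)) ** 2 <= 1.0
    if shape == "heart":
        # classic sextic heart, apex toward -y at orientation 0, scaled so
        # the lobes fit inside ~1.2 r.  Its centroid is slightly off the
        # implicit-curve origin; we recentre numerically below.
        u = px / (0.8 * r)
        v = -py / (0.8 * r)
        return (u * u + v * v - 1.0) ** 3 - u * u * v ** 3 <= 0.0
    raise ValueError(f"unknown shape {shape!r}")


def _in_triangle(px, py, v1, v2, v3):
    def half_plane(ax, ay, bx, by):
        return (bx - ax) * (py - ay) - (by - ay) * (px - ax)

    d1 = half_plane(*v1, *v2)
    d2 = half_plane(*v2, *v3)
    d3 = half_plane(*v3, *v1)
    neg = (d1 < 0) | (d2 < 0) | (d3 < 0)
    pos = (d1 > 0) | (d2 > 0) | (d3 > 0)
    return ~(neg & pos)


_SHAPE_BOUND = {
    "circle": 1.0,
    "triangle": math.hypot(0.5, _TRI_ASPECT) + 0.01,
    "rectangle": math.hypot(1.0, 0.5),
    "square": 0.7 * math.sqrt(2.0),
    "ellipse": 1.0,
    "heart": 1.25,
}

# numerically determined centroid offset (in units of r) of the canonical
# heart silhouette; subtracted at render time so the recorded (x, y)
# factors match the moment centroid like the other shapes.
_HEART_CENTROID = {"computed": False, "dx": 0.0, "dy": 0.0}


def _heart_centroid_offset(r: float = 40.0) -> tuple[float, float]:
    if not _HEART_CENTROID["computed"]:
        g = np.arange(-1.5 * r, 1.5 * r, 0.25)
        px, py = np.meshgrid(g, g, indexing="xy")
        m = _membership("heart", px, py, r).astype(float)
        tot = m.sum()
        _HEART_CENTROID["dx"] = float((px * m).sum() / tot) / r
        _HEART_CENTROID["dy"] = float((py * m).sum() / tot) / r
        _HEART_CENTROID["computed"] = True
    return _HEART_CENTROID["dx"], _HEART_CENTROID["dy"]


def render_shape(
    shape: str,
    x: float,
    y: float,
    orientation: float,
    intensity: float,
    image_size: int,
    radius: float,
    antialias: int = 4,
) -> np.ndarray:
    """Render one silhouette; returns a float32 (H, W) array in [0, 1].

    The silhouette centroid lands at ``(centre + x, centre + y)`` and the
    canonical +x axis of the shape points along ``orientation``.
    """
    a = antialias
    size = image_size
    c = (size - 1) / 2.0
    # supersample pixel centres
    sub = (np.arange(size * a) + 0.5) / a - 0.5
    gx, gy = np.meshgrid(sub, sub, indexing="xy")  # gx: column coord
    cx, cy = c + x, c + y
    if shape == "heart":
        hx, hy = _heart_centroid_offset()
        # shift the implicit curve so its centroid, not its origin, lands
        # at the requested position
        ox, oy = hx * radius, hy * radius
    else:
        ox = oy = 0.0
    ct, st = math.cos(orientation), math.sin(orientation)
    dx, dy = gx - cx, gy - cy
    px = ct * dx + st * dy + ox
    py = -st * dx + ct * dy + oy
    mask = _membership(shape, px, py, radius).astype(np.float32)
    # box down-sample a x a blocks
    img = mask.reshape(size, a, size, a).mean(axis=(1, 3))
    return (intensity * img).astype(np.float32)


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def _sample_factors(cfg: SynthConfig, rng: np.random.Generator,
                    value_name: str, value_range) -> pd.DataFrame:
    shape_idx = rng.integers(0, len(cfg.shapes), size=cfg.n)
    table = pd.DataFrame(
        {
            "x": rng.uniform(*cfg.x_range, size=cfg.n),
            "y": rng.uniform(*cfg.y_range, size=cfg.n),
            "orientation": rng.uniform(*cfg.orientation_range, size=cfg.n),
            "shape": [cfg.shapes[i] for i in shape_idx],
            value_name: rng.uniform(*value_range, size=cfg.n),
        }
    )
    return table


def _render_table(cfg: SynthConfig, table: pd.DataFrame,
                  scale_mode: bool) -> ImageBatch:
    imgs = np.zeros((len(table), 1, cfg.image_size, cfg.image_size),
                    dtype=np.float32)
    for i, row in enumerate(table.itertuples(index=False)):
        if scale_mode:
            radius = cfg.radius * row.scale
            intensity = 1.0
        else:
            radius = cfg.radius
            intensity = row.brightness
        imgs[i, 0] = render_shape(
            row.shape, row.x, row.y, row.orientation, intensity,
            cfg.image_size, radius, cfg.antialias,
        )
    return ImageBatch(imgs)


def generate_xyrcs(config: SynthConfig) -> tuple[ImageBatch, pd.DataFrame]:
    """Generate the XYRCS benchmark (position, rotation, colour, shape).

    Returns an :class:`ImageBatch` and a factor table with columns
    ``x, y, orientation, shape, brightness``, one row per image.
    Deterministic for a fixed ``(seed, config)``.
    """
    cfg = config.resolved()
    if cfg.shapes == DSPRITES_SHAPES:
        raise ValueError("use generate_dsprites_like for the dSprites shapes")
    bound = max(_SHAPE_BOUND[s] for s in cfg.shapes)
    cfg.validate(max_bound_factor=bound)
    rng = np.random.default_rng(cfg.seed)
    table = _sample_factors(cfg, rng, "brightness", cfg.brightness_range)
    return _render_table(cfg, table, scale_mode=False), table


def generate_dsprites_like(config: SynthConfig) -> tuple[ImageBatch, pd.DataFrame]:
    """Generate square/ellipse/heart silhouettes with a scale factor.

    A programmatic stand-in for the dSprites benchmark: same factor set
    (x, y, orientation, shape, scale) without the fixed 737k-image grid.
    """
    cfg = config.resolved()
    if cfg.shapes == XYRCS_SHAPES:
        cfg = replace(cfg, shapes=DSPRITES_SHAPES)
    bound = max(_SHAPE_BOUND[s] for s in cfg.shapes)
    cfg.validate(max_bound_factor=bound * cfg.scale_range[1])
    rng = np.random.default_rng(cfg.seed)
    table = _sample_factors(cfg, rng, "scale", cfg.scale_range)
    return _render_table(cfg, table, scale_mode=True), table


# ---------------------------------------------------------------------------
# deterministic fixtures with analytically known moments
# ---------------------------------------------------------------------------

def fixture_bank(image_size: int = 33) -> dict[str, np.ndarray]:
    """Deterministic single-channel test images (odd size, exact centre).

    Keys:

    - ``"pixel_3_5"``  — a single unit pixel at column 3, row 5
    - ``"disk"``       — a centred uniform disk (centroid = image centre)
    - ``"gauss_4_1_30"`` — anisotropic Gaussian, sigma = (4, 1) px, major
      axis at 30 degrees (moment orientation 30 deg analytically)
    - ``"bar"``        — an off-centre axis-aligned bar
    - ``"two_pixel"``  — unit pixels at (0, 0) and (2, 4)
      (centroid (1, 2), moment orientation atan2(8, -6) / 2)
    """
    if image_size % 2 == 0 or image_size < 11:
        raise ValueError("fixtures use an odd image size >= 11")
    s = image_size
    c = (s - 1) // 2
    out: dict[str, np.ndarray] = {}

    pixel = np.zeros((s, s), dtype=np.float32)
    pixel[5, 3] = 1.0  # row 5, column 3
    out["pixel_3_5"] = pixel

    out["disk"] = render_shape("circle", 0.0, 0.0, 0.0, 1.0, s, s / 4.0, 8)

    # rotated anisotropic Gaussian; orientation measured from +x toward +y
    phi = math.radians(30.0)
    sx, sy = 4.0, 1.0
    g = np.arange(s, dtype=np.float64)
    gx, gy = np.meshgrid(g, g, indexing="xy")
    dx, dy = gx - c, gy - c
    u = math.cos(phi) * dx + math.sin(phi) * dy
    v = -math.sin(phi) * dx + math.cos(phi) * dy
    gauss = np.exp(-0.5 * ((u / sx) ** 2 + (v / sy) ** 2))
    out["gauss_4_1_30"] = gauss.astype(np.float32)

    bar = np.zeros((s, s), dtype=np.float32)
    bar[c + 3, 4 : s - 8] = 1.0  # horizontal bar, off centre
    out["bar"] = bar

    two = np.zeros((s, s), dtype=np.float32)
    two[0, 0] = 1.0
    two[4, 2] = 1.0  # row 4 = y, column 2 = x
    out["two_pixel"] = two
    return out
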