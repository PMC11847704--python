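"""Image moments: centroid and orientation guidance targets.

Raw moments are :math:`M_{pq} = \\sum_{x,y} x^p y^q I(x, y)` with
``x`` the column and ``y`` the row index (see the package-wide
coordinate convention in :mod:`codae.synth`).  The first-order moments
give the intensity centroid; the second-order central moments give an
orientation

.. math:: \\bar\\alpha = \\tfrac12 \\operatorname{atan2}(2\\mu_{11},
          \\mu_{20} - \\mu_{02}),

defined only modulo pi (a shape and its 180-degree rotation have the
same second moments).  These quantities supply the guidance targets of
the moment loss, and the COM features used for centred diffraction
patterns.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

HALF_PI = math.pi / 2.0


class DegenerateImageError(ValueError):
    """Raised when moments are requested for an all-zero image."""


@dataclass(frozen=True)
class MomentSummary:
    """First- and second-order moment summary of a single image."""

    m00: float
    xbar: float          # centroid column, pixels
    ybar: float          # centroid row, pixels
    mu20: float
    mu02: float
    mu11: float
    alpha: float         # orientation in [-pi/2, pi/2), radians


@dataclass(frozen=True)
class ComFeatures:
    """Centre-of-mass descriptors relative to the geometric pattern centre."""

    com_x: float
    com_y: float
    com_angle: float     # atan2(com_y, com_x)
    com_mag: float       # hypot(com_x, com_y)


def _as_plane(image: np.ndarray) -> np.ndarray:
    """Reduce an image to one float64 channel (channel mean for RGB)."""
    arr = np.asarray(image, dtype=np.float64)
    if arr.ndim == 3:
        arr = arr.mean(axis=0)
    if arr.ndim != 2:
        raise ValueError("expected a (H, W) or (channels, H, W) image")
    return arr


def raw_moment(image: np.ndarray, p: int, q: int) -> float:
    """Raw image moment M_pq = sum x^p y^q I(x, y)."""
    if p < 0 or q < 0:
        raise ValueError("moment orders must be non-negative")
    arr = _as_plane(image)
    if np.any(arr < 0):
        raise ValueError("image must be non-negative")
    h, w = arr.shape
    x = np.arange(w, dtype=np.float64) ** p
    y = np.arange(h, dtype=np.float64) ** q
    return float(y @ arr @ x)


def compute_moments(image: np.ndarray, *, background_percentile: float | None = None
                    ) -> MomentSummary:
    """Centroid and second-moment orientation of a single image.

    ``background_percentile`` optionally subtracts that intensity
    percentile (clipping at zero) before the sums — useful for noisy
    stacks where a constant background would drag the centroid toward
    the frame centre.  Default is no thresholding.
    """
    arr = _as_plane(image)
    if background_percentile is not None:
        arr = np.clip(arr - np.percentile(arr, background_percentile), 0.0, None)
    m00 = float(arr.sum())
    if m00 <= 0.0:
        raise DegenerateImageError("all-zero image: centroid undefined")
    h, w = arr.shape
    x = np.arange(w, dtype=np.float64)
    y = np.arange(h, dtype=np.float64)
    colsum = arr.sum(axis=0)   # over rows -> per column
    rowsum = arr.sum(axis=1)
    xbar = float(colsum @ x) / m00
    ybar = float(rowsum @ y) / m00
    dx = x - xbar
    dy = y - ybar
    mu20 = float(colsum @ dx**2)
    mu02 = float(rowsum @ dy**2)
    mu11 = float(dy @ arr @ dx)
    if abs(mu11) < 1e-12 * m00 and abs(mu20 - mu02) < 1e-12 * m00:
        alpha = 0.0  # isotropic: orientation defined as 0 by convention
    else:
        alpha = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    alpha = wrap_half_pi(alpha)
    return MomentSummary(m00, xbar, ybar, mu20, mu02, mu11, alpha)


def wrap_half_pi(angle: float) -> float:
    """Reduce an angle to [-pi/2, pi/2) modulo pi."""
    a = (angle + HALF_PI) % math.pi - HALF_PI
    # the modulo can return exactly +pi/2 through floating rounding
    return -HALF_PI if a >= HALF_PI else a


def angular_difference_mod_pi(a, b):
    """Smallest signed difference a - b modulo pi, in [-pi/2, pi/2)."""
    d = np.asarray(a, dtype=np.float64) - np.asarray(b, dtype=np.float64)
    return (d + HALF_PI) % math.pi - HALF_PI


def com_features(pattern: np.ndarray) -> ComFeatures:
    """COM of a (centred) pattern relative to its geometric centre.

    Standard 4D-STEM descriptors: the (x, y) components of the intensity
    centroid measured from the frame centre, plus their polar form.
    """
    arr = _as_plane(pattern)
    m = compute_moments(arr)
    h, w = arr.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    com_x = m.xbar - cx
    com_y = m.ybar - cy
    return ComFeatures(
        com_x=com_x,
        com_y=com_y,
        com_angle=math.atan2(com_y, com_x),
        com_mag=math.hypot(com_x, com_y),
    )


#: second-moment eigenvalue ratio below which an image is treated as
#: isotropic: its orientation is undefined and gives no angle guidance.
ANISOTROPY_MIN_RATIO = 1.2


def anisotropy_ratio(m: MomentSummary) -> float:
    """Ratio of the principal second-moment eigenvalues (>= 1)."""
    mean = (m.mu20 + m.mu02) / 2.0
    half = math.hypot((m.mu20 - m.mu02) / 2.0, m.mu11)
    lam2 = mean - half
    if lam2 <= 0:
        return math.inf
    return (mean + half) / lam2


def moment_targets(images: np.ndarray, *, source: str = "image_moments"
                   ) -> tuple[np.ndarray, np.ndarray, np.ndarray,
                              np.ndarray, np.ndarray]:
    """Per-image guidance targets for the moment loss.

    Parameters
    ----------
    images : array of shape (n, channels, H, W)
    source : ``"image_moments"`` uses the centroid and second-moment
        orientation; ``"com"`` uses the COM angle as the orientation
        target (the centred-diffraction-pattern protocol).

    Returns
    -------
    (tx, ty, talpha, valid, angle_valid) : target x/y centroid offsets
        from the image centre (pixels), target orientation (radians),
        a validity mask (False for degenerate all-zero frames, whose
        loss terms are skipped entirely) and an angle-validity mask
        (False additionally for near-isotropic frames — e.g. a circle —
        whose second-moment orientation is undefined, so only their
        position terms contribute).
    """
    arr = np.asarray(images)
    if arr.ndim != 4:
        raise ValueError("expected (n, channels, H, W)")
    n, _, h, w = arr.shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    tx = np.zeros(n)
    ty = np.zeros(n)
    ta = np.zeros(n)
    valid = np.ones(n, dtype=bool)
    angle_valid = np.ones(n, dtype=bool)
    n_bad = 0
    for i in range(n):
        try:
            if source == "com":
                f = com_features(arr[i])
                tx[i], ty[i], ta[i] = f.com_x, f.com_y, f.com_angle
                angle_valid[i] = f.com_mag > 0.5  # angle undefined near 0
            elif source == "image_moments":
                m = compute_moments(arr[i])
                tx[i], ty[i], ta[i] = m.xbar - cx, m.ybar - cy, m.alpha
                angle_valid[i] = anisotropy_ratio(m) >= ANISOTROPY_MIN_RATIO
            else:
                raise ValueError(f"unknown moment source {source!r}")
        except DegenerateImageError:
            valid[i] = False
            angle_valid[i] = False
            n_bad += 1
    if n_bad:
        warnings.warn(f"{n_bad} degenerate (all-zero) frames: moment-loss "
                      "terms skipped for these samples")
    return tx, ty, ta, valid, angle_valid
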