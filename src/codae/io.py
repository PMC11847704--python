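"""Image-stack readers/writers and run provenance.

Supported stack formats: a directory of PNGs, a multi-page TIFF, an
MRC/MRCS particle stack (cryo-EM convention: frames along the slowest
axis), and NPZ dense-array archives.  Loading normalizes to the
package's in-memory contract — square float32 frames in [0, 1], shape
(n, channels, H, W).  NPZ round trips are lossless; MRC (float32 mode
2) is lossless up to float32; 8-bit PNG quantizes to 1/255.

The MRC support is a small hand-written MRC2014 subset (modes 0, 1, 2
and 6 for reading; mode 2 for writing) — see the header layout comments
in :func:`save_stack`.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .synth import ImageBatch

_MRC_MODES = {0: np.int8, 1: np.int16, 2: np.float32, 6: np.uint16}


@dataclass(frozen=True)
class StackSource:
    """Where a stack lives and how to normalize it on load.

    ``fmt`` is auto-detected from the path when None.  ``normalize``:
    ``"stack"`` min–max over the whole stack (default: keeps relative
    frame brightness, which can itself be a generative factor),
    ``"frame"`` per frame, or ``"none"``.  ``channel``: ``"keep"`` or
    ``"mean"`` (collapse RGB to one channel).
    """

    path: str | Path
    fmt: str | None = None  # png_dir | tiff_stack | mrc | npz
    normalize: str = "stack"
    channel: str = "keep"

    def resolved_format(self) -> str:
        if self.fmt is not None:
            return self.fmt
        p = Path(self.path)
        if p.is_dir():
            return "png_dir"
        suf = p.suffix.lower()
        if suf in (".tif", ".tiff"):
            return "tiff_stack"
        if suf in (".mrc", ".mrcs"):
            return "mrc"
        if suf == ".npz":
            return "npz"
        raise ValueError(f"cannot infer stack format from {p}")


@dataclass
class RunManifest:
    """Provenance of one pipeline stage (written next to its outputs)."""

    command: str
    seed: int | None
    config_hash: str
    software_version: str
    input_digest: str | None
    outputs: list[str] = field(default_factory=list)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    p = Path(path)
    files = sorted(p.iterdir()) if p.is_dir() else [p]
    for f in files:
        if f.is_file():
            h.update(f.name.encode())
            h.update(f.read_bytes())
    return h.hexdigest()[:16]


# ---------------------------------------------------------------------------
# loading
# ---------------------------------------------------------------------------

def load_stack(src: StackSource | str | Path) -> ImageBatch:
    """Load an image stack and normalize it to the ImageBatch contract.

    Non-square frames are centre-cropped to square (with a warning);
    frames of inconsistent size raise an error naming the frame.
    """
    if not isinstance(src, StackSource):
        src = StackSource(src)
    fmt = src.resolved_format()
    path = Path(src.path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "png_dir":
        arr = _load_png_dir(path)
    elif fmt == "tiff_stack":
        import tifffile
        arr = np.asarray(tifffile.imread(str(path)))
        if arr.ndim == 2:
            arr = arr[None]
        if arr.ndim == 4:  # (n, H, W, C) -> (n, C, H, W)
            arr = np.moveaxis(arr, -1, 1)
        elif arr.ndim == 3:
            arr = arr[:, None]
    elif fmt == "mrc":
        arr = _read_mrc(path)[:, None]
    elif fmt == "npz":
        with np.load(path) as z:
            key = "data" if "data" in z else list(z.keys())[0]
            arr = np.asarray(z[key])
        if arr.ndim == 3:
            arr = arr[:, None]
    else:
        raise ValueError(f"unsupported format {fmt!r}")
    if np.issubdtype(arr.dtype, np.integer):
        # integer images carry their dtype's full-scale convention
        arr = arr.astype(np.float32) / np.iinfo(arr.dtype).max
    arr = arr.astype(np.float32)
    arr = _square_crop(arr)
    if src.channel == "mean" and arr.shape[1] > 1:
        arr = arr.mean(axis=1, keepdims=True)
    arr = _normalize(arr, src.normalize)
    return ImageBatch(arr)


def _load_png_dir(path: Path) -> np.ndarray:
    from PIL import Image
    files = sorted(p for p in path.iterdir()
                   if p.suffix.lower() in (".png", ".jpg", ".jpeg"))
    if not files:
        raise ValueError(f"no images found in {path}")
    frames = []
    shape = None
    for f in files:
        a = np.asarray(Image.open(f))
        if a.ndim == 3:
            a = np.moveaxis(a, -1, 0)
        else:
            a = a[None]
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError(
                f"inconsistent frame size in {f.name}: {a.shape[1:]} "
                f"(expected {shape[1:]})")
        frames.append(a)
    return np.stack(frames)  # keeps the integer dtype for later scaling


def _square_crop(arr: np.ndarray) -> np.ndarray:
    n, c, h, w = arr.shape
    if h == w:
        return arr
    import warnings
    s = min(h, w)
    warnings.warn(f"non-square frames ({h}x{w}); centre-cropping to {s}x{s}")
    oy, ox = (h - s) // 2, (w - s) // 2
    return arr[:, :, oy:oy + s, ox:ox + s]


def _normalize(arr: np.ndarray, mode: str) -> np.ndarray:
    if mode == "none":
        return np.clip(arr, 0.0, 1.0)
    if mode == "stack":
        lo, hi = float(arr.min()), float(arr.max())
        return (arr - lo) / (hi - lo) if hi > lo else np.zeros_like(arr)
    if mode == "frame":
        lo = arr.min(axis=(1, 2, 3), keepdims=True)
        hi = arr.max(axis=(1, 2, 3), keepdims=True)
        rng = np.where(hi > lo, hi - lo, 1.0)
        return (arr - lo) / rng
    raise ValueError(f"unknown normalization {mode!r}")


# ---------------------------------------------------------------------------
# saving
# ---------------------------------------------------------------------------

def save_stack(batch: ImageBatch | np.ndarray, dst: StackSource | str | Path
               ) -> None:
    """Write an image stack in the destination's format."""
    if not isinstance(dst, StackSource):
        dst = StackSource(dst)
    arr = batch.data if isinstance(batch, ImageBatch) else np.asarray(
        batch, dtype=np.float32)
    if arr.ndim == 3:
        arr = arr[:, None]
    fmt = dst.resolved_format()
    path = Path(dst.path)
    if fmt == "npz":
        np.savez(path, data=arr)
    elif fmt == "tiff_stack":
        import tifffile
        tifffile.imwrite(str(path), arr[:, 0] if arr.shape[1] == 1
                         else np.moveaxis(arr, 1, -1))
    elif fmt == "png_dir":
        from PIL import Image
        path.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(arr):
            img = (np.clip(frame, 0, 1) * 255).round().astype(np.uint8)
            img = img[0] if img.shape[0] == 1 else np.moveaxis(img, 0, -1)
            Image.fromarray(img).save(path / f"frame_{i:05d}.png")
    elif fmt == "mrc":
        if arr.shape[1] != 1:
            raise ValueError("MRC stacks are single-channel")
        _write_mrc(path, arr[:, 0])
    else:
        raise ValueError(f"unsupported format {fmt!r}")


# ---------------------------------------------------------------------------
# minimal MRC2014
# ---------------------------------------------------------------------------

def _read_mrc(path: Path) -> np.ndarray:
    """Read an MRC/MRCS stack as (n, H, W) (frames on the slowest axis)."""
    raw = path.read_bytes()
    if len(raw) < 1024:
        raise ValueError(f"{path}: truncated MRC header")
    nx, ny, nz, mode = struct.unpack_from("<4i", raw, 0)
    (nsymbt,) = struct.unpack_from("<i", raw, 92)
    if mode not in _MRC_MODES:
        raise ValueError(f"{path}: unsupported MRC mode {mode}")
    dtype = np.dtype(_MRC_MODES[mode]).newbyteorder("<")
    count = nx * ny * nz
    data = np.frombuffer(raw, dtype=dtype, count=count, offset=1024 + nsymbt)
    return data.reshape(nz, ny, nx).astype(np.float32)


def _write_mrc(path: Path, frames: np.ndarray) -> None:
    """Write float32 (mode 2) MRC2014 with frames on the slowest axis."""
    n, h, w = frames.shape
    data = np.ascontiguousarray(frames, dtype="<f4")
    header = bytearray(1024)
    struct.pack_into("<4i", header, 0, w, h, n, 2)       # nx ny nz mode
    struct.pack_into("<3i", header, 28, w, h, n)         # mx my mz
    struct.pack_into("<3f", header, 40, float(w), float(h), float(n))  # cella
    struct.pack_into("<3f", header, 52, 90.0, 90.0, 90.0)              # cellb
    struct.pack_into("<3i", header, 64, 1, 2, 3)         # mapc mapr maps
    struct.pack_into("<3f", header, 76, float(data.min()), float(data.max()),
                     float(data.mean()))
    struct.pack_into("<i", header, 92, 0)                # nsymbt
    header[208:212] = b"MAP "
    header[212:216] = bytes((0x44, 0x44, 0x00, 0x00))    # little-endian
    struct.pack_into("<f", header, 216, float(data.std()))
    path.write_bytes(bytes(header) + data.tobytes())


def mrc_header_dims(path: str | Path) -> tuple[int, int, int]:
    """(nx, ny, nz) from an MRC header."""
    raw = Path(path).read_bytes()[:16]
    nx, ny, nz, _ = struct.unpack("<4i", raw)
    return nx, ny, nz
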