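"""Image, mask and map raster I/O.

Reads photographs into linear-intensity arrays in [0, 1], reads hand-drawn
region-of-interest masks, converts to and from log colour-space, and encodes
normal/height maps into the 8-bit display rasters used for output: normal
maps as RGB = (x, y, z) components, height maps min-max normalised between
0 (black) and 255 (white).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import ValidationError

#: 4-connectivity structuring element for component labelling.
_FOUR_CONN = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)

MIN_SIDE = 8  # reconstruction needs pixel neighbourhoods


@dataclass
class RadianceImage:
    """H x W x C linear-intensity raster with values in [0, 1].

    Grayscale images carry C = 1; colour images C = 3.
    """

    pixels: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.pixels, dtype=np.float64)
        if p.ndim == 2:
            p = p[:, :, None]
        if p.ndim != 3:
            raise ValidationError(f"expected H x W or H x W x C pixels, got shape {p.shape}")
        if p.shape[0] < MIN_SIDE or p.shape[1] < MIN_SIDE:
            raise ValidationError(
                f"image must be at least {MIN_SIDE}x{MIN_SIDE}, got {p.shape[0]}x{p.shape[1]}"
            )
        if not np.all(np.isfinite(p)):
            raise ValidationError("image contains non-finite values")
        if p.min() < 0.0 or p.max() > 1.0:
            raise ValidationError("image values must lie in [0, 1]")
        self.pixels = p

    @property
    def height_px(self) -> int:
        return self.pixels.shape[0]

    @property
    def width_px(self) -> int:
        return self.pixels.shape[1]

    @property
    def channels(self) -> int:
        return self.pixels.shape[2]


@dataclass
class RegionMask:
    """Binary region of interest; the true set is a single 4-connected blob."""

    inside: np.ndarray

    def __post_init__(self):
        m = np.asarray(self.inside, dtype=bool)
        if m.ndim != 2:
            raise ValidationError("mask must be 2-D")
        if not m.any():
            raise ValidationError("mask has no inside pixel")
        _, n_comp = ndimage.label(m, structure=_FOUR_CONN)
        if n_comp != 1:
            raise ValidationError(
                f"mask inside set must be one 4-connected component, found {n_comp}"
            )
        self.inside = m

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "RegionMask":
        """Lenient constructor: any nonzero value is inside; if the inside
        set splits into several 4-connected components, keep the largest one
        and warn (hand-drawn masks often carry stray pixels)."""
        m = np.asarray(arr)
        if m.ndim == 3:
            m = m.any(axis=2)
        m = m.astype(bool)
        if not m.any():
            raise ValidationError("mask has no inside pixel")
        labels, n_comp = ndimage.label(m, structure=_FOUR_CONN)
        if n_comp > 1:
            sizes = ndimage.sum_labels(m, labels, index=np.arange(1, n_comp + 1))
            keep = int(np.argmax(sizes)) + 1
            warnings.warn(
                f"mask has {n_comp} 4-connected components; keeping the "
                f"largest ({int(sizes.max())} px)",
                stacklevel=2,
            )
            m = labels == keep
        return cls(m)

    @property
    def count(self) -> int:
        return int(self.inside.sum())


@dataclass
class LogImage:
    """Log colour-space image, clamped from below at ``eps_floor``."""

    log_pixels: np.ndarray
    eps_floor: float = 1e-4

    def __post_init__(self):
        self.log_pixels = np.asarray(self.log_pixels, dtype=np.float64)


def load_image(path, bit_depth_hint: int | None = None) -> RadianceImage:
    """Read a PNG/TIFF/JPEG file into a :class:`RadianceImage`.

    8-bit data is divided by 255 and 16-bit by 65535; an alpha channel is
    dropped; grayscale loads as C = 1.  ``bit_depth_hint`` overrides the
    divisor for integer data (8 or 16).
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"cannot read image file: {path}") from None
    except Exception as exc:
        raise IOError(f"cannot read image file: {path} ({exc})") from exc
    if raw.size == 0:
        raise ValidationError(f"zero-size image: {path}")
    if raw.ndim == 3 and raw.shape[2] in (2, 4):  # drop alpha
        raw = raw[:, :, : raw.shape[2] - 1]
    if np.issubdtype(raw.dtype, np.integer):
        if bit_depth_hint is not None:
            scale = float(2**bit_depth_hint - 1)
        else:
            scale = 65535.0 if raw.dtype.itemsize > 1 else 255.0
        pixels = raw.astype(np.float64) / scale
    else:
        pixels = np.clip(raw.astype(np.float64), 0.0, 1.0)
    return RadianceImage(pixels)


def load_mask(path, image: RadianceImage) -> RegionMask:
    """Read a region-of-interest raster; any nonzero pixel is inside.

    The mask must match the image's height and width.  Multiple 4-connected
    components are reduced to the largest with a warning.
    """
    path = Path(path)
    try:
        raw = iio.imread(path)
    except FileNotFoundError:
        raise IOError(f"cannot read mask file: {path}") from None
    except Exception as exc:
        raise IOError(f"cannot read mask file: {path} ({exc})") from exc
    if raw.shape[:2] != (image.height_px, image.width_px):
        raise ValidationError(
            f"mask shape {raw.shape[:2]} does not match image "
            f"{(image.height_px, image.width_px)}"
        )
    return RegionMask.from_array(raw)


def srgb_to_linear(pixels: np.ndarray) -> np.ndarray:
    """Standard sRGB electro-optical transfer (display -> linear radiance)."""
    p = np.asarray(pixels, dtype=np.float64)
    return np.where(p <= 0.04045, p / 12.92, ((p + 0.055) / 1.055) ** 2.4)


def linear_to_srgb(pixels: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(pixels, dtype=np.float64), 0.0, 1.0)
    return np.where(p <= 0.0031308, 12.92 * p, 1.055 * p ** (1 / 2.4) - 0.055)


def to_log(image: RadianceImage, eps_floor: float = 1e-4) -> LogImage:
    """Convert to log colour-space: ``log(max(pixel, eps_floor))``.

    Invertible via exponentiation for pixels at or above the floor.
    """
    if not (0.0 < eps_floor < 1.0):
        raise ValidationError(f"eps_floor must be in (0, 1), got {eps_floor}")
    return LogImage(np.log(np.maximum(image.pixels, eps_floor)), eps_floor=eps_floor)


def encode_normal_map(normals: np.ndarray, mask: RegionMask) -> np.ndarray:
    """8-bit RGB raster of a normal map: R, G, B = x, y, z components.

    x and y map linearly from [-1, 1] to [0, 255]; z from [0, 1] to
    [0, 255].  Pixels outside the mask are 0.
    """
    n = np.asarray(normals, dtype=np.float64)
    out = np.zeros(n.shape[:2] + (3,), dtype=np.uint8)
    m = mask.inside
    xy = np.clip(np.round((n[:, :, :2] + 1.0) / 2.0 * 255.0), 0, 255)
    z = np.clip(np.round(n[:, :, 2] * 255.0), 0, 255)
    out[m, 0] = xy[m, 0]
    out[m, 1] = xy[m, 1]
    out[m, 2] = z[m]
    return out


def decode_normal_map(rgb: np.ndarray, mask: RegionMask) -> np.ndarray:
    """Inverse of :func:`encode_normal_map` (up to 8-bit quantisation).

    Returns raw component values; no renormalisation is applied so the
    quantisation round-trip bound is directly observable.
    """
    r = np.asarray(rgb, dtype=np.float64)
    out = np.zeros(r.shape[:2] + (3,), dtype=np.float64)
    out[:, :, 2] = 1.0
    m = mask.inside
    out[m, 0] = r[m, 0] / 255.0 * 2.0 - 1.0
    out[m, 1] = r[m, 1] / 255.0 * 2.0 - 1.0
    out[m, 2] = r[m, 2] / 255.0
    return out


def encode_height_map(height, mask: RegionMask) -> np.ndarray:
    """8-bit grayscale raster of a height field, min-max normalised inside
    the mask (minimum -> 0, maximum -> 255; constant field -> uniform 128).
    Larger height means closer to the viewer (lighter)."""
    values = getattr(height, "values", height)
    h = np.asarray(values, dtype=np.float64)
    out = np.zeros(h.shape, dtype=np.uint8)
    m = mask.inside
    lo, hi = h[m].min(), h[m].max()
    if hi - lo < 1e-300:
        out[m] = 128
    else:
        out[m] = np.round((h[m] - lo) / (hi - lo) * 255.0)
    return out


def save_raster(path, raster: np.ndarray) -> None:
    """Write an 8-bit or 16-bit raster (PNG/TIFF by extension)."""
    iio.imwrite(Path(path), raster)


def save_float_tiff(path, array: np.ndarray) -> None:
    """Write a float32 TIFF (ground truth / final height maps)."""
    import tifffile

    arr = np.asarray(array, dtype=np.float32)
    photometric = "rgb" if arr.ndim == 3 and arr.shape[2] == 3 else "minisblack"
    tifffile.imwrite(Path(path), arr, photometric=photometric)


def load_float_tiff(path) -> np.ndarray:
    import tifffile

    return np.asarray(tifffile.imread(Path(path)), dtype=np.float64)


def export_height_mesh_ply(height, mask: RegionMask, path, z_scale: float = 1.0) -> int:
    """Export a height field over the mask as an ASCII PLY mesh.

    One vertex per inside pixel at (x, y, z_scale * height); faces are the
    two triangles of every 2 x 2 pixel quad fully inside the mask.  Returns
    the number of vertices written.
    """
    values = getattr(height, "values", height)
    h = np.asarray(values, dtype=np.float64)
    m = mask.inside
    H, W = m.shape
    vid = np.full((H, W), -1, dtype=np.int64)
    rows, cols = np.nonzero(m)
    vid[rows, cols] = np.arange(rows.size)

    quad = m[:-1, :-1] & m[:-1, 1:] & m[1:, :-1] & m[1:, 1:]
    qr, qc = np.nonzero(quad)
    a = vid[qr, qc]
    b = vid[qr, qc + 1]
    c = vid[qr + 1, qc]
    d = vid[qr + 1, qc + 1]

    lines = [
        "ply",
        "format ascii 1.0",
        f"element vertex {rows.size}",
        "property float x",
        "property float y",
        "property float z",
        f"element face {2 * qr.size}",
        "property list uchar int vertex_indices",
        "end_header",
    ]
    zs = z_scale * h[rows, cols]
    lines.extend(f"{x} {y} {z:.6f}" for x, y, z in zip(cols, rows, zs))
    lines.extend(f"3 {i} {j} {k}" for i, j, k in zip(a, b, c))
    lines.extend(f"3 {j} {l} {k}" for j, l, k in zip(b, d, c))
    Path(path).write_text("\n".join(lines) + "\n")
    return int(rows.size)
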