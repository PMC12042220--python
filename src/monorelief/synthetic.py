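"""Ground-truth Lambertian scene generation.

Every pipeline stage is validated against scenes built here: a height
field with known normals, a piecewise reflectance pattern, a directional
light, and the Lambertian rendering

    I = clip(R * (max(0, <D, N>) + ambient), 0, 1).

Scenes are deterministic given their seed and serialisable to a directory
of plain rasters plus a JSON sidecar.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import _grid, raster_io
from .errors import ValidationError
from .normals import LightDirection
from .raster_io import RadianceImage, RegionMask

HEIGHT_KINDS = ("flat", "tilted_plane", "hemisphere", "curled_sheet", "gabor_bumps")
REFLECTANCE_KINDS = ("uniform", "mondrian", "spots", "stripes", "eyespot")

_R_MIN, _R_MAX = 0.05, 1.0  # reflectance range kept strictly positive


def _size2d(size) -> tuple[int, int]:
    if np.isscalar(size):
        size = (int(size), int(size))
    h, w = int(size[0]), int(size[1])
    if h < 16 or w < 16:
        raise ValidationError(f"size must be at least 16x16, got {h}x{w}")
    return h, w


def make_height_field(kind: str, size, params: dict | None = None,
                      seed: int = 0) -> np.ndarray:
    """Deterministic ground-truth height fields.

    Kinds: ``flat`` (zeros), ``tilted_plane`` (slope_x * x + slope_y * y),
    ``hemisphere`` (spherical cap, apex height = radius, rim at 0),
    ``curled_sheet`` (one edge rolled upward, a curled-leaf analogue) and
    ``gabor_bumps`` (sum of seeded Gaussian bumps, a bark analogue).
    """
    h, w = _size2d(size)
    params = dict(params or {})
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    if kind == "flat":
        return np.zeros((h, w))
    if kind == "tilted_plane":
        sx = float(params.get("slope_x", 1.0))
        sy = float(params.get("slope_y", 0.0))
        return sx * xx + sy * yy
    if kind == "hemisphere":
        radius = float(params.get("radius", 0.4 * min(h, w)))
        cy = float(params.get("center_y", (h - 1) / 2))
        cx = float(params.get("center_x", (w - 1) / 2))
        d2 = (xx - cx) ** 2 + (yy - cy) ** 2
        return np.sqrt(np.maximum(radius**2 - d2, 0.0))
    if kind == "curled_sheet":
        # raised-cosine ridge along one edge: the sheet rolls up and over,
        # returning to the base plane (a half-cylinder-like leaf curl with
        # bounded slopes at the roll boundaries)
        amplitude = float(params.get("amplitude", 0.08 * w))
        start = float(params.get("curl_start", 0.5))
        x0 = start * (w - 1)
        span = max(w - 1 - x0, 1.0)
        u = np.clip((xx - x0) / span, 0.0, 1.0)
        return amplitude * 0.5 * (1.0 - np.cos(2.0 * np.pi * u))
    if kind == "gabor_bumps":
        n_bumps = int(params.get("n_bumps", 8))
        amp = float(params.get("amplitude", 2.0))
        rng = np.random.default_rng(seed)
        field = np.zeros((h, w))
        for _ in range(n_bumps):
            cy, cx = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
            sigma = rng.uniform(0.05, 0.15) * min(h, w)
            a = rng.uniform(0.5, 1.0) * amp * rng.choice([-1.0, 1.0])
            field += a * np.exp(-((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2))
        return field
    raise ValidationError(f"unknown height kind {kind!r}; expected one of {HEIGHT_KINDS}")


def _check_albedos(values) -> None:
    arr = np.asarray(values, dtype=np.float64)
    if arr.min() < _R_MIN or arr.max() > _R_MAX:
        raise ValidationError(
            f"reflectance values must lie in [{_R_MIN}, {_R_MAX}], got "
            f"[{arr.min():.3g}, {arr.max():.3g}]"
        )


def make_reflectance(kind: str, size, params: dict | None = None,
                     seed: int = 0, channels: int = 3) -> np.ndarray:
    """Deterministic piecewise reflectance patterns in [0.05, 1].

    ``mondrian`` builds a seeded Voronoi tessellation coloured from a
    log-spaced palette, guaranteeing adjacent-patch log contrast well above
    typical Retinex thresholds; ``spots``/``eyespot``/``stripes`` emulate
    wing markings.
    """
    h, w = _size2d(size)
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)

    def expand(gray: np.ndarray) -> np.ndarray:
        return np.repeat(gray[:, :, None], channels, axis=2)

    if kind == "uniform":
        value = float(params.get("value", 0.6))
        _check_albedos([value])
        return np.full((h, w, channels), value)
    if kind == "mondrian":
        n_patches = int(params.get("n_patches", 6))
        palette = params.get("palette")
        if palette is None:
            palette = np.exp(np.linspace(np.log(0.12), np.log(0.9), n_patches))
            palette = rng.permutation(palette)
        palette = np.asarray(palette, dtype=np.float64)
        _check_albedos(palette)
        sites = np.column_stack([rng.uniform(0, h - 1, n_patches),
                                 rng.uniform(0, w - 1, n_patches)])
        d2 = (yy[:, :, None] - sites[:, 0]) ** 2 + (xx[:, :, None] - sites[:, 1]) ** 2
        labels = np.argmin(d2, axis=2)
        return expand(palette[labels])
    if kind == "spots":
        n_spots = int(params.get("n_spots", 5))
        base = float(params.get("base", 0.7))
        spot = float(params.get("spot", 0.2))
        radius = float(params.get("radius", 0.06 * min(h, w)))
        _check_albedos([base, spot])
        gray = np.full((h, w), base)
        margin = radius + 1
        for _ in range(n_spots):
            cy = rng.uniform(margin, h - 1 - margin)
            cx = rng.uniform(margin, w - 1 - margin)
            gray[(yy - cy) ** 2 + (xx - cx) ** 2 <= radius**2] = spot
        return expand(gray)
    if kind == "stripes":
        period = float(params.get("period", 0.12 * w))
        angle = float(params.get("angle", 0.0))
        lo, hi = float(params.get("low", 0.25)), float(params.get("high", 0.8))
        _check_albedos([lo, hi])
        coord = xx * np.cos(angle) + yy * np.sin(angle)
        gray = np.where((coord // (period / 2)) % 2 == 0, hi, lo)
        return expand(gray)
    if kind == "eyespot":
        base = float(params.get("base", 0.6))
        rings = params.get("rings", (0.18, 0.12, 0.06))
        ring_values = params.get("ring_values", (0.15, 0.85, 0.1))
        _check_albedos([base, *ring_values])
        cy = float(params.get("center_y", (h - 1) / 2))
        cx = float(params.get("center_x", (w - 1) / 2))
        gray = np.full((h, w), base)
        d = np.hypot(yy - cy, xx - cx)
        for frac, value in zip(rings, ring_values):
            gray[d <= frac * min(h, w)] = value
        return expand(gray)
    raise ValidationError(
        f"unknown reflectance kind {kind!r}; expected one of {REFLECTANCE_KINDS}"
    )


def make_shading_field(size, kind: str = "blobs", seed: int = 0,
                       low: float = 0.3, high: float = 0.95) -> np.ndarray:
    """Smooth, low-frequency positive shading fields for decomposition
    tests (no geometric backing; useful when the true height is flat)."""
    h, w = _size2d(size)
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    if kind == "constant":
        field = np.ones((h, w))
    elif kind == "gradient":
        field = xx / max(w - 1, 1)
    elif kind == "blobs":
        field = np.zeros((h, w))
        for _ in range(4):
            cy, cx = rng.uniform(0, h - 1), rng.uniform(0, w - 1)
            sigma = rng.uniform(0.25, 0.5) * min(h, w)
            field += rng.uniform(-1, 1) * np.exp(
                -((xx - cx) ** 2 + (yy - cy) ** 2) / (2 * sigma**2)
            )
    else:
        raise ValidationError(f"unknown shading kind {kind!r}")
    lo, hi = field.min(), field.max()
    if hi - lo < 1e-12:
        return np.full((h, w), high)
    return low + (field - lo) / (hi - lo) * (high - low)


def wing_mask(size, overlap: float = 0.1) -> RegionMask:
    """Non-rectangular ROI: union of two mirrored ellipses (a wing pair)."""
    h, w = _size2d(size)
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    cy = (h - 1) / 2
    ax, ay = 0.28 * w, 0.38 * h
    # ellipse centres symmetric about the vertical midline, overlapping
    cx_left = 0.5 * (w - 1) - (0.5 - overlap) * ax
    cx_right = 0.5 * (w - 1) + (0.5 - overlap) * ax
    left = ((xx - cx_left) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    right = ((xx - cx_right) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    return RegionMask.from_array(left | right)


def height_to_normals(height: np.ndarray) -> np.ndarray:
    """Unit normals of a height field: normalise (-dH/dx, -dH/dy, 1).

    Forward differences with replicate boundary, matching the convention
    used by the reconstruction stages.
    """
    hx, hy = _grid.forward_gradient(height)
    n = np.stack([-hx, -hy, np.ones_like(height)], axis=2)
    return n / np.linalg.norm(n, axis=2, keepdims=True)


@dataclass
class SyntheticScene:
    """Ground-truth bundle: geometry, reflectance, light and rendering."""

    true_height: np.ndarray
    true_reflectance: np.ndarray
    true_normals: np.ndarray
    light: LightDirection
    ambient: float
    rendered: RadianceImage
    mask: RegionMask
    seed: int
    noise_sigma: float = 0.0

    @property
    def true_shading(self) -> np.ndarray:
        lam = np.tensordot(self.true_normals, self.light.vector, axes=([2], [0]))
        return np.maximum(lam, 0.0) + self.ambient

    def check_invariants(self) -> None:
        # normals must round-trip to the forward-difference height gradient
        hx, hy = _grid.forward_gradient(self.true_height)
        n = self.true_normals
        gx = -n[:, :, 0] / n[:, :, 2]
        gy = -n[:, :, 1] / n[:, :, 2]
        if max(np.abs(gx - hx).max(), np.abs(gy - hy).max()) > 1e-10:
            raise ValidationError("scene normals inconsistent with height field")
        if self.noise_sigma == 0.0:
            expected = np.clip(
                self.true_reflectance * self.true_shading[:, :, None], 0.0, 1.0
            )
            if np.abs(expected - self.rendered.pixels).max() > 1e-12:
                raise ValidationError("rendering inconsistent with scene model")


def render_scene(height: np.ndarray, reflectance: np.ndarray,
                 light: LightDirection, ambient: float = 0.1,
                 mask: RegionMask | None = None,
                 noise_sigma: float = 0.0, seed: int = 0) -> SyntheticScene:
    """Render a Lambertian scene and bundle it with its ground truth."""
    height = np.asarray(height, dtype=np.float64)
    reflectance = np.asarray(reflectance, dtype=np.float64)
    if reflectance.ndim == 2:
        reflectance = reflectance[:, :, None]
    if reflectance.shape[:2] != height.shape:
        raise ValidationError("height and reflectance sizes differ")
    if not (0.0 <= ambient < 1.0):
        raise ValidationError("ambient must be in [0, 1)")

    normals = height_to_normals(height)
    lam = np.tensordot(normals, light.vector, axes=([2], [0]))
    shading = np.maximum(lam, 0.0) + ambient
    image = np.clip(reflectance * shading[:, :, None], 0.0, 1.0)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        image = np.clip(image + rng.normal(0.0, noise_sigma, image.shape), 0.0, 1.0)
    if mask is None:
        mask = RegionMask(np.ones(height.shape, dtype=bool))

    scene = SyntheticScene(
        true_height=height,
        true_reflectance=reflectance,
        true_normals=normals,
        light=light,
        ambient=float(ambient),
        rendered=RadianceImage(image),
        mask=mask,
        seed=int(seed),
        noise_sigma=float(noise_sigma),
    )
    scene.check_invariants()
    return scene


def save_scene(scene: SyntheticScene, directory) -> Path:
    """Materialise a scene: 8-bit display PNG plus exact float32 TIFF of
    the rendering, mask PNG, float32 TIFF ground truth, JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rendered8 = np.round(scene.rendered.pixels * 255.0).astype(np.uint8)
    raster_io.save_raster(directory / "rendered.png", np.squeeze(rendered8))
    raster_io.save_float_tiff(directory / "rendered_f32.tif", scene.rendered.pixels)
    raster_io.save_raster(directory / "mask.png",
                          scene.mask.inside.astype(np.uint8) * 255)
    raster_io.save_float_tiff(directory / "true_height.tif", scene.true_height)
    raster_io.save_float_tiff(directory / "true_normals.tif", scene.true_normals)
    raster_io.save_float_tiff(directory / "true_reflectance.tif",
                              scene.true_reflectance)
    meta = {
        "light_vector": [float(v) for v in scene.light.vector],
        "light_azimuth_rad": scene.light.azimuth_rad,
        "ambient": scene.ambient,
        "seed": scene.seed,
        "noise_sigma": scene.noise_sigma,
        "linear_intensity": True,
    }
    (directory / "scene.json").write_text(json.dumps(meta, indent=2))
    return directory


def load_scene(directory) -> SyntheticScene:
    directory = Path(directory)
    meta = json.loads((directory / "scene.json").read_text())
    f32 = directory / "rendered_f32.tif"
    if f32.exists():
        pixels = np.clip(raster_io.load_float_tiff(f32), 0.0, 1.0)
        rendered = raster_io.RadianceImage(pixels)
    else:
        rendered = raster_io.load_image(directory / "rendered.png")
    mask = raster_io.load_mask(directory / "mask.png", rendered)
    height = raster_io.load_float_tiff(directory / "true_height.tif")
    reflectance = raster_io.load_float_tiff(directory / "true_reflectance.tif")
    light = LightDirection.from_azimuth(meta["light_azimuth_rad"])
    scene = SyntheticScene(
        true_height=height,
        true_reflectance=reflectance,
        true_normals=height_to_normals(height),  # re-derive at full precision
        light=light,
        ambient=float(meta["ambient"]),
        rendered=rendered,
        mask=mask,
        seed=int(meta["seed"]),
        noise_sigma=float(meta.get("noise_sigma", 0.0)),
    )
    return scene
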