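"""Intrinsic image decomposition: I = R x S.

Splits an image into a monochromatic shading map S and a per-channel
reflectance map R by minimising, in log colour-space and in the
least-squares sense, a weighted sum of three terms over log S:

* a Retinex term attributing small image gradients to shading and large
  ones to reflectance edges,
* a texture term linking similarly textured patches to the same
  reflectance, and
* a scale term pinning log S to zero at the brightest pixels.

The resulting sparse linear system is solved iteratively (LSQR).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _grid
from ._solve import build_csr, solve_sparse_lsq
from .errors import ValidationError
from .raster_io import LogImage, RadianceImage, RegionMask, to_log


@dataclass
class DecompositionConfig:
    """Weights, thresholds and solver settings for :func:`decompose`.

    Defaults follow the reference setting: Retinex and texture terms
    balanced at weight 1, the scale term enforced much more strongly
    (weight 1000) because it touches only the few brightest pixels, and a
    below-threshold Retinex gradient weight of 100.
    """

    lambda_rx: float = 1.0
    lambda_tx: float = 1.0
    lambda_sc: float = 1000.0
    retinex_threshold_t: float = 0.1
    retinex_smooth_weight: float = 100.0
    edge_weight_zero: float = 0.0
    brightness_quantile: float = 0.95  # fraction of the brightest pixel
    texture_patch_px: int = 5
    texture_knn: int = 4
    texture_corr_min: float = 0.9
    texture_stride: int = 2
    texture_max_candidates: int = 2000
    texture_var_min: float = 1e-3
    solver_tol: float = 1e-8
    solver_max_iter: int = 10_000
    rng_seed: int = 0

    def __post_init__(self):
        if min(self.lambda_rx, self.lambda_tx, self.lambda_sc) < 0:
            raise ValidationError("term weights must be >= 0")
        if not (0.0 < self.brightness_quantile < 1.0):
            raise ValidationError("brightness_quantile must be in (0, 1)")
        if self.texture_patch_px < 3 or self.texture_patch_px % 2 == 0:
            raise ValidationError("texture_patch_px must be odd and >= 3")
        if self.retinex_threshold_t <= 0:
            raise ValidationError("retinex_threshold_t must be > 0")


@dataclass
class ShadingMap:
    """Monochromatic shading; strictly positive inside the mask."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class ReflectanceMap:
    """Per-channel reflectance; strictly positive inside the mask."""

    values: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


@dataclass
class TexturePairSet:
    """Links between similarly textured pixel locations.

    ``pairs`` holds (flat-index, flat-index, weight) triplets; flat indices
    address the H x W grid in row-major order.
    """

    pairs: list[tuple[int, int, float]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.pairs)


def retinex_weight(log_image: LogImage, t: float, smooth_weight: float = 100.0) -> np.ndarray:
    """Per-pixel Retinex gradient weight.

    The weight is exactly 0 where the forward-difference gradient magnitude
    of the log image exceeds the threshold ``t`` (a reflectance edge) and
    exactly ``smooth_weight`` (default 100) otherwise.  For colour images
    the gradient magnitude is pooled as the max over channels.
    """
    if t <= 0:
        raise ValidationError(f"threshold t must be > 0, got {t}")
    lg = log_image.log_pixels
    if lg.ndim == 2:
        lg = lg[:, :, None]
    mag = np.zeros(lg.shape[:2], dtype=np.float64)
    for c in range(lg.shape[2]):
        gx, gy = _grid.forward_gradient(lg[:, :, c])
        mag = np.maximum(mag, np.hypot(gx, gy))
    return np.where(mag > t, 0.0, float(smooth_weight))


def scale_indicator(image: RadianceImage, quantile: float = 0.95,
                    mask: RegionMask | None = None) -> np.ndarray:
    """Binary raster marking the brightest pixels.

    A pixel is flagged (1) when its brightness — the per-pixel max across
    channels — is at least ``quantile`` times the brightest pixel in the
    (masked) image; otherwise 0.
    """
    brightness = image.pixels.max(axis=2)
    if mask is not None:
        peak = brightness[mask.inside].max()
        b = (brightness >= quantile * peak) & mask.inside
    else:
        peak = brightness.max()
        b = brightness >= quantile * peak
    return b.astype(np.uint8)


def texture_pairs(log_image: LogImage, mask: RegionMask,
                  config: DecompositionConfig) -> TexturePairSet:
    """Find pairs of similarly textured locations.

    Candidate patch centres lie on a stride grid (fully inside the mask);
    patches are mean-subtracted windows of the channel-averaged log image.
    Two kinds of candidates are dropped: near-constant patches (variance
    below ``texture_var_min``), which carry no texture to correlate, and
    patches containing a Retinex edge (log-gradient above
    ``retinex_threshold_t``) — above-threshold edges are already claimed by
    the Retinex term, and mean-subtracted correlation cannot tell apart
    reflectance steps of different heights, so linking edge patches would
    equate reflectances across distinct regions.  Each surviving centre
    links to at most ``texture_knn`` others whose normalised correlation
    reaches ``texture_corr_min``; links carry unit weight.  Deterministic
    given ``rng_seed`` (used only to subsample oversized candidate sets).
    """
    lg = log_image.log_pixels
    gray = lg.mean(axis=2) if lg.ndim == 3 else lg
    H, W = gray.shape
    half = config.texture_patch_px // 2
    p = config.texture_patch_px
    if p > min(H, W):
        raise ValidationError("texture patch does not fit inside the image")

    from scipy import ndimage

    fits = ndimage.minimum_filter(mask.inside.astype(np.uint8), size=p,
                                  mode="constant", cval=0).astype(bool)
    edge = retinex_weight(log_image, config.retinex_threshold_t, 1.0) == 0.0
    edge_free = ~ndimage.maximum_filter(edge, size=p, mode="constant", cval=False)
    fits &= edge_free
    rows = np.arange(half, H - half, config.texture_stride)
    cols = np.arange(half, W - half, config.texture_stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    rr, cc = rr.ravel(), cc.ravel()
    keep = fits[rr, cc]
    rr, cc = rr[keep], cc[keep]
    if rr.size == 0:
        return TexturePairSet([])

    windows = np.lib.stride_tricks.sliding_window_view(gray, (p, p))
    patches = windows[rr - half, cc - half].reshape(rr.size, -1)
    patches = patches - patches.mean(axis=1, keepdims=True)
    var = (patches**2).mean(axis=1)
    textured = var > config.texture_var_min
    rr, cc, patches = rr[textured], cc[textured], patches[textured]
    if rr.size < 2:
        return TexturePairSet([])

    if rr.size > config.texture_max_candidates:
        rng = np.random.default_rng(config.rng_seed)
        sel = np.sort(rng.choice(rr.size, config.texture_max_candidates, replace=False))
        rr, cc, patches = rr[sel], cc[sel], patches[sel]

    norm = np.linalg.norm(patches, axis=1, keepdims=True)
    unit = patches / norm
    corr = unit @ unit.T
    np.fill_diagonal(corr, -np.inf)

    flat = rr.astype(np.int64) * W + cc.astype(np.int64)
    pairs: set[tuple[int, int]] = set()
    k = config.texture_knn
    order = np.argsort(-corr, axis=1, kind="stable")[:, :k]
    for i in range(flat.size):
        for j in order[i]:
            if corr[i, j] >= config.texture_corr_min:
                a, b = int(flat[i]), int(flat[j])
                if a != b:
                    pairs.add((min(a, b), max(a, b)))
    return TexturePairSet(sorted((a, b, 1.0) for a, b in pairs))


def _assemble_system(log_image: LogImage, image: RadianceImage, mask: RegionMask,
                     config: DecompositionConfig, pair_set: TexturePairSet):
    """Build the sparse system A @ logS = b over inside-mask variables."""
    lg = log_image.log_pixels
    H, W, C = lg.shape
    idx, n = _grid.index_map(mask.inside)
    omega = retinex_weight(log_image, config.retinex_threshold_t,
                           config.retinex_smooth_weight)

    rows_l, cols_l, vals_l, b_l = [], [], [], []
    row0 = 0
    srx = np.sqrt(config.lambda_rx)

    # Retinex rows: (1 - w) * (s_q - s_p) = -w * (logI_q - logI_p), per
    # channel and per inside-mask forward pair; w is the weight at the base
    # pixel of the pair.
    if config.lambda_rx > 0:
        for axis in ("x", "y"):
            pr, pc = _grid.forward_pairs(mask.inside, axis)
            if pr.size == 0:
                continue
            qr = pr + (1 if axis == "y" else 0)
            qc = pc + (1 if axis == "x" else 0)
            p_var = idx[pr, pc]
            q_var = idx[qr, qc]
            w = omega[pr, pc]
            coef = srx * (1.0 - w)
            for c in range(C):
                dlog = lg[qr, qc, c] - lg[pr, pc, c]
                r = row0 + np.arange(pr.size)
                rows_l.extend([r, r])
                cols_l.extend([q_var, p_var])
                vals_l.extend([coef, -coef])
                b_l.append(-srx * w * dlog)
                row0 += pr.size
    n_retinex = row0

    # Texture rows: equal log R across linked locations, i.e. the log S
    # difference must equal the log I difference, per channel.
    if config.lambda_tx > 0 and len(pair_set) > 0:
        pa = np.array([p[0] for p in pair_set.pairs], dtype=np.int64)
        pb = np.array([p[1] for p in pair_set.pairs], dtype=np.int64)
        pw = np.array([p[2] for p in pair_set.pairs], dtype=np.float64)
        ar, ac = np.divmod(pa, W)
        br, bc = np.divmod(pb, W)
        a_var = idx[ar, ac]
        b_var = idx[br, bc]
        ok = (a_var >= 0) & (b_var >= 0)
        ar, ac, br, bc = ar[ok], ac[ok], br[ok], bc[ok]
        a_var, b_var, pw = a_var[ok], b_var[ok], pw[ok]
        coef = np.sqrt(config.lambda_tx * pw)
        for c in range(C):
            dlog = lg[br, bc, c] - lg[ar, ac, c]
            r = row0 + np.arange(a_var.size)
            rows_l.extend([r, r])
            cols_l.extend([b_var, a_var])
            vals_l.extend([coef, -coef])
            b_l.append(coef * dlog)
            row0 += a_var.size
    n_texture = row0 - n_retinex

    # Scale rows: pin log S to 0 at the brightest pixels.
    b_ind = scale_indicator(image, config.brightness_quantile, mask)
    sr, sc_ = np.nonzero(b_ind)
    s_var = idx[sr, sc_]
    r = row0 + np.arange(s_var.size)
    rows_l.append(r)
    cols_l.append(s_var)
    vals_l.append(np.full(s_var.size, np.sqrt(config.lambda_sc)))
    b_l.append(np.zeros(s_var.size))
    row0 += s_var.size

    A = build_csr(rows_l, cols_l, vals_l, shape=(row0, n))
    b = np.concatenate(b_l) if b_l else np.zeros(0)
    counts = {"retinex_rows": n_retinex, "texture_rows": n_texture,
              "scale_rows": int(s_var.size), "n_vars": n}
    return A, b, idx, counts


def decompose(image: RadianceImage, mask: RegionMask,
              config: DecompositionConfig | None = None,
              eps_floor: float = 1e-4):
    """Decompose an image into reflectance and shading.

    Solves the sparse regularised least-squares problem for log S inside
    the mask, then returns ``S = exp(log S)`` and ``R = exp(log I - log S)``
    per channel (so that R x S reproduces the eps-floored image exactly).

    Returns
    -------
    (ReflectanceMap, ShadingMap, dict)
        The dict carries solver diagnostics (relative residual, iteration
        count, row counts).
    """
    config = config or DecompositionConfig()
    if image.pixels[mask.inside].max() <= 0.0:
        raise ValidationError("masked region is entirely black; nothing to decompose")
    log_image = to_log(image, eps_floor)
    pair_set = texture_pairs(log_image, mask, config) if config.lambda_tx > 0 \
        else TexturePairSet([])
    A, b, idx, counts = _assemble_system(log_image, image, mask, config, pair_set)
    s_vec, diag = solve_sparse_lsq(A, b, config.solver_tol, config.solver_max_iter)

    H, W, C = log_image.log_pixels.shape
    log_s = np.zeros((H, W), dtype=np.float64)
    log_s[mask.inside] = s_vec
    shading = np.exp(log_s)
    shading[~mask.inside] = 1.0
    reflectance = np.exp(log_image.log_pixels - log_s[:, :, None])
    reflectance[~mask.inside] = image.pixels[~mask.inside]

    diag = dict(diag, **counts, texture_pairs=len(pair_set))
    return ReflectanceMap(reflectance), ShadingMap(shading), diag
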