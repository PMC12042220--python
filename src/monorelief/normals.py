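"""Normal-map estimation from a shading map under the Lambertian model.

The light direction is the dominant in-plane shading gradient orientation
with the incident elevation fixed at 45 degrees.  Normals are then
recovered per pixel by solving, in the least-squares sense, the stacked
linear system of Lambertian data rows <D, N> = S, normal-smoothness rows
and reflectance-edge orientation rows, treating each normal as a free
3-vector that is renormalised afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import _grid
from ._solve import build_csr, solve_sparse_lsq
from .errors import ValidationError
from .intrinsic import ReflectanceMap, ShadingMap
from .raster_io import RegionMask

#: z floor applied before the final renormalisation; keeps -Nx/Nz bounded.
NZ_CLAMP = 1e-3

_ELEVATION = np.pi / 4  # fixed 45-degree incident elevation


@dataclass
class LightDirection:
    """Unit illumination vector with a fixed 45-degree elevation."""

    vector: np.ndarray
    azimuth_rad: float
    elevation_rad: float = _ELEVATION

    def __post_init__(self):
        self.vector = np.asarray(self.vector, dtype=np.float64)
        if abs(np.linalg.norm(self.vector) - 1.0) > 1e-12:
            raise ValidationError("light direction must be a unit vector")

    @classmethod
    def from_azimuth(cls, azimuth_rad: float) -> "LightDirection":
        ce = np.cos(_ELEVATION)
        v = np.array([np.cos(azimuth_rad) * ce, np.sin(azimuth_rad) * ce,
                      np.sin(_ELEVATION)])
        v /= np.linalg.norm(v)
        return cls(v, float(azimuth_rad))


@dataclass
class NormalConfig:
    """Weights and solver settings for :func:`estimate_normals`.

    ``edge_threshold_c`` of ``None`` means "use the 90th percentile of the
    inside-mask reflectance log-gradient magnitude".  The small
    ``flat_prior_weight`` breaks the per-pixel ambiguity of the Lambertian
    data row by pulling free normals gently toward flat-up (0, 0, 1); it is
    orders of magnitude weaker than the data and smoothness terms.
    """

    edge_threshold_c: float | None = None
    smooth_weight: float = 1.0
    edge_weight: float = 1.0
    data_weight: float = 1.0
    flat_prior_weight: float = 1e-3
    solver_tol: float = 1e-8
    solver_max_iter: int = 10_000

    def __post_init__(self):
        for w in (self.smooth_weight, self.edge_weight, self.data_weight,
                  self.flat_prior_weight):
            if w < 0:
                raise ValidationError("weights must be >= 0")
        if self.edge_threshold_c is not None and self.edge_threshold_c <= 0:
            raise ValidationError("edge_threshold_c must be > 0")


@dataclass
class NormalMap:
    """H x W x 3 unit normals, front-facing (z > 0) inside the mask."""

    normals: np.ndarray

    def __post_init__(self):
        self.normals = np.asarray(self.normals, dtype=np.float64)

    def validate(self, mask: RegionMask, tol: float = 1e-6) -> None:
        n = self.normals[mask.inside]
        norms = np.linalg.norm(n, axis=1)
        if np.max(np.abs(norms - 1.0)) > tol:
            raise ValidationError("normals are not unit length inside the mask")
        if n[:, 2].min() <= 0:
            raise ValidationError("normals must be front-facing inside the mask")


def estimate_light_direction(shading: ShadingMap, mask: RegionMask) -> LightDirection:
    """Dominant shading-gradient azimuth, 45-degree elevation.

    The azimuth is the orientation of the principal eigenvector of the
    structure tensor of inside-mask shading gradients; its sign is chosen
    so the mean gradient projection onto it is non-negative.  A constant
    shading map is degenerate: a warning is emitted and azimuth 0 returned.
    """
    gx, gy = _grid.forward_gradient(shading.values, mask.inside)
    m = mask.inside
    gx, gy = gx[m], gy[m]
    txx, txy, tyy = np.sum(gx * gx), np.sum(gx * gy), np.sum(gy * gy)
    if txx + tyy < 1e-24 * max(1, gx.size):
        warnings.warn("shading map has no variation; defaulting light azimuth to 0",
                      stacklevel=2)
        return LightDirection.from_azimuth(0.0)
    tensor = np.array([[txx, txy], [txy, tyy]])
    eigvals, eigvecs = np.linalg.eigh(tensor)
    principal = eigvecs[:, np.argmax(eigvals)]
    proj = gx * principal[0] + gy * principal[1]
    total = proj.sum()
    if total < 0:
        principal = -principal
    az = float(np.arctan2(principal[1], principal[0]))
    if total == 0 and az < 0:  # orientation only: canonicalise to [0, pi)
        az += np.pi
    return LightDirection.from_azimuth(az)


def _reflectance_log_gradient(reflectance: ReflectanceMap, mask: RegionMask):
    r = np.maximum(reflectance.values, 1e-6)
    log_r = np.log(r).mean(axis=2) if r.ndim == 3 else np.log(r)
    gx, gy = _grid.forward_gradient(log_r, mask.inside)
    return gx, gy, np.hypot(gx, gy)


def assemble_normal_system(shading: ShadingMap, reflectance: ReflectanceMap,
                           light: LightDirection, mask: RegionMask,
                           config: NormalConfig):
    """Build the sparse system over [nx | ny | nz] blocks of free normals."""
    s = np.array(shading.values, dtype=np.float64)
    m = mask.inside
    smax = s[m].max()
    if smax > 1.0:
        s = s / smax
    if s[m].max() > 1.0 + 1e-12:
        raise ValidationError("shading exceeds 1 after rescaling")

    idx, n = _grid.index_map(m)
    dx, dy, dz = light.vector
    rows_l, cols_l, vals_l, b_l = [], [], [], []
    row0 = 0

    # Lambertian data rows: dx*nx + dy*ny + dz*nz = S.
    pr, pc = np.nonzero(m)
    pv = idx[pr, pc]
    r = row0 + np.arange(pv.size)
    w = config.data_weight
    rows_l.extend([r, r, r])
    cols_l.extend([pv, n + pv, 2 * n + pv])
    vals_l.extend([np.full(pv.size, w * dx), np.full(pv.size, w * dy),
                   np.full(pv.size, w * dz)])
    b_l.append(w * s[pr, pc])
    row0 += pv.size
    n_data = pv.size

    # Smoothness rows: component differences vanish across 4-neighbours.
    w = config.smooth_weight
    n_smooth = 0
    if w > 0:
        for axis in ("x", "y"):
            ar, ac = _grid.forward_pairs(m, axis)
            if ar.size == 0:
                continue
            br = ar + (1 if axis == "y" else 0)
            bc = ac + (1 if axis == "x" else 0)
            av, bv = idx[ar, ac], idx[br, bc]
            for comp in range(3):
                r = row0 + np.arange(av.size)
                rows_l.extend([r, r])
                cols_l.extend([comp * n + bv, comp * n + av])
                vals_l.extend([np.full(av.size, w), np.full(av.size, -w)])
                b_l.append(np.zeros(av.size))
                row0 += av.size
                n_smooth += av.size

    # Edge rows: at strong reflectance edges the planar normal component is
    # orthogonal to the 90-degree-rotated reflectance gradient.
    n_edge = 0
    if config.edge_weight > 0:
        gx, gy, mag = _reflectance_log_gradient(reflectance, mask)
        c_thr = config.edge_threshold_c
        if c_thr is None:
            c_thr = float(np.percentile(mag[m], 90.0))
        strong = m & (mag > c_thr)
        er, ec = np.nonzero(strong)
        if er.size:
            ev = idx[er, ec]
            rot_x, rot_y = -gy[er, ec], gx[er, ec]  # Rot90 @ grad
            r = row0 + np.arange(ev.size)
            w = config.edge_weight
            rows_l.extend([r, r])
            cols_l.extend([ev, n + ev])
            vals_l.extend([w * rot_x, w * rot_y])
            b_l.append(np.zeros(ev.size))
            row0 += ev.size
            n_edge = ev.size

    # Weak flat prior: resolves the one-equation/three-unknowns ambiguity.
    w = config.flat_prior_weight
    if w > 0:
        for comp, target in ((0, 0.0), (1, 0.0), (2, 1.0)):
            r = row0 + np.arange(n)
            rows_l.append(r)
            cols_l.append(comp * n + np.arange(n))
            vals_l.append(np.full(n, w))
            b_l.append(np.full(n, w * target))
            row0 += n

    A = build_csr(rows_l, cols_l, vals_l, shape=(row0, 3 * n))
    b = np.concatenate(b_l)
    counts = {"data_rows": int(n_data), "smooth_rows": int(n_smooth),
              "edge_rows": int(n_edge), "n_vars": 3 * n}
    return A, b, idx, counts


def estimate_normals(shading: ShadingMap, reflectance: ReflectanceMap,
                     light: LightDirection, mask: RegionMask,
                     config: NormalConfig | None = None):
    """Recover a unit normal map from shading and reflectance.

    Solves the stacked least-squares system for free per-pixel 3-vectors,
    then clamps the z component to at least ``NZ_CLAMP`` and renormalises
    to unit length.

    Returns
    -------
    (NormalMap, dict)
        Normal map (outside-mask pixels are flat-up) and solver diagnostics.
    """
    config = config or NormalConfig()
    A, b, idx, counts = assemble_normal_system(shading, reflectance, light,
                                               mask, config)
    x, diag = solve_sparse_lsq(A, b, config.solver_tol, config.solver_max_iter)
    n = counts["n_vars"] // 3
    nx, ny, nz = x[:n], x[n : 2 * n], x[2 * n :]
    nz = np.maximum(nz, NZ_CLAMP)
    norm = np.sqrt(nx**2 + ny**2 + nz**2)
    nx, ny, nz = nx / norm, ny / norm, nz / norm
    # Re-impose the z floor on the unit vectors (normalisation can undo the
    # pre-normalisation clamp); shrink the planar part to stay unit length.
    low = nz < NZ_CLAMP
    if np.any(low):
        planar = np.hypot(nx[low], ny[low])
        shrink = np.sqrt(1.0 - NZ_CLAMP**2) / np.maximum(planar, 1e-300)
        nx[low] *= shrink
        ny[low] *= shrink
        nz[low] = NZ_CLAMP

    H, W = mask.inside.shape
    out = np.zeros((H, W, 3), dtype=np.float64)
    out[:, :, 2] = 1.0
    out[mask.inside, 0] = nx
    out[mask.inside, 1] = ny
    out[mask.inside, 2] = nz
    return NormalMap(out), dict(diag, **counts)
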