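"""Height-map reconstruction from a normal map.

Converts normals to a height-gradient field via grad H = -(Nx/Nz, Ny/Nz),
integrates the field over the region of interest by solving the
forward-difference equations in the least-squares sense with one border
pixel anchored at zero, and finally removes the best-fit plane so only
nonlinear relief remains.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _grid
from ._solve import build_csr, solve_sparse_lsq
from .errors import ValidationError
from .normals import NZ_CLAMP, NormalMap
from .raster_io import RegionMask


@dataclass
class GradientField:
    """Per-pixel height gradient (gx, gy); zero outside the mask."""

    gx: np.ndarray
    gy: np.ndarray

    def __post_init__(self):
        self.gx = np.asarray(self.gx, dtype=np.float64)
        self.gy = np.asarray(self.gy, dtype=np.float64)


@dataclass
class HeightMap:
    """Relative height field on the region of interest.

    ``anchor_index`` is the border pixel pinned to zero during integration;
    ``detrended`` records whether the best-fit plane has been removed.
    """

    values: np.ndarray
    anchor_index: tuple[int, int] | None = None
    detrended: bool = False

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)


def normals_to_gradient(normals: NormalMap, mask: RegionMask) -> GradientField:
    """gx = -Nx/Nz, gy = -Ny/Nz inside the mask; zeros outside."""
    n = normals.normals
    m = mask.inside
    nz = n[:, :, 2]
    if nz[m].min() < NZ_CLAMP * (1.0 - 1e-9):
        raise RuntimeError("normal z-component below clamp floor; upstream contract violated")
    gx = np.where(m, -n[:, :, 0] / nz, 0.0)
    gy = np.where(m, -n[:, :, 1] / nz, 0.0)
    return GradientField(gx, gy)


def integrate_height(grad: GradientField, mask: RegionMask,
                     solver_tol: float = 1e-13,
                     solver_max_iter: int = 20_000):
    """Least-squares integration of a gradient field over the mask.

    Solves H(x+1, y) - H(x, y) = gx and H(x, y+1) - H(x, y) = gy over all
    inside-mask forward neighbour pairs; the translation ambiguity is fixed
    by anchoring the first border pixel (row-major order) to exactly zero.
    Inconsistent (curl-bearing) fields yield the least-squares compromise
    surface; the residual is reported in the diagnostics.

    Returns
    -------
    (HeightMap, dict)
    """
    m = mask.inside
    idx, n = _grid.index_map(m)
    rows_l, cols_l, vals_l, b_l = [], [], [], []
    row0 = 0
    for axis, g in (("x", grad.gx), ("y", grad.gy)):
        ar, ac = _grid.forward_pairs(m, axis)
        if ar.size == 0:
            continue
        br = ar + (1 if axis == "y" else 0)
        bc = ac + (1 if axis == "x" else 0)
        av, bv = idx[ar, ac], idx[br, bc]
        r = row0 + np.arange(av.size)
        rows_l.extend([r, r])
        cols_l.extend([bv, av])
        vals_l.extend([np.ones(av.size), -np.ones(av.size)])
        b_l.append(g[ar, ac])
        row0 += av.size

    A = build_csr(rows_l, cols_l, vals_l, shape=(row0, n))
    b = np.concatenate(b_l)
    x, diag = solve_sparse_lsq(A, b, solver_tol, solver_max_iter)

    anchor = _grid.first_border_pixel(m)
    # Anchoring is exact: a global shift leaves all difference rows'
    # residuals unchanged, so the shifted solution is still optimal.
    x = x - x[idx[anchor]]

    values = np.zeros(m.shape, dtype=np.float64)
    values[m] = x
    return HeightMap(values, anchor_index=anchor, detrended=False), diag


def fit_plane(values: np.ndarray, mask: RegionMask) -> tuple[float, float, float]:
    """OLS plane a*x + b*y + c over inside-mask pixels; returns (a, b, c)."""
    m = mask.inside
    rows, cols = np.nonzero(m)
    design = np.column_stack([cols.astype(np.float64), rows.astype(np.float64),
                              np.ones(rows.size)])
    if np.linalg.matrix_rank(design) < 3:
        raise ValidationError("mask support is collinear; cannot fit a plane")
    coef, *_ = np.linalg.lstsq(design, values[m], rcond=None)
    return float(coef[0]), float(coef[1]), float(coef[2])


def detrend_plane(height: HeightMap, mask: RegionMask) -> HeightMap:
    """Subtract the best-fit plane over the region of interest.

    Compensates for the arbitrary 45-degree incident-light assumption: on
    average the surface becomes flat and only nonlinear relief remains.
    Idempotent.
    """
    a, b, c = fit_plane(height.values, mask)
    m = mask.inside
    rows, cols = np.nonzero(m)
    values = np.zeros_like(height.values)
    values[m] = height.values[m] - (a * cols + b * rows + c)
    return HeightMap(values, anchor_index=height.anchor_index, detrended=True)
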