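"""Pixel-grid bookkeeping shared by the sparse solvers.

Coordinate convention (used everywhere in the package): ``x`` is the column
index and increases to the right, ``y`` is the row index and increases
downward, ``z`` points toward the viewer.  Gradients are forward differences;
where the forward neighbour is unavailable (image edge or outside the mask)
the difference is zero (replicate boundary).
"""

from __future__ import annotations

import numpy as np


def index_map(mask: np.ndarray) -> tuple[np.ndarray, int]:
    """Assign one variable index to every inside-mask pixel.

    Returns an ``H x W`` int array (``-1`` outside the mask) and the number
    of variables.  Indices follow row-major scan order, so diagnostics that
    talk about "the first border pixel in row-major order" are reproducible.
    """
    mask = np.asarray(mask, dtype=bool)
    idx = np.full(mask.shape, -1, dtype=np.int64)
    n = int(mask.sum())
    idx[mask] = np.arange(n)
    return idx, n


def forward_pairs(mask: np.ndarray, axis: str) -> tuple[np.ndarray, np.ndarray]:
    """Row/column coordinates of base pixels whose forward neighbour along
    ``axis`` ('x' or 'y') is also inside the mask.

    Returns ``(rows, cols)`` of the base pixels; the neighbour is at
    ``(rows, cols + 1)`` for 'x' and ``(rows + 1, cols)`` for 'y'.
    """
    mask = np.asarray(mask, dtype=bool)
    if axis == "x":
        ok = mask[:, :-1] & mask[:, 1:]
        rows, cols = np.nonzero(ok)
    elif axis == "y":
        ok = mask[:-1, :] & mask[1:, :]
        rows, cols = np.nonzero(ok)
    else:  # pragma: no cover - internal misuse
        raise ValueError(f"axis must be 'x' or 'y', got {axis!r}")
    return rows, cols


def forward_gradient(field: np.ndarray, mask: np.ndarray | None = None):
    """Forward-difference gradient (gx, gy) with replicate boundary.

    If ``mask`` is given, differences across the mask boundary are zeroed
    (pairs straddling the boundary contribute nothing).
    """
    f = np.asarray(field, dtype=np.float64)
    gx = np.zeros_like(f)
    gy = np.zeros_like(f)
    gx[:, :-1] = f[:, 1:] - f[:, :-1]
    gy[:-1, :] = f[1:, :] - f[:-1, :]
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        okx = np.zeros_like(m)
        okx[:, :-1] = m[:, :-1] & m[:, 1:]
        oky = np.zeros_like(m)
        oky[:-1, :] = m[:-1, :] & m[1:, :]
        gx = np.where(okx, gx, 0.0)
        gy = np.where(oky, gy, 0.0)
    return gx, gy


def first_border_pixel(mask: np.ndarray) -> tuple[int, int]:
    """First inside pixel (row-major) that touches the boundary of the
    inside set: a 4-neighbour is outside the mask or off the image."""
    m = np.asarray(mask, dtype=bool)
    padded = np.pad(m, 1, constant_values=False)
    interior = (
        padded[:-2, 1:-1] & padded[2:, 1:-1] & padded[1:-1, :-2] & padded[1:-1, 2:]
    )
    border = m & ~interior
    rows, cols = np.nonzero(border)
    if rows.size == 0:  # pragma: no cover - impossible for a finite true set
        raise ValueError("mask has no border pixel")
    return int(rows[0]), int(cols[0])
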