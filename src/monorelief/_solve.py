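"""Sparse least-squares front end.

All three reconstruction stages reduce to overdetermined sparse linear
systems solved in the least-squares sense with an iterative Krylov method
(LSQR).  This wrapper normalises the convergence reporting.
"""

from __future__ import annotations

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import lsqr

from .errors import ConvergenceError


def solve_sparse_lsq(
    A: csr_matrix,
    b: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 10_000,
) -> tuple[np.ndarray, dict]:
    """Minimise ``||A x - b||_2`` with LSQR.

    Returns the solution and a diagnostics dict with the relative residual,
    iteration count and LSQR stop flag.  Raises :class:`ConvergenceError`
    if the iteration cap is hit before the tolerance is met.
    """
    b = np.asarray(b, dtype=np.float64)
    result = lsqr(A, b, atol=tol, btol=tol, conlim=1e14, iter_lim=max_iter)
    x, istop, itn, r1norm = result[0], result[1], result[2], result[3]
    bnorm = float(np.linalg.norm(b))
    rel = float(r1norm) / bnorm if bnorm > 0 else float(r1norm)
    diagnostics = {
        "residual": rel,
        "residual_abs": float(r1norm),
        "iterations": int(itn),
        "istop": int(istop),
        "n_rows": int(A.shape[0]),
        "n_vars": int(A.shape[1]),
    }
    if istop == 7:
        raise ConvergenceError(
            f"least-squares solver hit the iteration cap ({max_iter}) with "
            f"relative residual {rel:.3e} (tolerance {tol:.1e})",
            residual=rel,
            iterations=int(itn),
        )
    return x, diagnostics


def build_csr(
    rows: list[np.ndarray],
    cols: list[np.ndarray],
    vals: list[np.ndarray],
    shape: tuple[int, int],
) -> csr_matrix:
    """Concatenate COO triplet chunks into one CSR matrix."""
    r = np.concatenate([np.asarray(c, dtype=np.int64) for c in rows])
    c = np.concatenate([np.asarray(c, dtype=np.int64) for c in cols])
    v = np.concatenate([np.asarray(c, dtype=np.float64) for c in vals])
    return csr_matrix((v, (r, c)), shape=shape)
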