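"""Batched matrix-exponential propagation for stacks of small generators."""

from __future__ import annotations

import numpy as np
import scipy.linalg


def expm_multiply_stack(Ls: np.ndarray, t: float, v: np.ndarray) -> np.ndarray:
    """Compute ``expm(L * t) @ v`` for every L in a stack.

    Uses one batched eigendecomposition (the generators encountered here are
    generically diagonalizable); falls back to a per-matrix Pade matrix
    exponential if the eigenvector matrix is singular or the result is not
    finite.

    Parameters
    ----------
    Ls : (m, n, n) real array
    t : float
    v : (n,) real start vector, shared by all matrices.

    Returns
    -------
    (m, n) real array.
    """
    Ls = np.asarray(Ls, dtype=float)
    m, n = Ls.shape[0], Ls.shape[-1]
    try:
        w, V = np.linalg.eig(Ls)
        b = np.broadcast_to(v.astype(complex)[:, None], (m, n, 1))
        c = np.linalg.solve(V, b)[..., 0]
        out = np.einsum("mij,mj->mi", V, np.exp(w * t) * c).real
        if np.all(np.isfinite(out)):
            return out
    except np.linalg.LinAlgError:
        pass
    out = np.empty((m, n))
    for k in range(m):
        out[k] = scipy.linalg.expm(Ls[k] * t) @ v
    return out
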