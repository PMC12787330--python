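"""Independent reference CP-ALS used as a cross-check oracle.

Deliberately written through a different route than the package solver:
explicit Khatri-Rao design matrices assembled column by column with
Kronecker products, unfoldings built by index loops, and unregularized
``np.linalg.lstsq`` solves.  Initialization matches the package convention
(uniform(0,1) entries from ``numpy.random.default_rng(seed)``) so that both
solvers follow the same trajectory and their final errors are directly
comparable.
"""

from __future__ import annotations

import numpy as np


def unfold_mode0(x: np.ndarray) -> np.ndarray:
    i_dim, j_dim, k_dim = x.shape
    out = np.empty((i_dim, j_dim * k_dim))
    for k in range(k_dim):
        for j in range(j_dim):
            out[:, k * j_dim + j] = x[:, j, k]
    return out


def unfold_mode1(x: np.ndarray) -> np.ndarray:
    i_dim, j_dim, k_dim = x.shape
    out = np.empty((j_dim, i_dim * k_dim))
    for k in range(k_dim):
        for i in range(i_dim):
            out[:, k * i_dim + i] = x[i, :, k]
    return out


def unfold_mode2(x: np.ndarray) -> np.ndarray:
    i_dim, j_dim, k_dim = x.shape
    out = np.empty((k_dim, i_dim * j_dim))
    for j in range(j_dim):
        for i in range(i_dim):
            out[:, j * i_dim + i] = x[i, j, :]
    return out


def khatri_rao(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Column-wise Kronecker product (u o v), columns kron(u_r, v_r)."""
    rank = u.shape[1]
    out = np.empty((u.shape[0] * v.shape[0], rank))
    for r in range(rank):
        out[:, r] = np.kron(u[:, r], v[:, r])
    return out


def full_tensor(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> np.ndarray:
    x = np.zeros((a.shape[0], b.shape[0], c.shape[0]))
    for r in range(a.shape[1]):
        x += np.einsum("i,j,k->ijk", a[:, r], b[:, r], c[:, r])
    return x


def reference_cp_als(
    x: np.ndarray, rank: int, seed: int, tol: float = 1e-7, max_iter: int = 500
) -> tuple[float, int]:
    """Plain ALS with lstsq solves; returns (relative error, iterations)."""
    i_dim, j_dim, k_dim = x.shape
    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(i_dim, rank))
    b = rng.uniform(size=(j_dim, rank))
    c = rng.uniform(size=(k_dim, rank))
    norm_x = np.linalg.norm(x)
    x0, x1, x2 = unfold_mode0(x), unfold_mode1(x), unfold_mode2(x)
    prev = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        a = np.linalg.lstsq(khatri_rao(c, b), x0.T, rcond=None)[0].T
        b = np.linalg.lstsq(khatri_rao(c, a), x1.T, rcond=None)[0].T
        c = np.linalg.lstsq(khatri_rao(b, a), x2.T, rcond=None)[0].T
        err = np.linalg.norm(x - full_tensor(a, b, c)) / norm_x
        if abs(prev - err) < tol:
            break
        prev = err
    return float(err), n_iter
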