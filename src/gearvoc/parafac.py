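"""Canonical polyadic (CP/PARAFAC) decomposition by alternating least squares.

The three-way tensor X (time x sensor x gear) is modelled as a sum of R
rank-one components

    X_ijk  ~=  sum_r  w_r * A_ir * B_jr * C_kr  +  E_ijk

with unit-Euclidean-norm factor columns and all scale absorbed into the
nonnegative weight vector w.  ALS cyclically solves the linear least-squares
problem for one factor matrix with the other two fixed; the normal equations
use the Hadamard-product Gram identity (Z^T Z = (B^T B) * (C^T C) for the
Khatri-Rao design Z), with a tiny ridge guarding rank-deficient iterates.

Model adequacy is measured by the cumulative explained variance

    VEC = 100 * (1 - ||X - Xhat||_F^2 / ||X||_F^2)

and the working rank is chosen at the elbow of the mean VEC-versus-rank
curve over many random initializations.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import DataTensor

__all__ = [
    "CPModel",
    "VECCurve",
    "cp_als",
    "reconstruct",
    "vec",
    "sweep_schedule",
    "rank_sweep",
    "select_rank_elbow",
    "save_model",
    "load_model",
]

logger = logging.getLogger(__name__)

RIDGE = 1e-12
UNIT_NORM_TOL = 1e-8


@dataclass
class CPModel:
    """One fitted CP decomposition with normalized factors."""

    rank: int
    weights: np.ndarray  # [R], nonnegative
    A: np.ndarray  # time factors [I x R], unit-norm columns
    B: np.ndarray  # channel factors [J x R]
    C: np.ndarray  # gear factors [K x R]
    seed: int
    n_iterations: int
    converged: bool
    relative_error: float
    gear_labels: list[str] | None = None
    error_history: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        for name, m in (("A", self.A), ("B", self.B), ("C", self.C)):
            norms = np.linalg.norm(m, axis=0)
            live = self.weights > 0
            if np.any(np.abs(norms[live] - 1.0) > UNIT_NORM_TOL):
                raise ValueError(f"columns of {name} are not unit-norm")
        if np.any(self.weights < 0):
            raise ValueError("weights must be nonnegative")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.A.shape[0], self.B.shape[0], self.C.shape[0]


@dataclass
class VECCurve:
    """Explained-variance curve of a multi-seed rank sweep (percent)."""

    ranks: np.ndarray  # [n_ranks]
    per_seed_vec: np.ndarray  # [n_ranks x n_seeds]
    mean_vec: np.ndarray  # [n_ranks]

    def __post_init__(self) -> None:
        self.ranks = np.asarray(self.ranks, dtype=int)
        self.per_seed_vec = np.asarray(self.per_seed_vec, dtype=float)
        self.mean_vec = np.asarray(self.mean_vec, dtype=float)
        if not np.allclose(self.mean_vec, self.per_seed_vec.mean(axis=1)):
            raise ValueError("mean_vec must be the row mean of per_seed_vec")
        if np.any(self.per_seed_vec > 100.0 + 1e-9):
            raise ValueError("VEC cannot exceed 100%")


def _as_array(x: DataTensor | np.ndarray) -> np.ndarray:
    return x.values if isinstance(x, DataTensor) else np.asarray(x, dtype=float)


def cp_als(
    x: DataTensor | np.ndarray,
    rank: int,
    seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> CPModel:
    """Fit a rank-``rank`` CP model by ALS from a seeded uniform(0,1) init.

    Stops when the change in relative reconstruction error between sweeps
    falls below ``tol`` or after ``max_iter`` sweeps.  The reconstruction
    error is non-increasing across sweeps (a property of exact ALS updates;
    the 1e-12 ridge perturbs it below measurement precision).
    """
    values = _as_array(x)
    if values.ndim != 3:
        raise ValueError("CP-ALS expects a three-way tensor")
    i_dim, j_dim, k_dim = values.shape
    max_rank = min(i_dim * j_dim, i_dim * k_dim, j_dim * k_dim)
    if rank < 1 or rank > max_rank:
        raise ValueError(f"rank must be in [1, {max_rank}] for shape {values.shape}")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    rng = np.random.default_rng(seed)
    a = rng.uniform(size=(i_dim, rank))
    b = rng.uniform(size=(j_dim, rank))
    c = rng.uniform(size=(k_dim, rank))

    norm_x_sq = float(np.sum(values**2))
    if norm_x_sq == 0:
        raise ValueError("cannot decompose the zero tensor")

    def solve(mttkrp: np.ndarray, g1: np.ndarray, g2: np.ndarray) -> np.ndarray:
        gram = (g1.T @ g1) * (g2.T @ g2)
        try:
            return np.linalg.solve(gram + RIDGE * np.eye(rank), mttkrp.T).T
        except np.linalg.LinAlgError:  # pragma: no cover - ridge makes this rare
            logger.warning("singular normal equations; escalating ridge")
            return np.linalg.solve(gram + 1e-6 * np.eye(rank), mttkrp.T).T

    errors: list[float] = []
    prev_err = np.inf
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        a = solve(np.einsum("ijk,jr,kr->ir", values, b, c, optimize=True), b, c)
        b = solve(np.einsum("ijk,ir,kr->jr", values, a, c, optimize=True), a, c)
        m2 = np.einsum("ijk,ir,jr->kr", values, a, b, optimize=True)
        c = solve(m2, a, b)
        # error via Gram identities: ||X - Xhat||^2 = ||X||^2 - 2<X,Xhat> + ||Xhat||^2
        inner = float(np.sum(m2 * c))
        norm_hat_sq = float(np.sum((a.T @ a) * (b.T @ b) * (c.T @ c)))
        err = float(np.sqrt(max(norm_x_sq - 2.0 * inner + norm_hat_sq, 0.0)) / np.sqrt(norm_x_sq))
        errors.append(err)
        if abs(prev_err - err) < tol:
            converged = True
            break
        prev_err = err

    # normalize columns, absorb scale into weights
    weights = np.ones(rank)
    factors = []
    for m in (a, b, c):
        norms = np.linalg.norm(m, axis=0)
        weights *= norms
        safe = np.where(norms > 0, norms, 1.0)
        factors.append(m / safe)
    a, b, c = factors

    # sign convention: flip A and B columns positive at their largest-magnitude
    # entry, compensate in C so the reconstruction is unchanged
    s_a = np.sign(a[np.abs(a).argmax(axis=0), np.arange(rank)])
    s_b = np.sign(b[np.abs(b).argmax(axis=0), np.arange(rank)])
    s_a[s_a == 0] = 1.0
    s_b[s_b == 0] = 1.0
    a *= s_a
    b *= s_b
    c *= s_a * s_b

    return CPModel(
        rank=rank,
        weights=weights,
        A=a,
        B=b,
        C=c,
        seed=seed,
        n_iterations=n_iter,
        converged=converged,
        relative_error=errors[-1],
        gear_labels=list(x.gear_labels) if isinstance(x, DataTensor) else None,
        error_history=np.asarray(errors),
    )


def reconstruct(model: CPModel) -> np.ndarray:
    """Dense reconstruction Xhat_ijk = sum_r w_r A_ir B_jr C_kr."""
    return np.einsum(
        "r,ir,jr,kr->ijk", model.weights, model.A, model.B, model.C, optimize=True
    )


def vec(x: DataTensor | np.ndarray, model: CPModel) -> float:
    """Cumulative explained variance, percent.  Not clamped: a model worse
    than the zero model yields a negative value."""
    values = _as_array(x)
    if values.shape != model.shape:
        raise ValueError(f"tensor shape {values.shape} != model shape {model.shape}")
    denom = float(np.sum(values**2))
    if denom == 0:
        raise ZeroDivisionError("VEC is undefined for the zero tensor")
    resid = float(np.sum((values - reconstruct(model)) ** 2))
    return 100.0 * (1.0 - resid / denom)


def sweep_schedule(
    ranks: list[int] | np.ndarray, n_seeds: int, base_seed: int = 0
) -> list[tuple[int, int]]:
    """The (rank, seed) grid of a sweep: every rank fitted from ``n_seeds``
    seeded initializations, seeds shared across ranks."""
    ranks = list(ranks)
    if not ranks or n_seeds < 1:
        raise ValueError("need at least one rank and one seed")
    return [(int(r), base_seed + s) for r in ranks for s in range(n_seeds)]


def rank_sweep(
    x: DataTensor | np.ndarray,
    ranks: list[int] | np.ndarray,
    n_seeds: int = 100,
    base_seed: int = 0,
    tol: float = 1e-7,
    max_iter: int = 500,
) -> tuple[VECCurve, list[CPModel]]:
    """Fit every (rank, seed) pair of the sweep and collect the VEC curve."""
    schedule = sweep_schedule(ranks, n_seeds, base_seed)
    ranks = sorted(set(r for r, _ in schedule))
    models = [cp_als(x, rank=r, seed=s, tol=tol, max_iter=max_iter) for r, s in schedule]
    per_seed = np.empty((len(ranks), n_seeds))
    for idx, model in enumerate(models):
        ri, si = divmod(idx, n_seeds)
        per_seed[ri, si] = vec(x, model)
    curve = VECCurve(
        ranks=np.asarray(ranks), per_seed_vec=per_seed, mean_vec=per_seed.mean(axis=1)
    )
    return curve, models


def select_rank_elbow(
    curve: VECCurve, default_rank: int = 10, linear_tol: float = 1e-6
) -> int:
    """Elbow of the mean VEC curve by maximum distance to the chord joining
    its endpoints, computed on the [0,1]-normalized curve.  A curve within
    ``linear_tol`` of linear has no elbow; the default rank is returned."""
    if len(curve.ranks) < 3:
        raise ValueError("elbow selection needs at least 3 ranks")
    x = curve.ranks.astype(float)
    y = curve.mean_vec.astype(float)
    x_span = x[-1] - x[0]
    y_span = y[-1] - y[0]
    if x_span == 0 or abs(y_span) < 1e-15:
        logger.info("flat VEC curve; falling back to default rank %d", default_rank)
        return int(default_rank)
    xn = (x - x[0]) / x_span
    yn = (y - y[0]) / y_span
    dist = np.abs(yn - xn) / np.sqrt(2.0)  # distance to the (0,0)-(1,1) chord
    if dist.max() < linear_tol:
        logger.info("VEC curve is linear; falling back to default rank %d", default_rank)
        return int(default_rank)
    return int(curve.ranks[int(np.argmax(dist))])


def save_model(model: CPModel, directory: str | Path) -> None:
    """Persist a model as delimited text matrices plus JSON metadata."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    cols = [f"r{r}" for r in range(model.rank)]
    for name, m in (("A", model.A), ("B", model.B), ("C", model.C)):
        pd.DataFrame(m, columns=cols).to_csv(directory / f"{name}.csv", index=False)
    pd.DataFrame({"weight": model.weights}).to_csv(
        directory / "weights.csv", index=False
    )
    meta = {
        "rank": model.rank,
        "seed": model.seed,
        "n_iterations": model.n_iterations,
        "converged": model.converged,
        "relative_error": model.relative_error,
        "gear_labels": model.gear_labels,
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def load_model(directory: str | Path) -> CPModel:
    directory = Path(directory)
    meta = json.loads((directory / "meta.json").read_text())
    mats = {
        name: pd.read_csv(directory / f"{name}.csv").to_numpy(dtype=float)
        for name in ("A", "B", "C")
    }
    weights = pd.read_csv(directory / "weights.csv")["weight"].to_numpy(dtype=float)
    return CPModel(
        rank=meta["rank"],
        weights=weights,
        A=mats["A"],
        B=mats["B"],
        C=mats["C"],
        seed=meta["seed"],
        n_iterations=meta["n_iterations"],
        converged=meta["converged"],
        relative_error=meta["relative_error"],
        gear_labels=meta.get("gear_labels"),
        error_history=None,
    )
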