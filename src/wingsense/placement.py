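"""Sparse sensor placement optimisation for classification (SSPOC).

Given first-spike latency matrices for two motion classes, find a small set
of grid nodes whose readings best separate the classes:

1. standardise the pooled training matrix per node;
2. compute an m-dimensional PCA basis Psi of the standardised data;
3. find the Fisher discriminant direction w between the classes in that
   subspace;
4. solve the elastic-net constrained program

       s = argmin_{s'}  lam * ||s'||_1 + (1 - lam) * ||s'||_2^2
           subject to   Psi^T s' = w,

   whose solution concentrates weight on few nodes;
5. keep the n_sensors largest-magnitude entries of s.

The constrained program is solved through its Lagrangian dual: minimising
over s' for fixed multipliers nu separates per coordinate into a
soft-threshold map, leaving a smooth convex m-dimensional dual
    h(nu) = nu^T w + sum_i soft(|(Psi nu)_i|, lam)^2 / (4 (1 - lam)),
minimised by a semismooth Newton iteration (BFGS fallback).  At the dual
optimum the primal reconstruction Psi^T s = w holds to solver tolerance.
The lam = 1 boundary (pure L1) is a linear program and is delegated to
scipy's HiGHS solver.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog, minimize
from sklearn.decomposition import PCA

__all__ = [
    "SSPOCParams", "Standardizer", "SensorSet", "DegenerateClassesError",
    "OptimizationFailedError", "standardize", "pca_basis", "lda_direction",
    "elastic_net_sensors", "select_top_k", "sspoc",
]


class DegenerateClassesError(ValueError):
    """Raised when the two classes cannot define a discriminant direction."""


class OptimizationFailedError(RuntimeError):
    """Raised when the elastic-net program cannot be solved to tolerance."""


@dataclass(frozen=True)
class SSPOCParams:
    """Optimisation hyper-parameters."""

    n_basis: int = 3          # PCA subspace dimension m
    lam: float = 0.9          # L1/L2 mixing weight lambda
    n_sensors: int = 10
    train_frac: float = 0.9
    n_iterations: int = 20
    seed: int = 0
    ridge: float = 1e-6       # trace-scaled ridge on the within-class scatter

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")
        if self.n_basis < 1:
            raise ValueError("n_basis must be at least 1")
        if self.n_sensors < 1:
            raise ValueError("n_sensors must be at least 1")
        if not 0.0 < self.train_frac < 1.0:
            raise ValueError("train_frac must lie in (0, 1)")


@dataclass(frozen=True)
class Standardizer:
    """Per-node affine transform fitted on training data."""

    mean: np.ndarray
    scale: np.ndarray          # standard deviation; zero marks constant nodes

    def transform(self, X: np.ndarray) -> np.ndarray:
        safe = np.where(self.scale > 0, self.scale, 1.0)
        Z = (np.asarray(X, dtype=float) - self.mean) / safe
        Z[:, self.scale == 0] = 0.0
        return Z


@dataclass
class SensorSet:
    """Optimised sensor weights and the selected node subset."""

    weights: np.ndarray        # full per-node weight vector s
    selected: np.ndarray       # indices of the top |s| nodes, |s| descending
    locations: np.ndarray | None = None   # (k, 2) (x, y) coordinates, metres
    params: SSPOCParams | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def n_sensors(self) -> int:
        return len(self.selected)


# ---------------------------------------------------------------------------

def standardize(X: np.ndarray) -> tuple[np.ndarray, Standardizer]:
    """Zero-mean, unit-variance per node on the training matrix.

    Constant (zero-variance) nodes — e.g. sensors that never spike in any
    trial — map to zero rather than being dropped, keeping node indexing
    stable across conditions.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two trials to standardize")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    # nodes constant up to rounding noise count as degenerate
    scale[scale <= 1e-12 * (1.0 + np.abs(mean))] = 0.0
    tf = Standardizer(mean=mean, scale=scale)
    return tf.transform(X), tf


def pca_basis(Z: np.ndarray, n_basis: int) -> np.ndarray:
    """Orthonormal basis of the top principal directions (nodes x n_basis).

    Columns are ordered by explained variance with a deterministic sign
    convention (the largest-magnitude loading of each column is positive).
    If the data have fewer effective dimensions than requested the basis is
    truncated with a warning.
    """
    Z = np.asarray(Z, dtype=float)
    max_rank = min(Z.shape[0] - 1, Z.shape[1])
    if n_basis > max_rank:
        raise ValueError(f"n_basis={n_basis} exceeds max rank {max_rank}")
    pca = PCA(n_components=n_basis, svd_solver="full")
    pca.fit(Z)
    keep = pca.explained_variance_ > max(1e-12 * pca.explained_variance_[0], 0.0)
    if keep.sum() < n_basis:
        warnings.warn(
            f"data support only {int(keep.sum())} of {n_basis} requested "
            "basis directions; basis truncated"
        )
    Psi = pca.components_[keep].T.copy()
    for j in range(Psi.shape[1]):
        i = np.argmax(np.abs(Psi[:, j]))
        if Psi[i, j] < 0:
            Psi[:, j] = -Psi[:, j]
    return Psi


def lda_direction(P: np.ndarray, labels: np.ndarray,
                  ridge: float = 1e-6) -> np.ndarray:
    """Two-class Fisher discriminant direction, unit norm.

    ``labels`` is boolean with True marking the rotation class; the returned
    direction is oriented so the rotation class projects positive.  The
    within-class scatter is regularised with ``ridge`` times its mean
    diagonal to stay invertible in small subspaces.
    """
    P = np.asarray(P, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if P.ndim != 2:
        raise ValueError("projected data must be 2-D")
    n1, n0 = labels.sum(), (~labels).sum()
    if n0 < 2 or n1 < 2:
        raise DegenerateClassesError("each class needs at least two trials")
    mu0 = P[~labels].mean(axis=0)
    mu1 = P[labels].mean(axis=0)
    diff = mu1 - mu0
    if not np.any(np.abs(diff) > 0):
        raise DegenerateClassesError("identical class means: no discriminant direction")
    d = P.shape[1]
    Sw = np.zeros((d, d))
    for mask, mu in ((~labels, mu0), (labels, mu1)):
        R = P[mask] - mu
        Sw += R.T @ R
    Sw += ridge * (np.trace(Sw) / d + 1.0e-300) * np.eye(d)
    if np.trace(Sw) == 0:
        Sw = np.eye(d)
    w = np.linalg.solve(Sw, diff)
    w /= np.linalg.norm(w)
    if diff @ w < 0:
        w = -w
    return w


# ---------------------------------------------------------------------------
# elastic net
# ---------------------------------------------------------------------------

def _soft(a: np.ndarray, lam: float) -> np.ndarray:
    return np.sign(a) * np.maximum(np.abs(a) - lam, 0.0)


def _dual_primal(nu: np.ndarray, Psi: np.ndarray, lam: float) -> np.ndarray:
    gamma = 1.0 - lam
    return -_soft(Psi @ nu, lam) / (2.0 * gamma)


def elastic_net_sensors(Psi: np.ndarray, w: np.ndarray, lam: float = 0.9,
                        tol: float = 1e-8) -> np.ndarray:
    """Solve  min lam ||s||_1 + (1 - lam) ||s||_2^2  s.t.  Psi^T s = w.

    ``Psi`` is (n_nodes x m) with full column rank, ``w`` is (m,).  The
    feasibility residual of the returned solution satisfies
    ||Psi^T s - w||_inf <= tol * max(1, ||w||_inf).
    """
    Psi = np.asarray(Psi, dtype=float)
    w = np.asarray(w, dtype=float).ravel()
    n, m = Psi.shape
    if w.size != m:
        raise ValueError("w length must match the basis dimension")
    scale = max(1.0, np.abs(w).max())

    if lam >= 1.0 - 1e-12:
        s = _l1_linprog(Psi, w)
    else:
        s = _dual_solve(Psi, w, lam, tol * scale)

    resid = np.abs(Psi.T @ s - w).max()
    if resid > max(tol * scale, 1e-6):
        raise OptimizationFailedError(
            f"elastic-net feasibility residual {resid:.3g} exceeds tolerance"
        )
    return s


def _dual_solve(Psi, w, lam, atol):
    gamma = 1.0 - lam

    def h_and_grad(nu):
        a = Psi @ nu
        u = _soft(a, lam)
        h = nu @ w + (u @ u) / (4.0 * gamma)
        s = -u / (2.0 * gamma)
        return h, w - Psi.T @ s

    # start from the lam=0 (least-norm) multipliers
    G = Psi.T @ Psi
    nu = -2.0 * gamma * np.linalg.solve(G, w)

    # semismooth Newton with backtracking on the dual
    for _ in range(100):
        h, grad = h_and_grad(nu)
        if np.abs(grad).max() <= atol:
            return _dual_primal(nu, Psi, lam)
        a = Psi @ nu
        active = np.abs(a) > lam
        H = (Psi[active].T @ Psi[active]) / (2.0 * gamma)
        H += 1e-12 * np.eye(len(nu))
        try:
            step = -np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            step = -grad
        t = 1.0
        for _ in range(60):
            h_new, _ = h_and_grad(nu + t * step)
            if h_new <= h + 1e-4 * t * (grad @ step):
                break
            t *= 0.5
        nu = nu + t * step

    # fall back to quasi-Newton if the Newton loop stalls
    res = minimize(h_and_grad, nu, jac=True, method="BFGS",
                   options={"gtol": atol / 10.0, "maxiter": 2000})
    if np.abs(res.jac).max() > atol:
        raise OptimizationFailedError(
            f"dual solver stalled (residual {np.abs(res.jac).max():.3g})"
        )
    return _dual_primal(res.x, Psi, lam)


def _l1_linprog(Psi, w):
    """Pure-L1 boundary case as an LP: split s = p - q, p, q >= 0."""
    n, m = Psi.shape
    A_eq = np.hstack([Psi.T, -Psi.T])
    res = linprog(c=np.ones(2 * n), A_eq=A_eq, b_eq=w,
                  bounds=[(0, None)] * (2 * n), method="highs")
    if not res.success:
        raise OptimizationFailedError(f"L1 linear program failed: {res.message}")
    return res.x[:n] - res.x[n:]


# ---------------------------------------------------------------------------

def select_top_k(s: np.ndarray, n_sensors: int,
                 locations: np.ndarray | None = None,
                 params: SSPOCParams | None = None) -> SensorSet:
    """Keep the ``n_sensors`` largest-magnitude weights.

    Ties break deterministically toward the lower node index.  An all-zero
    weight vector selects the first ``n_sensors`` nodes with a warning.
    """
    s = np.asarray(s, dtype=float).ravel()
    if s.size < n_sensors:
        raise ValueError("fewer weights than requested sensors")
    if not np.any(s != 0):
        warnings.warn("all sensor weights are zero; selection is degenerate")
    order = np.lexsort((np.arange(s.size), -np.abs(s)))
    sel = order[:n_sensors]
    loc = locations[sel] if locations is not None else None
    return SensorSet(weights=s, selected=sel, locations=loc, params=params)


def sspoc(train_flap: np.ndarray, train_rot: np.ndarray,
          params: SSPOCParams | None = None,
          locations: np.ndarray | None = None) -> SensorSet:
    """Full placement optimisation from per-class training matrices.

    ``train_flap`` and ``train_rot`` are (trials x nodes) first-spike
    matrices of the two classes.  Standardisation and the PCA basis use the
    pooled training data.
    """
    params = params or SSPOCParams()
    X = np.vstack([train_flap, train_rot])
    labels = np.concatenate([
        np.zeros(len(train_flap), dtype=bool),
        np.ones(len(train_rot), dtype=bool),
    ])
    Z, tf = standardize(X)
    Psi = pca_basis(Z, params.n_basis)
    P = Z @ Psi
    w = lda_direction(P, labels, ridge=params.ridge)
    s = elastic_net_sensors(Psi, w, lam=params.lam)
    out = select_top_k(s, params.n_sensors, locations=locations, params=params)
    out.provenance = {"standardizer": tf, "basis": Psi, "w": w}
    return out
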