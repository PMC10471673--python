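"""Uniform finite-difference grids, discrete Laplacians and eigenvalue helpers.

Supports intervals and rectangles.  Dirichlet grids eliminate the boundary
nodes; Neumann grids use cell-centred nodes, whose reflecting ghost-cell
closure keeps the Laplacian matrix symmetric while every row still sums to
zero.  Both closures are second-order accurate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import scipy.sparse as sp
from scipy.linalg import eigh
from scipy.sparse.linalg import eigsh

__all__ = [
    "DIRICHLET",
    "NEUMANN",
    "SpaceGrid",
    "AgeGrid",
    "Grids",
    "make_space_grid",
    "make_age_grid",
    "laplacian_matrix",
    "laplacian_eigenpairs",
    "principal_eigenvalue",
    "principal_eigenpair",
]

DIRICHLET = 0
NEUMANN = 1

_DENSE_LIMIT = 2000  # dense eigensolver below, shift-invert Lanczos above


@dataclass(frozen=True)
class SpaceGrid:
    """Uniform grid on an interval [0, L] or rectangle [0, L1] x [0, L2].

    ``shape`` holds the number of active (degree-of-freedom) nodes per axis:
    Dirichlet axes store only interior nodes, Neumann axes store cell centres.
    """

    lengths: tuple[float, ...]
    shape: tuple[int, ...]
    dx: tuple[float, ...]
    delta: int

    @property
    def dimension(self) -> int:
        return len(self.lengths)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.shape))

    @property
    def weight(self) -> float:
        """Quadrature weight of one node (cell volume)."""
        return float(np.prod(self.dx))

    def axis_coords(self, axis: int = 0) -> np.ndarray:
        L, n, h = self.lengths[axis], self.shape[axis], self.dx[axis]
        if self.delta == NEUMANN:
            return (np.arange(n) + 0.5) * h
        return (np.arange(n) + 1.0) * h

    @property
    def coords(self) -> np.ndarray:
        """Node coordinates: shape (N,) in 1D, (N, 2) in 2D (row-major)."""
        if self.dimension == 1:
            return self.axis_coords(0)
        X, Y = np.meshgrid(self.axis_coords(0), self.axis_coords(1), indexing="ij")
        return np.column_stack([X.ravel(), Y.ravel()])

    def inner(self, u: np.ndarray, v: np.ndarray) -> float:
        """Grid approximation of the L2(Omega) inner product."""
        return self.weight * float(np.dot(np.conj(u), v).real)

    def norm(self, u: np.ndarray) -> float:
        return float(np.sqrt(self.weight) * np.linalg.norm(u))


@dataclass(frozen=True)
class AgeGrid:
    """Uniform age grid 0 = a_0 < ... < a_K = a_m."""

    a_m: float
    n_intervals: int

    def __post_init__(self) -> None:
        if self.a_m <= 0 or not np.isfinite(self.a_m):
            raise ValueError("a_m must be positive and finite")
        if self.n_intervals < 2:
            raise ValueError("age grid needs at least 3 nodes (2 intervals)")

    @property
    def da(self) -> float:
        return self.a_m / self.n_intervals

    @property
    def nodes(self) -> np.ndarray:
        return np.linspace(0.0, self.a_m, self.n_intervals + 1)

    @property
    def trapezoid_weights(self) -> np.ndarray:
        w = np.full(self.n_intervals + 1, self.da)
        w[0] = w[-1] = 0.5 * self.da
        return w

    def index_of(self, a: float, tol: float = 1e-9) -> int:
        """Node index of age ``a``; raises if ``a`` is off-grid."""
        k = int(round(a / self.da))
        if k < 0 or k > self.n_intervals or abs(a - k * self.da) > tol * max(1.0, self.a_m):
            raise ValueError(f"age {a} is not a grid node (da={self.da})")
        return k


class Grids(NamedTuple):
    """Bundle of the two discretization axes used throughout the package."""

    age: AgeGrid
    space: SpaceGrid


def make_space_grid(domain, n, delta: int) -> SpaceGrid:
    """Build a grid with ``n`` cells per axis on the given domain.

    ``domain`` is a length (interval) or tuple of lengths (rectangle).
    Neumann grids have ``n`` nodes per axis, Dirichlet grids ``n - 1``.
    """
    if delta not in (DIRICHLET, NEUMANN):
        raise ValueError("delta must be 0 (Dirichlet) or 1 (Neumann)")
    lengths = tuple(float(L) for L in (np.atleast_1d(domain)))
    if len(lengths) > 2:
        raise ValueError("only intervals and rectangles are supported")
    ns = tuple(int(v) for v in np.broadcast_to(np.atleast_1d(n), (len(lengths),)))
    if any(L <= 0 for L in lengths):
        raise ValueError("domain lengths must be positive")
    shape, dxs = [], []
    for L, ni in zip(lengths, ns):
        if ni < 3:
            raise ValueError("need at least 3 cells per axis")
        h = L / ni
        shape.append(ni if delta == NEUMANN else ni - 1)
        dxs.append(h)
    return SpaceGrid(lengths=lengths, shape=tuple(shape), dx=tuple(dxs), delta=delta)


def make_age_grid(a_m: float, n_intervals: int) -> AgeGrid:
    return AgeGrid(a_m=float(a_m), n_intervals=int(n_intervals))


def _laplacian_1d(n: int, h: float, delta: int) -> sp.csr_matrix:
    if n < 3:
        raise ValueError("fewer than 3 nodes")
    main = np.full(n, -2.0)
    off = np.ones(n - 1)
    if delta == NEUMANN:
        # reflecting ghost cell: flux through the wall vanishes
        main[0] = main[-1] = -1.0
    A = sp.diags([off, main, off], [-1, 0, 1], format="csr")
    return (A / h**2).tocsr()


def laplacian_matrix(grid: SpaceGrid) -> sp.csr_matrix:
    """Second-order discrete Laplacian with the grid's boundary closure.

    The matrix is symmetric; ``-L`` is positive semidefinite (Neumann, with
    the constant vector in its kernel) or positive definite (Dirichlet).
    """
    if grid.dimension == 1:
        return _laplacian_1d(grid.shape[0], grid.dx[0], grid.delta)
    Lx = _laplacian_1d(grid.shape[0], grid.dx[0], grid.delta)
    Ly = _laplacian_1d(grid.shape[1], grid.dx[1], grid.delta)
    Ix = sp.identity(grid.shape[0], format="csr")
    Iy = sp.identity(grid.shape[1], format="csr")
    return (sp.kron(Lx, Iy) + sp.kron(Ix, Ly)).tocsr()


def laplacian_eigenpairs(grid: SpaceGrid, count: int):
    """Eigenvalues 0 <= mu_0 <= mu_1 <= ... of -Laplacian and eigenvectors.

    Eigenvectors are orthonormal in the grid inner product (cell-volume
    weighted), approximating L2(Omega)-normalized eigenfunctions.
    """
    N = grid.n_nodes
    if count > N:
        raise ValueError(f"requested {count} eigenpairs but grid has {N} nodes")
    A = -laplacian_matrix(grid)
    if N <= _DENSE_LIMIT:
        vals, vecs = eigh(A.toarray())
        vals, vecs = vals[:count], vecs[:, :count]
    else:
        # shift-invert targets the bottom of the spectrum
        vals, vecs = eigsh(A.tocsc(), k=count, sigma=-1e-8, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]
    vals = np.where(np.abs(vals) < 1e-12, np.maximum(vals, 0.0), vals)
    vecs = vecs / np.sqrt(grid.weight)
    return vals, vecs


def principal_eigenpair(grid: SpaceGrid, q) -> tuple[float, np.ndarray]:
    """Smallest eigenvalue and positive eigenvector of -Laplacian + q.

    ``q`` is a scalar or a field on the grid.  The principal eigenvector of
    the (shifted) M-matrix is a Perron vector and can be chosen strictly
    positive; this is verified before returning.
    """
    N = grid.n_nodes
    qv = np.broadcast_to(np.asarray(q, dtype=float), (N,))
    A = (-laplacian_matrix(grid) + sp.diags(qv)).tocsc()
    if N <= _DENSE_LIMIT:
        vals, vecs = eigh(A.toarray(), subset_by_index=[0, 0])
        lam0, v = float(vals[0]), vecs[:, 0]
    else:
        shift = float(qv.min()) - 1.0
        vals, vecs = eigsh(A, k=1, sigma=shift, which="LM")
        lam0, v = float(vals[0]), vecs[:, 0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    if v.min() < -1e-8 * v.max():
        raise RuntimeError("principal eigenvector is not single-signed")
    v = np.abs(v)
    v = v / grid.norm(v)
    return lam0, v


def principal_eigenvalue(grid: SpaceGrid, q) -> float:
    """Smallest eigenvalue of -Laplacian + diag(q); equals mu_0 for q = 0."""
    lam0, _ = principal_eigenpair(grid, q)
    return lam0
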