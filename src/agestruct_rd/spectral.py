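"""Operator machinery: evolution operator, Q^lambda, spectral radius and bound.

The age-parameterized linear problem  dv/da = d(a) Lap v - (m + r) v  is
advanced one age interval at a time: an exact exponential integrating factor
for the reaction part (trapezoid of m + r over the interval, so products of
substeps reproduce the cumulative-trapezoid survival function exactly) and a
backward-Euler solve for the diffusion part, which keeps the substep an
M-matrix inverse and hence positivity-preserving.

One forward age sweep yields the whole family U(a_k, 0); the transmission
output operators Q^lambda are trapezoid sums over that sweep, reused for all
lambda.  The spectral radius of S* Q^lambda is a Perron root obtained by
power iteration; the spectral bound is the unique real s with radius 1,
bracketed via the strict monotone decay of the radius curve.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.linalg import expm
from scipy.sparse.linalg import splu

from .grids import AgeGrid, Grids, SpaceGrid, laplacian_matrix
from .model_core import (
    ModelParameters,
    eval_age_coefficient,
    eval_age_space_coefficient,
)

__all__ = [
    "EvolutionOperator",
    "QFamily",
    "QLambdaOperator",
    "SpectralSummary",
    "evolution_apply",
    "q_lambda",
    "spectral_radius_weighted",
    "spectral_bound",
    "radius_curve",
    "volterra_renewal_solve",
]


class EvolutionOperator:
    """Discrete solution operator U(a_j, a_i) of dv/da = (d Lap - m - r) v."""

    def __init__(
        self,
        params: ModelParameters,
        age_grid: AgeGrid,
        space_grid: SpaceGrid,
        include_recovery: bool = True,
    ):
        self.age_grid = age_grid
        self.space_grid = space_grid
        ages = age_grid.nodes
        coords = space_grid.coords
        L = laplacian_matrix(space_grid)
        self.laplacian = L
        mr = eval_age_space_coefficient(params.m, ages, coords)
        if include_recovery:
            mr = mr + eval_age_space_coefficient(params.r, ages, coords)
        da = age_grid.da
        # decay over interval k uses the trapezoid of (m + r); products of
        # these factors reproduce exp(-cumtrapz) exactly
        self.decay = np.exp(-0.5 * da * (mr[:-1] + mr[1:]))  # (K, N)
        d_nodes = eval_age_coefficient(params.d, ages)
        self.d_mid = 0.5 * (d_nodes[:-1] + d_nodes[1:])  # (K,)
        N = space_grid.n_nodes
        I = sp.identity(N, format="csc")
        self._solvers = {}
        self._solver_of = []
        for dm in self.d_mid:
            key = round(float(dm), 14)
            if key not in self._solvers:
                self._solvers[key] = splu((I - da * dm * L).tocsc())
            self._solver_of.append(self._solvers[key])

    def step(self, k: int, v: np.ndarray) -> np.ndarray:
        """Advance from age node k to k+1; v is (N,) or (N, m)."""
        w = self.decay[k][:, None] * v if v.ndim == 2 else self.decay[k] * v
        if np.iscomplexobj(w):
            return self._solver_of[k].solve(w.real) + 1j * self._solver_of[k].solve(w.imag)
        return self._solver_of[k].solve(w)

    def apply(self, j: int, i: int, v: np.ndarray) -> np.ndarray:
        """U(a_j, a_i) v for node indices i <= j."""
        if not 0 <= i <= j <= self.age_grid.n_intervals:
            raise ValueError("need 0 <= i <= j <= K")
        out = np.array(v, dtype=v.dtype if np.iscomplexobj(v) else float)
        for k in range(i, j):
            out = self.step(k, out)
        return out

    def sweep(self) -> np.ndarray:
        """Dense stack U[k] = U(a_k, 0), shape (K+1, N, N)."""
        N = self.space_grid.n_nodes
        K = self.age_grid.n_intervals
        out = np.empty((K + 1, N, N))
        out[0] = np.eye(N)
        for k in range(K):
            out[k + 1] = self.step(k, out[k])
        return out


def evolution_apply(
    params: ModelParameters,
    grids: Grids,
    a: float,
    sigma: float,
    v: np.ndarray,
    include_recovery: bool = True,
) -> np.ndarray:
    """Apply U(a, sigma) to a space vector; a and sigma must be grid nodes."""
    if sigma > a:
        raise ValueError("need sigma <= a")
    j = grids.age.index_of(a)
    i = grids.age.index_of(sigma)
    ev = EvolutionOperator(params, grids.age, grids.space, include_recovery)
    return ev.apply(j, i, np.asarray(v, dtype=float))


@dataclass
class QLambdaOperator:
    """Discretized Q^lambda = int b(a) e^{-lambda a} U(a,0) da."""

    lam: complex
    matrix: np.ndarray
    age_grid: AgeGrid
    space_grid: SpaceGrid

    @property
    def is_real(self) -> bool:
        return np.isrealobj(self.matrix) or np.all(self.matrix.imag == 0)


@dataclass
class SpectralSummary:
    r0: float
    spectral_bound: float
    radius_curve: list  # (lambda, radius) pairs


class QFamily:
    """Caches one forward age sweep and assembles Q^lambda for any lambda."""

    def __init__(self, params: ModelParameters, grids: Grids):
        self.params = params
        self.grids = grids
        self.evolution = EvolutionOperator(params, grids.age, grids.space)
        ages = grids.age.nodes
        b = eval_age_space_coefficient(params.b, ages, grids.space.coords)  # (K+1, N)
        Us = self.evolution.sweep()  # (K+1, N, N)
        self._bU = b[:, :, None] * Us  # diag(b_k) @ U_k stacked
        self._ages = ages
        self._weights = grids.age.trapezoid_weights

    def assemble(self, lam: complex) -> np.ndarray:
        coeff = self._weights * np.exp(-lam * self._ages)
        Q = np.tensordot(coeff, self._bU, axes=1)
        if np.isrealobj(coeff) or np.all(np.imag(coeff) == 0):
            return np.real(Q)
        return Q

    def operator(self, lam: complex) -> QLambdaOperator:
        return QLambdaOperator(
            lam=lam, matrix=self.assemble(lam), age_grid=self.grids.age, space_grid=self.grids.space
        )


def q_lambda(params: ModelParameters, grids: Grids, lam: complex = 0.0) -> QLambdaOperator:
    """Assemble the discretized Q^lambda operator (one age sweep)."""
    return QFamily(params, grids).operator(lam)


def spectral_radius_weighted(
    S_star: np.ndarray,
    Q,
    tol: float = 1e-10,
    maxiter: int = 20000,
    return_eigenvector: bool = False,
):
    """Spectral radius of diag(S*) Q by power iteration (Perron root).

    For real lambda and nonnegative data the matrix is entrywise nonnegative
    and the dominant eigenvalue is real, simple and carries a positive
    eigenvector, which is verified on exit.
    """
    Qm = Q.matrix if isinstance(Q, QLambdaOperator) else np.asarray(Q)
    if np.iscomplexobj(Qm) and np.any(Qm.imag != 0):
        raise ValueError("spectral radius is defined here for real lambda only")
    S_star = np.asarray(S_star, dtype=float)
    if S_star.min() < 0 or not np.any(S_star > 0):
        raise ValueError("S_star must be nonnegative and not identically zero")
    M = S_star[:, None] * np.real(Qm)
    v = np.ones(M.shape[0])
    v /= np.linalg.norm(v)
    lam_old = np.inf
    history = []
    for _ in range(maxiter):
        w = M @ v
        nw = np.linalg.norm(w)
        if nw == 0.0:
            return (0.0, v) if return_eigenvector else 0.0
        lam = float(v @ w)
        history.append(lam)
        v = w / nw
        if abs(lam - lam_old) <= tol * max(1.0, abs(lam)):
            break
        lam_old = lam
    else:
        raise RuntimeError(
            f"power iteration did not converge in {maxiter} iterations; "
            f"last Rayleigh quotients: {history[-5:]}"
        )
    if v.min() < -1e-8 * v.max():
        raise RuntimeError("dominant eigenvector is not positive (Perron check failed)")
    radius = float(abs(lam))
    return (radius, np.abs(v)) if return_eigenvector else radius


def radius_curve(qfam: QFamily, S_star: np.ndarray, lams) -> list:
    """Sample lambda -> r(S* Q^lambda) on real values."""
    return [(float(l), spectral_radius_weighted(S_star, qfam.assemble(l))) for l in lams]


def spectral_bound(
    params: ModelParameters,
    grids: Grids,
    S_star: np.ndarray,
    tol: float = 1e-8,
    qfam: QFamily | None = None,
    max_bracket: float = 1e6,
) -> float:
    """The unique real s with r(S* Q^s) = 1.

    Bracketed by geometric expansion using the monotone decay of the radius
    curve (radius -> infinity as s -> -infinity, -> 0 as s -> +infinity),
    then bisected to ``tol``.  sign(s) = sign(r(S* Q^0) - 1).
    """
    fam = qfam if qfam is not None else QFamily(params, grids)

    def g(s: float) -> float:
        return spectral_radius_weighted(S_star, fam.assemble(s)) - 1.0

    g0 = g(0.0)
    if g0 == 0.0:
        return 0.0
    step = 1.0
    if g0 > 0:  # radius decreasing in s, so the root lies to the right
        lo, hi = 0.0, step
        while g(hi) > 0:
            lo, hi = hi, hi * 2.0
            if hi > max_bracket:
                raise RuntimeError("bracket expansion exceeded bounds (s -> +inf)")
    else:
        lo, hi = -step, 0.0
        while g(lo) < 0:
            lo, hi = lo * 2.0, lo
            if -lo > max_bracket:
                raise RuntimeError("bracket expansion exceeded bounds (s -> -inf)")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if g(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def volterra_renewal_solve(
    params: ModelParameters,
    grids: Grids,
    state,
    S0: np.ndarray,
    I0: np.ndarray,
    T: float,
):
    """March the linearized renewal (Volterra) equation for B(t).

    ``state`` supplies the frozen steady state (S*, I*) around which the
    problem is linearized; it fixes S*, the infection pressure q* and the
    reaction-diffusion generator of the S-component.  The kernel is lower
    triangular in time, so forward marching with time step dt = da solves it
    exactly at the nodes; the age-zero kernel node is dropped (left-rectangle
    rule), which keeps the march explicit and first-order accurate.

    Returns (times, B) with B of shape (n_t + 1, N); B >= 0 for nonnegative
    inputs.
    """
    ag, sg = grids.age, grids.space
    N = sg.n_nodes
    K = ag.n_intervals
    dt = ag.da
    n_t = int(round(T / dt))
    S_star = np.asarray(state.S_star, dtype=float)
    coords = sg.coords
    b = eval_age_space_coefficient(params.b, ag.nodes, coords)  # (K+1, N)
    w = ag.trapezoid_weights
    if state.I_star is not None:
        q_star = np.tensordot(w, b * state.I_star, axes=1)
    else:
        q_star = np.zeros(N)
    L = laplacian_matrix(sg)
    A1 = (
        params.d1 * L
        + sp.diags(params.kappa1 - 2.0 * params.kappa1 * S_star / params.kappa2 - q_star)
    ).toarray()
    E1 = expm(dt * A1)

    ev = EvolutionOperator(params, ag, sg)
    I0 = np.asarray(I0, dtype=float)
    if I0.shape != (K + 1, N):
        raise ValueError("I0 must have shape (K+1, N)")
    S0 = np.asarray(S0, dtype=float)

    times = dt * np.arange(n_t + 1)
    B = np.zeros((n_t + 1, N))
    # F[i] tracks U(a_{i+k}, a_i) I0(a_i); advanced one age interval per step
    F = I0.copy()
    # H[j] tracks U(a_j, 0) B(t_k - a_j)
    H = np.zeros((K + 1, N))

    s_vec = S0.copy()
    for k in range(n_t + 1):
        if k > 0:
            s_vec = E1 @ s_vec
            for j in range(min(k, K), 0, -1):
                H[j] = ev.step(j - 1, H[j - 1])
            for i in range(0, K - k + 1):
                F[i] = ev.step(i + k - 1, F[i])
        # initial-age contribution: integral over a in [0, a_m - t_k]
        term2 = np.zeros(N)
        if k <= K:
            idx = np.arange(0, K - k + 1)
            wk = np.full(idx.size, dt)
            wk[0] *= 0.5
            if idx.size > 1:
                wk[-1] *= 0.5
            term2 = np.tensordot(wk, b[idx + k] * F[idx], axes=1)
        term1 = np.zeros(N)
        for j in range(1, min(k, K) + 1):
            term1 += dt * b[j] * H[j]
        B[k] = S_star * (term1 + term2) + q_star * s_vec
        H[0] = B[k]
    return times, B
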