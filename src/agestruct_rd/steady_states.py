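"""Steady-state families: trivial, disease-free and endemic.

The disease-free state solves the semilinear equation
``-Lap S + (kappa1/kappa2) S^2 = kappa1 S`` (constant kappa2 under Neumann
conditions; a damped-Newton solve under Dirichlet conditions, which admits a
positive solution exactly when kappa1 exceeds the principal Laplacian
eigenvalue).  Endemic candidates are verified through the residuals of the
coupled system in (S*, I0) with I*(a) reconstructed by the evolution
operator; the general endemic existence problem is deliberately not solved
(open in the heterogeneous/Dirichlet case), but for R0 <= 1 a seeded
fixed-point scan certifies collapse of the candidate map to zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .grids import NEUMANN, Grids, SpaceGrid, laplacian_matrix, principal_eigenpair
from .model_core import ModelParameters

__all__ = [
    "SteadyState",
    "NoPositiveSolutionError",
    "disease_free_solve",
    "endemic_residual",
    "endemic_nonexistence_scan",
    "trivial_state",
]

_NEWTON_TOL = 1e-10
_POSITIVITY_FLOOR = 1e-14


class NoPositiveSolutionError(ValueError):
    """No positive disease-free state exists (kappa1 <= mu0)."""


@dataclass
class SteadyState:
    """A steady state with fields and discrete residual norms."""

    kind: str  # "trivial" | "disease_free" | "endemic"
    S_star: np.ndarray
    I_star: np.ndarray | None
    residual_S: float | None
    residual_I: float | None
    info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in ("trivial", "disease_free", "endemic"):
            raise ValueError(f"unknown steady-state kind {self.kind!r}")
        if np.min(self.S_star) < -1e-12:
            raise ValueError("S_star must be nonnegative")
        if self.I_star is not None and np.min(self.I_star) < -1e-12:
            raise ValueError("I_star must be nonnegative")


def trivial_state(space_grid: SpaceGrid, age_intervals: int) -> SteadyState:
    N = space_grid.n_nodes
    return SteadyState(
        kind="trivial",
        S_star=np.zeros(N),
        I_star=np.zeros((age_intervals + 1, N)),
        residual_S=0.0,
        residual_I=0.0,
    )


def _semilinear_newton(
    L: sp.spmatrix,
    kappa1: float,
    kappa2: float,
    extra_potential: np.ndarray | None,
    x0: np.ndarray,
    tol: float = _NEWTON_TOL,
    maxiter: int = 60,
):
    """Damped Newton for -Lap S + q S + (k1/k2) S^2 - k1 S = 0, S >= 0."""
    N = x0.shape[0]
    q = np.zeros(N) if extra_potential is None else np.asarray(extra_potential, dtype=float)
    A = (-L).tocsr()

    def F(S):
        return A @ S + q * S + (kappa1 / kappa2) * S**2 - kappa1 * S

    x = np.maximum(x0, _POSITIVITY_FLOOR)
    scale = max(kappa1 * float(np.max(np.abs(x))), 1.0)
    history = []
    for _ in range(maxiter):
        f = F(x)
        res = float(np.linalg.norm(f, np.inf)) / scale
        history.append(res)
        if res < tol:
            return x, history
        J = (A + sp.diags(q + 2.0 * (kappa1 / kappa2) * x - kappa1)).tocsc()
        dx = spsolve(J, -f)
        # Armijo backtracking on the residual norm with a positivity floor
        t, f_norm = 1.0, np.linalg.norm(f)
        for _ in range(40):
            x_new = np.maximum(x + t * dx, _POSITIVITY_FLOOR)
            if np.linalg.norm(F(x_new)) <= (1.0 - 1e-4 * t) * f_norm:
                break
            t *= 0.5
        else:
            raise RuntimeError(f"Newton line search failed; residual history: {history}")
        x = x_new
    raise RuntimeError(f"Newton did not converge; residual history: {history}")


def disease_free_solve(params: ModelParameters, grids: Grids) -> SteadyState:
    """Unique positive disease-free state (exists iff kappa1 > mu0).

    Neumann: S* = kappa2 identically.  Dirichlet: damped Newton from the
    scaled principal eigenvector of the Laplacian.
    """
    sg = grids.space
    N = sg.n_nodes
    K = grids.age.n_intervals
    L = laplacian_matrix(sg)
    if sg.delta == NEUMANN:
        S = np.full(N, params.kappa2)
        res = float(np.linalg.norm((-L) @ S + (params.kappa1 / params.kappa2) * S**2 - params.kappa1 * S, np.inf))
        return SteadyState("disease_free", S, np.zeros((K + 1, N)), res, 0.0, {"mu0": 0.0})
    mu0, phi0 = principal_eigenpair(sg, 0.0)
    if params.kappa1 <= mu0:
        raise NoPositiveSolutionError(
            f"no positive disease-free state: kappa1 = {params.kappa1:.6g} <= mu0 = {mu0:.6g}"
        )
    amplitude = params.kappa2 * (1.0 - mu0 / params.kappa1)
    x0 = amplitude * phi0 / float(np.max(phi0))
    S, history = _semilinear_newton(L, params.kappa1, params.kappa2, None, x0)
    res = float(np.linalg.norm((-L) @ S + (params.kappa1 / params.kappa2) * S**2 - params.kappa1 * S, np.inf))
    return SteadyState(
        "disease_free",
        S,
        np.zeros((K + 1, N)),
        res,
        0.0,
        {"mu0": mu0, "newton_residuals": history},
    )


def endemic_residual(
    params: ModelParameters,
    grids: Grids,
    S_star: np.ndarray,
    I0: np.ndarray,
    qfam=None,
    reconstruct: bool = False,
):
    """Sup-norm residuals of the endemic steady-state system in (S*, I0).

    res_S: || -Lap S* + (Q^0 I0) S* + (k1/k2) S*^2 - k1 S* ||_inf
    res_I: || I0 - S* Q^0 I0 ||_inf

    With ``reconstruct=True`` additionally returns I*(a) = U(a, 0) I0.
    """
    from .spectral import EvolutionOperator, QFamily  # local: avoids cycle

    fam = qfam if qfam is not None else QFamily(params, grids)
    Q0 = fam.assemble(0.0)
    L = laplacian_matrix(grids.space)
    S_star = np.asarray(S_star, dtype=float)
    I0 = np.asarray(I0, dtype=float)
    pressure = Q0 @ I0
    res_S = float(
        np.linalg.norm(
            (-L) @ S_star
            + pressure * S_star
            + (params.kappa1 / params.kappa2) * S_star**2
            - params.kappa1 * S_star,
            np.inf,
        )
    )
    res_I = float(np.linalg.norm(I0 - S_star * pressure, np.inf))
    if not reconstruct:
        return res_S, res_I
    ev = EvolutionOperator(params, grids.age, grids.space)
    K, N = grids.age.n_intervals, grids.space.n_nodes
    I_star = np.empty((K + 1, N))
    I_star[0] = I0
    for k in range(K):
        I_star[k + 1] = ev.step(k, I_star[k])
    return res_S, res_I, I_star


@dataclass
class NonexistenceScanReport:
    r0: float
    boundary_case: bool
    trials: int
    all_collapsed: bool
    final_norms: list
    iterations: list


def endemic_nonexistence_scan(
    params: ModelParameters,
    grids: Grids,
    trials: int = 10,
    seed: int = 0,
    tol: float = 1e-10,
    maxiter: int = 5000,
    boundary_tol: float = 1e-4,
) -> NonexistenceScanReport:
    """Fixed-point scan I0 -> S*(I0) Q^0 I0 certifying collapse when R0 <= 1.

    For each seeded random positive start the map is iterated; when R0 < 1
    all iterates must fall below ``tol`` in sup norm.  At R0 = 1 (within
    ``boundary_tol``, which absorbs the quadrature error of the discrete
    radius) collapse can be arbitrarily slow, so only monotone decrease is
    demanded and the report is flagged as a boundary case.  R0 > 1 is
    refused: existence there is open in general and the scan is undefined.
    """
    from .spectral import QFamily, spectral_radius_weighted

    fam = QFamily(params, grids)
    df = disease_free_solve(params, grids)
    r0_val = spectral_radius_weighted(df.S_star, fam.assemble(0.0))
    boundary = abs(r0_val - 1.0) < boundary_tol
    if r0_val > 1.0 + boundary_tol:
        raise ValueError(f"scan undefined for R0 = {r0_val:.6g} > 1")
    L = laplacian_matrix(grids.space)
    Q0 = fam.assemble(0.0)
    N = grids.space.n_nodes
    rng = np.random.default_rng(seed)
    final_norms, iters, collapsed = [], [], []
    for _ in range(trials):
        I0 = params.kappa2 * rng.uniform(0.5, 1.5, size=N)
        S_guess = df.S_star.copy()
        history = [float(np.linalg.norm(I0, np.inf))]
        for it in range(maxiter):
            S_of_I0, _ = _semilinear_newton(L, params.kappa1, params.kappa2, Q0 @ I0, S_guess)
            S_guess = S_of_I0
            I0 = S_of_I0 * (Q0 @ I0)
            nrm = float(np.linalg.norm(I0, np.inf))
            history.append(nrm)
            if nrm < tol:
                break
        final = history[-1]
        final_norms.append(final)
        iters.append(len(history) - 1)
        if boundary:
            collapsed.append(all(b <= a * (1 + 1e-12) for a, b in zip(history, history[1:])))
        else:
            collapsed.append(final < tol)
    return NonexistenceScanReport(
        r0=float(r0_val),
        boundary_case=boundary,
        trials=trials,
        all_collapsed=all(collapsed),
        final_norms=final_norms,
        iterations=iters,
    )
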