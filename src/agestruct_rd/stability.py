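"""Stability classification of steady states.

Three routes, used according to what the steady state admits:

* trivial state: the rightmost spectral point is kappa1 - mu0 in closed form;
* disease-free state: sign of R0 - 1, cross-checked by the spectral bound s
  with r(S* Q^s) = 1;
* endemic state (homogeneous Neumann): per-Laplacian-mode characteristic
  equation, whose complex roots are located by argument-principle winding on
  a rectangle boundary followed by Newton polishing.  A dominated-decay
  certificate (|R_{lambda,mu}| <= R_{0,mu} for Re lambda >= 0, and the
  rational factor bounded by 1/r0) silences modes that cannot carry roots.

The discrete linearization generator is also assembled as a sparse block
matrix on (S, I) with the renewal constraint eliminated into the age-zero
row, providing an independent eigenvalue route for cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import eigs

from .grids import AgeGrid, Grids, laplacian_eigenpairs, laplacian_matrix, make_age_grid
from .model_core import (
    ModelParameters,
    eval_age_coefficient,
    eval_age_space_coefficient,
    survival_on_grid,
)
from .steady_states import SteadyState, disease_free_solve

__all__ = [
    "CharRoot",
    "StabilityReport",
    "LinearizationAssembly",
    "char_R",
    "characteristic_roots",
    "classify_trivial",
    "classify_disease_free",
    "classify_endemic",
    "linearization_matrix",
    "rightmost_eigenvalue",
]

_MARGIN = 1e-6  # verdicts inside this band around 0 are "inconclusive"


@dataclass
class CharRoot:
    lam: complex
    mode_index: int
    mu: float
    residual: float


@dataclass
class StabilityReport:
    state_kind: str
    verdict: str  # linearly_stable | linearly_unstable | inconclusive
    r0: float | None = None
    evidence: dict = field(default_factory=dict)
    methods: list = field(default_factory=list)


class _CharIngredients:
    """Precomputed quadrature arrays for the characteristic integral."""

    def __init__(self, params: ModelParameters, age_grid: AgeGrid):
        from scipy.integrate import cumulative_trapezoid

        self.ages = age_grid.nodes
        self.weights = age_grid.trapezoid_weights
        self.b = eval_age_coefficient(params.b, self.ages)
        self.pi = survival_on_grid(params, age_grid)
        d = eval_age_coefficient(params.d, self.ages)
        self.cum_d = cumulative_trapezoid(d, dx=age_grid.da, initial=0.0)
        self.kappa1 = params.kappa1
        self.kappa2 = params.kappa2
        r0_big = params.kappa2 * float(np.trapezoid(self.b * self.pi, dx=age_grid.da))
        if r0_big <= 1.0:
            raise ValueError(f"endemic characteristic analysis requires R0 > 1, got {r0_big:.6g}")
        self.R0 = r0_big
        self.r0 = 1.0 / r0_big

    def _mode_integrand(self, mu: float) -> np.ndarray:
        # clamp the exponent: high modes underflow and subnormals are slow
        return self.b * self.pi * np.exp(np.maximum(-mu * self.cum_d, -700.0))

    def R(self, lam, mu: float):
        """R_{lambda,mu}, vectorized over an array of lambda values."""
        lam_arr = np.atleast_1d(np.asarray(lam, dtype=complex))
        integrand = self._mode_integrand(mu)
        phases = np.exp(-np.outer(lam_arr, self.ages))
        vals = self.r0 * self.kappa2 * (phases * integrand) @ self.weights
        return vals if np.ndim(lam) else complex(vals[0])

    def F(self, lam, mu: float):
        """Characteristic function F(lambda) = 1 - R * (1 - (1-r0)/(zeta+r0))."""
        lam_arr = np.atleast_1d(np.asarray(lam, dtype=complex))
        zeta = (lam_arr + mu) / self.kappa1
        g = 1.0 - (1.0 - self.r0) / (zeta + self.r0)
        vals = 1.0 - self.R(lam_arr, mu) * g
        return vals if np.ndim(lam) else complex(vals[0])

    def dF(self, lam: complex, mu: float) -> complex:
        """Analytic derivative of F for Newton polishing."""
        zeta = (lam + mu) / self.kappa1
        g = 1.0 - (1.0 - self.r0) / (zeta + self.r0)
        dg = (1.0 - self.r0) / (self.kappa1 * (zeta + self.r0) ** 2)
        integrand = self._mode_integrand(mu)
        phases = np.exp(-lam * self.ages)
        Rv = self.r0 * self.kappa2 * complex((phases * integrand) @ self.weights)
        dR = -self.r0 * self.kappa2 * complex((self.ages * phases * integrand) @ self.weights)
        return -(dR * g + Rv * dg)

    def pole(self, mu: float) -> complex:
        return complex(-self.kappa1 * self.r0 - mu)


def _ingredients(params: ModelParameters, age_grid: AgeGrid | None) -> _CharIngredients:
    ag = age_grid if age_grid is not None else params.default_age_grid()
    return _CharIngredients(params, ag)


def char_R(
    params: ModelParameters,
    lam: complex,
    mu: float,
    age_grid: AgeGrid | None = None,
) -> complex:
    """Characteristic integral R_{lambda,mu} of the endemic linearization.

    R = r0 kappa2 int b(a) Pi(a) e^{-lambda a} exp(-mu int_0^a d) da with
    r0 = 1/R0 computed by the same composite trapezoid, so that the identity
    R_{0,0} = r0 R0 = 1 holds to round-off on any grid.
    """
    if mu < 0:
        raise ValueError("mu must be >= 0")
    ing = _ingredients(params, age_grid)
    return ing.R(complex(lam), mu)


def _winding_number(ing: _CharIngredients, mu: float, rect, n_boundary: int):
    (re0, re1), (im0, im1) = rect
    per_edge = max(n_boundary // 4, 64)
    tt = np.linspace(0.0, 1.0, per_edge, endpoint=False)
    bottom = re0 + (re1 - re0) * tt + 1j * im0
    right = re1 + 1j * (im0 + (im1 - im0) * tt)
    top = re1 - (re1 - re0) * tt + 1j * im1
    left = re0 + 1j * (im1 - (im1 - im0) * tt)
    boundary = np.concatenate([bottom, right, top, left, bottom[:1]])
    vals = ing.F(boundary, mu)
    min_abs = float(np.min(np.abs(vals)))
    total = float(np.sum(np.diff(np.unwrap(np.angle(vals))))) / (2.0 * np.pi)
    return total, min_abs


def _newton_polish(ing: _CharIngredients, mu: float, lam0: complex, tol: float = 1e-12) -> complex | None:
    lam = complex(lam0)
    for _ in range(60):
        f = ing.F(lam, mu)
        if abs(f) < tol:
            return lam
        df = ing.dF(lam, mu)
        if df == 0:
            return None
        step_ = f / df
        lam -= step_
        if abs(step_) < 1e-14 * max(1.0, abs(lam)):
            return lam
    return lam if abs(ing.F(lam, mu)) < 1e-9 else None


def _locate_roots(ing, mu, rect, n_boundary, depth=0):
    (re0, re1), (im0, im1) = rect
    size = max(re1 - re0, im1 - im0)
    attempts, w, min_abs = 0, None, None
    nb = n_boundary
    while attempts < 3:
        w, min_abs = _winding_number(ing, mu, ((re0, re1), (im0, im1)), nb)
        if min_abs < 1e-11:
            # boundary grazes a root: inflate the rectangle slightly
            pad = 0.05 * size
            re0, re1, im0, im1 = re0 - pad, re1 + pad, im0 - pad, im1 + pad
            attempts += 1
            continue
        if abs(w - round(w)) > 0.25:
            nb *= 4
            attempts += 1
            continue
        break
    else:
        raise RuntimeError("winding-number computation unstable after 3 attempts")
    w = int(round(w))
    if w <= 0:
        return []
    center = complex(0.5 * (re0 + re1), 0.5 * (im0 + im1))
    if w == 1 and size < 0.5:
        # a single enclosed root: Newton from the centre usually lands on it
        root = _newton_polish(ing, mu, center)
        if root is not None and re0 <= root.real <= re1 and im0 <= root.imag <= im1:
            return [root]
    if size < 1e-6 or depth > 48:
        root = _newton_polish(ing, mu, center)
        return [root] if root is not None else []
    # slightly off-center split to avoid cutting through a root
    rm = re0 + 0.5001 * (re1 - re0)
    im_mid = im0 + 0.5001 * (im1 - im0)
    roots = []
    nb_sub = max(n_boundary // 2, 1024)
    for sub in (
        ((re0, rm), (im0, im_mid)),
        ((rm, re1), (im0, im_mid)),
        ((re0, rm), (im_mid, im1)),
        ((rm, re1), (im_mid, im1)),
    ):
        roots.extend(_locate_roots(ing, mu, sub, nb_sub, depth + 1))
    return roots


def characteristic_roots(
    params: ModelParameters,
    mu: float,
    search_region=((0.0, 10.0), (-50.0, 50.0)),
    age_grid: AgeGrid | None = None,
    mode_index: int = 0,
    n_boundary: int = 4000,
) -> list:
    """All roots of the per-mode characteristic equation inside a rectangle.

    Located by argument-principle winding on the rectangle boundary with
    recursive subdivision, then Newton-polished; the rational factor's pole
    at lambda = -kappa1 r0 - mu must lie outside the region.
    """
    ing = _ingredients(params, age_grid)
    (re0, re1), (im0, im1) = search_region
    pole = ing.pole(mu)
    if re0 <= pole.real <= re1 and im0 <= pole.imag <= im1:
        raise ValueError(f"search region contains the excluded pole at {pole}")
    raw = _locate_roots(ing, mu, search_region, n_boundary)
    roots: list[CharRoot] = []
    for lam in raw:
        if not (re0 - 1e-9 <= lam.real <= re1 + 1e-9 and im0 - 1e-9 <= lam.imag <= im1 + 1e-9):
            continue
        if any(abs(lam - r.lam) < 1e-8 * max(1.0, abs(lam)) for r in roots):
            continue
        roots.append(CharRoot(lam=lam, mode_index=mode_index, mu=mu, residual=abs(ing.F(lam, mu))))
    for r in roots:
        if r.residual > 1e-9:
            raise RuntimeError(f"root {r.lam} failed the residual check ({r.residual:.2e})")
    return sorted(roots, key=lambda r: -r.lam.real)


def classify_trivial(params: ModelParameters, grids: Grids) -> StabilityReport:
    """Verdict for (0, 0): sign of kappa1 - mu0 (closed-form rightmost point)."""
    mu0 = float(laplacian_eigenpairs(grids.space, 1)[0][0])
    s = params.kappa1 - mu0
    if s > _MARGIN:
        verdict = "linearly_unstable"
    elif s < -_MARGIN:
        verdict = "linearly_stable"
    else:
        verdict = "inconclusive"
    return StabilityReport(
        state_kind="trivial",
        verdict=verdict,
        evidence={"rightmost": s, "mu0": mu0},
        methods=["closed_form_spectrum"],
    )


def classify_disease_free(params: ModelParameters, grids: Grids) -> StabilityReport:
    """Verdict for the disease-free state from R0 and the spectral bound."""
    from .spectral import QFamily, spectral_bound, spectral_radius_weighted

    state = disease_free_solve(params, grids)  # raises if the state does not exist
    fam = QFamily(params, grids)
    r0_val = spectral_radius_weighted(state.S_star, fam.assemble(0.0))
    s = spectral_bound(params, grids, state.S_star, qfam=fam)
    if not (np.sign(s) == np.sign(r0_val - 1.0) or abs(s) < 1e-6 or abs(r0_val - 1.0) < 1e-6):
        raise RuntimeError(f"spectral bound s = {s} inconsistent with R0 = {r0_val}")
    if r0_val - 1.0 > _MARGIN:
        verdict = "linearly_unstable"
    elif r0_val - 1.0 < -_MARGIN:
        verdict = "linearly_stable"
    else:
        verdict = "inconclusive"
    return StabilityReport(
        state_kind="disease_free",
        verdict=verdict,
        r0=float(r0_val),
        evidence={"spectral_bound": float(s), "R0_minus_1": float(r0_val - 1.0)},
        methods=["power_iteration", "spectral_bound_bisection"],
    )


def classify_endemic(
    params: ModelParameters,
    grids: Grids,
    n_modes: int = 21,
    search_region=((-1e-6, 10.0), (-50.0, 50.0)),
    age_grid: AgeGrid | None = None,
) -> StabilityReport:
    """Verdict for the homogeneous Neumann endemic state via mode-wise roots.

    Modes whose characteristic integral satisfies R_{0,mu_j} * R0 < 1 cannot
    carry a right-half-plane root (|R_{lam,mu}| <= R_{0,mu} for
    Re lambda >= 0 and the rational factor's modulus is at most 1/r0 = R0)
    and are certified without a contour scan.  The same bound at mu_{n_modes}
    certifies the tail; if it fails the verdict is inconclusive.
    """
    ing = _ingredients(params, age_grid if age_grid is not None else grids.age)
    if grids.space.n_nodes <= n_modes:
        raise ValueError(
            f"grid has {grids.space.n_nodes} nodes, too few to resolve {n_modes} modes"
        )
    mus = laplacian_eigenpairs(grids.space, n_modes + 1)[0]
    roots: list[CharRoot] = []
    certified = []
    for j in range(n_modes):
        mu_j = float(mus[j])
        if abs(ing.R(0.0, mu_j)) * ing.R0 < 1.0 - 1e-9:
            certified.append(j)
            continue
        roots.extend(
            characteristic_roots(
                params, mu_j, search_region, age_grid=age_grid or grids.age, mode_index=j
            )
        )
    tail_ok = abs(ing.R(0.0, float(mus[n_modes]))) * ing.R0 < 1.0 - 1e-9
    rightmost = max((r.lam.real for r in roots), default=None)
    methods = ["argument_principle_winding", "mode_decay_certificate"]
    evidence = {
        "n_modes": n_modes,
        "certified_modes": certified,
        "tail_certified": bool(tail_ok),
        "rightmost_root_real_part": rightmost,
        "roots": [(r.mode_index, r.lam.real, r.lam.imag) for r in roots],
    }
    if rightmost is not None and rightmost > _MARGIN:
        verdict = "linearly_unstable"
    elif rightmost is not None and rightmost >= -_MARGIN:
        verdict = "inconclusive"
    elif not tail_ok:
        verdict = "inconclusive"
        evidence["advice"] = "raise n_modes: tail certificate failed"
    else:
        verdict = "linearly_stable"
    report = StabilityReport(
        state_kind="endemic", verdict=verdict, r0=ing.R0, evidence=evidence, methods=methods
    )
    if ing.R0 >= 3.0:
        report.methods.append("conjectural_regime")
        report.evidence["conjectural_regime"] = True
    return report


@dataclass
class LinearizationAssembly:
    """Discrete generator on (S, I_1..I_K) with I_0 eliminated."""

    q_star: np.ndarray
    A1: sp.spmatrix
    matrix: sp.spmatrix
    i0_from_state: tuple  # (coef_S (N,), coef_I (K, N)) reconstructing I_0
    grids: Grids


def linearization_matrix(
    params: ModelParameters, grids: Grids, state: SteadyState, coupled: bool = True
) -> LinearizationAssembly:
    """Assemble the discrete linearized generator around a steady state.

    Age advection is first-order upwind (matching the simulator's
    characteristic scheme); the renewal constraint is eliminated into the
    age-zero row, so the unknowns are S and I at age nodes 1..K.

    With ``coupled=False`` the infection-pressure/recovery feedback into the
    S-row is dropped, leaving the generator of the unperturbed semigroup
    (the one solved by the Volterra renewal march); the renewal constraint,
    which belongs to that generator's domain, is kept in either case.
    """
    if state.residual_S is not None and state.residual_S > 1e-5:
        raise ValueError(f"state is not steady (residual_S = {state.residual_S:.2e})")
    ag, sg = grids.age, grids.space
    K, N = ag.n_intervals, sg.n_nodes
    da = ag.da
    coords = sg.coords
    L = laplacian_matrix(sg)
    b = eval_age_space_coefficient(params.b, ag.nodes, coords)
    r = eval_age_space_coefficient(params.r, ag.nodes, coords)
    m = eval_age_space_coefficient(params.m, ag.nodes, coords)
    d = eval_age_coefficient(params.d, ag.nodes)
    w = ag.trapezoid_weights
    S_star = np.asarray(state.S_star, dtype=float)
    if state.I_star is not None:
        q_star = np.tensordot(w, b * state.I_star, axes=1)
    else:
        q_star = np.zeros(N)

    # I_0 = Dinv * (q* S + S* sum_{k>=1} w_k b_k I_k)
    Dinv = 1.0 / (1.0 - w[0] * b[0] * S_star)
    i0_coef_S = Dinv * q_star
    i0_coef_I = Dinv[None, :] * S_star[None, :] * (w[1:, None] * b[1:])  # (K, N)

    A1 = (
        params.d1 * L
        + sp.diags(params.kappa1 - 2.0 * params.kappa1 * S_star / params.kappa2 - q_star)
    ).tocsr()

    size = N + K * N
    Mx = sp.lil_matrix((size, size))
    Mx[:N, :N] = A1
    if coupled:
        # S-row coupling: sum_k w_k (-S* b_k + r_k) I_k, with the k = 0 term
        # routed through the eliminated I_0
        c0 = w[0] * (-S_star * b[0] + r[0])
        Mx[:N, :N] += sp.diags(c0 * i0_coef_S)
        for k in range(1, K + 1):
            col = slice(N + (k - 1) * N, N + k * N)
            Mx[:N, col] = sp.diags(w[k] * (-S_star * b[k] + r[k]) + c0 * i0_coef_I[k - 1])
    # I rows: -(I_k - I_{k-1})/da + d_k Lap - (m_k + r_k)
    for k in range(1, K + 1):
        row = slice(N + (k - 1) * N, N + k * N)
        Mx[row, row] = d[k] * L - sp.diags(m[k] + r[k] + 1.0 / da)
        if k == 1:
            Mx[row, :N] = sp.diags(i0_coef_S / da)
            for kk in range(1, K + 1):
                col = slice(N + (kk - 1) * N, N + kk * N)
                Mx[row, col] += sp.diags(i0_coef_I[kk - 1] / da)
        else:
            col = slice(N + (k - 2) * N, N + (k - 1) * N)
            Mx[row, col] = sp.identity(N) / da
    return LinearizationAssembly(
        q_star=q_star,
        A1=A1,
        matrix=Mx.tocsr(),
        i0_from_state=(i0_coef_S, i0_coef_I),
        grids=grids,
    )


def rightmost_eigenvalue(
    assembly: LinearizationAssembly,
    dense_limit: int = 3000,
    k: int = 8,
    shifts=None,
) -> complex:
    """Eigenvalue of the discrete generator with the largest real part.

    Dense solve below ``dense_limit`` unknowns; otherwise shift-invert
    Arnoldi around several shifts to avoid blind spots.
    """
    M = assembly.matrix
    n = M.shape[0]
    if n <= dense_limit:
        vals = np.linalg.eigvals(M.toarray())
        return vals[np.argmax(vals.real)]
    kappa1 = None
    if shifts is None:
        kappa1 = 1.0
        shifts = [0.0, kappa1, -kappa1]
    best = None
    for s in shifts:
        try:
            vals = eigs(M.tocsc(), k=k, sigma=s, return_eigenvectors=False)
        except Exception:
            continue
        cand = vals[np.argmax(vals.real)]
        if best is None or cand.real > best.real:
            best = cand
    if best is None:
        raise RuntimeError("shift-invert eigenvalue search failed for all shifts")
    return best
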