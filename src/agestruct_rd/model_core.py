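"""Model parameters, coefficient evaluation and closed-form homogeneous quantities.

Coefficients (diffusion ``d``, mortality ``m``, recovery ``r``, transmission
``b``) may be given as scalars, callables of age ``a`` (or of ``(a, x)`` for
space-dependent data on an interval), or as arrays already evaluated on the
grids.  Internally everything is canonicalized to grid arrays so that all
age integrals go through a single composite-trapezoid path.

The spatially homogeneous Neumann specialization carries closed forms for
the survival function, the basic reproduction number and the endemic steady
state; these are the analytic anchors for the numerical machinery elsewhere.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Union

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .grids import DIRICHLET, NEUMANN, AgeGrid, SpaceGrid, make_age_grid

__all__ = [
    "Coefficient",
    "ModelParameters",
    "HomogeneousParameters",
    "NoEndemicStateError",
    "eval_age_coefficient",
    "eval_age_space_coefficient",
    "survival_on_grid",
    "survival_Pi",
    "r0_homogeneous",
    "endemic_state_homogeneous",
]

Coefficient = Union[float, int, np.ndarray, Callable]


class NoEndemicStateError(ValueError):
    """Raised when an endemic steady state is requested but R0 <= 1."""


def eval_age_coefficient(coef: Coefficient, ages: np.ndarray) -> np.ndarray:
    """Evaluate an age-dependent coefficient on the age nodes -> (K+1,)."""
    ages = np.asarray(ages, dtype=float)
    if callable(coef):
        out = np.asarray(coef(ages), dtype=float)
        if out.shape != ages.shape:
            out = np.broadcast_to(out, ages.shape).astype(float)
        return out
    arr = np.asarray(coef, dtype=float)
    if arr.ndim == 0:
        return np.full_like(ages, float(arr))
    if arr.shape != ages.shape:
        raise ValueError(f"coefficient array of shape {arr.shape} does not match age grid {ages.shape}")
    return arr.copy()


def eval_age_space_coefficient(coef: Coefficient, ages: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Evaluate a coefficient of (a, x) on the tensor grid -> (K+1, N)."""
    ages = np.asarray(ages, dtype=float)
    n_nodes = coords.shape[0]
    shape = (ages.size, n_nodes)
    if callable(coef):
        try:
            if coords.ndim == 1:
                out = np.asarray(coef(ages[:, None], coords[None, :]), dtype=float)
            else:  # 2D coords: call per age row
                out = np.asarray([coef(a, coords) for a in ages], dtype=float)
        except TypeError:
            # age-only callable
            out = np.repeat(eval_age_coefficient(coef, ages)[:, None], n_nodes, axis=1)
        return np.broadcast_to(out, shape).astype(float)
    arr = np.asarray(coef, dtype=float)
    if arr.ndim == 0:
        return np.full(shape, float(arr))
    if arr.shape == (ages.size,):
        return np.repeat(arr[:, None], n_nodes, axis=1)
    if arr.shape == shape:
        return arr.copy()
    raise ValueError(f"cannot broadcast coefficient of shape {arr.shape} to {shape}")


@dataclass
class ModelParameters:
    """All model coefficients, the domain and the boundary-condition flag.

    Parameters
    ----------
    kappa1, kappa2:
        Intrinsic growth rate and carrying capacity of the susceptibles (> 0).
    d:
        Diffusion coefficient of the infected, function of age; must be
        bounded below by a positive constant.
    m, r, b:
        Mortality, recovery and transmission rates, functions of (a, x),
        nonnegative; ``b`` must not vanish identically.
    a_m:
        Maximal (finite) infection age.
    domain:
        Interval length L or rectangle (L1, L2).
    delta:
        0 for Dirichlet, 1 for Neumann boundary conditions.
    d1:
        Susceptible diffusion rate (default 1, as in the model normalization).
    """

    kappa1: float
    kappa2: float
    d: Coefficient
    m: Coefficient
    b: Coefficient
    a_m: float
    domain: Union[float, tuple]
    delta: int
    r: Coefficient = 0.0
    d1: float = 1.0

    def __post_init__(self) -> None:
        if not (self.kappa1 > 0 and self.kappa2 > 0):
            raise ValueError("kappa1 and kappa2 must be positive")
        if not (np.isfinite(self.a_m) and self.a_m > 0):
            raise ValueError("a_m must be positive and finite")
        if self.delta not in (DIRICHLET, NEUMANN):
            raise ValueError("delta must be 0 (Dirichlet) or 1 (Neumann)")
        if self.d1 <= 0:
            raise ValueError("d1 must be positive")
        self.validate_coefficients()

    def validate_coefficients(self, n_check: int = 201) -> None:
        """Spot-check sign conditions on a probe age grid."""
        ages = np.linspace(0.0, self.a_m, n_check)
        d = eval_age_coefficient(self.d, ages)
        if d.min() <= 0:
            raise ValueError("d(a) must be bounded below by a positive constant")
        for name in ("m", "r", "b"):
            coef = getattr(self, name)
            try:
                vals = coef(ages) if callable(coef) else coef
                vals = np.asarray(vals, dtype=float)
            except TypeError:
                continue  # space-dependent callable; checked on full grids later
            if np.nanmin(vals) < 0:
                raise ValueError(f"{name} must be nonnegative")
        b = getattr(self, "b")
        if not callable(b) and np.max(np.abs(np.asarray(b, dtype=float))) == 0:
            raise ValueError("b must not vanish identically")

    def default_age_grid(self, n_intervals: int = 2000) -> AgeGrid:
        return make_age_grid(self.a_m, n_intervals)


@dataclass
class HomogeneousParameters(ModelParameters):
    """Spatially homogeneous rates with Neumann boundary conditions.

    ``m``, ``b``, ``d`` depend on age only, ``b > 0`` on the whole age span,
    recovery is switched off (the regime of the stability analysis) and the
    boundary flag is fixed to Neumann.
    """

    delta: int = NEUMANN

    def __post_init__(self) -> None:
        if self.delta != NEUMANN:
            raise ValueError("homogeneous specialization requires Neumann conditions")
        super().__post_init__()
        ages = np.linspace(0.0, self.a_m, 201)
        if eval_age_coefficient(self.b, ages).min() <= 0:
            raise ValueError("b(a) must be strictly positive on [0, a_m]")
        if np.any(eval_age_coefficient(self.r, ages) != 0):
            raise ValueError("homogeneous stability setting assumes r = 0")


def survival_on_grid(params: ModelParameters, age_grid: AgeGrid) -> np.ndarray:
    """Survival probability Pi on the age nodes, Pi(a) = exp(-int_0^a m).

    Computed by cumulative trapezoid of ``m`` followed by exponentiation,
    which keeps it deterministic and consistent with every other age
    quadrature in the package.
    """
    m = eval_age_coefficient(params.m, age_grid.nodes)
    cum = cumulative_trapezoid(m, dx=age_grid.da, initial=0.0)
    return np.exp(-cum)


def survival_Pi(params: ModelParameters, a, n: int = 513):
    """Survival probability at age(s) ``a`` in [0, a_m]."""
    a_arr = np.atleast_1d(np.asarray(a, dtype=float))
    if np.any(a_arr < 0) or np.any(a_arr > params.a_m * (1 + 1e-12)):
        raise ValueError("age outside [0, a_m]")
    out = np.empty_like(a_arr)
    for i, ai in enumerate(a_arr):
        if ai == 0.0:
            out[i] = 1.0
            continue
        s = np.linspace(0.0, ai, n)
        out[i] = np.exp(-np.trapezoid(eval_age_coefficient(params.m, s), s))
    return float(out[0]) if np.isscalar(a) or np.ndim(a) == 0 else out


def r0_homogeneous(
    params: ModelParameters,
    age_grid: AgeGrid | None = None,
    check_rtol: float | None = 1e-6,
) -> float:
    """Basic reproduction number R0 = kappa2 * int_0^{a_m} b(a) Pi(a) da.

    Uses composite trapezoid on the (given or default) age grid.  When
    ``check_rtol`` is set, the value is compared against the half-resolution
    grid as a Richardson-style accuracy probe and a warning is emitted if
    the estimated relative error exceeds it.
    """
    ag = age_grid if age_grid is not None else params.default_age_grid()
    pi = survival_on_grid(params, ag)
    b = eval_age_coefficient(params.b, ag.nodes)
    r0 = params.kappa2 * float(np.trapezoid(b * pi, dx=ag.da))
    if check_rtol is not None and ag.n_intervals >= 4 and ag.n_intervals % 2 == 0:
        coarse = make_age_grid(ag.a_m, ag.n_intervals // 2)
        pi_c = survival_on_grid(params, coarse)
        b_c = eval_age_coefficient(params.b, coarse.nodes)
        r0_c = params.kappa2 * float(np.trapezoid(b_c * pi_c, dx=coarse.da))
        est = abs(r0 - r0_c) / (3.0 * max(abs(r0), 1e-300))
        if est > check_rtol:
            warnings.warn(
                f"R0 quadrature error estimate {est:.2e} exceeds {check_rtol:.1e};"
                " refine the age grid",
                stacklevel=2,
            )
    return r0


def endemic_state_homogeneous(
    params: ModelParameters,
    age_grid: AgeGrid | None = None,
    space_grid: SpaceGrid | None = None,
):
    """Closed-form endemic steady state for homogeneous Neumann data.

    Returns a ``SteadyState`` with S* = kappa2 / R0 and
    I*(a) = (kappa1 kappa2 / R0) (1 - 1/R0) Pi(a); requires R0 > 1.
    """
    from .steady_states import SteadyState  # deferred: avoids an import cycle

    ag = age_grid if age_grid is not None else params.default_age_grid()
    r0_val = r0_homogeneous(params, ag, check_rtol=None)
    if r0_val <= 1.0:
        raise NoEndemicStateError(f"no endemic state: R0 = {r0_val:.6g} <= 1")
    pi = survival_on_grid(params, ag)
    s_bar = params.kappa2 / r0_val
    i_profile = (params.kappa1 * params.kappa2 / r0_val) * (1.0 - 1.0 / r0_val) * pi
    n_nodes = space_grid.n_nodes if space_grid is not None else 1
    S = np.full(n_nodes, s_bar)
    I = np.repeat(i_profile[:, None], n_nodes, axis=1)
    return SteadyState(
        kind="endemic",
        S_star=S,
        I_star=I,
        residual_S=None,
        residual_I=None,
        info={"R0": r0_val, "I0": float(i_profile[0]), "age_intervals": ag.n_intervals},
    )
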