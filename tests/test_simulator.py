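"""Time integration: fixed points, positivity, convergence and diagnostics."""

import numpy as np
import pytest

from agestruct_rd import (
    Grids,
    PopulationState,
    endemic_state_homogeneous,
    logistic_solution,
    logistic_upper_bound_check,
    make_age_grid,
    make_space_grid,
    mass_balance_residual,
    simulate,
    step,
    survival_on_grid,
)
from agestruct_rd.scenarios import initial_state, make_scenario, scenario_grids, scenario_params


def space_free_oracle(kappa1, kappa2, m, b, a_m, S0, I0_of_age, T, K):
    """Independent x-free integrator of the age-structured reduction.

    Characteristics marching on its own (much finer) grid; used as the
    reference for spatially homogeneous Neumann runs.
    """
    da = a_m / K
    ages = np.linspace(0.0, a_m, K + 1)
    I = np.asarray(I0_of_age(ages), dtype=float)
    S = float(S0)
    w = np.full(K + 1, da)
    w[0] = w[-1] = 0.5 * da
    for _ in range(int(round(T / da))):
        I_new = np.empty_like(I)
        I_new[1:] = np.exp(-m * da) * I[:-1]
        I_new[0] = S * float((w[1:] * b * I_new[1:]).sum())
        bI = float((w * b * I_new).sum())
        S = S + da * (kappa1 * (1.0 - S / kappa2) * S - S * bI)
        I = I_new
    return S, I


def compatible_initial(params, grids, scale=0.1):
    """Initial data satisfying the renewal condition at t = 0 exactly."""
    pi = survival_on_grid(params, grids.age)
    w = grids.age.trapezoid_weights
    from agestruct_rd.model_core import eval_age_coefficient

    b = eval_age_coefficient(params.b, grids.age.nodes)
    S0 = 1.0 / float(np.sum(w * b * pi))  # then I(0) = S0 int b I da holds
    N = grids.space.n_nodes
    return PopulationState(
        t=0.0, S=np.full(N, S0), I=scale * np.outer(pi, np.ones(N))
    )


class TestStepBasics:
    def test_disease_free_fixed_point(self, homog_params, small_grids):
        p = homog_params()
        N = small_grids.space.n_nodes
        st = PopulationState(0.0, np.full(N, p.kappa2), np.zeros((41, N)))
        out = step(st, p, small_grids, small_grids.age.da)
        assert np.abs(out.S - p.kappa2).max() < 1e-13
        assert np.abs(out.I).max() == 0.0

    def test_trivial_fixed_point(self, homog_params, small_grids):
        p = homog_params()
        N = small_grids.space.n_nodes
        st = PopulationState(0.0, np.zeros(N), np.zeros((41, N)))
        out = step(st, p, small_grids, small_grids.age.da)
        assert np.abs(out.S).max() == 0.0

    def test_wrong_dt_rejected(self, homog_params, small_grids):
        p = homog_params()
        N = small_grids.space.n_nodes
        st = PopulationState(0.0, np.ones(N), np.zeros((41, N)))
        with pytest.raises(ValueError):
            step(st, p, small_grids, 0.5 * small_grids.age.da)

    def test_negative_input_rejected(self, homog_params, small_grids):
        p = homog_params()
        N = small_grids.space.n_nodes
        st = PopulationState(0.0, -np.ones(N), np.zeros((41, N)))
        with pytest.raises(ValueError):
            step(st, p, small_grids, small_grids.age.da)

    def test_endemic_near_fixed_point(self, homog_r0):
        """Endemic formula is a discrete fixed point up to O(da + dx^2).

        The dominant drift is the renewal assignment at age zero (its
        quadrature drops the implicit age-zero node), which is O(da); it must
        also halve under grid refinement.
        """
        drifts = []
        for K in (100, 200):
            params, grids, _ = homog_r0(2.0, n_age=K, n_cells=16)
            state = endemic_state_homogeneous(params, grids.age, grids.space)
            st = PopulationState(0.0, state.S_star, state.I_star)
            out = step(st, params, grids, grids.age.da)
            drift = max(np.abs(out.S - st.S).max(), np.abs(out.I - st.I).max())
            scale = (grids.age.da + grids.space.dx[0] ** 2) * state.I_star.max()
            assert drift < scale
            drifts.append(drift)
        assert drifts[0] / drifts[1] == pytest.approx(2.0, rel=0.2)


class TestPositivityAndStability:
    def test_positivity_preserved(self, homog_r0):
        params, grids, sc = homog_r0(
            2.5, n_age=40, n_cells=12, init_family="perturbed_disease_free", init_amplitude=0.5
        )
        traj = simulate(params, grids, initial_state(sc, grids), T=10.0, save_every=20)
        for st in traj.states:
            assert st.S.min() >= -1e-12
            assert st.I.min() >= -1e-12

    def test_subthreshold_convergence_to_disease_free(self, homog_r0):
        """R0 < 1: solutions converge to (kappa2, 0)."""
        params, grids, sc = homog_r0(
            0.8, n_age=40, n_cells=12, init_family="perturbed_disease_free", init_amplitude=0.3
        )
        traj = simulate(params, grids, initial_state(sc, grids), T=40.0, save_every=200)
        last = traj.states[-1]
        assert np.abs(last.S - params.kappa2).max() < 1e-4
        assert last.I.max() < 1e-4
        # decreasing distance along the trajectory tail
        dists = [np.abs(s.S - params.kappa2).max() + s.I.max() for s in traj.states[1:]]
        assert dists[-1] < dists[0]

    def test_endemic_return_after_perturbation(self, homog_r0):
        """1 < R0 < 3: perturbations of the endemic state decay."""
        params, grids, sc = homog_r0(
            2.0, n_age=80, n_cells=12, init_family="perturbed_endemic", init_amplitude=0.2
        )
        endemic = endemic_state_homogeneous(params, grids.age, grids.space)
        traj = simulate(params, grids, initial_state(sc, grids), T=30.0, save_every=400)

        def dist(s):
            return np.abs(s.S - endemic.S_star).max() + np.abs(s.I - endemic.I_star).max()

        assert dist(traj.states[-1]) < 0.25 * dist(traj.states[0])

    def test_dirichlet_subcritical_growth_decays(self):
        """kappa1 < mu0 (Dirichlet): S decays toward zero."""
        grids = Grids(make_age_grid(2.0, 40), make_space_grid(1.0, 16, 0))
        from agestruct_rd import ModelParameters

        params = ModelParameters(
            kappa1=0.5 * np.pi**2, kappa2=1.0, d=1.0, m=0.5, b=1.0, a_m=2.0, domain=(1.0,), delta=0
        )
        N = grids.space.n_nodes
        x = grids.space.coords
        init = PopulationState(
            0.0, 0.2 * np.sin(np.pi * x), 0.05 * np.outer(np.ones(41), np.sin(np.pi * x))
        )
        traj = simulate(params, grids, init, T=5.0, save_every=20)
        norms = [np.abs(s.S).max() for s in traj.states]
        assert norms[-1] < 0.05 * norms[0]


class TestOracleEquivalence:
    def test_matches_space_free_reduction(self, homog_r0):
        params, grids, _ = homog_r0(2.0, n_age=40, n_cells=8)
        ages = grids.age.nodes
        N = grids.space.n_nodes
        init = PopulationState(
            0.0, np.full(N, 0.8), np.outer(0.1 * np.exp(-0.5 * ages), np.ones(N))
        )
        traj = simulate(params, grids, init, T=4.0, save_every=10**6)
        S_ref, I_ref = space_free_oracle(
            1.0, 1.0, 0.5, params.b, 2.0, 0.8, lambda a: 0.1 * np.exp(-0.5 * a), 4.0, 2560
        )
        last = traj.states[-1]
        # fields stay spatially homogeneous and match the reduction to O(da)
        assert np.ptp(last.S) < 1e-12
        assert abs(last.S[0] - S_ref) < grids.age.da

    def test_first_order_self_convergence(self, homog_r0):
        errs = []
        for K in (40, 80, 160):
            params, grids, _ = homog_r0(2.0, n_age=K, n_cells=8)
            ages = grids.age.nodes
            N = grids.space.n_nodes
            init = PopulationState(
                0.0, np.full(N, 0.8), np.outer(0.1 * np.exp(-0.5 * ages), np.ones(N))
            )
            traj = simulate(params, grids, init, T=4.0, save_every=10**6)
            S_ref, _ = space_free_oracle(
                1.0, 1.0, 0.5, params.b, 2.0, 0.8, lambda a: 0.1 * np.exp(-0.5 * a), 4.0, 2560
            )
            errs.append(abs(traj.states[-1].S[0] - S_ref))
        assert errs[0] / errs[1] == pytest.approx(2.0, rel=0.25)
        assert errs[1] / errs[2] == pytest.approx(2.0, rel=0.25)


class TestMassBalance:
    def test_nothing_flows_machine_zero(self, homog_params, small_grids):
        from agestruct_rd import ModelParameters

        p = ModelParameters(
            kappa1=1.0, kappa2=1.0, d=1.0, m=0.0, b=1e-300, a_m=2.0, domain=(1.0,), delta=1
        )
        N = small_grids.space.n_nodes
        init = PopulationState(0.0, np.full(N, p.kappa2), np.zeros((41, N)))
        traj = simulate(p, small_grids, init, T=1.0)
        res = mass_balance_residual(traj, p, small_grids)
        assert np.abs(res).max() < 1e-12

    def test_first_order_residual_convergence(self, homog_r0):
        """Residual of the balance law shrinks at first order in dt = da."""
        maxima = []
        for K in (20, 40, 80):
            params, grids, _ = homog_r0(2.0, n_age=K, n_cells=16)
            init = compatible_initial(params, grids)
            traj = simulate(params, grids, init, T=1.0)
            res = mass_balance_residual(traj, params, grids)
            maxima.append(np.abs(res).max())
        assert maxima[0] / maxima[1] == pytest.approx(2.0, rel=0.35)
        assert maxima[1] / maxima[2] == pytest.approx(2.0, rel=0.35)

    def test_dirichlet_refused(self):
        from agestruct_rd import ModelParameters

        grids = Grids(make_age_grid(2.0, 20), make_space_grid(1.0, 12, 0))
        params = ModelParameters(
            kappa1=15.0, kappa2=1.0, d=1.0, m=0.5, b=1.0, a_m=2.0, domain=(1.0,), delta=0
        )
        N = grids.space.n_nodes
        init = PopulationState(0.0, 0.1 * np.ones(N), np.zeros((21, N)))
        traj = simulate(params, grids, init, T=0.5)
        with pytest.raises(ValueError):
            mass_balance_residual(traj, params, grids)

    def test_no_age_boundary_outflow_short_horizon(self, homog_r0):
        """I supported away from a_m: outflow term stays machine-small."""
        params, grids, _ = homog_r0(2.0, n_age=40, n_cells=8)
        ages = grids.age.nodes
        N = grids.space.n_nodes
        profile = np.exp(-40.0 * (ages - 0.3) ** 2)
        profile[ages > 1.0] = 0.0
        init = PopulationState(0.0, np.full(N, 0.8), 0.1 * np.outer(profile, np.ones(N)))
        traj = simulate(params, grids, init, T=0.5, save_every=10**6)
        assert traj.states[-1].I[-1].max() < 1e-12


class TestLogisticBound:
    def test_carrying_capacity_tight(self, homog_params, small_grids):
        p = homog_params()
        N = small_grids.space.n_nodes
        init = PopulationState(0.0, np.full(N, p.kappa2), np.zeros((41, N)))
        traj = simulate(p, small_grids, init, T=2.0)
        ok, worst = logistic_upper_bound_check(traj, p, small_grids, tol=1e-10)
        assert ok
        assert abs(worst) < 1e-10  # z = kappa2 and S = kappa2: bound is tight

    def test_below_capacity_stays_below_logistic(self, homog_params, small_grids):
        p = homog_params()
        N = small_grids.space.n_nodes
        x = small_grids.space.coords
        init = PopulationState(
            0.0, 0.4 * p.kappa2 * (1.0 + 0.3 * np.cos(np.pi * x)), np.zeros((41, N))
        )
        traj = simulate(p, small_grids, init, T=5.0, save_every=5)
        ok, worst = logistic_upper_bound_check(traj, p, small_grids)
        assert ok, f"violation {worst}"

    def test_recovery_active_refused(self, small_grids):
        from agestruct_rd import ModelParameters

        p = ModelParameters(
            kappa1=1.0, kappa2=1.0, d=1.0, m=0.5, r=0.3, b=1.0, a_m=2.0, domain=(1.0,), delta=1
        )
        N = small_grids.space.n_nodes
        init = PopulationState(0.0, np.ones(N), np.zeros((41, N)))
        traj = simulate(p, small_grids, init, T=0.5)
        with pytest.raises(ValueError):
            logistic_upper_bound_check(traj, p, small_grids)

    def test_production_cap(self):
        """sup over S >= 0 of k1 (1 - S/k2) S equals k1 k2 / 4."""
        from scipy.optimize import minimize_scalar

        kappa1, kappa2 = 3.0, 7.0
        res = minimize_scalar(
            lambda S: -kappa1 * (1.0 - S / kappa2) * S, bounds=(0.0, 10.0 * kappa2), method="bounded"
        )
        assert -res.fun == pytest.approx(kappa1 * kappa2 / 4.0, rel=1e-9)

    def test_logistic_closed_form_solves_ode(self):
        ts = np.linspace(0.0, 3.0, 31)
        z = logistic_solution(ts, 0.3, 1.2, 2.0)
        dz = np.gradient(z, ts)
        rhs = 1.2 * (1.0 - z / 2.0) * z
        assert np.abs(dz[1:-1] - rhs[1:-1]).max() < 5e-3
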