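# agestruct-rd

Numerical toolkit for an infection-age-structured reaction–diffusion
epidemic model: susceptibles with logistic growth and diffusion, infected
individuals structured by time since infection, a renewal boundary condition
at infection age zero, and Dirichlet or Neumann boundary conditions in
space.

The package provides

* a **simulator** for the nonlinear system, integrating along
  characteristics in (t, a) with an exponential integrating factor for the
  mortality/recovery decay and backward-Euler diffusion — positivity
  preserving by construction, deterministic, first order in the (aligned)
  time/age step and second order in space;
* **steady states**: the trivial state, the disease-free state (constant
  under Neumann conditions; a damped-Newton semilinear solve under
  Dirichlet conditions, which exists exactly when the growth rate exceeds
  the principal Laplacian eigenvalue), the closed-form endemic state of the
  homogeneous Neumann specialization, residual verification of endemic
  candidates, and a seeded fixed-point scan certifying endemic
  non-existence below threshold;
* **spectral machinery**: the evolution operator of the age-parameterized
  diffusion–decay problem, the transmission operators `Q^lambda`, the basic
  reproduction number `R0` as the spectral radius of `S* Q^0` (power
  iteration on a positive matrix), the spectral bound `s` with
  `r(S* Q^s) = 1` (bisection along the strictly decreasing radius curve),
  and a forward-marching solver for the linearized Volterra renewal
  equation;
* **stability classification** of all three steady-state families,
  including per-Laplacian-mode characteristic-equation root finding by
  argument-principle winding with Newton polishing, a dominated-decay
  certificate that silences modes unable to carry right-half-plane roots,
  and an independently assembled discrete linearization matrix used for
  cross-validation.

Thresholds reproduced numerically: the disease-free state loses stability
exactly at `R0 = 1`, and the endemic state is linearly stable throughout
the proved window `1 < R0 < 3` (the mode-0 root scan locates an eventual
Hopf-type crossing near `R0 ≈ 5` for the default parameter family, well
outside that window; verdicts beyond `R0 = 3` are labeled as the
conjectural regime).

## CLI

One TOML file describes one scenario (model parameters, grids, initial
condition, seed). The scenario generator can prescribe `R0` exactly for the
spatially homogeneous Neumann family by closed-form inversion of the
transmission scale.

```bash
agestruct-rd make-scenario --target-r0 2.0 --seed 1 --out run.toml
agestruct-rd r0 --config run.toml
agestruct-rd spectral-bound --config run.toml
agestruct-rd steady-state --config run.toml --out runs/demo
agestruct-rd stability --config run.toml --modes 21
agestruct-rd simulate --config run.toml --out runs/demo
agestruct-rd scan-r0 --from 1.05 --to 6.0 --step 0.05 --modes 21
```

Pipelines (`--out` variants) write plain-text artifacts — CSV fields,
JSON reports and a manifest with a configuration hash; unchanged re-runs
are detected and skipped.

## Layout

```
src/agestruct_rd/
  grids.py          spatial/age grids, Laplacians, eigenpairs, principal eigenvalue
  model_core.py     parameters, coefficient evaluation, survival function, closed forms
  simulator.py      nonlinear time integration + mass-balance / comparison diagnostics
  steady_states.py  disease-free solve, endemic residuals, nonexistence scan
  spectral.py       evolution operator, Q^lambda, spectral radius/bound, Volterra march
  stability.py      characteristic equation, root finding, classifiers, linearization
  scenarios.py      scenario generation, TOML config, pipeline orchestration
  cli.py            agestruct-rd command group
```

Notes on conventions: Neumann grids are cell-centred (the reflecting
ghost-cell closure keeps the Laplacian symmetric), Dirichlet grids drop the
boundary nodes; the time step always equals the age step; all age
integrals use composite trapezoid weights shared by every code path, so
closed-form identities hold to round-off on any grid.
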