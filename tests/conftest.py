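"""Shared fixtures: parameter sets and grids used across the suite."""

import numpy as np
import pytest

from agestruct_rd import (
    Grids,
    HomogeneousParameters,
    make_age_grid,
    make_space_grid,
)
from agestruct_rd.scenarios import make_scenario, scenario_grids, scenario_params


@pytest.fixture
def homog_params():
    """Baseline homogeneous Neumann parameters: k1 = k2 = 1, m = 0.5, a_m = 2."""

    def factory(b=1.0, m=0.5, d=1.0, a_m=2.0, kappa1=1.0, kappa2=1.0, L=1.0):
        return HomogeneousParameters(
            kappa1=kappa1, kappa2=kappa2, d=d, m=m, b=b, a_m=a_m, domain=(L,), delta=1
        )

    return factory


@pytest.fixture
def homog_r0():
    """Homogeneous Neumann scenario with exactly prescribed R0."""

    def factory(target_r0, n_age=100, n_cells=16, **kw):
        sc = make_scenario(target_r0, "homogeneous_neumann", n_age=n_age, n_cells=n_cells, **kw)
        return scenario_params(sc), scenario_grids(sc), sc

    return factory


@pytest.fixture
def neumann_grid():
    return make_space_grid(1.0, 32, 1)


@pytest.fixture
def dirichlet_grid():
    return make_space_grid(1.0, 32, 0)


@pytest.fixture
def small_grids():
    return Grids(age=make_age_grid(2.0, 40), space=make_space_grid(1.0, 12, 1))
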