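"""Shared fixtures: meshes, targets, and the expensive scenario runs.

Scenario solves are session-scoped so the qualitative-behavior tests and
the acceptance suite share one set of runs.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from neurotransport.fields import (ParameterSet, make_mt_density,
                                   solve_predefined_velocity)
from neurotransport.geometry import GeometrySpec, make_synthetic_skeleton
from neurotransport.meshing import build_spline_space, sweep_mesh
from neurotransport.optimizer import solve_pdeco
from neurotransport.scenarios import (parameter_sweep, pipe_config,
                                      run_scenario, swollen_pipe_config,
                                      tree_config)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pipe_setup():
    """Standard 80 x 4 um pipe: skeleton, mesh, quadratic spline space."""
    skel = make_synthetic_skeleton(
        GeometrySpec("pipe", length=80.0, base_radius=2.0, spacing=10.0)
    )
    mesh = sweep_mesh(skel, n_transverse=4, axial_density=0.25)
    space = build_spline_space(mesh, degree=2)
    return skel, mesh, space


@pytest.fixture(scope="session")
def pipe_target(pipe_setup):
    _, _, space = pipe_setup
    return solve_predefined_velocity(space, 1.0)


@pytest.fixture(scope="session")
def steady_params():
    return ParameterSet()


@pytest.fixture(scope="session")
def steady_uniform_solution(pipe_setup, pipe_target, steady_params):
    """Converged steady optimization on the uniform (healthy) pipe."""
    _, _, space = pipe_setup
    mt = make_mt_density(space, "uniform", params=steady_params)
    return solve_pdeco(space, steady_params, mt, pipe_target)


@pytest.fixture(scope="session")
def pipe_normal_result():
    return run_scenario(pipe_config("normal"))


@pytest.fixture(scope="session")
def pipe_reduced_result():
    return run_scenario(pipe_config("reduced_mt"))


@pytest.fixture(scope="session")
def pipe_sweep():
    """Alpha/beta/k-ratio sweeps on the reduced-MT pipe (shared runs)."""
    return parameter_sweep(pipe_config("reduced_mt"))


@pytest.fixture(scope="session")
def swirl_result():
    return run_scenario(swollen_pipe_config("swirl"))


@pytest.fixture(scope="session")
def tree_results():
    """Normal and jammed runs on the 5-outlet tree (shared mesh/target)."""
    normal = run_scenario(tree_config("normal"))
    jam = run_scenario(tree_config("reduced_mt"))
    return normal, jam


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
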