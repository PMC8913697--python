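"""All-at-once KKT assembly, gradient verification and the solver."""

import numpy as np
import pytest

from neurotransport.errors import ConfigurationError
from neurotransport.fields import (ParameterSet, make_mt_density,
                                   solve_predefined_velocity)
from neurotransport.meshing import build_spline_space, sweep_mesh
from neurotransport.optimizer import (AdjointFields, SolverOptions,
                                      assemble_kkt,
                                      finite_difference_gradient_check,
                                      forward_solve, n_unknown_field_groups,
                                      solve_pdeco)
from neurotransport.transport_pde import (ControlFields, StateFields,
                                          TransportSystem)


def test_unknown_field_group_counts():
    """The bidirectional model carries exactly 7 unknown field groups
    (n0, n+, n-, v+, v-, f+, f-); unidirectional exactly 4."""
    assert n_unknown_field_groups(ParameterSet(mode="bidirectional")) == 7
    assert n_unknown_field_groups(ParameterSet()) == 4


def test_gradient_check_on_pipe(pipe_setup, pipe_target):
    """Assembled Lagrangian gradients match central finite differences to
    better than 1e-5 along random directions."""
    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    err = finite_difference_gradient_check(space, params, mt, pipe_target,
                                           epsilon=1e-6)
    assert err < 1e-5


def test_gradient_check_quadratic_lagrangian_is_fd_exact(pipe_setup,
                                                         pipe_target):
    """With the stabilization frozen at the target velocity the Lagrangian
    is exactly quadratic in (state, control) at fixed adjoint, so central
    differences are exact to roundoff."""
    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    sys_ = TransportSystem(space, params, mt, pipe_target)
    rng = np.random.default_rng(2)
    xv = sys_.reduce(sys_.initial_state(), sys_.sfields)
    uv = 0.1 * rng.standard_normal(sys_.nc_red)
    pv = np.zeros(sys_.ns_red)
    err = finite_difference_gradient_check(space, params, mt, pipe_target,
                                           iterate=(xv, uv, pv),
                                           epsilon=1e-4)
    assert err < 1e-9


def test_fd_error_scales_quadratically_along_joint_directions(pipe_setup,
                                                              pipe_target):
    """The Lagrangian is cubic along joint state–adjoint directions, so
    for large FD steps the central-difference discrepancy grows like
    epsilon^2 (Richardson slope 2 on a log-log fit)."""
    from neurotransport import optimizer as O

    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    sys_ = TransportSystem(space, params, mt, pipe_target)
    rng = np.random.default_rng(4)
    ns, nc = sys_.ns_red, sys_.nc_red
    xv = sys_.reduce(sys_.initial_state(), sys_.sfields)
    uv = np.zeros(nc)
    pv = rng.standard_normal(ns)

    def L(x, u, p):
        return (sys_.objective(sys_.expand_state(x),
                               sys_.expand_control(u)).total
                + p @ sys_.residual_reduced(x, u))

    g, _, _ = O._kkt_residual(sys_, xv, uv, pv)
    d = rng.standard_normal(2 * ns + nc)
    d *= 20.0 / np.linalg.norm(d)
    eps = np.array([0.02, 0.04, 0.08])
    errs = []
    for e in eps:
        fd = (L(xv + e * d[:ns], uv + e * d[ns:ns + nc],
                pv + e * d[ns + nc:])
              - L(xv - e * d[:ns], uv - e * d[ns:ns + nc],
                  pv - e * d[ns + nc:])) / (2 * e)
        errs.append(abs(fd - g @ d))
    slope = np.polyfit(np.log(eps), np.log(errs), 1)[0]
    assert 1.8 < slope < 2.2


def test_kkt_rhs_vanishes_at_manufactured_stationary_point(pipe_setup):
    """Compatible boundary data (n_out = n_in, lambda_in = k/k') and zero
    target make the uniform state with f = p = 0 exactly KKT-stationary."""
    _, _, space = pipe_setup
    c = 0.7
    params = ParameterSet(n_in=c, n_out=c, lambda_in=10.0, lambda_out=10.0)
    mt = make_mt_density(space, "uniform", params=params)
    target = solve_predefined_velocity(space, 0.0, params)
    n = space.n_dofs
    state = StateFields(n0=np.full(n, c), n_plus=np.full(n, 10 * c),
                        v_plus=(np.zeros(n), np.zeros(n)))
    control = ControlFields.zeros(n)
    adjoint = AdjointFields(np.zeros(n), np.zeros(n),
                            (np.zeros(n), np.zeros(n)))
    kkt = assemble_kkt(space, params, mt, (state, control, adjoint), target)
    assert np.linalg.norm(kkt.rhs) < 1e-8


def test_kkt_matrix_blocks_match_fd_directional_derivatives(pipe_setup,
                                                            pipe_target):
    """Each KKT matrix block times a random vector matches a central finite
    difference of the corresponding KKT-residual block."""
    from neurotransport import optimizer as O

    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "reduced", params=params,
                         region=(0, 30.0, 50.0), depth=0.5)
    sys_ = TransportSystem(space, params, mt, pipe_target)
    rng = np.random.default_rng(12)
    ns, nc = sys_.ns_red, sys_.nc_red
    xv = sys_.reduce(sys_.initial_state(), sys_.sfields) \
        + 0.1 * rng.standard_normal(ns)
    uv = 0.1 * rng.standard_normal(nc)
    pv = rng.standard_normal(ns)
    g0, Ax, Au = O._kkt_residual(sys_, xv, uv, pv)
    K, _, _ = O._kkt_matrix(sys_, xv, pv, Ax, Au)
    z = np.concatenate([xv, uv, pv])

    def g(zz):
        return O._kkt_residual(sys_, zz[:ns], zz[ns:ns + nc],
                               zz[ns + nc:])[0]

    eps = 1e-6
    for _ in range(4):
        dz = rng.standard_normal(len(z))
        dz /= np.linalg.norm(dz)
        fd = (g(z + eps * dz) - g(z - eps * dz)) / (2 * eps)
        an = K @ dz
        assert np.abs(fd - an).max() / max(1.0, np.abs(an).max()) < 1e-5


def test_kkt_matrix_symmetric_for_the_frozen_linear_subproblem(pipe_setup):
    """At a zero iterate (no convection, zero adjoint, zero target) the
    saddle-point matrix is exactly symmetric."""
    from neurotransport import optimizer as O

    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    sys_ = TransportSystem(space, params, mt, None)
    ns, nc = sys_.ns_red, sys_.nc_red
    xv, uv, pv = np.zeros(ns), np.zeros(nc), np.zeros(ns)
    _, Ax, Au = O._kkt_residual(sys_, xv, uv, pv)
    K, _, _ = O._kkt_matrix(sys_, xv, pv, Ax, Au)
    diff = (K - K.T).tocoo()
    denom = np.abs(K.data).max()
    assert (np.abs(diff.data).max() if diff.nnz else 0.0) / denom < 1e-10


def test_steady_pipe_solve_reaches_kkt_tolerance(steady_uniform_solution):
    sol = steady_uniform_solution
    assert sol.converged
    assert sol.history[-1] <= 1e-7
    assert sol.objective.total == pytest.approx(
        sol.objective.tracking_term + sol.objective.gradient_term
        + sol.objective.control_term)


def test_solver_is_deterministic(pipe_setup, pipe_target):
    """Two runs from the same configuration produce bitwise-identical
    convergence histories."""
    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    a = solve_pdeco(space, params, mt, pipe_target, SolverOptions())
    b = solve_pdeco(space, params, mt, pipe_target, SolverOptions())
    assert np.array_equal(a.history, b.history)
    assert np.array_equal(a.state.n_plus, b.state.n_plus)


def test_large_beta_limit_recovers_forward_solution(pipe_setup):
    """At beta = 1e6 the optimization reproduces the uncontrolled forward
    transient to 1e-3 relative in every state norm, and the control force
    is negligible against the target velocity."""
    _, _, space = pipe_setup
    params = ParameterSet(n_time_steps=4, T_horizon=2.0)
    mt = make_mt_density(space, "uniform", params=params)
    target = solve_predefined_velocity(space, 1.0, params)
    fwd = forward_solve(space, params, mt, target)
    sol = solve_pdeco(space, params.with_(beta=1e6), mt, target)
    assert sol.converged

    def rel(a, b):
        return np.linalg.norm(a - b) / max(np.linalg.norm(b), 1e-12)

    assert rel(sol.state.n0, fwd.n0) < 1e-3
    assert rel(sol.state.n_plus, fwd.n_plus) < 1e-3
    assert rel(sol.state.v_plus[0], fwd.v_plus[0]) < 1e-3
    f_norm = np.linalg.norm(np.concatenate(sol.control.f_plus))
    v_norm = np.linalg.norm(np.concatenate([target.vx_plus, target.vy_plus]))
    assert f_norm < 1e-3 * v_norm


def test_objective_total_stable_under_mesh_refinement(pipe_setup):
    """In the study configuration (transient pipe) the converged objective
    changes by < 5% between successive uniform refinements."""
    skel, _, _ = pipe_setup
    params = ParameterSet(n_time_steps=8, T_horizon=20.0)
    totals = []
    for ntr, dens in ((6, 0.5), (8, 1.0)):
        mesh = sweep_mesh(skel, n_transverse=ntr, axial_density=dens)
        space = build_spline_space(mesh, 2)
        mt = make_mt_density(space, "uniform", params=params)
        vt = solve_predefined_velocity(space, 1.0)
        sol = solve_pdeco(space, params, mt, vt)
        assert sol.converged
        totals.append(sol.objective.total)
    assert abs(totals[1] - totals[0]) / totals[0] < 0.05


def test_large_alpha_suppresses_concentration_gradients(pipe_setup,
                                                        pipe_target):
    """Raising alpha tenfold monotonically lowers the converged
    concentration-gradient energy."""
    _, _, space = pipe_setup
    energies = []
    for alpha in (1.0, 10.0, 100.0):
        params = ParameterSet(alpha=alpha)
        mt = make_mt_density(space, "uniform", params=params)
        sol = solve_pdeco(space, params, mt, pipe_target)
        assert sol.converged
        energies.append(sol.objective.gradient_term / (alpha / 2.0))
    assert energies[0] > energies[1] > energies[2]


def test_objective_monotone_once_nearly_feasible(steady_uniform_solution):
    """With the line search active, the objective is non-increasing over
    the Newton tail where the KKT residual has dropped below 1e-4."""
    sol = steady_uniform_solution
    mask = sol.history < 1e-4
    tail = sol.objective_history[mask]
    assert len(tail) >= 1
    assert np.all(np.diff(tail) <= 1e-8 * max(tail.max(), 1.0))


def test_solver_options_validation():
    with pytest.raises(ConfigurationError):
        SolverOptions(kkt_tolerance=0.0)
    with pytest.raises(ConfigurationError):
        SolverOptions(preconditioner="magic")


def test_unconverged_run_reports_instead_of_raising(pipe_setup, pipe_target):
    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    sol = solve_pdeco(space, params, mt, pipe_target,
                      SolverOptions(max_newton_iterations=1))
    assert not sol.converged
    assert len(sol.history) >= 1
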