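"""Weak-form constraint residuals and the traffic-regulation objective."""

import numpy as np
import pytest

from neurotransport import splines
from neurotransport.errors import ConfigurationError
from neurotransport.fields import ParameterSet, make_mt_density
from neurotransport.geometry import GeometrySpec, Skeleton, SkeletonNode, \
    make_synthetic_skeleton
from neurotransport.meshing import build_spline_space, project, sweep_mesh
from neurotransport.transport_pde import (ControlFields, StateFields,
                                          TransportSystem,
                                          assemble_constraint_residual,
                                          evaluate_objective)


def _uniform_state(n, c0=0.5, ratio=10.0):
    return StateFields(n0=np.full(n, c0), n_plus=np.full(n, ratio * c0),
                       v_plus=(np.zeros(n), np.zeros(n)))


def test_uniform_reaction_balance_annihilates_interior_residual(pipe_setup):
    """n+ = (k+/(k'+ l+)) n0 = 10 n0 with default rates and v = f = 0 is a
    pointwise steady balance; every non-Dirichlet residual row vanishes."""
    _, _, space = pipe_setup
    params = ParameterSet()
    mt = make_mt_density(space, "uniform", params=params)
    n = space.n_dofs
    state = _uniform_state(n)
    control = ControlFields.zeros(n)
    sys_ = TransportSystem(space, params, mt)
    blocks = sys_.residual_blocks(sys_.state_to_dict(state),
                                  sys_.control_to_dict(control))
    for b in sys_.blocks:
        free = sys_.free[sys_.block_field[b]]
        assert np.abs(blocks[b][free]).max() < 1e-10


def test_zero_fields_zero_boundary_data_zero_residual(pipe_setup):
    _, _, space = pipe_setup
    params = ParameterSet(n_in=0.0, n_out=0.0)
    mt = make_mt_density(space, "uniform", params=params)
    n = space.n_dofs
    res = assemble_constraint_residual(
        space, params, mt, StateFields.zeros(n), ControlFields.zeros(n))
    assert np.abs(res).max() < 1e-14


def test_pure_advection_matches_independent_quadrature_oracle(pipe_setup):
    """With D = 0, k = k' = 0, constant v and linear n+, the moving-pool
    residual reduces to the pure-advection Galerkin vector; an independent
    per-patch Gauss quadrature of int phi_i dA reproduces it to 1e-10."""
    _, mesh, space = pipe_setup
    params = ParameterSet(D_plus=0.0, k_plus=0.0, kprime_plus=0.0,
                          n_in=0.0, n_out=0.0)
    mt = make_mt_density(space, "uniform", params=params)
    n = space.n_dofs
    vconst, slope = 0.7, 0.03
    npl = project(space, lambda x, y: slope * x)
    state = StateFields(n0=np.zeros(n), n_plus=npl,
                        v_plus=(np.full(n, vconst), np.zeros(n)))
    res = assemble_constraint_residual(space, params, mt, state,
                                       ControlFields.zeros(n))
    bp = res[n:2 * n]

    # oracle: v . grad(w) = vconst * slope everywhere, so the residual is
    # (vconst * slope) int phi_i dA, with the basis integrals from a dense
    # 1D Gauss rule per patch direction (independent of element caches)
    phi_int = np.zeros(n)
    g, w = np.polynomial.legendre.leggauss(6)

    def cellwise_integral(n_cells):
        # per-cell Gauss (the basis is only piecewise polynomial)
        allx = np.concatenate(
            [(c + (g + 1) / 2) / n_cells for c in range(n_cells)]
        )
        allw = np.tile(w / 2 / n_cells, n_cells)
        B, _ = splines.basis_values(n_cells, space.degree, allx)
        return allw @ B

    for pi, patch in enumerate(mesh.patches):
        Lx = patch.length
        Ly = 2.0  # half-tube height: radius 2 over t in [0, 1]
        iu = cellwise_integral(patch.n_ax) * Lx
        iv = cellwise_integral(patch.n_tr) * Ly
        grid = space.patch_dof_grids[pi]
        np.add.at(phi_int, grid.ravel(), np.outer(iu, iv).ravel())
    expected = vconst * slope * phi_int
    inlet = space.dirichlet_dofs("inlet")
    free = np.setdiff1d(np.arange(n), inlet)
    assert np.abs(bp[free] - expected[free]).max() < 1e-10


def test_transient_mode_requires_previous_state(pipe_setup):
    _, _, space = pipe_setup
    params = ParameterSet(n_time_steps=4, T_horizon=2.0)
    mt = make_mt_density(space, "uniform", params=params)
    n = space.n_dofs
    with pytest.raises(ConfigurationError):
        assemble_constraint_residual(space, params, mt,
                                     StateFields.zeros(n),
                                     ControlFields.zeros(n))


def test_state_mode_mismatch_is_configuration_error(pipe_setup):
    _, _, space = pipe_setup
    params = ParameterSet(mode="bidirectional")
    mt = make_mt_density(space, "uniform", params=params)
    n = space.n_dofs
    with pytest.raises(ConfigurationError):
        assemble_constraint_residual(space, params, mt,
                                     StateFields.zeros(n, bidirectional=False),
                                     ControlFields.zeros(n))


# -- objective ---------------------------------------------------------------

def test_objective_perfect_tracking_is_zero(pipe_setup, pipe_target):
    _, _, space = pipe_setup
    n = space.n_dofs
    state = StateFields(n0=np.full(n, 0.3), n_plus=np.full(n, 1.0),
                        v_plus=(pipe_target.vx_plus.copy(),
                                pipe_target.vy_plus.copy()))
    ob = evaluate_objective(space, ParameterSet(), state,
                            ControlFields.zeros(n), pipe_target)
    assert ob.tracking_term < 1e-20
    assert ob.gradient_term < 1e-20
    assert ob.control_term == 0.0
    assert ob.total == pytest.approx(ob.tracking_term + ob.gradient_term
                                     + ob.control_term)


def test_objective_constant_offsets_closed_form(pipe_setup, pipe_target):
    """v - V = 1 in one component and f = 1 on the 320 um^2 pipe give
    tracking = control = 1/2 * 1 * 320 = 160 and zero gradient term."""
    _, _, space = pipe_setup
    n = space.n_dofs
    state = StateFields(n0=np.full(n, 0.3), n_plus=np.full(n, 1.0),
                        v_plus=(pipe_target.vx_plus + 1.0,
                                pipe_target.vy_plus.copy()))
    control = ControlFields((np.ones(n), np.zeros(n)))
    ob = evaluate_objective(space, ParameterSet(), state, control,
                            pipe_target)
    assert ob.tracking_term == pytest.approx(160.0, rel=1e-12)
    assert ob.control_term == pytest.approx(160.0, rel=1e-12)
    assert ob.gradient_term < 1e-20


def test_objective_monte_carlo_quadrature_oracle(pipe_setup, pipe_target):
    """Quasi-random fields: the assembled objective matches a Monte-Carlo
    estimate of the three integrals within 0.5%."""
    _, mesh, space = pipe_setup
    n = space.n_dofs
    r = np.random.default_rng(11)
    smooth = project(space, lambda x, y: 0.4 * np.sin(0.1 * x)
                     * np.cos(0.6 * y) + 0.1 * y)
    state = StateFields(
        n0=np.full(n, 0.2),
        n_plus=smooth,
        v_plus=(pipe_target.vx_plus + 0.5 * smooth,
                pipe_target.vy_plus - 0.3 * smooth),
    )
    control = ControlFields((0.7 * smooth, 0.2 + 0.0 * smooth))
    params = ParameterSet(alpha=1.3, beta=0.8)
    ob = evaluate_objective(space, params, state, control, pipe_target)

    bot, top = mesh.branches[0]["patch_indices"]

    def field_at(coefs, x, y):
        u = x / 80.0
        out = np.empty_like(x)
        lo = y <= 0
        out[lo] = space.evaluate_patch(bot, u[lo], (y[lo] + 2) / 2, coefs)
        out[~lo] = space.evaluate_patch(top, u[~lo], y[~lo] / 2, coefs)
        return out

    N = 120_000
    x = r.uniform(1e-3, 80 - 1e-3, N)
    y = r.uniform(-2 + 1e-3, 2 - 1e-3, N)
    area = 320.0
    dvx = field_at(state.v_plus[0], x, y) - field_at(pipe_target.vx_plus, x, y)
    dvy = field_at(state.v_plus[1], x, y) - field_at(pipe_target.vy_plus, x, y)
    track_mc = 0.5 * area * np.mean(dvx**2 + dvy**2)
    h = 1e-4
    gx = (field_at(state.n_plus, x + h, y)
          - field_at(state.n_plus, x - h, y)) / (2 * h)
    gy = (field_at(state.n_plus, x, y + h)
          - field_at(state.n_plus, x, y - h)) / (2 * h)
    grad_mc = 0.5 * params.alpha * area * np.mean(gx**2 + gy**2)
    fx = field_at(control.f_plus[0], x, y)
    fy = field_at(control.f_plus[1], x, y)
    ctrl_mc = 0.5 * params.beta * area * np.mean(fx**2 + fy**2)
    total_mc = track_mc + grad_mc + ctrl_mc
    assert ob.total == pytest.approx(total_mc, rel=5e-3)


def test_penalty_linearity(pipe_setup, pipe_target):
    """Doubling alpha doubles the gradient term; doubling beta doubles the
    control term; the other terms are unchanged."""
    _, _, space = pipe_setup
    n = space.n_dofs
    smooth = project(space, lambda x, y: np.sin(0.1 * x) + 0.2 * y)
    state = StateFields(n0=np.full(n, 0.1), n_plus=smooth,
                        v_plus=(pipe_target.vx_plus + 0.1,
                                pipe_target.vy_plus.copy()))
    control = ControlFields((0.3 * smooth, np.zeros(n)))
    o1 = evaluate_objective(space, ParameterSet(alpha=1.0, beta=1.0),
                            state, control, pipe_target)
    o2 = evaluate_objective(space, ParameterSet(alpha=2.0, beta=2.0),
                            state, control, pipe_target)
    assert o2.gradient_term == pytest.approx(2 * o1.gradient_term, rel=1e-12)
    assert o2.control_term == pytest.approx(2 * o1.control_term, rel=1e-12)
    assert o2.tracking_term == pytest.approx(o1.tracking_term, rel=1e-12)


def test_objective_invariant_under_rigid_translation():
    """The same coefficient vectors on a translated pipe give the same
    objective."""
    def build(offset):
        sk0 = make_synthetic_skeleton(
            GeometrySpec("pipe", length=40, base_radius=2, spacing=10))
        nodes = [SkeletonNode(nd.node_id, nd.structure_type,
                              nd.position + offset, nd.radius, nd.parent_id)
                 for nd in sk0.nodes.values()]
        mesh = sweep_mesh(Skeleton(nodes), 4, 0.25)
        return build_spline_space(mesh, 2)

    sp_a = build(np.array([0.0, 0.0]))
    sp_b = build(np.array([13.0, -41.0]))
    n = sp_a.n_dofs
    assert sp_b.n_dofs == n
    r = np.random.default_rng(5)
    coefs = r.normal(size=n)
    state = StateFields(n0=np.full(n, 0.2), n_plus=coefs,
                        v_plus=(0.5 * coefs, np.zeros(n)))
    control = ControlFields((coefs, 0.1 * coefs))
    oa = evaluate_objective(sp_a, ParameterSet(), state, control)
    ob = evaluate_objective(sp_b, ParameterSet(), state, control)
    assert ob.total == pytest.approx(oa.total, rel=1e-10)


def test_steady_global_balance(steady_uniform_solution, pipe_setup,
                               pipe_target):
    """Converged steady state: the advective exchange of l+ n+ minus the
    reactive exchange with the free pool equals the weak boundary flux
    carried by the constrained inlet/outlet rows, to 1% of the gross
    reactive turnover.

    The advective and reactive volume integrals are recomputed by an
    independent Monte-Carlo quadrature (bulk patch evaluation + finite
    differences); the weak boundary term is the summed raw Galerkin
    residual at the Dirichlet rows.  (The governing advection is in
    non-conservative form, so a pointwise surface-flux statement does not
    close; the weak statement is what the scheme conserves.)"""
    _, mesh, space = pipe_setup
    sol = steady_uniform_solution
    assert sol.converged
    st = sol.state
    p = ParameterSet()
    mt = make_mt_density(space, "uniform", params=p)
    sys_ = TransportSystem(space, p, mt, pipe_target)
    raw = sys_.residual_blocks(sys_.state_to_dict(st),
                               sys_.control_to_dict(sol.control),
                               replace_dirichlet=False)
    weak_boundary = float(raw["bp"].sum())

    bot, top = mesh.branches[0]["patch_indices"]

    def field_at(coefs, x, y):
        u = x / 80.0
        out = np.empty_like(x)
        lo = y <= 0
        out[lo] = space.evaluate_patch(bot, u[lo], (y[lo] + 2) / 2, coefs)
        out[~lo] = space.evaluate_patch(top, u[~lo], y[~lo] / 2, coefs)
        return out

    r = np.random.default_rng(17)
    N = 150_000
    x = r.uniform(1e-3, 80 - 1e-3, N)
    y = r.uniform(-2 + 1e-3, 2 - 1e-3, N)
    area = 320.0
    h = 1e-4
    gx = (field_at(st.n_plus, x + h, y)
          - field_at(st.n_plus, x - h, y)) / (2 * h)
    gy = (field_at(st.n_plus, x, y + h)
          - field_at(st.n_plus, x, y - h)) / (2 * h)
    vx = field_at(st.v_plus[0], x, y)
    vy = field_at(st.v_plus[1], x, y)
    adv_mc = area * np.mean(vx * gx + vy * gy)
    n0v = field_at(st.n0, x, y)
    wv = field_at(st.n_plus, x, y)
    react_mc = area * np.mean(p.k_plus * n0v - p.kprime_plus * wv)
    turnover = area * np.mean(np.abs(p.k_plus * n0v)
                              + np.abs(p.kprime_plus * wv))
    assert abs(adv_mc - react_mc - weak_boundary) / turnover < 0.01
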