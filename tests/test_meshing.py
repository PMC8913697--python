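"""Swept meshing, spline spaces and the isoparametric map."""

import math

import numpy as np
import pytest
from scipy.spatial import cKDTree

from neurotransport.errors import MeshingError
from neurotransport.geometry import (GeometrySpec, make_synthetic_skeleton,
                                     swelling_radius_profile)
from neurotransport.meshing import (build_spline_space, evaluate_geometry,
                                    project, sweep_mesh, _invert_bilinear)


@pytest.fixture(scope="module")
def tree_setup():
    br = [(-1, 30.0, 0.0, 2.0), (0, 25.0, 0.6, 1.8), (0, 30.0, -0.7, 1.8),
          (1, 20.0, 0.55, 1.5), (1, 20.0, -0.55, 1.5)]
    sk = make_synthetic_skeleton(GeometrySpec("tree", branches=br, spacing=4))
    mesh = sweep_mesh(sk, 4, 0.25)
    return mesh, build_spline_space(mesh, 2)


def test_pipe_mesh_counts_and_area(pipe_setup):
    _, mesh, _ = pipe_setup
    assert mesh.n_elements == 20 * 4
    assert mesh.area() == pytest.approx(80 * 4, abs=1e-9)


def test_swollen_pipe_area_matches_radius_integral_oracle():
    """Mesh area equals the straight-pipe area plus the 1D integral of the
    excess diameter, computed independently from the skeleton's
    piecewise-linear radius profile."""
    spec = GeometrySpec("swollen_pipe", length=80, base_radius=2, spacing=1,
                        swelling=(40.0, 20.0, 2.0))
    sk = make_synthetic_skeleton(spec)
    mesh = sweep_mesh(sk, 4, axial_density=1.0)
    # oracle: fine trapezoid of 2 r(s) over the piecewise-linear node radii
    nodes = sorted(sk.nodes.values(), key=lambda nd: nd.position[0])
    s_nodes = np.array([nd.position[0] for nd in nodes])
    r_nodes = np.array([nd.radius for nd in nodes])
    s_fine = np.linspace(0, 80, 40001)
    area_oracle = np.trapezoid(2 * np.interp(s_fine, s_nodes, r_nodes),
                               s_fine)
    assert mesh.area() == pytest.approx(area_oracle, rel=2e-3)


def test_swollen_pipe_area_converges_to_analytic_at_second_order():
    prof = swelling_radius_profile(2.0, (40.0, 20.0, 2.0))
    s_fine = np.linspace(0, 80, 200001)
    exact = np.trapezoid(2 * prof(s_fine), s_fine)
    for spacing, dens in ((2.0, 0.5), (1.0, 1.0), (0.5, 2.0)):
        spec = GeometrySpec("swollen_pipe", length=80, base_radius=2,
                            spacing=spacing, swelling=(40.0, 20.0, 2.0))
        mesh = sweep_mesh(make_synthetic_skeleton(spec), 4, dens)
        # comfortably inside a second-order bound C h^2 with C ~ O(1);
        # the trapezoid telescoping over the C1 bump makes the actual
        # error superconvergent
        assert abs(mesh.area() - exact) < 1e-2 * spacing**2
        assert abs(mesh.area() - exact) < 1e-6


def test_bifurcation_mesh_mirror_symmetry():
    spec = GeometrySpec("bifurcation", length=40, base_radius=2, spacing=5,
                        angles=(math.pi / 6, -math.pi / 6),
                        child_lengths=(40, 40))
    mesh = sweep_mesh(make_synthetic_skeleton(spec), 4, 0.25)
    V = mesh.vertices
    d, _ = cKDTree(V).query(V * np.array([1.0, -1.0]))
    assert d.max() < 1e-9
    assert mesh.min_jacobian() > 0


def test_degree_one_dof_count_matches_tensor_count():
    """A 2 x 2-cell pipe with a linear basis carries 9 global dofs (the
    3 x 3 tensor grid, seam dofs shared)."""
    sk = make_synthetic_skeleton(GeometrySpec("pipe", length=8, base_radius=2,
                                              spacing=4))
    mesh = sweep_mesh(sk, n_transverse=2, axial_density=0.25)
    assert mesh.n_elements == 4
    space = build_spline_space(mesh, degree=1)
    assert space.n_dofs == 9


@pytest.mark.parametrize("degree", [1, 2])
def test_partition_of_unity_and_gradient_sum(pipe_setup, degree):
    _, mesh, _ = pipe_setup
    space = build_spline_space(mesh, degree)
    assert np.abs(space.PHI.sum(axis=2) - 1.0).max() < 1e-12
    assert np.abs(space.DPHI.sum(axis=2)).max() < 1e-10


def test_linear_reproduction_on_affine_patches(pipe_setup):
    _, _, space = pipe_setup
    c = project(space, lambda x, y: x + 2 * y)
    r = np.random.default_rng(3)
    pts = np.stack([r.uniform(0.5, 79.5, 40), r.uniform(-1.9, 1.9, 40)],
                   axis=1)
    vals = space.evaluate_at_points(c, pts)
    assert np.abs(vals - (pts[:, 0] + 2 * pts[:, 1])).max() < 1e-10


def test_evaluate_geometry_affine_map(pipe_setup):
    _, mesh, space = pipe_setup
    pt, J, det = evaluate_geometry(space, 0, (0.0, 0.0))
    corners = mesh.element_corners(0)
    assert np.allclose(pt, corners.mean(axis=0))
    # bi-unit reference: det = element area / 4
    assert det == pytest.approx(4.0 * 1.0 / 4.0)


def test_evaluate_geometry_translation_invariance():
    sk = make_synthetic_skeleton(GeometrySpec("pipe", length=20,
                                              base_radius=2, spacing=5))
    mesh = sweep_mesh(sk, 2, 0.25)
    space = build_spline_space(mesh, 2)
    _, J0, d0 = evaluate_geometry(space, 1, (0.3, -0.4))
    mesh.vertices += np.array([5.0, -7.0])
    _, J1, d1 = evaluate_geometry(space, 1, (0.3, -0.4))
    assert np.allclose(J0, J1)
    assert d0 == pytest.approx(d1)


def test_evaluate_geometry_det_matches_finite_difference(tree_setup):
    """On a genuinely non-affine (junction) element the Jacobian matches a
    finite-difference of the map."""
    mesh, space = tree_setup
    # pick a junction element
    e = next(i for i in range(mesh.n_elements)
             if mesh.patches[mesh.elem_patch[i]].kind == "junction")
    xi, eta = 0.21, -0.37
    _, J, det = evaluate_geometry(space, e, (xi, eta))
    h = 1e-6
    px1, _, _ = evaluate_geometry(space, e, (xi + h, eta))
    px0, _, _ = evaluate_geometry(space, e, (xi - h, eta))
    py1, _, _ = evaluate_geometry(space, e, (xi, eta + h))
    py0, _, _ = evaluate_geometry(space, e, (xi, eta - h))
    J_fd = np.stack([(px1 - px0) / (2 * h), (py1 - py0) / (2 * h)], axis=1)
    assert np.abs(J - J_fd).max() < 1e-6
    det_fd = J_fd[0, 0] * J_fd[1, 1] - J_fd[0, 1] * J_fd[1, 0]
    assert det == pytest.approx(det_fd, rel=1e-6)


def test_evaluate_geometry_rejects_outside_reference_square(pipe_setup):
    _, _, space = pipe_setup
    with pytest.raises(MeshingError):
        evaluate_geometry(space, 0, (1.5, 0.0))


def test_junction_conformity_fields_continuous(tree_setup):
    """An interpolated smooth field has no jump across patch interfaces."""
    mesh, space = tree_setup
    c = project(space, lambda x, y: np.sin(0.07 * x) * np.cos(0.05 * y))
    from collections import defaultdict

    edge_owner = defaultdict(list)
    for e, q in enumerate(mesh.quads):
        for k in range(4):
            a, b = q[k], q[(k + 1) % 4]
            edge_owner[(min(a, b), max(a, b))].append(e)
    worst = 0.0
    n_checked = 0
    for (a, b), els in edge_owner.items():
        if len(els) != 2 or mesh.elem_patch[els[0]] == mesh.elem_patch[els[1]]:
            continue
        p0, p1 = mesh.vertices[a], mesh.vertices[b]
        for t in (0.3, 0.7):
            pt = p0 + t * (p1 - p0)
            vals = []
            for e in els:
                ref = _invert_bilinear(mesh.element_corners(e), pt)
                if ref is not None:
                    vals.append(space.evaluate(c, e, *ref))
            if len(vals) == 2:
                worst = max(worst, abs(vals[0] - vals[1]))
                n_checked += 1
    assert n_checked > 50
    assert worst < 1e-10


def test_meshing_rejects_odd_transverse_count(pipe_setup):
    skel, _, _ = pipe_setup
    with pytest.raises(MeshingError):
        sweep_mesh(skel, n_transverse=3)
    with pytest.raises(MeshingError):
        sweep_mesh(skel, n_transverse=1)


def test_boundary_tags_cover_inlet_outlets_walls(pipe_setup):
    _, mesh, space = pipe_setup
    tags = {t for _, _, t in mesh.boundary_edges}
    assert "inlet" in tags and "wall" in tags
    assert any(t.startswith("outlet:") for t in tags)
    assert space.edge_length("inlet") == pytest.approx(4.0, abs=1e-12)
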