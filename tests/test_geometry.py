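"""Skeleton I/O, cleaning and synthetic geometry construction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from neurotransport.errors import (GeometrySpecError, SkeletonError,
                                   SWCParseError)
from neurotransport.geometry import (GeometrySpec, Skeleton, SkeletonNode,
                                     clean_skeleton, make_synthetic_skeleton,
                                     read_swc, smoothstep,
                                     swelling_radius_profile, write_swc)


# -- SWC reading -------------------------------------------------------------

def test_read_swc_three_node_chain(tmp_path):
    p = tmp_path / "chain.swc"
    p.write_text("1 1 0 0 0 1 -1\n2 3 10 0 0 1 1\n3 3 20 0 0 1 2\n")
    sk = read_swc(p)
    assert len(sk) == 3
    assert sk.inlet_node == 1
    assert sk.outlet_nodes == [3]
    assert sk.nodes[2].radius == 1.0
    assert np.allclose(sk.nodes[3].position, [20, 0])


def test_read_swc_header_only_is_structure_error(tmp_path):
    p = tmp_path / "empty.swc"
    p.write_text("# just a header\n# nothing else\n")
    with pytest.raises(SkeletonError):
        read_swc(p)


def test_read_swc_malformed_line_names_line_number(tmp_path):
    p = tmp_path / "bad.swc"
    p.write_text("1 1 0 0 0 1 -1\n2 3 ten 0 0 1 1\n")
    with pytest.raises(SWCParseError, match="line 2"):
        read_swc(p)
    p.write_text("1 1 0 0 0 1 -1\n2 3 1 0 0 1\n")
    with pytest.raises(SWCParseError, match="line 2"):
        read_swc(p)


def test_read_swc_multiple_roots_rejected(tmp_path):
    p = tmp_path / "tworoots.swc"
    p.write_text("1 1 0 0 0 1 -1\n2 3 10 0 0 1 -1\n")
    with pytest.raises(SkeletonError):
        read_swc(p)


def test_read_swc_warns_on_nonzero_z(tmp_path, caplog):
    p = tmp_path / "z.swc"
    p.write_text("1 1 0 0 5.0 1 -1\n2 3 10 0 5.0 1 1\n")
    import logging

    with caplog.at_level(logging.WARNING, logger="neurotransport.geometry"):
        sk = read_swc(p)
    assert "z" in caplog.text
    assert sk.nodes[1].position.shape == (2,)


@st.composite
def random_trees(draw):
    n = draw(st.integers(min_value=2, max_value=12))
    nodes = [SkeletonNode(1, 1, np.array([0.0, 0.0]), 1.0, -1)]
    r = np.random.default_rng(draw(st.integers(min_value=0, max_value=10**6)))
    for i in range(2, n + 1):
        parent = int(r.integers(1, i))
        pos = nodes[parent - 1].position + r.normal(size=2) * 10 + 1.0
        nodes.append(SkeletonNode(i, 3, pos, float(r.uniform(0.5, 3.0)),
                                  parent))
    return Skeleton(nodes)


@given(random_trees())
def test_swc_round_trip_is_identity(tmp_path_factory, sk):
    """write_swc then read_swc reproduces every node field."""
    p = tmp_path_factory.mktemp("rt") / "tree.swc"
    write_swc(sk, p)
    sk2 = read_swc(p)
    assert sk2.equals(sk, coord_tol=1e-9)


# -- cleaning ----------------------------------------------------------------

def _chain_skeleton(positions, radius=1.0):
    nodes = []
    for i, pos in enumerate(positions, start=1):
        nodes.append(SkeletonNode(i, 3, np.array(pos, dtype=float), radius,
                                  -1 if i == 1 else i - 1))
    return Skeleton(nodes)


def test_clean_merges_coincident_nodes():
    sk = _chain_skeleton([(0, 0), (10, 0), (10, 0), (20, 0)])
    out = clean_skeleton(sk, tol=1e-6)
    assert len(out) == 3
    assert out.outlet_nodes == [4]  # leaf survives, relinked


def test_clean_is_idempotent_on_clean_input():
    sk = _chain_skeleton([(0, 0), (10, 0), (20, 0), (30, 0)])
    out = clean_skeleton(sk, tol=1e-6)
    assert out.equals(sk)
    assert clean_skeleton(out, tol=1e-6).equals(out)


def test_clean_collapses_short_edge_against_pairwise_scan():
    """An edge shorter than tol collapses; verified against an exhaustive
    pairwise-distance scan of the result."""
    tol = 1e-3
    sk = _chain_skeleton([(0, 0), (10, 0), (10 + 2e-4, 0), (20, 0)])
    out = clean_skeleton(sk, tol=tol)
    assert len(out) == 3
    assert len(out.outlet_nodes) == len(sk.outlet_nodes)
    pos = np.array([nd.position for nd in out.nodes.values()])
    d = np.linalg.norm(pos[:, None] - pos[None, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    assert d.min() >= tol  # no remaining pair closer than tol


@given(random_trees(), st.floats(min_value=1e-6, max_value=1.0))
def test_clean_never_increases_node_count(sk, tol):
    try:
        out = clean_skeleton(sk, tol=tol)
    except SkeletonError:
        return
    assert len(out) <= len(sk)
    # and cleaning twice changes nothing
    assert clean_skeleton(out, tol=tol).equals(out)


# -- synthetic geometries ----------------------------------------------------

def test_pipe_construction():
    sk = make_synthetic_skeleton(
        GeometrySpec("pipe", length=80, base_radius=2, spacing=10)
    )
    assert len(sk) == 9
    assert all(nd.radius == 2.0 for nd in sk.nodes.values())
    assert sk.outlet_nodes == [9]


def test_swollen_pipe_bump_endpoints():
    spec = GeometrySpec("swollen_pipe", length=80, base_radius=2, spacing=1,
                        swelling=(40.0, 20.0, 2.0))
    sk = make_synthetic_skeleton(spec)
    prof = swelling_radius_profile(2.0, (40.0, 20.0, 2.0))
    assert prof(40.0) == pytest.approx(4.0)
    assert prof(10.0) == pytest.approx(2.0)
    assert prof(29.999) == pytest.approx(2.0, abs=1e-6)
    # node radii follow the profile
    mid = [nd for nd in sk.nodes.values()
           if abs(nd.position[0] - 40.0) < 0.51]
    assert max(nd.radius for nd in mid) == pytest.approx(4.0, abs=1e-2)


def test_swelling_profile_is_c1_at_support_boundary():
    """Finite-difference slope jump at the bump edge is tiny compared with
    the interior slope."""
    prof = swelling_radius_profile(2.0, (40.0, 20.0, 2.0))
    h = 1e-7
    edge = 30.0
    slope_out = (prof(edge) - prof(edge - h)) / h
    slope_in = (prof(edge + h) - prof(edge)) / h
    interior_slope = (prof(35.0 + h) - prof(35.0)) / h
    assert abs(slope_in - slope_out) < 1e-6 * abs(interior_slope)


def test_bifurcation_children_are_mirror_images():
    spec = GeometrySpec("bifurcation", length=40, base_radius=2, spacing=5,
                        angles=(math.pi / 6, -math.pi / 6),
                        child_lengths=(40, 40))
    sk = make_synthetic_skeleton(spec)
    pos = np.array([nd.position for nd in sk.nodes.values()])
    mirrored = pos * np.array([1.0, -1.0])
    from scipy.spatial import cKDTree

    d, _ = cKDTree(pos).query(mirrored)
    assert d.max() < 1e-12


def test_geometry_spec_validation():
    with pytest.raises(GeometrySpecError):
        GeometrySpec("pipe", length=-1)
    with pytest.raises(GeometrySpecError):
        GeometrySpec("swollen_pipe", swelling=(40, 20, 0.5))  # amp <= 1
    with pytest.raises(GeometrySpecError):
        GeometrySpec("tree")  # no branch list
    with pytest.raises(GeometrySpecError):
        GeometrySpec("nonsense")


@given(st.floats(min_value=-2, max_value=3))
def test_smoothstep_bounds_and_saturation(x):
    s = smoothstep(x)
    assert 0.0 <= s <= 1.0
    if x <= 0:
        assert s == 0.0
    if x >= 1:
        assert s == 1.0
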