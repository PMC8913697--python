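"""Swept quadrilateral meshing of planar tube domains and spline spaces.

A cleaned skeleton is swept into a conforming quadrilateral control mesh:
every unbranched skeleton chain becomes a structured "branch patch" of
cross-sections placed perpendicular to the local centerline (section width
= tube diameter), and every junction becomes a fan of small structured
"junction patches", one per incident branch, meeting at the junction node
so that the mesh stays conforming and weakly conservative.

On top of the mesh, :func:`build_spline_space` constructs a globally
indexed tensor-product B-spline basis (degree 1 or 2): C^(degree-1) inside
each patch, C0 across patch interfaces.  Gluing is purely geometric — dof
anchor points (Greville abscissae pushed through the patch map) that
coincide are identified; only patch-boundary dofs are eligible, so interior
dofs of tubes that merely pass near each other are never merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from . import splines
from .errors import MeshingError
from .geometry import Skeleton

logger = logging.getLogger(__name__)

__all__ = ["ControlMesh", "SplineSpace", "sweep_mesh", "build_spline_space",
           "evaluate_geometry", "project"]

_MERGE_TOL = 1e-7  # um; vertices/anchors closer than this are the same point


# ---------------------------------------------------------------------------
# control mesh
# ---------------------------------------------------------------------------

@dataclass
class Patch:
    """One structured block of the mesh: a swept branch or a junction fan."""

    kind: str                      # "branch" | "junction"
    n_ax: int                      # cells along the first grid axis
    n_tr: int                      # cells along the second grid axis
    coords: np.ndarray             # (n_ax+1, n_tr+1, 2) vertex coordinates
    side_tags: dict                # side name ("u0","u1","v0","v1") -> tag
    branch_index: int = -1         # index into skeleton.branches() (branch)
    s_start: float = 0.0           # arc length from the inlet at patch start
    length: float = 0.0            # meshed (trimmed) branch length
    t_lo: float = -1.0             # transverse coordinate at the v=0 side
    t_hi: float = 1.0              # transverse coordinate at the v=1 side
    vgrid: np.ndarray | None = None  # (n_ax+1, n_tr+1) global vertex ids


@dataclass
class ControlMesh:
    """Conforming quadrilateral control mesh of the tube domain."""

    vertices: np.ndarray           # (Nv, 2)
    quads: np.ndarray              # (Ne, 4) CCW vertex indices
    patches: list
    elem_patch: np.ndarray         # (Ne,) patch index
    elem_cell: np.ndarray          # (Ne, 2) (i_ax, j_tr) within the patch
    boundary_edges: list           # (v0, v1, tag)
    outlet_tags: dict              # leaf node id -> tag string
    branches: list                 # skeleton branch decomposition (dicts)
    n_tr: int

    @property
    def n_elements(self) -> int:
        return len(self.quads)

    def element_corners(self, e: int) -> np.ndarray:
        return self.vertices[self.quads[e]]

    def area(self, n_gauss: int = 3) -> float:
        """Domain area by Gauss quadrature of the bilinear Jacobians."""
        g, w = np.polynomial.legendre.leggauss(n_gauss)
        total = 0.0
        for e in range(self.n_elements):
            X = self.element_corners(e)
            for a, wa in zip(g, w):
                for b, wb in zip(g, w):
                    _, _, det = _bilinear_map(X, a, b)
                    total += wa * wb * det
        return float(total)

    def min_jacobian(self, n_gauss: int = 3) -> float:
        g, _ = np.polynomial.legendre.leggauss(n_gauss)
        best = np.inf
        for e in range(self.n_elements):
            X = self.element_corners(e)
            for a in g:
                for b in g:
                    _, _, det = _bilinear_map(X, a, b)
                    best = min(best, det)
        return float(best)


def _rot90(v: np.ndarray) -> np.ndarray:
    return np.array([-v[1], v[0]])


def _bilinear_map(X: np.ndarray, xi: float, eta: float):
    """Bilinear quad map on the bi-unit reference square.

    X is (4, 2) CCW corners; returns (point, Jacobian 2x2, det).
    """
    N = 0.25 * np.array(
        [(1 - xi) * (1 - eta), (1 + xi) * (1 - eta),
         (1 + xi) * (1 + eta), (1 - xi) * (1 + eta)]
    )
    dN_xi = 0.25 * np.array([-(1 - eta), (1 - eta), (1 + eta), -(1 + eta)])
    dN_eta = 0.25 * np.array([-(1 - xi), -(1 + xi), (1 + xi), (1 - xi)])
    pt = N @ X
    J = np.stack([dN_xi @ X, dN_eta @ X], axis=1)  # columns d/dxi, d/deta
    det = J[0, 0] * J[1, 1] - J[0, 1] * J[1, 0]
    return pt, J, det


def _polyline_arc(points: np.ndarray) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(seg)])


def _resample_polyline(points, radii, s_lo, s_hi, n_stations):
    """Evenly spaced stations (position, radius, tangent) on a trimmed polyline."""
    arc = _polyline_arc(points)
    s = np.linspace(s_lo, s_hi, n_stations)
    pos = np.stack(
        [np.interp(s, arc, points[:, 0]), np.interp(s, arc, points[:, 1])], axis=1
    )
    rad = np.interp(s, arc, radii)
    tang = np.zeros_like(pos)
    tang[1:-1] = pos[2:] - pos[:-2]
    tang[0] = pos[1] - pos[0]
    tang[-1] = pos[-1] - pos[-2]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MeshingError("zero-length station spacing while resampling centerline")
    return s, pos, rad, tang / norms


def sweep_mesh(skel: Skeleton, n_transverse: int = 4,
               axial_density: float = 0.25) -> ControlMesh:
    """Sweep a cleaned skeleton into a conforming quad control mesh.

    Each branch gets ``round(length * axial_density)`` (min 2) axial strips
    of ``n_transverse`` quads; branches incident to a junction are trimmed
    back by a gap-dependent distance (at least the junction radius) and
    the gap is filled by the conforming junction template, whose patches
    all meet at the junction node.
    """
    if n_transverse < 2:
        raise MeshingError("n_transverse must be >= 2")
    branches = skel.branches()
    if not branches:
        raise MeshingError("skeleton has no branches")
    if len(skel.children[skel.root]) != 1:
        raise MeshingError(
            "the root (inlet) node must have exactly one child branch"
        )

    # per-branch polylines
    for b in branches:
        pts = np.array([skel.nodes[i].position for i in b["nodes"]])
        rad = np.array([skel.nodes[i].radius for i in b["nodes"]])
        b["points"], b["radii"] = pts, rad
        b["arc"] = _polyline_arc(pts)
        b["total_length"] = float(b["arc"][-1])
        b["start_node"] = b["nodes"][0]
        b["end_node"] = b["nodes"][-1]
        b["is_leaf"] = len(skel.children[b["end_node"]]) == 0

    junctions = {}  # junction node id -> list of (branch index, role)
    for bi, b in enumerate(branches):
        if len(skel.children[b["end_node"]]) >= 2:
            junctions.setdefault(b["end_node"], {"parent": None, "children": []})
            junctions[b["end_node"]]["parent"] = bi
        if b["start_node"] != skel.root and len(skel.children[b["start_node"]]) >= 2:
            junctions.setdefault(b["start_node"], {"parent": None, "children": []})
            junctions[b["start_node"]]["children"].append(bi)

    # junction trim distances: sections sit at distance delta from the
    # junction node; delta grows beyond the tube radius when incident
    # branches are angularly close, so neighbouring sections cannot overlap
    for jn, inc in junctions.items():
        if inc["parent"] is None:
            raise MeshingError(f"junction node {jn} has no parent branch")
        c = skel.nodes[jn].position
        r_j = skel.nodes[jn].radius
        dirs = []
        pb = branches[inc["parent"]]
        d = pb["points"][-1] - pb["points"][-2]
        dirs.append(-d / np.linalg.norm(d))
        for cbi in inc["children"]:
            cb = branches[cbi]
            d = cb["points"][1] - cb["points"][0]
            dirs.append(d / np.linalg.norm(d))
        angles = np.sort([np.arctan2(dd[1], dd[0]) for dd in dirs])
        gaps = np.diff(np.concatenate([angles, [angles[0] + 2 * np.pi]]))
        min_gap, max_gap = float(gaps.min()), float(gaps.max())
        if max_gap > np.deg2rad(176):
            raise MeshingError(
                f"junction at node {jn}: incident branches leave an angular "
                f"gap of {np.rad2deg(max_gap):.0f} deg; the junction template "
                f"needs all gaps < 176 deg"
            )
        delta = max(r_j, r_j / np.tan(0.4 * min_gap)) if min_gap < np.pi else r_j
        inc["delta"] = float(delta)

    # trims and station grids per branch
    patches: list[Patch] = []
    for bi, b in enumerate(branches):
        trim_lo = junctions[b["start_node"]]["delta"] if b["start_node"] in junctions else 0.0
        trim_hi = junctions[b["end_node"]]["delta"] if b["end_node"] in junctions else 0.0
        L = b["total_length"] - trim_lo - trim_hi
        if L <= max(trim_lo, trim_hi, 1e-9):
            raise MeshingError(
                f"branch {bi} (nodes {b['start_node']}->{b['end_node']}) is too "
                f"short ({b['total_length']:.3g} um) for its junction trims"
            )
        n_ax = max(2, int(round(L * axial_density)))
        s, pos, rad, tang = _resample_polyline(
            b["points"], b["radii"], trim_lo, b["total_length"] - trim_hi, n_ax + 1
        )
        # snap terminal tangents to the exact junction-template directions
        jpos_s = skel.nodes[b["start_node"]].position
        jpos_e = skel.nodes[b["end_node"]].position
        if trim_lo > 0:
            d = pos[0] - jpos_s
            tang[0] = d / np.linalg.norm(d)
        if trim_hi > 0:
            d = jpos_e - pos[-1]
            tang[-1] = d / np.linalg.norm(d)
        if n_transverse % 2 != 0:
            raise MeshingError("n_transverse must be even")
        t_coords = np.linspace(-1.0, 1.0, n_transverse + 1)
        coords = (
            pos[:, None, :]
            + t_coords[None, :, None]
            * rad[:, None, None]
            * np.stack([-tang[:, 1], tang[:, 0]], axis=1)[:, None, :]
        )
        b["trim_lo"], b["meshed_length"] = trim_lo, float(L)
        b["coords"] = coords
        # a branch is swept as two half-tube patches joined C0 along the
        # centerline seam, so that junction templates (which address the
        # two section halves separately) glue trace-exactly
        nh = n_transverse // 2
        inlet_tag = "inlet" if b["start_node"] == skel.root else None
        outlet_tag = f"outlet:{b['end_node']}" if b["is_leaf"] else None
        b["patch_indices"] = []
        for half, (j0, j1, t0, t1, wall_side, seam_side) in enumerate(
            ((0, nh, -1.0, 0.0, "v0", "v1"), (nh, n_transverse, 0.0, 1.0, "v1", "v0"))
        ):
            side_tags = {"v0": None, "v1": None, "u0": inlet_tag, "u1": outlet_tag}
            side_tags[wall_side] = "wall"
            patches.append(
                Patch("branch", n_ax, nh, np.ascontiguousarray(coords[:, j0:j1 + 1]),
                      side_tags, branch_index=bi, length=float(L),
                      t_lo=t0, t_hi=t1)
            )
            b["patch_indices"].append(len(patches) - 1)

    # arc length from the inlet to each branch start (centerline path,
    # junction crossings contribute 2 * junction radius)
    for bi, b in enumerate(branches):
        if b["parent"] == -1:
            b["s_start"] = b["trim_lo"]
        else:
            pb = branches[b["parent"]]
            b["s_start"] = (
                pb["s_start"] + pb["meshed_length"]
                + junctions[b["start_node"]]["delta"]
                + b["trim_lo"]
            )
        for pidx in b["patch_indices"]:
            patches[pidx].s_start = b["s_start"]

    # junction template patches
    for jn, inc in junctions.items():
        c = skel.nodes[jn].position
        entries = []
        pb = branches[inc["parent"]]
        entries.append(("parent", inc["parent"], pb["coords"][-1]))
        for cbi in inc["children"]:
            cb = branches[cbi]
            entries.append(("child", cbi, cb["coords"][0]))
        # away-pointing direction and CCW ordering around the junction
        def away_dir(section):
            mid = 0.5 * (section[0] + section[-1])
            d = mid - c
            return d / np.linalg.norm(d)

        entries.sort(key=lambda e: np.arctan2(*away_dir(e[2])[::-1]))
        m = len(entries)
        if n_transverse % 2 != 0:
            raise MeshingError("junction templates require an even n_transverse")
        nh = n_transverse // 2

        def _arc(p0, p1, npts):
            """Arc around the junction node from p0 CCW to p1."""
            a0 = np.arctan2(*(p0 - c)[::-1])
            a1 = np.arctan2(*(p1 - c)[::-1])
            while a1 <= a0:
                a1 += 2 * np.pi
            tloc = np.linspace(0.0, 1.0, npts)
            ang = a0 + tloc * (a1 - a0)
            rr = np.linalg.norm(p0 - c) + tloc * (
                np.linalg.norm(p1 - c) - np.linalg.norm(p0 - c)
            )
            return c[None, :] + rr[:, None] * np.stack(
                [np.cos(ang), np.sin(ang)], axis=1
            )

        # sections ordered R (clockwise side) -> L (CCW side), and the
        # midpoints of the wall arcs between CCW-consecutive branches
        secs = []
        for role, bidx, sec in entries:
            d_i = away_dir(sec)
            secs.append(sec if (sec[-1] - sec[0]) @ _rot90(d_i) > 0 else sec[::-1])
        wall_mid = []
        for i in range(m):
            L_i = secs[i][-1]
            R_next = secs[(i + 1) % m][0]
            wall_mid.append(_arc(L_i, R_next, 3)[1])

        def _straight(p0, p1, npts):
            tloc = np.linspace(0.0, 1.0, npts)[:, None]
            return p0[None, :] * (1 - tloc) + p1[None, :] * tloc

        def _transfinite(E_u0, E_u1, E_v0, E_v1):
            """Coons patch grid from its four discretized sides.

            E_u0/E_u1 are the u=0 / u=1 sides (indexed by v); E_v0/E_v1
            the v=0 / v=1 sides (indexed by u).  Corner consistency is
            assumed.
            """
            nu = len(E_v0) - 1
            nv = len(E_u0) - 1
            u = np.linspace(0.0, 1.0, nu + 1)[:, None, None]
            v = np.linspace(0.0, 1.0, nv + 1)[None, :, None]
            P00, P10 = E_v0[0], E_v0[-1]
            P01, P11 = E_v1[0], E_v1[-1]
            return (
                (1 - u) * E_u0[None, :, :] + u * E_u1[None, :, :]
                + (1 - v) * E_v0[:, None, :] + v * E_v1[:, None, :]
                - ((1 - u) * (1 - v) * P00 + u * (1 - v) * P10
                   + (1 - u) * v * P01 + u * v * P11)
            )

        for i in range(m):
            sec = secs[i]
            R_i, L_i, m_i = sec[0], sec[-1], sec[nh]
            M_prev, M_i = wall_mid[(i - 1) % m], wall_mid[i]
            # two mirror-image quads per incident branch, meeting at the
            # junction node c, the section midpoint m_i and the wall-arc
            # midpoints M_prev / M_i
            # quad A: corners c, M_prev, m_i, R_i (wall on the u=1 side)
            grid_a = _transfinite(
                _straight(c, m_i, nh + 1),          # u0: c -> m_i
                _arc(M_prev, R_i, nh + 1),          # u1: wall half-arc
                _straight(c, M_prev, nh + 1),       # v0: c -> M_prev
                np.ascontiguousarray(sec[: nh + 1][::-1]),  # v1: m_i -> R_i
            )
            patches.append(Patch(
                "junction", nh, nh, grid_a,
                {"u0": None, "u1": "wall", "v0": None, "v1": None},
            ))
            # quad B: corners c, m_i, M_i, L_i (wall on the v=1 side)
            grid_b = _transfinite(
                _straight(c, M_i, nh + 1),          # u0: c -> M_i
                np.ascontiguousarray(sec[nh:]),     # u1: m_i -> L_i
                _straight(c, m_i, nh + 1),          # v0: c -> m_i
                np.ascontiguousarray(_arc(L_i, M_i, nh + 1)[::-1]),  # v1
            )
            patches.append(Patch(
                "junction", nh, nh, grid_b,
                {"u0": None, "u1": None, "v0": None, "v1": "wall"},
            ))

    # ---- global vertex numbering (merge coincident patch-boundary vertices)
    all_pts, owners = [], []
    for pi, p in enumerate(patches):
        na, nt = p.n_ax, p.n_tr
        for i in range(na + 1):
            for j in range(nt + 1):
                all_pts.append(p.coords[i, j])
                owners.append((pi, i, j, i in (0, na) or j in (0, nt)))
    all_pts = np.array(all_pts)
    vid = _merge_points(all_pts, [o[3] for o in owners])
    vertices = np.zeros((vid.max() + 1, 2))
    for k, (pi, i, j, _) in enumerate(owners):
        vertices[vid[k]] = all_pts[k]
    for p in patches:
        p.vgrid = np.zeros((p.n_ax + 1, p.n_tr + 1), dtype=int)
    k = 0
    for pi, i, j, _ in owners:
        patches[pi].vgrid[i, j] = vid[k]
        k += 1

    quads, elem_patch, elem_cell = [], [], []
    for pi, p in enumerate(patches):
        for i in range(p.n_ax):
            for j in range(p.n_tr):
                g = p.vgrid
                quads.append([g[i, j], g[i + 1, j], g[i + 1, j + 1], g[i, j + 1]])
                elem_patch.append(pi)
                elem_cell.append((i, j))
    quads = np.array(quads, dtype=int)

    boundary_edges = []
    outlet_tags = {}
    for p in patches:
        g = p.vgrid
        sides = {
            "u0": [(g[0, j], g[0, j + 1]) for j in range(p.n_tr)],
            "u1": [(g[-1, j], g[-1, j + 1]) for j in range(p.n_tr)],
            "v0": [(g[i, 0], g[i + 1, 0]) for i in range(p.n_ax)],
            "v1": [(g[i, -1], g[i + 1, -1]) for i in range(p.n_ax)],
        }
        for side, tag in p.side_tags.items():
            if tag is None:
                continue
            for v0, v1 in sides[side]:
                boundary_edges.append((v0, v1, tag))
            if tag.startswith("outlet:"):
                outlet_tags[int(tag.split(":")[1])] = tag

    mesh = ControlMesh(vertices, quads, patches, np.array(elem_patch),
                       np.array(elem_cell), boundary_edges, outlet_tags,
                       branches, n_transverse)
    bad = mesh.min_jacobian()
    if bad <= 0:
        # identify an offending branch for the error message
        for e in range(mesh.n_elements):
            X = mesh.element_corners(e)
            if _bilinear_map(X, 0.0, 0.0)[2] <= 0:
                p = patches[mesh.elem_patch[e]]
                where = (f"branch {p.branch_index}" if p.kind == "branch"
                         else "a junction template")
                raise MeshingError(
                    f"self-intersecting tube: non-positive Jacobian in {where} "
                    f"(radius exceeds the local turning room)"
                )
        raise MeshingError("self-intersecting tube: non-positive Jacobian")
    logger.info("swept mesh: %d elements, %d vertices, min det J = %.3g",
                mesh.n_elements, len(vertices), bad)
    return mesh


def _merge_points(pts: np.ndarray, eligible) -> np.ndarray:
    """Assign shared ids to coincident eligible points; unique ids otherwise."""
    n = len(pts)
    ids = -np.ones(n, dtype=int)
    el_idx = [k for k in range(n) if eligible[k]]
    next_id = 0
    if el_idx:
        sub = pts[el_idx]
        tree = cKDTree(sub)
        groups = tree.query_ball_point(sub, _MERGE_TOL)
        for a, grp in enumerate(groups):
            if ids[el_idx[a]] != -1:
                continue
            gid = next_id
            next_id += 1
            for b in grp:
                ids[el_idx[b]] = gid
    for k in range(n):
        if ids[k] == -1:
            ids[k] = next_id
            next_id += 1
    return ids


# ---------------------------------------------------------------------------
# spline space
# ---------------------------------------------------------------------------

class SplineSpace:
    """Global tensor-product B-spline basis on a swept control mesh.

    Degree 1 or 2; C^(degree-1) inside each patch, C0 across patch
    interfaces.  All element-level quantities used by assembly are cached
    as stacked arrays:

    - ``PHI`` (Ne, nq, nl): basis values at quadrature points
    - ``DPHI`` (Ne, nq, nl, 2): physical gradients
    - ``W`` (Ne, nq): quadrature weight x |det J|
    - ``XY`` (Ne, nq, 2): physical quadrature points
    - ``ELEM_DOFS`` (Ne, nl): global dof indices
    - ``ST`` (Ne, nq, 2): (arc length s, transverse t in [-1,1]); NaN on
      junction patches
    - ``JTINV`` (Ne, nq, 2, 2): inverse-transpose geometry Jacobians
    - ``ST_SCALE`` (Ne, 2): d s / d xi and d t / d eta per element
    """

    def __init__(self, mesh: ControlMesh, degree: int = 2, n_gauss: int | None = None):
        if degree not in (1, 2):
            raise MeshingError("spline degree must be 1 or 2")
        self.mesh = mesh
        self.degree = degree
        p = degree
        nq1 = n_gauss or (degree + 1)
        gauss_x, gauss_w = np.polynomial.legendre.leggauss(nq1)
        self.nq = nq1 * nq1
        self.nl = (p + 1) ** 2

        # ---- global dof numbering via geometric anchors
        anchors, eligible, patch_dof_grids = [], [], []
        for pi, patch in enumerate(mesh.patches):
            na, nt = patch.n_ax, patch.n_tr
            ga = splines.greville(na, p)
            gt = splines.greville(nt, p)
            grid = np.zeros((len(ga), len(gt)), dtype=int)
            patch_dof_grids.append(grid)
            for a, ua in enumerate(ga):
                for b, vb in enumerate(gt):
                    anchors.append(_patch_point(patch, ua, vb))
                    eligible.append(
                        a in (0, len(ga) - 1) or b in (0, len(gt) - 1)
                    )
        anchors = np.array(anchors)
        dof_ids = _merge_points(anchors, eligible)
        self.n_dofs = int(dof_ids.max()) + 1
        k = 0
        for pi, patch in enumerate(mesh.patches):
            grid = patch_dof_grids[pi]
            for a in range(grid.shape[0]):
                for b in range(grid.shape[1]):
                    grid[a, b] = dof_ids[k]
                    k += 1
        self.patch_dof_grids = patch_dof_grids
        self.dof_anchor = np.zeros((self.n_dofs, 2))
        self.dof_anchor[dof_ids] = anchors

        # ---- per-patch 1D bases at mapped quadrature points, then tensor
        Ne = mesh.n_elements
        nl, nq = self.nl, self.nq
        self.PHI = np.zeros((Ne, nq, nl))
        self.DPHI = np.zeros((Ne, nq, nl, 2))
        self.W = np.zeros((Ne, nq))
        self.XY = np.zeros((Ne, nq, 2))
        self.ELEM_DOFS = np.zeros((Ne, nl), dtype=int)
        self.ST = np.full((Ne, nq, 2), np.nan)
        self.JTINV = np.zeros((Ne, nq, 2, 2))
        self.ST_SCALE = np.zeros((Ne, 2))

        ref = np.array([(a, b) for a in gauss_x for b in gauss_x])
        refw = np.array([wa * wb for wa in gauss_w for wb in gauss_w])
        self._ref_pts, self._ref_w = ref, refw

        for e in range(Ne):
            pi = mesh.elem_patch[e]
            patch = mesh.patches[pi]
            i, j = mesh.elem_cell[e]
            na, nt = patch.n_ax, patch.n_tr
            du, dv = 1.0 / na, 1.0 / nt
            u_pts = (i + (ref[:, 0] + 1) / 2) * du
            v_pts = (j + (ref[:, 1] + 1) / 2) * dv
            Bu, dBu = splines.basis_values(na, p, u_pts)
            Bv, dBv = splines.basis_values(nt, p, v_pts)
            su = splines.cell_support(i, p)
            sv = splines.cell_support(j, p)
            grid = patch_dof_grids[pi]
            self.ELEM_DOFS[e] = np.array(
                [grid[a, b] for a in su for b in sv]
            )
            X = mesh.element_corners(e)
            for q in range(nq):
                xi, eta = ref[q]
                pt, J, det = _bilinear_map(X, xi, eta)
                if det <= 0:
                    raise MeshingError(
                        f"non-positive Jacobian in element {e}"
                    )
                Jinv = np.linalg.inv(J)
                self.XY[e, q] = pt
                self.W[e, q] = refw[q] * det
                self.JTINV[e, q] = Jinv.T
                loc = 0
                for ai, a in enumerate(su):
                    for bi_, b in enumerate(sv):
                        val = Bu[q, a] * Bv[q, b]
                        d_xi = dBu[q, a] * Bv[q, b] * (du / 2)
                        d_eta = Bu[q, a] * dBv[q, b] * (dv / 2)
                        self.PHI[e, q, loc] = val
                        self.DPHI[e, q, loc] = Jinv.T @ np.array([d_xi, d_eta])
                        loc += 1
            if patch.kind == "branch":
                s = patch.s_start + u_pts * patch.length
                t = patch.t_lo + v_pts * (patch.t_hi - patch.t_lo)
                self.ST[e, :, 0] = s
                self.ST[e, :, 1] = t
                # d s / d xi, d t / d eta within this element
                self.ST_SCALE[e] = (
                    patch.length * du / 2,
                    (patch.t_hi - patch.t_lo) * dv / 2,
                )

        # Dirichlet dof lists per boundary tag
        self.boundary_dofs: dict[str, np.ndarray] = {}
        for pi, patch in enumerate(mesh.patches):
            grid = patch_dof_grids[pi]
            rows = {"u0": grid[0, :], "u1": grid[-1, :],
                    "v0": grid[:, 0], "v1": grid[:, -1]}
            for side, tag in patch.side_tags.items():
                if tag is None:
                    continue
                cur = self.boundary_dofs.get(tag, np.empty(0, dtype=int))
                self.boundary_dofs[tag] = np.union1d(cur, rows[side])
        self._point_cache: dict = {}

    # ------------------------------------------------------------------
    @property
    def element_sizes(self) -> np.ndarray:
        """Characteristic size sqrt(area) per element."""
        return np.sqrt(self.W.sum(axis=1))

    def dirichlet_dofs(self, tag: str) -> np.ndarray:
        return self.boundary_dofs.get(tag, np.empty(0, dtype=int))

    # -- boundary edge quadrature --------------------------------------
    def edge_data(self, tag: str) -> list[dict]:
        """1D quadrature data along every boundary edge cell of a tag.

        Each entry carries the trace dofs, basis values at the edge Gauss
        points, weights (including the metric), physical points, outward
        unit normals and the swept parameter (transverse t for inlet /
        outlet sections, arc length s for walls).
        """
        key = ("edge", tag)
        if key in self._point_cache:
            return self._point_cache[key]
        p = self.degree
        g1, w1 = np.polynomial.legendre.leggauss(p + 1)
        out = []
        for pi, patch in enumerate(self.mesh.patches):
            for side, stag in patch.side_tags.items():
                if stag != tag:
                    continue
                grid = self.patch_dof_grids[pi]
                na, nt = patch.n_ax, patch.n_tr
                if side in ("u0", "u1"):
                    n_cells, n_other = nt, na
                    dof_row = grid[0, :] if side == "u0" else grid[-1, :]
                    vrow = patch.vgrid[0, :] if side == "u0" else patch.vgrid[-1, :]
                else:
                    n_cells, n_other = na, nt
                    dof_row = grid[:, 0] if side == "v0" else grid[:, -1]
                    vrow = patch.vgrid[:, 0] if side == "v0" else patch.vgrid[:, -1]
                for j in range(n_cells):
                    dv = 1.0 / n_cells
                    v_pts = (j + (g1 + 1) / 2) * dv
                    B, _ = splines.basis_values(n_cells, p, v_pts)
                    sup = splines.cell_support(j, p)
                    v0x = self.mesh.vertices[vrow[j]]
                    v1x = self.mesh.vertices[vrow[j + 1]]
                    dvec = v1x - v0x
                    elen = np.linalg.norm(dvec)
                    dirn = dvec / elen
                    # outward: away from the patch interior
                    if side in ("u0", "u1"):
                        interior = _patch_point(
                            patch, 0.05 if side == "u0" else 0.95, (j + 0.5) * dv
                        )
                    else:
                        interior = _patch_point(
                            patch, (j + 0.5) * dv, 0.05 if side == "v0" else 0.95
                        )
                    nrm = _rot90(dirn)
                    mid = 0.5 * (v0x + v1x)
                    if nrm @ (mid - interior) < 0:
                        nrm = -nrm
                    if side in ("u0", "u1"):
                        param = patch.t_lo + v_pts * (patch.t_hi - patch.t_lo)
                    else:
                        param = patch.s_start + v_pts * patch.length
                    out.append({
                        "dofs": dof_row[sup],
                        "B": B[:, sup],
                        "W": w1 * elen / 2,
                        "XY": v0x[None, :] + ((g1 + 1) / 2)[:, None] * dvec[None, :],
                        "normal": nrm,
                        "param": param,
                        "patch": pi,
                    })
        self._point_cache[key] = out
        return out

    def edge_flux(self, tag: str, cx: np.ndarray, cy: np.ndarray) -> float:
        """Outward flux of the vector field (cx, cy) through a tagged boundary."""
        total = 0.0
        for ed in self.edge_data(tag):
            vx = ed["B"] @ cx[ed["dofs"]]
            vy = ed["B"] @ cy[ed["dofs"]]
            total += np.sum(ed["W"] * (vx * ed["normal"][0] + vy * ed["normal"][1]))
        return float(total)

    def edge_trace_values(self, tag: str, fn) -> tuple[np.ndarray, np.ndarray]:
        """L2-project ``fn(param)`` onto a tagged boundary's trace space.

        Returns (dof indices, coefficient values).  Exact whenever fn
        restricted to the edge lies in the trace space (e.g. a parabola in
        the transverse coordinate for degree 2).
        """
        eds = self.edge_data(tag)
        dofs = np.unique(np.concatenate([ed["dofs"] for ed in eds]))
        remap = {d: k for k, d in enumerate(dofs)}
        n = len(dofs)
        M = np.zeros((n, n))
        b = np.zeros(n)
        for ed in eds:
            idx = np.array([remap[d] for d in ed["dofs"]])
            f = fn(ed["param"])
            Mloc = np.einsum("qa,qb,q->ab", ed["B"], ed["B"], ed["W"])
            M[np.ix_(idx, idx)] += Mloc
            b[idx] += np.einsum("qa,q,q->a", ed["B"], f, ed["W"])
        return dofs, np.linalg.solve(M, b)

    def edge_length(self, tag: str) -> float:
        return float(sum(ed["W"].sum() for ed in self.edge_data(tag)))

    def evaluate(self, coefs: np.ndarray, e: int, xi: float, eta: float):
        """Field value at a reference point of one element."""
        mesh = self.mesh
        pi = mesh.elem_patch[e]
        patch = mesh.patches[pi]
        i, j = mesh.elem_cell[e]
        na, nt = patch.n_ax, patch.n_tr
        u = (i + (xi + 1) / 2) / na
        v = (j + (eta + 1) / 2) / nt
        return float(self.evaluate_patch(pi, u, v, coefs)[0])

    def evaluate_patch(self, patch_index: int, u, v, coefs: np.ndarray):
        """Field value(s) at patch parameters (u, v) in [0,1]^2."""
        patch = self.mesh.patches[patch_index]
        p = self.degree
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        Bu, _ = splines.basis_values(patch.n_ax, p, u)
        Bv, _ = splines.basis_values(patch.n_tr, p, v)
        grid = self.patch_dof_grids[patch_index]
        C = coefs[grid]
        return np.einsum("ka,kb,ab->k", Bu, Bv, C, optimize=True)

    def patch_physical(self, patch_index: int, u, v) -> np.ndarray:
        patch = self.mesh.patches[patch_index]
        u = np.atleast_1d(np.asarray(u, dtype=float))
        v = np.atleast_1d(np.asarray(v, dtype=float))
        return np.array([_patch_point(patch, uu, vv) for uu, vv in zip(u, v)])

    def locate(self, pts: np.ndarray):
        """Find (element, xi, eta) for physical points (brute bbox search)."""
        mesh = self.mesh
        if "bbox" not in self._point_cache:
            corners = mesh.vertices[mesh.quads]  # (Ne,4,2)
            self._point_cache["bbox"] = (
                corners.min(axis=1) - 1e-9, corners.max(axis=1) + 1e-9
            )
        lo, hi = self._point_cache["bbox"]
        out = []
        for pt in np.atleast_2d(pts):
            cand = np.where(np.all((pt >= lo) & (pt <= hi), axis=1))[0]
            hit = None
            for e in cand:
                ref = _invert_bilinear(mesh.element_corners(e), pt)
                if ref is not None:
                    hit = (int(e), float(ref[0]), float(ref[1]))
                    break
            if hit is None:
                raise MeshingError(f"point {pt} lies outside the mesh")
            out.append(hit)
        return out

    def evaluate_at_points(self, coefs: np.ndarray, pts: np.ndarray) -> np.ndarray:
        locs = self.locate(pts)
        return np.array([self.evaluate(coefs, e, xi, eta) for e, xi, eta in locs])


def _patch_point(patch: Patch, u: float, v: float) -> np.ndarray:
    """Piecewise-bilinear patch map (vertex grid interpolation) at (u, v)."""
    na, nt = patch.n_ax, patch.n_tr
    x = min(max(u, 0.0), 1.0) * na
    y = min(max(v, 0.0), 1.0) * nt
    i = min(int(x), na - 1)
    j = min(int(y), nt - 1)
    fx, fy = x - i, y - j
    c = patch.coords
    return (
        (1 - fx) * (1 - fy) * c[i, j]
        + fx * (1 - fy) * c[i + 1, j]
        + fx * fy * c[i + 1, j + 1]
        + (1 - fx) * fy * c[i, j + 1]
    )


def _invert_bilinear(X: np.ndarray, pt: np.ndarray, tol: float = 1e-11):
    """Newton inversion of the bilinear map; None if outside the element."""
    ref = np.zeros(2)
    for _ in range(30):
        p, J, det = _bilinear_map(X, ref[0], ref[1])
        r = p - pt
        if np.linalg.norm(r) < tol:
            break
        if abs(det) < 1e-300:
            return None
        ref = ref - np.linalg.solve(J, r)
        ref = np.clip(ref, -1.5, 1.5)
    p, _, _ = _bilinear_map(X, ref[0], ref[1])
    if np.linalg.norm(p - pt) > 1e-8 or np.any(np.abs(ref) > 1 + 1e-8):
        return None
    return np.clip(ref, -1.0, 1.0)


def build_spline_space(mesh: ControlMesh, degree: int = 2) -> SplineSpace:
    """Construct the global quadratic (or linear) spline basis on a mesh."""
    return SplineSpace(mesh, degree=degree)


def evaluate_geometry(space: SplineSpace, element: int, ref_point):
    """Isoparametric map support: physical point, Jacobian and determinant.

    ``ref_point`` lives on the bi-unit reference square.  Raises
    :class:`MeshingError` on a non-positive determinant, naming the element.
    """
    xi, eta = ref_point
    if abs(xi) > 1 + 1e-12 or abs(eta) > 1 + 1e-12:
        raise MeshingError("reference point outside the bi-unit square")
    X = space.mesh.element_corners(element)
    pt, J, det = _bilinear_map(X, xi, eta)
    if det <= 0:
        raise MeshingError(f"non-positive Jacobian in element {element}")
    return pt, J, det


def project(space: SplineSpace, fn) -> np.ndarray:
    """Global L2 projection of ``fn(x, y)`` onto the spline space."""
    from scipy.sparse import coo_matrix
    from scipy.sparse.linalg import spsolve

    Ne, nq, nl = space.PHI.shape
    Mloc = np.einsum("eqa,eqb,eq->eab", space.PHI, space.PHI, space.W)
    rows = np.repeat(space.ELEM_DOFS, nl, axis=1).ravel()
    cols = np.tile(space.ELEM_DOFS, (1, nl)).ravel()
    M = coo_matrix((Mloc.ravel(), (rows, cols)),
                   shape=(space.n_dofs, space.n_dofs)).tocsc()
    f = fn(space.XY[:, :, 0], space.XY[:, :, 1])
    b = np.zeros(space.n_dofs)
    np.add.at(b, space.ELEM_DOFS.ravel(),
              np.einsum("eqa,eq,eq->ea", space.PHI, f, space.W).ravel())
    return spsolve(M, b)
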