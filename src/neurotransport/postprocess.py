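"""Diagnostics and exporters: centerline profiles, vortex summaries, VTK.

The centerline concentration profile (free + anterograde pools sampled
along the skeleton path from the inlet to an outlet) is the model's
principal quantitative readout; the vortex summary (scalar curl of the
summed transport velocity, its circulation over a region, and the overlap
between high concentration and counter-clockwise vorticity) quantifies the
swirl phenomenology.  Mesh and fields are exported as legacy-ASCII and XML
VTK unstructured grids for standard viewers, profiles/histories as CSV and
the fully resolved configuration as a JSON manifest.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .meshing import SplineSpace

logger = logging.getLogger(__name__)

__all__ = [
    "CenterlineProfile",
    "VortexSummary",
    "centerline_profile",
    "vortex_diagnostics",
    "export_result",
    "write_vtk",
    "write_vtu",
    "read_vtk",
]


@dataclass
class CenterlineProfile:
    """Concentration along the inlet-to-outlet centerline path."""

    s: np.ndarray          # arc length from the inlet, um (strictly increasing)
    value: np.ndarray      # n0 + n+ (+ n- when requested), mol/um^2
    path: list             # branch indices from the inlet to the outlet
    outlet_id: int

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["s_um", "concentration"])
            for s, v in zip(self.s, self.value):
                w.writerow([f"{s:.10g}", f"{v:.10g}"])


@dataclass
class VortexSummary:
    """Curl statistics of the summed transport velocity over a region."""

    curl: np.ndarray         # per-quadrature-point scalar curl, 1/s
    circulation: float       # integral of curl over the region
    overlap_score: float     # fraction of top-decile-concentration area
                             # inside the counter-clockwise (positive curl)
                             # region
    region_area: float


def _branch_path(mesh, outlet_id: int) -> list[int]:
    leaf_branch = None
    for bi, b in enumerate(mesh.branches):
        if b["end_node"] == outlet_id and b["is_leaf"]:
            leaf_branch = bi
            break
    if leaf_branch is None:
        raise KeyError(f"unknown outlet {outlet_id}")
    path = [leaf_branch]
    while mesh.branches[path[0]]["parent"] != -1:
        path.insert(0, mesh.branches[path[0]]["parent"])
    return path


def centerline_profile(result, outlet_id: int, spacing: float | None = None,
                       include_minus: bool = False) -> CenterlineProfile:
    """Sample the summed concentration along the centerline to an outlet.

    ``result`` is anything carrying ``space`` and ``state`` attributes (a
    :class:`~neurotransport.scenarios.ScenarioResult`, or an object with
    the same fields).  Points are evenly spaced (default half the axial
    element size) along the skeleton path, which crosses junction regions
    through the junction node.  The value is ``n0 + n+`` — the quantity
    the concentration figures plot — with ``n-`` added on request.
    """
    space: SplineSpace = result.space
    state = result.state
    mesh = space.mesh
    if outlet_id not in mesh.outlet_tags:
        raise KeyError(f"unknown outlet {outlet_id}")
    path = _branch_path(mesh, outlet_id)

    # polyline: branch section centers, with junction-node crossings
    pts = []
    for k, bi in enumerate(path):
        b = mesh.branches[bi]
        centers = 0.5 * (b["coords"][:, 0] + b["coords"][:, -1])
        if k > 0:
            # crossing through the junction node between branches
            pts.append(_node_position(mesh, b["start_node"])[None, :])
        pts.append(centers)
    poly = np.vstack(pts)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    if spacing is None:
        spacing = 0.5 * float(np.mean(space.element_sizes))
    n_samples = max(8, int(np.ceil(arc[-1] / spacing)) + 1)
    s = np.linspace(0.0, arc[-1], n_samples)
    xy = np.stack([np.interp(s, arc, poly[:, 0]),
                   np.interp(s, arc, poly[:, 1])], axis=1)
    # nudge the endpoints inside the mesh
    xy[0] = xy[0] + 1e-9 * (xy[1] - xy[0])
    xy[-1] = xy[-1] + 1e-9 * (xy[-2] - xy[-1])
    val = (result.space.evaluate_at_points(state.n0, xy)
           + result.space.evaluate_at_points(state.n_plus, xy))
    if include_minus and state.bidirectional:
        val = val + result.space.evaluate_at_points(state.n_minus, xy)
    return CenterlineProfile(s, val, path, outlet_id)


def _node_position(mesh, node_id):
    for b in mesh.branches:
        if b["start_node"] == node_id:
            return b["points"][0]
        if b["end_node"] == node_id:
            return b["points"][-1]
    raise KeyError(node_id)


def vortex_diagnostics(result, region) -> VortexSummary:
    """Curl / circulation / concentration-overlap over a branch region.

    ``region = (branch_id, s_lo, s_hi)`` in arc length along the branch.
    Requires a bidirectional result (the summed velocity ``v+ + v-`` is
    the rotating field); unidirectional runs raise
    :class:`ConfigurationError`.
    """
    state = result.state
    space: SplineSpace = result.space
    if not state.bidirectional:
        raise ConfigurationError("vortex diagnostics require a bidirectional run")
    vx = state.v_plus[0] + state.v_minus[0]
    vy = state.v_plus[1] + state.v_minus[1]
    ED = space.ELEM_DOFS
    curl = (np.einsum("eqad,ea->eqd", space.DPHI, vy[ED])[:, :, 0]
            - np.einsum("eqad,ea->eqd", space.DPHI, vx[ED])[:, :, 1])
    bid_, lo, hi = region
    mesh = space.mesh
    in_branch = np.array([
        mesh.patches[mesh.elem_patch[e]].kind == "branch"
        and mesh.patches[mesh.elem_patch[e]].branch_index == bid_
        for e in range(mesh.n_elements)
    ])
    mask = (in_branch[:, None]
            & (space.ST[:, :, 0] >= lo) & (space.ST[:, :, 0] <= hi))
    circ = float((curl * space.W)[mask].sum())
    area = float(space.W[mask].sum())
    conc = state.n0 + state.n_plus
    if state.bidirectional:
        conc = conc + state.n_minus
    cq = np.einsum("eqa,ea->eq", space.PHI, conc[ED])
    cr, wr, cc = curl[mask], space.W[mask], cq[mask]
    if len(cc) == 0:
        raise ConfigurationError("empty vortex region")
    thr = np.quantile(cc, 0.9)
    sel = cc >= thr
    overlap = float(wr[sel & (cr > 0)].sum() / max(wr[sel].sum(), 1e-300))
    return VortexSummary(curl, circ, overlap, area)


# ---------------------------------------------------------------------------
# VTK export (legacy ASCII and XML unstructured grids)
# ---------------------------------------------------------------------------

def vertex_field_values(space: SplineSpace, coefs: np.ndarray) -> np.ndarray:
    """Field values at the control-mesh vertices."""
    mesh = space.mesh
    out = np.zeros(len(mesh.vertices))
    for pi, patch in enumerate(mesh.patches):
        na, nt = patch.n_ax, patch.n_tr
        u = np.repeat(np.linspace(0, 1, na + 1), nt + 1)
        v = np.tile(np.linspace(0, 1, nt + 1), na + 1)
        vals = space.evaluate_patch(pi, u, v, coefs)
        out[patch.vgrid.ravel()] = vals
    return out


def _mt_vertex_values(mt, mesh, which: str) -> np.ndarray:
    """MT density at mesh vertices (baseline on junction patches)."""
    base = 1.0 if which == "plus" else (
        1.0 if mt.mode == "bidirectional" else 0.0
    )
    out = np.full(len(mesh.vertices), base)
    fn = mt.l_plus if which == "plus" else mt.l_minus
    for patch in mesh.patches:
        if patch.kind != "branch":
            continue
        if mt.region is not None and patch.branch_index != mt.region[0]:
            continue
        na, nt = patch.n_ax, patch.n_tr
        s = patch.s_start + np.linspace(0, 1, na + 1) * patch.length
        t = patch.t_lo + np.linspace(0, 1, nt + 1) * (patch.t_hi - patch.t_lo)
        S, T = np.meshgrid(s, t, indexing="ij")
        out[patch.vgrid.ravel()] = np.asarray(fn(S.ravel(), T.ravel()))
    return out


def write_vtk(path, mesh, point_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with scalar point data."""
    point_data = point_data or {}
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nneurotransport mesh\nASCII\n")
        fh.write("DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(mesh.vertices)} double\n")
        for x, y in mesh.vertices:
            fh.write(f"{x:.12g} {y:.12g} 0\n")
        ne = len(mesh.quads)
        fh.write(f"CELLS {ne} {5 * ne}\n")
        for q in mesh.quads:
            fh.write("4 " + " ".join(str(i) for i in q) + "\n")
        fh.write(f"CELL_TYPES {ne}\n")
        fh.write("\n".join(["9"] * ne) + "\n")
        if point_data:
            fh.write(f"POINT_DATA {len(mesh.vertices)}\n")
            for name, arr in point_data.items():
                fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
                fh.write("\n".join(f"{v:.12g}" for v in arr) + "\n")


def write_vtu(path, mesh, point_data: dict | None = None) -> None:
    """XML (.vtu) VTK unstructured grid with scalar point data."""
    point_data = point_data or {}
    nv, ne = len(mesh.vertices), len(mesh.quads)
    lines = [
        '<?xml version="1.0"?>',
        '<VTKFile type="UnstructuredGrid" version="0.1" byte_order="LittleEndian">',
        "<UnstructuredGrid>",
        f'<Piece NumberOfPoints="{nv}" NumberOfCells="{ne}">',
        "<Points>",
        '<DataArray type="Float64" NumberOfComponents="3" format="ascii">',
    ]
    lines += [f"{x:.12g} {y:.12g} 0" for x, y in mesh.vertices]
    lines += ["</DataArray>", "</Points>", "<Cells>",
              '<DataArray type="Int64" Name="connectivity" format="ascii">']
    lines += [" ".join(str(i) for i in q) for q in mesh.quads]
    lines += ["</DataArray>",
              '<DataArray type="Int64" Name="offsets" format="ascii">',
              " ".join(str(4 * (k + 1)) for k in range(ne)),
              "</DataArray>",
              '<DataArray type="UInt8" Name="types" format="ascii">',
              " ".join(["9"] * ne),
              "</DataArray>", "</Cells>"]
    if point_data:
        lines.append("<PointData>")
        for name, arr in point_data.items():
            lines.append(
                f'<DataArray type="Float64" Name="{name}" format="ascii">'
            )
            lines += [f"{v:.12g}" for v in arr]
            lines.append("</DataArray>")
        lines.append("</PointData>")
    lines += ["</Piece>", "</UnstructuredGrid>", "</VTKFile>"]
    Path(path).write_text("\n".join(lines) + "\n")


def read_vtk(path):
    """Minimal legacy-ASCII VTK reader (points, quads, scalar point data)."""
    points, cells, data = [], [], {}
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    i = 0
    while i < len(lines):
        ln = lines[i]
        if ln.startswith("POINTS"):
            n = int(ln.split()[1])
            for k in range(n):
                i += 1
                x, y, _ = (float(v) for v in lines[i].split())
                points.append((x, y))
        elif ln.startswith("CELLS"):
            n = int(ln.split()[1])
            for k in range(n):
                i += 1
                parts = [int(v) for v in lines[i].split()]
                cells.append(parts[1:])
        elif ln.startswith("SCALARS"):
            name = ln.split()[1]
            i += 1  # LOOKUP_TABLE line
            vals = []
            while len(vals) < len(points):
                i += 1
                vals.extend(float(v) for v in lines[i].split())
            data[name] = np.array(vals)
        i += 1
    return np.array(points), np.array(cells, dtype=int), data


def export_result(result, what=("mesh", "fields", "profiles", "history"),
                  path="out") -> list[str]:
    """Write mesh + fields (VTK), profiles and history (CSV) and a JSON
    manifest of the resolved configuration.

    Returns the list of files written.  Every artifact is regenerable from
    the manifest alone.
    """
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    space: SplineSpace = result.space
    mesh = space.mesh
    written = []
    if "mesh" in what or "fields" in what:
        pd = {}
        if "fields" in what:
            st = result.state
            fields = {"n0": st.n0, "n_plus": st.n_plus,
                      "v_plus_x": st.v_plus[0], "v_plus_y": st.v_plus[1],
                      "f_plus_x": result.control.f_plus[0],
                      "f_plus_y": result.control.f_plus[1]}
            if st.bidirectional:
                fields.update({"n_minus": st.n_minus,
                               "v_minus_x": st.v_minus[0],
                               "v_minus_y": st.v_minus[1],
                               "f_minus_x": result.control.f_minus[0],
                               "f_minus_y": result.control.f_minus[1]})
            if getattr(result, "target", None) is not None:
                fields["V_plus_x"] = result.target.vx_plus
                fields["V_plus_y"] = result.target.vy_plus
            if getattr(result, "mt", None) is not None:
                pd["l_plus"] = _mt_vertex_values(result.mt, mesh, "plus")
                if st.bidirectional:
                    pd["l_minus"] = _mt_vertex_values(result.mt, mesh, "minus")
            for name, coefs in fields.items():
                pd[name] = vertex_field_values(space, coefs)
        for writer, suffix in ((write_vtk, ".vtk"), (write_vtu, ".vtu")):
            p = out / f"result{suffix}"
            writer(p, mesh, pd)
            written.append(str(p))
    if "profiles" in what:
        for outlet in mesh.outlet_tags:
            prof = centerline_profile(result, outlet)
            p = out / f"profile_outlet_{outlet}.csv"
            prof.to_csv(p)
            written.append(str(p))
    if "history" in what:
        p = out / "history.csv"
        with open(p, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["iteration", "kkt_residual"])
            for k, r in enumerate(result.solution.history):
                w.writerow([k, f"{r:.12g}"])
        written.append(str(p))
    manifest = out / "manifest.json"
    manifest.write_text(json.dumps(getattr(result, "config_dict", lambda: {})(),
                                   indent=2, default=str) + "\n")
    written.append(str(manifest))
    return written
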