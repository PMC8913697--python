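"""Neuron skeleton handling: SWC I/O, cleaning, and synthetic geometries.

A skeleton is a rooted tree of centerline points with radii, following the
semantics of the 7-column SWC morphology format (node id, structure type,
x, y, z, radius, parent id).  The package works in the plane, so the z
coordinate is discarded on read (with a warning when it is non-trivial).
The root node is taken as the transport inlet and every leaf as an outlet.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import GeometrySpecError, SkeletonError, SWCParseError

logger = logging.getLogger(__name__)

__all__ = [
    "SkeletonNode",
    "Skeleton",
    "GeometrySpec",
    "read_swc",
    "write_swc",
    "clean_skeleton",
    "make_synthetic_skeleton",
    "smoothstep",
]


def smoothstep(x: np.ndarray | float) -> np.ndarray | float:
    """Cubic smoothstep ``3x^2 - 2x^3`` clamped to [0, 1].

    C1 on the whole real line; used for all smooth bump/dip profiles.
    """
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


@dataclass(frozen=True)
class SkeletonNode:
    """One centerline sample: id, SWC structure code, 2D position, radius."""

    node_id: int
    structure_type: int
    position: np.ndarray  # shape (2,), micrometres
    radius: float  # micrometres, > 0
    parent_id: int  # -1 for the root

    def __post_init__(self):
        object.__setattr__(self, "position", np.asarray(self.position, dtype=float))
        if self.position.shape != (2,):
            raise SkeletonError(f"node {self.node_id}: position must be 2D")
        if not self.radius > 0:
            raise SkeletonError(f"node {self.node_id}: radius must be > 0")
        if self.node_id <= 0:
            raise SkeletonError(f"node id must be positive, got {self.node_id}")


class Skeleton:
    """Rooted tree of :class:`SkeletonNode`.

    The root is the inlet; leaves are outlets.  Invariants (checked on
    construction): unique ids, exactly one root, valid parentage, acyclic
    and connected, positive radii.
    """

    def __init__(self, nodes: Iterable[SkeletonNode]):
        self.nodes: dict[int, SkeletonNode] = {}
        for nd in nodes:
            if nd.node_id in self.nodes:
                raise SkeletonError(f"duplicate node id {nd.node_id}")
            self.nodes[nd.node_id] = nd
        if not self.nodes:
            raise SkeletonError("skeleton has no nodes")
        roots = [n.node_id for n in self.nodes.values() if n.parent_id == -1]
        if len(roots) != 1:
            raise SkeletonError(f"expected exactly one root, found {len(roots)}")
        self.root = roots[0]
        self.children: dict[int, list[int]] = {i: [] for i in self.nodes}
        for nd in self.nodes.values():
            if nd.parent_id != -1:
                if nd.parent_id not in self.nodes:
                    raise SkeletonError(
                        f"node {nd.node_id} refers to missing parent {nd.parent_id}"
                    )
                self.children[nd.parent_id].append(nd.node_id)
        # connectivity / acyclicity: DFS from the root must reach every node
        seen: set[int] = set()
        stack = [self.root]
        while stack:
            i = stack.pop()
            if i in seen:
                raise SkeletonError("cycle detected in skeleton")
            seen.add(i)
            stack.extend(self.children[i])
        if seen != set(self.nodes):
            raise SkeletonError("skeleton is not connected")

    # -- basic queries -------------------------------------------------
    @property
    def inlet_node(self) -> int:
        return self.root

    @property
    def outlet_nodes(self) -> list[int]:
        return sorted(i for i, ch in self.children.items() if not ch)

    def __len__(self) -> int:
        return len(self.nodes)

    def edge_length(self, child_id: int) -> float:
        nd = self.nodes[child_id]
        if nd.parent_id == -1:
            raise SkeletonError("root has no incoming edge")
        return float(np.linalg.norm(nd.position - self.nodes[nd.parent_id].position))

    def depths(self) -> dict[int, int]:
        d = {self.root: 0}
        stack = [self.root]
        while stack:
            i = stack.pop()
            for c in self.children[i]:
                d[c] = d[i] + 1
                stack.append(c)
        return d

    def branches(self) -> list[dict]:
        """Decompose into maximal unbranched chains ("branches").

        Returns a list of dicts with keys ``nodes`` (node-id chain from the
        inlet side towards the outlet side), ``parent`` (index of the parent
        branch, -1 for the branch leaving the root) in BFS order.  Interior
        chain nodes have exactly one child; chains start/stop at the root,
        at junctions (>= 2 children) and at leaves.
        """
        out: list[dict] = []
        # queue of (start_node, parent_branch_index); start_node is a
        # root/junction node from which a chain departs via each child
        queue: list[tuple[int, int, int]] = [
            (self.root, c, -1) for c in sorted(self.children[self.root])
        ]
        while queue:
            start, first, parent_branch = queue.pop(0)
            chain = [start, first]
            cur = first
            while len(self.children[cur]) == 1:
                cur = self.children[cur][0]
                chain.append(cur)
            idx = len(out)
            out.append({"nodes": chain, "parent": parent_branch})
            for c in sorted(self.children[cur]):
                queue.append((cur, c, idx))
        return out

    # -- comparisons (used by round-trip tests) ------------------------
    def equals(self, other: "Skeleton", coord_tol: float = 1e-9) -> bool:
        if set(self.nodes) != set(other.nodes):
            return False
        for i, nd in self.nodes.items():
            od = other.nodes[i]
            if nd.parent_id != od.parent_id or nd.structure_type != od.structure_type:
                return False
            if np.any(np.abs(nd.position - od.position) > coord_tol):
                return False
            if abs(nd.radius - od.radius) > coord_tol:
                return False
        return True


def read_swc(path, z_tol: float = 1e-9) -> Skeleton:
    """Read a 7-column SWC morphology file into a :class:`Skeleton`.

    The z column is discarded (planar model); a warning is logged when any
    ``|z|`` exceeds ``z_tol``.  ``#`` comment lines and blank lines are
    ignored.  Malformed records raise :class:`SWCParseError` naming the
    line number; structural problems raise :class:`SkeletonError`.
    """
    nodes: list[SkeletonNode] = []
    max_abs_z = 0.0
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(
                    f"{path}: line {lineno}: expected 7 fields, got {len(parts)}"
                )
            try:
                nid = int(parts[0])
                stype = int(parts[1])
                x, y, z, r = (float(v) for v in parts[2:6])
                pid = int(parts[6])
            except ValueError as exc:
                raise SWCParseError(f"{path}: line {lineno}: {exc}") from None
            max_abs_z = max(max_abs_z, abs(z))
            nodes.append(SkeletonNode(nid, stype, np.array([x, y]), r, pid))
    if max_abs_z > z_tol:
        logger.warning(
            "SWC file %s has non-zero z coordinates (max |z| = %g); "
            "z is discarded in the planar model",
            path,
            max_abs_z,
        )
    if not nodes:
        raise SkeletonError(f"{path}: no skeleton records found")
    return Skeleton(nodes)


def write_swc(skel: Skeleton, path) -> None:
    """Write a skeleton as a standard 7-column SWC file (z = 0)."""
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid in sorted(skel.nodes):
            nd = skel.nodes[nid]
            fh.write(
                f"{nd.node_id} {nd.structure_type} "
                f"{nd.position[0]:.12g} {nd.position[1]:.12g} 0 "
                f"{nd.radius:.12g} {nd.parent_id}\n"
            )


def clean_skeleton(skel: Skeleton, tol: float = 1e-6) -> Skeleton:
    """Merge nodes closer than ``tol`` and drop the resulting degenerate edges.

    Nodes are clustered transitively by the ``< tol`` proximity relation;
    each cluster survives as its lowest node id, keeping that node's
    position/radius, placed at the tree position of the cluster's
    shallowest member.  Idempotent; never increases the node count.
    Raises :class:`SkeletonError` if the result violates the skeleton
    invariants.
    """
    ids = sorted(skel.nodes)
    pos = np.array([skel.nodes[i].position for i in ids])
    n = len(ids)
    # union-find over the proximity graph
    parent = list(range(n))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    if n > 1:
        from scipy.spatial import cKDTree

        tree = cKDTree(pos)
        for a, b in tree.query_pairs(tol):
            union(a, b)

    cluster_of = {ids[k]: ids[find(k)] for k in range(n)}
    survivor: dict[int, int] = {}
    members: dict[int, list[int]] = {}
    for nid, root in cluster_of.items():
        members.setdefault(root, []).append(nid)
    for root, mem in members.items():
        survivor[root] = min(mem)

    depths = skel.depths()
    new_nodes: list[SkeletonNode] = []
    for root, mem in members.items():
        surv = survivor[root]
        # tree position: parent of the shallowest member, mapped to survivors
        shallow = min(mem, key=lambda i: depths[i])
        pid = skel.nodes[shallow].parent_id
        if pid != -1:
            pid = survivor[cluster_of[pid]]
        nd = skel.nodes[surv]
        new_nodes.append(replace(nd, parent_id=pid))
    try:
        out = Skeleton(new_nodes)
    except SkeletonError as exc:
        raise SkeletonError(f"cleaning would break the skeleton: {exc}") from exc
    return out


@dataclass
class GeometrySpec:
    """Specification of a synthetic planar tube geometry.

    kind:
        one of ``pipe``, ``bifurcation``, ``tree``, ``swollen_pipe``,
        ``from_swc``.
    length / lengths, angles:
        micrometres and radians per branch (see the individual builders).
    swelling:
        ``(s0, extent, amplification)`` — centre arc length, support length
        L2 and radius amplification factor (> 1) of a local swelling.
    branches:
        for ``tree``: list of ``(parent_index, length, relative_angle,
        radius)`` tuples; ``parent_index`` is -1 for the root branch and the
        relative angle is measured against the parent branch direction.
    """

    kind: str
    length: float = 80.0
    base_radius: float = 2.0
    spacing: float = 10.0
    angles: tuple[float, float] = (math.pi / 6, -math.pi / 6)
    child_lengths: tuple[float, float] | None = None
    swelling: tuple[float, float, float] | None = None
    branches: Sequence[tuple[int, float, float, float]] | None = None
    swc_path: str | None = None

    def __post_init__(self):
        if self.kind not in {"pipe", "bifurcation", "tree", "swollen_pipe", "from_swc"}:
            raise GeometrySpecError(f"unknown geometry kind {self.kind!r}")
        if self.kind != "from_swc":
            if self.length <= 0 or self.base_radius <= 0 or self.spacing <= 0:
                raise GeometrySpecError("lengths, radii and spacing must be > 0")
        if self.swelling is not None:
            s0, extent, amp = self.swelling
            if extent <= 0:
                raise GeometrySpecError("swelling extent must be > 0")
            if not amp > 1:
                raise GeometrySpecError("swelling amplification must be > 1")
        if self.kind == "tree" and not self.branches:
            raise GeometrySpecError("tree geometry requires a branch list")
        if self.kind == "from_swc" and not self.swc_path:
            raise GeometrySpecError("from_swc geometry requires swc_path")


def swelling_radius_profile(
    base_radius: float, swelling: tuple[float, float, float]
) -> Callable[[np.ndarray], np.ndarray]:
    """Radius profile r(s) of a locally swollen pipe.

    ``r(s) = base * (1 + (amplification - 1) * bump(s))`` with a C1 cubic
    smoothstep bump supported on ``[s0 - L2/2, s0 + L2/2]`` that reaches 1
    at the centre s0.
    """
    s0, extent, amp = swelling

    def profile(s):
        q = np.abs((np.asarray(s, dtype=float) - s0) / (extent / 2.0))
        bump = smoothstep(1.0 - q)
        return base_radius * (1.0 + (amp - 1.0) * bump)

    return profile


def _chain(
    nodes: list[SkeletonNode],
    start_pos: np.ndarray,
    direction: np.ndarray,
    length: float,
    spacing: float,
    radius_fn: Callable[[float], float],
    parent_id: int,
    s_offset: float = 0.0,
    structure_type: int = 3,
) -> int:
    """Append a straight chain of nodes; returns the id of the last node."""
    n_seg = max(1, int(round(length / spacing)))
    ds = length / n_seg
    last = parent_id
    for j in range(1, n_seg + 1):
        nid = (max((nd.node_id for nd in nodes), default=0)) + 1
        s = s_offset + j * ds
        pos = start_pos + direction * (j * ds)
        nodes.append(
            SkeletonNode(nid, structure_type, pos, float(radius_fn(s)), last)
        )
        last = nid
    return last


def make_synthetic_skeleton(spec: GeometrySpec) -> Skeleton:
    """Build a synthetic skeleton from a :class:`GeometrySpec`.

    * ``pipe`` — straight chain along +x, constant radius.
    * ``swollen_pipe`` — pipe whose radius follows the C1 swelling profile.
    * ``bifurcation`` — Y: a parent branch splitting into two children at
      the spec angles (relative to +x).
    * ``tree`` — recursive branching from the ``branches`` list.
    """
    if spec.kind == "from_swc":
        return read_swc(spec.swc_path)

    nodes: list[SkeletonNode] = []
    if spec.kind in {"pipe", "swollen_pipe"}:
        if spec.kind == "swollen_pipe":
            if spec.swelling is None:
                raise GeometrySpecError("swollen_pipe requires a swelling spec")
            rfn = swelling_radius_profile(spec.base_radius, spec.swelling)
        else:
            rfn = lambda s: spec.base_radius  # noqa: E731
        nodes.append(SkeletonNode(1, 1, np.array([0.0, 0.0]), float(rfn(0.0)), -1))
        _chain(
            nodes,
            np.array([0.0, 0.0]),
            np.array([1.0, 0.0]),
            spec.length,
            spec.spacing,
            rfn,
            parent_id=1,
        )
        return Skeleton(nodes)

    if spec.kind == "bifurcation":
        child_lengths = spec.child_lengths or (spec.length, spec.length)
        r = spec.base_radius
        nodes.append(SkeletonNode(1, 1, np.array([0.0, 0.0]), r, -1))
        junction = _chain(
            nodes,
            np.array([0.0, 0.0]),
            np.array([1.0, 0.0]),
            spec.length,
            spec.spacing,
            lambda s: r,
            parent_id=1,
        )
        jpos = nodes[-1].position
        for ang, clen in zip(spec.angles, child_lengths):
            d = np.array([math.cos(ang), math.sin(ang)])
            _chain(nodes, jpos, d, clen, spec.spacing, lambda s: r, parent_id=junction)
        return Skeleton(nodes)

    # tree
    nodes.append(
        SkeletonNode(1, 1, np.array([0.0, 0.0]), spec.branches[0][3], -1)
    )
    branch_end: list[int] = []  # last node id of each branch
    branch_dir: list[np.ndarray] = []
    for bi, (parent_idx, length, rel_angle, radius) in enumerate(spec.branches):
        if length <= 0 or radius <= 0:
            raise GeometrySpecError(f"tree branch {bi}: length and radius must be > 0")
        if parent_idx == -1:
            start_id = 1
            base_angle = 0.0
        else:
            if not (0 <= parent_idx < bi):
                raise GeometrySpecError(
                    f"tree branch {bi}: parent index {parent_idx} must precede it"
                )
            start_id = branch_end[parent_idx]
            base_angle = math.atan2(*branch_dir[parent_idx][::-1])
        ang = base_angle + rel_angle
        d = np.array([math.cos(ang), math.sin(ang)])
        start_pos = next(
            nd.position for nd in nodes if nd.node_id == start_id
        )
        end = _chain(
            nodes, start_pos, d, length, spec.spacing, lambda s: radius, start_id
        )
        branch_end.append(end)
        branch_dir.append(d)
    return Skeleton(nodes)
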