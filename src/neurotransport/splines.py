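"""Univariate B-spline bases on open uniform knot vectors.

Each swept patch carries a tensor product of two of these bases.  Open
(clamped) knots make the basis interpolatory at the parameter endpoints,
which is what lets patches be glued C0 along shared edges by identifying
edge degree-of-freedom rows.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import BSpline


def open_uniform_knots(n_cells: int, degree: int) -> np.ndarray:
    """Clamped uniform knot vector on [0, 1] with ``n_cells`` elements."""
    if n_cells < 1:
        raise ValueError("need at least one cell")
    interior = np.linspace(0.0, 1.0, n_cells + 1)
    return np.concatenate(
        [np.zeros(degree), interior, np.ones(degree)]
    )


def n_dofs(n_cells: int, degree: int) -> int:
    return n_cells + degree


def greville(n_cells: int, degree: int) -> np.ndarray:
    """Greville abscissae (dof anchors) of the clamped basis."""
    t = open_uniform_knots(n_cells, degree)
    nd = n_dofs(n_cells, degree)
    return np.array([t[i + 1 : i + degree + 1].mean() for i in range(nd)])


def basis_values(n_cells: int, degree: int, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Dense (len(x), ndof) arrays of basis values and first derivatives."""
    t = open_uniform_knots(n_cells, degree)
    x = np.atleast_1d(np.asarray(x, dtype=float))
    nd = n_dofs(n_cells, degree)
    vals = BSpline.design_matrix(x, t, degree).toarray()
    if degree == 0:
        return vals, np.zeros_like(vals)
    # derivative via the lower-degree recurrence
    low = BSpline.design_matrix(x, t, degree - 1).toarray()  # (npts, nd + 1)
    der = np.zeros_like(vals)
    for i in range(nd):
        d1 = t[i + degree] - t[i]
        d2 = t[i + degree + 1] - t[i + 1]
        if d1 > 0:
            der[:, i] += degree * low[:, i] / d1
        if d2 > 0:
            der[:, i] -= degree * low[:, i + 1] / d2
    return vals, der


def cell_support(cell: int, degree: int) -> np.ndarray:
    """Indices of basis functions supported on a given cell."""
    return np.arange(cell, cell + degree + 1)
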