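"""Prescribed fields of the transport model.

This module owns everything the optimizer treats as *given*:

* :class:`ParameterSet` — the biophysical parameters (diffusivities,
  attachment/detachment rates, loading degrees, penalty weights, ...),
* :class:`MTDensityField` — the microtubule density fields ``l±`` for the
  uniform / reduced / swirl configurations,
* :func:`solve_predefined_velocity` — the target velocity ``V±`` from a
  steady incompressible flow solve on the tube domain,
* :func:`stokes_einstein_diffusivity` — the Stokes–Einstein estimate of
  the free-particle diffusivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import scipy.sparse as sps
import scipy.sparse.linalg as spla

from .errors import ConfigurationError, SolverError
from .geometry import smoothstep
from .meshing import SplineSpace

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSet",
    "MTDensityField",
    "VelocityTarget",
    "make_mt_density",
    "solve_predefined_velocity",
    "stokes_einstein_diffusivity",
]

_KB = 1.380649e-23  # Boltzmann constant, J/K


@dataclass(frozen=True)
class ParameterSet:
    """Model parameters with the standard defaults.

    Units: diffusivities um^2/s, rates 1/s, concentrations mol/um^2,
    velocities um/s.  ``n_time_steps = 0`` selects the steady formulation;
    otherwise backward-Euler steps over ``[0, T_horizon]``.
    """

    D_plus: float = 0.1
    D_minus: float = 0.1
    k_plus: float = 1.0
    k_minus: float = 1.0
    kprime_plus: float = 0.1
    kprime_minus: float = 0.1
    mu: float = 0.1            # viscosity of the traffic flow
    lambda_in: float = 2.0     # degree of loading at the inlet
    lambda_out: float = 2.0    # degree of loading at the outlets
    n_in: float = 1.0          # free concentration at the inlet
    n_out: float = 0.0         # free concentration at the outlets
    alpha: float = 1.0         # concentration-gradient penalty
    beta: float = 1.0          # control-force penalty
    T_horizon: float = 1.0
    n_time_steps: int = 0
    mode: str = "unidirectional"

    def __post_init__(self):
        for name in ("D_plus", "D_minus", "k_plus", "k_minus", "kprime_plus",
                     "kprime_minus", "mu", "lambda_in", "lambda_out"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.alpha <= 0 or self.beta <= 0:
            raise ConfigurationError("alpha and beta must be > 0")
        if self.mode not in ("unidirectional", "bidirectional"):
            raise ConfigurationError(f"unknown mode {self.mode!r}")
        if self.n_time_steps < 0:
            raise ConfigurationError("n_time_steps must be >= 0")

    @property
    def bidirectional(self) -> bool:
        return self.mode == "bidirectional"

    @property
    def steady(self) -> bool:
        return self.n_time_steps == 0

    def with_(self, **kw) -> "ParameterSet":
        return replace(self, **kw)


def stokes_einstein_diffusivity(diameter: float, temperature: float,
                                dynamic_viscosity: float) -> float:
    """Diffusivity of a sphere from the Stokes–Einstein relation.

    ``D = kB T / (6 pi eta r)`` with the diameter in um, temperature in K
    and viscosity in Pa s; the result is returned in um^2/s.  For a 1 um
    sphere in water at room temperature this gives 0.44 um^2/s (0.4 after
    one-decimal rounding).
    """
    if diameter <= 0 or temperature <= 0 or dynamic_viscosity <= 0:
        raise ValueError("diameter, temperature and viscosity must be > 0")
    radius_m = 0.5 * diameter * 1e-6
    d_si = _KB * temperature / (6.0 * np.pi * dynamic_viscosity * radius_m)
    return d_si * 1e12  # m^2/s -> um^2/s


# ---------------------------------------------------------------------------
# microtubule density fields
# ---------------------------------------------------------------------------

def _bump(s, s0, s1, w):
    """Smooth plateau bump: 0 outside [s0, s1], 1 on [s0+w, s1-w], C1."""
    u1 = (np.asarray(s, dtype=float) - s0) / w
    u2 = (s1 - np.asarray(s, dtype=float)) / w
    return smoothstep(u1) * smoothstep(u2)


def _dbump(s, s0, s1, w):
    s = np.asarray(s, dtype=float)
    u1 = (s - s0) / w
    u2 = (s1 - s) / w

    def dS(x):
        x = np.asarray(x)
        inside = (x > 0) & (x < 1)
        xc = np.clip(x, 0.0, 1.0)
        return np.where(inside, 6.0 * xc * (1.0 - xc), 0.0)

    return (dS(u1) / w) * smoothstep(u2) - smoothstep(u1) * (dS(u2) / w)


class MTDensityField:
    """Microtubule densities ``l±`` evaluated on a spline space.

    Carries quadrature-point arrays (values and physical gradients) used
    directly by assembly, plus pointwise evaluators for diagnostics.  The
    density is always >= 0; in unidirectional mode ``l- = 0`` identically.
    """

    def __init__(self, space: SplineSpace, kind: str, mode: str,
                 region=None, depth: float = 0.0, amplification: float = 1.0,
                 asymmetry: float = 0.0, transition: float | None = None):
        self.space = space
        self.kind = kind
        self.mode = mode
        self.region = region
        self.depth = depth
        self.amplification = amplification
        self.asymmetry = asymmetry
        self.transition = transition
        Ne, nq = space.W.shape
        self.LP = np.ones((Ne, nq))
        self.GLP = np.zeros((Ne, nq, 2))
        baseline_minus = 1.0 if mode == "bidirectional" else 0.0
        self.LM = np.full((Ne, nq), baseline_minus)
        self.GLM = np.zeros((Ne, nq, 2))
        if kind == "uniform":
            return

        branch_id, s0, s1 = region
        w = transition if transition is not None else (s1 - s0) / 4.0
        if w <= 0 or 2 * w > (s1 - s0):
            raise ConfigurationError("transition width must be in (0, (s1-s0)/2]")
        self._w = w

        mesh = space.mesh
        for e in range(Ne):
            patch = mesh.patches[mesh.elem_patch[e]]
            if patch.kind != "branch" or patch.branch_index != branch_id:
                continue
            s = space.ST[e, :, 0]
            t = space.ST[e, :, 1]
            bump = _bump(s, s0, s1, w)
            dbump = _dbump(s, s0, s1, w)
            if kind == "reduced":
                lp = 1.0 - depth * bump
                dlp_ds = -depth * dbump
                dlp_dt = np.zeros_like(t)
                self._set(e, self.LP, self.GLP, lp, dlp_ds, dlp_dt)
            elif kind == "swirl":
                A, a = amplification, asymmetry
                lp_in = A * (1.0 - a * t)
                lm_in = A * (1.0 + a * t)
                self._set(e, self.LP, self.GLP,
                          1.0 + bump * (lp_in - 1.0),
                          dbump * (lp_in - 1.0), bump * (-A * a))
                self._set(e, self.LM, self.GLM,
                          baseline_minus + bump * (lm_in - baseline_minus),
                          dbump * (lm_in - baseline_minus), bump * (A * a))
            else:
                raise ConfigurationError(f"unknown MT density kind {kind!r}")
        np.clip(self.LP, 0.0, None, out=self.LP)
        np.clip(self.LM, 0.0, None, out=self.LM)

    def _set(self, e, L, GL, val, d_ds, d_dt):
        space = self.space
        L[e] = val
        dxi = np.stack(
            [np.broadcast_to(d_ds, val.shape) * space.ST_SCALE[e, 0],
             np.broadcast_to(d_dt, val.shape) * space.ST_SCALE[e, 1]], axis=-1
        )
        GL[e] = np.einsum("qij,qj->qi", space.JTINV[e], dxi)

    # pointwise evaluators -------------------------------------------------
    def _eval_st(self, s, t, which: str):
        base = 1.0 if which == "plus" else (1.0 if self.mode == "bidirectional" else 0.0)
        s = np.asarray(s, dtype=float)
        t = np.asarray(t, dtype=float)
        if self.kind == "uniform" or self.region is None:
            return np.broadcast_to(base, np.broadcast(s, t).shape).copy()
        _, s0, s1 = self.region
        bump = _bump(s, s0, s1, self._w)
        if self.kind == "reduced":
            if which == "plus":
                return 1.0 - self.depth * bump
            return np.broadcast_to(base, bump.shape).copy()
        A, a = self.amplification, self.asymmetry
        inner = A * (1.0 - a * t) if which == "plus" else A * (1.0 + a * t)
        return np.clip(base + bump * (inner - base), 0.0, None)

    def l_plus(self, s, t=0.0):
        """l+ at branch arc length s, transverse t (region branch only)."""
        return self._eval_st(s, t, "plus")

    def l_minus(self, s, t=0.0):
        return self._eval_st(s, t, "minus")

    def l_plus_at(self, pts: np.ndarray) -> np.ndarray:
        """l+ at physical points (locates the containing elements)."""
        return self._at(pts, "plus")

    def l_minus_at(self, pts: np.ndarray) -> np.ndarray:
        return self._at(pts, "minus")

    def _at(self, pts, which):
        space = self.space
        mesh = space.mesh
        locs = space.locate(np.atleast_2d(pts))
        out = []
        base = 1.0 if which == "plus" else (
            1.0 if self.mode == "bidirectional" else 0.0
        )
        for e, xi, eta in locs:
            patch = mesh.patches[mesh.elem_patch[e]]
            if patch.kind != "branch" or (
                self.region is not None and patch.branch_index != self.region[0]
            ):
                out.append(base if self.kind != "uniform" else base)
                continue
            i, j = mesh.elem_cell[e]
            u = (i + (xi + 1) / 2) / patch.n_ax
            v = (j + (eta + 1) / 2) / patch.n_tr
            s = patch.s_start + u * patch.length
            t = patch.t_lo + v * (patch.t_hi - patch.t_lo)
            out.append(float(self._eval_st(s, t, which)))
        return np.array(out)


def make_mt_density(space: SplineSpace, kind: str = "uniform", *,
                    params: ParameterSet | None = None,
                    mode: str | None = None,
                    region=None, depth: float = 0.0,
                    amplification: float = 1.0, asymmetry: float = 0.0,
                    transition: float | None = None) -> MTDensityField:
    """Construct the microtubule density field ``l±``.

    * ``uniform`` — the default density 1.0 everywhere (both directions in
      bidirectional mode).
    * ``reduced`` — ``l+`` dips smoothly to ``1 - depth`` at the centre of
      ``region = (branch_id, s0, s1)`` (arc length along that branch),
      modeling a local loss of microtubules.
    * ``swirl`` — inside the region both densities rise to
      ``amplification`` on the centerline with opposite transverse biases:
      ``l+ = A (1 - asymmetry t)``, ``l- = A (1 + asymmetry t)`` with
      ``t = +1`` the top wall, blending back to the baseline over a
      transition band.  Requires bidirectional mode.
    """
    mode = mode or (params.mode if params is not None else "unidirectional")
    if kind == "swirl" and mode != "bidirectional":
        raise ConfigurationError("swirl densities require bidirectional mode")
    if kind in ("reduced", "swirl"):
        if region is None:
            raise ConfigurationError(f"{kind} density requires a region")
        if kind == "reduced" and not (0 <= depth < 1):
            raise ConfigurationError("depth must be in [0, 1)")
        if amplification < 1:
            raise ConfigurationError("amplification must be >= 1")
        if not (0 <= asymmetry <= 1):
            raise ConfigurationError("asymmetry must be in [0, 1]")
        branch_id, s0, s1 = region
        mesh = space.mesh
        if branch_id < 0 or branch_id >= len(mesh.branches):
            raise ConfigurationError(f"region names unknown branch {branch_id}")
        b = mesh.branches[branch_id]
        lo, hi = b["s_start"], b["s_start"] + b["meshed_length"]
        if not (lo - 1e-9 <= s0 < s1 <= hi + 1e-9):
            raise ConfigurationError(
                f"region [{s0}, {s1}] must lie inside branch {branch_id} "
                f"(arc range [{lo:.3g}, {hi:.3g}])"
            )
    return MTDensityField(space, kind, mode, region=region, depth=depth,
                          amplification=amplification, asymmetry=asymmetry,
                          transition=transition)


# ---------------------------------------------------------------------------
# predefined velocity target
# ---------------------------------------------------------------------------

@dataclass
class VelocityTarget:
    """Coefficients of the target velocity V± on the scalar spline space."""

    vx_plus: np.ndarray
    vy_plus: np.ndarray
    vx_minus: np.ndarray | None = None
    vy_minus: np.ndarray | None = None

    @property
    def bidirectional(self) -> bool:
        return self.vx_minus is not None


def solve_predefined_velocity(space: SplineSpace, inflow_speed: float = 1.0,
                              params: ParameterSet | None = None, *,
                              viscosity: float = 10.0,
                              newton_tol: float = 1e-10,
                              max_newton: int = 25) -> VelocityTarget:
    """Steady incompressible flow on the tube domain as the target V±.

    Mixed Galerkin discretization with quadratic spline velocities and a
    linear spline pressure on the same mesh (a Taylor–Hood-type stable
    pair, so no pressure stabilization is needed); parabolic inlet profile
    with peak ``inflow_speed``, no-slip walls, traction-free outlets.
    Newton iteration started from the Stokes solution.  In bidirectional
    mode the minus target is the negated field.
    """
    if inflow_speed == 0.0:
        z = np.zeros(space.n_dofs)
        bid = params is not None and params.bidirectional
        return VelocityTarget(z, z.copy(),
                              z.copy() if bid else None,
                              z.copy() if bid else None)

    from .meshing import SplineSpace as _SS

    n = space.n_dofs
    pspace = space if space.degree == 1 else _SS(space.mesh, degree=1,
                                                n_gauss=space.degree + 1)
    npr = pspace.n_dofs
    PHI, DPHI, W = space.PHI, space.DPHI, space.W
    ED = space.ELEM_DOFS
    Ne, nq, nl = PHI.shape
    nlp = pspace.PHI.shape[2]

    rows = np.repeat(ED, nl, axis=1).ravel()
    cols = np.tile(ED, (1, nl)).ravel()

    def asm(loc):
        return sps.coo_matrix((loc.ravel(), (rows, cols)), shape=(n, n)).tocsr()

    K = asm(np.einsum("eqad,eqbd,eq->eab", DPHI, DPHI, W))      # stiffness
    # divergence coupling: pressure test x velocity trial
    prow = np.repeat(pspace.ELEM_DOFS, nl, axis=1).ravel()
    pcol = np.tile(ED, (1, nlp)).ravel()
    Gx = sps.coo_matrix(
        (np.einsum("eqa,eqb,eq->eab", pspace.PHI, DPHI[:, :, :, 0], W).ravel(),
         (prow, pcol)), shape=(npr, n)).tocsr()
    Gy = sps.coo_matrix(
        (np.einsum("eqa,eqb,eq->eab", pspace.PHI, DPHI[:, :, :, 1], W).ravel(),
         (prow, pcol)), shape=(npr, n)).tocsr()

    # Dirichlet data
    wall = space.dirichlet_dofs("wall")
    inlet = space.dirichlet_dofs("inlet")
    root_patch = next(p for p in space.mesh.patches
                      if p.kind == "branch" and p.side_tags.get("u0") == "inlet")
    d0 = _patch_dir(space, root_patch)
    prof_dofs, prof_vals = space.edge_trace_values(
        "inlet", lambda t: inflow_speed * (1.0 - t**2)
    )
    ux_bc = np.zeros(n)
    uy_bc = np.zeros(n)
    ux_bc[prof_dofs] = prof_vals * d0[0]
    uy_bc[prof_dofs] = prof_vals * d0[1]
    ux_bc[wall] = 0.0
    uy_bc[wall] = 0.0
    fixed = np.union1d(wall, inlet)
    free = np.setdiff1d(np.arange(n), fixed)

    def momentum_residual(ux, uy, pr):
        uxl, uyl = ux[ED], uy[ED]
        uq = np.einsum("eqa,ea->eq", PHI, uxl)
        vq = np.einsum("eqa,ea->eq", PHI, uyl)
        gux = np.einsum("eqad,ea->eqd", DPHI, uxl)
        guy = np.einsum("eqad,ea->eqd", DPHI, uyl)
        conv_x = uq * gux[:, :, 0] + vq * gux[:, :, 1]
        conv_y = uq * guy[:, :, 0] + vq * guy[:, :, 1]
        rx = np.zeros(n)
        ry = np.zeros(n)
        np.add.at(rx, ED.ravel(),
                  np.einsum("eqa,eq->ea", PHI, conv_x * W).ravel())
        np.add.at(ry, ED.ravel(),
                  np.einsum("eqa,eq->ea", PHI, conv_y * W).ravel())
        rx += viscosity * (K @ ux) - Gx.T @ pr
        ry += viscosity * (K @ uy) - Gy.T @ pr
        rp = Gx @ ux + Gy @ uy
        return rx, ry, rp, (uq, vq, gux, guy)

    def convection_jacobian(uq, vq, gux, guy):
        # directional derivative of u . grad(u): phi_b grad(u) + u . grad(phi_b)
        ugradb = (uq[:, :, None] * DPHI[:, :, :, 0]
                  + vq[:, :, None] * DPHI[:, :, :, 1])  # (e, q, b)
        Jxx = np.einsum("eqa,eq,eqb,eq->eab", PHI, gux[:, :, 0], PHI, W) \
            + np.einsum("eqa,eqb,eq->eab", PHI, ugradb, W)
        Jxy = np.einsum("eqa,eq,eqb,eq->eab", PHI, gux[:, :, 1], PHI, W)
        Jyx = np.einsum("eqa,eq,eqb,eq->eab", PHI, guy[:, :, 0], PHI, W)
        Jyy = np.einsum("eqa,eq,eqb,eq->eab", PHI, guy[:, :, 1], PHI, W) \
            + np.einsum("eqa,eqb,eq->eab", PHI, ugradb, W)
        return asm(Jxx), asm(Jxy), asm(Jyx), asm(Jyy)

    nf = len(free)
    idx_free = np.concatenate([free, n + free, 2 * n + np.arange(npr)])

    def solve_newton():
        ux, uy, pr = ux_bc.copy(), uy_bc.copy(), np.zeros(npr)
        for it in range(max_newton + 1):
            rx, ry, rp, aux = momentum_residual(ux, uy, pr)
            res = np.concatenate([rx[free], ry[free], rp])
            rnorm = np.linalg.norm(res)
            if it == 0:
                # Stokes start: drop convection entirely
                A = sps.bmat([
                    [viscosity * K, None, -Gx.T],
                    [None, viscosity * K, -Gy.T],
                    [Gx, Gy, None],
                ]).tocsr()
                rhs = -np.concatenate([
                    (viscosity * (K @ ux) - Gx.T @ pr)[free],
                    (viscosity * (K @ uy) - Gy.T @ pr)[free],
                    Gx @ ux + Gy @ uy,
                ])
            else:
                if rnorm < newton_tol * max(1.0, abs(inflow_speed)):
                    logger.info("flow solve converged: |r| = %.3e after %d "
                                "Newton steps", rnorm, it)
                    return ux, uy, pr
                Jxx, Jxy, Jyx, Jyy = convection_jacobian(*aux)
                A = sps.bmat([
                    [viscosity * K + Jxx, Jxy, -Gx.T],
                    [Jyx, viscosity * K + Jyy, -Gy.T],
                    [Gx, Gy, None],
                ]).tocsr()
                rhs = -res
            Af = A[idx_free][:, idx_free].tocsc()
            try:
                d = spla.splu(Af).solve(rhs)
            except RuntimeError as exc:
                raise SolverError(f"flow solve: sparse LU failed: {exc}") from exc
            ux[free] += d[:nf]
            uy[free] += d[nf:2 * nf]
            pr += d[2 * nf:]
        rx, ry, rp, _ = momentum_residual(ux, uy, pr)
        rnorm = np.linalg.norm(np.concatenate([rx[free], ry[free], rp]))
        if rnorm > 1e-6:
            raise SolverError(
                f"flow solve did not converge: final residual {rnorm:.3e}"
            )
        return ux, uy, pr

    ux, uy, _ = solve_newton()
    bid = params is not None and params.bidirectional
    return VelocityTarget(ux, uy, -ux if bid else None, -uy if bid else None)


def _patch_dir(space: SplineSpace, patch) -> np.ndarray:
    """Downstream unit direction of a branch patch at its inlet section."""
    c0 = 0.5 * (patch.coords[0, 0] + patch.coords[0, -1])
    c1 = 0.5 * (patch.coords[1, 0] + patch.coords[1, -1])
    d = c1 - c0
    return d / np.linalg.norm(d)
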