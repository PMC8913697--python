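"""Discrete weak forms of the motor-assisted transport constraints.

The governing system couples the free-particle concentration ``n0``, the
moving-particle concentrations ``n±`` and the transport velocities ``v±``
with control forces ``f±``:

* free pool:      dn0/dt = -(k+ + k-) n0 + k'+ l+ n+ + k'- l- n-
* moving pools:   d(l± n±)/dt + v± . grad(l± n±)
                      = D± lap(l± n±) + k± n0 - k'± (l± n±)
* momentum:       dv±/dt + v± . grad(v±) = -grad(n±) + div(mu grad v±) + f±

with inlet data ``n0 = n_i``, ``n+ = lambda_i n_i`` and outlet data
``n0 = n_o``, ``n- = lambda_o n_o``; transport velocities match the target
``V±`` on the inlet.  Walls carry zero diffusive flux (nothing leaves
through the membrane) and the momentum equation is natural (free) on all
other boundaries.

Everything is discretized with the same scalar spline basis (Galerkin,
with SUPG streamline stabilization built on the *target* velocity so that
the discrete constraint stays exactly quadratic in the unknowns).  The
module also evaluates the traffic-regulation objective

    J = 1/2 int (v± - V±)^2 + alpha/2 int |grad n±|^2 + beta/2 int f±^2.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sps

from .errors import ConfigurationError
from .fields import MTDensityField, ParameterSet, VelocityTarget
from .meshing import SplineSpace

logger = logging.getLogger(__name__)

__all__ = [
    "StateFields",
    "ControlFields",
    "ObjectiveBreakdown",
    "assemble_constraint_residual",
    "evaluate_objective",
    "TransportSystem",
]


@dataclass
class StateFields:
    """Coefficient vectors of the state on the scalar spline space."""

    n0: np.ndarray
    n_plus: np.ndarray
    v_plus: tuple[np.ndarray, np.ndarray]
    n_minus: np.ndarray | None = None
    v_minus: tuple[np.ndarray, np.ndarray] | None = None

    @property
    def bidirectional(self) -> bool:
        return self.n_minus is not None

    @classmethod
    def zeros(cls, n: int, bidirectional: bool = False) -> "StateFields":
        z = lambda: np.zeros(n)  # noqa: E731
        if bidirectional:
            return cls(z(), z(), (z(), z()), z(), (z(), z()))
        return cls(z(), z(), (z(), z()))


@dataclass
class ControlFields:
    """Coefficient vectors of the control forces."""

    f_plus: tuple[np.ndarray, np.ndarray]
    f_minus: tuple[np.ndarray, np.ndarray] | None = None

    @classmethod
    def zeros(cls, n: int, bidirectional: bool = False) -> "ControlFields":
        z = lambda: np.zeros(n)  # noqa: E731
        if bidirectional:
            return cls((z(), z()), (z(), z()))
        return cls((z(), z()))


@dataclass
class ObjectiveBreakdown:
    """The three objective terms and their total."""

    tracking_term: float
    gradient_term: float
    control_term: float

    @property
    def total(self) -> float:
        return self.tracking_term + self.gradient_term + self.control_term

    def __iter__(self):
        yield from (self.tracking_term, self.gradient_term,
                    self.control_term, self.total)


# ---------------------------------------------------------------------------
# the assembled system
# ---------------------------------------------------------------------------

class TransportSystem:
    """Assembler for the constraint residual, its derivatives and the
    objective on a fixed (space, parameters, MT density, target) tuple.

    Works in *reduced* coordinates internally: Dirichlet dofs of each field
    are eliminated and constraint rows at those dofs are dropped, which is
    the symmetric elimination the KKT solve needs.  Public helpers convert
    between reduced vectors and full :class:`StateFields` /
    :class:`ControlFields`.
    """

    def __init__(self, space: SplineSpace, params: ParameterSet,
                 mt: MTDensityField, target: VelocityTarget | None = None):
        if params.bidirectional and target is not None and not target.bidirectional:
            raise ConfigurationError(
                "bidirectional mode requires a bidirectional velocity target"
            )
        self.space = space
        self.params = params
        self.mt = mt
        self.target = target
        bid = params.bidirectional
        self.bidirectional = bid

        self.sfields = ["n0", "np", "vpx", "vpy"] + (
            ["nm", "vmx", "vmy"] if bid else []
        )
        self.cfields = ["fpx", "fpy"] + (["fmx", "fmy"] if bid else [])
        # constraint blocks, one per state equation, in the same order
        self.blocks = ["b0", "bp", "bvx", "bvy"] + (
            ["bm", "bvmx", "bvmy"] if bid else []
        )

        n = space.n_dofs
        self.n = n
        inlet = space.dirichlet_dofs("inlet")
        outlets = [space.dirichlet_dofs(t)
                   for t in space.mesh.outlet_tags.values()]
        outlet = (np.unique(np.concatenate(outlets))
                  if outlets else np.empty(0, dtype=int))
        p = params

        tvx = target.vx_plus if target is not None else np.zeros(n)
        tvy = target.vy_plus if target is not None else np.zeros(n)
        # n0 carries Dirichlet data at both ends (inlet takes precedence
        # should a dof ever sit in both sets)
        both = np.union1d(inlet, outlet)
        vals = np.where(np.isin(both, inlet), p.n_in, p.n_out)
        self.bc: dict[str, tuple[np.ndarray, np.ndarray]] = {
            "n0": (both, vals),
            "np": (inlet, np.full(len(inlet), p.lambda_in * p.n_in)),
            "vpx": (inlet, tvx[inlet]),
            "vpy": (inlet, tvy[inlet]),
        }
        if bid:
            tvmx = target.vx_minus if target is not None else np.zeros(n)
            tvmy = target.vy_minus if target is not None else np.zeros(n)
            self.bc["nm"] = (outlet, np.full(len(outlet),
                                             p.lambda_out * p.n_out))
            self.bc["vmx"] = (inlet, tvmx[inlet])
            self.bc["vmy"] = (inlet, tvmy[inlet])

        alln = np.arange(n)
        self.free = {f: np.setdiff1d(alln, self.bc[f][0])
                     if f in self.bc else alln for f in self.sfields}
        for f in self.cfields:
            self.free[f] = alln
        self.nfree = {f: len(self.free[f]) for f in self.free}
        self.ns_red = sum(self.nfree[f] for f in self.sfields)
        self.nc_red = sum(self.nfree[f] for f in self.cfields)
        # block rows mirror their state field's free set
        self.block_field = {"b0": "n0", "bp": "np", "bvx": "vpx", "bvy": "vpy",
                            "bm": "nm", "bvmx": "vmx", "bvmy": "vmy"}

        self._prepare_quadrature()
        self._prepare_matrices()

    # -- cached quadrature-level data ----------------------------------
    def _prepare_quadrature(self):
        sp = self.space
        ED = sp.ELEM_DOFS
        self.ED = ED
        self.PHI, self.DPHI, self.W = sp.PHI, sp.DPHI, sp.W
        Ne, nq, nl = sp.PHI.shape
        self.Ne, self.nq, self.nl = Ne, nq, nl
        n = self.n

        if self.target is not None:
            self.Vxq = np.einsum("eqa,ea->eq", sp.PHI, self.target.vx_plus[ED])
            self.Vyq = np.einsum("eqa,ea->eq", sp.PHI, self.target.vy_plus[ED])
        else:
            self.Vxq = np.zeros((Ne, nq))
            self.Vyq = np.zeros((Ne, nq))

        h = sp.element_sizes
        p = self.params
        vmag = np.sqrt(self.Vxq**2 + self.Vyq**2).mean(axis=1)
        dt_term = 0.0
        if not p.steady:
            dt = p.T_horizon / p.n_time_steps
            dt_term = (2.0 / dt) ** 2

        def tau(D, sigma):
            denom2 = (2 * vmag / h) ** 2 + (4 * D / h**2) ** 2 + sigma**2 + dt_term
            out = np.zeros_like(denom2)
            mask = denom2 > 1e-30
            out[mask] = 1.0 / np.sqrt(denom2[mask])
            return out

        self.tau_p = tau(p.D_plus, p.kprime_plus)
        self.tau_v = tau(p.mu, 0.0)
        if self.bidirectional:
            self.tau_m = tau(p.D_minus, p.kprime_minus)

        # SUPG-augmented test functions, built on the target velocity
        vgrad = (self.Vxq[:, :, None] * self.DPHI[:, :, :, 0]
                 + self.Vyq[:, :, None] * self.DPHI[:, :, :, 1])
        self.TST_p = self.PHI + self.tau_p[:, None, None] * vgrad
        self.TST_v = self.PHI + self.tau_v[:, None, None] * vgrad
        if self.bidirectional:
            # the minus species is advected against the target direction
            self.TST_m = self.PHI - self.tau_m[:, None, None] * vgrad
        self.VGRAD = vgrad

    def _prepare_matrices(self):
        nl, n = self.nl, self.n
        ED = self.ED
        self._rows = np.repeat(ED, nl, axis=1).ravel()
        self._cols = np.tile(ED, (1, nl)).ravel()
        self.M = self._asm(np.einsum("eqa,eqb,eq->eab", self.PHI, self.PHI, self.W))
        self.K = self._asm(np.einsum("eqad,eqbd,eq->eab", self.DPHI, self.DPHI,
                                     self.W))
        self.Mlump = np.asarray(self.M.sum(axis=1)).ravel()

    def _asm(self, loc) -> sps.csr_matrix:
        return sps.coo_matrix((loc.ravel(), (self._rows, self._cols)),
                              shape=(self.n, self.n)).tocsr()

    # -- packing helpers ------------------------------------------------
    def state_to_dict(self, st: StateFields) -> dict[str, np.ndarray]:
        d = {"n0": st.n0, "np": st.n_plus,
             "vpx": st.v_plus[0], "vpy": st.v_plus[1]}
        if self.bidirectional:
            d.update({"nm": st.n_minus, "vmx": st.v_minus[0],
                      "vmy": st.v_minus[1]})
        return d

    def control_to_dict(self, ct: ControlFields) -> dict[str, np.ndarray]:
        d = {"fpx": ct.f_plus[0], "fpy": ct.f_plus[1]}
        if self.bidirectional:
            d.update({"fmx": ct.f_minus[0], "fmy": ct.f_minus[1]})
        return d

    def dict_to_state(self, d) -> StateFields:
        if self.bidirectional:
            return StateFields(d["n0"], d["np"], (d["vpx"], d["vpy"]),
                               d["nm"], (d["vmx"], d["vmy"]))
        return StateFields(d["n0"], d["np"], (d["vpx"], d["vpy"]))

    def dict_to_control(self, d) -> ControlFields:
        if self.bidirectional:
            return ControlFields((d["fpx"], d["fpy"]), (d["fmx"], d["fmy"]))
        return ControlFields((d["fpx"], d["fpy"]))

    def reduce(self, d: dict, fields: list[str]) -> np.ndarray:
        return np.concatenate([d[f][self.free[f]] for f in fields])

    def expand_state(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        out, k = {}, 0
        for f in self.sfields:
            full = np.zeros(self.n)
            if f in self.bc:
                dofs, vals = self.bc[f]
                full[dofs] = vals
            nf = self.nfree[f]
            full[self.free[f]] = vec[k:k + nf]
            k += nf
            out[f] = full
        return out

    def expand_control(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        out, k = {}, 0
        for f in self.cfields:
            full = np.zeros(self.n)
            nf = self.nfree[f]
            full[self.free[f]] = vec[k:k + nf]
            k += nf
            out[f] = full
        return out

    def expand_adjoint(self, vec: np.ndarray) -> dict[str, np.ndarray]:
        out, k = {}, 0
        for b in self.blocks:
            f = self.block_field[b]
            full = np.zeros(self.n)
            nf = self.nfree[f]
            full[self.free[f]] = vec[k:k + nf]
            k += nf
            out[b] = full
        return out

    def initial_state(self) -> dict[str, np.ndarray]:
        """Initial iterate: v = V, concentrations from boundary-data
        interpolation along the arc length, f = p = 0."""
        p = self.params
        sp = self.space
        n = self.n
        smax = np.nanmax(sp.ST[:, :, 0]) if np.any(np.isfinite(sp.ST)) else 1.0
        # arc length at each dof anchor, from the branch-patch Greville grid
        svals = np.full(n, np.nan)
        for pi, patch in enumerate(sp.mesh.patches):
            grid = sp.patch_dof_grids[pi]
            if patch.kind != "branch":
                continue
            from . import splines as _spl
            g = _spl.greville(patch.n_ax, sp.degree)
            for a in range(grid.shape[0]):
                svals[grid[a, :]] = patch.s_start + g[a] * patch.length
        svals[np.isnan(svals)] = 0.5 * smax
        frac = np.clip(svals / smax, 0.0, 1.0)
        d = {
            "n0": p.n_in + (p.n_out - p.n_in) * frac,
            "np": p.lambda_in * p.n_in * (1.0 - frac),
            "vpx": (self.target.vx_plus.copy() if self.target is not None
                    else np.zeros(n)),
            "vpy": (self.target.vy_plus.copy() if self.target is not None
                    else np.zeros(n)),
        }
        if self.bidirectional:
            d["nm"] = p.lambda_out * p.n_out * frac
            d["vmx"] = (self.target.vx_minus.copy()
                        if self.target is not None else np.zeros(n))
            d["vmy"] = (self.target.vy_minus.copy()
                        if self.target is not None else np.zeros(n))
        # overwrite Dirichlet dofs with their exact values
        for f, (dofs, vals) in self.bc.items():
            d[f][dofs] = vals
        return d

    # ------------------------------------------------------------------
    # constraint residual and derivatives
    # ------------------------------------------------------------------
    def _qp_fields(self, xd: dict) -> dict:
        """Values / gradients of the current iterate at quadrature points."""
        ED = self.ED
        out = {}
        for f in ("n0", "np", "vpx", "vpy") + (
            ("nm", "vmx", "vmy") if self.bidirectional else ()
        ):
            loc = xd[f][ED]
            out[f] = np.einsum("eqa,ea->eq", self.PHI, loc)
            out["g" + f] = np.einsum("eqad,ea->eqd", self.DPHI, loc)
        return out

    def _w_fields(self, q: dict, which: str) -> tuple[np.ndarray, np.ndarray]:
        """w = l n and grad w for the plus or minus species."""
        mt = self.mt
        if which == "p":
            l, gl = mt.LP, mt.GLP
            nf, gn = q["np"], q["gnp"]
        else:
            l, gl = mt.LM, mt.GLM
            nf, gn = q["nm"], q["gnm"]
        w = l * nf
        gw = l[:, :, None] * gn + nf[:, :, None] * gl
        return w, gw

    def residual_blocks(self, xd: dict, ud: dict,
                        prev: dict | None = None,
                        replace_dirichlet: bool = True
                        ) -> dict[str, np.ndarray]:
        """Full-size residual vectors per constraint block.

        Dirichlet rows are replaced by the constraint ``coef - value``
        (set ``replace_dirichlet=False`` to keep the raw Galerkin rows,
        whose boundary content is the weak boundary exchange).  ``prev``
        holds the previous time-step state in transient mode.
        """
        p = self.params
        if not p.steady and prev is None:
            raise ConfigurationError("transient mode requires previous_state")
        q = self._qp_fields(xd)
        W = self.W
        out = {}
        inv_dt = 0.0 if p.steady else p.n_time_steps / p.T_horizon

        def scatter(test, integrand):
            r = np.zeros(self.n)
            np.add.at(r, self.ED.ravel(),
                      np.einsum("eqa,eq->ea", test, integrand * W).ravel())
            return r

        # ---- free pool (no transport operator: plain Galerkin rows)
        kp, km = p.k_plus, (p.k_minus if self.bidirectional else 0.0)
        src = (kp + km) * q["n0"] - p.kprime_plus * self.mt.LP * q["np"]
        if self.bidirectional:
            src = src - p.kprime_minus * self.mt.LM * q["nm"]
        if inv_dt:
            qprev = np.einsum("eqa,ea->eq", self.PHI, prev["n0"][self.ED])
            src = src + inv_dt * (q["n0"] - qprev)
        out["b0"] = scatter(self.PHI, src)

        # ---- moving pools
        for which, tst, tag in (("p", self.TST_p, "p"),) + (
            (("m", self.TST_m, "m"),) if self.bidirectional else ()
        ):
            w, gw = self._w_fields(q, which)
            vx = q["vpx"] if which == "p" else q["vmx"]
            vy = q["vpy"] if which == "p" else q["vmy"]
            k = p.k_plus if which == "p" else p.k_minus
            kpr = p.kprime_plus if which == "p" else p.kprime_minus
            D = p.D_plus if which == "p" else p.D_minus
            strong = vx * gw[:, :, 0] + vy * gw[:, :, 1] - k * q["n0"] + kpr * w
            if inv_dt:
                l = self.mt.LP if which == "p" else self.mt.LM
                nprev = prev["np" if which == "p" else "nm"][self.ED]
                wprev = l * np.einsum("eqa,ea->eq", self.PHI, nprev)
                strong = strong + inv_dt * (w - wprev)
            r = scatter(tst, strong)
            # diffusion (Galerkin part only; walls are natural zero-flux)
            rd = np.zeros(self.n)
            np.add.at(rd, self.ED.ravel(),
                      np.einsum("eqad,eqd->ea", self.DPHI, gw * (D * W)[:, :, None]
                                ).ravel())
            r = r + rd
            out["bp" if which == "p" else "bm"] = r

        # ---- momentum
        for which in ("p",) + (("m",) if self.bidirectional else ()):
            tst = self.TST_v
            vx = q["vpx"] if which == "p" else q["vmx"]
            vy = q["vpy"] if which == "p" else q["vmy"]
            gvx = q["gvpx"] if which == "p" else q["gvmx"]
            gvy = q["gvpy"] if which == "p" else q["gvmy"]
            gn = q["gnp"] if which == "p" else q["gnm"]
            fx = ud["fpx"] if which == "p" else ud["fmx"]
            fy = ud["fpy"] if which == "p" else ud["fmy"]
            fxq = np.einsum("eqa,ea->eq", self.PHI, fx[self.ED])
            fyq = np.einsum("eqa,ea->eq", self.PHI, fy[self.ED])
            for comp, v_c, gv_c, f_c in (("x", vx, gvx, fxq),
                                         ("y", vy, gvy, fyq)):
                strong = (vx * gv_c[:, :, 0] + vy * gv_c[:, :, 1]
                          + gn[:, :, 0 if comp == "x" else 1] - f_c)
                if inv_dt:
                    key = ("v" + which + comp)
                    vprev = np.einsum("eqa,ea->eq", self.PHI,
                                      prev[key][self.ED])
                    strong = strong + inv_dt * (v_c - vprev)
                r = scatter(tst, strong)
                rd = np.zeros(self.n)
                np.add.at(rd, self.ED.ravel(),
                          np.einsum("eqad,eqd->ea", self.DPHI,
                                    gv_c * (p.mu * W)[:, :, None]).ravel())
                r = r + rd
                name = ("bvx" if comp == "x" else "bvy") if which == "p" else \
                       ("bvmx" if comp == "x" else "bvmy")
                out[name] = r

        # ---- Dirichlet rows replaced by coef - value
        if replace_dirichlet:
            for b in self.blocks:
                f = self.block_field[b]
                if f in self.bc:
                    dofs, vals = self.bc[f]
                    out[b][dofs] = xd[f][dofs] - vals
        return out

    def residual_reduced(self, xvec: np.ndarray, uvec: np.ndarray,
                         prev: dict | None = None) -> np.ndarray:
        xd = self.expand_state(xvec)
        ud = self.expand_control(uvec)
        blocks = self.residual_blocks(xd, ud, prev)
        return np.concatenate(
            [blocks[b][self.free[self.block_field[b]]] for b in self.blocks]
        )

    # -- Jacobian -------------------------------------------------------
    def jacobian(self, xd: dict) -> tuple[sps.csr_matrix, sps.csr_matrix]:
        """Reduced constraint Jacobians (d B / d state, d B / d control)."""
        p = self.params
        q = self._qp_fields(xd)
        W = self.W
        mt = self.mt
        inv_dt = 0.0 if p.steady else p.n_time_steps / p.T_horizon

        def loc(test, coefq):
            # integral of test_i * coefq * phi_j
            return np.einsum("eqa,eq,eqb->eab", test, coefq * W, self.PHI)

        def locg(test, cx, cy):
            # integral of test_i * (cx dphi_j/dx + cy dphi_j/dy)
            return np.einsum("eqa,eqb->eab", test,
                             cx[:, :, None] * W[:, :, None] * self.DPHI[:, :, :, 0]
                             + cy[:, :, None] * W[:, :, None] * self.DPHI[:, :, :, 1])

        J: dict[tuple[str, str], sps.csr_matrix] = {}
        km = p.k_minus if self.bidirectional else 0.0

        # b0 rows
        J["b0", "n0"] = self._asm(loc(self.PHI, np.full_like(W, p.k_plus + km)
                                      + inv_dt))
        J["b0", "np"] = self._asm(loc(self.PHI, -p.kprime_plus * mt.LP))
        if self.bidirectional:
            J["b0", "nm"] = self._asm(loc(self.PHI, -p.kprime_minus * mt.LM))

        # moving pools
        for which in ("p",) + (("m",) if self.bidirectional else ()):
            tst = self.TST_p if which == "p" else self.TST_m
            l = mt.LP if which == "p" else mt.LM
            gl = mt.GLP if which == "p" else mt.GLM
            k = p.k_plus if which == "p" else p.k_minus
            kpr = p.kprime_plus if which == "p" else p.kprime_minus
            D = p.D_plus if which == "p" else p.D_minus
            vx = q["vpx"] if which == "p" else q["vmx"]
            vy = q["vpy"] if which == "p" else q["vmy"]
            w, gw = self._w_fields(q, which)
            b = "bp" if which == "p" else "bm"
            nf = "np" if which == "p" else "nm"
            vxf = "vpx" if which == "p" else "vmx"
            vyf = "vpy" if which == "p" else "vmy"
            # d/dn: advection of (l phi_b + phi_b grad l) + reaction + time
            adv = np.einsum("eqa,eqb->eab", tst,
                            (vx * l)[:, :, None] * W[:, :, None]
                            * self.DPHI[:, :, :, 0]
                            + (vy * l)[:, :, None] * W[:, :, None]
                            * self.DPHI[:, :, :, 1]
                            + ((vx * gl[:, :, 0] + vy * gl[:, :, 1])
                               * W)[:, :, None] * self.PHI)
            react = loc(tst, (kpr + inv_dt) * l)
            diff = np.einsum("eqad,eqbd->eab", self.DPHI,
                             (D * W)[:, :, None, None]
                             * (l[:, :, None, None] * self.DPHI
                                + np.einsum("eqb,eqd->eqbd", self.PHI, gl)))
            J[b, nf] = self._asm(adv + react + diff)
            J[b, "n0"] = self._asm(loc(tst, np.full_like(W, -k)))
            J[b, vxf] = self._asm(loc(tst, gw[:, :, 0]))
            J[b, vyf] = self._asm(loc(tst, gw[:, :, 1]))

        # momentum
        for which in ("p",) + (("m",) if self.bidirectional else ()):
            tst = self.TST_v
            vx = q["vpx"] if which == "p" else q["vmx"]
            vy = q["vpy"] if which == "p" else q["vmy"]
            gvx = q["gvpx"] if which == "p" else q["gvmx"]
            gvy = q["gvpy"] if which == "p" else q["gvmy"]
            nf = "np" if which == "p" else "nm"
            for comp, gv_c in (("x", gvx), ("y", gvy)):
                b = ("bv" + ("m" if which == "m" else "") + comp)
                b = {"bvx": "bvx", "bvy": "bvy", "bvmx": "bvmx",
                     "bvmy": "bvmy"}[b]
                vxf = "vpx" if which == "p" else "vmx"
                vyf = "vpy" if which == "p" else "vmy"
                f_c = ("fp" if which == "p" else "fm") + comp
                # advection: v . grad(phi_b) delta_cd + phi_b dv_c/dx_d
                conv = locg(tst, vx, vy)
                visc = np.einsum("eqad,eqbd->eab", self.DPHI,
                                 (p.mu * W)[:, :, None, None] * self.DPHI)
                own = conv + loc(tst, gv_c[:, :, 0 if comp == "x" else 1]
                                 + inv_dt) + visc
                other = loc(tst, gv_c[:, :, 1 if comp == "x" else 0])
                if comp == "x":
                    J[b, vxf] = self._asm(own)
                    J[b, vyf] = self._asm(other)
                else:
                    J[b, vyf] = self._asm(own)
                    J[b, vxf] = self._asm(other)
                # pressure-like concentration gradient
                J[b, nf] = self._asm(np.einsum(
                    "eqa,eqb->eab", tst,
                    W[:, :, None] * self.DPHI[:, :, :, 0 if comp == "x" else 1]
                ))
                J[b, f_c] = self._asm(-loc(tst, np.ones_like(W)))

        Ax = self._compose(J, self.sfields)
        Au = self._compose(J, self.cfields)
        return Ax, Au

    def _compose(self, J: dict, cols: list[str]) -> sps.csr_matrix:
        rows = []
        for b in self.blocks:
            rfree = self.free[self.block_field[b]]
            row = []
            for f in cols:
                cfree = self.free[f]
                if (b, f) in J:
                    blk = J[b, f][rfree][:, cfree]
                else:
                    blk = sps.csr_matrix((len(rfree), len(cfree)))
                row.append(blk)
            rows.append(row)
        return sps.bmat(rows, format="csr")

    # -- Hessian of p^T B ----------------------------------------------
    def hessian_pTB(self, xd: dict, pd: dict) -> sps.csr_matrix:
        """Exact second derivative of the adjoint-weighted constraints.

        Because SUPG test directions are frozen at the target velocity the
        constraints are quadratic, so this matrix is state independent;
        ``xd`` is only used for shape bookkeeping.
        """
        W = self.W
        mt = self.mt
        C: dict[tuple[str, str], np.ndarray] = {}

        def acc(fa, fb, arr):
            key = (fa, fb)
            C[key] = C.get(key, 0.0) + arr

        for which in ("p",) + (("m",) if self.bidirectional else ()):
            tst = self.TST_p if which == "p" else self.TST_m
            l = mt.LP if which == "p" else mt.LM
            gl = mt.GLP if which == "p" else mt.GLM
            padj = pd["bp" if which == "p" else "bm"]
            Pq = np.einsum("eqa,ea->eq", tst, padj[self.ED])
            nf = "np" if which == "p" else "nm"
            vxf = "vpx" if which == "p" else "vmx"
            vyf = "vpy" if which == "p" else "vmy"
            # d2 / dv_c da dn_b of p . (v . grad(l n))
            for comp, vf in (("x", vxf), ("y", vyf)):
                di = 0 if comp == "x" else 1
                arr = np.einsum("eqa,eqb->eab", self.PHI,
                                (Pq * W)[:, :, None]
                                * (l[:, :, None] * self.DPHI[:, :, :, di]
                                   + gl[:, :, di][:, :, None] * self.PHI))
                acc(vf, nf, arr)
            # momentum convection p . (v . grad v_c)
            for comp in ("x", "y"):
                b = ("bv" + ("m" if which == "m" else "") + comp)
                b = {"bvx": "bvx", "bvy": "bvy",
                     "bvmx": "bvmx", "bvmy": "bvmy"}[b]
                padj = pd[b]
                Pq = np.einsum("eqa,ea->eq", self.TST_v, padj[self.ED])
                vcf = (vxf if comp == "x" else vyf)
                for d, vdf in ((0, vxf), (1, vyf)):
                    arr = np.einsum("eqa,eqb->eab", self.PHI,
                                    (Pq * W)[:, :, None] * self.DPHI[:, :, :, d])
                    acc(vdf, vcf, arr)

        # compose reduced symmetric matrix: H = C + C^T over state fields
        blocks = {}
        for (fa, fb), arr in C.items():
            mat = self._asm(arr)
            blocks[(fa, fb)] = blocks.get((fa, fb), 0) + mat
        rows = []
        for fa in self.sfields:
            row = []
            for fb in self.sfields:
                a = blocks.get((fa, fb))
                bT = blocks.get((fb, fa))
                tot = None
                if a is not None:
                    tot = a
                if bT is not None:
                    tot = bT.T if tot is None else tot + bT.T
                fra, frb = self.free[fa], self.free[fb]
                if tot is None:
                    row.append(sps.csr_matrix((len(fra), len(frb))))
                else:
                    row.append(tot[fra][:, frb])
            rows.append(row)
        return sps.bmat(rows, format="csr")

    # ------------------------------------------------------------------
    # objective
    # ------------------------------------------------------------------
    def objective(self, xd: dict, ud: dict) -> ObjectiveBreakdown:
        q = self._qp_fields(xd)
        W = self.W
        p = self.params
        track = 0.5 * np.sum(W * ((q["vpx"] - self.Vxq) ** 2
                                  + (q["vpy"] - self.Vyq) ** 2))
        grad = 0.5 * p.alpha * np.sum(
            W * np.einsum("eqd,eqd->eq", q["gnp"], q["gnp"]))
        fq = [np.einsum("eqa,ea->eq", self.PHI, ud[f][self.ED])
              for f in ("fpx", "fpy")]
        ctrl = 0.5 * p.beta * np.sum(W * (fq[0] ** 2 + fq[1] ** 2))
        if self.bidirectional:
            Vmx = np.einsum("eqa,ea->eq", self.PHI,
                            self.target.vx_minus[self.ED]) \
                if self.target is not None else 0.0
            Vmy = np.einsum("eqa,ea->eq", self.PHI,
                            self.target.vy_minus[self.ED]) \
                if self.target is not None else 0.0
            track += 0.5 * np.sum(W * ((q["vmx"] - Vmx) ** 2
                                       + (q["vmy"] - Vmy) ** 2))
            grad += 0.5 * p.alpha * np.sum(
                W * np.einsum("eqd,eqd->eq", q["gnm"], q["gnm"]))
            fqm = [np.einsum("eqa,ea->eq", self.PHI, ud[f][self.ED])
                   for f in ("fmx", "fmy")]
            ctrl += 0.5 * p.beta * np.sum(W * (fqm[0] ** 2 + fqm[1] ** 2))
        return ObjectiveBreakdown(float(track), float(grad), float(ctrl))

    def objective_grad_state(self, xd: dict) -> np.ndarray:
        """Reduced gradient of J with respect to the state."""
        p = self.params
        out = {}
        tv = self.target
        out["n0"] = np.zeros(self.n)
        out["np"] = p.alpha * (self.K @ xd["np"])
        vx0 = tv.vx_plus if tv is not None else 0.0
        vy0 = tv.vy_plus if tv is not None else 0.0
        out["vpx"] = self.M @ (xd["vpx"] - vx0)
        out["vpy"] = self.M @ (xd["vpy"] - vy0)
        if self.bidirectional:
            out["nm"] = p.alpha * (self.K @ xd["nm"])
            vmx0 = tv.vx_minus if tv is not None else 0.0
            vmy0 = tv.vy_minus if tv is not None else 0.0
            out["vmx"] = self.M @ (xd["vmx"] - vmx0)
            out["vmy"] = self.M @ (xd["vmy"] - vmy0)
        return self.reduce(out, self.sfields)

    def objective_grad_control(self, ud: dict) -> np.ndarray:
        p = self.params
        out = {f: p.beta * (self.M @ ud[f]) for f in self.cfields}
        return self.reduce(out, self.cfields)

    def objective_hess_state(self) -> sps.csr_matrix:
        """Reduced (constant) Hessian of J in the state variables."""
        p = self.params
        rows = []
        for fa in self.sfields:
            row = []
            for fb in self.sfields:
                fra, frb = self.free[fa], self.free[fb]
                if fa != fb:
                    row.append(sps.csr_matrix((len(fra), len(frb))))
                elif fa in ("np", "nm"):
                    row.append((p.alpha * self.K)[fra][:, frb])
                elif fa.startswith("v"):
                    row.append(self.M[fra][:, frb])
                else:
                    row.append(sps.csr_matrix((len(fra), len(frb))))
            rows.append(row)
        return sps.bmat(rows, format="csr")

    def objective_hess_control(self) -> sps.csr_matrix:
        p = self.params
        blocks = [(p.beta * self.M)[self.free[f]][:, self.free[f]]
                  for f in self.cfields]
        return sps.block_diag(blocks, format="csr")


# ---------------------------------------------------------------------------
# public module-level operations
# ---------------------------------------------------------------------------

def assemble_constraint_residual(space: SplineSpace, params: ParameterSet,
                                 mt: MTDensityField, state: StateFields,
                                 control: ControlFields,
                                 previous_state: StateFields | None = None,
                                 target: VelocityTarget | None = None,
                                 ) -> np.ndarray:
    """Galerkin residual of the transport constraints at the given fields.

    Returns the concatenated residual blocks (free pool, moving pools,
    momentum components), each of full dof length, with Dirichlet rows
    replaced by ``coefficient - boundary value``.
    """
    if state.bidirectional != params.bidirectional:
        raise ConfigurationError("state fields do not match the solver mode")
    sys_ = TransportSystem(space, params, mt, target)
    xd = sys_.state_to_dict(state)
    ud = sys_.control_to_dict(control)
    prev = sys_.state_to_dict(previous_state) if previous_state is not None \
        else None
    blocks = sys_.residual_blocks(xd, ud, prev)
    return np.concatenate([blocks[b] for b in sys_.blocks])


def evaluate_objective(space: SplineSpace, params: ParameterSet,
                       state: StateFields, control: ControlFields,
                       target: VelocityTarget | None = None,
                       mt: MTDensityField | None = None) -> ObjectiveBreakdown:
    """The traffic-regulation objective split into its three terms."""
    from .fields import make_mt_density

    if mt is None:
        mt = make_mt_density(space, "uniform", mode=params.mode)
    sys_ = TransportSystem(space, params, mt, target)
    return sys_.objective(sys_.state_to_dict(state),
                          sys_.control_to_dict(control))
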