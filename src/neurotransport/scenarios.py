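"""Named experiment configurations: normal transport, MT-reduction jams,
MT swirls with swelling, and the parameter sweeps.

Each scenario runs the full pipeline — skeleton, swept mesh, spline space,
microtubule densities, predefined velocity from the flow solve, and the
all-at-once KKT optimization — and attaches the standard diagnostics
(centerline profiles, concentration peaks, outlet means, and vortex
statistics for bidirectional runs).

Scenario runs use the transient formulation by default (backward Euler
over a horizon sized to the transport time scale of the geometry); the
steady formulation remains available through the parameter set but sits
close to solution-branch folds for strong jams.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fields import (MTDensityField, ParameterSet, VelocityTarget,
                     make_mt_density, solve_predefined_velocity)
from .geometry import GeometrySpec, Skeleton, clean_skeleton, \
    make_synthetic_skeleton
from .meshing import ControlMesh, SplineSpace, build_spline_space, sweep_mesh
from .optimizer import Solution, SolverOptions, solve_pdeco
from .postprocess import centerline_profile, vortex_diagnostics

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ScenarioResult",
    "SweepTable",
    "run_scenario",
    "parameter_sweep",
    "pipe_config",
    "swollen_pipe_config",
    "tree_config",
    "five_outlet_tree_spec",
    "ten_outlet_tree_spec",
]

#: default jam depth (fraction of MTs lost at the dip centre) and swirl
#: shape parameters; no measured magnitudes exist for these pathologies,
#: so the values below are the package's documented study conditions
DEFAULT_JAM_DEPTH = 0.6
DEFAULT_SWIRL_AMPLIFICATION = 2.0
DEFAULT_SWIRL_ASYMMETRY = 0.5


@dataclass
class ScenarioConfig:
    """Everything needed to run one experiment."""

    geometry: GeometrySpec
    scenario: str = "normal"          # normal | reduced_mt | swirl
    region: tuple | None = None       # (branch, s_lo, s_hi), branch arc length
    depth: float = DEFAULT_JAM_DEPTH
    amplification: float = DEFAULT_SWIRL_AMPLIFICATION
    asymmetry: float = DEFAULT_SWIRL_ASYMMETRY
    transition: float | None = None
    params: ParameterSet = field(default_factory=ParameterSet)
    n_transverse: int = 4
    axial_density: float = 0.25
    degree: int = 2
    inflow_speed: float = 1.0
    solver: SolverOptions = field(default_factory=SolverOptions)
    clean_tolerance: float = 1e-6

    def __post_init__(self):
        if self.scenario not in ("normal", "reduced_mt", "swirl"):
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "swirl":
            if not self.params.bidirectional:
                raise ConfigurationError("swirl scenarios require "
                                         "bidirectional mode")
            if self.geometry.kind not in ("swollen_pipe",) and \
                    self.geometry.swelling is None:
                raise ConfigurationError("swirl scenarios require a swelling")
        if self.scenario == "reduced_mt" and not (0 < self.depth < 1):
            raise ConfigurationError("reduced_mt requires depth in (0, 1)")

    def to_dict(self) -> dict:
        from dataclasses import asdict
        d = asdict(self)
        d["geometry"] = asdict(self.geometry)
        return d


@dataclass
class ScenarioResult:
    """A finished scenario: inputs, solution, and diagnostics."""

    config: ScenarioConfig
    skeleton: Skeleton
    mesh: ControlMesh
    space: SplineSpace
    mt: MTDensityField
    target: VelocityTarget
    solution: Solution
    diagnostics: dict

    # convenience pass-throughs used by postprocess
    @property
    def state(self):
        return self.solution.state

    @property
    def control(self):
        return self.solution.control

    def config_dict(self) -> dict:
        return self.config.to_dict()


# -- canned configurations ---------------------------------------------------

def pipe_config(scenario: str = "normal", **overrides) -> ScenarioConfig:
    """Single 80 x 4 um pipe; jam region over the middle quarter.

    Transient horizon 20 s (two detachment times) in 8 backward-Euler
    steps.
    """
    params = overrides.pop("params", ParameterSet(n_time_steps=8,
                                                  T_horizon=20.0))
    cfg = ScenarioConfig(
        geometry=GeometrySpec("pipe", length=80.0, base_radius=2.0,
                              spacing=10.0),
        scenario=scenario,
        region=(0, 30.0, 50.0) if scenario != "normal" else None,
        params=params,
        **overrides,
    )
    return cfg


def swollen_pipe_config(scenario: str = "swirl", **overrides) -> ScenarioConfig:
    """Pipe with a mid-length swelling (radius doubled over 20 um);
    the swirl region coincides with the swelling support."""
    params = overrides.pop("params",
                           ParameterSet(mode="bidirectional",
                                        n_time_steps=8, T_horizon=20.0))
    return ScenarioConfig(
        geometry=GeometrySpec("swollen_pipe", length=80.0, base_radius=2.0,
                              spacing=2.0, swelling=(40.0, 20.0, 2.0)),
        scenario=scenario,
        region=(0, 30.0, 50.0),
        params=params,
        **overrides,
    )


def five_outlet_tree_spec() -> GeometrySpec:
    """Synthetic 5-outlet tree (stand-in for a real traced morphology):
    a trunk splitting into a jam-prone limb (4 outlets) and one long
    unaffected branch."""
    br = [(-1, 30.0, 0.0, 2.0),
          (0, 25.0, 0.6, 1.8),     # branch 1: the jammed limb
          (0, 30.0, -0.7, 1.8),    # branch 2: the long free branch
          (1, 20.0, 0.55, 1.5),
          (1, 20.0, -0.55, 1.5),
          (3, 16.0, 0.5, 1.2), (3, 16.0, -0.5, 1.2),
          (4, 16.0, 0.5, 1.2), (4, 16.0, -0.5, 1.2)]
    return GeometrySpec("tree", branches=br, spacing=4.0)


def ten_outlet_tree_spec() -> GeometrySpec:
    """Synthetic 10-outlet tree (two limbs, one carrying a deeper
    sub-tree)."""
    br = [(-1, 26.0, 0.0, 2.0),
          (0, 22.0, 0.65, 1.7),    # limb A
          (0, 22.0, -0.65, 1.7),   # limb B
          (1, 18.0, 0.55, 1.4), (1, 18.0, -0.55, 1.4),   # A1, A2
          (2, 18.0, 0.55, 1.4), (2, 18.0, -0.55, 1.4),   # B1, B2
          (3, 14.0, 0.5, 1.1), (3, 14.0, -0.5, 1.1),     # leaves 1, 2
          (4, 14.0, 0.5, 1.1), (4, 14.0, -0.5, 1.1),     # leaves 3, 4
          (5, 14.0, 0.5, 1.1), (5, 14.0, -0.5, 1.1),     # leaves 5, 6
          (6, 14.0, 0.5, 1.1), (6, 14.0, -0.5, 1.1),     # B2a, B2b
          (13, 12.0, 0.45, 0.9), (13, 12.0, -0.45, 0.9),  # leaves 7, 8
          (14, 12.0, 0.45, 0.9), (14, 12.0, -0.45, 0.9)]  # leaves 9, 10
    return GeometrySpec("tree", branches=br, spacing=4.0)


def tree_config(scenario: str = "normal", n_outlets: int = 5,
                **overrides) -> ScenarioConfig:
    """Branched-tree scenario; jam on the first limb (branch 1).

    The horizon (100 s, 15 steps) covers the inlet-to-outlet transport
    time of the tree so jam effects reach the outlets.
    """
    spec = five_outlet_tree_spec() if n_outlets == 5 else ten_outlet_tree_spec()
    params = overrides.pop("params", ParameterSet(n_time_steps=15,
                                                  T_horizon=100.0))
    depth = overrides.pop("depth", 0.7)
    return ScenarioConfig(
        geometry=spec,
        scenario=scenario,
        region="branch1" if scenario != "normal" else None,  # resolved later
        params=params,
        depth=depth,
        **overrides,
    )


# -- the pipeline ------------------------------------------------------------

def _resolve_region(config: ScenarioConfig, mesh: ControlMesh):
    region = config.region
    if region is None:
        return None
    if region == "branch1":
        b = mesh.branches[1]
        L = b["meshed_length"]
        return (1, b["s_start"] + 0.2 * L, b["s_start"] + 0.9 * L)
    return region


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Execute the full pipeline for one scenario configuration.

    Stages: geometry -> mesh -> spline space -> MT densities -> predefined
    velocity -> all-at-once optimization -> diagnostics.  Errors are
    re-raised labeled with the failing stage.
    """
    stage = "geometry"
    try:
        skel = clean_skeleton(make_synthetic_skeleton(config.geometry),
                              config.clean_tolerance)
        stage = "meshing"
        mesh = sweep_mesh(skel, config.n_transverse, config.axial_density)
        space = build_spline_space(mesh, config.degree)
        stage = "mt_density"
        region = _resolve_region(config, mesh)
        kind = {"normal": "uniform", "reduced_mt": "reduced",
                "swirl": "swirl"}[config.scenario]
        mt = make_mt_density(space, kind, params=config.params, region=region,
                             depth=config.depth,
                             amplification=config.amplification,
                             asymmetry=config.asymmetry,
                             transition=config.transition)
        stage = "velocity"
        target = solve_predefined_velocity(space, config.inflow_speed,
                                           config.params)
        stage = "optimization"
        t0 = time.time()
        sol = solve_pdeco(space, config.params, mt, target, config.solver)
        logger.info("scenario %s: %s in %.1f s",
                    config.scenario,
                    "converged" if sol.converged else "NOT converged",
                    time.time() - t0)
        stage = "diagnostics"
        diag = _diagnostics(config, mesh, space, mt, target, sol, region)
    except Exception as exc:
        raise type(exc)(f"[stage: {stage}] {exc}") from exc
    return ScenarioResult(config, skel, mesh, space, mt, target, sol, diag)


class _FieldCarrier:
    """Minimal (space, state) view accepted by the postprocess helpers."""

    def __init__(self, space, state):
        self.space = space
        self.state = state


def _diagnostics(config, mesh, space, mt, target, sol, region) -> dict:
    res = _FieldCarrier(space, sol.state)
    diag: dict = {"converged": sol.converged,
                  "kkt_residual": float(sol.history[-1]) if len(sol.history)
                  else float("nan"),
                  "objective": tuple(sol.objective)}
    profiles = {}
    peaks = {}
    outlet_means = {}
    conc = sol.state.n0 + sol.state.n_plus
    for outlet in mesh.outlet_tags:
        prof = centerline_profile(res, outlet)
        profiles[outlet] = prof
        i = int(np.argmax(prof.value))
        peaks[outlet] = (float(prof.value[i]), float(prof.s[i]))
        num = den = 0.0
        for ed in space.edge_data(mesh.outlet_tags[outlet]):
            v = ed["B"] @ conc[ed["dofs"]]
            num += float((ed["W"] * v).sum())
            den += float(ed["W"].sum())
        outlet_means[outlet] = num / den
    diag["profiles"] = profiles
    diag["peaks"] = peaks
    diag["outlet_means"] = outlet_means
    vals = [p[0] for p in peaks.values()]
    locs = [p[1] for p in peaks.values()]
    diag["peak_value"] = max(vals)
    diag["peak_s"] = locs[int(np.argmax(vals))]
    if config.params.bidirectional and region is not None:
        diag["vortex"] = vortex_diagnostics(res, region)
    return diag


# -- parameter sweeps --------------------------------------------------------

DEFAULT_GRIDS = {
    "alpha": [1.0, 0.1, 0.01],
    "beta": [1.0, 0.1, 0.01],
    "k_ratio": [1.0, 10.0, 100.0],   # k fixed at 1/s; k' = k / ratio
}


@dataclass
class SweepTable:
    """Result of a parameter sweep as a tidy table.

    One row per grid point: parameter, value, the centerline concentration
    peak (value and arc-length location), the objective terms and the
    convergence flag.  All runs share the identical mesh and predefined
    velocity; only the parameter set varies.
    """

    table: pd.DataFrame

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def rows(self, parameter: str) -> pd.DataFrame:
        return self.table[self.table.parameter == parameter]


def parameter_sweep(base: ScenarioConfig,
                    grid: dict | None = None) -> SweepTable:
    """Run the scenario across parameter grids, sharing mesh and target.

    ``grid`` maps parameter names (any :class:`ParameterSet` field, or
    ``k_ratio`` for the attachment/detachment ratio with k fixed) to value
    lists; defaults to the standard alpha/beta/k-ratio grids.
    Non-converged runs are flagged in the table, not fatal.
    """
    grid = grid or DEFAULT_GRIDS
    skel = clean_skeleton(make_synthetic_skeleton(base.geometry),
                          base.clean_tolerance)
    mesh = sweep_mesh(skel, base.n_transverse, base.axial_density)
    space = build_spline_space(mesh, base.degree)
    region = _resolve_region(base, mesh)
    kind = {"normal": "uniform", "reduced_mt": "reduced",
            "swirl": "swirl"}[base.scenario]
    mt = make_mt_density(space, kind, params=base.params, region=region,
                         depth=base.depth, amplification=base.amplification,
                         asymmetry=base.asymmetry, transition=base.transition)
    target = solve_predefined_velocity(space, base.inflow_speed, base.params)

    rows = []
    for name, values in grid.items():
        for v in values:
            if name == "k_ratio":
                params = base.params.with_(kprime_plus=base.params.k_plus / v)
                if params.bidirectional:
                    params = params.with_(
                        kprime_minus=params.k_minus / v)
            elif hasattr(base.params, name):
                params = base.params.with_(**{name: v})
            else:
                raise ConfigurationError(f"unknown sweep parameter {name!r}")
            sol = solve_pdeco(space, params, mt, target, base.solver)
            res = _FieldCarrier(space, sol.state)
            peak_v, peak_s = -np.inf, np.nan
            for outlet in mesh.outlet_tags:
                prof = centerline_profile(res, outlet)
                i = int(np.argmax(prof.value))
                if prof.value[i] > peak_v:
                    peak_v, peak_s = float(prof.value[i]), float(prof.s[i])
            ob = sol.objective
            rows.append({
                "parameter": name, "value": v,
                "peak_concentration": peak_v, "peak_s": peak_s,
                "tracking_term": ob.tracking_term,
                "gradient_term": ob.gradient_term,
                "control_term": ob.control_term,
                "objective_total": ob.total,
                "converged": bool(sol.converged),
            })
            logger.info("sweep %s=%g: peak %.4f at s=%.1f (%s)",
                        name, v, peak_v, peak_s,
                        "ok" if sol.converged else "NOT CONVERGED")
    return SweepTable(pd.DataFrame(rows))
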