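"""Model / Results front end for the transport optimization.

:class:`TransportOptimizationModel` bundles a geometry, a parameter set
and a scenario into a fit-able object; :meth:`fit` runs the full pipeline
(mesh, microtubule densities, predefined velocity, all-at-once KKT solve)
and returns :class:`TransportResults`, which carries the estimated fields,
diagnostics and a printable summary, statsmodels-style.

    >>> model = TransportOptimizationModel.pipe(scenario="reduced_mt")
    >>> res = model.fit()
    >>> print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import replace
from pathlib import Path

import numpy as np

from .errors import ConfigurationError
from .fields import ParameterSet
from .geometry import GeometrySpec
from .optimizer import SolverOptions, n_unknown_field_groups
from .postprocess import centerline_profile, export_result
from .scenarios import (ScenarioConfig, ScenarioResult, SweepTable,
                        parameter_sweep, pipe_config, run_scenario,
                        swollen_pipe_config, tree_config)

__all__ = ["TransportOptimizationModel", "TransportResults"]


class TransportOptimizationModel:
    """PDE-constrained optimization model of motor-assisted transport.

    Construct from a :class:`ScenarioConfig` (or one of the convenience
    constructors), then call :meth:`fit`.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config

    # -- constructors ---------------------------------------------------
    @classmethod
    def pipe(cls, scenario: str = "normal", **kw):
        return cls(pipe_config(scenario, **kw))

    @classmethod
    def swollen_pipe(cls, scenario: str = "swirl", **kw):
        return cls(swollen_pipe_config(scenario, **kw))

    @classmethod
    def tree(cls, scenario: str = "normal", n_outlets: int = 5, **kw):
        return cls(tree_config(scenario, n_outlets, **kw))

    @classmethod
    def from_swc(cls, path, scenario: str = "normal", **kw):
        geometry = GeometrySpec("from_swc", swc_path=str(path))
        params = kw.pop("params", ParameterSet(n_time_steps=8, T_horizon=20.0))
        return cls(ScenarioConfig(geometry=geometry, scenario=scenario,
                                  params=params, **kw))

    @classmethod
    def from_config(cls, cfg) -> "TransportOptimizationModel":
        """Build from a configuration mapping or a YAML/JSON file path."""
        if isinstance(cfg, (str, Path)):
            import yaml

            with open(cfg) as fh:
                cfg = yaml.safe_load(fh)
        cfg = dict(cfg)
        geo = cfg.pop("geometry", None)
        if geo is None:
            raise ConfigurationError("configuration needs a geometry block")
        if isinstance(geo, dict):
            geo = dict(geo)
            for tupkey in ("swelling", "angles", "child_lengths"):
                if tupkey in geo and geo[tupkey] is not None:
                    geo[tupkey] = tuple(geo[tupkey])
            if geo.get("branches"):
                geo["branches"] = [tuple(b) for b in geo["branches"]]
            geometry = GeometrySpec(**geo)
        else:
            geometry = geo
        params = cfg.pop("params", {})
        if isinstance(params, dict):
            params = ParameterSet(**params)
        solver = cfg.pop("solver", {})
        if isinstance(solver, dict):
            solver = SolverOptions(**solver)
        region = cfg.pop("region", None)
        if isinstance(region, (list, tuple)):
            region = (int(region[0]), float(region[1]), float(region[2]))
        return cls(ScenarioConfig(geometry=geometry, params=params,
                                  solver=solver, region=region, **cfg))

    # -- fitting ---------------------------------------------------------
    def fit(self, options: SolverOptions | None = None) -> "TransportResults":
        """Run the pipeline and return the results object."""
        cfg = self.config
        if options is not None:
            cfg = replace(cfg, solver=options)
        result = run_scenario(cfg)
        return TransportResults(self, result)

    def sweep(self, grid: dict | None = None) -> SweepTable:
        """Parameter sweep sharing this model's mesh and target velocity."""
        return parameter_sweep(self.config, grid)

    @property
    def n_unknown_groups(self) -> int:
        return n_unknown_field_groups(self.config.params)


class TransportResults:
    """Fitted fields, diagnostics and reporting for one scenario run."""

    def __init__(self, model: TransportOptimizationModel,
                 result: ScenarioResult):
        self.model = model
        self.result = result

    # -- pass-throughs ---------------------------------------------------
    @property
    def state(self):
        return self.result.solution.state

    @property
    def control(self):
        return self.result.solution.control

    @property
    def adjoint(self):
        return self.result.solution.adjoint

    @property
    def objective(self):
        return self.result.solution.objective

    @property
    def converged(self) -> bool:
        return self.result.solution.converged

    @property
    def history(self) -> np.ndarray:
        return self.result.solution.history

    @property
    def diagnostics(self) -> dict:
        return self.result.diagnostics

    @property
    def space(self):
        return self.result.space

    # -- reporting -------------------------------------------------------
    def profile(self, outlet_id: int | None = None, **kw):
        """Centerline concentration profile to an outlet (default: first)."""
        mesh = self.result.mesh
        if outlet_id is None:
            outlet_id = sorted(mesh.outlet_tags)[0]
        return centerline_profile(self.result, outlet_id, **kw)

    def summary(self) -> str:
        """Plain-text summary table of the run."""
        r = self.result
        sol = r.solution
        cfg = r.config
        p = cfg.params
        lines = []
        w = 66
        lines.append("=" * w)
        lines.append("Transport optimization results".center(w))
        lines.append("=" * w)

        def row(a, b, c="", d=""):
            lines.append(f"{a:<22}{b:<14}{c:<20}{d}")

        row("Scenario:", cfg.scenario, "Geometry:", cfg.geometry.kind)
        row("Mode:", p.mode, "Unknown groups:",
            n_unknown_field_groups(p))
        row("Formulation:", "steady" if p.steady else
            f"transient ({p.n_time_steps} steps, T={p.T_horizon:g} s)")
        row("Elements:", r.mesh.n_elements, "Scalar dofs:", r.space.n_dofs)
        row("alpha:", f"{p.alpha:g}", "beta:", f"{p.beta:g}")
        row("k+/k'+:", f"{p.k_plus:g}/{p.kprime_plus:g}",
            "D+:", f"{p.D_plus:g} um^2/s")
        lines.append("-" * w)
        row("Converged:", str(sol.converged), "KKT residual:",
            f"{sol.history[-1]:.3e}" if len(sol.history) else "n/a")
        row("Newton evals:", len(sol.history) - 1)
        lines.append("-" * w)
        ob = sol.objective
        row("Objective total:", f"{ob.total:.6g}")
        row("  tracking:", f"{ob.tracking_term:.6g}")
        row("  gradient:", f"{ob.gradient_term:.6g}")
        row("  control:", f"{ob.control_term:.6g}")
        lines.append("-" * w)
        d = r.diagnostics
        row("Peak n0+n+:", f"{d['peak_value']:.4f}",
            "at s =", f"{d['peak_s']:.1f} um")
        for outlet, mean in sorted(d["outlet_means"].items()):
            row(f"  outlet {outlet} mean:", f"{mean:.4f}")
        if "vortex" in d:
            row("Vortex overlap:", f"{d['vortex'].overlap_score:.3f}",
                "circulation:", f"{d['vortex'].circulation:.3e}")
        lines.append("=" * w)
        return "\n".join(lines)

    def plot_profile(self, outlet_id: int | None = None, ax=None,
                     include_minus: bool = False):
        """Plot the centerline concentration profile (matplotlib axes)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        prof = self.profile(outlet_id, include_minus=include_minus)
        if ax is None:
            _, ax = plt.subplots()
        ax.plot(prof.s, prof.value)
        ax.set_xlabel("arc length from inlet (um)")
        ax.set_ylabel("concentration n0 + n+ (mol/um^2)")
        ax.set_title(f"centerline profile to outlet {prof.outlet_id}")
        return ax

    def save(self, path, what=("mesh", "fields", "profiles", "history")):
        """Export mesh/fields (VTK), profiles, history and the manifest."""
        return export_result(self.result, what, path)

    def to_json_manifest(self) -> str:
        return json.dumps(self.result.config_dict(), indent=2, default=str)
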