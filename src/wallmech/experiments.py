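"""Scenario sweeps of the inflated-cell model and their readouts.

A *scenario* is one condition of the in-silico experiment: which faces carry
anisotropic (transverse) microfibrils (case 1 = none, case 2 = longitudinal
anticlinal + inner periclinal, case 3 = those + outer periclinal), the factor
by which the three shear moduli are scaled at cell edges, the fractional
anisotropy assigned to isotropic and anisotropic faces, and the turgor
pressure.  The two headline readouts are the maximum displacement of the
outer-periclinal face (cell swelling) and the edge/face von Mises stress
concentration ratio.

Scenario solves use a quarter model with mirror-symmetry boundary conditions
by default: every case's material field is symmetric under reflection about
the cell's longitudinal and transverse mid-planes, and the symmetric branch
is the physically meaningful equilibrium (full-shell runs can wander onto
asymmetric lobed branches at high turgor).  Set ``full_model=True`` to run
the free shell with rigid-body pins instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .material import MaterialParameters
from .cellmesh import (CellGeometry, CellMesh, MaterialMap, assign_regions,
                       build_cell_mesh, quarter_cell_mesh, CASE_ANISO_FACES)
from .fesolver import (LoadCase, SolverOptions, Solution, solve_inflation,
                       compute_stress_field)

__all__ = [
    "ScenarioSpec",
    "SwellingReport",
    "make_scenario",
    "run_scenario",
    "sweep",
    "max_outer_displacement",
    "edge_stress_concentration",
    "DEFAULT_TURGOR_MPA",
]

#: default turgor pressure (MPa); typical root-cell turgor scale (assumption,
#: configurable per scenario)
DEFAULT_TURGOR_MPA = 0.8

#: experimentally measured CMT fractional anisotropies used as microfibril
#: proxies: 0.08 for the isotropic and 0.2 for the anisotropic condition
FA_MEASURED_ISO = 0.08
FA_MEASURED_ANISO = 0.2


@dataclass(frozen=True)
class ScenarioSpec:
    """One fully resolved inflation condition."""

    case_id: int = 1
    edge_factor: float = 1.0
    fa_iso: float = 0.0
    fa_aniso: float = 0.0
    turgor_pressure: float = DEFAULT_TURGOR_MPA
    overrides: dict = field(default_factory=dict)
    geometry: CellGeometry = field(default_factory=CellGeometry)
    load_steps: int = 6
    full_model: bool = False

    def __post_init__(self):
        if self.case_id not in CASE_ANISO_FACES:
            raise ValueError(f"unknown case id {self.case_id!r}")
        if self.edge_factor <= 0:
            raise ValueError("edge_factor must be positive")
        if not 0.0 <= self.fa_iso <= self.fa_aniso <= 1.0:
            raise ValueError("require 0 <= fa_iso <= fa_aniso <= 1")
        if self.turgor_pressure < 0:
            raise ValueError("turgor pressure must be >= 0")

    def face_parameters(self) -> MaterialParameters:
        """Baseline face parameter set (printed defaults + global overrides)."""
        p = MaterialParameters()
        glob = {k: v for k, v in self.overrides.items()
                if not isinstance(v, dict)}
        return p.with_overrides(**glob) if glob else p

    def label(self) -> str:
        return (f"case{self.case_id}_ef{self.edge_factor:g}"
                f"_fa{self.fa_iso:g}-{self.fa_aniso:g}")


def make_scenario(case_id: int, edge_factor: float = 1.0, fa_iso: float = 0.0,
                  fa_aniso: float | None = None, overrides: dict | None = None,
                  **kwargs) -> ScenarioSpec:
    """Build a scenario with defaults filled in.

    ``fa_aniso`` defaults to ``fa_iso`` (no face is effectively anisotropic).
    """
    if fa_aniso is None:
        fa_aniso = fa_iso
    return ScenarioSpec(case_id=case_id, edge_factor=edge_factor,
                        fa_iso=fa_iso, fa_aniso=fa_aniso,
                        overrides=dict(overrides or {}), **kwargs)


@dataclass
class SwellingReport:
    """Readouts of one converged scenario solve."""

    scenario: ScenarioSpec
    max_outer_displacement: float        # um
    max_displacement: float              # um, whole cell
    edge_face_vm_ratio: float
    n_newton_iterations: int
    n_load_steps: int

    def to_row(self) -> dict:
        s = self.scenario
        return {
            "case_id": s.case_id, "edge_factor": s.edge_factor,
            "fa_iso": s.fa_iso, "fa_aniso": s.fa_aniso,
            "turgor_MPa": s.turgor_pressure,
            "max_outer_displacement_um": self.max_outer_displacement,
            "max_displacement_um": self.max_displacement,
            "edge_face_vm_ratio": self.edge_face_vm_ratio,
            "newton_iterations": self.n_newton_iterations,
            "converged": True,
        }


def run_scenario(spec: ScenarioSpec,
                 opts: SolverOptions | None = None) -> SwellingReport:
    """Mesh, assign materials, solve the inflation, extract readouts."""
    if spec.full_model:
        mesh = build_cell_mesh(spec.geometry)
        constraint = "pins"
    else:
        mesh = quarter_cell_mesh(spec.geometry)
        constraint = "symmetry"
    mm = assign_regions(mesh, spec)
    load = LoadCase(turgor_pressure=spec.turgor_pressure,
                    load_steps=spec.load_steps, constraint=constraint)
    try:
        sol = solve_inflation(mesh, mm, load, opts)
    except Exception as err:
        raise type(err)(f"scenario {spec.label()}: {err}") from err
    _, vm = compute_stress_field(sol, mesh, mm, opts)
    return SwellingReport(
        scenario=spec,
        max_outer_displacement=max_outer_displacement(sol, mesh),
        max_displacement=float(np.linalg.norm(sol.u, axis=1).max()),
        edge_face_vm_ratio=edge_stress_concentration(vm, mesh),
        n_newton_iterations=len(sol.residual_history),
        n_load_steps=sol.n_steps_used,
    )


def sweep(specs, opts: SolverOptions | None = None) -> pd.DataFrame:
    """Run a grid of scenarios; one row per scenario, failures recorded."""
    specs = list(specs)
    if not specs:
        raise ValueError("empty scenario grid")
    rows = []
    for spec in specs:
        try:
            rows.append(run_scenario(spec, opts).to_row())
        except Exception as err:       # partial failures are data, not fatal
            rows.append({
                "case_id": spec.case_id, "edge_factor": spec.edge_factor,
                "fa_iso": spec.fa_iso, "fa_aniso": spec.fa_aniso,
                "turgor_MPa": spec.turgor_pressure,
                "max_outer_displacement_um": np.nan,
                "max_displacement_um": np.nan,
                "edge_face_vm_ratio": np.nan,
                "newton_iterations": np.nan,
                "converged": False, "error": str(err),
            })
    return pd.DataFrame(rows)


def max_outer_displacement(solution: Solution, mesh: CellMesh) -> float:
    """Maximum displacement magnitude over outer-periclinal face nodes (um)."""
    nid = mesh.nodes_on_face("outer-periclinal")
    return float(np.linalg.norm(solution.u[nid], axis=1).max())


def edge_stress_concentration(von_mises: np.ndarray, mesh: CellMesh) -> float:
    """Mean edge von Mises stress over mean face von Mises stress."""
    is_edge = mesh.is_edge
    if not is_edge.any() or is_edge.all():
        raise ValueError("mesh must contain both edge and face elements")
    return float(von_mises[is_edge].mean() / von_mises[~is_edge].mean())


def parameter_variation_grid(factors=(0.5, 2.0),
                             fields=("theta_f", "mu_c", "mu_m", "mu_f", "K"),
                             base_kwargs=None, **kwargs):
    """One-at-a-time constitutive-parameter variations of a base scenario.

    For each field and factor, returns a scenario whose global override
    multiplies the printed default by the factor (used for the
    sensitivity sweep around each condition).
    """
    base_kwargs = dict(base_kwargs or {"case_id": 1, "edge_factor": 1.0})
    defaults = MaterialParameters()
    specs = [make_scenario(**base_kwargs, **kwargs)]
    for f_ in fields:
        for c in factors:
            val = getattr(defaults, f_) * c
            if f_ == "theta_f":
                val = min(val, 1.0)
            specs.append(make_scenario(**base_kwargs,
                                       overrides={f_: val}, **kwargs))
    return specs


def figure_sweep_grid(edge_factors=(0.1, 1.0, 10.0),
                      fa_pairs=((0.0, 1.0), (FA_MEASURED_ISO, FA_MEASURED_ANISO)),
                      cases=(1, 2, 3), **kwargs):
    """The idealised + measured FA sweep over cases and edge factors."""
    return [make_scenario(case_id=c, edge_factor=ef, fa_iso=lo, fa_aniso=hi,
                          **kwargs)
            for (lo, hi) in fa_pairs for c in cases for ef in edge_factors]
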