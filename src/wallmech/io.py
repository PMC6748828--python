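"""Config reading/writing and mesh/solution export.

Scenario and material configs are YAML; material parameter blocks use the
keys ``K, mu_m, mu_f, mu_c, theta_f, a0, fa`` with an explicit ``units``
field ('MPa' internal, 'Pa' accepted with conversion).  Meshes and solution
fields are exported as legacy-ASCII VTK unstructured grids readable by
ParaView and friends.
"""

from __future__ import annotations

import numpy as np
import yaml

from .material import MaterialParameters
from .cellmesh import CellGeometry, CellMesh
from .experiments import ScenarioSpec, make_scenario

__all__ = [
    "load_scenario",
    "dump_scenario",
    "write_vtk",
]

_GEOM_KEYS = ("length_L", "width_T", "depth_R", "wall_thickness",
              "edge_band", "n_thickness", "face_spacing")


def load_scenario(path) -> ScenarioSpec:
    """Read a scenario spec from a YAML config file."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return scenario_from_dict(cfg)


def scenario_from_dict(cfg: dict) -> ScenarioSpec:
    cfg = dict(cfg)
    geom_cfg = cfg.pop("geometry", {})
    geometry = CellGeometry(**{k: geom_cfg[k] for k in _GEOM_KEYS
                               if k in geom_cfg})
    material = cfg.pop("material", None)
    overrides = dict(cfg.pop("overrides", {}))
    if material:
        # a full material block acts as a set of global overrides
        p = MaterialParameters.from_dict(material)
        overrides = {**p.to_dict(units="MPa"), **overrides}
        overrides.pop("units", None)
    return make_scenario(
        case_id=int(cfg.pop("case_id", 1)),
        edge_factor=float(cfg.pop("edge_factor", 1.0)),
        fa_iso=float(cfg.pop("fa_iso", 0.0)),
        fa_aniso=cfg.pop("fa_aniso", None),
        overrides=overrides,
        geometry=geometry,
        **{k: cfg[k] for k in ("turgor_pressure", "load_steps", "full_model")
           if k in cfg},
    )


def dump_scenario(spec: ScenarioSpec, path) -> None:
    cfg = {
        "case_id": spec.case_id,
        "edge_factor": spec.edge_factor,
        "fa_iso": spec.fa_iso,
        "fa_aniso": spec.fa_aniso,
        "turgor_pressure": spec.turgor_pressure,
        "load_steps": spec.load_steps,
        "full_model": spec.full_model,
        "overrides": spec.overrides,
        "geometry": {k: getattr(spec.geometry, k) for k in _GEOM_KEYS},
    }
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def write_vtk(path, mesh: CellMesh, cell_data: dict | None = None,
              point_data: dict | None = None) -> None:
    """Legacy-ASCII VTK unstructured grid with hexahedral cells."""
    nodes, elems = mesh.nodes, mesh.elems
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\nwallmech export\nASCII\n"
                 "DATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(nodes)} double\n")
        np.savetxt(fh, nodes, fmt="%.10g")
        fh.write(f"CELLS {len(elems)} {len(elems) * 9}\n")
        np.savetxt(fh, np.column_stack([np.full(len(elems), 8), elems]),
                   fmt="%d")
        fh.write(f"CELL_TYPES {len(elems)}\n")
        np.savetxt(fh, np.full(len(elems), 12), fmt="%d")   # VTK_HEXAHEDRON
        if cell_data:
            fh.write(f"CELL_DATA {len(elems)}\n")
            _write_fields(fh, cell_data, len(elems))
        if point_data:
            fh.write(f"POINT_DATA {len(nodes)}\n")
            _write_fields(fh, point_data, len(nodes))


def _write_fields(fh, fields: dict, n: int) -> None:
    for name, arr in fields.items():
        arr = np.asarray(arr)
        if len(arr) != n:
            raise ValueError(f"field {name!r} length mismatch")
        if arr.dtype.kind in "OU":        # labels -> integer codes
            labels, codes = np.unique(arr.astype(str), return_inverse=True)
            fh.write(f"SCALARS {name} int 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, codes, fmt="%d")
        elif arr.ndim == 1:
            fh.write(f"SCALARS {name} double 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, arr, fmt="%.10g")
        elif arr.ndim == 2 and arr.shape[1] == 3:
            fh.write(f"VECTORS {name} double\n")
            np.savetxt(fh, arr, fmt="%.10g")
        else:
            raise ValueError(f"cannot export field {name!r} of shape {arr.shape}")
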