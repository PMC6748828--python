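"""Shared fixtures.

The expensive finite-element computations (scenario sweep conditions, the
thin-sphere benchmark, the refinement pair) run once per session and are
shared between the module tests and the acceptance suite.
"""

import numpy as np
import pytest

from wallmech.cellmesh import (CellGeometry, MaterialMap, build_cell_mesh,
                               build_sphere_shell, quarter_cell_mesh)
from wallmech.experiments import (make_scenario, max_outer_displacement,
                                  run_scenario)
from wallmech.fesolver import LoadCase, compute_stress_field, solve_inflation
from wallmech.material import MaterialParameters

#: load-step count for the scenario suites (soft-edge cases need a fine ramp)
SCENARIO_STEPS = 16


@pytest.fixture(scope="session")
def scenario_results():
    """Converged swelling reports for every condition the suites compare."""
    specs = {
        "c1_ef0.1": make_scenario(1, 0.1, load_steps=SCENARIO_STEPS),
        "c1_ef1": make_scenario(1, 1.0, load_steps=SCENARIO_STEPS),
        "c1_ef10": make_scenario(1, 10.0, load_steps=SCENARIO_STEPS),
        "c2_fa1_ef0.1": make_scenario(2, 0.1, 0.0, 1.0,
                                      load_steps=SCENARIO_STEPS),
        "c3_fa1_ef0.1": make_scenario(3, 0.1, 0.0, 1.0,
                                      load_steps=SCENARIO_STEPS),
        "c3_meas_iso_ef0.1": make_scenario(3, 0.1, 0.08, 0.08,
                                           load_steps=SCENARIO_STEPS),
        "c3_meas_ani_ef0.1": make_scenario(3, 0.1, 0.08, 0.2,
                                           load_steps=SCENARIO_STEPS),
        "c1_theta25_ef1": make_scenario(1, 1.0, overrides={"theta_f": 0.25},
                                        load_steps=SCENARIO_STEPS),
        "c3_fa1_ef1": make_scenario(3, 1.0, 0.0, 1.0,
                                    load_steps=SCENARIO_STEPS),
    }
    return {k: run_scenario(s) for k, s in specs.items()}


@pytest.fixture(scope="session")
def quarter_mesh():
    return quarter_cell_mesh(CellGeometry())


@pytest.fixture(scope="session")
def sphere_hoop_result():
    """Near-incompressible thin-sphere benchmark: (mean hoop, pR/2t)."""
    R, t = 10.0, 0.4
    m = build_sphere_shell(R, t, n_face=16, n_thickness=2)
    mu = 2.0
    mm = MaterialMap.uniform(m.n_elems, MaterialParameters(
        K=1000 * mu, mu_m=mu, mu_f=0.0, mu_c=0.0, theta_f=0.0, fa=0.0))
    p = 0.01
    pins = []
    for tgt in ([0, 0, -(R - t)], [0, 0, R - t], [R - t, 0, 0]):
        n = int(np.argmin(np.abs(m.nodes - np.array(tgt)).sum(axis=1)))
        if n not in pins:
            pins.append(n)
    n0, n1, n2 = pins
    lc = LoadCase(turgor_pressure=p, load_steps=1, constraint="none",
                  prescribed={3 * n0: 0.0, 3 * n0 + 1: 0.0, 3 * n0 + 2: 0.0,
                              3 * n1: 0.0, 3 * n1 + 1: 0.0, 3 * n2 + 1: 0.0})
    sol = solve_inflation(m, mm, lc)
    sig, _ = compute_stress_field(sol, m, mm)
    cent = m.nodes[m.elems].mean(axis=1)
    rhat = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    srr = np.einsum("ei,eij,ej->e", rhat, sig, rhat)
    hoop = (np.trace(sig, axis1=1, axis2=2) - srr) / 2.0
    return float(hoop.mean()), p * (R - t / 2.0) / (2.0 * t)


@pytest.fixture(scope="session")
def refinement_pair():
    """Max outer displacement at successive in-plane refinements (default
    scenario, quarter model)."""
    outs = []
    for h in (1.5, 1.0):
        g = CellGeometry(n_thickness=2, face_spacing=h)
        m = quarter_cell_mesh(g)
        mm = MaterialMap.uniform(m.n_elems, MaterialParameters())
        sol = solve_inflation(m, mm, LoadCase(
            turgor_pressure=0.8, load_steps=16, constraint="symmetry"))
        outs.append(max_outer_displacement(sol, m))
    return outs
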