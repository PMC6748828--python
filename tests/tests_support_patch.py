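"""Single-element patch test helper shared by the solver and acceptance suites."""

import numpy as np

from wallmech import material as mat
from wallmech.cellmesh import CellMesh, MaterialMap
from wallmech.fesolver import LoadCase, compute_stress_field, solve_inflation
from wallmech.material import DeformationState, MaterialParameters


def run_patch_test(fa: float = 0.4):
    """Affine Dirichlet BCs on one hexahedron; returns (FE stress, exact)."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [1, 1, 0], [0, 1, 0],
                      [0, 0, 1], [1, 0, 1], [1, 1, 1], [0, 1, 1]],
                     dtype=float)
    elems = np.array([[0, 1, 2, 3, 4, 5, 6, 7]])
    mesh = CellMesh(nodes=nodes, elems=elems,
                    region=np.array(["face"], dtype=object),
                    inner_facets=np.empty((0, 4), dtype=int))
    p = MaterialParameters(K=200.0, fa=fa, a0=np.array([0, 0, 1.0]))
    mm = MaterialMap.uniform(1, p)
    G = np.array([[0.04, 0.015, 0.0],
                  [0.01, -0.02, 0.012],
                  [0.0, 0.02, 0.05]])
    prescribed = {3 * n + i: (G @ X)[i]
                  for n, X in enumerate(nodes) for i in range(3)}
    sol = solve_inflation(mesh, mm, LoadCase(
        turgor_pressure=0.0, load_steps=1, constraint="none",
        prescribed=prescribed))
    sig, _ = compute_stress_field(sol, mesh, mm)
    exact = mat.cauchy_stress(
        DeformationState.from_F(np.eye(3) + G, p.structure_tensor), p)
    return sig[0], exact
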