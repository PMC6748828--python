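"""Hexahedral mesh of an idealised meristematic-cell wall shell.

The cell is a rectangular box aligned with the organ axes — L (longitudinal,
x), T (transverse, y), R (radial, z) — whose wall of uniform thickness is
meshed with trilinear hexahedra.  Every element carries exactly one region
label: one of the six faces (outer/inner periclinal, two longitudinal
anticlinal, two transverse anticlinal) or one of the twelve edges, identified
by the pair of faces that meet there.  Edges are sharp (unfilleted); the
mechanical distinction is carried by a band of elements within ``edge_band``
of each geometric edge line, mirroring the 0-1 um edge definition used in the
image analysis.  Corner elements are assigned to the edge region (ties broken
toward edges).

The cavity side of the shell is recorded as an oriented facet list on which
the solver applies turgor pressure.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np

from .material import MaterialParameters

__all__ = [
    "CellGeometry",
    "CellMesh",
    "MaterialMap",
    "build_cell_mesh",
    "build_sphere_shell",
    "assign_regions",
    "FACE_NAMES",
    "EDGE_NAMES",
]

# face names keyed by (axis, side): side 0 = min coordinate, 1 = max
_FACE_BY_PLANE = {
    (0, 0): "transverse-anticlinal-min",
    (0, 1): "transverse-anticlinal-max",
    (1, 0): "longitudinal-anticlinal-min",
    (1, 1): "longitudinal-anticlinal-max",
    (2, 0): "inner-periclinal",
    (2, 1): "outer-periclinal",
}
FACE_NAMES = tuple(_FACE_BY_PLANE.values())

# the 12 geometric edges: pairs of orthogonal boundary planes
_EDGE_PLANES = [
    ((ax1, s1), (ax2, s2))
    for (ax1, ax2) in [(0, 1), (0, 2), (1, 2)]
    for s1 in (0, 1) for s2 in (0, 1)
]
EDGE_NAMES = tuple(
    "edge:" + "|".join(sorted((_FACE_BY_PLANE[p1], _FACE_BY_PLANE[p2])))
    for p1, p2 in _EDGE_PLANES
)


@dataclass(frozen=True)
class CellGeometry:
    """Outer dimensions (um) and discretisation of the idealised cell."""

    length_L: float = 20.0
    width_T: float = 10.0
    depth_R: float = 10.0
    wall_thickness: float = 0.5
    edge_band: float = 1.0
    n_thickness: int = 2          # element layers through the wall
    face_spacing: float = 2.0     # target in-plane element size away from edges

    def __post_init__(self):
        dims = (self.length_L, self.width_T, self.depth_R)
        if min(dims) <= 0 or self.wall_thickness <= 0:
            raise ValueError("all dimensions must be positive")
        if self.wall_thickness >= min(dims) / 4:
            raise ValueError("wall_thickness must be < min dimension / 4")
        if self.edge_band < self.wall_thickness:
            raise ValueError("edge_band must be >= wall_thickness")
        if self.n_thickness < 1 or self.face_spacing <= 0:
            raise ValueError("invalid resolution")

    @property
    def dims(self) -> tuple:
        return (self.length_L, self.width_T, self.depth_R)

    def refined(self, factor: int = 2) -> "CellGeometry":
        """Uniformly refined copy (both through-thickness and in-plane)."""
        return replace(self, n_thickness=self.n_thickness * factor,
                       face_spacing=self.face_spacing / factor)


@dataclass
class CellMesh:
    """Hexahedral shell mesh with region labels and pressurised cavity facets."""

    nodes: np.ndarray              # (N, 3) coordinates, um
    elems: np.ndarray              # (E, 8) connectivity, VTK hex ordering
    region: np.ndarray             # (E,) region label strings
    inner_facets: np.ndarray       # (M, 4) facet connectivity on the cavity
    geometry: CellGeometry | None = None
    symmetry_planes: tuple = ()    # ((axis, coordinate), ...) for cut models

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elems(self) -> int:
        return len(self.elems)

    @property
    def is_edge(self) -> np.ndarray:
        return np.char.startswith(self.region.astype(str), "edge:")

    def elements_in(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.region == label)

    def element_volumes(self) -> np.ndarray:
        """Exact volumes via 8-point Gauss quadrature of det(dX/dxi)."""
        from .fesolver import _grad_operators
        _, detJw = _grad_operators(self.nodes, self.elems)
        return detJw.sum(axis=1)

    def centroids(self) -> np.ndarray:
        return self.nodes[self.elems].mean(axis=1)

    def nodes_on_face(self, label: str, outer: bool = True) -> np.ndarray:
        """Node ids on the outer boundary surface of a named face region."""
        if self.geometry is None:
            raise ValueError("mesh has no box geometry attached")
        (ax, side) = next(k for k, v in _FACE_BY_PLANE.items() if v == label)
        coord = self.geometry.dims[ax] if side else 0.0
        elems = self.elements_in(label)
        if elems.size == 0:
            raise ValueError(f"no elements labelled {label!r}")
        nid = np.unique(self.elems[elems])
        on_plane = np.isclose(self.nodes[nid, ax], coord, atol=1e-9)
        return nid[on_plane]


def _axis_breakpoints(L: float, geom: CellGeometry) -> np.ndarray:
    """Graded 1D breakpoints: wall layers, one edge-band cell, coarse interior."""
    t, band, nt = geom.wall_thickness, geom.edge_band, geom.n_thickness
    pts = list(np.linspace(0.0, t, nt + 1))
    if band > t + 1e-12:
        # resolve the edge band with cells no larger than band - t
        nb = max(1, int(np.ceil((band - t) / min(geom.face_spacing, band - t))))
        pts += list(np.linspace(t, band, nb + 1))[1:]
    interior = L - 2 * band
    if interior <= 0:
        raise ValueError("edge bands overlap: cell too small for edge_band")
    ni = max(2, int(np.ceil(interior / geom.face_spacing)))
    ni += ni % 2          # even count => the mid-plane is a grid plane
    pts += list(np.linspace(band, L - band, ni + 1))[1:]
    pts += [L - p for p in reversed(pts[:-1]) if L - p > pts[-1] + 1e-12]
    return np.array(sorted(set(np.round(pts, 12))))


def _hex_grid(xs, ys, zs):
    """Structured node grid + full hex connectivity (VTK ordering)."""
    nx, ny, nz = len(xs), len(ys), len(zs)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * ny + j) * nz + k

    I, J, K = np.meshgrid(np.arange(nx - 1), np.arange(ny - 1),
                          np.arange(nz - 1), indexing="ij")
    I, J, K = I.ravel(), J.ravel(), K.ravel()
    elems = np.column_stack([
        nid(I, J, K), nid(I + 1, J, K), nid(I + 1, J + 1, K), nid(I, J + 1, K),
        nid(I, J, K + 1), nid(I + 1, J, K + 1), nid(I + 1, J + 1, K + 1),
        nid(I, J + 1, K + 1),
    ])
    return nodes, elems, (I, J, K)


# local faces of a hex (VTK ordering) keyed by (axis, side); node order chosen
# so the right-hand normal points in the -axis/+axis direction of *that* face.
_LOCAL_FACES = {
    (0, 0): (0, 4, 7, 3),   # -x
    (0, 1): (1, 2, 6, 5),   # +x
    (1, 0): (0, 1, 5, 4),   # -y
    (1, 1): (3, 7, 6, 2),   # +y
    (2, 0): (0, 3, 2, 1),   # -z
    (2, 1): (4, 5, 6, 7),   # +z
}


def build_cell_mesh(geom: CellGeometry) -> CellMesh:
    """Mesh the closed box-shell wall and label face/edge regions.

    Deterministic for fixed inputs.  Raises if the discretisation cannot
    separate the edge band from face interiors.
    """
    axes = [_axis_breakpoints(L, geom) for L in geom.dims]
    for ax, L in zip(axes, geom.dims):
        if len(ax) < 2 * geom.n_thickness + 3:
            raise ValueError("resolution too coarse to separate edge band")
    nodes, elems, (I, J, K) = _hex_grid(*axes)
    t = geom.wall_thickness
    dims = geom.dims

    # keep an element iff it is not fully inside the cavity box [t, L-t]^3
    cent = nodes[elems].mean(axis=1)
    inside = np.ones(len(elems), dtype=bool)
    for ax in range(3):
        lo = nodes[elems][:, :, ax].min(axis=1)
        hi = nodes[elems][:, :, ax].max(axis=1)
        inside &= (lo >= t - 1e-9) & (hi <= dims[ax] - t + 1e-9)
    keep = ~inside

    # cavity facets: faces of kept elements adjacent to removed elements
    grid_shape = tuple(len(a) - 1 for a in axes)
    lin = np.full(grid_shape, -1, dtype=int)
    lin[I, J, K] = np.arange(len(elems))
    inside_grid = np.zeros(grid_shape, dtype=bool)
    inside_grid[I[inside], J[inside], K[inside]] = True

    facets = []
    kept_ids = np.flatnonzero(keep)
    ijk = np.column_stack([I, J, K])
    for e in kept_ids:
        i, j, k = ijk[e]
        for ax, side in _LOCAL_FACES:
            step = [0, 0, 0]
            step[ax] = 1 if side else -1
            ni_, nj_, nk_ = i + step[0], j + step[1], k + step[2]
            if (0 <= ni_ < grid_shape[0] and 0 <= nj_ < grid_shape[1]
                    and 0 <= nk_ < grid_shape[2] and inside_grid[ni_, nj_, nk_]):
                local = _LOCAL_FACES[(ax, side)]
                facets.append(elems[e][list(local)])
    facets = np.array(facets, dtype=int)

    # compact node numbering
    elems = elems[keep]
    cent = cent[keep]
    used = np.unique(np.concatenate([elems.ravel(), facets.ravel()]))
    remap = np.full(len(nodes), -1, dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    elems = remap[elems]
    facets = remap[facets]

    region = _label_regions(cent, geom)
    return CellMesh(nodes=nodes, elems=elems, region=region,
                    inner_facets=facets, geometry=geom)


def _label_regions(cent: np.ndarray, geom: CellGeometry) -> np.ndarray:
    """Assign each element (by centroid) to a face or edge region."""
    t, band = geom.wall_thickness, geom.edge_band
    dims = geom.dims
    # distance of centroid to each boundary plane
    dplane = {}
    for ax in range(3):
        dplane[(ax, 0)] = cent[:, ax]
        dplane[(ax, 1)] = dims[ax] - cent[:, ax]

    # distance to each of the 12 edge lines
    dedge = np.stack([np.hypot(dplane[p1], dplane[p2])
                      for p1, p2 in _EDGE_PLANES], axis=1)
    nearest_edge = np.argmin(dedge, axis=1)
    dmin_edge = dedge[np.arange(len(cent)), nearest_edge]

    in_plane = np.stack([dplane[k] < t for k in _FACE_BY_PLANE], axis=1)
    n_planes = in_plane.sum(axis=1)
    plane_keys = list(_FACE_BY_PLANE)

    is_edge = (dmin_edge <= band) | (n_planes >= 2)
    region = np.empty(len(cent), dtype=object)
    region[is_edge] = np.array(EDGE_NAMES, dtype=object)[nearest_edge[is_edge]]
    face_idx = np.argmin(np.stack([dplane[k] for k in plane_keys], axis=1), axis=1)
    face_lbl = np.array([_FACE_BY_PLANE[plane_keys[i]] for i in face_idx],
                        dtype=object)
    region[~is_edge] = face_lbl[~is_edge]
    return region


def quarter_cell_mesh(geom: CellGeometry) -> CellMesh:
    """Quarter model exploiting the cell's mirror symmetry in L and T.

    All inflation scenarios have material fields symmetric under reflection
    about the mid-planes x = L/2 and y = T/2 (the inner/outer periclinal
    faces may differ, so the radial mid-plane is *not* assumed).  Keeping
    only x < L/2, y < T/2 quarters the system; the solver applies zero
    normal displacement on the cut planes.
    """
    full = build_cell_mesh(geom)
    L, T, _ = geom.dims
    cent = full.centroids()
    keep = (cent[:, 0] < L / 2 + 1e-9) & (cent[:, 1] < T / 2 + 1e-9)
    elems = full.elems[keep]
    region = full.region[keep]
    kept_nodes = np.unique(elems)
    fkeep = np.all(np.isin(full.inner_facets, kept_nodes), axis=1)
    # facets fully contained in the kept quarter
    fc = full.nodes[full.inner_facets].mean(axis=1)
    fkeep &= (fc[:, 0] < L / 2 + 1e-9) & (fc[:, 1] < T / 2 + 1e-9)
    facets = full.inner_facets[fkeep]
    used = np.unique(np.concatenate([elems.ravel(), facets.ravel()]))
    remap = np.full(full.n_nodes, -1, dtype=int)
    remap[used] = np.arange(len(used))
    return CellMesh(nodes=full.nodes[used], elems=remap[elems], region=region,
                    inner_facets=remap[facets], geometry=geom,
                    symmetry_planes=((0, L / 2), (1, T / 2)))


def build_sphere_shell(radius: float, thickness: float, n_face: int = 8,
                       n_thickness: int = 2) -> CellMesh:
    """Cubed-sphere hexahedral shell: verification fixture for the solver.

    Maps a cube shell radially onto a spherical shell with outer ``radius``
    and the given wall ``thickness``.  Region labels are all 'shell'.
    """
    if thickness >= radius:
        raise ValueError("thickness must be < radius")
    half = 1.0
    tau = 0.3  # cube-shell thickness before mapping (arbitrary, remapped)
    xs = np.concatenate([
        np.linspace(-half, -half + tau, n_thickness + 1),
        np.linspace(-half + tau, half - tau, n_face + 1)[1:-1],
        np.linspace(half - tau, half, n_thickness + 1),
    ])
    nodes, elems, (I, J, K) = _hex_grid(xs, xs, xs)
    lo = nodes[elems].min(axis=1)
    hi = nodes[elems].max(axis=1)
    inside = np.all(lo >= -half + tau - 1e-12, axis=1) & \
        np.all(hi <= half - tau + 1e-12, axis=1)
    keep = ~inside

    grid_shape = (len(xs) - 1,) * 3
    inside_grid = np.zeros(grid_shape, dtype=bool)
    inside_grid[I[inside], J[inside], K[inside]] = True
    facets = []
    ijk = np.column_stack([I, J, K])
    for e in np.flatnonzero(keep):
        i, j, k = ijk[e]
        for (ax, side), local in _LOCAL_FACES.items():
            step = [0, 0, 0]
            step[ax] = 1 if side else -1
            ni_, nj_, nk_ = i + step[0], j + step[1], k + step[2]
            if (0 <= ni_ < grid_shape[0] and 0 <= nj_ < grid_shape[1]
                    and 0 <= nk_ < grid_shape[2] and inside_grid[ni_, nj_, nk_]):
                facets.append(elems[e][list(local)])
    facets = np.array(facets, dtype=int)

    elems = elems[keep]
    used = np.unique(np.concatenate([elems.ravel(), facets.ravel()]))
    remap = np.full(len(nodes), -1, dtype=int)
    remap[used] = np.arange(len(used))
    nodes = nodes[used]
    elems = remap[elems]
    facets = remap[facets]

    # radial map: cube-shell depth -> spherical-shell depth
    rho = np.max(np.abs(nodes), axis=1)              # inf-norm in [1-tau, 1]
    s = np.clip((rho - (half - tau)) / tau, 0.0, 1.0)
    surf = nodes / rho[:, None]                       # point on unit cube face
    u = surf / np.linalg.norm(surf, axis=1, keepdims=True)
    r = (radius - thickness) + s * thickness
    nodes = u * r[:, None]

    region = np.full(len(elems), "shell", dtype=object)
    return CellMesh(nodes=nodes, elems=elems, region=region,
                    inner_facets=facets, geometry=None)


# ---------------------------------------------------------------------------
# Material assignment
# ---------------------------------------------------------------------------

# faces carrying anisotropic (transverse) microfibrils in each scenario case
CASE_ANISO_FACES = {
    1: frozenset(),
    2: frozenset({"longitudinal-anticlinal-min", "longitudinal-anticlinal-max",
                  "inner-periclinal"}),
    3: frozenset({"longitudinal-anticlinal-min", "longitudinal-anticlinal-max",
                  "inner-periclinal", "outer-periclinal"}),
}

# transverse microfibril direction within each wall plane: perpendicular to
# the organ longitudinal (x) axis, lying in the wall tangent plane
_TRANSVERSE_A0 = {
    "outer-periclinal": np.array([0.0, 1.0, 0.0]),
    "inner-periclinal": np.array([0.0, 1.0, 0.0]),
    "longitudinal-anticlinal-min": np.array([0.0, 0.0, 1.0]),
    "longitudinal-anticlinal-max": np.array([0.0, 0.0, 1.0]),
    "transverse-anticlinal-min": np.array([0.0, 1.0, 0.0]),
    "transverse-anticlinal-max": np.array([0.0, 1.0, 0.0]),
}


@dataclass
class MaterialMap:
    """Per-element constitutive parameters in array form for FE assembly."""

    K: np.ndarray
    mu_m: np.ndarray
    mu_f: np.ndarray
    mu_c: np.ndarray
    theta_f: np.ndarray
    fa: np.ndarray
    a0: np.ndarray                 # (E, 3)
    fibre_compression: bool = True

    @property
    def mu_iso(self) -> np.ndarray:
        return (1.0 - self.theta_f) * self.mu_m + self.mu_c

    @property
    def k_fibre(self) -> np.ndarray:
        return self.theta_f * self.mu_f

    def structure_tensors(self) -> np.ndarray:
        outer = np.einsum("ei,ej->eij", self.a0, self.a0)
        return (self.fa[:, None, None] * outer
                + ((1.0 - self.fa) / 3.0)[:, None, None] * np.eye(3))

    def element_parameters(self, e: int) -> MaterialParameters:
        return MaterialParameters(
            K=float(self.K[e]), mu_m=float(self.mu_m[e]),
            mu_f=float(self.mu_f[e]), mu_c=float(self.mu_c[e]),
            theta_f=float(self.theta_f[e]), a0=self.a0[e] / np.linalg.norm(self.a0[e]),
            fa=float(self.fa[e]), fibre_compression=self.fibre_compression)

    @classmethod
    def uniform(cls, n: int, p: MaterialParameters) -> "MaterialMap":
        return cls(K=np.full(n, p.K), mu_m=np.full(n, p.mu_m),
                   mu_f=np.full(n, p.mu_f), mu_c=np.full(n, p.mu_c),
                   theta_f=np.full(n, p.theta_f), fa=np.full(n, p.fa),
                   a0=np.tile(p.a0, (n, 1)),
                   fibre_compression=p.fibre_compression)


def assign_regions(mesh: CellMesh, scenario) -> MaterialMap:
    """Map a scenario onto per-element material parameters.

    Faces designated anisotropic by the case carry ``fa_aniso`` with a
    transverse mean fibril direction; all other faces (and edge bands) carry
    ``fa_iso``.  At edges the three shear moduli are multiplied by the
    scenario's ``edge_factor``; K and theta_f are never scaled.
    """
    if scenario.case_id not in CASE_ANISO_FACES:
        raise ValueError(f"unknown case id {scenario.case_id!r}")
    base = scenario.face_parameters()
    n = mesh.n_elems
    mm = MaterialMap.uniform(n, base)
    mm.fa = np.full(n, scenario.fa_iso, dtype=float)

    aniso = CASE_ANISO_FACES[scenario.case_id]
    for label in FACE_NAMES:
        idx = mesh.elements_in(label)
        mm.a0[idx] = _TRANSVERSE_A0[label]
        if label in aniso:
            mm.fa[idx] = scenario.fa_aniso

    edge_idx = np.flatnonzero(mesh.is_edge)
    for e_label in EDGE_NAMES:
        idx = mesh.elements_in(e_label)
        if idx.size == 0:
            continue
        # conventional in-wall direction for the (nearly) isotropic edge band
        f1, f2 = e_label[len("edge:"):].split("|")
        d = np.cross(_plane_normal(f1), _plane_normal(f2))
        d = d / np.linalg.norm(d)
        a0 = np.array([0.0, 1.0, 0.0]) if abs(d[1]) < 0.9 else np.array([0.0, 0.0, 1.0])
        mm.a0[idx] = a0
    if scenario.edge_factor != 1.0:
        for f_ in ("mu_m", "mu_f", "mu_c"):
            getattr(mm, f_)[edge_idx] *= scenario.edge_factor

    _apply_overrides(mm, mesh, scenario.overrides)
    return mm


def _plane_normal(face_label: str) -> np.ndarray:
    (ax, side) = next(k for k, v in _FACE_BY_PLANE.items() if v == face_label)
    n = np.zeros(3)
    n[ax] = 1.0 if side else -1.0
    return n


def _apply_overrides(mm: MaterialMap, mesh: CellMesh, overrides: dict | None):
    """Overrides: {field: value} globally, or {region_label: {field: value}}."""
    if not overrides:
        return
    scalar_fields = {"K", "mu_m", "mu_f", "mu_c", "theta_f", "fa"}
    for key, val in overrides.items():
        if key in scalar_fields:
            getattr(mm, key)[:] = val
        elif key == "a0":
            mm.a0[:] = np.asarray(val, dtype=float)
        elif isinstance(val, dict):
            idx = mesh.elements_in(key)
            if idx.size == 0:
                raise ValueError(f"override region {key!r} matches no elements")
            for f_, v_ in val.items():
                if f_ == "a0":
                    mm.a0[idx] = np.asarray(v_, dtype=float)
                elif f_ in scalar_fields:
                    getattr(mm, f_)[idx] = v_
                else:
                    raise ValueError(f"unknown material field {f_!r}")
        else:
            raise ValueError(f"unknown override key {key!r}")
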