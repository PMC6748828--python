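"""Quasi-static large-deformation FE solution of the pressurised wall shell.

Formulation notes
-----------------
* Total-Lagrangian trilinear hexahedra with 2x2x2 Gauss quadrature.
* Near-incompressibility (K/mu up to ~10^3-10^4) is handled by a
  mean-dilatation (Q1P0) treatment: the volumetric energy is evaluated at the
  element-average dilatation, which removes volumetric locking while keeping
  the displacement-only system.  The pressure-dilatation coupling enters the
  tangent as a rank-one per-element update, so Newton convergence stays
  quadratic.
* Turgor is a follower (deformation-dependent) pressure on the cavity facets;
  its load stiffness is included via per-facet central finite differences of
  the facet nodal force.  A dead-load option exists for debugging.
* Rigid-body motion is removed by a 3-2-1 pin set on the inner-periclinal
  face (the pressure on a closed cavity is self-equilibrated, so the pins
  carry no load); alternatives: a second pin set (for invariance checks) and
  an "in-tissue" mode with the inner face fully fixed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import material as mat
from .cellmesh import CellMesh, MaterialMap

__all__ = [
    "LoadCase",
    "SolverOptions",
    "Solution",
    "solve_inflation",
    "compute_stress_field",
    "NonConvergenceError",
    "ElementInversionError",
]


class NonConvergenceError(RuntimeError):
    def __init__(self, msg, residual_history=None):
        super().__init__(msg)
        self.residual_history = residual_history or []


class ElementInversionError(RuntimeError):
    pass


@dataclass
class LoadCase:
    """Turgor pressure (MPa) on the cavity plus kinematic constraints."""

    turgor_pressure: float = 0.8
    load_steps: int = 4
    constraint: str = "pins"       # 'pins' | 'pins-alt' | 'inner-face-fixed'
    prescribed: dict | None = None  # {dof index: displacement}, scaled with load

    def __post_init__(self):
        if self.turgor_pressure < 0:
            raise ValueError("pressure must be >= 0")
        if self.load_steps < 1:
            raise ValueError("load_steps must be >= 1")


@dataclass
class SolverOptions:
    tol_rel: float = 1e-8
    tol_abs: float = 1e-10
    max_iter: int = 80
    max_bisections: int = 8        # adaptive load-step halvings
    follower_load: bool = True
    load_stiffness: bool = True
    line_search: bool = True       # energy (potential) backtracking search


@dataclass
class Solution:
    u: np.ndarray                  # (N, 3) nodal displacements, um
    converged: bool
    residual_history: list
    load_case: LoadCase
    n_steps_used: int = 0


# ---------------------------------------------------------------------------
# Reference-element machinery
# ---------------------------------------------------------------------------

_XI = np.array([
    [-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
    [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1],
], dtype=float)
_G = 1.0 / np.sqrt(3.0)
_QP = _XI * _G                      # 2x2x2 Gauss points (weights all 1)


def _shape_grads_ref():
    """dN/dxi at each quadrature point: (nqp, 8, 3)."""
    out = np.empty((8, 8, 3))
    for q, (x, y, z) in enumerate(_QP):
        for a, (xa, ya, za) in enumerate(_XI):
            out[q, a] = 0.125 * np.array([
                xa * (1 + ya * y) * (1 + za * z),
                (1 + xa * x) * ya * (1 + za * z),
                (1 + xa * x) * (1 + ya * y) * za,
            ])
    return out


_DN_REF = _shape_grads_ref()


def _grad_operators(nodes, elems):
    """Physical shape-function gradients dN/dX (E, q, 8, 3) and detJ*w (E, q)."""
    Xe = nodes[elems]                                    # (E, 8, 3)
    Jmap = np.einsum("qaj,eai->eqji", _DN_REF, Xe)       # dX/dxi, (E,q,3,3)
    detJ = np.linalg.det(Jmap)
    if np.any(detJ <= 0):
        e = int(np.argwhere(detJ <= 0)[0][0])
        raise ElementInversionError(f"reference element {e} has non-positive Jacobian")
    Jinv = np.linalg.inv(Jmap)
    dNdX = np.einsum("qaj,eqji->eqai", _DN_REF, Jinv)
    return dNdX, detJ                                    # Gauss weights are 1


# facet quadrature (bilinear quad, 2x2 Gauss)
_QXI = np.array([[-1, -1], [1, -1], [1, 1], [-1, 1]], dtype=float)
_QQP = _QXI * _G


def _facet_shape():
    N = np.empty((4, 4))
    dN = np.empty((4, 4, 2))
    for q, (x, y) in enumerate(_QQP):
        for a, (xa, ya) in enumerate(_QXI):
            N[q, a] = 0.25 * (1 + xa * x) * (1 + ya * y)
            dN[q, a] = 0.25 * np.array([xa * (1 + ya * y), (1 + xa * x) * ya])
    return N, dN


_FN, _FDN = _facet_shape()


def _pressure_forces(xf, p):
    """Nodal forces from pressure p acting on facets with current coords xf.

    Facet connectivity is oriented with the normal pointing into the cavity,
    so the load on the wall is -p * n dA.
    """
    f = np.zeros_like(xf)                               # (M, 4, 3)
    for q in range(4):
        tu = np.einsum("a,fai->fi", _FDN[q, :, 0], xf)
        tv = np.einsum("a,fai->fi", _FDN[q, :, 1], xf)
        n = np.cross(tu, tv)
        f += -p * _FN[q][None, :, None] * n[:, None, :]
    return f


def _pressure_stiffness_fd(xf, p, h=1e-7):
    """d f_facet / d x_facet by central differences: (M, 12, 12)."""
    M = len(xf)
    K = np.empty((M, 12, 12))
    for d in range(12):
        a, i = divmod(d, 3)
        dx = np.zeros_like(xf)
        dx[:, a, i] = h
        fp = _pressure_forces(xf + dx, p).reshape(M, 12)
        fm = _pressure_forces(xf - dx, p).reshape(M, 12)
        K[:, :, d] = (fp - fm) / (2 * h)
    return K


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

class _System:
    """Precomputed mesh operators + assembly of residual and tangent."""

    def __init__(self, mesh: CellMesh, mm: MaterialMap, opts: SolverOptions):
        self.mesh, self.mm, self.opts = mesh, mm, opts
        self.dNdX, self.detJw = _grad_operators(mesh.nodes, mesh.elems)
        self.V0 = self.detJw.sum(axis=1)
        self.H = mm.structure_tensors()[:, None]         # (E,1,3,3) broadcast
        self.mu = mm.mu_iso[:, None]
        self.kf = mm.k_fibre[:, None]
        self.K_bulk = mm.K
        edof = (3 * mesh.elems[:, :, None] + np.arange(3)).reshape(-1, 24)
        self.edof = edof
        self.rows = np.repeat(edof, 24, axis=1).ravel()
        self.cols = np.tile(edof, (1, 24)).ravel()
        fdof = (3 * mesh.inner_facets[:, :, None] + np.arange(3)).reshape(-1, 12)
        self.fdof = fdof
        self.frows = np.repeat(fdof, 12, axis=1).ravel()
        self.fcols = np.tile(fdof, (1, 12)).ravel()
        self.ndof = 3 * mesh.n_nodes

    def deformation(self, u):
        ue = u.reshape(-1, 3)[self.mesh.elems]           # (E, 8, 3)
        F = np.eye(3) + np.einsum("eai,eqaj->eqij", ue, self.dNdX)
        Jq = np.linalg.det(F)
        if np.any(Jq <= 0):
            e = int(np.argwhere(Jq <= 0)[0][0])
            raise ElementInversionError(f"element {e} inverted (det F <= 0)")
        return F, Jq

    def internal(self, u, want_tangent=True):
        F, Jq = self.deformation(u)
        C = np.einsum("eqki,eqkj->eqij", F, F)
        Cinv = np.linalg.inv(C)
        comp = self.mm.fibre_compression

        Jbar = (self.detJw * Jq).sum(axis=1) / self.V0
        pbar = self.K_bulk * np.log(Jbar) / Jbar
        S = mat.pk2_dev(C, self.mu, self.kf, self.H, comp)
        S = S + (pbar[:, None] * Jq)[..., None, None] * Cinv

        P = np.einsum("eqiM,eqMJ->eqiJ", F, S)
        fe = np.einsum("eqiJ,eqaJ,eq->eai", P, self.dNdX, self.detJw)
        f_int = np.zeros(self.ndof)
        np.add.at(f_int, self.edof.reshape(-1, 8, 3).reshape(-1, 24),
                  fe.reshape(-1, 24))

        if not want_tangent:
            return f_int, None

        CC = mat.tangent_dev(C, self.mu, self.kf, self.H, comp)
        CC = CC + mat.tangent_vol_fixed_pressure(C, pbar[:, None])
        E, q = C.shape[:2]
        Eq = E * q
        # push-forward A_iJkL = F_iM CC_MJNL F_kN via batched matmuls
        Fq = F.reshape(Eq, 3, 3)
        T1 = (Fq @ CC.reshape(Eq, 3, 27)).reshape(Eq, 3, 3, 3, 3)   # iJNL
        T1 = T1.transpose(0, 1, 2, 4, 3).reshape(Eq, 27, 3)         # iJL,N
        A = (T1 @ Fq.transpose(0, 2, 1)).reshape(Eq, 3, 3, 3, 3)    # iJLk
        A = A.transpose(0, 1, 2, 4, 3)                              # iJkL
        # material part: Kmat_aibk = dN_aJ A_iJkL dN_bL
        dN = self.dNdX.reshape(Eq, 8, 3)
        B1 = dN @ A.transpose(0, 2, 1, 3, 4).reshape(Eq, 3, 27)     # a,(ikL)
        B1 = B1.reshape(Eq, 8, 3, 3, 3)                             # a,i,k,L
        Ke_q = (B1.reshape(Eq, 8 * 9, 3) @ dN.transpose(0, 2, 1))   # (aik),b
        Ke_q = Ke_q.reshape(Eq, 8, 3, 3, 8).transpose(0, 1, 2, 4, 3)  # a,i,b,k
        # geometric part: G_ab = dN_aJ S_JL dN_bL times delta_ik
        Gq = dN @ S.reshape(Eq, 3, 3) @ dN.transpose(0, 2, 1)       # (Eq,8,8)
        Ke_q = Ke_q + Gq[:, :, None, :, None] * np.eye(3)[None, None, :, None, :]
        w = self.detJw.reshape(Eq)
        Ke = (Ke_q * w[:, None, None, None, None]).reshape(E, q, 8, 3, 8, 3)
        Ke = Ke.sum(axis=1).reshape(E, 24, 24)

        # Q1P0 pressure-dilatation coupling (rank-one per element)
        Finv = np.linalg.inv(F)
        hvec = np.einsum("eq,eq,eqJi,eqaJ->eai", self.detJw, Jq, Finv,
                         self.dNdX).reshape(-1, 24)
        dpdJ = self.K_bulk * (1.0 - np.log(Jbar)) / Jbar ** 2
        Ke += (dpdJ / self.V0)[:, None, None] * hvec[:, :, None] * hvec[:, None, :]

        Kt = sp.coo_matrix((Ke.ravel(), (self.rows, self.cols)),
                           shape=(self.ndof, self.ndof)).tocsr()
        return f_int, Kt

    def cavity_volume(self, u):
        """Enclosed cavity volume from the oriented facet list (divergence thm).

        For symmetry-cut models the facet list is open; taking the flux of
        (x - x0) with x0 on the intersection of the cut planes makes the
        missing closure surfaces contribute exactly zero (cut nodes stay in
        plane for symmetric solutions).
        """
        x0 = np.zeros(3)
        for ax, coord in self.mesh.symmetry_planes:
            x0[ax] = coord
        x = (self.mesh.nodes + u.reshape(-1, 3))[self.mesh.inner_facets] - x0
        V = 0.0
        for q in range(4):
            tu = np.einsum("a,fai->fi", _FDN[q, :, 0], x)
            tv = np.einsum("a,fai->fi", _FDN[q, :, 1], x)
            n = np.cross(tu, tv)
            xq = np.einsum("a,fai->fi", _FN[q], x)
            V += np.einsum("fi,fi->", xq, n) / 3.0
        return -V        # facet normals point into the cavity

    def potential(self, u, p):
        """Total potential Pi = strain energy - p * cavity volume.

        The follower pressure on a closed cavity is conservative, so Pi is a
        valid merit function for the Newton line search.
        """
        F, Jq = self.deformation(u)
        C = np.einsum("eqki,eqkj->eqij", F, F)
        psi_dev = mat.psi_energy(C, 0.0, self.mu, self.kf, self.H,
                                 self.mm.fibre_compression)
        Jbar = (self.detJw * Jq).sum(axis=1) / self.V0
        E = (psi_dev * self.detJw).sum() \
            + (self.K_bulk / 2.0 * np.log(Jbar) ** 2 * self.V0).sum()
        if p != 0 and self.opts.follower_load:
            E -= p * self.cavity_volume(u)
        elif p != 0:
            f_ext, _ = self.external(u * 0.0, p)   # dead load at reference
            E -= f_ext @ u
        return E

    def external(self, u, p):
        """Follower (or dead) pressure load and, optionally, its stiffness."""
        f_ext = np.zeros(self.ndof)
        if p == 0 or len(self.mesh.inner_facets) == 0:
            return f_ext, None
        x = self.mesh.nodes + (u.reshape(-1, 3) if self.opts.follower_load
                               else 0.0)
        xf = x[self.mesh.inner_facets]
        ff = _pressure_forces(xf, p)
        np.add.at(f_ext, self.fdof, ff.reshape(-1, 12))
        Kl = None
        if self.opts.follower_load and self.opts.load_stiffness:
            Kf = _pressure_stiffness_fd(xf, p)
            Kl = sp.coo_matrix((Kf.ravel(), (self.frows, self.fcols)),
                               shape=(self.ndof, self.ndof)).tocsr()
        return f_ext, Kl


def _default_pins(mesh: CellMesh, alt: bool = False):
    """Statically determinate rigid-body pins on mid-plane nodes.

    Every pinned component vanishes identically in the cell's mirror-
    symmetric deformation, so the pins set a tilt-free gauge (and carry zero
    reaction for the self-equilibrated pressure load).
    """
    L, T, _ = mesh.geometry.dims

    def nearest(face, tx, ty, exclude=()):
        nid = mesh.nodes_on_face(face)
        pts = mesh.nodes[nid]
        order = np.argsort(np.hypot(pts[:, 0] - tx, pts[:, 1] - ty))
        return next(int(nid[i]) for i in order if int(nid[i]) not in exclude)

    n0 = nearest("inner-periclinal", L / 2, T / 2)          # face center
    n2 = nearest("outer-periclinal", L / 2, T / 2)          # opposite center
    if not alt:
        n1 = nearest("inner-periclinal", L * 0.75, T / 2, {n0})
        dofs = [3 * n0, 3 * n0 + 1, 3 * n0 + 2,   # translations
                3 * n1 + 1,                       # rotation about z (u_y ~ x)
                3 * n2, 3 * n2 + 1]               # rotations about y and x
    else:
        n1 = nearest("inner-periclinal", L / 2, T * 0.75, {n0})
        dofs = [3 * n0, 3 * n0 + 1, 3 * n0 + 2,
                3 * n1,                           # rotation about z (u_x ~ -y)
                3 * n2, 3 * n2 + 1]
    return np.array(dofs)


def _constraint_dofs(mesh: CellMesh, load: LoadCase):
    fixed, values = [], []
    if load.constraint == "pins":
        fixed = list(_default_pins(mesh, alt=False))
    elif load.constraint == "pins-alt":
        fixed = list(_default_pins(mesh, alt=True))
    elif load.constraint == "inner-face-fixed":
        nid = mesh.nodes_on_face("inner-periclinal")
        fixed = list((3 * nid[:, None] + np.arange(3)).ravel())
    elif load.constraint == "symmetry":
        if not mesh.symmetry_planes:
            raise ValueError("mesh has no symmetry planes; build a quarter model")
        for ax, coord in mesh.symmetry_planes:
            nid = np.flatnonzero(np.isclose(mesh.nodes[:, ax], coord, atol=1e-9))
            fixed.extend(3 * nid + ax)
        # one pin along the remaining axis kills the last rigid translation
        nid = mesh.nodes_on_face("inner-periclinal")
        pts = mesh.nodes[nid]
        pick = nid[np.argmax(pts[:, 0] + pts[:, 1])]
        fixed.append(3 * pick + 2)
        fixed = sorted(set(fixed))
    elif load.constraint == "none":
        pass
    else:
        raise ValueError(f"unknown constraint mode {load.constraint!r}")
    values = [0.0] * len(fixed)
    if load.prescribed:
        for d, v in load.prescribed.items():
            if d in fixed:
                values[fixed.index(d)] = v
            else:
                fixed.append(d)
                values.append(v)
    return np.asarray(fixed, dtype=int), np.asarray(values, dtype=float)


def solve_inflation(mesh: CellMesh, mm: MaterialMap, load: LoadCase,
                    opts: SolverOptions | None = None) -> Solution:
    """Newton-Raphson solution with incremental loading.

    Deterministic for fixed inputs.  Load increments are bisected adaptively
    on non-convergence; raises :class:`NonConvergenceError` with the residual
    history if the smallest increment still fails.
    """
    opts = opts or SolverOptions()
    sys_ = _System(mesh, mm, opts)
    fixed, fixed_vals = _constraint_dofs(mesh, load)
    free = np.setdiff1d(np.arange(sys_.ndof), fixed)

    u = np.zeros(sys_.ndof)
    history = []
    # quadratic ramp: small first increments where the flat shell is
    # bending-soft, larger ones once membrane tension stiffens it
    targets = [(k / load.load_steps) ** 2 for k in range(1, load.load_steps + 1)]
    lam = 0.0
    u_prev, lam_prev = None, None
    bisections = 0
    n_steps = 0

    while lam < 1.0 - 1e-12:
        lam_try = targets[0]
        u0 = u.copy()
        if u_prev is not None and lam > lam_prev:
            # secant predictor from the two previous converged states
            fac = (lam_try - lam) / (lam - lam_prev)
            u_pred = u + fac * (u - u_prev)
            try:
                sys_.deformation(u_pred)
                u0 = u_pred
            except ElementInversionError:
                pass
        u_try, ok, hist = _newton(sys_, u0, lam_try, load, fixed,
                                  fixed_vals, free, opts)
        history.extend(hist)
        if ok:
            u_prev, lam_prev = u, lam
            u, lam = u_try, lam_try
            targets.pop(0)
            n_steps += 1
        else:
            bisections += 1
            if bisections > opts.max_bisections:
                raise NonConvergenceError(
                    f"no convergence at load factor {lam_try:.4g} after "
                    f"{opts.max_bisections} bisections", history)
            targets.insert(0, lam + (lam_try - lam) / 2.0)
    return Solution(u=u.reshape(-1, 3), converged=True,
                    residual_history=history, load_case=load,
                    n_steps_used=n_steps)


def _newton(sys_, u, lam, load, fixed, fixed_vals, free, opts):
    p = lam * load.turgor_pressure
    if fixed.size:
        u[fixed] = lam * fixed_vals
    hist = []
    for it in range(opts.max_iter):
        try:
            f_int, Kt = sys_.internal(u)
        except ElementInversionError:
            return u, False, hist
        f_ext, Kl = sys_.external(u, p)
        r = f_int - f_ext
        rn = np.linalg.norm(r[free]) if free.size else 0.0
        ref = max(np.linalg.norm(f_ext[free]) if free.size else 0.0,
                  np.linalg.norm(f_int[free]) if free.size else 0.0)
        hist.append((lam, it, rn))
        if rn <= opts.tol_rel * ref + opts.tol_abs:
            return u, True, hist
        J = Kt if Kl is None else Kt - Kl
        Jff = J[free][:, free].tocsc()
        du = spla.spsolve(Jff, -r[free])
        if not np.all(np.isfinite(du)):
            return u, False, hist
        if opts.line_search and rn > 1e-3 * max(ref, opts.tol_abs):
            u, ok = _energy_line_search(sys_, u, du, free, p, r)
            if not ok:
                # tangent may be indefinite (soft-edge hinge regions):
                # Levenberg-style diagonal regularisation restores a descent
                # direction on the potential
                dscale = np.abs(Jff.diagonal()).mean()
                for beta in (1e-3, 1e-1, 10.0):
                    Jreg = Jff + sp.identity(Jff.shape[0], format="csc") \
                        * (beta * dscale)
                    du = spla.spsolve(Jreg, -r[free])
                    u, ok = _energy_line_search(sys_, u, du, free, p, r)
                    if ok:
                        break
            if not ok:
                # energy differences can fall below floating-point resolution
                # close to equilibrium; accept the step if the residual drops
                u_new = u.copy()
                u_new[free] += du
                try:
                    f_i = sys_.internal(u_new, want_tangent=False)[0]
                    f_e = sys_.external(u_new, p)[0]
                    if np.linalg.norm((f_i - f_e)[free]) < rn:
                        u = u_new
                    else:
                        return u, False, hist
                except ElementInversionError:
                    return u, False, hist
        elif opts.line_search:
            # quadratic basin: plain Newton update
            u = u.copy()
            u[free] += du
            try:
                sys_.deformation(u)
            except ElementInversionError:
                return u, False, hist
        else:
            u = u.copy()
            u[free] += du
            try:
                sys_.deformation(u)
            except ElementInversionError:
                return u, False, hist
    return u, False, hist


def _energy_line_search(sys_, u, du, free, p, r, c1=1e-4, alpha_min=2.0 ** -20):
    """Backtracking on the total potential (Armijo condition).

    The residual-norm merit stalls badly when inflating a flat shell (membrane
    forces grow quadratically along the bending-dominated Newton direction);
    the potential energy admits steps orders of magnitude longer.
    """
    try:
        E0 = sys_.potential(u, p)
    except ElementInversionError:
        return u, False
    g0 = float(r[free] @ du)           # directional derivative dPi/dalpha at 0
    alpha = 1.0
    while alpha >= alpha_min:
        u_new = u.copy()
        u_new[free] += alpha * du
        try:
            E = sys_.potential(u_new, p)
        except ElementInversionError:
            alpha /= 2.0
            continue
        if (g0 < 0 and E <= E0 + c1 * alpha * g0) or (g0 >= 0 and E < E0):
            return u_new, True
        alpha /= 2.0
    return u, False


def compute_stress_field(solution: Solution, mesh: CellMesh, mm: MaterialMap,
                         opts: SolverOptions | None = None):
    """Element-averaged Cauchy stress (E,3,3) and von Mises scalar (E,).

    Refuses to evaluate unconverged solutions.
    """
    if not solution.converged:
        raise ValueError("refusing to compute stresses from an unconverged solution")
    sys_ = _System(mesh, mm, opts or SolverOptions())
    F, Jq = sys_.deformation(solution.u.ravel())
    C = np.einsum("eqki,eqkj->eqij", F, F)
    Cinv = np.linalg.inv(C)
    Jbar = (sys_.detJw * Jq).sum(axis=1) / sys_.V0
    pbar = mm.K * np.log(Jbar) / Jbar
    S = mat.pk2_dev(C, sys_.mu, sys_.kf, sys_.H, mm.fibre_compression)
    S = S + (pbar[:, None] * Jq)[..., None, None] * Cinv
    sig = np.einsum("eqiM,eqMN,eqjN->eqij", F, S, F) / Jq[..., None, None]
    w = (sys_.detJw * Jq)                       # current-volume weights
    sig_el = (sig * w[..., None, None]).sum(axis=1) / w.sum(axis=1)[:, None, None]
    vm = mat.von_mises(sig_el)
    return sig_el, vm
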