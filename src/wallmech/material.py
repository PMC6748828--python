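"""Constitutive model of the growing plant cell wall.

The wall is treated as a fiber-reinforced hyperelastic composite:

* an isotropic, nearly incompressible polysaccharide *matrix* (neo-Hookean,
  shear modulus ``mu_m``),
* a dispersed *cellulose-microfibril* phase with mean orientation ``a0`` and
  fractional anisotropy ``fa`` (standard-reinforcing quadratic term, shear
  modulus ``mu_f``, volume fraction ``theta_f``),
* an isotropic *cross-linking* term representing cellulose-cellulose and
  matrix-mediated interactions (neo-Hookean, shear modulus ``mu_c``),
* a volumetric penalty ``(K/2)(ln J)^2`` enforcing near-incompressibility.

Fibre dispersion enters through the generalized structure tensor

    H = fa * (a0 x a0) + (1 - fa)/3 * I,      tr H = 1,

so that ``fa = 0`` is a fully random (isotropic) microfibril array and
``fa = 1`` a perfectly parallel one.  The fibre invariant is
``I4* = tr(H C_iso)`` with ``C_iso = J^(-2/3) C`` the isochoric right
Cauchy-Green tensor; at the reference state ``I4* = 1``.

Total strain energy density (stresses in MPa, lengths in micrometres):

    Psi = K/2 (ln J)^2
        + (1 - theta_f) mu_m / 2 (I1_iso - 3)
        + mu_c / 2 (I1_iso - 3)
        + theta_f mu_f / 2 (I4* - 1)^2

All heavy-weight routines are vectorised over leading array dimensions so the
finite-element assembly can evaluate whole meshes in one call.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaterialParameters",
    "DeformationState",
    "structure_tensor",
    "strain_energy",
    "cauchy_stress",
    "material_tangent",
    "InvalidDeformationError",
]

#: unit conversion helpers — the package works in micrometre-MPa units.
MPA_PER_PA = 1e-6

_I3 = np.eye(3)


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


def structure_tensor(a0: np.ndarray, fa: float) -> np.ndarray:
    """Generalized structure tensor of a dispersed fibre family.

    Parameters
    ----------
    a0 : unit 3-vector
        Mean microfibril direction in the reference configuration.
    fa : float in [0, 1]
        Fractional anisotropy; 0 = random array, 1 = perfectly parallel.

    Returns
    -------
    H : (3, 3) ndarray
        ``fa * outer(a0, a0) + (1 - fa)/3 * I``; symmetric positive
        semi-definite with unit trace.
    """
    a0 = np.asarray(a0, dtype=float)
    if a0.shape != (3,):
        raise ValueError("a0 must be a 3-vector")
    if abs(np.linalg.norm(a0) - 1.0) > 1e-12:
        raise ValueError("a0 must be a unit vector (||a0|| = 1 within 1e-12)")
    if not 0.0 <= fa <= 1.0:
        raise ValueError("fa must lie in [0, 1]")
    return fa * np.outer(a0, a0) + (1.0 - fa) / 3.0 * _I3


@dataclass(frozen=True)
class MaterialParameters:
    """The seven constitutive parameters of one wall region.

    Stresses are in MPa.  Defaults are the face parameter set used throughout
    the inflation scenarios: K = 10 GPa, mu_m = 18 MPa, mu_f = 1.2 GPa,
    mu_c = 18 MPa, theta_f = 0.5.
    """

    K: float = 10_000.0          # bulk modulus, MPa (10 GPa)
    mu_m: float = 18.0           # matrix shear modulus, MPa
    mu_f: float = 1_200.0        # microfibril shear modulus, MPa (1.2 GPa)
    mu_c: float = 18.0           # cross-link shear modulus, MPa
    theta_f: float = 0.5         # microfibril volume fraction
    a0: np.ndarray = field(default_factory=lambda: np.array([0.0, 1.0, 0.0]))
    fa: float = 0.0              # fractional anisotropy xi
    fibre_compression: bool = True  # keep fibre term active when I4* < 1

    def __post_init__(self):
        a0 = np.asarray(self.a0, dtype=float)
        object.__setattr__(self, "a0", a0)
        if self.K <= 0:
            raise ValueError("K must be positive")
        if min(self.mu_m, self.mu_f, self.mu_c) < 0:
            raise ValueError("shear moduli must be non-negative")
        if not 0.0 <= self.theta_f <= 1.0:
            raise ValueError("theta_f must lie in [0, 1]")
        if not 0.0 <= self.fa <= 1.0:
            raise ValueError("fa must lie in [0, 1]")
        if a0.shape != (3,) or abs(np.linalg.norm(a0) - 1.0) > 1e-12:
            raise ValueError("a0 must be a unit 3-vector")

    @property
    def structure_tensor(self) -> np.ndarray:
        return structure_tensor(self.a0, self.fa)

    @property
    def mu_iso(self) -> float:
        """Apparent small-strain shear modulus of the isotropic terms."""
        return (1.0 - self.theta_f) * self.mu_m + self.mu_c

    @property
    def k_fibre(self) -> float:
        """Effective fibre stiffness factor theta_f * mu_f."""
        return self.theta_f * self.mu_f

    def with_overrides(self, **kwargs) -> "MaterialParameters":
        return replace(self, **kwargs)

    def to_dict(self, units: str = "MPa") -> dict:
        """Flat config dict; ``units`` is 'MPa' (internal) or 'Pa' (SI)."""
        s = 1.0 if units == "MPa" else 1.0 / MPA_PER_PA if units == "Pa" else None
        if s is None:
            raise ValueError("units must be 'MPa' or 'Pa'")
        return {
            "K": self.K * s, "mu_m": self.mu_m * s, "mu_f": self.mu_f * s,
            "mu_c": self.mu_c * s, "theta_f": self.theta_f,
            "a0": list(map(float, self.a0)), "fa": self.fa, "units": units,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MaterialParameters":
        d = dict(d)
        units = d.pop("units", "MPa")
        s = 1.0 if units == "MPa" else MPA_PER_PA if units == "Pa" else None
        if s is None:
            raise ValueError("units must be 'MPa' or 'Pa'")
        for k in ("K", "mu_m", "mu_f", "mu_c"):
            if k in d:
                d[k] = float(d[k]) * s
        if "a0" in d:
            d["a0"] = np.asarray(d["a0"], dtype=float)
        return cls(**d)


@dataclass(frozen=True)
class DeformationState:
    """Kinematic quantities derived from a deformation gradient F."""

    F: np.ndarray
    J: float
    C: np.ndarray
    I1_iso: float
    I4_star: float | None = None

    @classmethod
    def from_F(cls, F: np.ndarray, H: np.ndarray | None = None) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        J = float(np.linalg.det(F))
        if J <= 0.0:
            raise InvalidDeformationError(f"det(F) = {J} <= 0")
        C = F.T @ F
        I1_iso = float(J ** (-2.0 / 3.0) * np.trace(C))
        I4 = None
        if H is not None:
            I4 = float(J ** (-2.0 / 3.0) * np.tensordot(H, C))
        return cls(F=F, J=J, C=C, I1_iso=I1_iso, I4_star=I4)


# ---------------------------------------------------------------------------
# Vectorised kernels (leading dimensions broadcast; tensors in last two axes).
# These are what the FE assembly calls; the public scalar API wraps them.
# ---------------------------------------------------------------------------

def _kinematics(C):
    """Common factors: C^{-1}, J, J^{-2/3}, I1."""
    C = np.asarray(C, dtype=float)
    detC = np.linalg.det(C)
    if np.any(detC <= 0):
        raise InvalidDeformationError("C must be positive definite")
    J = np.sqrt(detC)
    Cinv = np.linalg.inv(C)
    J23 = J ** (-2.0 / 3.0)
    I1 = np.trace(C, axis1=-2, axis2=-1)
    return Cinv, J, J23, I1


def _fibre_active(I4b, kf, compression_ok):
    """Mask out the fibre term where I4* < 1 under tension-only switch."""
    if compression_ok:
        return kf
    return np.where(I4b >= 1.0, kf, 0.0)


def psi_energy(C, K, mu_iso, kf, H, compression_ok=True):
    """Strain energy density from right Cauchy-Green tensors (vectorised)."""
    Cinv, J, J23, I1 = _kinematics(C)
    I1b = J23 * I1
    I4b = J23 * np.einsum("...ij,...ij->...", H, C)
    kf = _fibre_active(I4b, kf, compression_ok)
    lnJ = np.log(J)
    return (K / 2.0 * lnJ ** 2
            + mu_iso / 2.0 * (I1b - 3.0)
            + kf / 2.0 * (I4b - 1.0) ** 2)


def pk2_dev(C, mu_iso, kf, H, compression_ok=True):
    """Deviatoric (isochoric) second Piola-Kirchhoff stress (vectorised)."""
    Cinv, J, J23, I1 = _kinematics(C)
    I4b = J23 * np.einsum("...ij,...ij->...", H, C)
    kf = _fibre_active(I4b, kf, compression_ok)
    mu_iso = np.asarray(mu_iso)[..., None, None]
    S_iso = mu_iso * (J23[..., None, None] * _I3
                      - (J23 * I1 / 3.0)[..., None, None] * Cinv)
    G = J23[..., None, None] * H - (I4b / 3.0)[..., None, None] * Cinv
    S_f = (2.0 * kf * (I4b - 1.0))[..., None, None] * G
    return S_iso + S_f


def pk2_vol(C, K):
    """Volumetric second Piola-Kirchhoff stress K ln(J) C^{-1} (vectorised)."""
    Cinv, J, _, _ = _kinematics(C)
    return (np.asarray(K) * np.log(J))[..., None, None] * Cinv


def _obox(A, B):
    """(A (.) B)_ijkl = 1/2 (A_ik B_jl + A_il B_jk) — symmetrised product."""
    t1 = np.einsum("...ik,...jl->...ijkl", A, B)
    t2 = np.einsum("...il,...jk->...ijkl", A, B)
    return 0.5 * (t1 + t2)


def _oprod(A, B):
    return np.einsum("...ij,...kl->...ijkl", A, B)


def tangent_dev(C, mu_iso, kf, H, compression_ok=True):
    """Referential tangent 2 dS_dev/dC of the isochoric terms (vectorised)."""
    Cinv, J, J23, I1 = _kinematics(C)
    I4b = J23 * np.einsum("...ij,...ij->...", H, C)
    kf = _fibre_active(I4b, kf, compression_ok)
    mu = np.asarray(mu_iso)[..., None, None, None, None]
    J23e = J23[..., None, None, None, None]
    I1e = I1[..., None, None, None, None]
    Ie = np.broadcast_to(_I3, Cinv.shape)

    CC = 2.0 * mu * (
        -J23e / 3.0 * (_oprod(Ie, Cinv) + _oprod(Cinv, Ie))
        + J23e * I1e / 9.0 * _oprod(Cinv, Cinv)
        + J23e * I1e / 3.0 * _obox(Cinv, Cinv)
    )

    G = J23[..., None, None] * H - (I4b / 3.0)[..., None, None] * Cinv
    kfe = np.asarray(kf)[..., None, None, None, None]
    I4e = I4b[..., None, None, None, None]
    He = np.broadcast_to(H, Cinv.shape)
    CC = CC + 4.0 * kfe * (
        _oprod(G, G)
        + (I4e - 1.0) * (
            -J23e / 3.0 * (_oprod(He, Cinv) + _oprod(Cinv, He))
            + I4e / 9.0 * _oprod(Cinv, Cinv)
            + I4e / 3.0 * _obox(Cinv, Cinv)
        )
    )
    return CC


def tangent_vol(C, K):
    """Referential tangent 2 dS_vol/dC of the volumetric penalty."""
    Cinv, J, _, _ = _kinematics(C)
    Ke = np.asarray(K)[..., None, None, None, None]
    lnJ = np.log(J)[..., None, None, None, None]
    return Ke * _oprod(Cinv, Cinv) - 2.0 * Ke * lnJ * _obox(Cinv, Cinv)


def tangent_vol_fixed_pressure(C, pbar):
    """Tangent of S = pbar * J * C^{-1} holding the pressure-like scalar fixed.

    Used by the mean-dilatation (Q1P0) element where ``pbar`` depends on the
    element-average dilatation only; the coupling term is added at element
    level as a rank-one update.
    """
    Cinv, J, _, _ = _kinematics(C)
    pe = (np.asarray(pbar) * J)[..., None, None, None, None]
    return pe * _oprod(Cinv, Cinv) - 2.0 * pe * _obox(Cinv, Cinv)


# ---------------------------------------------------------------------------
# Public material-point API
# ---------------------------------------------------------------------------

def _unpack(p: MaterialParameters):
    return p.K, p.mu_iso, p.k_fibre, p.structure_tensor, p.fibre_compression


def strain_energy(state: DeformationState, p: MaterialParameters) -> float:
    """Strain energy density Psi(F) in MPa; zero at the reference state."""
    K, mu, kf, H, comp = _unpack(p)
    return float(psi_energy(state.C, K, mu, kf, H, comp))


def second_pk_stress(state: DeformationState, p: MaterialParameters) -> np.ndarray:
    """Second Piola-Kirchhoff stress S = 2 dPsi/dC (MPa)."""
    K, mu, kf, H, comp = _unpack(p)
    return pk2_dev(state.C, mu, kf, H, comp) + pk2_vol(state.C, K)


def cauchy_stress(state: DeformationState, p: MaterialParameters) -> np.ndarray:
    """Cauchy stress sigma = J^{-1} F S F^T (MPa); symmetric, zero at F = I."""
    S = second_pk_stress(state, p)
    F = state.F
    sig = F @ S @ F.T / state.J
    return 0.5 * (sig + sig.T)


def material_tangent(state: DeformationState, p: MaterialParameters) -> np.ndarray:
    """Referential elasticity tensor CC = 2 dS/dC = dS/dE (3,3,3,3 ndarray).

    Possesses both minor symmetries and, because it derives from a potential,
    major symmetry.  At F = I with fa = 0 it reduces to the classical
    isotropic operator with bulk modulus K and shear modulus
    ``(1 - theta_f) mu_m + mu_c``.
    """
    K, mu, kf, H, comp = _unpack(p)
    CC = tangent_dev(state.C, mu, kf, H, comp) + tangent_vol(state.C, K)
    # symmetrise minor indices against accumulated round-off
    CC = 0.5 * (CC + np.swapaxes(CC, -2, -1))
    CC = 0.5 * (CC + np.swapaxes(CC, 0, 1))
    return CC


def von_mises(sigma: np.ndarray) -> np.ndarray:
    """Von Mises equivalent stress of (..., 3, 3) Cauchy tensors."""
    tr = np.trace(sigma, axis1=-2, axis2=-1)[..., None, None]
    dev = sigma - tr / 3.0 * _I3
    return np.sqrt(1.5 * np.einsum("...ij,...ij->...", dev, dev))
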