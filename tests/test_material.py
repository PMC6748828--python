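"""Material-point checks of the fiber-reinforced wall model."""

import numpy as np
import pytest
from scipy.stats import special_ortho_group

from wallmech import material as mat
from wallmech.material import (DeformationState, MaterialParameters,
                               structure_tensor)


def rand_F(seed, scale=0.1):
    rng = np.random.default_rng(seed)
    return np.eye(3) + scale * rng.standard_normal((3, 3))


class TestStructureTensor:
    def test_isotropic_limit_is_identity_over_three(self):
        H = structure_tensor(np.array([0.3, -0.4, np.sqrt(0.75)]), 0.0)
        assert np.allclose(H, np.eye(3) / 3.0)

    def test_fully_aligned_limit_is_outer_product(self):
        H = structure_tensor(np.array([0.0, 0.0, 1.0]), 1.0)
        assert np.allclose(H, np.diag([0, 0, 1.0]))

    def test_partial_anisotropy_matches_mixture_formula(self):
        # fa = 0.2 along y: 0.2*e_y(x)e_y + 0.8/3 I
        H = structure_tensor(np.array([0.0, 1.0, 0.0]), 0.2)
        assert np.allclose(np.diag(H), [0.2667, 0.4667, 0.2667], atol=5e-5)
        assert np.isclose(np.trace(H), 1.0)

    def test_matches_second_moment_of_dispersed_fiber_sample(self):
        # numerical average of a (x) a over a fiber population built by
        # mixing aligned and uniformly random directions with weight fa
        rng = np.random.default_rng(0)
        fa, a0 = 0.35, np.array([0.0, 0.0, 1.0])
        n = 200_000
        dirs = rng.standard_normal((n, 3))
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
        aligned = rng.random(n) < fa
        dirs[aligned] = a0
        M = np.einsum("ni,nj->ij", dirs, dirs) / n
        assert np.allclose(M, structure_tensor(a0, fa), atol=5e-3)

    @pytest.mark.parametrize("a0,fa", [
        (np.array([1.0, 1.0, 0.0]), 0.5),    # not unit
        (np.array([0.0, 0.0, 1.0]), 1.5),    # fa out of range
        (np.array([0.0, 0.0, 1.0]), -0.1),
    ])
    def test_invalid_inputs_raise(self, a0, fa):
        with pytest.raises(ValueError):
            structure_tensor(a0, fa)


class TestEnergy:
    def test_reference_state_has_zero_energy(self):
        p = MaterialParameters(fa=0.4)
        st = DeformationState.from_F(np.eye(3), p.structure_tensor)
        assert mat.strain_energy(st, p) == pytest.approx(0.0, abs=1e-14)
        assert st.J == 1.0 and st.I1_iso == pytest.approx(3.0)
        assert st.I4_star == pytest.approx(1.0)

    def test_pure_rotation_has_zero_energy(self):
        p = MaterialParameters(fa=0.7, a0=np.array([0, 0, 1.0]))
        for k in range(5):
            Q = special_ortho_group.rvs(3, random_state=k)
            st = DeformationState.from_F(Q, p.structure_tensor)
            assert mat.strain_energy(st, p) == pytest.approx(0.0, abs=1e-9)

    def test_objectivity_under_100_random_rotations(self):
        p = MaterialParameters(fa=0.3, a0=np.array([0, 1.0, 0]))
        F = rand_F(1)
        st = DeformationState.from_F(F, p.structure_tensor)
        psi = mat.strain_energy(st, p)
        Qs = special_ortho_group.rvs(3, size=100, random_state=42)
        for Q in Qs:
            st_q = DeformationState.from_F(Q @ F, p.structure_tensor)
            assert mat.strain_energy(st_q, p) == pytest.approx(
                psi, rel=1e-10)

    def test_uniaxial_value_matches_symbolic_oracle(self):
        # independent sympy evaluation of the implemented energy forms for
        # F = diag(lambda, 1, 1) at the default face parameters with fa = 0
        import sympy as sp
        lam_s = sp.Rational(105, 100)
        K, mu_m, mu_f, mu_c, th = 10_000, 18, 1200, 18, sp.Rational(1, 2)
        J = lam_s
        I1 = lam_s ** 2 + 2
        I1b = J ** sp.Rational(-2, 3) * I1
        I4b = I1b / 3                      # H = I/3 at fa = 0
        psi_s = (K / sp.Integer(2) * sp.log(J) ** 2
                 + (1 - th) * mu_m / sp.Integer(2) * (I1b - 3)
                 + mu_c / sp.Integer(2) * (I1b - 3)
                 + th * mu_f / sp.Integer(2) * (I4b - 1) ** 2)
        expected = float(sp.N(psi_s, 30))

        p = MaterialParameters(fa=0.0)
        st = DeformationState.from_F(np.diag([1.05, 1.0, 1.0]),
                                     p.structure_tensor)
        assert mat.strain_energy(st, p) == pytest.approx(expected, rel=1e-12)

    def test_invalid_deformation_raises(self):
        with pytest.raises(mat.InvalidDeformationError):
            DeformationState.from_F(np.diag([1.0, 1.0, -1.0]))


class TestStress:
    def test_zero_at_reference(self):
        p = MaterialParameters(fa=0.5)
        st = DeformationState.from_F(np.eye(3), p.structure_tensor)
        assert np.allclose(mat.cauchy_stress(st, p), 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed,fa", [(0, 0.0), (1, 0.4), (2, 1.0)])
    def test_matches_finite_difference_of_energy(self, seed, fa):
        p = MaterialParameters(fa=fa, a0=np.array([0, 0, 1.0]))
        F = rand_F(seed)
        st = DeformationState.from_F(F, p.structure_tensor)
        sig = mat.cauchy_stress(st, p)
        assert np.allclose(sig, sig.T)
        h = 1e-6
        P = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                dF = np.zeros((3, 3))
                dF[i, j] = h
                Ep = mat.strain_energy(
                    DeformationState.from_F(F + dF, p.structure_tensor), p)
                Em = mat.strain_energy(
                    DeformationState.from_F(F - dF, p.structure_tensor), p)
                P[i, j] = (Ep - Em) / (2 * h)
        sig_fd = P @ F.T / np.linalg.det(F)
        sig_fd = 0.5 * (sig_fd + sig_fd.T)
        assert np.allclose(sig, sig_fd, rtol=1e-5,
                           atol=1e-5 * np.abs(sig).max())

    def test_isotropy_at_zero_fa_is_exact(self):
        F = rand_F(3)
        s1 = mat.cauchy_stress(
            DeformationState.from_F(F), MaterialParameters(
                fa=0.0, a0=np.array([1.0, 0, 0])))
        s2 = mat.cauchy_stress(
            DeformationState.from_F(F), MaterialParameters(
                fa=0.0, a0=np.array([0, 0, 1.0])))
        assert np.array_equal(s1, s2)

    def test_stiffening_monotone_in_fa_along_fiber(self):
        # uniaxial stretch along a0: fiber-direction stress non-decreasing
        a0 = np.array([0, 0, 1.0])
        F = np.diag([1.0, 1.0, 1.08])
        prev = -np.inf
        for fa in [0.0, 0.25, 0.5, 0.75, 1.0]:
            p = MaterialParameters(fa=fa, a0=a0)
            szz = mat.cauchy_stress(
                DeformationState.from_F(F, p.structure_tensor), p)[2, 2]
            assert szz >= prev - 1e-12
            prev = szz

    def test_deviatoric_stress_scales_with_shear_moduli(self):
        F = rand_F(4)
        st = DeformationState.from_F(F)
        p1 = MaterialParameters(fa=0.3, a0=np.array([0, 1.0, 0]))
        c = 3.7
        p2 = p1.with_overrides(mu_m=c * p1.mu_m, mu_f=c * p1.mu_f,
                               mu_c=c * p1.mu_c)
        def dev(p):
            s = mat.cauchy_stress(st, p)
            # remove the (unchanged) volumetric part before comparing
            sv = mat.cauchy_stress(st, p.with_overrides(
                mu_m=0.0, mu_f=0.0, mu_c=0.0))
            return s - sv
        assert np.allclose(dev(p2), c * dev(p1), rtol=1e-12)


class TestTangent:
    def test_consistent_with_stress_by_finite_differences(self):
        p = MaterialParameters(fa=0.4, a0=np.array([0, 1.0, 0]))
        F = rand_F(5)
        st = DeformationState.from_F(F, p.structure_tensor)
        CC = mat.material_tangent(st, p)
        C = st.C
        K, mu, kf, H = p.K, p.mu_iso, p.k_fibre, p.structure_tensor
        h = 1e-6
        scale = np.abs(CC).max()
        for i in range(3):
            for j in range(i, 3):
                dC = np.zeros((3, 3))
                dC[i, j] = dC[j, i] = h
                Sp = mat.pk2_dev(C + dC, mu, kf, H) + mat.pk2_vol(C + dC, K)
                Sm = mat.pk2_dev(C - dC, mu, kf, H) + mat.pk2_vol(C - dC, K)
                dS = (Sp - Sm) / (2 * h)
                pred = np.einsum("ijkl,kl->ij", CC, dC / 2.0) / h
                assert np.allclose(dS, pred, atol=1e-4 * scale)

    def test_small_strain_limit_is_classical_isotropic_operator(self):
        p = MaterialParameters()         # fa = 0
        st = DeformationState.from_F(np.eye(3), p.structure_tensor)
        CC = mat.material_tangent(st, p)
        I = np.eye(3)
        II = np.einsum("ij,kl->ijkl", I, I)
        Isym = 0.5 * (np.einsum("ik,jl->ijkl", I, I)
                      + np.einsum("il,jk->ijkl", I, I))
        classical = p.K * II + 2 * p.mu_iso * (Isym - II / 3.0)
        assert np.allclose(CC, classical, atol=1e-9 * p.K)

    def test_minor_and_major_symmetries(self):
        p = MaterialParameters(fa=0.6, a0=np.array([0, 0, 1.0]))
        CC = mat.material_tangent(
            DeformationState.from_F(rand_F(6), p.structure_tensor), p)
        assert np.allclose(CC, np.swapaxes(CC, 2, 3))
        assert np.allclose(CC, np.swapaxes(CC, 0, 1))
        assert np.allclose(CC, np.transpose(CC, (2, 3, 0, 1)))

    def test_transforms_tensorially_under_frame_rotation(self):
        p_z = MaterialParameters(fa=0.8, a0=np.array([0, 0, 1.0]))
        Q = special_ortho_group.rvs(3, random_state=7)
        F = rand_F(7)
        CC = mat.material_tangent(
            DeformationState.from_F(F, p_z.structure_tensor), p_z)
        # rotate material frame and deformation together
        p_q = MaterialParameters(fa=0.8, a0=Q @ np.array([0, 0, 1.0]))
        CC_q = mat.material_tangent(
            DeformationState.from_F(Q @ F @ Q.T, p_q.structure_tensor), p_q)
        CC_rot = np.einsum("ai,bj,ck,dl,ijkl->abcd", Q, Q, Q, Q, CC)
        assert np.allclose(CC_q, CC_rot, atol=1e-6 * np.abs(CC).max())


class TestParameters:
    def test_printed_face_defaults(self):
        p = MaterialParameters()
        assert (p.K, p.mu_m, p.mu_f, p.mu_c, p.theta_f) == \
            (10_000.0, 18.0, 1200.0, 18.0, 0.5)

    def test_si_round_trip(self):
        p = MaterialParameters(fa=0.2)
        d = p.to_dict(units="Pa")
        assert d["K"] == pytest.approx(10e9)
        p2 = MaterialParameters.from_dict(d)
        assert p2.K == pytest.approx(p.K)
        assert p2.fa == p.fa

    @pytest.mark.parametrize("kw", [
        {"K": -1.0}, {"mu_m": -1.0}, {"theta_f": 1.5}, {"fa": 2.0},
        {"a0": np.array([1.0, 1.0, 0.0])},
    ])
    def test_invalid_parameters_raise(self, kw):
        with pytest.raises(ValueError):
            MaterialParameters(**kw)
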