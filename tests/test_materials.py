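"""Constitutive-model checks against symbolic and finite-difference oracles."""

import numpy as np
import pytest
import sympy as sy

from forefem import materials as M

TABLE_MATERIALS = [
    M.OgdenParams(mu=452.0, alpha=5.6),            # skin
    M.OgdenParams(mu=36.0, alpha=4.5),             # soft tissue
    M.StorakersParams(mu=144.0, alpha=4.013, beta=0.057),   # orthosis
    M.StorakersParams(mu=1588.0, alpha=7.708, beta=0.292),  # sole
    M.LinearParams(E=200.0, nu=0.3),               # shoe upper
    M.LinearParams(E=1.8, nu=0.4),                 # sock
    M.LinearParams(E=7300.0, nu=0.3),              # bone
]


def _sympy_ogden(mu, alpha, lams, kappa_factor=1000.0):
    """Independent symbolic evaluation of the one-term Ogden energy."""
    l1, l2, l3 = [sy.Rational(str(v)) if isinstance(v, str) else sy.Float(v)
                  for v in lams]
    mu_, a_ = sy.Float(mu), sy.Float(alpha)
    J = l1 * l2 * l3
    W = (mu_ / a_) * (l1**a_ + l2**a_ + l3**a_ - 3)
    W += -mu_ * sy.log(J) + sy.Float(kappa_factor * mu) / 2 * (J - 1) ** 2
    return float(W)


def _sympy_storakers(mu, alpha, beta, lams):
    l1, l2, l3 = [sy.Float(v) for v in lams]
    mu_, a_, b_ = sy.Float(mu), sy.Float(alpha), sy.Float(beta)
    J = l1 * l2 * l3
    W = (2 * mu_ / a_**2) * (l1**a_ + l2**a_ + l3**a_ - 3
                             + (J ** (-a_ * b_) - 1) / b_)
    return float(W)


class TestStrainEnergy:
    @pytest.mark.parametrize("mat", TABLE_MATERIALS,
                             ids=lambda m: type(m).__name__ + str(m.mu if hasattr(m, "mu") else m.E))
    def test_zero_at_reference(self, mat):
        assert M.strain_energy(mat, (1.0, 1.0, 1.0), 1.0) == pytest.approx(0.0, abs=1e-10)

    def test_ogden_symbolic_value(self):
        lam = (1.1, 1.1 ** -0.5, 1.1 ** -0.5)
        got = float(M.strain_energy(M.OgdenParams(36.0, 4.5), lam))
        want = _sympy_ogden(36.0, 4.5, lam)
        assert got == pytest.approx(want, rel=1e-10)

    def test_storakers_symbolic_volumetric(self):
        J = 0.8
        lam = (J ** (1 / 3),) * 3
        mat = M.StorakersParams(144.0, 4.013, 0.057)
        got = float(M.strain_energy(mat, lam, J))
        want = _sympy_storakers(144.0, 4.013, 0.057, lam)
        assert got == pytest.approx(want, rel=1e-10)

    def test_isotropy_under_permutation(self):
        rng = np.random.default_rng(0)
        lam = 1.0 + 0.2 * rng.random(3)
        for mat in TABLE_MATERIALS[:4]:
            vals = {float(M.strain_energy(mat, np.asarray(p)))
                    for p in [lam, lam[[1, 0, 2]], lam[[2, 1, 0]]]}
            assert max(vals) - min(vals) < 1e-9 * max(abs(max(vals)), 1.0)

    def test_domain_errors(self):
        with pytest.raises(M.MaterialDomainError):
            M.strain_energy(TABLE_MATERIALS[0], (1.0, -0.5, 1.0))
        with pytest.raises(M.MaterialDomainError):
            M.strain_energy(TABLE_MATERIALS[2], (1.0, 1.0, 1.0), J=-1.0)


class TestStressAndTangent:
    @pytest.mark.parametrize("mat", TABLE_MATERIALS[:5],
                             ids=["skin", "tissue", "orthosis", "sole", "upper"])
    def test_identity_and_rotation_give_zero_stress(self, mat):
        S, _ = M.stress_and_tangent(mat, np.eye(3))
        assert np.allclose(S, 0.0, atol=1e-8)
        th = 0.3
        R = np.array([[np.cos(th), -np.sin(th), 0],
                      [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        S, _ = M.stress_and_tangent(mat, R)
        assert np.allclose(S, 0.0, atol=1e-6)

    @pytest.mark.parametrize("mat", TABLE_MATERIALS[:4],
                             ids=["skin", "tissue", "orthosis", "sole"])
    def test_stress_is_energy_gradient_100_states(self, mat):
        """Batched FD check of S = dW/dE at 100 random states."""
        rng = np.random.default_rng(42)
        F = np.eye(3) + 0.08 * rng.standard_normal((100, 3, 3))
        F = F[np.linalg.det(F) > 0.3]
        S, _ = M.stress_and_tangent(mat, F)
        C = np.einsum("eki,ekj->eij", F, F)
        h = 1e-6

        def W_of_C(Cm):
            lam2 = np.linalg.eigvalsh(Cm)
            lam = np.sqrt(np.maximum(lam2, 1e-12))
            return M.strain_energy(mat, lam)

        for i in range(3):
            for j in range(i, 3):
                dE = np.zeros((3, 3))
                dE[i, j] = dE[j, i] = 1.0
                Wp = W_of_C(C + 2 * h * dE)
                Wm = W_of_C(C - 2 * h * dE)
                fd = (Wp - Wm) / (2 * h)          # dW/dE : dE
                an = np.einsum("eij,ij->e", S, dE)
                scale = max(np.abs(an).max(), 1e-6)
                assert np.abs(an - fd).max() < 2e-4 * scale

    @pytest.mark.parametrize("mat", TABLE_MATERIALS[:4],
                             ids=["skin", "tissue", "orthosis", "sole"])
    def test_tangent_matches_finite_difference(self, mat):
        rng = np.random.default_rng(7)
        F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
        S, CC = M.stress_and_tangent(mat, F)
        C = F.T @ F
        h = 1e-6

        def S_of_C(Cm):
            lam2, N = np.linalg.eigh(Cm)
            lam = np.sqrt(lam2)
            Sp, _ = M.principal_stress_and_moduli(mat, lam)
            return np.einsum("a,ia,ja->ij", Sp, N, N)

        for i in range(3):
            for j in range(i, 3):
                dE = np.zeros((3, 3))
                dE[i, j] = dE[j, i] = 1.0
                fd = (S_of_C(C + 2 * h * dE) - S_of_C(C - 2 * h * dE)) / (2 * h)
                an = np.einsum("ijkl,kl->ij", CC, dE)
                assert np.abs(an - fd).max() < 1e-6 * np.abs(CC).max()

    def test_coincident_stretch_branch(self):
        # equitriaxial state exercises the repeated-eigenvalue limit
        for mat in TABLE_MATERIALS[:4]:
            S, CC = M.stress_and_tangent(mat, 1.03 * np.eye(3))
            assert np.all(np.isfinite(S)) and np.all(np.isfinite(CC))

    def test_inversion_error_carries_element_id(self):
        F = np.stack([np.eye(3), -np.eye(3)])
        with pytest.raises(M.ElementInversionError) as err:
            M.stress_and_tangent(TABLE_MATERIALS[1], F)
        assert err.value.element_id == 1


class TestAnalyticUniaxial:
    def test_soft_tissue_reference_value(self):
        # 36*(0.9^4.5 - 0.9^(-2.25)) ~ -23.2 kPa
        got = M.analytic_uniaxial(M.OgdenParams(36.0, 4.5), 0.9)
        assert got == pytest.approx(36.0 * (0.9**4.5 - 0.9**-2.25), rel=1e-12)
        assert got == pytest.approx(-23.2, abs=0.05)

    def test_zero_at_unit_stretch(self):
        for mat in TABLE_MATERIALS:
            assert M.analytic_uniaxial(mat, 1.0) == pytest.approx(0.0, abs=1e-9)

    def test_sign_and_monotonicity(self):
        skin = M.OgdenParams(452.0, 5.6)
        assert M.analytic_uniaxial(skin, 1.05) > 0 > M.analytic_uniaxial(skin, 0.95)

    def test_storakers_lateral_stretch_solution(self):
        """The closed form satisfies lateral traction-free equilibrium."""
        mat = M.StorakersParams(144.0, 4.013, 0.057)
        lam = 0.9
        b = mat.beta
        lam_t = lam ** (-b / (1 + 2 * b))
        Sp, _ = M.principal_stress_and_moduli(mat, np.array([lam, lam_t, lam_t]))
        assert Sp[1] == pytest.approx(0.0, abs=1e-9 * abs(Sp[0]))


class TestSmallStrainConsistency:
    def test_initial_shear_modulus_from_symbolic_expansion(self):
        """mu0 derived by sympy series of the uniaxial law, then checked
        against the closed-form property and a numeric simple-shear state."""
        mu, alpha = 36.0, 4.5
        lam_s, mu_s, a_s = sy.symbols("lam mu alpha", positive=True)
        sigma = mu_s * (lam_s**a_s - lam_s ** (-a_s / 2))
        E_t = sy.series(sigma, lam_s, 1, 2).removeO().diff(lam_s)
        E_num = float(E_t.subs({mu_s: mu, a_s: alpha}))
        mu0_sym = E_num / 3.0                      # incompressible: E = 3 mu0
        mat = M.OgdenParams(mu, alpha)
        assert mat.shear_modulus_initial == pytest.approx(mu0_sym, rel=1e-9)

        gam = 1e-5
        F = np.eye(3)
        F[0, 1] = gam
        S, _ = M.stress_and_tangent(mat, F)
        assert S[0, 1] == pytest.approx(mu0_sym * gam, rel=1e-3)

    def test_prefactor_conventions_differ_as_expected(self):
        paper = M.OgdenParams(36.0, 4.5, prefactor="paper")
        std = M.OgdenParams(36.0, 4.5, prefactor="standard")
        # (mu/alpha) vs (2 mu/alpha^2): ratio of initial moduli = alpha/2
        ratio = paper.shear_modulus_initial / std.shear_modulus_initial
        assert ratio == pytest.approx(4.5 / 2.0, rel=1e-12)


class TestMaterialLibrary:
    def test_defaults_and_lookup(self):
        lib = M.MaterialLibrary.defaults()
        assert lib["soft_tissue"].mu == 36.0
        assert lib["sole"].beta == 0.292
        with pytest.raises(KeyError):
            lib["cartilage"]

    def test_yaml_round_trip(self, tmp_path):
        lib = M.MaterialLibrary.defaults()
        path = tmp_path / "materials.yaml"
        lib.to_yaml(path)
        back = M.MaterialLibrary.from_yaml(path)
        assert back["skin"] == lib["skin"]
        assert back["orthosis"] == lib["orthosis"]
        assert back["bone"] == lib["bone"]

    def test_validate_regions(self):
        lib = M.MaterialLibrary.defaults()
        lib.validate_regions(["skin", "sole"])
        with pytest.raises(KeyError):
            lib.validate_regions(["skin", "tendon"])

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            M.OgdenParams(mu=-1.0, alpha=2.0)
        with pytest.raises(ValueError):
            M.OgdenParams(mu=1.0, alpha=0.0)
        with pytest.raises(ValueError):
            M.StorakersParams(mu=1.0, alpha=2.0, beta=-0.1)
        with pytest.raises(ValueError):
            M.LinearParams(E=1.0, nu=0.6)
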