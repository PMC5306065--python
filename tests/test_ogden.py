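"""Material model: strain energy, uniaxial stress, Cauchy stress, von Mises."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lamsim.errors import InvalidInputError
from lamsim.ogden import (OgdenParameters, bulk_modulus_from_poisson,
                          cauchy_stress, small_strain_shear_modulus,
                          stability_check, strain_energy,
                          uniaxial_nominal_stress, von_mises)

# frozen 30-digit oracle values (arbitrary-precision evaluation of the
# closed forms at the reference parameter set, lambda = 1.5)
P_AT_1P5 = 0.247292155107041587984486634394
W_AT_1P5 = 0.0214748769208932983593751520763


def stable_param_sets():
    """Fuzzed stable two-term parameter sets (mu > 0 keeps the margin > 0)."""
    mu = st.tuples(st.floats(1e-6, 1e-2), st.floats(1e-6, 1e-2))
    alpha = st.tuples(st.floats(0.5, 8.0), st.floats(8.5, 22.0))
    return st.tuples(mu, alpha).map(
        lambda t: OgdenParameters.from_poisson(t[0], t[1]))


class TestStrainEnergy:
    def test_reference_state_is_zero(self, default_params):
        assert strain_energy(default_params, (1.0, 1.0, 1.0)) == 0.0

    def test_uniaxial_matches_high_precision_oracle(self, default_params):
        lam = (1.5, 1.5 ** -0.5, 1.5 ** -0.5)
        assert strain_energy(default_params, lam) == pytest.approx(
            W_AT_1P5, rel=1e-12)

    @given(params=stable_param_sets(),
           lams=st.tuples(st.floats(0.5, 2.0), st.floats(0.5, 2.0),
                          st.floats(0.5, 2.0)))
    @settings(max_examples=50, deadline=None)
    def test_symmetric_in_principal_stretches(self, params, lams):
        base = strain_energy(params, lams)
        for perm in [(1, 0, 2), (2, 1, 0), (1, 2, 0)]:
            permuted = tuple(lams[i] for i in perm)
            assert strain_energy(params, permuted) == pytest.approx(
                base, rel=1e-12, abs=1e-18)

    def test_nonpositive_stretch_rejected(self, default_params):
        with pytest.raises(InvalidInputError):
            strain_energy(default_params, (1.0, -0.5, 1.0))
        with pytest.raises(InvalidInputError):
            strain_energy(default_params, (0.0, 1.0, 1.0))


class TestUniaxialStress:
    def test_zero_at_reference(self, default_params):
        assert uniaxial_nominal_stress(default_params, 1.0) == 0.0

    def test_matches_high_precision_oracle_on_grid(self, default_params):
        """20 grid points in [1, 1.6] against a 50-digit sympy evaluation."""
        sympy = pytest.importorskip("sympy")
        mu = [sympy.Rational(8, 100000), sympy.Rational(17, 100000)]
        alpha = [sympy.Rational(181, 100), sympy.Rational(69, 4)]
        for lam in np.linspace(1.0, 1.6, 20):
            lam_s = sympy.Rational(round(lam * 10 ** 12), 10 ** 12)
            oracle = float(sympy.N(
                sum(2 * m * (lam_s ** (a - 1) - lam_s ** (-a / 2 - 1))
                    for m, a in zip(mu, alpha)), 50))
            ours = uniaxial_nominal_stress(default_params, float(lam_s))
            assert ours == pytest.approx(oracle, rel=1e-10, abs=1e-25)

    def test_value_at_1p5(self, default_params):
        assert uniaxial_nominal_stress(default_params, 1.5) == pytest.approx(
            P_AT_1P5, rel=1e-12)

    @given(params=stable_param_sets())
    @settings(max_examples=30, deadline=None)
    def test_strictly_increasing_for_stable_params(self, params):
        grid = np.linspace(1.0, 2.0, 41)
        p = uniaxial_nominal_stress(params, grid)
        assert np.all(np.diff(p) > 0)

    @given(params=stable_param_sets(), lam=st.floats(1.01, 1.8))
    @settings(max_examples=30, deadline=None)
    def test_equals_energy_derivative_on_uniaxial_path(self, params, lam):
        """P = dW/dlambda along the incompressible uniaxial path."""
        h = 1e-6

        def w(la):
            return strain_energy(params, (la, la ** -0.5, la ** -0.5))

        fd = (w(lam + h) - w(lam - h)) / (2 * h)
        assert uniaxial_nominal_stress(params, lam) == pytest.approx(
            fd, rel=1e-6)

    def test_invalid_stretch_rejected(self, default_params):
        with pytest.raises(InvalidInputError):
            uniaxial_nominal_stress(default_params, -1.0)


class TestCauchyStress:
    def test_identity_gives_zero(self, default_params):
        sigma = cauchy_stress(default_params, np.eye(3))
        assert np.abs(sigma).max() < 1e-12

    def test_uniaxial_closed_form(self, default_params):
        """sigma_axial - sigma_lateral = lambda * P(lambda) at J = 1."""
        lam = 1.5
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        sigma = cauchy_stress(default_params, F)
        expected = lam * uniaxial_nominal_stress(default_params, lam)
        assert sigma[0, 0] - sigma[1, 1] == pytest.approx(expected, rel=1e-5)
        assert sigma[1, 1] == pytest.approx(sigma[2, 2], rel=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_objectivity(self, default_params, seed):
        """cauchy(R F) = R cauchy(F) R^T for any rotation R."""
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        R = Rotation.random(random_state=rng).as_matrix()
        F = np.eye(3) + rng.normal(0, 0.1, (3, 3))
        assert np.linalg.det(F) > 0
        left = cauchy_stress(default_params, R @ F)
        right = R @ cauchy_stress(default_params, F) @ R.T
        assert np.abs(left - right).max() < 1e-8

    def test_inverted_gradient_rejected(self, default_params):
        from lamsim.errors import ElementInversionError

        F = np.diag([-1.0, 1.0, 1.0])
        with pytest.raises(ElementInversionError):
            cauchy_stress(default_params, F)

    def test_matches_energy_gradient_on_random_F(self, default_params):
        """Piola stress vs central differences of W on 100 random F."""
        from lamsim.ogden import first_piola

        rng = np.random.default_rng(7)
        h = 1e-6
        checked = 0
        while checked < 100:
            F = np.eye(3) + rng.normal(0, 0.05, (3, 3))
            J = np.linalg.det(F)
            if not 0.95 <= J <= 1.05:
                continue
            checked += 1
            P = first_piola(default_params, F)
            fd = np.empty((3, 3))
            for a in range(3):
                for b in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[a, b] += h
                    Fm[a, b] -= h
                    wp = _energy_of_F(default_params, Fp)
                    wm = _energy_of_F(default_params, Fm)
                    fd[a, b] = (wp - wm) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-12)
            assert np.abs(P - fd).max() / scale < 1e-4


def _energy_of_F(params, F):
    lam = np.sqrt(np.clip(np.linalg.eigvalsh(F.T @ F), 1e-30, None))
    return strain_energy(params, lam)


class TestVonMises:
    def test_hydrostatic_is_zero(self):
        assert von_mises(2.5 * np.eye(3)) == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("s", [2.0, -3.5])
    def test_uniaxial_closed_form(self, s):
        assert von_mises(np.diag([s, 0.0, 0.0])) == pytest.approx(abs(s))

    @given(seed=st.integers(0, 1000), p=st.floats(-5, 5))
    @settings(max_examples=40, deadline=None)
    def test_rotation_and_pressure_invariance(self, seed, p):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(seed)
        A = rng.normal(size=(3, 3))
        sigma = 0.5 * (A + A.T)
        R = Rotation.random(random_state=rng).as_matrix()
        vm = von_mises(sigma)
        assert von_mises(R @ sigma @ R.T) == pytest.approx(vm, abs=1e-10)
        assert von_mises(sigma + p * np.eye(3)) == pytest.approx(vm, abs=1e-10)

    def test_asymmetric_input_rejected(self):
        bad = np.array([[1.0, 0.5, 0], [0, 1, 0], [0, 0, 1]])
        with pytest.raises(InvalidInputError):
            von_mises(bad)


class TestStability:
    def test_reference_set_is_stable(self, default_params):
        ok, margin = stability_check(default_params.mu, default_params.alpha)
        assert ok
        assert margin == pytest.approx(8e-5 * 1.81 + 1.7e-4 * 17.25)

    @pytest.mark.parametrize("mu, alpha", [
        ((1.0, -1.0), (1.0, 1.0)),       # margin exactly zero
        ((0.0, 0.0), (2.0, 5.0)),        # boundary excluded
        ((1e-3, -2e-3), (1.0, 1.0)),     # negative margin
    ])
    def test_unstable_sets_detected(self, mu, alpha):
        ok, _ = stability_check(mu, alpha)
        assert not ok

    def test_length_mismatch_rejected(self):
        with pytest.raises(InvalidInputError):
            stability_check((1.0, 2.0), (1.0,))

    def test_unstable_parameters_cannot_be_constructed(self):
        with pytest.raises(InvalidInputError):
            OgdenParameters((1.0, -1.0), (1.0, 1.0), K=1.0)

    @given(params=stable_param_sets())
    @settings(max_examples=30, deadline=None)
    def test_numeric_shear_modulus_matches_margin(self, params):
        """The FD-linearized shear modulus equals sum(mu_j alpha_j)."""
        g = small_strain_shear_modulus(params.mu, params.alpha)
        assert g == pytest.approx(params.stability_margin, rel=1e-5)

    def test_bulk_modulus_from_poisson(self, default_params):
        g = default_params.stability_margin
        nu = 0.499
        expected = 2 * g * (1 + nu) / (3 * (1 - 2 * nu))
        assert default_params.K == pytest.approx(expected, rel=1e-5)

    @given(params=stable_param_sets(),
           lams=st.tuples(st.floats(0.7, 1.5), st.floats(0.7, 1.5),
                          st.floats(0.7, 1.5)))
    @settings(max_examples=40, deadline=None)
    def test_energy_nonnegative_near_reference(self, params, lams):
        """W >= 0 and P(1) = 0 for all stable parameter sets."""
        assert strain_energy(params, lams) >= -1e-12
        assert uniaxial_nominal_stress(params, 1.0) == 0.0
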