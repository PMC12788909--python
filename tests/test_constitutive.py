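"""Ogden constitutive law: energies, stresses, tangents, material table."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from atrosim.constitutive import (
    InvertedElementError,
    MaterialParams,
    MaterialTable,
    bulk_modulus,
    cauchy_stress,
    default_material_table,
    isochoric_stretches,
    material_tangent,
    ogden_energy_density,
    ogden_pk1,
    strain_energy,
)
from atrosim.regions import CORTICAL_LABELS

RNG = np.random.default_rng(42)


def random_rotation(rng):
    q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


@pytest.mark.parametrize(
    "mu,nu,expected",
    [(1.0, 0.49, 2 * 1.49 / (3 * 0.02)),   # 49.666...
     (0.0, 0.3, 0.0),
     (3.0, 0.25, 5.0)],
)
def test_bulk_modulus_hand_values(mu, nu, expected):
    assert bulk_modulus(mu, nu) == pytest.approx(expected, rel=1e-12)


def test_bulk_modulus_rejects_incompressible():
    with pytest.raises(ValueError, match="incompressible"):
        bulk_modulus(1.0, 0.5)


def test_isochoric_stretches_examples():
    assert np.allclose(isochoric_stretches(np.eye(3)), 1.0)
    got = isochoric_stretches(np.diag([2.0, 1.0, 1.0]))
    assert np.allclose(got, 2 ** (-1 / 3) * np.array([2.0, 1.0, 1.0]))
    assert np.allclose(isochoric_stretches(0.37 * np.eye(3)), 1.0, atol=1e-12)
    # unit product, descending order for random states
    for _ in range(20):
        F = np.eye(3) + 0.3 * RNG.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.1:
            continue
        lb = isochoric_stretches(F)
        assert np.prod(lb) == pytest.approx(1.0, abs=1e-10)
        assert lb[0] >= lb[1] >= lb[2] > 0


def test_inverted_state_rejected():
    with pytest.raises(InvertedElementError):
        isochoric_stretches(np.diag([-1.0, 1.0, 1.0]))


class TestStrainEnergy:
    P = MaterialParams(mu=1.2, alpha=-18.0, nu=0.45)

    def test_reference_state_is_energy_free(self):
        e = strain_energy(np.eye(3), self.P, Ja=0.8)
        assert e.psi_iso == e.psi_vol == e.psi == e.psi0 == 0.0

    def test_alpha_two_closed_form(self):
        # isochoric simple stretch at alpha=2: psi_iso = mu/2 (l^2 + l^-2 - 2)
        p = MaterialParams(mu=0.7, alpha=2.0, nu=0.3)
        lam = 1.23
        F = np.diag([lam, 1 / lam, 1.0])
        e = strain_energy(F, p)
        assert e.psi_iso == pytest.approx(0.35 * (lam**2 + lam**-2 - 2), rel=1e-12)
        assert e.psi_vol == pytest.approx(0.0, abs=1e-12)

    def test_isochoric_state_has_zero_volumetric_energy(self):
        F = np.diag([1.4, 1 / 1.4, 1.0])
        assert strain_energy(F, self.P).psi_vol == pytest.approx(0.0, abs=1e-12)

    def test_breakdown_sums_and_atrophy_weight(self):
        F = np.eye(3) + 0.05 * RNG.standard_normal((3, 3))
        e = strain_energy(F, self.P, Ja=0.9)
        assert e.psi == pytest.approx(e.psi_iso + e.psi_vol, rel=1e-12)
        assert e.psi0 == pytest.approx(0.9 * e.psi, rel=1e-12)
        assert e.psi >= 0

    def test_frame_indifference(self):
        for _ in range(10):
            F = np.eye(3) + 0.1 * RNG.standard_normal((3, 3))
            R = random_rotation(RNG)
            a = strain_energy(F, self.P).psi
            b = strain_energy(R @ F, self.P).psi
            assert b == pytest.approx(a, rel=1e-10, abs=1e-14)

    def test_energy_zero_iff_rotation(self):
        R = random_rotation(RNG)
        assert strain_energy(R, self.P).psi == pytest.approx(0.0, abs=1e-12)
        F = np.diag([1.01, 1.0, 1.0])
        assert strain_energy(F, self.P).psi > 0


class TestCauchyStress:
    P = MaterialParams(mu=1.1, alpha=-20.0, nu=0.49)

    def test_stress_free_reference(self):
        for ja in (1.0, 0.8):
            assert np.allclose(cauchy_stress(np.eye(3), self.P, ja), 0.0)

    def test_linear_scaling_in_mu(self):
        F = np.eye(3) + 0.04 * RNG.standard_normal((3, 3))
        s1 = cauchy_stress(F, MaterialParams(1.0, -20.0, 0.49))
        s3 = cauchy_stress(F, MaterialParams(3.0, -20.0, 0.49))
        assert np.allclose(s3, 3 * s1, rtol=1e-10)

    def test_pure_dilatation_is_hydrostatic(self):
        for c in (0.97, 1.05):
            s = cauchy_stress(c * np.eye(3), self.P)
            dev = s - np.trace(s) / 3 * np.eye(3)
            assert np.abs(dev).max() < 1e-12
            assert np.sign(np.trace(s)) == np.sign(c**3 - 1)

    def test_symmetry_and_rotation_covariance(self):
        F = np.eye(3) + 0.06 * RNG.standard_normal((3, 3))
        s = cauchy_stress(F, self.P)
        assert np.allclose(s, s.T)
        R = random_rotation(RNG)
        s_rot = cauchy_stress(R @ F, self.P)
        assert np.allclose(s_rot, R @ s @ R.T, atol=1e-10)

    def test_neo_hookean_limit_alpha_two(self):
        """At alpha = 2 the Ogden stress must coincide with an
        independently coded compressible neo-Hookean stress."""
        p = MaterialParams(mu=0.9, alpha=2.0, nu=0.4)
        for _ in range(100):
            F = np.eye(3) + 0.1 * RNG.standard_normal((3, 3))
            J = np.linalg.det(F)
            if J <= 0.3:
                continue
            b = F @ F.T
            dev_b = b - np.trace(b) / 3 * np.eye(3)
            s_ref = p.mu * J ** (-5 / 3) * dev_b \
                + p.kappa / 2 * (J - 1 / J) * np.eye(3)
            s = cauchy_stress(F, p)
            assert np.allclose(s, s_ref, rtol=1e-9, atol=1e-12)


class TestMaterialTangent:
    def test_identity_limit_is_isotropic_elasticity(self):
        p = MaterialParams(mu=1.3, alpha=-15.0, nu=0.45)
        A = material_tangent(np.eye(3), p)
        lam_l = p.kappa - 2 * p.mu / 3
        I = np.eye(3)
        iso = (lam_l * np.einsum("ij,kl->ijkl", I, I)
               + p.mu * (np.einsum("ik,jl->ijkl", I, I)
                         + np.einsum("il,jk->ijkl", I, I)))
        assert np.allclose(A, iso, atol=1e-12)

    def test_finite_difference_agreement(self):
        p = MaterialParams(mu=1.0, alpha=-12.0, nu=0.4)
        h = 1e-6
        for _ in range(5):
            F = np.eye(3) + 0.05 * RNG.standard_normal((3, 3))
            A = material_tangent(F, p)
            for idx in [(0, 0), (0, 1), (2, 1)]:
                dF = np.zeros((3, 3))
                dF[idx] = h
                fd = (ogden_pk1(F + dF, p.mu, p.alpha, p.kappa)
                      - ogden_pk1(F - dF, p.mu, p.alpha, p.kappa)) / (2 * h)
                assert np.allclose(A[:, :, idx[0], idx[1]], fd, rtol=2e-5, atol=1e-9)

    def test_zero_shear_modulus_has_zero_deviatoric_block(self):
        p = MaterialParams(mu=0.0, alpha=2.0, nu=0.3)
        A = material_tangent(np.eye(3), p)
        assert np.abs(A).max() == pytest.approx(0.0, abs=1e-14)


@given(st.floats(0.8, 1.25), st.floats(0.8, 1.25), st.floats(0.8, 1.25))
@settings(max_examples=30, deadline=None, derandomize=True)
def test_energy_nonnegative_over_admissible_stretches(l1, l2, l3):
    p = MaterialParams(mu=1.0, alpha=-20.0, nu=0.49)
    e = strain_energy(np.diag([l1, l2, l3]), p)
    assert e.psi >= -1e-12


def test_near_incompressibility_monotone_volume_response():
    """Under a fixed hydrostatic load, equilibrium J approaches 1
    monotonically as nu -> 0.5 at fixed mu (volumetric stiffening)."""
    from scipy.optimize import brentq

    load = 0.5  # kPa tension
    J_prev = None
    for nu in (0.3, 0.4, 0.45, 0.49, 0.499):
        kap = bulk_modulus(1.0, nu)
        J = brentq(lambda j: kap / 2 * (j - 1 / j) - load, 1.0, 10.0)
        assert J > 1
        if J_prev is not None:
            assert J < J_prev
        J_prev = J
    assert J_prev == pytest.approx(1.0, abs=5e-3)


class TestMaterialTable:
    def test_default_table_complete_and_contrasted(self, table17):
        cortical_mu = np.mean([table17[lab].mu for lab in CORTICAL_LABELS])
        assert table17["CSF"].mu == pytest.approx(cortical_mu / 10, rel=1e-10)
        for lab, p in table17.params.items():
            if lab in ("CSF", "VENTRICLE"):
                continue
            assert p.nu == 0.49
            assert p.kappa == pytest.approx(bulk_modulus(p.mu, 0.49))

    def test_csv_round_trip_lossless(self, table17):
        buf = io.StringIO()
        table17.to_csv(buf)
        buf.seek(0)
        back = MaterialTable.from_csv(buf)
        assert back.params == table17.params

    def test_missing_region_rejected(self, table17):
        params = dict(table17.params)
        params.pop("Hi")
        with pytest.raises(ValueError, match="Hi"):
            MaterialTable(scheme="17R", params=params)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            MaterialParams(mu=1.0, alpha=-20.0, nu=0.6)
        with pytest.raises(ValueError):
            MaterialParams(mu=-1.0, alpha=-20.0, nu=0.3)
        with pytest.raises(ValueError):
            MaterialParams(mu=1.0, alpha=0.0, nu=0.3)
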