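"""Energy calibration, (ρe, Z_eff) maps, basis decomposition, VNC and VMI."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phasedect.analysis import iodine_recovery_simulation
from phasedect.dect import (
    BasisMaterial,
    DecompositionBasis,
    EnergyCalibration,
    basis_inverse_matrix,
    calibrate_energy_from_delta,
    calibrate_energy_from_mu,
    decompose,
    iodine_map_from_nai,
    rhoe_map,
    vmi,
    vnc_image,
    zeff_map,
)
from phasedect.interactions import delta_from_rhoe, mu_model, zeff_from
from phasedect.materials import get_material, make_nai_solution


@pytest.fixture(scope="module")
def water_nai_basis():
    return DecompositionBasis.nai_against("water")


class TestEnergyCalibration:
    def test_pmma_delta_gives_phase_energy(self):
        assert calibrate_energy_from_delta(4.70e-7, "pmma") == pytest.approx(
            23.8, abs=0.2)

    def test_water_delta_consistency(self):
        assert calibrate_energy_from_delta(4.07e-7, "water") == pytest.approx(
            23.8, abs=0.2)

    def test_quadrupled_delta_halves_energy(self):
        e1 = calibrate_energy_from_delta(4.70e-7, "pmma")
        e2 = calibrate_energy_from_delta(4.0 * 4.70e-7, "pmma")
        assert e2 == pytest.approx(e1 / 2.0, rel=1e-12)

    def test_nonpositive_delta_rejected(self):
        with pytest.raises(ValueError):
            calibrate_energy_from_delta(0.0, "pmma")

    def test_pmma_mu_against_literature_curve(self):
        assert calibrate_energy_from_mu(0.470, "pmma") == pytest.approx(
            24.6, abs=0.3)

    def test_model_source_is_self_consistent(self):
        pmma = get_material("pmma")
        e = calibrate_energy_from_mu(pmma.mu(25.0), "pmma", source="model")
        assert e == pytest.approx(25.0, abs=1e-6)

    def test_energy_window_validated(self):
        with pytest.raises(ValueError):
            EnergyCalibration(e_mu_kev=60.0, e_delta_kev=23.8)


class TestVoxelMaps:
    def test_rhoe_map_water_value(self):
        assert rhoe_map(np.array(4.07e-7), 23.8) / 1e29 == pytest.approx(
            3.34, abs=0.01)

    def test_rhoe_map_inverts_delta(self, rng):
        rhoe = 3e29 * (0.5 + rng.random((8, 8)))
        delta = delta_from_rhoe(rhoe, 23.8)
        np.testing.assert_allclose(rhoe_map(delta, 23.8), rhoe, rtol=1e-12)

    def test_zeff_map_uniform_water(self):
        mu = np.full((4, 4), 0.523)
        rhoe = np.full((4, 4), 3.34e29)
        z, valid = zeff_map(mu, rhoe, 24.6)
        assert valid.all()
        np.testing.assert_allclose(z, 7.51, atol=0.05)

    def test_zeff_map_uniform_nylon(self):
        z, valid = zeff_map(np.full((2, 2), 0.423), np.full((2, 2), 3.79e29), 24.6)
        assert valid.all()
        assert z[0, 0] == pytest.approx(6.25, abs=0.07)

    def test_zeff_map_clamps_and_masks(self):
        mu = np.array([[0.523, 0.01], [0.523, 0.523]])
        rhoe = np.array([[3.34e29, 3.34e29], [-1e29, 3.34e29]])
        z, valid = zeff_map(mu, rhoe, 24.6)
        assert not valid[0, 1] and not valid[1, 0]
        assert z[0, 1] == 0.0 and z[1, 0] == 0.0
        assert valid[1, 1]


class TestBasis:
    def test_inverse_matrix_identity_for_orthonormal_toy_basis(self):
        b = DecompositionBasis(
            material_i=BasisMaterial("i", 1.0, 0.0, 1.0),
            material_x=BasisMaterial("x", 0.0, 1e29, 1.0))
        np.testing.assert_allclose(
            basis_inverse_matrix(b, coords="zeff-rhoe"), np.eye(2), atol=1e-15)

    @settings(derandomize=True, deadline=None)
    @given(zi=st.floats(8.0, 12.0), zx=st.floats(6.0, 7.9),
           ri=st.floats(3.0e29, 4.0e29), rx=st.floats(2.5e29, 2.99e29))
    def test_ninv_times_n_is_identity(self, zi, zx, ri, rx):
        b = DecompositionBasis(material_i=BasisMaterial("i", zi, ri, 20.0),
                               material_x=BasisMaterial("x", zx, rx, 1000.0))
        for coords in ("zeff-rhoe", "photo-compton"):
            n = b.coordinates(coords)
            np.testing.assert_allclose(basis_inverse_matrix(b, coords) @ n,
                                       np.eye(2), atol=1e-12)

    def test_basis_vector_maps_to_unit_vector(self, water_nai_basis):
        n = water_nai_basis.coordinates("photo-compton")
        v = basis_inverse_matrix(water_nai_basis, "photo-compton") @ n[:, 0]
        np.testing.assert_allclose(v, [1.0, 0.0], atol=1e-12)

    def test_degenerate_basis_rejected(self):
        with pytest.raises(ValueError, match="linearly dependent"):
            DecompositionBasis(material_i=BasisMaterial("i", 7.5, 3.3e29, 20.0),
                               material_x=BasisMaterial("x", 7.5, 3.3e29, 1000.0))

    def test_blood_background_uses_measured_record(self):
        b = DecompositionBasis.nai_against("blood")
        assert b.material_x.zeff == 7.60
        assert b.material_x.rhoe_m3 == 3.54e29


class TestDecompose:
    def test_pixel_at_basis_material_i(self, water_nai_basis):
        m = water_nai_basis.material_i
        ci, cx = decompose(np.array([[m.zeff]]), np.array([[m.rhoe_m3]]),
                           water_nai_basis)
        assert ci[0, 0] == pytest.approx(20.0, rel=1e-10)
        assert cx[0, 0] == pytest.approx(0.0, abs=1e-8)

    def test_pure_water_pixel_has_zero_nai(self, water_nai_basis):
        m = water_nai_basis.material_x
        for coords in ("photo-compton", "zeff-rhoe"):
            ci, cx = decompose(np.array([[m.zeff]]), np.array([[m.rhoe_m3]]),
                               water_nai_basis, coords=coords)
            assert abs(ci[0, 0]) < 1e-10
            assert cx[0, 0] == pytest.approx(1000.0, rel=1e-10)

    @settings(derandomize=True, deadline=None)
    @given(a=st.floats(0.0, 1.0), b=st.floats(0.0, 1.0))
    def test_identity_on_basis_simplex(self, water_nai_basis, a, b):
        # any nonnegative combination of the basis vectors is recovered
        # exactly (2x2 linear algebra)
        for coords in ("photo-compton", "zeff-rhoe"):
            n = water_nai_basis.coordinates(coords)
            u = a * n[:, 0] + b * n[:, 1]
            if u[1] <= 0:
                continue
            rho = u[1] * 1e29
            if coords == "zeff-rhoe":
                zeff = u[0]
            else:
                zeff = (u[0] / u[1]) ** (1.0 / water_nai_basis.params.c_z)
            ci, cx = decompose(np.array([[zeff]]), np.array([[rho]]),
                               water_nai_basis, coords=coords)
            assert ci[0, 0] == pytest.approx(20.0 * a, abs=1e-9 * 20.0)
            assert cx[0, 0] == pytest.approx(1000.0 * b, abs=1e-9 * 1000.0)

    def test_forward_modelled_solution_recovered_noiselessly(self, water_nai_basis):
        # quantifies the linearization bias of the decomposition: in the
        # additive photo/Compton coordinates it vanishes
        sol = make_nai_solution(5.0)
        rhoe = rhoe_map(np.array([[sol.delta(23.8)]]), 23.8)
        z, _ = zeff_map(np.array([[sol.mu(24.6)]]), rhoe, 24.6)
        ci, _ = decompose(z, rhoe, water_nai_basis)
        assert ci[0, 0] == pytest.approx(5.0, abs=0.3)

    def test_literal_zeff_coordinates_carry_concavity_bias(self, water_nai_basis):
        # the (Z_eff, rho_e) vector is concave in concentration; the literal
        # decomposition must overestimate dilute solutions
        sol = make_nai_solution(5.0)
        rhoe = rhoe_map(np.array([[sol.delta(23.8)]]), 23.8)
        z, _ = zeff_map(np.array([[sol.mu(24.6)]]), rhoe, 24.6)
        ci, _ = decompose(z, rhoe, water_nai_basis, coords="zeff-rhoe")
        assert ci[0, 0] > 5.0 + 0.3

    def test_iodine_map_scaling(self):
        nai = np.array([[5.9]])
        assert iodine_map_from_nai(nai)[0, 0] == pytest.approx(5.0, abs=0.05)

    def test_iodine_recovery_under_measurement_noise(self):
        res = iodine_recovery_simulation(n_replicates=100, seed=11)
        assert res["overall_max_abs_error_mg_ml"] <= 0.7


class TestVNC:
    def test_no_iodine_means_bitwise_identity(self, rng):
        mu = rng.random((16, 16))
        out = vnc_image(mu, np.zeros_like(mu), 0.5, 0.01)
        np.testing.assert_array_equal(out, mu)

    def test_only_flagged_pixels_modified(self, rng):
        mu = rng.random((16, 16))
        iod = np.zeros_like(mu)
        iod[3:6, 4:9] = 2.0
        out = vnc_image(mu, iod, 0.5, 0.01, rng=3)
        sel = iod > 0
        np.testing.assert_array_equal(out[~sel], mu[~sel])
        assert np.all(out[sel] != mu[sel])

    def test_replacement_statistics(self, rng):
        mu = np.zeros((100, 100))
        iod = np.ones_like(mu)
        out = vnc_image(mu, iod, 0.523, 0.006, rng=5)
        n = mu.size
        assert out.mean() == pytest.approx(0.523, abs=3 * 0.006 / np.sqrt(n))
        assert out.std() == pytest.approx(0.006, rel=0.1)

    def test_deterministic_for_seed(self, rng):
        mu = rng.random((8, 8))
        iod = (mu > 0.5).astype(float)
        a = vnc_image(mu, iod, 0.5, 0.01, rng=9)
        b = vnc_image(mu, iod, 0.5, 0.01, rng=9)
        np.testing.assert_array_equal(a, b)

    def test_threshold_respected(self, rng):
        mu = rng.random((8, 8))
        iod = np.full_like(mu, 0.2)
        out = vnc_image(mu, iod, 0.5, 0.01, threshold=0.5)
        np.testing.assert_array_equal(out, mu)


class TestVMI:
    def test_inversion_identity_at_calibration_energy(self, rng):
        rhoe = 3e29 * (0.8 + 0.4 * rng.random((12, 12)))
        z = 6.0 + 2.0 * rng.random((12, 12))
        mu = mu_model(rhoe, z, 24.6)
        z_map, valid = zeff_map(mu, rhoe, 24.6)
        out = vmi(z_map, rhoe, 24.6, valid=valid)
        np.testing.assert_allclose(out, mu, rtol=1e-10)

    def test_water_pixel_at_25_kev(self):
        w = get_material("water")
        out = vmi(np.array([[w.zeff()]]), np.array([[w.electron_density()]]), 25.0)
        assert out[0, 0] == pytest.approx(0.505, abs=0.003)

    def test_high_energy_limit_proportional_to_rhoe(self):
        # at 120 keV the Compton term dominates: mu/rho_e constant within 2%
        mats = [get_material(n) for n in
                ("water", "pmma", "pom", "nylon6", "ethanol", "blood")]
        mats.append(make_nai_solution(5.9))
        rhoe = np.array([[m.electron_density() for m in mats]])
        z = np.array([[m.zeff() for m in mats]])
        ratios = vmi(z, rhoe, 120.0) / rhoe
        assert ratios.max() / ratios.min() - 1.0 < 0.02

    def test_masked_pixels_use_compton_only(self):
        z = np.array([[0.0]])
        rhoe = np.array([[3.34e29]])
        out = vmi(z, rhoe, 70.0, valid=np.array([[False]]))
        assert out[0, 0] == pytest.approx(mu_model(3.34e29, 0.0, 70.0), rel=1e-12)

    def test_rejects_nonpositive_energy(self):
        with pytest.raises(ValueError):
            vmi(np.ones((2, 2)), np.ones((2, 2)), 0.0)
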