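"""Phantom rasterization and the phase-stepping forward model."""

import numpy as np
import pytest

from phasedect.forward import (
    AcquisitionGeometry,
    PhaseWrapWarning,
    TruncationWarning,
    dphase_from_delta_integrals,
    differential_phase_sinogram,
    phantom_line_integrals,
    project_line_integrals,
    synthesize_stepping,
)
from phasedect.materials import get_material
from phasedect.phantom import CylinderInsert, PhantomSpec, rasterize, table1_phantom
from phasedect.stepping import extract_from_frames


@pytest.fixture(scope="module")
def geo():
    return AcquisitionGeometry(n_pixels=128, n_angles=60)


@pytest.fixture(scope="module")
def water_bath():
    return PhantomSpec(inserts=(), container_radius_mm=8.0,
                       field_of_view_mm=128 * 0.16)


class TestPhantomSpec:
    def test_insert_must_stay_inside_container(self):
        with pytest.raises(ValueError, match="protrudes"):
            PhantomSpec(
                inserts=(CylinderInsert((17.0, 0.0), 3.0, "pmma"),),
                container_radius_mm=18.0,
            )

    def test_container_must_fit_field_of_view(self):
        with pytest.raises(ValueError, match="field of view"):
            PhantomSpec(inserts=(), container_radius_mm=25.0,
                        field_of_view_mm=40.0)

    def test_default_phantom_has_six_inserts_in_water(self):
        spec = table1_phantom()
        assert len(spec.inserts) == 6
        assert spec.bath().name == "water"
        names = {i.resolved().name for i in spec.inserts}
        assert {"blood", "ethanol", "pmma", "pom", "nylon6"} <= names

    def test_unknown_material_raises(self):
        spec = PhantomSpec(inserts=(CylinderInsert((0, 0), 2.0, "adamantium"),),
                           container_radius_mm=15.0)
        with pytest.raises(KeyError):
            spec.disks(25.0)


class TestRasterize:
    def test_water_field_is_uniform_at_table_values(self, water_bath):
        mu, delta = rasterize(water_bath, 128, 160.0, 24.6)
        _, delta_238 = rasterize(water_bath, 128, 160.0, 23.8)
        w = get_material("water")
        c = slice(54, 74)
        assert mu[c, c] == pytest.approx(w.mu(24.6), rel=1e-12)
        # published value: 0.523 1/cm (model carries no coherent term, ~1% low)
        assert mu[64, 64] == pytest.approx(0.523, rel=0.015)
        assert delta_238[c, c] == pytest.approx(4.07e-7, rel=0.005)

    def test_empty_field_is_zero(self):
        spec = PhantomSpec(inserts=(), container_radius_mm=1e-6,
                           container_material="water", field_of_view_mm=20.0)
        mu, delta = rasterize(spec, 64, 160.0, 25.0)
        assert np.count_nonzero(mu) <= 4  # only the sub-pixel container

    def test_pmma_disk_gives_two_level_map(self, water_bath):
        spec = PhantomSpec(
            inserts=(CylinderInsert((0.0, 0.0), 3.0, "pmma"),),
            container_radius_mm=8.0, field_of_view_mm=128 * 0.16)
        mu, _ = rasterize(spec, 128, 160.0, 24.6)
        assert mu[64, 64] == pytest.approx(get_material("pmma").mu(24.6), rel=1e-9)
        assert mu[64, 64] == pytest.approx(0.470, rel=0.02)
        assert mu[64, 110] == pytest.approx(get_material("water").mu(24.6), rel=1e-9)

    def test_edges_are_antialiased(self, water_bath):
        mu, _ = rasterize(water_bath, 128, 160.0, 25.0)
        interior = mu.max()
        edge_vals = mu[(mu > 0.05 * interior) & (mu < 0.95 * interior)]
        assert edge_vals.size > 0  # fractional-coverage pixels exist


class TestProjection:
    def test_zero_map_gives_zero_sinogram(self, geo):
        sino = project_line_integrals(np.zeros((64, 64)), geo.angles_rad, 160.0)
        assert np.all(sino == 0)

    def test_linearity(self, geo, rng):
        c = np.arange(64) - 31.5
        inside = np.hypot(*np.meshgrid(c, c)) < 28  # keep off the edges
        a = rng.random((64, 64)) * inside
        b = rng.random((64, 64)) * inside
        angles = geo.angles_rad[:5]
        s = project_line_integrals(2.0 * a + 3.0 * b, angles, 160.0)
        sa = project_line_integrals(a, angles, 160.0)
        sb = project_line_integrals(b, angles, 160.0)
        np.testing.assert_allclose(s, 2.0 * sa + 3.0 * sb, atol=1e-10)

    def test_mass_conservation(self, water_bath):
        mu, _ = rasterize(water_bath, 128, 160.0, 25.0)
        angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        sino = project_line_integrals(mu, angles, 160.0)
        mass = mu.sum() * 0.016  # pixel size in cm
        np.testing.assert_allclose(sino.sum(axis=1), mass, rtol=1e-3)

    def test_opposed_projections_are_mirror_images(self, water_bath, rng):
        mu, _ = rasterize(
            PhantomSpec(inserts=(CylinderInsert((3.0, 1.5), 2.0, "pmma"),),
                        container_radius_mm=8.0, field_of_view_mm=128 * 0.16),
            128, 160.0, 25.0)
        s = project_line_integrals(mu, np.array([0.3, 0.3 + np.pi]), 160.0)
        np.testing.assert_allclose(s[0], s[1][::-1], atol=2e-3 * s.max())

    def test_central_ray_chord_of_uniform_disk(self, geo):
        spec = PhantomSpec(inserts=(), container_radius_mm=10.0,
                           field_of_view_mm=geo.field_of_view_mm)
        p_mu, _ = phantom_line_integrals(spec, geo, 25.0)
        mu_w = get_material("water").mu(25.0)
        # central ray: chord = 2r = 2 cm
        assert p_mu[:, 63:65].mean() == pytest.approx(2.0 * mu_w, rel=1e-3)

    def test_truncation_warning(self, geo):
        img = np.ones((64, 64))
        with pytest.warns(TruncationWarning):
            project_line_integrals(img, geo.angles_rad[:2], 160.0)

    def test_analytic_and_numeric_projectors_agree(self, geo, water_bath):
        mu, _ = rasterize(water_bath, 128, 160.0, 25.0)
        angles = geo.angles_rad[:8]
        numeric = project_line_integrals(mu, angles, 160.0)
        p_mu, _ = phantom_line_integrals(water_bath, geo, 25.0)
        # bilinear rotation smooths the rim; agreement to 2% of peak there
        np.testing.assert_allclose(numeric, p_mu[:8], atol=0.02 * p_mu.max())
        assert np.median(np.abs(numeric - p_mu[:8])) < 1e-3 * p_mu.max()


class TestDifferentialPhase:
    def test_apex_ray_has_zero_phase(self, geo, water_bath):
        _, p_delta = phantom_line_integrals(water_bath, geo, 25.0)
        phi = dphase_from_delta_integrals(p_delta, geo)
        # detector center is between pixels 63/64: mirror antisymmetry
        np.testing.assert_allclose(phi, -phi[:, ::-1], atol=1e-9)

    def test_refraction_angle_matches_analytic_cylinder(self, geo):
        spec = PhantomSpec(inserts=(), container_radius_mm=8.0,
                           field_of_view_mm=geo.field_of_view_mm)
        _, p_delta = phantom_line_integrals(spec, geo, 25.0)
        phi = dphase_from_delta_integrals(p_delta, geo)
        alpha = phi[0] / geo.phase_coeff
        d_w = get_material("water").delta(25.0)
        s = (np.arange(128) + 0.5 - 64) * 0.016  # cm
        r = 0.8
        inside = np.abs(s) < 0.7 * r
        s = np.where(inside, s, 0.0)  # keep sqrt in-domain off the rim
        expected = -2.0 * d_w * s / np.sqrt(r**2 - s**2)
        # central differences approximate the analytic derivative away from
        # the rim
        np.testing.assert_allclose(alpha[inside], expected[inside],
                                   atol=3e-3 * np.abs(expected[inside]).max()
                                   + 1e-12)

    def test_phase_linear_in_grating_distance(self, geo, water_bath):
        import dataclasses

        _, p_delta = phantom_line_integrals(water_bath, geo, 25.0)
        phi1 = dphase_from_delta_integrals(p_delta, geo)
        geo2 = dataclasses.replace(geo, d_mm=2 * geo.d_mm)
        phi2 = dphase_from_delta_integrals(p_delta, geo2)
        np.testing.assert_allclose(phi2, 2.0 * phi1, rtol=1e-12)

    def test_wrap_warning_on_large_phase(self, geo):
        p_delta = np.zeros((3, 128))
        p_delta[:, 60] = 1.0  # absurd step -> |phi| >> pi
        with pytest.warns(PhaseWrapWarning):
            dphase_from_delta_integrals(p_delta, geo)

    def test_map_based_wrapper_matches_analytic_route(self, geo, water_bath):
        mu_map, delta_map = rasterize(water_bath, 128, 160.0, 25.0)
        phi_map = differential_phase_sinogram(delta_map, geo)
        _, p_delta = phantom_line_integrals(water_bath, geo, 25.0)
        phi_ana = dphase_from_delta_integrals(p_delta, geo)
        # agreement away from the rim singularity
        assert np.median(np.abs(phi_map - phi_ana)) < 0.02 * np.abs(phi_ana).max()


class TestStepping:
    def test_noise_off_identity_for_unit_transmission(self, geo):
        t = np.ones((4, geo.n_pixels))
        phi = np.zeros_like(t)
        fr = synthesize_stepping(t, phi, geo, noise=False)
        np.testing.assert_array_equal(fr.sample, fr.reference)

    def test_noise_off_roundtrip_recovers_t_and_phi(self, geo, rng):
        t = 0.2 + 0.7 * rng.random((5, geo.n_pixels))
        phi = rng.uniform(-2.5, 2.5, t.shape)
        fr = synthesize_stepping(t, phi, geo, noise=False)
        ch = extract_from_frames(fr)
        np.testing.assert_allclose(ch.transmission, t, atol=1e-12)
        np.testing.assert_allclose(ch.dphase, phi, atol=1e-12)
        np.testing.assert_allclose(ch.visibility_ratio, 1.0, atol=1e-12)

    def test_same_seed_reproduces_frames(self, geo, rng):
        t = 0.5 * np.ones((3, geo.n_pixels))
        phi = np.zeros_like(t)
        f1 = synthesize_stepping(t, phi, geo, noise=True, rng=123)
        f2 = synthesize_stepping(t, phi, geo, noise=True, rng=123)
        np.testing.assert_array_equal(f1.sample, f2.sample)
        np.testing.assert_array_equal(f1.reference, f2.reference)

    def test_noisy_frames_are_integer_counts(self, geo):
        t = 0.5 * np.ones((2, geo.n_pixels))
        fr = synthesize_stepping(t, np.zeros_like(t), geo, noise=True, rng=0)
        assert fr.sample.dtype.kind == "i" and fr.sample.min() >= 0

    def test_transmission_domain_validated(self, geo):
        bad = 1.5 * np.ones((2, geo.n_pixels))
        with pytest.raises(ValueError):
            synthesize_stepping(bad, np.zeros_like(bad), geo, noise=False)

    def test_geometry_validation(self):
        with pytest.raises(ValueError):
            AcquisitionGeometry(visibility=0.0)
        with pytest.raises(ValueError):
            AcquisitionGeometry(n_steps=2)
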