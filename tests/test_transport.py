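"""Transport physics checks: phase function, Fresnel, Beer-Lambert,
diffusion limit, energy budget, determinism."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import phototherm as pt
from phototherm.transport import TransportError


class TestPhaseFunction:
    def test_isotropic_mean_is_zero(self, rng):
        u = rng.random(10**6)
        sampled = np.array([pt.sample_phase_function(0.0, ui) for ui in u[:1000]])
        assert np.allclose(sampled, 2.0 * u[:1000] - 1.0)  # g=0 is uniform in cos
        cos = 2.0 * u - 1.0
        se = cos.std() / math.sqrt(len(cos))
        assert abs(cos.mean()) < 3 * se

    @pytest.mark.parametrize("g", [0.9, 0.5, -0.4])
    def test_first_moment_equals_g(self, g, rng):
        """The Henyey-Greenstein first moment is the anisotropy parameter."""
        u = rng.random(10**6)
        cos = np.array([pt.sample_phase_function(g, ui) for ui in u])
        se = cos.std() / math.sqrt(len(cos))
        assert abs(cos.mean() - g) < 3 * se

    def test_second_moment_matches_numerical_integration(self, rng):
        """Empirical second moment against direct integration of the HG pdf."""
        g = 0.5
        pdf = lambda c: 0.5 * (1 - g**2) / (1 + g**2 - 2 * g * c) ** 1.5
        norm, _ = quad(pdf, -1, 1)
        second, _ = quad(lambda c: c * c * pdf(c), -1, 1)
        assert norm == pytest.approx(1.0, abs=1e-9)
        u = rng.random(10**6)
        cos = np.array([pt.sample_phase_function(g, ui) for ui in u])
        emp = (cos**2).mean()
        se = (cos**2).std() / math.sqrt(len(cos))
        assert abs(emp - second) < 3 * se

    def test_values_in_range(self, rng):
        for g in (-0.99, -0.5, 0.0, 0.5, 0.99):
            cos = [pt.sample_phase_function(g, ui) for ui in rng.random(1000)]
            assert all(-1.0 <= c <= 1.0 for c in cos)

    def test_invalid_anisotropy_rejected(self):
        with pytest.raises(TransportError):
            pt.sample_phase_function(1.0, 0.5)


class TestFresnel:
    def test_matched_media_reflect_nothing(self):
        for cos_i in (1.0, 0.5, 0.01):
            assert pt.fresnel_reflectance(1.34, 1.34, cos_i) == 0.0

    def test_total_internal_reflection(self):
        # critical angle for 1.34 -> 1.0 is ~48.3 deg; take 60 deg
        assert pt.fresnel_reflectance(1.34, 1.0, math.cos(math.radians(60))) == 1.0

    def test_normal_incidence_closed_form(self):
        r = pt.fresnel_reflectance(1.0, 1.34, 1.0)
        assert r == pytest.approx(((1.0 - 1.34) / (1.0 + 1.34)) ** 2, rel=1e-12)
        assert r == pytest.approx(0.0211, abs=5e-5)

    def test_reciprocity_at_normal_incidence(self):
        assert pt.fresnel_reflectance(1.0, 1.5, 1.0) == pytest.approx(
            pt.fresnel_reflectance(1.5, 1.0, 1.0), rel=1e-12
        )


class TestTransport:
    def test_beer_lambert_in_nonscattering_medium(self):
        """Laterally averaged fluence follows exp(-mu_a z) within 2% for
        mu_a z <= 3 (no scattering, matched indices)."""
        mu_a = 0.15
        geom = pt.Geometry(radius=10, height=20, n_lateral=20, n_depth=40)
        med = pt.CompositeOptics(mu_a_total=mu_a, mu_s_total=0.0, g_eff=0.0, n=1.0)
        beam = pt.BeamSpec(power=1.0, beam_radius=6.0)
        fmap, amap = pt.run_transport(
            med, geom, beam, pt.TransportSettings(n_photons=1_000_000, seed=3)
        )
        prof = pt.depth_profile(fmap)
        incident = 1.0 / (math.pi * beam.beam_radius**2)
        mask = mu_a * prof.z <= 3.0
        rel = prof.value[mask] / (incident * np.exp(-mu_a * prof.z[mask])) - 1.0
        assert np.abs(rel).max() < 0.02

    def test_vacuum_gives_collimated_beam(self):
        geom = pt.Geometry(radius=10, height=20, n_lateral=20, n_depth=40)
        med = pt.CompositeOptics(mu_a_total=0.0, mu_s_total=0.0, g_eff=0.0, n=1.0)
        beam = pt.BeamSpec(power=1.0, beam_radius=6.0)
        fmap, _ = pt.run_transport(
            med, geom, beam, pt.TransportSettings(n_photons=50_000, seed=1)
        )
        prof = pt.depth_profile(fmap)
        incident = 1.0 / (math.pi * beam.beam_radius**2)
        assert prof.value == pytest.approx(incident, rel=1e-6)
        assert fmap.budget["transmitted"] == pytest.approx(1.0, abs=1e-9)

    def test_conservation_without_absorber(self):
        geom = pt.Geometry(radius=10, height=15, n_lateral=15, n_depth=20)
        med = pt.CompositeOptics(mu_a_total=0.0, mu_s_total=1.0, g_eff=0.3, n=1.0)
        fmap, _ = pt.run_transport(
            med, geom, pt.BeamSpec(1.0, 5.0),
            pt.TransportSettings(n_photons=100_000, seed=8),
        )
        b = fmap.budget
        assert b["absorbed"] == 0.0
        assert b["reflected"] + b["transmitted"] + b["side_escaped"] == pytest.approx(
            1.0, abs=1e-3
        )

    def test_energy_budget_closes(self, scatterer_run, absorber_run, blank_run):
        for fmap, _ in (scatterer_run, absorber_run, blank_run):
            assert sum(fmap.budget.values()) == pytest.approx(1.0, abs=1e-3)

    def test_absorbed_equals_integrated_absorption_map(self, absorber_run):
        """Volume integral of mu_a * phi equals the absorbed budget fraction."""
        fmap, amap = absorber_run
        integral = (amap.a_total * fmap.geometry.voxel_volumes()).sum()
        assert integral == pytest.approx(fmap.budget["absorbed"], abs=1e-3)
        assert integral == pytest.approx(amap.absorbed_fraction, rel=1e-9)

    def test_diffusion_limit_decay_constant(self):
        """Deep-fluence decay in a high-albedo wide slab matches the
        diffusion-approximation effective attenuation within 10%."""
        mu_a, mu_s = 0.01, 1.0
        geom = pt.Geometry(radius=40, height=30, n_lateral=20, n_depth=30)
        med = pt.CompositeOptics(mu_a_total=mu_a, mu_s_total=mu_s, g_eff=0.0, n=1.0)
        fmap, _ = pt.run_transport(
            med, geom, pt.BeamSpec(1.0, 30.0),
            pt.TransportSettings(n_photons=150_000, seed=41),
        )
        prof = pt.depth_profile(fmap)
        mask = (prof.z >= 5.0) & (prof.z <= 15.0)  # >= 5 transport mfp
        slope = np.polyfit(prof.z[mask], np.log(prof.value[mask]), 1)[0]
        mu_eff = math.sqrt(3 * mu_a * (mu_s + mu_a))
        assert abs(-slope - mu_eff) / mu_eff < 0.10

    def test_seed_determinism(self, small_geom, beam, blank_medium):
        settings = pt.TransportSettings(n_photons=20_000, seed=77)
        f1, a1 = pt.run_transport(blank_medium, small_geom, beam, settings)
        f2, a2 = pt.run_transport(blank_medium, small_geom, beam, settings)
        assert np.array_equal(f1.phi, f2.phi)
        assert np.array_equal(a1.a_total, a2.a_total)
        assert f1.budget == f2.budget

    def test_adding_absorber_never_increases_fluence(self, blank_run, absorber_run):
        """Monotonicity in mu_a: extra absorption cannot raise local fluence
        beyond Monte Carlo noise (3 pooled standard errors)."""
        (fb, _), (fa, _) = blank_run, absorber_run
        pooled = np.sqrt(fb.stderr**2 + fa.stderr**2)
        excess = fa.phi - fb.phi - 3 * pooled
        assert (excess <= 0).all()

    def test_scattering_prolongs_pathlength(self, blank_run, scatterer_run):
        (fb, _), (fs, _) = blank_run, scatterer_run
        assert fs.mean_pathlength > fb.mean_pathlength
        assert fs.mean_scatter_events > fb.mean_scatter_events

    def test_voxelized_medium_matches_homogeneous(self, small_geom, beam):
        """A uniform voxel field reproduces the homogeneous run bit for bit."""
        shape = (small_geom.n_lateral, small_geom.n_depth)
        vox = pt.VoxelMedium(
            mu_a=np.full(shape, 0.06), mu_s=np.full(shape, 0.1),
            g=np.full(shape, 0.9), n=1.34,
        )
        hom = pt.CompositeOptics(mu_a_total=0.06, mu_s_total=0.1, g_eff=0.9, n=1.34)
        settings = pt.TransportSettings(n_photons=20_000, seed=55)
        fv, _ = pt.run_transport(vox, small_geom, beam, settings)
        fh, _ = pt.run_transport(hom, small_geom, beam, settings)
        assert np.array_equal(fv.phi, fh.phi)

    def test_invalid_inputs_rejected(self, small_geom, blank_medium):
        with pytest.raises(TransportError):
            pt.BeamSpec(power=1.0, beam_radius=0.0)
        with pytest.raises(TransportError):
            pt.Geometry(radius=5.0, height=10.0, n_lateral=1, n_depth=10)
        with pytest.raises(TransportError):
            pt.TransportSettings(n_photons=10)
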