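"""Synergy coefficient, dose-response fitting, dose conversion and
sensitivity-scan behaviour."""

import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import phototherm as pt
from phototherm.scenarios import DOSE_GRID, gen_dose_response
from phototherm.stats import StatsError, four_param_logistic


class TestSynergy:
    def test_measured_triple_is_synergistic(self):
        """dT 9.04 over components 5.38 + 2.6 exceeds the additive threshold."""
        res = pt.synergy_coefficient(9.04, 5.38, 2.6)
        assert res.s == pytest.approx(9.04 / 7.98, rel=1e-12)
        assert res.s > 1.0
        assert res.synergistic

    def test_additive_boundary_is_not_synergistic(self):
        res = pt.synergy_coefficient(7.0, 4.0, 3.0)
        assert res.s == 1.0
        assert not res.synergistic

    def test_zero_combined(self):
        assert pt.synergy_coefficient(0.0, 1.0, 1.0).s == 0.0

    def test_nonpositive_denominator_rejected(self):
        with pytest.raises(StatsError, match="must be > 0"):
            pt.synergy_coefficient(1.0, 0.0, 0.0)

    @given(c=st.floats(1e-6, 1e6))
    @settings(max_examples=50, derandomize=True, deadline=None)
    def test_scale_invariance(self, c):
        base = pt.synergy_coefficient(9.04, 5.38, 2.6).s
        scaled = pt.synergy_coefficient(9.04 * c, 5.38 * c, 2.6 * c).s
        assert scaled == pytest.approx(base, rel=1e-9)


class TestDoseResponse:
    def test_noiseless_round_trip(self):
        df = gen_dose_response(100.0, slope=3.0, noise_sd=0.0, replicates=1,
                               doses=np.linspace(0, 300, 13))
        fit = pt.fit_dose_response(df)
        assert fit.ld50 == pytest.approx(100.0, rel=0.01)
        assert fit.slope == pytest.approx(3.0, rel=0.05)

    def test_step_function_brackets_ld50(self):
        doses = [10.0, 20.0, 40.0, 80.0]
        df = pd.DataFrame(
            {"dose": doses * 2, "viability": [1, 1, 0, 0] * 2}
        )
        fit = pt.fit_dose_response(df)
        assert 20.0 <= fit.ld50 <= 40.0

    def test_noisy_recovery_on_canonical_grid(self):
        """5% noise, 3 replicates on the six-point power-density grid:
        LD50 back within 10% for a mid-grid truth."""
        errs = []
        for seed in range(100):
            df = gen_dose_response(100.0, slope=3.0, noise_sd=0.05, replicates=3,
                                   seed=seed)
            fit = pt.fit_dose_response(df)
            errs.append(abs(fit.ld50 - 100.0) / 100.0)
        errs = np.array(errs)
        assert np.median(errs) <= 0.05
        assert np.quantile(errs, 0.9) <= 0.10

    def test_too_few_doses_rejected(self):
        df = pd.DataFrame({"dose": [0, 10, 20], "viability": [1.0, 0.6, 0.1]})
        with pytest.raises(StatsError):
            pt.fit_dose_response(df)

    def test_out_of_range_viability_rejected(self):
        df = pd.DataFrame({"dose": [0, 10, 20, 30], "viability": [1.2, 0.6, 0.3, 0.1]})
        with pytest.raises(StatsError):
            pt.fit_dose_response(df)

    def test_increasing_trend_flagged(self):
        df = pd.DataFrame(
            {"dose": [0, 10, 20, 40, 80], "viability": [0.1, 0.25, 0.5, 0.8, 0.95]}
        )
        with pytest.warns(UserWarning, match="increases with dose"):
            fit = pt.fit_dose_response(df)
        assert fit.increasing_warning


class TestFoldReduction:
    def test_printed_ld50_pair(self):
        """143 over 34 mW/cm^2 is a 4.2-fold dose reduction."""
        assert round(pt.ld50_fold_reduction(143.0, 34.0), 1) == 4.2

    def test_control_extrapolation_pair(self):
        assert pt.ld50_fold_reduction(350.0, 34.0) == pytest.approx(10.3, abs=0.05)

    def test_equal_inputs(self):
        assert pt.ld50_fold_reduction(50.0, 50.0) == 1.0

    def test_antisymmetry_under_swap(self):
        r = pt.ld50_fold_reduction(143.0, 34.0)
        assert pt.ld50_fold_reduction(34.0, 143.0) == pytest.approx(1.0 / r, rel=1e-12)

    def test_accepts_fit_objects(self):
        df = gen_dose_response(80.0, noise_sd=0.0, replicates=1,
                               doses=np.linspace(0, 240, 13))
        fit = pt.fit_dose_response(df)
        assert pt.ld50_fold_reduction(fit, fit) == pytest.approx(1.0, rel=1e-9)

    def test_zero_rejected(self):
        with pytest.raises(StatsError):
            pt.ld50_fold_reduction(143.0, 0.0)


class TestPowerDensity:
    def test_canonical_dose_grid(self):
        """The 100-900 mW series over a 2.5-cm beam maps onto the printed
        power densities at one-decimal rounding (paper-rounded area)."""
        powers = [0, 100, 300, 500, 700, 900]
        got = [round(pt.power_density(p, 2.5, paper_rounding=True), 1) for p in powers]
        assert got == [0.0, 20.4, 61.2, 102.0, 142.9, 183.7]

    def test_exact_vs_rounded_area(self):
        exact = pt.power_density(500.0, 2.5)
        assert exact == pytest.approx(101.86, abs=0.01)
        assert round(pt.power_density(500.0, 2.5, paper_rounding=True), 1) == 102.0

    def test_first_dose_one_decimal(self):
        assert round(pt.power_density(100.0, 2.5), 1) == 20.4

    def test_zero_power(self):
        assert pt.power_density(0.0, 2.5) == 0.0

    def test_bad_diameter(self):
        with pytest.raises(StatsError):
            pt.power_density(100.0, 0.0)


class TestSensitivityScan:
    def test_empty_grid_gives_empty_report(self):
        sc = pt.preset("combined")
        reports = pt.sensitivity_scan(
            sc, parameters=("mu_a_bkg",), grid=(),
            settings=pt.TransportSettings(n_photons=10_000, seed=1),
        )
        rep = reports["mu_a_bkg"]
        assert rep.perturbations.size == 0
        assert rep.index_absorbed == 0.0

    def test_unphysical_perturbations_skipped(self):
        sc = pt.preset("combined")
        with pytest.warns(UserWarning, match="skipping"):
            reports = pt.sensitivity_scan(
                sc, parameters=("g_bkg",), grid=(0.2,),
                settings=pt.TransportSettings(n_photons=10_000, seed=1),
            )
        assert reports["g_bkg"].skipped == [0.2]

    def test_absorber_doubling_follows_beer_lambert(self):
        """In a pure-absorber slab the absorbed fraction tracks
        1 - exp(-mu_a L) as mu_a is perturbed."""
        sp = pt.ParticleSpecies(name="absorber", sigma_abs=2.3e4, sigma_sca=0.0)
        bg = pt.BackgroundOptics(mu_a_bkg=0.0, mu_s_bkg=0.0, g_bkg=0.0, n=1.0)
        ld = pt.Loading(species=sp, amount=3.6, unit="pM")
        sc = pt.Scenario(
            label="slab", background=bg, loadings=(ld,),
            geometry=pt.Geometry(radius=7.5, height=20.0, n_lateral=8, n_depth=10),
            beam=pt.BeamSpec(power=1.0, beam_radius=5.0),
        )
        mu_a = sc.medium().mu_a_total
        L = sc.geometry.height
        reports = pt.sensitivity_scan(
            sc, parameters=("mu_a_absorber",), grid=(1.0,),  # doubling
            settings=pt.TransportSettings(n_photons=100_000, seed=3),
        )
        rep = reports["mu_a_absorber"]
        expect = 1.0 - np.exp(-2.0 * mu_a * L)
        assert rep.absorbed_fraction[0] == pytest.approx(expect, rel=0.01)

    def test_zero_perturbation_gives_zero_delta(self):
        sc = pt.preset("absorber_only")
        reports = pt.sensitivity_scan(
            sc, parameters=("mu_a_absorber",), grid=(0.0,),
            settings=pt.TransportSettings(n_photons=10_000, seed=2),
        )
        rep = reports["mu_a_absorber"]
        assert rep.absorbed_fraction_delta[0] == 0.0
        assert rep.spatial_delta[0] == 0.0
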