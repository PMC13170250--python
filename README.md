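# phototherm

Monte Carlo photon transport and photothermal heating in nanoparticle-loaded
turbid phantoms.

`phototherm` simulates a two-component photon-management strategy for
near-infrared (NIR) photothermal heating: a **scattering** particle species
(e.g. nanodiamonds, with negligible intrinsic absorption at 808 nm) multiply
scatters and traps incident photons, elevating the local photon density
Φ(r, z), while an **absorbing** species (e.g. plasmonic gold nanostars with a
localized surface-plasmon resonance near 800 nm) converts the enriched flux
into heat. The package is aimed at researchers designing such
scatterer/absorber composites who want to predict enhancement maps,
thermocouple temperature traces and dose-response summaries before running
gel-phantom or cell experiments.

## What it computes

**Composite optics.** Particle loadings declared in number density, pM, v% or
µg/ml are canonicalized and combined with background optics under
independent-scattering additivity:

    µ_a = µ_a,bkg + Σ_i ρ_i σ_abs,i κ_i        µ_s = µ_s,bkg + Σ_i ρ_i σ_sca,i

with the scattering-weighted anisotropy g_eff and an optional near-field
coupling gain κ ≥ 1 on the absorber cross-section when a scatterer is
co-loaded.

**Photon transport.** Photon packets propagate through a cylindrical phantom
with Henyey-Greenstein scattering, exponential weight attenuation (implicit
capture), Russian roulette, and unpolarized Fresnel reflection at all
boundaries. Fluence is tallied with a track-length estimator on an (r, z)
grid, per unit incident power, with batch-based Monte Carlo standard errors
and a per-face energy budget that closes to 10⁻³.

**Enhancement analysis.** The enhancement factor

    E(r, z) = Φ_case(r, z) / Φ_reference(r, z)

is evaluated voxelwise wherever the reference is statistically significant
(floor-σ mask), along with absorption-enhancement maps (µ_a·Φ ratios) and
laterally averaged depth profiles.

**Thermal response.** The absorbed-power map drives an axisymmetric
finite-volume conduction model with convective (Robin) boundaries, reporting
ΔT(t) at virtual thermocouples; a lumped heat balance
ΔT(t) = ΔT_ss(1 − e^(−t/τ)) with ΔT_ss = P_abs/(hA), τ = mc_p/(hA) provides
the analytic fast-conduction limit.

**Summary statistics.** The synergy coefficient
S = ΔT_combined/(ΔT_a + ΔT_b) (S > 1 ⇒ supra-additive heating),
four-parameter-logistic dose-response fits with LD50 and fold-reduction
ratios, power-density conversion, and one-at-a-time parameter sensitivity
scans with common random numbers.

## Worked example

```python
import phototherm as pt

# enhancement of a scatterer-loaded gel over the blank gel
case = pt.preset("scatterer_only",
                 transport=pt.TransportSettings(n_photons=200_000, seed=1))
ref = pt.preset("blank_gel",
                transport=pt.TransportSettings(n_photons=200_000, seed=2))
res = pt.run_compare(case, ref)
print(res["summary"]["fluence_enhancement"]["max_entry_region"])  # 5.08

# synergy coefficient from measured 3-mm, 20-min temperature rises
syn = pt.synergy_coefficient(9.04, 5.38, 2.6)
print(syn.s, syn.synergistic)                    # 1.133 True

# LD50 fold reduction between two formulations
print(pt.ld50_fold_reduction(143.0, 34.0))       # 4.2 (one decimal)

# synthetic dose-response assay and 4PL fit
df = pt.gen_dose_response(ld50=100.0, slope=3.0, noise_sd=0.05,
                          replicates=3, seed=1)
print(pt.fit_dose_response(df).ld50)             # 97.7 mW/cm2
```

The scatterer-only preset composes to µ_a = 0.010 mm⁻¹, µ_s = 3.10 mm⁻¹,
g_eff = 0.029: the isotropic scatterer dominates scattering, and the
enhancement map shows a ~5× build-up of photon density within the first 2 mm
of depth — trapped photons linger near the entry face instead of streaming
through. The synergy coefficient 1.133 > 1 declares the measured combined
rise supra-additive, and 143/34 ≈ 4.2 is the fold by which the combined
formulation lowers the power density needed for 50% cell kill.

A CLI mirrors the pipeline stages:

```bash
phototherm compose --preset combined
phototherm compare --case scatterer_only --reference blank_gel --seed 1 --out out/
phototherm heat --preset combined --duration 1200 --out out/traces.csv
phototherm synergy 9.04 5.38 2.6
phototherm gen-dose --ld50 100 --out dr.csv && phototherm dose-fit --table dr.csv
phototherm sensitivity --preset combined --out out/sens.json
```

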