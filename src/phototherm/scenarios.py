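"""Scenario configuration, presets, pipeline drivers and output writers.

A Scenario bundles everything one simulated experiment needs: background
optics, particle loadings, near-field coupling, phantom geometry, beam,
Monte Carlo settings and thermal properties.  Scenarios load from YAML or
JSON with strict unit-checked validation, and presets mirror the four
canonical cases of a scatterer/absorber co-loading study (blank,
scatterer-only, absorber-only, combined) plus a concentration series.

Units in config files: mm, mm^-1, nm^2, pM / v% / ug_per_ml / per_mm3, W,
degC, s.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    DEFAULT_FLOOR_SIGMA,
    absorption_enhancement_map,
    depth_profile,
    enhancement_map,
)
from .media import (
    BackgroundOptics,
    CompositeOptics,
    CouplingModel,
    Loading,
    MediumError,
    ParticleSpecies,
    compose_medium,
)
from .thermal import ProbeSet, ThermalProps
from .transport import BeamSpec, Geometry, TransportSettings, run_transport

__all__ = [
    "Scenario",
    "ScenarioError",
    "load_scenario",
    "scenario_from_dict",
    "preset",
    "PRESET_NAMES",
    "run_compare",
    "gen_dose_response",
    "load_dose_response",
    "fluence_to_csv",
    "DEFAULT_ABSORBER",
    "DEFAULT_SCATTERER",
    "DEFAULT_BACKGROUND",
]

__version__ = "0.1.0"


class ScenarioError(ValueError):
    """Malformed scenario configuration."""


# --------------------------------------------------------------------------
# illustrative species and background defaults
# --------------------------------------------------------------------------
# Cross sections are illustrative working values for an 808-nm system: the
# absorber is a plasmonic nanostar treated as a pure absorber (sigma_sca = 0)
# whose default loading of 3.6 pM contributes mu_a ~ 0.05 mm^-1; the
# scatterer is a 10-nm diamond particle with negligible absorption whose
# mid-series loading of 3.2e-3 v% contributes mu_s ~ 3 mm^-1 (aggregated
# effective cross section, not a single-particle Rayleigh value).

DEFAULT_ABSORBER = ParticleSpecies(
    name="absorber",
    sigma_abs=2.3e4,
    sigma_sca=0.0,
    g_p=0.0,
    diameter=60.0,
    mass_density=19.3,
)

DEFAULT_SCATTERER = ParticleSpecies(
    name="scatterer",
    sigma_abs=0.0,
    sigma_sca=49.1,
    g_p=0.0,
    diameter=10.0,
    mass_density=3.51,
)

#: agarose-like background (illustrative)
DEFAULT_BACKGROUND = BackgroundOptics(mu_a_bkg=0.01, mu_s_bkg=0.1, g_bkg=0.9, n=1.34)

DEFAULT_GEOMETRY = Geometry(radius=7.5, height=20.0, n_lateral=30, n_depth=40)
DEFAULT_BEAM = BeamSpec(power=0.5, beam_radius=5.0, profile="flat")

#: absorber molar concentration (pM) and scatterer volume-fraction series (v%)
ABSORBER_PM = 3.6
SCATTERER_SERIES_VPC = (3.2e-4, 3.2e-3, 9.6e-3)


@dataclass(frozen=True)
class Scenario:
    """One fully specified simulated experiment."""

    label: str
    background: BackgroundOptics = DEFAULT_BACKGROUND
    loadings: tuple[Loading, ...] = ()
    coupling: CouplingModel = CouplingModel()
    geometry: Geometry = DEFAULT_GEOMETRY
    beam: BeamSpec = DEFAULT_BEAM
    transport: TransportSettings = TransportSettings()
    thermal: ThermalProps = ThermalProps()
    probes: ProbeSet | None = None
    duration: float = 1200.0

    def medium(self) -> CompositeOptics:
        return compose_medium(self.background, list(self.loadings), self.coupling)


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

PRESET_NAMES = (
    "blank_gel",
    "scatterer_only",
    "absorber_only",
    "combined",
    "combined_low",
    "combined_high",
)


def _loading(species: ParticleSpecies, amount: float, unit: str) -> Loading:
    return Loading(species=species, amount=amount, unit=unit)


def preset(name: str, **overrides) -> Scenario:
    """Build a named preset scenario; keyword overrides replace fields.

    The 2x2 design: ``blank_gel``, ``scatterer_only``, ``absorber_only``,
    ``combined``; plus ``combined_low`` / ``combined_high`` for the low and
    high points of the scatterer concentration series.
    """
    if name not in PRESET_NAMES:
        raise ScenarioError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
    absorber = _loading(DEFAULT_ABSORBER, ABSORBER_PM, "pM")
    mid = SCATTERER_SERIES_VPC[1]
    loadings: tuple[Loading, ...]
    if name == "blank_gel":
        loadings = ()
    elif name == "scatterer_only":
        loadings = (_loading(DEFAULT_SCATTERER, mid, "v_percent"),)
    elif name == "absorber_only":
        loadings = (absorber,)
    elif name == "combined":
        loadings = (absorber, _loading(DEFAULT_SCATTERER, mid, "v_percent"))
    elif name == "combined_low":
        loadings = (absorber, _loading(DEFAULT_SCATTERER, SCATTERER_SERIES_VPC[0], "v_percent"))
    else:  # combined_high
        loadings = (absorber, _loading(DEFAULT_SCATTERER, SCATTERER_SERIES_VPC[2], "v_percent"))
    return replace(Scenario(label=name, loadings=loadings), **overrides)


# --------------------------------------------------------------------------
# config loading
# --------------------------------------------------------------------------

_SCHEMA = {
    "label": str,
    "background": dict,
    "species": dict,
    "loadings": list,
    "coupling": dict,
    "geometry": dict,
    "beam": dict,
    "transport": dict,
    "thermal": dict,
    "probes": list,
    "duration": (int, float),
    "preset": str,
}

_SECTION_KEYS = {
    "background": {"mu_a_bkg", "mu_s_bkg", "g_bkg", "n"},
    "coupling": {"kappa", "active", "absorber", "scatterer"},
    "geometry": {"radius", "height", "n_lateral", "n_depth"},
    "beam": {"power", "beam_radius", "profile"},
    "transport": {"n_photons", "seed", "w_min", "p_survive", "n_outside", "n_batches"},
    "thermal": {"k", "rho", "c_p", "h_conv", "t_amb"},
}

_SPECIES_KEYS = {"sigma_abs", "sigma_sca", "g_p", "diameter", "mass_density"}
_LOADING_KEYS = {"species", "amount", "unit"}


def _check_keys(mapping: dict, allowed: set, where: str, strict: bool) -> None:
    unknown = set(mapping) - allowed
    if unknown:
        msg = f"unknown key(s) {sorted(unknown)} in {where}"
        if strict:
            raise ScenarioError(msg)
        warnings.warn(msg, stacklevel=3)


def scenario_from_dict(cfg: dict, strict: bool = True) -> Scenario:
    """Validate a raw config mapping into a Scenario."""
    if not isinstance(cfg, dict):
        raise ScenarioError("scenario config must be a mapping")
    _check_keys(cfg, set(_SCHEMA), "scenario", strict)

    base = preset(cfg["preset"]) if "preset" in cfg else Scenario(label=cfg.get("label", "scenario"))

    try:
        species = {}
        for sp_name, sp_cfg in cfg.get("species", {}).items():
            _check_keys(sp_cfg, _SPECIES_KEYS, f"species {sp_name!r}", strict)
            species[sp_name] = ParticleSpecies(name=sp_name, **sp_cfg)
        # preset species remain available unless redefined
        for ld in base.loadings:
            species.setdefault(ld.species.name, ld.species)
        species.setdefault(DEFAULT_ABSORBER.name, DEFAULT_ABSORBER)
        species.setdefault(DEFAULT_SCATTERER.name, DEFAULT_SCATTERER)

        fields: dict = {}
        if "label" in cfg:
            fields["label"] = cfg["label"]
        if "background" in cfg:
            _check_keys(cfg["background"], _SECTION_KEYS["background"], "background", strict)
            fields["background"] = BackgroundOptics(**cfg["background"])
        if "loadings" in cfg:
            lds = []
            for i, ld_cfg in enumerate(cfg["loadings"]):
                _check_keys(ld_cfg, _LOADING_KEYS, f"loadings[{i}]", strict)
                sp_name = ld_cfg["species"]
                if sp_name not in species:
                    raise ScenarioError(f"loadings[{i}]: unknown species {sp_name!r}")
                lds.append(
                    Loading(species=species[sp_name], amount=ld_cfg["amount"], unit=ld_cfg["unit"])
                )
            fields["loadings"] = tuple(lds)
        if "coupling" in cfg:
            _check_keys(cfg["coupling"], _SECTION_KEYS["coupling"], "coupling", strict)
            fields["coupling"] = CouplingModel(**cfg["coupling"])
        if "geometry" in cfg:
            _check_keys(cfg["geometry"], _SECTION_KEYS["geometry"], "geometry", strict)
            fields["geometry"] = Geometry(**cfg["geometry"])
        if "beam" in cfg:
            _check_keys(cfg["beam"], _SECTION_KEYS["beam"], "beam", strict)
            fields["beam"] = BeamSpec(**cfg["beam"])
        if "transport" in cfg:
            _check_keys(cfg["transport"], _SECTION_KEYS["transport"], "transport", strict)
            fields["transport"] = TransportSettings(**cfg["transport"])
        if "thermal" in cfg:
            _check_keys(cfg["thermal"], _SECTION_KEYS["thermal"], "thermal", strict)
            fields["thermal"] = ThermalProps(**cfg["thermal"])
        if "probes" in cfg:
            fields["probes"] = ProbeSet(tuple((float(r), float(z)) for r, z in cfg["probes"]))
        if "duration" in cfg:
            if cfg["duration"] <= 0:
                raise ScenarioError("duration must be > 0 seconds")
            fields["duration"] = float(cfg["duration"])
    except (TypeError, MediumError, ValueError) as err:
        if isinstance(err, ScenarioError):
            raise
        raise ScenarioError(f"invalid scenario config: {err}") from err

    scenario = replace(base, **fields)
    if scenario.probes is not None:
        scenario.probes.validate(scenario.geometry)
    return scenario


def load_scenario(path: str | Path, strict: bool = True) -> Scenario:
    """Load and validate a scenario from a YAML or JSON file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    return scenario_from_dict(cfg, strict=strict)


# --------------------------------------------------------------------------
# pipeline driver
# --------------------------------------------------------------------------

def fluence_to_csv(fmap, path: str | Path) -> None:
    """Long-format (r, z, value, stderr) CSV export of a fluence/absorption map."""
    geom = fmap.geometry
    value = fmap.phi if hasattr(fmap, "phi") else fmap.a_total
    rr, zz = np.meshgrid(geom.r_centers, geom.z_centers, indexing="ij")
    pd.DataFrame(
        {
            "r_mm": rr.ravel(),
            "z_mm": zz.ravel(),
            "value": value.ravel(),
            "stderr": fmap.stderr.ravel(),
        }
    ).to_csv(path, index=False, float_format="%.8g")


def run_compare(
    case: Scenario,
    reference: Scenario,
    outputs: str | Path | None = None,
    floor_sigma: float = DEFAULT_FLOOR_SIGMA,
    identical_seeds: bool = False,
):
    """Run case and reference transport and compute enhancement maps.

    Returns a dict with the two (FluenceMap, AbsorptionMap) pairs, the
    fluence and absorption EnhancementMaps, depth profiles and a run
    manifest.  When ``outputs`` is given, maps (CSV + NPZ), summaries and
    the manifest (JSON) are written there.

    Case and reference use their own transport seeds by default; pass
    ``identical_seeds=True`` to force the reference onto the case's seed
    (identity checks).  If the two scenarios share a seed otherwise, the
    reference is nudged to an independent stream to avoid correlated-ratio
    bias.
    """
    if case.geometry != reference.geometry:
        raise ScenarioError("case and reference must share the same geometry/grid")

    ref_settings = reference.transport
    if identical_seeds:
        ref_settings = replace(ref_settings, seed=case.transport.seed)
    elif ref_settings.seed == case.transport.seed:
        ref_settings = replace(ref_settings, seed=ref_settings.seed + 7919)

    t0 = time.time()
    case_f, case_a = run_transport(case.medium(), case.geometry, case.beam, case.transport)
    ref_f, ref_a = run_transport(
        reference.medium(), reference.geometry, reference.beam, ref_settings
    )

    emap = enhancement_map(case_f, ref_f, floor_sigma=floor_sigma)
    amap = absorption_enhancement_map(case_a, ref_a, floor_sigma=floor_sigma, beam=case.beam)
    profiles = {
        f"fluence_{case.label}": depth_profile(case_f),
        f"fluence_{reference.label}": depth_profile(ref_f),
        f"absorption_{case.label}": depth_profile(case_a, beam=case.beam),
        f"absorption_{reference.label}": depth_profile(ref_a, beam=reference.beam),
    }

    result = {
        "case": (case_f, case_a),
        "reference": (ref_f, ref_a),
        "enhancement": emap,
        "absorption_enhancement": amap,
        "profiles": profiles,
        "summary": {
            "fluence_enhancement": emap.summary,
            "absorption_enhancement": amap.summary,
            "case_budget": case_f.budget,
            "reference_budget": ref_f.budget,
        },
    }

    manifest = {
        "software_version": __version__,
        "scenarios": [case.label, reference.label],
        "seeds": {case.label: case.transport.seed, reference.label: ref_settings.seed},
        "n_photons": {
            case.label: case.transport.n_photons,
            reference.label: ref_settings.n_photons,
        },
        "wall_clock_s": None,
        "outputs": [],
    }

    if outputs is not None:
        outdir = Path(outputs)
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for tag, fmap in (
            (f"fluence_{case.label}", case_f),
            (f"fluence_{reference.label}", ref_f),
            (f"absorption_{case.label}", case_a),
            (f"absorption_{reference.label}", ref_a),
        ):
            p = outdir / f"{tag}.csv"
            fluence_to_csv(fmap, p)
            written.append(p.name)
        np.savez(
            outdir / "maps.npz",
            enhancement=emap.e,
            enhancement_stderr=emap.stderr,
            valid_mask=emap.valid_mask,
            absorption_enhancement=amap.e,
            case_phi=case_f.phi,
            reference_phi=ref_f.phi,
        )
        written.append("maps.npz")
        for name, prof in profiles.items():
            p = outdir / f"profile_{name}.csv"
            pd.DataFrame({"z_mm": prof.z, "value": prof.value, "stderr": prof.stderr}).to_csv(
                p, index=False, float_format="%.8g"
            )
            written.append(p.name)
        with open(outdir / "summary.json", "w") as fh:
            json.dump(result["summary"], fh, indent=2, default=float)
        written.append("summary.json")
        manifest["outputs"] = written
        manifest["wall_clock_s"] = round(time.time() - t0, 3)
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)

    result["manifest"] = manifest
    return result


# --------------------------------------------------------------------------
# synthetic dose-response fixture generator
# --------------------------------------------------------------------------

#: the canonical six-point power-density grid (mW cm^-2) of the ablation assay
DOSE_GRID = (0.0, 20.4, 61.2, 102.0, 142.9, 183.7)


def gen_dose_response(
    ld50: float,
    slope: float = 3.0,
    upper: float = 1.0,
    lower: float = 0.0,
    doses=DOSE_GRID,
    replicates: int = 3,
    noise_sd: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic viability table from a 4PL curve with gaussian noise.

    Emulates a plate-reader viability assay on a power-density grid: each
    replicate draws i.i.d. gaussian noise (sd ``noise_sd``) around the exact
    logistic value, clipped into [0, 1].  ``noise_sd = 0`` returns the exact
    curve; a fixed seed reproduces the table bit for bit.
    """
    from .stats import four_param_logistic

    if ld50 <= 0:
        raise ScenarioError("ld50 must be > 0")
    if noise_sd < 0:
        raise ScenarioError("noise_sd must be >= 0")
    if replicates < 1:
        raise ScenarioError("need at least one replicate")
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ScenarioError("doses must be >= 0")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        v = four_param_logistic(doses, ld50, slope, upper, lower)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        v = np.clip(v, 0.0, 1.0)
        rows.append(pd.DataFrame({"dose": doses, "viability": v, "replicate": rep}))
    return pd.concat(rows, ignore_index=True)


def load_dose_response(path: str | Path) -> pd.DataFrame:
    """Read and range-check a dose-response CSV (dose, viability[, replicate])."""
    df = pd.read_csv(path)
    if not {"dose", "viability"}.issubset(df.columns):
        raise ScenarioError("dose-response CSV needs 'dose' and 'viability' columns")
    if (df["dose"] < 0).any():
        raise ScenarioError("doses must be >= 0")
    if ((df["viability"] < 0) | (df["viability"] > 1)).any():
        raise ScenarioError("viability values must lie in [0, 1]")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df
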