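"""Summary statistics: synergy coefficient, dose-response LD50, dose
conversions, and one-at-a-time parameter sensitivity.

The synergy coefficient compares the temperature rise of a combined
scatterer + absorber system against the sum of the single-component rises:

    S = dT_combined / (dT_a + dT_b),

with S > 1 declaring supra-additive (synergistic) heating.

Cell-kill dose-response curves are fit with a four-parameter logistic (4PL)
in the incident power density d:

    v(d) = lower + (upper - lower) / (1 + (d / ld50)^slope),

whose ld50 parameter is the dose at viability midway between the asymptotes.
The upper asymptote is left free (untreated controls can plateau well above
50% viability over the tested range, making their LD50 an extrapolation)
while the lower asymptote is bounded at 0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .media import compose_medium
from .transport import TransportSettings, run_transport

__all__ = [
    "SynergyResult",
    "LogisticFit",
    "SensitivityReport",
    "StatsError",
    "synergy_coefficient",
    "fit_dose_response",
    "ld50_fold_reduction",
    "power_density",
    "sensitivity_scan",
]


class StatsError(ValueError):
    """Invalid input to a summary statistic."""


# --------------------------------------------------------------------------
# synergy coefficient
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SynergyResult:
    s: float
    dT_combined: float
    dT_a: float
    dT_b: float

    @property
    def synergistic(self) -> bool:
        return self.s > 1.0


def synergy_coefficient(dT_combined: float, dT_a: float, dT_b: float) -> SynergyResult:
    """S = dT_combined / (dT_a + dT_b); synergistic iff S > 1 (strict)."""
    denom = dT_a + dT_b
    if denom <= 0:
        raise StatsError(
            "synergy coefficient undefined: the single-component temperature "
            f"rises sum to {denom} degC (must be > 0)"
        )
    return SynergyResult(
        s=dT_combined / denom, dT_combined=dT_combined, dT_a=dT_a, dT_b=dT_b
    )


# --------------------------------------------------------------------------
# dose-response fitting
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """4PL fit result; ld50 in the dose units of the input table."""

    ld50: float
    slope: float
    upper: float
    lower: float
    covariance: np.ndarray
    increasing_warning: bool = False

    @property
    def ld50_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))


def four_param_logistic(dose, ld50, slope, upper, lower):
    """Decreasing 4PL: upper at dose 0, lower at high dose (slope > 0)."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(dose > 0, (dose / ld50) ** slope, 0.0)
    return lower + (upper - lower) / (1.0 + ratio)


def fit_dose_response(data: pd.DataFrame) -> LogisticFit:
    """Least-squares 4PL fit of viability against dose.

    ``data`` needs columns ``dose`` (power density, mW cm^-2) and
    ``viability`` (fraction in [0, 1]); replicate rows are fit jointly.
    A monotone-increasing dose-viability trend is fit anyway but flagged.
    """
    if not {"dose", "viability"}.issubset(data.columns):
        raise StatsError("dose-response table needs 'dose' and 'viability' columns")
    dose = data["dose"].to_numpy(dtype=float)
    viab = data["viability"].to_numpy(dtype=float)
    if np.any(dose < 0):
        raise StatsError("doses must be >= 0")
    if np.any((viab < 0) | (viab > 1)):
        raise StatsError("viability must lie in [0, 1]")
    if np.unique(dose).size < 4:
        raise StatsError("need at least 4 distinct doses for a 4PL fit")

    # warn on an overall increasing trend (dose means)
    means = pd.DataFrame({"dose": dose, "v": viab}).groupby("dose")["v"].mean()
    increasing = bool(means.iloc[-1] > means.iloc[0])

    d_pos = dose[dose > 0]
    p0 = [float(np.median(d_pos)) if d_pos.size else 1.0, 2.0,
          float(means.iloc[0]), float(max(means.min(), 0.0))]
    bounds = ([1e-6, 0.05, 0.0, 0.0], [np.inf, 50.0, 1.5, 1.0])
    try:
        popt, pcov = curve_fit(
            four_param_logistic, dose, viab, p0=p0, bounds=bounds, maxfev=20000
        )
    except RuntimeError as err:  # non-convergence
        raise StatsError(f"dose-response fit did not converge: {err}") from err
    ld50, slope, upper, lower = popt
    if lower > upper:
        warnings.warn("4PL fit returned lower asymptote above upper", stacklevel=2)
    if increasing:
        warnings.warn(
            "viability increases with dose; fit returned with warning flag",
            stacklevel=2,
        )
    return LogisticFit(
        ld50=float(ld50),
        slope=float(slope),
        upper=float(upper),
        lower=float(lower),
        covariance=pcov,
        increasing_warning=increasing,
    )


def ld50_fold_reduction(fit_ref, fit_new) -> float:
    """LD50_ref / LD50_new: how many-fold the required dose drops.

    Accepts LogisticFit objects or bare LD50 scalars.
    """
    ld_ref = fit_ref.ld50 if isinstance(fit_ref, LogisticFit) else float(fit_ref)
    ld_new = fit_new.ld50 if isinstance(fit_new, LogisticFit) else float(fit_new)
    if ld_ref <= 0 or ld_new <= 0:
        raise StatsError("LD50 values must be > 0")
    return ld_ref / ld_new


def power_density(power_mw: float, beam_diameter_cm: float, paper_rounding: bool = False) -> float:
    """Incident power density mW cm^-2 for a given total power and beam diameter.

    With ``paper_rounding`` the beam area is first rounded to one decimal
    (cm^2), a presentation convention that reproduces some printed dose
    tables exactly; the default uses the exact area.
    """
    if beam_diameter_cm <= 0:
        raise StatsError("beam diameter must be > 0")
    area = math.pi * (beam_diameter_cm / 2.0) ** 2
    if paper_rounding:
        area = round(area, 1)
    return power_mw / area


# --------------------------------------------------------------------------
# sensitivity analysis
# --------------------------------------------------------------------------

#: parameters the one-at-a-time scan understands
SENSITIVITY_PARAMETERS = (
    "mu_a_bkg",
    "mu_s_bkg",
    "g_bkg",
    "n",
    "mu_a_absorber",
    "mu_s_scatterer",
)


@dataclass
class SensitivityReport:
    """One-at-a-time sensitivity of transport outputs to one parameter.

    ``index_absorbed`` and ``index_spatial`` are normalized log-derivative
    indices d log(output) / d log(parameter), estimated by least squares
    over the perturbation grid.  ``spatial_delta`` is the normalized L1
    distance between the perturbed and base fluence maps.
    """

    parameter: str
    perturbations: np.ndarray
    absorbed_fraction: np.ndarray
    absorbed_fraction_delta: np.ndarray
    spatial_delta: np.ndarray
    index_absorbed: float
    index_spatial: float
    skipped: list


def _perturbed_scenario(scenario, parameter: str, rel: float):
    """Return a copy of the scenario with one parameter scaled by (1 + rel)."""
    factor = 1.0 + rel
    bg = scenario.background
    loadings = list(scenario.loadings)
    if parameter == "mu_a_bkg":
        bg = replace(bg, mu_a_bkg=bg.mu_a_bkg * factor)
    elif parameter == "mu_s_bkg":
        bg = replace(bg, mu_s_bkg=bg.mu_s_bkg * factor)
    elif parameter == "g_bkg":
        g_new = bg.g_bkg * factor
        if not -1.0 < g_new < 1.0:
            return None
        bg = replace(bg, g_bkg=g_new)
    elif parameter == "n":
        n_new = bg.n * factor
        if n_new < 1.0:
            return None
        bg = replace(bg, n=n_new)
    elif parameter in ("mu_a_absorber", "mu_s_scatterer"):
        role = "absorber" if parameter == "mu_a_absorber" else "scatterer"
        found = False
        for i, ld in enumerate(loadings):
            if ld.species.name == role:
                sp = ld.species
                if role == "absorber":
                    sp = replace(sp, sigma_abs=sp.sigma_abs * factor)
                else:
                    sp = replace(sp, sigma_sca=sp.sigma_sca * factor)
                new_ld = type(ld)(species=sp, amount=ld.amount, unit=ld.unit)
                loadings[i] = new_ld
                found = True
        if not found:
            return None
    else:
        raise StatsError(
            f"unknown sensitivity parameter {parameter!r}; "
            f"expected one of {SENSITIVITY_PARAMETERS}"
        )
    return replace(scenario, background=bg, loadings=tuple(loadings))


def sensitivity_scan(
    base_scenario,
    parameters=SENSITIVITY_PARAMETERS,
    grid=(-0.2, -0.1, 0.1, 0.2),
    settings: TransportSettings | None = None,
) -> dict[str, SensitivityReport]:
    """One-at-a-time relative perturbation scan with common random numbers.

    For each parameter, the base scenario is re-run with the parameter
    scaled by (1 + delta) for every delta in ``grid`` using the same seed
    (common random numbers), and the change in absorbed fraction and in the
    spatial fluence pattern is recorded.  Perturbations that push g outside
    (-1, 1) or n below 1, or that target an absent species, are skipped with
    a warning.
    """
    if settings is None:
        settings = base_scenario.transport
    grid = np.asarray(grid, dtype=float)

    base_med = compose_medium(
        base_scenario.background, list(base_scenario.loadings), base_scenario.coupling
    )
    base_f, base_a = run_transport(
        base_med, base_scenario.geometry, base_scenario.beam, settings
    )
    base_phi_l1 = float(np.abs(base_f.phi).sum())

    reports: dict[str, SensitivityReport] = {}
    for param in parameters:
        absorbed = []
        spatial = []
        used = []
        skipped = []
        for rel in grid:
            if rel == 0.0:
                absorbed.append(base_a.absorbed_fraction)
                spatial.append(0.0)
                used.append(rel)
                continue
            pert = _perturbed_scenario(base_scenario, param, float(rel))
            if pert is None:
                warnings.warn(
                    f"skipping {param} perturbation {rel:+.0%}: unphysical or "
                    "species not present",
                    stacklevel=2,
                )
                skipped.append(float(rel))
                continue
            med = compose_medium(pert.background, list(pert.loadings), pert.coupling)
            fmap, amap = run_transport(med, pert.geometry, pert.beam, settings)
            absorbed.append(amap.absorbed_fraction)
            spatial.append(float(np.abs(fmap.phi - base_f.phi).sum()) / base_phi_l1)
            used.append(float(rel))

        used_arr = np.asarray(used)
        absorbed_arr = np.asarray(absorbed)
        spatial_arr = np.asarray(spatial)
        delta_arr = absorbed_arr - base_a.absorbed_fraction

        index_abs = _log_slope(used_arr, absorbed_arr, base_a.absorbed_fraction)
        index_spat = _abs_slope(used_arr, spatial_arr)
        reports[param] = SensitivityReport(
            parameter=param,
            perturbations=used_arr,
            absorbed_fraction=absorbed_arr,
            absorbed_fraction_delta=delta_arr,
            spatial_delta=spatial_arr,
            index_absorbed=index_abs,
            index_spatial=index_spat,
            skipped=skipped,
        )
    return reports


def _log_slope(rel, out, base) -> float:
    """d log(output) / d log(parameter) by least squares over the grid."""
    if rel.size == 0 or base <= 0:
        return 0.0
    mask = out > 0
    if mask.sum() < 1:
        return 0.0
    x = np.log1p(rel[mask])
    y = np.log(out[mask] / base)
    denom = float(np.sum(x * x))
    if denom == 0.0:
        return 0.0
    return float(np.sum(x * y) / denom)


def _abs_slope(rel, delta) -> float:
    """|spatial delta| per unit relative perturbation (L1 metric slope)."""
    if rel.size == 0:
        return 0.0
    x = np.abs(rel)
    denom = float(np.sum(x * x))
    if denom == 0.0:
        return 0.0
    return float(np.sum(x * np.abs(delta)) / denom)
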