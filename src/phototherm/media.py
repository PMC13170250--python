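"""Composite-medium optics: particle loadings to bulk coefficients.

A dilute suspension of nanoparticles in a turbid background medium is
described by independent-scattering additivity: each species contributes
``rho * sigma`` to the bulk absorption and scattering coefficients, where
``rho`` is its number density and ``sigma`` its single-particle cross
section.  Loadings may be declared in any one of four representations
(number density, molar concentration, volume fraction, mass concentration);
all are canonicalized to number density in mm^-3.

Unit conventions (fixed throughout the package):

* cross sections       nm^2
* number densities     mm^-3
* optical coefficients mm^-1
* particle diameter    nm
* mass density         g cm^-3
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

AVOGADRO = 6.02214076e23  # mol^-1

_NM2_TO_MM2 = 1e-12
# unit factors used by the canonical conversion routine
_PM_TO_MOL_PER_MM3 = 1e-12 / 1e6       # pM -> mol/mm^3
_UG_PER_ML_TO_G_PER_MM3 = 1e-6 / 1e3   # µg/ml -> g/mm^3
_NM3_TO_MM3 = 1e-18  # (1 nm = 1e-6 mm)^3
_NM3_TO_CM3 = 1e-21  # (1 nm = 1e-7 cm)^3


class MediumError(ValueError):
    """Invalid species, loading or background specification."""


@dataclass(frozen=True)
class ParticleSpecies:
    """Optical and physical properties of one particle species.

    Parameters
    ----------
    name : str
        Label, e.g. ``"absorber"`` or ``"scatterer"``.
    sigma_abs : float
        Absorption cross section at the working wavelength, nm^2.
    sigma_sca : float
        Scattering cross section, nm^2.
    g_p : float
        Single-particle scattering anisotropy (mean cosine), in [-1, 1].
    diameter : float
        Particle diameter, nm (spherical equivalent).
    mass_density : float
        Bulk material density, g cm^-3.
    """

    name: str
    sigma_abs: float
    sigma_sca: float
    g_p: float = 0.0
    diameter: float = 10.0
    mass_density: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_abs < 0 or self.sigma_sca < 0:
            raise MediumError(f"{self.name}: cross sections must be >= 0")
        if not -1.0 <= self.g_p <= 1.0:
            raise MediumError(f"{self.name}: anisotropy g_p must lie in [-1, 1]")
        if self.diameter <= 0:
            raise MediumError(f"{self.name}: diameter must be > 0")
        if self.mass_density <= 0:
            raise MediumError(f"{self.name}: mass density must be > 0")

    @property
    def volume_nm3(self) -> float:
        """Spherical particle volume, nm^3."""
        return math.pi / 6.0 * self.diameter**3

    @property
    def particle_mass_g(self) -> float:
        """Mass of one particle, g."""
        return self.mass_density * self.volume_nm3 * _NM3_TO_CM3


#: loading representations accepted by :func:`convert_loading`
LOADING_UNITS = ("per_mm3", "pM", "v_percent", "ug_per_ml")


@dataclass
class Loading:
    """One species loading, declared in exactly one representation."""

    species: ParticleSpecies
    amount: float
    unit: str
    canonical_density: float = field(init=False, default=0.0)

    def __post_init__(self) -> None:
        if self.unit not in LOADING_UNITS:
            raise MediumError(
                f"unknown loading unit {self.unit!r}; expected one of {LOADING_UNITS}"
            )
        if self.amount < 0:
            raise MediumError("loading amount must be >= 0")
        self.canonical_density = convert_loading(self)


def convert_loading(loading: Loading, species: ParticleSpecies | None = None) -> float:
    """Canonicalize a loading to number density in mm^-3.

    Conversions:

    * ``pM``        : c [pM] -> mol/mm^3 -> * N_A
    * ``v_percent`` : volume fraction / particle volume
    * ``ug_per_ml`` : mass concentration / particle mass
    """
    sp = species if species is not None else loading.species
    amount = loading.amount
    if amount < 0:
        raise MediumError("loading amount must be >= 0")
    if amount == 0:
        return 0.0
    unit = loading.unit
    if unit == "per_mm3":
        return amount
    if unit == "pM":
        return amount * _PM_TO_MOL_PER_MM3 * AVOGADRO
    if unit == "v_percent":
        vol_fraction = amount / 100.0
        vp_mm3 = sp.volume_nm3 * _NM3_TO_MM3
        if vp_mm3 <= 0:
            raise MediumError("volume-fraction loading needs a positive particle diameter")
        return vol_fraction / vp_mm3
    if unit == "ug_per_ml":
        mass_g_per_mm3 = amount * _UG_PER_ML_TO_G_PER_MM3
        return mass_g_per_mm3 / sp.particle_mass_g
    raise MediumError(f"unknown loading unit {unit!r}")


def loading_as(density_per_mm3: float, species: ParticleSpecies, unit: str) -> float:
    """Express a canonical number density in another representation (inverse
    of :func:`convert_loading`); used for round-trip checks and reporting."""
    if unit == "per_mm3":
        return density_per_mm3
    if unit == "pM":
        return density_per_mm3 / (_PM_TO_MOL_PER_MM3 * AVOGADRO)
    if unit == "v_percent":
        return density_per_mm3 * species.volume_nm3 * _NM3_TO_MM3 * 100.0
    if unit == "ug_per_ml":
        return density_per_mm3 * species.particle_mass_g / _UG_PER_ML_TO_G_PER_MM3
    raise MediumError(f"unknown loading unit {unit!r}")


@dataclass(frozen=True)
class BackgroundOptics:
    """Bulk optical properties of the unloaded host medium."""

    mu_a_bkg: float  # mm^-1
    mu_s_bkg: float  # mm^-1
    g_bkg: float
    n: float

    def __post_init__(self) -> None:
        if self.mu_a_bkg < 0 or self.mu_s_bkg < 0:
            raise MediumError("background coefficients must be >= 0")
        if not -1.0 <= self.g_bkg <= 1.0:
            raise MediumError("background anisotropy must lie in [-1, 1]")
        if self.n < 1.0:
            raise MediumError("refractive index must be >= 1")


@dataclass(frozen=True)
class CouplingModel:
    """Scalar near-field coupling gain on absorber cross sections.

    When a designated scatterer species is co-loaded with a designated
    absorber species, nanoscale proximity can raise the absorber's effective
    absorption cross section.  That electrodynamic effect is folded into a
    single multiplicative gain ``kappa >= 1`` applied to sigma_abs of the
    absorber; it is inert (kappa treated as 1) when the scatterer loading is
    zero or the model is inactive.
    """

    kappa: float = 1.0
    active: bool = False
    absorber: str = "absorber"
    scatterer: str = "scatterer"

    def __post_init__(self) -> None:
        if self.kappa < 1.0:
            raise MediumError("coupling gain kappa must be >= 1")

    def gain_for(self, species_name: str, scatterer_density: float) -> float:
        if (
            self.active
            and species_name == self.absorber
            and scatterer_density > 0.0
        ):
            return self.kappa
        return 1.0


@dataclass(frozen=True)
class CompositeOptics:
    """Effective bulk optics of the loaded medium."""

    mu_a_total: float
    mu_s_total: float
    g_eff: float
    n: float
    mu_a_by_species: tuple[tuple[str, float], ...] = ()
    mu_s_by_species: tuple[tuple[str, float], ...] = ()


NO_COUPLING = CouplingModel()


def compose_medium(
    background: BackgroundOptics,
    loadings: list[Loading] | tuple[Loading, ...] = (),
    coupling: CouplingModel = NO_COUPLING,
) -> CompositeOptics:
    """Combine background optics with particle loadings.

    Independent-scattering additivity (valid for dilute loadings,
    volume fractions <~ 1e-2):

    * ``mu_a = mu_a_bkg + sum_i rho_i * sigma_abs_i * kappa_i``
    * ``mu_s = mu_s_bkg + sum_i rho_i * sigma_sca_i``
    * ``g_eff`` is the scattering-weighted mean anisotropy, 0 if mu_s = 0.
    """
    for ld in loadings:
        if not -1.0 <= ld.species.g_p <= 1.0:
            raise MediumError(f"{ld.species.name}: anisotropy outside [-1, 1]")

    scat_density = sum(
        ld.canonical_density
        for ld in loadings
        if ld.species.name == coupling.scatterer
    )

    mu_a = background.mu_a_bkg
    mu_s = background.mu_s_bkg
    g_weighted = background.mu_s_bkg * background.g_bkg
    mu_a_by: list[tuple[str, float]] = []
    mu_s_by: list[tuple[str, float]] = []
    for ld in loadings:
        sp = ld.species
        kappa = coupling.gain_for(sp.name, scat_density)
        mu_a_i = ld.canonical_density * sp.sigma_abs * _NM2_TO_MM2 * kappa
        mu_s_i = ld.canonical_density * sp.sigma_sca * _NM2_TO_MM2
        mu_a += mu_a_i
        mu_s += mu_s_i
        g_weighted += mu_s_i * sp.g_p
        mu_a_by.append((sp.name, mu_a_i))
        mu_s_by.append((sp.name, mu_s_i))

    g_eff = g_weighted / mu_s if mu_s > 0 else 0.0
    return CompositeOptics(
        mu_a_total=mu_a,
        mu_s_total=mu_s,
        g_eff=g_eff,
        n=background.n,
        mu_a_by_species=tuple(mu_a_by),
        mu_s_by_species=tuple(mu_s_by),
    )
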