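"""Monte Carlo photon-packet transport in a turbid cylinder.

Photon packets are launched normally onto the top face of a cylindrical
phantom and propagated with implicit capture: packet weight decays
exponentially along the track at the local absorption coefficient while
scattering events are sampled from the local scattering coefficient and the
Henyey-Greenstein phase function.  Fluence is tallied with a track-length
estimator on a cylindrical (r, z) grid; the absorbed power density is then
exactly ``mu_a * phi`` voxel by voxel, so the energy budget closes by
construction up to Russian-roulette noise.

All boundaries (top, bottom, side) receive the same unpolarized Fresnel
treatment against the ambient index; escaped weight is tallied per face.
Specular reflection of the incident beam at the mismatched top interface is
applied before injection.

Fluence is reported per unit incident power, units mm^-2 (the classic
track-length normalization: summed weighted pathlength per voxel volume per
launched packet).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .media import CompositeOptics

__all__ = [
    "Geometry",
    "BeamSpec",
    "TransportSettings",
    "FluenceMap",
    "AbsorptionMap",
    "VoxelMedium",
    "TransportError",
    "sample_phase_function",
    "fresnel_reflectance",
    "run_transport",
]


class TransportError(ValueError):
    """Invalid transport configuration."""


# --------------------------------------------------------------------------
# geometry / beam / settings
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Geometry:
    """Cylindrical phantom with a uniform (r, z) tally grid.

    z = 0 is the illuminated face; depth increases downward.  Voxels are
    half-open rings [r_i, r_{i+1}) x [z_j, z_{j+1}).
    """

    radius: float  # mm
    height: float  # mm
    n_lateral: int = 30
    n_depth: int = 40

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.height <= 0:
            raise TransportError("radius and height must be > 0")
        if self.n_lateral < 2 or self.n_depth < 2:
            raise TransportError("grid must have at least 2 voxels per axis")

    @property
    def dr(self) -> float:
        return self.radius / self.n_lateral

    @property
    def dz(self) -> float:
        return self.height / self.n_depth

    @property
    def r_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.radius, self.n_lateral + 1)

    @property
    def z_edges(self) -> np.ndarray:
        return np.linspace(0.0, self.height, self.n_depth + 1)

    @property
    def r_centers(self) -> np.ndarray:
        e = self.r_edges
        return 0.5 * (e[:-1] + e[1:])

    @property
    def z_centers(self) -> np.ndarray:
        e = self.z_edges
        return 0.5 * (e[:-1] + e[1:])

    def voxel_volumes(self) -> np.ndarray:
        """Ring volumes, mm^3, shape (n_lateral, n_depth)."""
        e = self.r_edges
        ring = math.pi * (e[1:] ** 2 - e[:-1] ** 2)
        return np.repeat(ring[:, None], self.n_depth, axis=1) * self.dz


@dataclass(frozen=True)
class BeamSpec:
    """Normally incident, axially centered beam at z = 0."""

    power: float  # W
    beam_radius: float  # mm; 1/e^2 radius for the gaussian profile
    profile: str = "flat"

    def __post_init__(self) -> None:
        if self.power < 0:
            raise TransportError("beam power must be >= 0")
        if self.beam_radius <= 0:
            raise TransportError("beam radius must be > 0")
        if self.profile not in ("flat", "gaussian"):
            raise TransportError("profile must be 'flat' or 'gaussian'")


@dataclass(frozen=True)
class TransportSettings:
    """Monte Carlo run controls.

    w_min / p_survive are the Russian-roulette threshold and survival
    probability; n_batches controls the batch estimate of the per-voxel
    standard error.
    """

    n_photons: int = 100_000
    seed: int = 0
    w_min: float = 1e-4
    p_survive: float = 0.1
    n_outside: float = 1.0
    n_batches: int = 16

    def __post_init__(self) -> None:
        if self.n_photons < 1_000:
            raise TransportError("n_photons must be >= 1000")
        if not 0.0 < self.w_min < 1.0:
            raise TransportError("w_min must be in (0, 1)")
        if not 0.0 < self.p_survive < 1.0:
            raise TransportError("p_survive must be in (0, 1)")
        if self.n_outside < 1.0:
            raise TransportError("ambient index must be >= 1")
        if self.n_batches < 2:
            raise TransportError("need >= 2 batches for error estimates")


@dataclass(frozen=True)
class VoxelMedium:
    """Voxelized optical properties on the tally grid (shape (nr, nz))."""

    mu_a: np.ndarray
    mu_s: np.ndarray
    g: np.ndarray
    n: float


# --------------------------------------------------------------------------
# result containers
# --------------------------------------------------------------------------

@dataclass
class FluenceMap:
    """Normalized fluence tally with Monte Carlo errors and energy budget."""

    phi: np.ndarray          # (nr, nz), mm^-2 per incident W
    stderr: np.ndarray       # per-voxel standard error, same units
    budget: dict             # reflected / transmitted / absorbed / side_escaped
    mean_pathlength: float   # mm, geometric path per launched packet
    mean_scatter_events: float
    geometry: Geometry
    beam: BeamSpec
    n_photons: int
    seed: int


@dataclass
class AbsorptionMap:
    """Deposited power density ``mu_a * phi`` per incident W (mm^-3)."""

    a_total: np.ndarray
    stderr: np.ndarray
    a_by_species: dict
    absorbed_fraction: float
    geometry: Geometry


# --------------------------------------------------------------------------
# elementary samplers (numba kernels, callable from python)
# --------------------------------------------------------------------------

@njit(cache=True)
def _hg_cosine(g: float, u: float) -> float:
    if abs(g) < 1e-8:
        return 2.0 * u - 1.0
    tmp = (1.0 - g * g) / (1.0 - g + 2.0 * g * u)
    c = (1.0 + g * g - tmp * tmp) / (2.0 * g)
    if c > 1.0:
        c = 1.0
    elif c < -1.0:
        c = -1.0
    return c


def sample_phase_function(g: float, u: float) -> float:
    """Cosine of the Henyey-Greenstein deflection angle for uniform u in [0,1).

    g = 0 is handled as isotropic scattering; |g| >= 1 is rejected.
    """
    if abs(g) >= 1.0:
        raise TransportError("anisotropy must satisfy |g| < 1")
    if not 0.0 <= u <= 1.0:
        raise TransportError("u must be a uniform variate in [0, 1]")
    return _hg_cosine(g, u)


@njit(cache=True)
def _fresnel(n1: float, n2: float, cos_i: float) -> float:
    if n1 == n2:
        return 0.0
    sin_t2 = (n1 / n2) ** 2 * (1.0 - cos_i * cos_i)
    if sin_t2 >= 1.0:
        return 1.0  # total internal reflection
    cos_t = math.sqrt(1.0 - sin_t2)
    rs = (n1 * cos_i - n2 * cos_t) / (n1 * cos_i + n2 * cos_t)
    rp = (n1 * cos_t - n2 * cos_i) / (n1 * cos_t + n2 * cos_i)
    return 0.5 * (rs * rs + rp * rp)


def fresnel_reflectance(n1: float, n2: float, cos_incident: float) -> float:
    """Unpolarized Fresnel reflectance from medium n1 into n2."""
    if n1 < 1.0 or n2 < 1.0:
        raise TransportError("refractive indices must be >= 1")
    if not 0.0 < cos_incident <= 1.0:
        raise TransportError("cos_incident must lie in (0, 1]")
    return _fresnel(n1, n2, cos_incident)


# --------------------------------------------------------------------------
# the transport kernel
# --------------------------------------------------------------------------

_ESC_TOP = 0
_ESC_BOTTOM = 1
_ESC_SIDE = 2


@njit(cache=True)
def _mc_kernel(
    mu_a_map, mu_s_map, g_map,
    n_med, n_out,
    radius, height, nr, nz,
    beam_radius, gaussian_profile,
    n_photons, seed, w_min, p_survive, n_batches, substep,
):
    np.random.seed(seed)
    dr = radius / nr
    dz = height / nz

    phi_b = np.zeros((n_batches, nr, nz))
    batch_counts = np.zeros(n_batches, dtype=np.int64)
    esc = np.zeros(3)
    dep_total = 0.0
    path_total = 0.0
    scat_total = 0.0
    eps = 1e-9

    # specular reflection of the collimated beam at the top interface
    r_sp = ((n_out - n_med) / (n_out + n_med)) ** 2

    for ip in range(n_photons):
        batch = ip * n_batches // n_photons
        batch_counts[batch] += 1

        # launch position on the top face
        u = np.random.random()
        if gaussian_profile:
            r0 = beam_radius * math.sqrt(-math.log(1.0 - u) / 2.0)
        else:
            r0 = beam_radius * math.sqrt(u)
        if r0 >= radius:
            esc[_ESC_SIDE] += 1.0  # beam tail misses the phantom
            continue
        ang = 2.0 * math.pi * np.random.random()
        x = r0 * math.cos(ang)
        y = r0 * math.sin(ang)
        z = eps
        ux = 0.0
        uy = 0.0
        uz = 1.0

        w = 1.0 - r_sp
        esc[_ESC_TOP] += r_sp

        tau = -math.log(np.random.random() + 1e-300)
        alive = True
        while alive:
            r2 = x * x + y * y
            # local optics from the current voxel
            ir = int(math.sqrt(r2) / dr)
            if ir >= nr:
                ir = nr - 1
            iz = int(z / dz)
            if iz >= nz:
                iz = nz - 1
            mu_a = mu_a_map[ir, iz]
            mu_s = mu_s_map[ir, iz]
            g_loc = g_map[ir, iz]

            # candidate segment: substep, interaction, or boundary
            step = substep
            interact = False
            if mu_s > 0.0:
                d_int = tau / mu_s
                if d_int <= step:
                    step = d_int
                    interact = True

            boundary = False
            face = -1
            # distance to top/bottom planes
            if uz > 0.0:
                d_plane = (height - z) / uz
                pface = _ESC_BOTTOM
            elif uz < 0.0:
                d_plane = -z / uz
                pface = _ESC_TOP
            else:
                d_plane = 1e30
                pface = -1
            # distance to the cylindrical side
            a_q = ux * ux + uy * uy
            if a_q > 0.0:
                b_q = x * ux + y * uy
                c_q = r2 - radius * radius
                disc = b_q * b_q - a_q * c_q
                if disc > 0.0:
                    d_side = (-b_q + math.sqrt(disc)) / a_q
                else:
                    d_side = 1e30
            else:
                d_side = 1e30
            if d_plane <= d_side:
                d_bnd = d_plane
                bface = pface
            else:
                d_bnd = d_side
                bface = _ESC_SIDE
            if d_bnd <= step:
                step = d_bnd
                boundary = True
                face = bface
                interact = False

            # tally the segment (exact exponential attenuation integral)
            mx = x + 0.5 * step * ux
            my = y + 0.5 * step * uy
            mz = z + 0.5 * step * uz
            tir = int(math.sqrt(mx * mx + my * my) / dr)
            if tir >= nr:
                tir = nr - 1
            tiz = int(mz / dz)
            if tiz < 0:
                tiz = 0
            elif tiz >= nz:
                tiz = nz - 1
            if mu_a > 0.0:
                att = math.exp(-mu_a * step)
                contrib = w * (1.0 - att) / mu_a
                dep_total += mu_a * contrib
                w *= att
            else:
                contrib = w * step
            phi_b[batch, tir, tiz] += contrib
            path_total += step
            tau -= mu_s * step

            x += step * ux
            y += step * uy
            z += step * uz

            if boundary:
                # Fresnel decision against the ambient medium
                if face == _ESC_SIDE:
                    rad = math.sqrt(x * x + y * y)
                    nx = x / rad
                    ny = y / rad
                    cos_i = ux * nx + uy * ny
                    if cos_i < 0.0:
                        cos_i = -cos_i
                    refl = _fresnel(n_med, n_out, cos_i)
                    if np.random.random() < refl:
                        dot = ux * nx + uy * ny
                        ux -= 2.0 * dot * nx
                        uy -= 2.0 * dot * ny
                        # nudge back inside
                        scale = (radius - eps) / rad
                        x *= scale
                        y *= scale
                    else:
                        esc[_ESC_SIDE] += w
                        alive = False
                else:
                    cos_i = uz if uz > 0.0 else -uz
                    refl = _fresnel(n_med, n_out, cos_i)
                    if np.random.random() < refl:
                        uz = -uz
                        if face == _ESC_BOTTOM:
                            z = height - eps
                        else:
                            z = eps
                    else:
                        esc[face] += w
                        alive = False
            elif interact:
                scat_total += 1.0
                cos_t = _hg_cosine(g_loc, np.random.random())
                sin_t = math.sqrt(max(0.0, 1.0 - cos_t * cos_t))
                phi_ang = 2.0 * math.pi * np.random.random()
                cos_p = math.cos(phi_ang)
                sin_p = math.sin(phi_ang)
                if abs(uz) > 0.99999:
                    ux = sin_t * cos_p
                    uy = sin_t * sin_p
                    uz = cos_t if uz > 0.0 else -cos_t
                else:
                    den = math.sqrt(1.0 - uz * uz)
                    tx = sin_t * (ux * uz * cos_p - uy * sin_p) / den + ux * cos_t
                    ty = sin_t * (uy * uz * cos_p + ux * sin_p) / den + uy * cos_t
                    tz = -sin_t * cos_p * den + uz * cos_t
                    ux, uy, uz = tx, ty, tz
                norm = math.sqrt(ux * ux + uy * uy + uz * uz)
                ux /= norm
                uy /= norm
                uz /= norm
                tau = -math.log(np.random.random() + 1e-300)

            # Russian roulette on low-weight packets
            if alive and w < w_min:
                if np.random.random() < p_survive:
                    w /= p_survive
                else:
                    alive = False

    return phi_b, batch_counts, esc, dep_total, path_total, scat_total


# --------------------------------------------------------------------------
# python driver
# --------------------------------------------------------------------------

def _medium_maps(medium, geom: Geometry):
    nr, nz = geom.n_lateral, geom.n_depth
    if isinstance(medium, CompositeOptics):
        mu_a = np.full((nr, nz), medium.mu_a_total)
        mu_s = np.full((nr, nz), medium.mu_s_total)
        g = np.full((nr, nz), medium.g_eff)
        return mu_a, mu_s, g, medium.n
    if isinstance(medium, VoxelMedium):
        shape = (nr, nz)
        for name, arr in (("mu_a", medium.mu_a), ("mu_s", medium.mu_s), ("g", medium.g)):
            a = np.asarray(arr, dtype=float)
            if a.shape != shape:
                raise TransportError(f"voxel field {name} must have shape {shape}")
        if np.any(medium.mu_a < 0) or np.any(medium.mu_s < 0):
            raise TransportError("voxel coefficients must be >= 0")
        if np.any(np.abs(medium.g) > 1):
            raise TransportError("voxel anisotropy must lie in [-1, 1]")
        return (
            np.ascontiguousarray(medium.mu_a, dtype=float),
            np.ascontiguousarray(medium.mu_s, dtype=float),
            np.ascontiguousarray(medium.g, dtype=float),
            medium.n,
        )
    raise TransportError("medium must be CompositeOptics or VoxelMedium")


def run_transport(
    medium,
    geom: Geometry,
    beam: BeamSpec,
    settings: TransportSettings,
) -> tuple[FluenceMap, AbsorptionMap]:
    """Run the Monte Carlo transport and return fluence and absorption maps.

    Deterministic for a given (configuration, seed).  The fluence map is
    normalized per unit incident power; multiply by ``beam.power`` for
    absolute fluence rates.
    """
    mu_a_map, mu_s_map, g_map, n_med = _medium_maps(medium, geom)
    substep = 0.5 * min(geom.dr, geom.dz)

    phi_b, counts, esc, dep, path_total, scat_total = _mc_kernel(
        mu_a_map, mu_s_map, g_map,
        float(n_med), float(settings.n_outside),
        float(geom.radius), float(geom.height),
        geom.n_lateral, geom.n_depth,
        float(beam.beam_radius), beam.profile == "gaussian",
        int(settings.n_photons), int(settings.seed),
        float(settings.w_min), float(settings.p_survive),
        int(settings.n_batches), float(substep),
    )

    n = settings.n_photons
    vol = geom.voxel_volumes()
    phi = phi_b.sum(axis=0) / (n * vol)

    # batch means -> standard error of the mean
    batch_means = phi_b / (counts[:, None, None] * vol[None, :, :])
    stderr = batch_means.std(axis=0, ddof=1) / math.sqrt(settings.n_batches)

    budget = {
        "reflected": esc[_ESC_TOP] / n,
        "transmitted": esc[_ESC_BOTTOM] / n,
        "side_escaped": esc[_ESC_SIDE] / n,
        "absorbed": dep / n,
    }

    fmap = FluenceMap(
        phi=phi,
        stderr=stderr,
        budget=budget,
        mean_pathlength=path_total / n,
        mean_scatter_events=scat_total / n,
        geometry=geom,
        beam=beam,
        n_photons=n,
        seed=settings.seed,
    )

    a_total = mu_a_map * phi
    a_err = mu_a_map * stderr
    by_species: dict[str, np.ndarray] = {}
    if isinstance(medium, CompositeOptics) and medium.mu_a_total > 0:
        if medium.mu_a_by_species:
            named = sum(mu for _, mu in medium.mu_a_by_species)
            bkg = medium.mu_a_total - named
            if bkg > 1e-15:
                by_species["background"] = a_total * (bkg / medium.mu_a_total)
            for name, mu in medium.mu_a_by_species:
                if mu > 0:
                    by_species[name] = a_total * (mu / medium.mu_a_total)
        else:
            by_species["background"] = a_total

    amap = AbsorptionMap(
        a_total=a_total,
        stderr=a_err,
        a_by_species=by_species,
        absorbed_fraction=budget["absorbed"],
        geometry=geom,
    )
    return fmap, amap
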