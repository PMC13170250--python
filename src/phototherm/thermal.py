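"""Transient heat conduction driven by the absorbed-power map.

The absorbed optical power density from transport (per incident W) is
scaled by the laser power and used as the volumetric source of an
axisymmetric (r, z) finite-volume conduction model with Robin (convective)
boundaries on all faces.  Temperatures are reported as rises dT above
ambient, so the initial condition is dT = 0 everywhere and the Robin terms
are homogeneous.

A lumped heat-balance model (uniform body, Newton cooling) is provided both
as a fast design estimate and as the analytic limit the full solver must
approach when conduction is fast compared to surface loss:

    dT(t) = dT_ss * (1 - exp(-t / tau)),
    dT_ss = P_abs / (h A),  tau = m c_p / (h A).

Implicit (backward Euler) stepping is the default: unconditionally stable on
the 10-20 minute horizons of interest.  An explicit stepper is available and
auto-refines its step to the diffusive stability limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.linalg import splu

from .transport import AbsorptionMap, Geometry

__all__ = [
    "ThermalProps",
    "ProbeSet",
    "TemperatureTrace",
    "ThermalError",
    "solve_heat",
    "steady_state",
    "lumped_heat_balance",
]


class ThermalError(ValueError):
    """Invalid thermal configuration."""


@dataclass(frozen=True)
class ThermalProps:
    """Bulk thermal properties and surface loss coefficient.

    Defaults are water-like gel values (illustrative): k in W m^-1 K^-1,
    rho in kg m^-3, c_p in J kg^-1 K^-1, h_conv in W m^-2 K^-1.
    """

    k: float = 0.6
    rho: float = 1000.0
    c_p: float = 4186.0
    h_conv: float = 10.0
    t_amb: float = 25.0

    def __post_init__(self) -> None:
        if min(self.k, self.rho, self.c_p, self.h_conv) <= 0:
            raise ThermalError("thermal properties must be positive")


@dataclass(frozen=True)
class ProbeSet:
    """Virtual thermocouple positions as (radial distance mm, depth mm)."""

    probes: tuple[tuple[float, float], ...]

    @staticmethod
    def default(geom: Geometry) -> "ProbeSet":
        """Four probes at 3, 6, 9, 12 mm radial distance, mid-height."""
        mid = 0.5 * geom.height
        return ProbeSet(tuple((r, mid) for r in (3.0, 6.0, 9.0, 12.0) if r <= geom.radius))

    def validate(self, geom: Geometry) -> None:
        if not self.probes:
            raise ThermalError("probe set is empty")
        for r, z in self.probes:
            if not (0.0 <= r <= geom.radius and 0.0 <= z <= geom.height):
                raise ThermalError(f"probe (r={r} mm, z={z} mm) lies outside the phantom")


@dataclass
class TemperatureTrace:
    """Per-probe temperature rise dT(t) above ambient."""

    t: np.ndarray                       # s
    dT: np.ndarray                      # (n_probes, n_times), degC
    probes: tuple[tuple[float, float], ...]

    def at_time(self, t_query: float) -> np.ndarray:
        """Linear interpolation of every probe trace at t_query seconds."""
        return np.array([np.interp(t_query, self.t, row) for row in self.dT])


_MM = 1e-3  # mm -> m


def _assemble(geom: Geometry, props: ThermalProps):
    """Capacity vector (J/K), stiffness matrix (W/K) with Robin losses folded in."""
    nr, nz = geom.n_lateral, geom.n_depth
    dr = geom.dr * _MM
    dz = geom.dz * _MM
    r_edges = geom.r_edges * _MM

    ring_area = math.pi * (r_edges[1:] ** 2 + 0.0) - math.pi * (r_edges[:-1] ** 2)
    vol = ring_area * dz                       # (nr,) cell volumes, m^3
    side_area = 2.0 * math.pi * r_edges[1:] * dz  # (nr,) outer lateral face areas

    n = nr * nz
    cap = np.empty(n)
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    diag = np.zeros(n)
    k, h = props.k, props.h_conv

    def idx(i, j):
        return i * nz + j

    for i in range(nr):
        for j in range(nz):
            p = idx(i, j)
            cap[p] = props.rho * props.c_p * vol[i]
            # radial neighbours across face at r_edges[i+1]
            if i + 1 < nr:
                g_r = k * side_area[i] / dr
                q = idx(i + 1, j)
                rows += [p, p, q, q]
                cols += [q, p, p, q]
                vals += [-g_r, g_r, -g_r, g_r]
            else:
                # Robin loss through the outer side: half-cell conduction in
                # series with the convective film
                a = side_area[i]
                g_b = 1.0 / (1.0 / (h * a) + (dr / 2.0) / (k * a))
                diag[p] += g_b
            # axial neighbour across face at z_edges[j+1]
            if j + 1 < nz:
                g_z = k * ring_area[i] / dz
                q = idx(i, j + 1)
                rows += [p, p, q, q]
                cols += [q, p, p, q]
                vals += [-g_z, g_z, -g_z, g_z]
            else:
                a = ring_area[i]
                g_b = 1.0 / (1.0 / (h * a) + (dz / 2.0) / (k * a))
                diag[p] += g_b
            if j == 0:
                a = ring_area[i]
                g_b = 1.0 / (1.0 / (h * a) + (dz / 2.0) / (k * a))
                diag[p] += g_b

    stiff = csr_matrix((vals, (rows, cols)), shape=(n, n))
    stiff = stiff + csr_matrix((diag, (np.arange(n), np.arange(n))), shape=(n, n))
    # accumulate duplicate entries
    stiff.sum_duplicates()
    return cap, stiff, vol


def _probe_weights(geom: Geometry, probes: ProbeSet):
    """Bilinear interpolation weights on the (r, z) cell-center grid."""
    rc = geom.r_centers
    zc = geom.z_centers
    weights = []
    for r, z in probes.probes:
        ri = np.clip(np.searchsorted(rc, r) - 1, 0, len(rc) - 2)
        zi = np.clip(np.searchsorted(zc, z) - 1, 0, len(zc) - 2)
        fr = np.clip((r - rc[ri]) / (rc[ri + 1] - rc[ri]), 0.0, 1.0)
        fz = np.clip((z - zc[zi]) / (zc[zi + 1] - zc[zi]), 0.0, 1.0)
        weights.append((ri, zi, fr, fz))
    return weights


def _probe_values(field: np.ndarray, weights) -> np.ndarray:
    out = np.empty(len(weights))
    for m, (ri, zi, fr, fz) in enumerate(weights):
        out[m] = (
            field[ri, zi] * (1 - fr) * (1 - fz)
            + field[ri + 1, zi] * fr * (1 - fz)
            + field[ri, zi + 1] * (1 - fr) * fz
            + field[ri + 1, zi + 1] * fr * fz
        )
    return out


def solve_heat(
    absorption: AbsorptionMap,
    power: float,
    geom: Geometry,
    props: ThermalProps,
    duration: float,
    probes: ProbeSet | None = None,
    dt: float = 1.0,
    method: str = "implicit",
    store_every: int = 1,
) -> tuple[TemperatureTrace, np.ndarray]:
    """March the conduction problem and return probe traces and final field.

    The source per cell is ``power * a_total * V_cell`` watts (a_total is the
    deposited power density per incident watt, mm^-3).
    """
    if power < 0:
        raise ThermalError("laser power must be >= 0")
    if duration <= 0 or dt <= 0:
        raise ThermalError("duration and dt must be > 0")
    if method not in ("implicit", "explicit"):
        raise ThermalError("method must be 'implicit' or 'explicit'")
    if absorption.a_total.shape != (geom.n_lateral, geom.n_depth):
        raise ThermalError("absorption map grid does not match the geometry")
    if probes is None:
        probes = ProbeSet.default(geom)
    probes.validate(geom)

    cap, stiff, _vol = _assemble(geom, props)
    # W per cell: a_total [mm^-3 per W] * voxel volume [mm^3] * power [W]
    q = (power * absorption.a_total * geom.voxel_volumes()).ravel()

    if method == "explicit":
        # diffusive stability limit with safety margin; auto-refine
        diag = stiff.diagonal()
        dt_max = 0.8 * float(np.min(cap / np.maximum(diag, 1e-300)))
        if dt > dt_max:
            n_sub = int(math.ceil(dt / dt_max))
            dt = dt / n_sub

    n_steps = int(round(duration / dt))
    if abs(n_steps * dt - duration) > 1e-9 * max(duration, 1.0):
        n_steps = int(math.ceil(duration / dt))

    n = cap.size
    temp = np.zeros(n)
    weights = _probe_weights(geom, probes)
    times = [0.0]
    traces = [np.zeros(len(weights))]

    if method == "implicit":
        a_mat = stiff.tocsc() * dt
        a_mat = a_mat + csr_matrix(
            (cap, (np.arange(n), np.arange(n))), shape=(n, n)
        ).tocsc()
        lu = splu(a_mat)
        rhs_src = q * dt
        for step in range(1, n_steps + 1):
            temp = lu.solve(cap * temp + rhs_src)
            if step % store_every == 0 or step == n_steps:
                times.append(step * dt)
                traces.append(
                    _probe_values(temp.reshape(geom.n_lateral, geom.n_depth), weights)
                )
    else:
        for step in range(1, n_steps + 1):
            temp = temp + dt * (q - stiff @ temp) / cap
            if step % store_every == 0 or step == n_steps:
                times.append(step * dt)
                traces.append(
                    _probe_values(temp.reshape(geom.n_lateral, geom.n_depth), weights)
                )

    trace = TemperatureTrace(
        t=np.array(times),
        dT=np.array(traces).T,
        probes=probes.probes,
    )
    return trace, temp.reshape(geom.n_lateral, geom.n_depth)


def steady_state(
    absorption: AbsorptionMap,
    power: float,
    geom: Geometry,
    props: ThermalProps,
    probes: ProbeSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Steady-state temperature rise field: solve K dT = q directly.

    Returns (probe dT values, dT field).  Useful for long-time limits and
    closed-form conduction checks without marching the transient.
    """
    if power < 0:
        raise ThermalError("laser power must be >= 0")
    if absorption.a_total.shape != (geom.n_lateral, geom.n_depth):
        raise ThermalError("absorption map grid does not match the geometry")
    if probes is None:
        probes = ProbeSet.default(geom)
    probes.validate(geom)
    _cap, stiff, _vol = _assemble(geom, props)
    q = (power * absorption.a_total * geom.voxel_volumes()).ravel()
    temp = splu(stiff.tocsc()).solve(q)
    field = temp.reshape(geom.n_lateral, geom.n_depth)
    return _probe_values(field, _probe_weights(geom, probes)), field


def lumped_heat_balance(
    p_abs: float,
    surface_area: float,
    mass: float,
    props: ThermalProps,
    t: np.ndarray | None = None,
) -> tuple[float, float, TemperatureTrace]:
    """Uniform-body heat balance: steady rise, time constant, and trace.

    p_abs in W, surface_area in m^2, mass in kg.  Returns
    (dT_ss, tau, trace) with dT_ss = P/(hA) and tau = m c_p/(hA).
    """
    if p_abs < 0:
        raise ThermalError("absorbed power must be >= 0")
    if surface_area <= 0 or mass <= 0:
        raise ThermalError("surface area and mass must be > 0")
    ha = props.h_conv * surface_area
    dt_ss = p_abs / ha
    tau = mass * props.c_p / ha
    if t is None:
        t = np.linspace(0.0, 5.0 * tau, 256)
    t = np.asarray(t, dtype=float)
    dT = dt_ss * (1.0 - np.exp(-t / tau))
    trace = TemperatureTrace(t=t, dT=dT[None, :], probes=((0.0, 0.0),))
    return dt_ss, tau, trace
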