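"""Enhancement maps and depth profiles from paired transport runs.

The enhancement factor E(r, z) is the voxelwise ratio of the fluence (or
absorbed power density) of a *case* medium to that of a *reference* medium
under identical illumination.  Ratios are only reported where the reference
signal is statistically distinguishable from zero (the floor_sigma mask);
deep voxels where the reference tally is noise are masked out rather than
clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transport import AbsorptionMap, FluenceMap

__all__ = [
    "EnhancementMap",
    "DepthProfile",
    "AnalysisError",
    "enhancement_map",
    "absorption_enhancement_map",
    "depth_profile",
]

#: default reference-significance threshold (reference > floor * stderr)
DEFAULT_FLOOR_SIGMA = 10.0


class AnalysisError(ValueError):
    """Incompatible or invalid inputs to a field analysis."""


@dataclass
class EnhancementMap:
    """Masked ratio field with pooled Monte Carlo errors and summaries.

    ``e`` is NaN outside ``valid_mask``.  ``summary`` holds
    ``max_entry_region`` (maximum laterally averaged ratio within the first
    2 mm of depth, beam footprint only), ``median_valid`` (volume median
    over valid voxels), ``median_upper_half`` (median over valid voxels in
    the upper half-depth) and ``fraction_above_one``.
    """

    e: np.ndarray
    stderr: np.ndarray
    valid_mask: np.ndarray
    summary: dict


@dataclass
class DepthProfile:
    """Laterally averaged fluence or absorption versus depth."""

    z: np.ndarray
    value: np.ndarray
    stderr: np.ndarray


#: depth (mm) of the "entry region" used for the entry-side summary
ENTRY_DEPTH_MM = 2.0


def _ratio_map(case_val, case_err, ref_val, ref_err, floor_sigma, geometry, beam):
    if case_val.shape != ref_val.shape:
        raise AnalysisError("case and reference maps are on different grids")
    valid = ref_val > floor_sigma * ref_err
    e = np.full_like(ref_val, np.nan)
    err = np.full_like(ref_val, np.nan)
    np.divide(case_val, ref_val, out=e, where=valid)
    # pooled relative error of the ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        rel2 = np.where(
            valid & (case_val > 0),
            (case_err / np.where(case_val > 0, case_val, 1.0)) ** 2,
            0.0,
        ) + np.where(valid, (ref_err / np.where(valid, ref_val, 1.0)) ** 2, 0.0)
    err[valid] = (e * np.sqrt(rel2))[valid]

    summary = _summaries(e, valid, geometry, beam)
    return EnhancementMap(e=e, stderr=err, valid_mask=valid, summary=summary)


def _summaries(e, valid, geometry, beam):
    if not valid.any():
        return {
            "max_entry_region": float("nan"),
            "median_valid": float("nan"),
            "median_upper_half": float("nan"),
            "fraction_above_one": float("nan"),
            "n_valid": 0,
        }
    zc = geometry.z_centers
    rc = geometry.r_centers
    in_beam = rc <= beam.beam_radius
    entry = zc < ENTRY_DEPTH_MM
    # laterally averaged ratio inside the beam footprint, entry region only
    max_entry = float("nan")
    if in_beam.any() and entry.any():
        sub = e[np.ix_(in_beam, entry)]
        sub_valid = valid[np.ix_(in_beam, entry)]
        profile = np.full(entry.sum(), np.nan)
        for j in range(entry.sum()):
            col = sub[:, j][sub_valid[:, j]]
            if col.size:
                profile[j] = col.mean()
        if np.isfinite(profile).any():
            max_entry = float(np.nanmax(profile))
    upper = zc < 0.5 * geometry.height
    upper_vals = e[:, upper][valid[:, upper]]
    return {
        "max_entry_region": max_entry,
        "median_valid": float(np.median(e[valid])),
        "median_upper_half": float(np.median(upper_vals)) if upper_vals.size else float("nan"),
        "fraction_above_one": float(np.mean(e[valid] > 1.0)),
        "n_valid": int(valid.sum()),
    }


def enhancement_map(
    case: FluenceMap,
    ref: FluenceMap,
    floor_sigma: float = DEFAULT_FLOOR_SIGMA,
) -> EnhancementMap:
    """Fluence enhancement E = phi_case / phi_ref on statistically valid voxels."""
    if case.geometry != ref.geometry:
        raise AnalysisError("case and reference maps are on different grids")
    return _ratio_map(
        case.phi, case.stderr, ref.phi, ref.stderr, floor_sigma, ref.geometry, ref.beam
    )


def absorption_enhancement_map(
    case: AbsorptionMap,
    ref: AbsorptionMap,
    floor_sigma: float = DEFAULT_FLOOR_SIGMA,
    beam=None,
) -> EnhancementMap:
    """Absorption enhancement (mu_a * phi ratio) on statistically valid voxels.

    A reference with zero absorber everywhere yields an all-invalid mask and
    NaN summaries rather than an error.
    """
    if case.geometry != ref.geometry:
        raise AnalysisError("case and reference maps are on different grids")
    if beam is None:
        from .transport import BeamSpec

        beam = BeamSpec(power=1.0, beam_radius=ref.geometry.radius)
    return _ratio_map(
        case.a_total, case.stderr, ref.a_total, ref.stderr, floor_sigma, ref.geometry, beam
    )


def depth_profile(fmap: FluenceMap | AbsorptionMap, beam=None) -> DepthProfile:
    """Laterally average a map over radii within the beam footprint.

    The average is voxel-volume weighted (a true areal mean over the beam
    footprint); the standard error is propagated as the pooled per-voxel
    error of that weighted mean.
    """
    if isinstance(fmap, FluenceMap):
        value, err, geom = fmap.phi, fmap.stderr, fmap.geometry
        beam = fmap.beam if beam is None else beam
    else:
        value, err, geom = fmap.a_total, fmap.stderr, fmap.geometry
        if beam is None:
            from .transport import BeamSpec

            beam = BeamSpec(power=1.0, beam_radius=geom.radius)
    rc = geom.r_centers
    in_beam = rc <= beam.beam_radius
    if not in_beam.any():
        in_beam = np.zeros_like(rc, dtype=bool)
        in_beam[0] = True  # beam narrower than one radial bin
    vol = geom.voxel_volumes()[in_beam, :]
    wsum = vol.sum(axis=0)
    v = (value[in_beam, :] * vol).sum(axis=0) / wsum
    se = np.sqrt(((err[in_beam, :] * vol) ** 2).sum(axis=0)) / wsum
    return DepthProfile(z=geom.z_centers.copy(), value=v, stderr=se)
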