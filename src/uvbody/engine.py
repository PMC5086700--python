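"""Exposure engine: radiance-field integration over the body surface.

For every exposed surface patch p and discrete sky/ground direction d the
engine accumulates

    area(p) * L(d, lambda) * max(0, n_p . d) * dOmega(d) * visible(p, d)

plus a separate delta-function term for the direct solar beam (the sun is
never smeared over an angular bin).  Spectral integration against an
action spectrum then yields the biologically weighted radiant power
intercepted by bare skin, in mW, split by body part and by component
(direct / diffuse sky / ground-reflected upwelling).  A virtual
unobstructed up-facing unit patch provides the conventional horizontal
irradiance (mW m^-2) for comparison.

Self-shadowing uses voxel ray casting; the ground plane itself never
occludes upwelling radiance (the body effectively floats above an
infinite Lambertian plane), only the body blocks its own patches.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import _raytrace
from .atmosphere import RadianceField
from .body import BodyPatch, PatchSet, VoxelBody, extract_patches
from .spectral import ActionSpectrum, ERYTHEMAL, Spectrum, weight_spectrum

__all__ = [
    "AngularGrid",
    "ExposureResult",
    "make_angular_grid",
    "patch_visibility",
    "compute_exposure",
    "exposure_components_report",
    "write_results_csv",
]

COMPONENTS = ("direct", "diffuse_down", "upwelling")


@dataclass(frozen=True)
class AngularGrid:
    """Discretisation of the full sphere of directions.

    Zenith bins cover [0, pi] (upper then lower hemisphere), azimuth bins
    [0, 2 pi).  Solid angles use the exact cosine difference, so they sum
    to 4 pi to machine precision.  Directions point from the body toward
    the radiation source; azimuth 0 is the +y axis.
    """

    theta_edges: np.ndarray
    phi_edges: np.ndarray

    @property
    def theta_centers(self) -> np.ndarray:
        return 0.5 * (self.theta_edges[:-1] + self.theta_edges[1:])

    @property
    def phi_centers(self) -> np.ndarray:
        return 0.5 * (self.phi_edges[:-1] + self.phi_edges[1:])

    @property
    def d_omega(self) -> np.ndarray:
        """Per-bin solid angle, shape (n_theta, n_phi)."""
        dcos = np.cos(self.theta_edges[:-1]) - np.cos(self.theta_edges[1:])
        dphi = np.diff(self.phi_edges)
        return dcos[:, None] * dphi[None, :]

    @property
    def directions(self) -> np.ndarray:
        """Unit vectors, shape (n_theta, n_phi, 3); azimuth 0 = +y."""
        th = self.theta_centers[:, None]
        ph = self.phi_centers[None, :]
        return np.stack(
            [
                np.sin(th) * np.sin(ph),
                np.sin(th) * np.cos(ph),
                np.cos(th) * np.ones_like(ph),
            ],
            axis=-1,
        )

    @property
    def upper_mask(self) -> np.ndarray:
        """Bins belonging to the upper hemisphere (sky)."""
        return self.theta_centers < math.pi / 2.0

    @property
    def n_bins_per_hemisphere(self) -> int:
        return int(self.upper_mask.sum()) * (len(self.phi_edges) - 1)


def make_angular_grid(n_zenith: int = 18, n_azimuth: int = 36) -> AngularGrid:
    """Angular grid with ``n_zenith`` zenith bins per hemisphere.

    The default 18 x 36 (5 deg x 10 deg) yields 648 bins per hemisphere.
    """
    if n_zenith < 9:
        raise ValueError("need at least 9 zenith bins per hemisphere")
    if n_azimuth < 12:
        raise ValueError("need at least 12 azimuth bins")
    return AngularGrid(
        theta_edges=np.linspace(0.0, math.pi, 2 * n_zenith + 1),
        phi_edges=np.linspace(0.0, 2.0 * math.pi, n_azimuth + 1),
    )


def patch_visibility(patch: BodyPatch, direction: np.ndarray, body: VoxelBody) -> bool:
    """Whether a ray from the patch (offset half a voxel along its normal)
    escapes the occupancy grid travelling toward ``direction``."""
    start_world = patch.center + 0.5 * body.voxel_size * patch.normal
    start_vox = (start_world - body.origin) / body.voxel_size
    return _raytrace.ray_visible(body.occupancy, start_vox, direction)


@dataclass(frozen=True)
class ExposureResult:
    """Erythemally (or otherwise) weighted exposure of the body.

    ``weighted_exposure`` is the biologically weighted radiant power
    intercepted by exposed skin (mW); it equals both the per-part and the
    per-component sums by construction.  ``horizontal_irradiance`` is the
    weighted global irradiance on an unobstructed horizontal surface
    (mW m^-2), the conventional reference quantity.
    """

    weighted_exposure: float
    per_part: Mapping[str, float]
    components: Mapping[str, float]
    horizontal_irradiance: float
    action: str = "erythemal"
    meta: Mapping[str, float] = dc_field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"weighted exposure ({self.action}): {self.weighted_exposure:.4f} mW",
            f"horizontal irradiance: {self.horizontal_irradiance:.4f} mW/m^2",
            "components [mW]: "
            + ", ".join(f"{k}={v:.4f}" for k, v in self.components.items()),
            "per part [mW]: "
            + ", ".join(f"{k}={v:.4f}" for k, v in sorted(self.per_part.items())),
        ]
        return "\n".join(lines)


def compute_exposure(
    body: VoxelBody,
    field: RadianceField,
    grid: AngularGrid | None = None,
    action: ActionSpectrum = ERYTHEMAL,
) -> ExposureResult:
    """Integrate the radiance field over the body's exposed patches.

    The diffuse sky and the Lambertian upwelling are angularly separable
    from their spectra, so each patch first accumulates a geometric factor
    (cosine x solid angle x visibility, weighted by the sky shape) per
    component, and the spectral weighting is applied once per component.
    """
    if grid is None:
        grid = make_angular_grid()
    patches = extract_patches(body)
    exposed = patches[patches.exposed]
    if len(exposed) == 0:
        warnings.warn("body has no exposed patches; exposure is zero")
        zero = {c: 0.0 for c in COMPONENTS}
        return ExposureResult(0.0, {}, zero, _horizontal(field, action), action.name)

    dirs = grid.directions.reshape(-1, 3)
    d_omega = grid.d_omega.reshape(-1)
    theta = np.repeat(grid.theta_centers, len(grid.phi_centers))
    upper = theta < math.pi / 2.0

    cosines = np.clip(exposed.normals @ dirs.T, 0.0, None)  # (P, D)
    relevant = cosines > 0.0
    vis = _raytrace.visibility_matrix(
        body.occupancy, exposed.ray_starts_voxel(), dirs, relevant
    )
    geom = cosines * vis * d_omega[None, :]

    # sky shape multiplier: L_down(theta, lambda) = shape * E_diff(lambda)
    shape_up = field.sky_shape(theta)
    g_diff = geom[:, upper] @ shape_up[upper]          # per patch, units sr * shape
    g_upw = geom[:, ~upper].sum(axis=1)                # L_up is isotropic below

    sun = field.sun_direction
    cos_sun = np.clip(exposed.normals @ sun, 0.0, None)
    vis_sun = _raytrace.visibility_matrix(
        body.occupancy, exposed.ray_starts_voxel(), sun[None, :],
        (cos_sun > 0)[:, None],
    )[:, 0]
    g_dir = cos_sun * vis_sun

    w_diff = weight_spectrum(field.diffuse_down_total, action)
    w_up = weight_spectrum(field.up, action)
    w_dir = weight_spectrum(field.direct_normal, action)

    a = exposed.areas
    p_diff = a * g_diff * w_diff
    p_upw = a * g_upw * w_up
    p_dir = a * g_dir * w_dir
    p_total = p_diff + p_upw + p_dir

    per_part: dict[str, float] = {}
    for part in np.unique(exposed.parts):
        sel = exposed.parts == part
        per_part[str(part)] = float(p_total[sel].sum())

    components = {
        "direct": float(p_dir.sum()),
        "diffuse_down": float(p_diff.sum()),
        "upwelling": float(p_upw.sum()),
    }
    total = float(p_total.sum())
    return ExposureResult(
        weighted_exposure=total,
        per_part=per_part,
        components=components,
        horizontal_irradiance=_horizontal(field, action),
        action=action.name,
        meta={
            "n_exposed_patches": float(len(exposed)),
            "exposed_area_m2": float(a.sum()),
        },
    )


def _horizontal(field: RadianceField, action: ActionSpectrum) -> float:
    """Weighted global irradiance on an unobstructed horizontal surface."""
    return weight_spectrum(field.global_horizontal, action)


def exposure_components_report(result: ExposureResult) -> pd.DataFrame:
    """Tabular breakdown with a bookkeeping-closure row.

    The closure row reports |total - sum(parts)| / total (and the same for
    components); both are zero up to floating-point rounding.
    """
    rows = [{"row": "total", "quantity": "exposure_mW",
             "value": result.weighted_exposure}]
    for part, val in sorted(result.per_part.items()):
        rows.append({"row": f"part:{part}", "quantity": "exposure_mW", "value": val})
    for comp, val in result.components.items():
        rows.append({"row": f"component:{comp}", "quantity": "exposure_mW",
                     "value": val})
    total = result.weighted_exposure
    part_sum = sum(result.per_part.values())
    comp_sum = sum(result.components.values())
    closure = 0.0
    if total > 0:
        closure = max(abs(total - part_sum), abs(total - comp_sum)) / total
    rows.append({"row": "closure_rel_error", "quantity": "dimensionless",
                 "value": closure})
    return pd.DataFrame(rows)


RESULTS_COLUMNS = [
    "scenario_id", "albedo", "altitude_m", "sza_deg",
    "exposure_mW", "irradiance_mWm2",
    "direct_mW", "diffuse_down_mW", "upwelling_mW",
]


def write_results_csv(df: pd.DataFrame, path) -> None:
    """Write a scenario results table with a stable schema and formatting.

    Uses a temp-then-rename so a crash never leaves a partial file; fixed
    float formatting makes repeated runs byte-identical.
    """
    path = Path(path)
    missing = [c for c in RESULTS_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"results table missing columns: {missing}")
    extra = [c for c in df.columns if c not in RESULTS_COLUMNS]
    tmp = path.with_suffix(path.suffix + ".tmp")
    df[RESULTS_COLUMNS + extra].to_csv(tmp, index=False, float_format="%.6f",
                                       lineterminator="\n")
    tmp.replace(path)
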