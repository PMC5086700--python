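"""Valley/mountain scenario battery, altitude gradients and sweeps.

The reference experiment compares two hypothetical alpine sites on
2016-03-31 at 47 deg N: a snow-free valley at 600 m (albedo 0.02, 300 DU,
20 km visibility) and a mountain top at 2200 m (snow albedo varied over
0.02/0.2/0.4/0.6, 294.4 DU, 30 km visibility), both under rural aerosol
by default; an urban-valley variant swaps only the valley aerosol class.
Altitude gradients normalise the mountain/valley ratio per 100 m:

    gradient [% per 100 m] = ((mountain / valley) - 1) / (dAltitude / 100 m) * 100

For the default pair dAltitude = 1600 m.  Gradients of the whole-body
exposure are compared against gradients of the horizontal erythemal
irradiance, the conventional metric.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .atmosphere import AtmosphereState, build_radiance_field
from .body import (
    ClothingConfig,
    PATCH_PARTS,
    VoxelBody,
    WINTER,
    apply_clothing,
    export_obj,
    make_voxel_human,
)
from .engine import (
    AngularGrid,
    compute_exposure,
    make_angular_grid,
    write_results_csv,
)
from .spectral import (
    ActionSpectrum,
    ERYTHEMAL,
    SpectralGrid,
    bundled_extraterrestrial_path,
    get_action_spectrum,
)

__all__ = [
    "GradientResult",
    "ScenarioPair",
    "altitude_gradient",
    "run_scenario_pair",
    "sza_sweep",
    "load_config",
    "validate_config",
    "default_config_path",
    "run_from_config",
]

#: Default altitudes of the reference experiment (m).
VALLEY_ALTITUDE_M = 600.0
MOUNTAIN_ALTITUDE_M = 2200.0
#: Default mountain effective albedos (snow-free .. spring snow).
MOUNTAIN_ALBEDOS = (0.02, 0.2, 0.4, 0.6)


def altitude_gradient(mountain_value: float, valley_value: float,
                      delta_altitude_m: float) -> float:
    """Altitude gradient in % per 100 m of a radiation quantity.

    ``((mountain / valley) - 1) / (delta_altitude / 100 m) * 100``.
    Positive when the mountain value exceeds the valley value.
    """
    if valley_value <= 0:
        raise ValueError("valley value must be positive")
    if delta_altitude_m <= 0:
        raise ValueError("delta_altitude_m must be positive")
    return (mountain_value / valley_value - 1.0) / (delta_altitude_m / 100.0) * 100.0


@dataclass(frozen=True)
class GradientResult:
    """Inputs and output of one altitude-gradient computation."""

    valley_value: float
    mountain_value: float
    delta_altitude_m: float

    @property
    def gradient_pct_per_100m(self) -> float:
        return altitude_gradient(self.mountain_value, self.valley_value,
                                 self.delta_altitude_m)


@dataclass(frozen=True)
class ScenarioPair:
    """A valley reference site plus mountain sites at several albedos.

    ``latitude_deg`` and ``date`` are metadata tags only; the operative
    solar input is the SZA carried by each :class:`AtmosphereState`.
    """

    valley: AtmosphereState
    mountains: tuple
    latitude_deg: float = 47.0
    date: str = "2016-03-31"
    sky_model: str = "isotropic"
    sun_azimuth_deg: float = 0.0

    def __post_init__(self) -> None:
        for m in self.mountains:
            if m.altitude_m <= self.valley.altitude_m:
                raise ValueError("mountain altitude must exceed valley altitude")

    @property
    def delta_altitude_m(self) -> float:
        return float(self.mountains[0].altitude_m - self.valley.altitude_m)

    @classmethod
    def default(
        cls,
        sza_deg: float = 45.0,
        valley_aerosol: str = "rural",
        mountain_albedos: Sequence[float] = MOUNTAIN_ALBEDOS,
        sky_model: str = "isotropic",
    ) -> "ScenarioPair":
        """The reference configuration (rural mountain, 1600 m difference)."""
        valley = AtmosphereState(
            altitude_m=VALLEY_ALTITUDE_M,
            total_ozone_column_du=300.0,
            horizontal_visibility_km=20.0,
            aerosol_class=valley_aerosol,
            surface_albedo=0.02,
            solar_zenith_angle_deg=sza_deg,
        )
        mountains = tuple(
            AtmosphereState(
                altitude_m=MOUNTAIN_ALTITUDE_M,
                total_ozone_column_du=294.4,
                horizontal_visibility_km=30.0,
                aerosol_class="rural",
                surface_albedo=a,
                solar_zenith_angle_deg=sza_deg,
            )
            for a in mountain_albedos
        )
        return cls(valley=valley, mountains=mountains, sky_model=sky_model)


def _run_site(state: AtmosphereState, body: VoxelBody, grid: SpectralGrid,
              angular: AngularGrid, action: ActionSpectrum,
              sky_model: str, sun_azimuth_deg: float):
    field_ = build_radiance_field(state, grid, sky_model=sky_model,
                                  sun_azimuth_deg=sun_azimuth_deg)
    return compute_exposure(body, field_, angular, action)


def run_scenario_pair(
    pair: ScenarioPair | None = None,
    body: VoxelBody | None = None,
    clothing: ClothingConfig = WINTER,
    spectral_grid: SpectralGrid | None = None,
    angular_grid: AngularGrid | None = None,
    action: ActionSpectrum = ERYTHEMAL,
) -> pd.DataFrame:
    """Exposure/irradiance table for the valley and each mountain albedo.

    One row per site; mountain rows carry Eq.-style altitude gradients of
    both quantities computed against the (gradient-free) valley reference
    row, from unrounded values.
    """
    if pair is None:
        pair = ScenarioPair.default()
    if body is None:
        body = make_voxel_human()
    if spectral_grid is None:
        spectral_grid = SpectralGrid.default()
    if angular_grid is None:
        angular_grid = make_angular_grid()
    body = apply_clothing(body, clothing)

    rows = []
    states = [("valley", pair.valley)] + [("mountain", m) for m in pair.mountains]
    valley_res = None
    for i, (loc, state) in enumerate(states):
        res = _run_site(state, body, spectral_grid, angular_grid, action,
                        pair.sky_model, pair.sun_azimuth_deg)
        if valley_res is None:
            valley_res = res
        row = {
            "scenario_id": f"{loc}_a{state.surface_albedo:g}",
            "location": loc,
            "albedo": state.surface_albedo,
            "altitude_m": state.altitude_m,
            "sza_deg": state.solar_zenith_angle_deg,
            "aerosol": state.aerosol_class,
            "irradiance_mWm2": res.horizontal_irradiance,
            "exposure_mW": res.weighted_exposure,
            "direct_mW": res.components["direct"],
            "diffuse_down_mW": res.components["diffuse_down"],
            "upwelling_mW": res.components["upwelling"],
        }
        if loc == "valley":
            row["irradiance_gradient_pct_per_100m"] = float("nan")
            row["exposure_gradient_pct_per_100m"] = float("nan")
        else:
            dh = state.altitude_m - pair.valley.altitude_m
            row["irradiance_gradient_pct_per_100m"] = altitude_gradient(
                res.horizontal_irradiance, valley_res.horizontal_irradiance, dh)
            row["exposure_gradient_pct_per_100m"] = altitude_gradient(
                res.weighted_exposure, valley_res.weighted_exposure, dh)
        rows.append(row)
    return pd.DataFrame(rows)


def sza_sweep(
    sza_list: Iterable[float] | None = None,
    mountain_albedo: float = 0.6,
    valley_aerosol: str = "rural",
    body: VoxelBody | None = None,
    clothing: ClothingConfig = WINTER,
    spectral_grid: SpectralGrid | None = None,
    angular_grid: AngularGrid | None = None,
    action: ActionSpectrum = ERYTHEMAL,
    sky_model: str = "isotropic",
) -> pd.DataFrame:
    """Gradients of exposure and irradiance across a solar-zenith sweep.

    Defaults to SZA 45-89 degrees with the snow-covered (albedo 0.6)
    mountain versus the snow-free valley.  The returned frame carries a
    ``dispersion`` attribute, (max - min)/mean of the exposure gradient,
    a stability statistic of the diurnal variation.
    """
    if sza_list is None:
        sza_list = [45, 50, 55, 60, 65, 70, 75, 80, 85, 89]
    sza_list = list(sza_list)
    for s in sza_list:
        if not 0 <= s < 90:
            raise ValueError(f"SZA {s} outside [0, 90)")
    if body is None:
        body = make_voxel_human()
    if spectral_grid is None:
        spectral_grid = SpectralGrid.default()
    if angular_grid is None:
        angular_grid = make_angular_grid()
    body = apply_clothing(body, clothing)

    rows = []
    for sza in sza_list:
        pair = ScenarioPair.default(sza_deg=sza, valley_aerosol=valley_aerosol,
                                    mountain_albedos=(mountain_albedo,),
                                    sky_model=sky_model)
        v = _run_site(pair.valley, body, spectral_grid, angular_grid, action,
                      pair.sky_model, pair.sun_azimuth_deg)
        m = _run_site(pair.mountains[0], body, spectral_grid, angular_grid,
                      action, pair.sky_model, pair.sun_azimuth_deg)
        dh = pair.delta_altitude_m
        rows.append({
            "sza_deg": sza,
            "exposure_gradient_pct_per_100m": altitude_gradient(
                m.weighted_exposure, v.weighted_exposure, dh),
            "irradiance_gradient_pct_per_100m": altitude_gradient(
                m.horizontal_irradiance, v.horizontal_irradiance, dh),
        })
    df = pd.DataFrame(rows)
    g = df["exposure_gradient_pct_per_100m"]
    df.attrs["dispersion"] = float((g.max() - g.min()) / g.mean())
    return df


# ---------------------------------------------------------------------------
# structured configuration

class ConfigError(ValueError):
    """Malformed scenario configuration; lists every offending key."""


def default_config_path() -> Path:
    """Bundled configuration reproducing the reference experiment design."""
    return Path(resources.files("uvbody").joinpath("data/default_config.yaml"))


_SITE_KEYS = {"altitude_m", "ozone_DU", "visibility_km", "aerosol", "albedo",
              "albedos"}


def validate_config(cfg: dict) -> list[str]:
    """Return a list of validation error strings (empty when valid)."""
    errors: list[str] = []

    def num(block, key, lo=None, hi=None, lo_open=False):
        val = block.get(key)
        if not isinstance(val, (int, float)) or isinstance(val, bool):
            errors.append(f"{key}: missing or not a number")
            return None
        if lo is not None and (val <= lo if lo_open else val < lo):
            errors.append(f"{key}: value {val} below allowed range")
        if hi is not None and val > hi:
            errors.append(f"{key}: value {val} above allowed range")
        return val

    scen = cfg.get("scenario")
    if not isinstance(scen, dict):
        errors.append("scenario: missing block")
        return errors
    num(scen, "sza_deg", 0.0, 89.999)
    if scen.get("sky_model", "isotropic") not in ("isotropic", "gradated"):
        errors.append("sky_model: must be isotropic or gradated")
    for site in ("valley", "mountain"):
        block = scen.get(site)
        if not isinstance(block, dict):
            errors.append(f"{site}: missing block")
            continue
        unknown = set(block) - _SITE_KEYS
        if unknown:
            errors.append(f"{site}: unknown keys {sorted(unknown)}")
        num(block, "altitude_m")
        num(block, "ozone_DU", 0.0, lo_open=True)
        num(block, "visibility_km", 0.0, lo_open=True)
        if block.get("aerosol") not in ("rural", "urban"):
            errors.append(f"{site}.aerosol: must be rural or urban")
        albedos = block.get("albedos", [block.get("albedo")])
        if not isinstance(albedos, list):
            albedos = [albedos]
        for a in albedos:
            if not isinstance(a, (int, float)) or not 0.0 <= a <= 1.0:
                errors.append(f"{site}.albedo: value {a!r} outside [0, 1]")

    body = cfg.get("body", {})
    if not isinstance(body, dict):
        errors.append("body: must be a mapping")
    else:
        h = num(body, "height_m", 0.0, lo_open=True) if "height_m" in body else 1.8
        v = num(body, "voxel_size_m", 0.0, lo_open=True) if "voxel_size_m" in body else 0.02
        if h and v and v > h / 50.0:
            errors.append("voxel_size_m: too coarse for height_m (need <= height/50)")

    clothing = cfg.get("clothing", {})
    if isinstance(clothing, dict):
        parts = clothing.get("exposed_parts", [])
        bad = [p for p in parts if p not in PATCH_PARTS]
        if bad:
            errors.append(f"clothing.exposed_parts: unknown parts {bad}")
    else:
        errors.append("clothing: must be a mapping")
    return errors


def load_config(path) -> dict:
    """Load and validate a YAML scenario configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    errors = validate_config(cfg)
    if errors:
        raise ConfigError(f"{path}: invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def _pair_from_config(cfg: dict) -> ScenarioPair:
    scen = cfg["scenario"]
    sza = float(scen["sza_deg"])
    vb = scen["valley"]
    mb = scen["mountain"]
    valley = AtmosphereState(
        altitude_m=float(vb["altitude_m"]),
        total_ozone_column_du=float(vb["ozone_DU"]),
        horizontal_visibility_km=float(vb["visibility_km"]),
        aerosol_class=vb["aerosol"],
        surface_albedo=float(vb.get("albedo", 0.02)),
        solar_zenith_angle_deg=sza,
    )
    albedos = mb.get("albedos", [mb.get("albedo", 0.02)])
    mountains = tuple(
        AtmosphereState(
            altitude_m=float(mb["altitude_m"]),
            total_ozone_column_du=float(mb["ozone_DU"]),
            horizontal_visibility_km=float(mb["visibility_km"]),
            aerosol_class=mb["aerosol"],
            surface_albedo=float(a),
            solar_zenith_angle_deg=sza,
        )
        for a in albedos
    )
    return ScenarioPair(
        valley=valley,
        mountains=mountains,
        latitude_deg=float(scen.get("latitude_deg", 47.0)),
        date=str(scen.get("date", "2016-03-31")),
        sky_model=scen.get("sky_model", "isotropic"),
        sun_azimuth_deg=float(scen.get("sun_azimuth_deg", 0.0)),
    )


def _objects_from_config(cfg: dict):
    pair = _pair_from_config(cfg)
    body_cfg = cfg.get("body", {})
    body = make_voxel_human(
        height=float(body_cfg.get("height_m", 1.8)),
        voxel_size=float(body_cfg.get("voxel_size_m", 0.02)),
        facing_azimuth_deg=float(body_cfg.get("facing_azimuth_deg", 0.0)),
    )
    cl = cfg.get("clothing", {})
    clothing = ClothingConfig(cl.get("name", "winter"),
                              frozenset(cl.get("exposed_parts", ["face", "hands"])))
    ag_cfg = cfg.get("angular_grid", {})
    angular = make_angular_grid(int(ag_cfg.get("n_zenith", 18)),
                                int(ag_cfg.get("n_azimuth", 36)))
    sg_cfg = cfg.get("spectral_grid", {})
    spectral = SpectralGrid.default(float(sg_cfg.get("step_nm", 1.0)))
    action = get_action_spectrum(cfg.get("action_spectrum", "erythemal"))
    return pair, body, clothing, angular, spectral, action


def run_from_config(config_path, output_dir, export_body: bool = False) -> dict:
    """Run the scenario battery described by a config file.

    Writes ``results.csv`` (fixed schema), ``run_manifest.json`` (resolved
    parameters, package version, checksum of the bundled source spectrum)
    and optionally ``body.obj``.  Deterministic for identical configs;
    output files are written via temp-then-rename.
    """
    cfg = load_config(config_path)
    pair, body, clothing, angular, spectral, action = _objects_from_config(cfg)
    out = Path(output_dir)
    out.mkdir(parents=True, exist_ok=True)

    df = run_scenario_pair(pair, body, clothing, spectral, angular, action)
    write_results_csv(df, out / "results.csv")

    et_path = bundled_extraterrestrial_path()
    manifest = {
        "package": "uvbody",
        "version": __version__,
        "config": cfg,
        "n_rows": int(len(df)),
        "clothing": {"name": clothing.name,
                     "exposed_parts": sorted(clothing.exposed_parts)},
        "spectral_grid": {"step_nm": spectral.step, "n": len(spectral)},
        "angular_bins_per_hemisphere": angular.n_bins_per_hemisphere,
        "extraterrestrial_sha256": hashlib.sha256(et_path.read_bytes()).hexdigest(),
    }
    tmp = out / "run_manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    tmp.replace(out / "run_manifest.json")

    if export_body:
        export_obj(body, out / "body.obj")
    return manifest
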