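"""Clear-sky spectral radiance field: direct beam, diffuse sky, ground reflection.

The full radiative-transfer chain is deliberately compact: a single
effective atmospheric layer holding Rayleigh scattering, ozone absorption
(Hartley-Huggins band shape) and boundary-layer aerosol, solved with a
delta-Eddington two-stream approximation.  Surface-atmosphere multiple
reflection is the usual geometric series 1 / (1 - albedo * s_atm), where
s_atm is the spherical backscatter fraction of the atmosphere for
radiation reflected up by the ground.

The ground is a Lambertian reflector with a single effective albedo that
extends to infinity: the reflected spectral irradiance is

    E_up(lambda) = E_glo(lambda) * albedo

and the (direction-independent) reflected spectral radiance is

    L_up(lambda) = E_up(lambda) / pi  [per steradian],

whose cosine-weighted integral over a hemisphere closes back to E_up.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Tuple

import numpy as np

from .spectral import (
    SpectralGrid,
    Spectrum,
    extraterrestrial_spectrum,
)

__all__ = [
    "AtmosphereState",
    "RadianceField",
    "SurfaceReflection",
    "AEROSOL_CLASSES",
    "optical_depths",
    "direct_horizontal_irradiance",
    "two_stream_layer",
    "two_stream_diffuse",
    "albedo_enhancement",
    "global_irradiance",
    "upwelling_radiance",
    "build_radiance_field",
    "radiance_field_from_spectra",
]

# Pressure scale height for Rayleigh scaling, m.  Conventional value; only
# the valley/mountain ratio matters downstream.
PRESSURE_SCALE_HEIGHT_M = 8000.0
# Aerosol scale height, m: the boundary-layer column above the observer is
# taken exponential with this scale, anchored to the site-level extinction
# inferred from horizontal visibility (Koschmieder).
AEROSOL_SCALE_HEIGHT_M = 1200.0
# Rayleigh optical depth at sea level: tau = A * (lambda/um)^-B.
_RAYLEIGH_A = 0.00877
_RAYLEIGH_B = 4.09
# Ozone: smooth Hartley-band Gaussian fit, cm^2 per molecule, peaking at
# 255 nm; 1 DU = 2.687e16 molecules cm^-2.
_O3_SIGMA_PEAK_CM2 = 1.1e-17
_O3_PEAK_NM = 255.0
_O3_WIDTH_NM = 24.0
_DU_TO_MOLEC_CM2 = 2.687e16

#: Aerosol class parameters: Angstrom exponent, single-scattering albedo,
#: asymmetry parameter, and an extinction multiplier relative to rural at
#: equal visibility (urban air holds more extinguishing aerosol per km of
#: visual range and absorbs more strongly).
AEROSOL_CLASSES = {
    "rural": {"angstrom": 1.3, "ssa": 0.96, "g": 0.70, "ext_factor": 1.0},
    "urban": {"angstrom": 1.1, "ssa": 0.90, "g": 0.70, "ext_factor": 1.3},
}


@dataclass(frozen=True)
class AtmosphereState:
    """Scenario-level atmospheric and surface parameters.

    altitude_m : observer altitude above sea level (m)
    total_ozone_column_du : total ozone column (Dobson units)
    horizontal_visibility_km : Koschmieder visual range at the site (km)
    aerosol_class : ``"rural"`` or ``"urban"``
    surface_albedo : effective Lambertian albedo in [0, 1]
    solar_zenith_angle_deg : SZA in [0, 90); the sun below the horizon is
        not modelled (plane-parallel geometry)
    """

    altitude_m: float
    total_ozone_column_du: float
    horizontal_visibility_km: float
    aerosol_class: str
    surface_albedo: float
    solar_zenith_angle_deg: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.surface_albedo <= 1.0:
            raise ValueError(f"surface_albedo must lie in [0, 1], got {self.surface_albedo}")
        if self.total_ozone_column_du <= 0:
            raise ValueError("total_ozone_column_du must be positive")
        if self.horizontal_visibility_km <= 0:
            raise ValueError("horizontal_visibility_km must be positive")
        if self.aerosol_class not in AEROSOL_CLASSES:
            raise ValueError(
                f"aerosol_class must be one of {sorted(AEROSOL_CLASSES)}, "
                f"got {self.aerosol_class!r}"
            )
        if not 0.0 <= self.solar_zenith_angle_deg < 90.0:
            raise ValueError("solar_zenith_angle_deg must lie in [0, 90)")

    @property
    def mu0(self) -> float:
        """Cosine of the solar zenith angle."""
        return math.cos(math.radians(self.solar_zenith_angle_deg))


def optical_depths(wavelength_nm, state: AtmosphereState) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vertical optical depths (Rayleigh, ozone, aerosol) above the observer.

    Rayleigh scales with the barometric pressure ratio; ozone is linear in
    the column with a Gaussian Hartley-band cross-section (negligible above
    ~340 nm); aerosol comes from the visibility via Koschmieder at 550 nm
    and an Angstrom power law.
    """
    wl = np.asarray(wavelength_nm, dtype=float)
    pressure_ratio = math.exp(-state.altitude_m / PRESSURE_SCALE_HEIGHT_M)
    tau_ray = _RAYLEIGH_A * (wl / 1000.0) ** (-_RAYLEIGH_B) * pressure_ratio

    sigma = _O3_SIGMA_PEAK_CM2 * np.exp(-(((wl - _O3_PEAK_NM) / _O3_WIDTH_NM) ** 2))
    tau_o3 = sigma * state.total_ozone_column_du * _DU_TO_MOLEC_CM2

    cls = AEROSOL_CLASSES[state.aerosol_class]
    beta_550_per_km = cls["ext_factor"] * max(
        3.912 / state.horizontal_visibility_km - 0.0116, 0.0
    )
    tau_a_550 = beta_550_per_km * (AEROSOL_SCALE_HEIGHT_M / 1000.0)
    tau_aer = tau_a_550 * (wl / 550.0) ** (-cls["angstrom"])
    tau_aer = np.broadcast_to(np.asarray(tau_aer, float), wl.shape).copy()
    return tau_ray, tau_o3, tau_aer


def direct_horizontal_irradiance(state: AtmosphereState, grid: SpectralGrid) -> Spectrum:
    """Beer-Lambert direct-beam irradiance on a horizontal surface.

    E_dir(lambda) = E0(lambda) exp(-(tau_r + tau_o3 + tau_a)/mu0) * mu0.
    """
    tau_r, tau_o3, tau_a = optical_depths(grid.wavelengths, state)
    e0 = extraterrestrial_spectrum(grid).values
    mu0 = state.mu0
    vals = e0 * np.exp(-(tau_r + tau_o3 + tau_a) / mu0) * mu0
    return Spectrum(grid, vals, kind="irradiance")


def two_stream_layer(tau, omega, g, mu0) -> dict:
    """Delta-Eddington two-stream solution for one homogeneous layer.

    Collimated unit irradiance (normal to the beam) is incident at the top;
    the lower boundary is black.  Inputs broadcast elementwise.

    Returns a dict with, per wavelength/element:

    ``direct``        true direct transmission exp(-tau/mu0) (unscaled)
    ``diffuse_down``  downward diffuse flux at the bottom per unit
                      normal-beam irradiance, including the delta-scaled
                      forward peak folded back into the diffuse field
    ``reflect_top``   upward diffuse flux leaving the top
    ``s_atm``         spherical backscatter fraction of the layer for
                      diffuse illumination from below, in [0, 1)
    """
    tau = np.asarray(tau, dtype=float)
    omega = np.clip(np.asarray(omega, dtype=float), 1e-12, 1.0 - 1e-9)
    g = np.asarray(g, dtype=float)
    tau, omega, g = np.broadcast_arrays(tau, omega, g)

    # delta-Eddington scaling removes the forward diffraction peak
    f = g * g
    tau_s = (1.0 - omega * f) * tau
    om_s = (1.0 - f) * omega / (1.0 - omega * f)
    g_s = g / (1.0 + g)

    g1 = (7.0 - om_s * (4.0 + 3.0 * g_s)) / 4.0
    g2 = -(1.0 - om_s * (4.0 - 3.0 * g_s)) / 4.0
    g3 = (2.0 - 3.0 * g_s * mu0) / 4.0
    g4 = 1.0 - g3
    lam = np.sqrt(np.maximum(g1 * g1 - g2 * g2, 1e-24))
    big_gamma = g2 / (g1 + lam)

    # avoid the removable resonance lambda == 1/mu0
    mu = np.where(np.abs(lam - 1.0 / mu0) < 1e-6, mu0 * (1.0 + 1e-6), mu0)

    denom = lam * lam - 1.0 / mu**2
    a_part = om_s * ((g1 - 1.0 / mu) * g3 + g2 * g4) / denom
    b_part = om_s * ((g1 + 1.0 / mu) * g4 + g2 * g3) / denom

    exp_lam = np.exp(lam * tau_s)
    exp_beam = np.exp(-tau_s / mu)
    # boundary conditions: no diffuse down at the top, none up at the
    # (black) bottom
    k1 = (big_gamma * b_part / exp_lam - a_part * exp_beam) / (
        exp_lam - big_gamma**2 / exp_lam
    )
    k2 = -b_part - big_gamma * k1

    f_down_bottom = big_gamma * k1 * exp_lam + k2 / exp_lam + b_part * exp_beam
    f_up_top = k1 + big_gamma * k2 + a_part

    direct_true = np.exp(-tau / mu0)
    # forward peak removed by delta scaling re-enters as diffuse
    diffuse_down = f_down_bottom + mu0 * (exp_beam - direct_true)

    e2 = np.exp(-2.0 * lam * tau_s)
    s_atm = big_gamma * (1.0 - e2) / (1.0 - big_gamma**2 * e2)

    zero = tau <= 0
    return {
        "direct": np.where(zero, 1.0, direct_true),
        "diffuse_down": np.clip(np.where(zero, 0.0, diffuse_down), 0.0, None),
        "reflect_top": np.clip(np.where(zero, 0.0, f_up_top), 0.0, None),
        "s_atm": np.clip(np.where(zero, 0.0, s_atm), 0.0, 1.0 - 1e-12),
    }


def _mixture_optics(state: AtmosphereState, grid: SpectralGrid):
    """Combine Rayleigh + ozone + aerosol into layer (tau, omega, g)."""
    tau_r, tau_o3, tau_a = optical_depths(grid.wavelengths, state)
    cls = AEROSOL_CLASSES[state.aerosol_class]
    tau_tot = tau_r + tau_o3 + tau_a
    tau_sca = tau_r + cls["ssa"] * tau_a
    omega = np.where(tau_tot > 0, tau_sca / np.maximum(tau_tot, 1e-30), 0.0)
    g_mix = np.where(
        tau_sca > 0, cls["g"] * cls["ssa"] * tau_a / np.maximum(tau_sca, 1e-30), 0.0
    )
    return tau_tot, omega, g_mix


def two_stream_diffuse(state: AtmosphereState, grid: SpectralGrid) -> Tuple[Spectrum, np.ndarray]:
    """Diffuse downwelling irradiance for a black surface plus s_atm(lambda).

    Returns ``(E_diff_down, s_atm)`` where the diffuse irradiance excludes
    any surface reflection (albedo 0) and ``s_atm`` is the fraction of
    ground-reflected radiation the atmosphere scatters back down, used for
    the multiple-reflection enhancement.
    """
    tau_tot, omega, g_mix = _mixture_optics(state, grid)
    sol = two_stream_layer(tau_tot, omega, g_mix, state.mu0)
    e0 = extraterrestrial_spectrum(grid).values
    e_diff = e0 * sol["diffuse_down"]
    return Spectrum(grid, e_diff, kind="irradiance"), sol["s_atm"]


def albedo_enhancement(albedo: float, s_atm: np.ndarray) -> np.ndarray:
    """Geometric-series surface-atmosphere coupling factor 1/(1 - a*s).

    Raises for the nonphysical case ``albedo * s_atm >= 1``.
    """
    x = albedo * np.asarray(s_atm, dtype=float)
    if np.any(x >= 1.0):
        raise ValueError("albedo * s_atm >= 1 is nonphysical")
    return 1.0 / (1.0 - x)


def global_irradiance(state: AtmosphereState, grid: SpectralGrid) -> Spectrum:
    """Global downwelling spectral irradiance on a horizontal surface.

    E_glo = (E_dir + E_diff_black) / (1 - albedo * s_atm): the black-surface
    downwelling enhanced by every order of ground-atmosphere reflection.
    """
    e_dir = direct_horizontal_irradiance(state, grid)
    e_diff, s_atm = two_stream_diffuse(state, grid)
    enh = albedo_enhancement(state.surface_albedo, s_atm)
    return Spectrum(grid, (e_dir.values + e_diff.values) * enh, kind="irradiance")


@dataclass(frozen=True)
class SurfaceReflection:
    """Lambertian ground reflection bundle: E_up = albedo*E_glo, L_up = E_up/pi."""

    e_glo_down: Spectrum
    albedo: float
    e_up: Spectrum
    l_up: Spectrum


def upwelling_radiance(e_glo: Spectrum, albedo: float) -> Tuple[Spectrum, Spectrum]:
    """Reflected irradiance and constant Lambertian radiance of the ground.

    Returns ``(E_up, L_up)`` with E_up(lambda) = E_glo(lambda) * albedo and
    L_up(lambda) = E_up(lambda) / pi per steradian, independent of direction.
    """
    if not 0.0 <= albedo <= 1.0:
        raise ValueError(f"albedo must lie in [0, 1], got {albedo}")
    e_up = Spectrum(e_glo.grid, e_glo.values * albedo, kind="irradiance")
    l_up = Spectrum(e_glo.grid, e_up.values / math.pi, kind="radiance")
    return e_up, l_up


def surface_reflection(e_glo: Spectrum, albedo: float) -> SurfaceReflection:
    """Convenience constructor for :class:`SurfaceReflection`."""
    e_up, l_up = upwelling_radiance(e_glo, albedo)
    return SurfaceReflection(e_glo, albedo, e_up, l_up)


_SKY_MODELS = ("isotropic", "gradated")

# normalization of the gradated shape (1 + 2 cos(theta)):
# integral of (1+2cos) cos sin dtheta dphi over the upper hemisphere = 7 pi/3
_GRADATED_NORM = 7.0 * math.pi / 3.0


@dataclass(frozen=True)
class RadianceField:
    """Angularly resolved spectral radiance surrounding the body.

    Three components: a collimated direct beam (spectral irradiance normal
    to the beam plus its direction), a diffuse downwelling distribution
    integrating to ``diffuse_down_total`` over the upper hemisphere, and a
    direction-independent Lambertian upwelling radiance ``up``.

    Azimuth convention: degrees clockwise from +y (the default body-facing
    axis), so azimuth 0 puts the sun in front of a body facing +y.
    """

    grid: SpectralGrid
    direct_normal: Spectrum
    sun_zenith_deg: float
    sun_azimuth_deg: float
    diffuse_down_total: Spectrum
    up: Spectrum
    sky_model: str = "isotropic"

    def __post_init__(self) -> None:
        if self.sky_model not in _SKY_MODELS:
            raise ValueError(
                f"sky_model must be one of {_SKY_MODELS}, got {self.sky_model!r}"
            )
        if self.up.kind != "radiance":
            raise ValueError("up component must be a radiance spectrum")

    @property
    def sun_direction(self) -> np.ndarray:
        """Unit vector pointing from the body toward the sun."""
        z = math.radians(self.sun_zenith_deg)
        a = math.radians(self.sun_azimuth_deg)
        return np.array([math.sin(z) * math.sin(a), math.sin(z) * math.cos(a), math.cos(z)])

    def sky_shape(self, theta: np.ndarray) -> np.ndarray:
        """Radiance multiplier m(theta): L_down = m(theta) * E_diff(lambda).

        Integrates against cos(theta) dOmega to exactly 1 over the upper
        hemisphere for either sky model.
        """
        th = np.asarray(theta, dtype=float)
        if self.sky_model == "isotropic":
            shape = np.full_like(th, 1.0 / math.pi)
        else:
            shape = (1.0 + 2.0 * np.cos(th)) / _GRADATED_NORM
        return np.where(th < math.pi / 2.0, shape, 0.0)

    def diffuse_down(self, theta: float, phi: float) -> np.ndarray:
        """Spectral diffuse sky radiance from direction (theta, phi); zero
        below the horizon."""
        return float(self.sky_shape(np.asarray(theta))) * self.diffuse_down_total.values

    def upwelling(self, theta: float | None = None, phi: float | None = None) -> np.ndarray:
        """Spectral upwelling radiance; identical for every lower-hemisphere
        direction (Lambertian ground)."""
        return self.up.values

    @property
    def direct_horizontal(self) -> np.ndarray:
        """Direct-beam spectral irradiance on a horizontal surface."""
        return self.direct_normal.values * math.cos(math.radians(self.sun_zenith_deg))

    @property
    def global_horizontal(self) -> Spectrum:
        """Global (direct + diffuse) downwelling irradiance spectrum."""
        return Spectrum(
            self.grid,
            self.direct_horizontal + self.diffuse_down_total.values,
            kind="irradiance",
        )


def build_radiance_field(
    state: AtmosphereState,
    grid: SpectralGrid | None = None,
    sky_model: str = "isotropic",
    sun_azimuth_deg: float = 0.0,
) -> RadianceField:
    """Run the internal solver and assemble the full radiance field.

    The diffuse downwelling total includes the albedo multiple-reflection
    enhancement, so the field's global horizontal irradiance equals
    :func:`global_irradiance` for the same state.
    """
    if sky_model not in _SKY_MODELS:
        raise ValueError(f"sky_model must be one of {_SKY_MODELS}, got {sky_model!r}")
    if grid is None:
        grid = SpectralGrid.default()
    tau_tot, _, _ = _mixture_optics(state, grid)
    e0 = extraterrestrial_spectrum(grid).values
    direct_normal = Spectrum(grid, e0 * np.exp(-tau_tot / state.mu0), kind="irradiance")
    e_glo = global_irradiance(state, grid)
    e_dir_h = direct_normal.values * state.mu0
    diffuse_total = Spectrum(
        grid, np.clip(e_glo.values - e_dir_h, 0.0, None), kind="irradiance"
    )
    _, l_up = upwelling_radiance(e_glo, state.surface_albedo)
    return RadianceField(
        grid=grid,
        direct_normal=direct_normal,
        sun_zenith_deg=state.solar_zenith_angle_deg,
        sun_azimuth_deg=sun_azimuth_deg,
        diffuse_down_total=diffuse_total,
        up=l_up,
        sky_model=sky_model,
    )


def radiance_field_from_spectra(
    direct_normal: Spectrum,
    diffuse_down_total: Spectrum,
    albedo: float,
    sun_zenith_deg: float,
    sun_azimuth_deg: float = 0.0,
    sky_model: str = "isotropic",
) -> RadianceField:
    """Assemble a field from externally supplied spectra (e.g. accurate RT
    output read with :func:`uvbody.spectral.read_spectrum`), bypassing the
    internal solver.  The upwelling component follows from the Lambertian
    ground relations applied to the implied global irradiance.
    """
    grid = direct_normal.grid
    e_glo = Spectrum(
        grid,
        direct_normal.values * math.cos(math.radians(sun_zenith_deg))
        + diffuse_down_total.values,
        kind="irradiance",
    )
    _, l_up = upwelling_radiance(e_glo, albedo)
    return RadianceField(
        grid=grid,
        direct_normal=direct_normal,
        sun_zenith_deg=sun_zenith_deg,
        sun_azimuth_deg=sun_azimuth_deg,
        diffuse_down_total=diffuse_down_total,
        up=l_up,
        sky_model=sky_model,
    )
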