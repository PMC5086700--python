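"""Optical depths, two-stream solver, and Lambertian surface coupling."""

import math

import numpy as np
import pytest

from oracles import geometric_series, mc_layer_fluxes
from uvbody.atmosphere import (
    AEROSOL_CLASSES,
    AtmosphereState,
    albedo_enhancement,
    build_radiance_field,
    direct_horizontal_irradiance,
    global_irradiance,
    optical_depths,
    radiance_field_from_spectra,
    two_stream_diffuse,
    two_stream_layer,
    upwelling_radiance,
)
from uvbody.spectral import ERYTHEMAL, SpectralGrid, Spectrum, extraterrestrial_spectrum, weight_spectrum


def make_state(**overrides) -> AtmosphereState:
    defaults = dict(
        altitude_m=600.0,
        total_ozone_column_du=300.0,
        horizontal_visibility_km=20.0,
        aerosol_class="rural",
        surface_albedo=0.02,
        solar_zenith_angle_deg=45.0,
    )
    defaults.update(overrides)
    return AtmosphereState(**defaults)


class TestOpticalDepths:
    def test_rayleigh_vanishes_at_high_altitude(self):
        wl = np.array([305.0, 350.0])
        tau_lo, _, _ = optical_depths(wl, make_state(altitude_m=0.0))
        tau_hi, _, _ = optical_depths(wl, make_state(altitude_m=80_000.0))
        assert np.all(tau_hi < 1e-4 * tau_lo)

    def test_ozone_negligible_in_uva(self):
        wl = np.array([305.0, 400.0])
        _, tau_o3, _ = optical_depths(wl, make_state())
        assert tau_o3[1] < 1e-3 * tau_o3[0]

    def test_ozone_linear_in_column(self):
        wl = np.array([305.0])
        _, tau1, _ = optical_depths(wl, make_state(total_ozone_column_du=300.0))
        _, tau2, _ = optical_depths(wl, make_state(total_ozone_column_du=600.0))
        assert tau2 == pytest.approx(2.0 * tau1, rel=1e-12)

    def test_ozone_peaks_near_hartley_band(self):
        wl = np.array([255.0, 305.0, 340.0])
        _, tau_o3, _ = optical_depths(wl, make_state())
        assert tau_o3[0] > tau_o3[1] > tau_o3[2]

    def test_urban_aerosol_thicker_than_rural_at_equal_visibility(self):
        wl = np.array([310.0, 400.0])
        _, _, rural = optical_depths(wl, make_state(aerosol_class="rural"))
        _, _, urban = optical_depths(wl, make_state(aerosol_class="urban"))
        assert np.all(urban > rural)

    def test_aerosol_decreases_with_visibility(self):
        wl = np.array([310.0])
        _, _, hazy = optical_depths(wl, make_state(horizontal_visibility_km=10.0))
        _, _, clear = optical_depths(wl, make_state(horizontal_visibility_km=40.0))
        assert hazy > clear

    def test_all_depths_nonnegative(self, spectral_grid):
        for tau in optical_depths(spectral_grid.wavelengths, make_state()):
            assert np.all(tau >= 0)


class TestDirectBeam:
    def test_transparent_limit_recovers_cosine_law(self, spectral_grid):
        # extreme altitude + clean air: tau ~ 0 in the UV-A
        state = make_state(altitude_m=80_000.0, horizontal_visibility_km=1e6,
                           total_ozone_column_du=1e-6, solar_zenith_angle_deg=60.0)
        e_dir = direct_horizontal_irradiance(state, spectral_grid)
        e0 = extraterrestrial_spectrum(spectral_grid)
        idx = spectral_grid.wavelengths >= 350
        np.testing.assert_allclose(
            e_dir.values[idx], 0.5 * e0.values[idx], rtol=1e-3)

    def test_attenuation_strict_below_extraterrestrial(self, spectral_grid):
        state = make_state()
        e_dir = direct_horizontal_irradiance(state, spectral_grid)
        ceiling = extraterrestrial_spectrum(spectral_grid).values * state.mu0
        assert np.all(e_dir.values < ceiling)

    def test_more_ozone_means_less_uvb(self, spectral_grid):
        thin = direct_horizontal_irradiance(
            make_state(total_ozone_column_du=250.0), spectral_grid)
        thick = direct_horizontal_irradiance(
            make_state(total_ozone_column_du=400.0), spectral_grid)
        i305 = np.searchsorted(spectral_grid.wavelengths, 305.0)
        assert thick.values[i305] < thin.values[i305]

    def test_sun_below_horizon_rejected(self):
        with pytest.raises(ValueError):
            make_state(solar_zenith_angle_deg=90.0)


class TestTwoStream:
    def test_conservative_scattering_closes_energy(self):
        for tau in (0.1, 0.5, 2.0):
            for g in (0.0, 0.7):
                sol = two_stream_layer(tau, 1.0, g, 0.7071)
                total = (sol["direct"] * 0.7071 + sol["diffuse_down"]
                         + sol["reflect_top"])
                assert total == pytest.approx(0.7071, rel=1e-6)

    def test_pure_absorption_gives_no_diffuse(self):
        sol = two_stream_layer(1.0, 1e-12, 0.0, 0.8)
        assert sol["diffuse_down"] < 1e-10
        assert sol["reflect_top"] < 1e-10

    def test_direct_plus_diffuse_bounded_by_incident(self, spectral_grid):
        state = make_state()
        e_dir = direct_horizontal_irradiance(state, spectral_grid).values
        e_diff, _ = two_stream_diffuse(state, spectral_grid)
        incident = extraterrestrial_spectrum(spectral_grid).values * state.mu0
        assert np.all(e_dir + e_diff.values <= incident * (1 + 1e-9))

    @pytest.mark.parametrize(
        "label, tau, omega, g, phase",
        [
            ("pure_rayleigh", 0.3, 1.0, 0.0, "rayleigh"),
            # UV-like mixture: tau_ray 1.0 plus absorbing aerosol tau 0.3
            # (ssa 0.9, g 0.7) -> bulk omega 0.977, g 0.149
            ("rayleigh_plus_aerosol", 1.3, 1.27 / 1.3, 0.7 * 0.27 / 1.27, "hg"),
        ],
    )
    @pytest.mark.parametrize("albedo", [0.0, 0.6])
    def test_matches_photon_monte_carlo(self, label, tau, omega, g, phase, albedo):
        """Diffuse transmission within 5% of an independent photon-tracing
        Monte Carlo, with and without a bright Lambertian surface."""
        mu0 = math.cos(math.radians(45.0))
        sol = two_stream_layer(tau, omega, g, mu0)
        e_dir = float(sol["direct"]) * mu0
        s_atm = float(sol["s_atm"])
        e_glo = (e_dir + float(sol["diffuse_down"])) / (1.0 - albedo * s_atm)
        ts_diffuse = e_glo - e_dir
        mc = mc_layer_fluxes(tau, omega, g, mu0, albedo=albedo,
                             n_photons=150_000, seed=1234, phase=phase)
        assert ts_diffuse == pytest.approx(mc["diffuse_down"], rel=0.05)


class TestSurfaceCoupling:
    def test_enhancement_equals_geometric_series(self):
        s = np.array([0.1, 0.35, 0.6])
        enh = albedo_enhancement(0.6, s)
        expected = np.array([geometric_series(0.6 * x) for x in s])
        np.testing.assert_allclose(enh, expected, rtol=1e-12)

    def test_enhancement_rejects_runaway_reflection(self):
        with pytest.raises(ValueError):
            albedo_enhancement(1.0, np.array([1.0]))

    def test_black_surface_is_plain_sum(self, spectral_grid):
        state = make_state(surface_albedo=0.0)
        e_glo = global_irradiance(state, spectral_grid)
        e_dir = direct_horizontal_irradiance(state, spectral_grid)
        e_diff, _ = two_stream_diffuse(state, spectral_grid)
        np.testing.assert_allclose(
            e_glo.values, e_dir.values + e_diff.values, rtol=1e-12)

    def test_bright_surface_raises_global_everywhere(self, spectral_grid):
        dark = global_irradiance(make_state(surface_albedo=0.02), spectral_grid)
        bright = global_irradiance(make_state(surface_albedo=0.6), spectral_grid)
        # below ~290 nm the ozone Hartley band extinguishes the flux to
        # floating-point zero at both albedos; strict monotonicity applies
        # wherever any light survives
        assert np.all(bright.values >= dark.values)
        # strict increase wherever the atmosphere backscatters at all
        _, s_atm = two_stream_diffuse(make_state(), spectral_grid)
        lit = (s_atm > 1e-9) & (dark.values > 0)
        assert lit.any()
        assert np.all(bright.values[lit] > dark.values[lit])

    def test_upwelling_radiance_from_flat_spectrum(self, spectral_grid):
        e_glo = Spectrum(spectral_grid, np.full(len(spectral_grid), 100.0))
        e_up, l_up = upwelling_radiance(e_glo, 0.6)
        np.testing.assert_allclose(e_up.values, 60.0)
        np.testing.assert_allclose(l_up.values, 60.0 / math.pi)
        e_up0, l_up0 = upwelling_radiance(e_glo, 0.0)
        assert np.all(l_up0.values == 0.0)
        with pytest.raises(ValueError):
            upwelling_radiance(e_glo, 1.5)

    def test_hemisphere_integral_of_lambertian_radiance_recovers_exitance(
            self, spectral_grid):
        """Riemann sum of L_up cos(theta) dOmega on a 5x10 degree grid."""
        e_glo = global_irradiance(make_state(surface_albedo=0.6), spectral_grid)
        e_up, l_up = upwelling_radiance(e_glo, 0.6)
        th_edges = np.radians(np.arange(0, 91, 5.0))
        ph_edges = np.radians(np.arange(0, 361, 10.0))
        thc = 0.5 * (th_edges[:-1] + th_edges[1:])
        d_omega = np.outer(np.sin(thc) * np.diff(th_edges), np.diff(ph_edges))
        factor = float((np.cos(thc)[:, None] * d_omega).sum())
        np.testing.assert_allclose(factor * l_up.values, e_up.values, rtol=5e-3)


class TestRadianceField:
    @pytest.mark.parametrize("sky_model", ["isotropic", "gradated"])
    def test_sky_shape_normalised_to_diffuse_total(self, spectral_grid, sky_model):
        field = build_radiance_field(make_state(), spectral_grid, sky_model)
        th_edges = np.linspace(0, math.pi / 2, 37)
        ph_edges = np.linspace(0, 2 * math.pi, 73)
        thc = 0.5 * (th_edges[:-1] + th_edges[1:])
        d_omega = np.outer(np.sin(thc) * np.diff(th_edges), np.diff(ph_edges))
        integral = float((field.sky_shape(thc)[:, None] * np.cos(thc)[:, None]
                          * d_omega).sum())
        assert integral == pytest.approx(1.0, rel=5e-3)

    def test_upwelling_is_direction_independent(self, spectral_grid):
        field = build_radiance_field(make_state(surface_albedo=0.6), spectral_grid)
        a = field.upwelling(math.radians(95.0), 0.0)
        b = field.upwelling(math.radians(175.0), 2.0)
        np.testing.assert_array_equal(a, b)

    def test_bright_albedo_dominates_in_lower_hemisphere(self, spectral_grid):
        dark = build_radiance_field(make_state(surface_albedo=0.02), spectral_grid)
        bright = build_radiance_field(make_state(surface_albedo=0.6), spectral_grid)
        assert np.all(bright.up.values > dark.up.values)

    def test_unknown_sky_model_rejected(self, spectral_grid):
        with pytest.raises(ValueError):
            build_radiance_field(make_state(), spectral_grid, "mackerel")

    def test_field_from_external_spectra(self, spectral_grid):
        n = len(spectral_grid)
        field = radiance_field_from_spectra(
            direct_normal=Spectrum(spectral_grid, np.full(n, 10.0)),
            diffuse_down_total=Spectrum(spectral_grid, np.full(n, 40.0)),
            albedo=0.5,
            sun_zenith_deg=60.0,
        )
        # implied global: 10*cos60 + 40 = 45; L_up = 45*0.5/pi
        np.testing.assert_allclose(field.up.values, 22.5 / math.pi, rtol=1e-12)


class TestScenarioLevelMonotonicity:
    def test_mountain_air_transmits_more_erythemal_irradiance(self, spectral_grid):
        valley = make_state(altitude_m=600.0)
        mountain = make_state(altitude_m=2200.0)
        w_v = weight_spectrum(global_irradiance(valley, spectral_grid), ERYTHEMAL)
        w_m = weight_spectrum(global_irradiance(mountain, spectral_grid), ERYTHEMAL)
        assert w_m > w_v

    def test_urban_aerosol_reduces_erythemal_irradiance(self, spectral_grid):
        rural = make_state(aerosol_class="rural")
        urban = make_state(aerosol_class="urban")
        w_r = weight_spectrum(global_irradiance(rural, spectral_grid), ERYTHEMAL)
        w_u = weight_spectrum(global_irradiance(urban, spectral_grid), ERYTHEMAL)
        assert w_u < w_r


@pytest.mark.parametrize(
    "kwargs",
    [
        {"surface_albedo": -0.1},
        {"surface_albedo": 1.1},
        {"total_ozone_column_du": 0.0},
        {"horizontal_visibility_km": -5.0},
        {"aerosol_class": "volcanic"},
        {"solar_zenith_angle_deg": 95.0},
    ],
)
def test_state_validation(kwargs):
    with pytest.raises(ValueError):
        make_state(**kwargs)
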