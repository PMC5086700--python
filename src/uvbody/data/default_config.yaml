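# Reference valley/mountain experiment design.
# Two hypothetical sites at 47 deg N on 2016-03-31, SZA 45 deg:
# a snow-free valley (600 m) and a mountain top (2200 m) whose effective
# snow albedo is varied; winter clothing leaves only hands and face bare.
scenario:
  sza_deg: 45.0
  sun_azimuth_deg: 0.0        # degrees clockwise from +y; 0 = body faces the sun
  sky_model: isotropic
  latitude_deg: 47.0
  date: "2016-03-31"
  valley:
    altitude_m: 600
    ozone_DU: 300.0
    visibility_km: 20.0
    aerosol: rural
    albedo: 0.02
  mountain:
    altitude_m: 2200
    ozone_DU: 294.4
    visibility_km: 30.0
    aerosol: rural
    albedos: [0.02, 0.2, 0.4, 0.6]
body:
  height_m: 1.8
  voxel_size_m: 0.02
  facing_azimuth_deg: 0.0
clothing:
  name: winter
  exposed_parts: [face, hands]
angular_grid:
  n_zenith: 18                # per hemisphere (5 degree bins)
  n_azimuth: 36               # 10 degree bins
spectral_grid:
  step_nm: 1.0
action_spectrum: erythemal
sweeps:
  sza_deg: [45, 50, 55, 60, 65, 70, 75, 80, 85, 89]
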