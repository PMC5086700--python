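# Methods

This note records the model, its assumptions, the defaults that matter,
and the places where the design was genuinely open.

## Quantities and units

All spectral computation happens on a uniform wavelength grid covering
250–400 nm (default step 1 nm). Spectral irradiance is mW m⁻² nm⁻¹,
spectral radiance mW m⁻² nm⁻¹ sr⁻¹. Biological weighting uses the CIE
(1998) erythema reference action spectrum (plateau of 1 up to 298 nm,
then `10^(0.094(298−λ))` to 328 nm, then `10^(0.015(140−λ))` to
400 nm); other weightings can be registered by name. Spectral integrals
use trapezoidal quadrature; refining the grid from 1 nm to 0.25 nm
changes a smooth weighted integral by under 0.1 %, which is why 1 nm is
the default. *Exposure* is the weighted radiant power intercepted by
exposed skin (mW, instantaneous); dose would be its time integral and
is out of scope.

## Source spectrum

The top-of-atmosphere spectrum is a deterministic analytic surrogate: a
5778 K Planck curve diluted by the Sun–Earth geometry factor. It is
smooth, strictly positive and versioned in the repository
(`data/extraterrestrial_synthetic.txt`). No result reported by the
package depends on absolute top-of-atmosphere values — the scientific
outputs are ratios, gradients and closures — so a measured solar
spectrum is deliberately not bundled. Users can substitute accurate
radiative-transfer output through the plain-text spectral reader and
`radiance_field_from_spectra`.

## Atmosphere

A single effective layer holds three constituents above the observer
altitude *z*:

- **Rayleigh**: τ = 0.00877 (λ/µm)⁻⁴·⁰⁹ · exp(−z/8 km). The 8 km
  pressure scale height is conventional; only valley/mountain ratios
  matter.
- **Ozone**: a Gaussian Hartley-band cross-section (peak 1.1×10⁻¹⁷ cm²
  at 255 nm, width 24 nm), linear in the total column (DU). This
  reproduces the qualitative behaviour that matters here — strong
  absorption at 255–310 nm, negligible beyond ~340 nm — without a
  tabulated cross-section database. The valley/mountain column
  difference (300 vs 294.4 DU) carries the tropospheric-ozone altitude
  effect directly.
- **Aerosol**: Koschmieder extinction at 550 nm from the site-measured
  horizontal visibility, `β = f·(3.912/V − 0.0116)` km⁻¹, times a
  1.2 km scale height (the column is assumed exponential above the
  observer, anchored at the site, so no extra altitude factor is
  applied — visibility is a local observation). An Ångström power law
  extrapolates to the UV. Rural: exponent 1.3, single-scattering albedo
  0.96, f = 1; urban: exponent 1.1, SSA 0.90, f = 1.3 (more extinction
  per km of visual range, more absorption). Asymmetry g = 0.7 for both.

The diffuse field solves the delta-Eddington two-stream equations for
the mixed layer over a black surface (collimated incidence, the
forward-diffraction peak folded back into the diffuse transmission).
Surface–atmosphere multiple reflection enters as the exact geometric
series `E_glo = (E_dir + E_diff,black)/(1 − a·s_atm)`, where `s_atm(λ)`
is the layer's diffuse reflectance for illumination from below
(closed-form two-stream expression). Energy is conserved to machine
precision for conservative scattering, and the solver agrees with an
independent photon-tracing Monte Carlo (in `tests/oracles.py`) to
within 5 % for the configurations exercised in the tests; under strong
absorption the Eddington closure can drive its reflectance coefficient
slightly negative, which is clipped to zero (a known artifact,
irrelevant above ~300 nm).

Geometry is plane-parallel; SZA is capped below 90°, so sweeps to 89°
run in plane-parallel mode and grazing-sun values should be read as
qualitative. Clouds, multi-layer structure, polarization and
terrain-resolved albedo are out of scope; the ground is an infinite
Lambertian plane with one effective albedo.

## Sky radiance distribution

The angular shape of the diffuse sky is not constrained by the package's
targets, so two normalized options exist: isotropic (default,
L = E_diff/π) and a graded shape ∝ (1 + 2 cos θ). Both integrate back
to E_diff against cos θ over the hemisphere by construction, which is
the only property downstream code relies on.

## Body model

A parametric primitive assembly (sphere head r = 0.11 m; neck cylinder;
0.30×0.20×0.60 m torso box; arm/leg cylinders r = 0.05/0.08 m; hand
boxes 0.08×0.02×0.18 m; feet boxes), scaled to the configured height
(default 1.80 m) and rasterised at a 0.02 m voxel edge (~10⁴ surface
patches; halving the voxel changes total patch area by <2 %). The
figure stands on the ground plane facing +y (rotatable); by default the
sun azimuth coincides with the facing direction. Surface patches are
the axis-aligned faces between occupied and empty voxels (area =
voxel², outward normals). The "face" is the set of head patches whose
normal azimuth lies strictly within ±90° of the facing azimuth; winter
clothing exposes exactly {face, hands}. The published body model the
reference experiment used is not available, so absolute mW values here
embed this package's own geometry — comparisons should use ratios and
gradients, never absolute exposures.

## Exposure integration

Directions are discretised into zenith × azimuth bins (default 5°×10°,
648 bins per hemisphere, exact cosine-difference solid angles summing
to 4π). Per patch and bin the engine adds
`area·L·max(0,n·d)·ΔΩ·visible`, with the direct beam as a separate
delta-function term (never smeared over a bin). Doubling both angular
resolutions changes the result by <1 %. Visibility traces an
Amanatides–Woo DDA ray through the occupancy lattice from the patch
centre offset half a voxel along the normal (a documented constant
preventing self-intersection); the ground plane never occludes
upwelling radiance — the body floats above an infinite reflecting
plane — but the body shadows itself. Patch irradiance is a patch-centre
point sample; the grid-convergence property bounds the residual error.

Binary centre-sampled visibility on a staircase surface is accurate for
flat geometry but overestimates grazing transmission on curved voxel
surfaces; the analytic fixtures (`make_fixture`) therefore carry smooth
patch tilings (e.g. a Fibonacci tiling of the sphere with radial
normals and exact areas, ray origins offset √3 voxels to clear the
rasterisation's corner protrusions) so the closed-form oracles —
π·L·A for an unobstructed up-facing plate, 4πr²·πL for a convex sphere
in an isotropic field — are realised to their stated tolerances, while
the two-sphere fixture exercises genuine DDA occlusion.

## Scenarios and gradients

`ScenarioPair.default()` encodes the reference design: valley 600 m
(300 DU, 20 km visibility, rural or urban aerosol, albedo 0.02) vs
mountain 2200 m (294.4 DU, 30 km, rural, albedo 0.02/0.2/0.4/0.6),
SZA 45°, latitude/date as metadata tags. Gradients are
`((mountain/valley) − 1)/(Δaltitude/100 m)·100` in % per 100 m,
computed from unrounded internal values; the reference-table
reproduction in the tests feeds the published rounded values into the
same formula instead (the published table rounds inconsistently in one
urban cell, so only self-consistent cells are asserted numerically and
the urban variant is checked qualitatively: it lowers valley exposure
and therefore raises every gradient). The mountain states are
independent of the valley aerosol choice, as in the reference design.

With these defaults the internal model reproduces every qualitative
claim it targets: all mountain values exceed valley values; exposure
gradients exceed irradiance gradients at every albedo and every SZA in
the 45–89° sweep; both rise monotonically with albedo; the albedo-0.6
exposure gradient is more than 3× the irradiance gradient; and the
sweep's relative dispersion stays below 0.25. Absolute gradients differ
from the reference experiment's (which used a multi-stream DISORT
atmosphere and a different body), deliberately so: those numbers are
outside what a self-contained parameterized model can pin down.

## Problem sizes and determinism

Default runs use the 1 nm spectral grid, the 5°×10° angular grid and
the 0.02 m body (≈260 exposed winter patches), which keeps the full
five-site battery plus sweeps in the seconds-to-a-minute range on one
CPU. Everything is deterministic: identical configs yield byte-identical
CSVs (fixed float formatting, temp-then-rename writes), and the run
manifest records resolved parameters, package version and the checksum
of the bundled source spectrum. The only randomness anywhere is in the
test-suite Monte Carlo oracle, which is explicitly seeded.
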