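"""Independent oracles used by the test suite.

These deliberately avoid the package's own solution paths: a photon-tracing
Monte Carlo for single-layer radiative transfer, analytic ray-sphere
occlusion, fine-grid adaptive quadrature, and explicit series summation.
"""

from __future__ import annotations

import math

import numpy as np


def mc_layer_fluxes(
    tau: float,
    omega: float,
    g: float,
    mu0: float,
    albedo: float = 0.0,
    n_photons: int = 200_000,
    seed: int = 0,
    phase: str = "hg",
) -> dict:
    """Photon Monte Carlo for one homogeneous plane-parallel layer.

    A collimated beam of unit normal irradiance enters the top with zenith
    cosine ``mu0``.  Scattering uses a Henyey-Greenstein phase function of
    asymmetry ``g`` (``phase="rayleigh"`` samples the Rayleigh phase
    function instead and ignores ``g``).  The lower boundary reflects
    Lambertian with the given albedo.  Returns horizontal fluxes at the
    boundaries per unit incident *normal-beam* irradiance, i.e. directly
    comparable with ``uvbody.atmosphere.two_stream_layer`` scaled by E0=1:

    ``direct``        never-scattered flux through the bottom
    ``diffuse_down``  scattered (or surface-bounced) downward flux through
                      the bottom, summed over every crossing
    ``reflect_top``   diffuse flux escaping through the top
    """
    rng = np.random.default_rng(seed)
    n = int(n_photons)
    # direction unit vectors; z component positive downward
    u = np.zeros((n, 3))
    u[:, 2] = mu0
    u[:, 0] = math.sqrt(max(0.0, 1.0 - mu0 * mu0))
    t = np.zeros(n)  # vertical optical depth position, 0 = top
    nscat = np.zeros(n, dtype=np.int64)
    alive = np.ones(n, dtype=bool)

    down_direct = 0.0
    down_diffuse = 0.0
    up_top = 0.0

    for _ in range(100_000):
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            break
        s = rng.exponential(size=idx.size)
        tn = t[idx] + s * u[idx, 2]

        going_down = u[idx, 2] > 0
        hit_bottom = going_down & (tn >= tau)
        hit_top = (~going_down) & (tn <= 0.0)
        scatter = ~(hit_bottom | hit_top)

        # bottom crossings
        b = idx[hit_bottom]
        first_pass = nscat[b] == 0
        down_direct += int(first_pass.sum())
        down_diffuse += int((~first_pass).sum())
        if albedo > 0.0 and b.size:
            keep = rng.random(b.size) < albedo
            kb = b[keep]
            t[kb] = tau
            # Lambertian reflection: cosine-weighted upward direction
            mu_r = np.sqrt(rng.random(kb.size))
            phi_r = 2.0 * math.pi * rng.random(kb.size)
            sin_r = np.sqrt(1.0 - mu_r * mu_r)
            u[kb, 0] = sin_r * np.cos(phi_r)
            u[kb, 1] = sin_r * np.sin(phi_r)
            u[kb, 2] = -mu_r
            nscat[kb] += 1
            alive[b[~keep]] = False
        else:
            alive[b] = False

        # top escapes
        tp = idx[hit_top]
        up_top += tp.size
        alive[tp] = False

        # volume scattering events
        sc = idx[scatter]
        if sc.size:
            t[sc] = tn[scatter]
            survive = rng.random(sc.size) < omega
            alive[sc[~survive]] = False
            sv = sc[survive]
            if sv.size:
                if phase == "hg" and abs(g) > 1e-8:
                    xi = rng.random(sv.size)
                    frac = (1.0 - g * g) / (1.0 - g + 2.0 * g * xi)
                    mu_s = (1.0 + g * g - frac * frac) / (2.0 * g)
                elif phase == "rayleigh":
                    # rejection sampling of (3/8)(1 + cos^2)
                    mu_s = np.empty(sv.size)
                    todo = np.arange(sv.size)
                    while todo.size:
                        cand = rng.uniform(-1.0, 1.0, todo.size)
                        acc = rng.random(todo.size) < (1.0 + cand * cand) / 2.0
                        mu_s[todo[acc]] = cand[acc]
                        todo = todo[~acc]
                else:  # isotropic
                    mu_s = rng.uniform(-1.0, 1.0, sv.size)
                mu_s = np.clip(mu_s, -1.0, 1.0)
                phi_s = 2.0 * math.pi * rng.random(sv.size)
                u[sv] = _rotate_directions(u[sv], mu_s, phi_s)
                nscat[sv] += 1

    scale = mu0 / n  # each photon carries mu0/n of horizontal flux
    return {
        "direct": down_direct * scale,
        "diffuse_down": down_diffuse * scale,
        "reflect_top": up_top * scale,
    }


def _rotate_directions(u: np.ndarray, cos_theta: np.ndarray, phi: np.ndarray) -> np.ndarray:
    """Rotate unit vectors ``u`` by scattering angle (cos_theta, phi)."""
    sin_theta = np.sqrt(np.clip(1.0 - cos_theta**2, 0.0, 1.0))
    uz = u[:, 2]
    near_pole = np.abs(uz) > 0.999999
    denom = np.sqrt(np.clip(1.0 - uz * uz, 1e-24, None))
    new = np.empty_like(u)
    new[:, 0] = (
        sin_theta * (u[:, 0] * uz * np.cos(phi) - u[:, 1] * np.sin(phi)) / denom
        + u[:, 0] * cos_theta
    )
    new[:, 1] = (
        sin_theta * (u[:, 1] * uz * np.cos(phi) + u[:, 0] * np.sin(phi)) / denom
        + u[:, 1] * cos_theta
    )
    new[:, 2] = -sin_theta * np.cos(phi) * denom + uz * cos_theta
    # polar special case: rotate about an arbitrary horizontal axis
    pole = np.flatnonzero(near_pole)
    if pole.size:
        sign = np.sign(uz[pole])
        new[pole, 0] = sin_theta[pole] * np.cos(phi[pole])
        new[pole, 1] = sin_theta[pole] * np.sin(phi[pole])
        new[pole, 2] = sign * cos_theta[pole]
    norm = np.linalg.norm(new, axis=1, keepdims=True)
    return new / norm


def ray_hits_sphere(origin: np.ndarray, direction: np.ndarray,
                    center: np.ndarray, radius: float) -> bool:
    """True if the ray origin + s*direction (s > 0) intersects the sphere."""
    oc = np.asarray(origin, float) - np.asarray(center, float)
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    b = float(np.dot(oc, d))
    c = float(np.dot(oc, oc)) - radius * radius
    disc = b * b - c
    if disc < 0:
        return False
    s = -b - math.sqrt(disc)
    return s > 1e-12 or (-b + math.sqrt(disc)) > 1e-12 and c < 0


def geometric_series(x: float, n_terms: int = 200) -> float:
    """Explicit partial sum of sum_k x^k (surface-atmosphere bounces)."""
    return float(sum(x**k for k in range(n_terms)))
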