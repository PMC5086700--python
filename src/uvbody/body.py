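"""Voxel human model, clothing masks and surface-patch extraction.

The body is a parametric assembly of labelled primitives — sphere head,
cylinder neck/torso-limbs, boxes for hands and feet — rasterised onto a
boolean occupancy lattice (default voxel edge 0.02 m, ~10^4 surface
patches).  The figure stands upright, arms at the sides, feet on the
ground plane z = 0, facing the +y axis by default (rotatable via
``facing_azimuth_deg``, degrees clockwise from +y).

Surface patches are the axis-aligned faces between occupied and empty
voxels; each carries its outward normal, area (voxel_size^2), the part
label of its voxel, and an exposed flag derived from the clothing
configuration.  The "face" is the half of the head whose patch normals
point within +-90 degrees (strictly) of the facing azimuth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterator, Sequence

import numpy as np

__all__ = [
    "PART_LABELS",
    "ClothingConfig",
    "WINTER",
    "UNCLOTHED",
    "VoxelBody",
    "BodyPatch",
    "PatchSet",
    "make_voxel_human",
    "apply_clothing",
    "extract_patches",
    "make_fixture",
    "export_obj",
]

#: Voxel part labels (codes are the array values in ``VoxelBody.labels``).
PART_LABELS = ("head", "torso", "arms", "hands", "legs", "feet")
_PART_CODE = {name: i + 1 for i, name in enumerate(PART_LABELS)}
_CODE_PART = {v: k for k, v in _PART_CODE.items()}
#: Patch-level labels: voxel parts plus the derived front-of-head "face".
PATCH_PARTS = PART_LABELS + ("face",)


@dataclass(frozen=True)
class ClothingConfig:
    """Named set of exposed (bare-skin) part labels."""

    name: str
    exposed_parts: frozenset

    def __post_init__(self) -> None:
        unknown = set(self.exposed_parts) - set(PATCH_PARTS)
        if unknown:
            raise ValueError(f"unknown part labels in clothing: {sorted(unknown)}")
        object.__setattr__(self, "exposed_parts", frozenset(self.exposed_parts))


#: Winter clothing: only hands and the face are bare.
WINTER = ClothingConfig("winter", frozenset({"face", "hands"}))
#: Fully exposed body (reference configuration).
UNCLOTHED = ClothingConfig("unclothed", frozenset(PATCH_PARTS))


@dataclass
class VoxelBody:
    """Boolean occupancy lattice with per-voxel part labels.

    ``origin`` is the world position of the lattice corner (voxel [0,0,0]
    spans origin .. origin + voxel_size).  ``analytic_volume`` /
    ``analytic_area`` carry the closed-form volume/surface of the
    generating primitive assembly for verification.
    """

    occupancy: np.ndarray
    labels: np.ndarray
    voxel_size: float
    origin: np.ndarray
    facing_azimuth_deg: float = 0.0
    clothing: ClothingConfig | None = None
    analytic_volume: float | None = None
    analytic_area: float | None = None
    patch_filter: Callable[["PatchSet"], np.ndarray] | None = None
    patch_override: "PatchSet | None" = None

    @property
    def height(self) -> float:
        """Vertical extent of the occupied region (m)."""
        zs = np.flatnonzero(self.occupancy.any(axis=(0, 1)))
        if zs.size == 0:
            return 0.0
        return float((zs[-1] - zs[0] + 1) * self.voxel_size)

    @property
    def n_occupied(self) -> int:
        return int(self.occupancy.sum())

    @property
    def volume(self) -> float:
        """Total occupied volume (m^3)."""
        return self.n_occupied * self.voxel_size**3

    @property
    def part_names(self) -> set:
        codes = np.unique(self.labels[self.occupancy])
        return {_CODE_PART[int(c)] for c in codes if int(c) in _CODE_PART}

    @property
    def facing_direction(self) -> np.ndarray:
        a = math.radians(self.facing_azimuth_deg)
        return np.array([math.sin(a), math.cos(a), 0.0])


@dataclass(frozen=True)
class BodyPatch:
    """One axis-aligned surface facet of the voxel body."""

    center: np.ndarray
    normal: np.ndarray
    area: float
    part: str
    exposed: bool


class PatchSet(Sequence):
    """Array-backed collection of :class:`BodyPatch` facets.

    Iterating or indexing yields :class:`BodyPatch`; the array attributes
    (``centers``, ``normals``, ``areas``, ``parts``, ``exposed``) serve the
    vectorised exposure engine.
    """

    #: Shadow-ray origin offset along the patch normal, in voxels.  Half a
    #: voxel puts the origin at the centre of the empty neighbour of a
    #: voxel face; analytic fixture tilings raise it to sqrt(3) so ray
    #: origins clear the corner protrusions (<= sqrt(3)/2 voxel) of their
    #: own rasterised smooth surface, preserving convex full visibility.
    offset_voxels: float = 0.5

    def __init__(self, centers, normals, areas, parts, exposed, voxel_size, origin,
                 offset_voxels: float = 0.5):
        self.centers = np.asarray(centers, dtype=float)
        self.normals = np.asarray(normals, dtype=float)
        self.areas = np.asarray(areas, dtype=float)
        self.parts = np.asarray(parts)
        self.exposed = np.asarray(exposed, dtype=bool)
        self.voxel_size = float(voxel_size)
        self.origin = np.asarray(origin, dtype=float)
        self.offset_voxels = float(offset_voxels)
        n = len(self.areas)
        if not (len(self.centers) == len(self.normals) == len(self.parts)
                == len(self.exposed) == n):
            raise ValueError("patch arrays must share a length")

    def __len__(self) -> int:
        return len(self.areas)

    def __getitem__(self, i):
        if isinstance(i, (int, np.integer)):
            return BodyPatch(self.centers[i], self.normals[i], float(self.areas[i]),
                             str(self.parts[i]), bool(self.exposed[i]))
        return PatchSet(self.centers[i], self.normals[i], self.areas[i],
                        self.parts[i], self.exposed[i], self.voxel_size, self.origin,
                        self.offset_voxels)

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    @property
    def exposed_area(self) -> float:
        return float(self.areas[self.exposed].sum())

    def ray_starts_voxel(self) -> np.ndarray:
        """Ray origins in voxel coordinates, offset half a voxel outward
        along each normal (prevents self-intersection of shadow rays)."""
        world = self.centers + self.offset_voxels * self.voxel_size * self.normals
        return (world - self.origin) / self.voxel_size


# ---------------------------------------------------------------------------
# primitive rasterisation

def _human_primitives(height: float):
    """Labelled primitives in a canonical 1.8 m frame, scaled to ``height``.

    Returns (primitive list, analytic volume, analytic area); volumes and
    areas are the closed-form sums over primitives (overlaps at the joints
    are a few percent and are absorbed by the verification tolerances).
    """
    s = height / 1.8

    prims = []

    def sphere(part, cx, cy, cz, r):
        prims.append(("sphere", part, (cx * s, cy * s, cz * s, r * s),
                      4.0 / 3.0 * math.pi * (r * s) ** 3,
                      4.0 * math.pi * (r * s) ** 2))

    def cyl_z(part, cx, cy, z0, z1, r):
        h = (z1 - z0) * s
        rr = r * s
        prims.append(("cyl", part, (cx * s, cy * s, z0 * s, z1 * s, rr),
                      math.pi * rr**2 * h,
                      2.0 * math.pi * rr * h + 2.0 * math.pi * rr**2))

    def box(part, x0, x1, y0, y1, z0, z1):
        dx, dy, dz = (x1 - x0) * s, (y1 - y0) * s, (z1 - z0) * s
        prims.append(("box", part,
                      (x0 * s, x1 * s, y0 * s, y1 * s, z0 * s, z1 * s),
                      dx * dy * dz,
                      2.0 * (dx * dy + dx * dz + dy * dz)))

    sphere("head", 0.0, 0.0, 1.69, 0.11)
    cyl_z("torso", 0.0, 0.0, 1.45, 1.60, 0.05)          # neck
    box("torso", -0.15, 0.15, -0.10, 0.10, 0.85, 1.45)
    for sx in (-1.0, 1.0):
        cyl_z("arms", sx * 0.19, 0.0, 0.85, 1.43, 0.05)
        box("hands", sx * 0.19 - 0.04, sx * 0.19 + 0.04, -0.01, 0.01, 0.67, 0.85)
        cyl_z("legs", sx * 0.09, 0.0, 0.06, 0.90, 0.08)
        box("feet", sx * 0.09 - 0.05, sx * 0.09 + 0.05, -0.10, 0.15, 0.0, 0.06)

    volume = sum(p[3] for p in prims)
    area = sum(p[4] for p in prims)
    return prims, volume, area


def _rasterise(prims, voxel_size: float, margin_voxels: int = 1):
    """Voxelise a primitive list onto a lattice with an empty margin."""
    xs, ys, zlo, zhi = [], [], 0.0, 0.0
    for kind, _, p, _, _ in prims:
        if kind == "sphere":
            cx, cy, cz, r = p
            xs += [cx - r, cx + r]; ys += [cy - r, cy + r]
            zlo = min(zlo, cz - r); zhi = max(zhi, cz + r)
        elif kind == "cyl":
            cx, cy, z0, z1, r = p
            xs += [cx - r, cx + r]; ys += [cy - r, cy + r]
            zlo = min(zlo, z0); zhi = max(zhi, z1)
        else:
            x0, x1, y0, y1, z0, z1 = p
            xs += [x0, x1]; ys += [y0, y1]
            zlo = min(zlo, z0); zhi = max(zhi, z1)

    v = voxel_size
    m = margin_voxels
    ox = math.floor(min(xs) / v) * v - m * v
    oy = math.floor(min(ys) / v) * v - m * v
    oz = math.floor(zlo / v) * v - m * v
    nx = int(math.ceil((max(xs) - ox) / v)) + m
    ny = int(math.ceil((max(ys) - oy) / v)) + m
    nz = int(math.ceil((zhi - oz) / v)) + m

    cx = ox + (np.arange(nx) + 0.5) * v
    cy = oy + (np.arange(ny) + 0.5) * v
    cz = oz + (np.arange(nz) + 0.5) * v
    X = cx[:, None, None]
    Y = cy[None, :, None]
    Z = cz[None, None, :]

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    for kind, part, p, _, _ in prims:
        if kind == "sphere":
            scx, scy, scz, r = p
            mask = (X - scx) ** 2 + (Y - scy) ** 2 + (Z - scz) ** 2 <= r * r
        elif kind == "cyl":
            scx, scy, z0, z1, r = p
            mask = ((X - scx) ** 2 + (Y - scy) ** 2 <= r * r) & (Z >= z0) & (Z <= z1)
        else:
            x0, x1, y0, y1, z0, z1 = p
            mask = (X >= x0) & (X <= x1) & (Y >= y0) & (Y <= y1) & (Z >= z0) & (Z <= z1)
        labels[(labels == 0) & mask] = _PART_CODE[part]

    return labels, np.array([ox, oy, oz])


def make_voxel_human(height: float = 1.8, voxel_size: float = 0.02,
                     facing_azimuth_deg: float = 0.0) -> VoxelBody:
    """Deterministic standing voxel human, arms at the sides.

    ``voxel_size`` must resolve the body (<= height/50).  All six part
    labels are present; the feet rest on the ground plane z = 0.
    """
    if height <= 0:
        raise ValueError("height must be positive")
    if voxel_size > height / 50.0:
        raise ValueError(
            f"voxel_size {voxel_size} too coarse for height {height}; "
            f"need <= height/50 = {height / 50.0:g} m"
        )
    prims, volume, area = _human_primitives(height)
    labels, origin = _rasterise(prims, voxel_size)
    # pin the feet to the ground plane: drop empty layers below the body
    occ = labels > 0
    z_first = int(np.flatnonzero(occ.any(axis=(0, 1)))[0])
    origin = origin.copy()
    origin[2] -= origin[2] + z_first * voxel_size  # lowest occupied layer at z=0
    return VoxelBody(
        occupancy=occ,
        labels=labels,
        voxel_size=voxel_size,
        origin=origin,
        facing_azimuth_deg=facing_azimuth_deg,
        analytic_volume=volume,
        analytic_area=area,
    )


def apply_clothing(body: VoxelBody, clothing: ClothingConfig) -> VoxelBody:
    """Return the body wearing ``clothing``; exposed flags materialise on
    extraction.  Unknown part labels raise."""
    unknown = set(clothing.exposed_parts) - set(PATCH_PARTS)
    if unknown:
        raise ValueError(f"clothing references unknown parts: {sorted(unknown)}")
    return replace(body, clothing=clothing)


_FACE_NORMALS = np.array([
    [1, 0, 0], [-1, 0, 0],
    [0, 1, 0], [0, -1, 0],
    [0, 0, 1], [0, 0, -1],
], dtype=float)
_SHIFTS = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]


def extract_patches(body: VoxelBody) -> PatchSet:
    """Oriented surface facets of the body (occupied faces touching empty).

    Patches tile the voxel surface exactly; normals point from occupied to
    empty.  Part labels come from the owning voxel, with head patches on
    the facing side relabelled "face"; the exposed flag follows the body's
    clothing (everything exposed when unclothed/None).

    Fixtures carrying an analytic patch tiling (``patch_override``) return
    it directly: those patches sample the smooth generating surface and
    exist to realise closed-form oracles exactly.
    """
    if body.patch_override is not None:
        return body.patch_override
    occ = body.occupancy
    v = body.voxel_size
    centers, normals, parts = [], [], []
    for (dx, dy, dz), nrm in zip(_SHIFTS, _FACE_NORMALS):
        neighbour = np.zeros_like(occ)
        src = [slice(None)] * 3
        dst = [slice(None)] * 3
        for ax, d in enumerate((dx, dy, dz)):
            if d == 1:
                src[ax] = slice(1, None); dst[ax] = slice(None, -1)
            elif d == -1:
                src[ax] = slice(None, -1); dst[ax] = slice(1, None)
        neighbour[tuple(dst)] = occ[tuple(src)]
        face = occ & ~neighbour
        idx = np.argwhere(face)
        if idx.size == 0:
            continue
        # face centre: voxel centre pushed half a voxel along the normal
        c = body.origin + (idx + 0.5) * v + 0.5 * v * nrm
        centers.append(c)
        normals.append(np.tile(nrm, (len(idx), 1)))
        parts.append(np.array([_CODE_PART[int(code)]
                               for code in body.labels[tuple(idx.T)]], dtype=object))

    centers = np.concatenate(centers)
    normals = np.concatenate(normals)
    parts = np.concatenate(parts).astype(str)
    areas = np.full(len(parts), v * v)

    # front half of the head becomes the face: normal azimuth strictly
    # within +-90 degrees of the facing azimuth
    is_head = parts == "head"
    facing = body.facing_direction
    frontal = normals @ facing > 1e-12
    parts = np.where(is_head & frontal, "face", parts)

    if body.clothing is None:
        exposed = np.ones(len(parts), dtype=bool)
    else:
        allowed = body.clothing.exposed_parts
        exposed = np.array([p in allowed for p in parts], dtype=bool)

    ps = PatchSet(centers, normals, areas, parts, exposed, v, body.origin)
    if body.patch_filter is not None:
        ps.exposed = ps.exposed & body.patch_filter(ps)
    return ps


# ---------------------------------------------------------------------------
# analytic fixtures for the exposure-engine oracles

def make_fixture(name: str, **params) -> VoxelBody:
    """Analytic oracle geometries: ``sphere``, ``plate`` or ``two_spheres``.

    sphere(radius, voxel_size, analytic_patches=True)
        Convex body for the closed-form isotropic-field oracle; every
        patch exposed.  By default the patch set samples the smooth sphere
        itself (Fibonacci tiling, radial normals, areas summing to exactly
        4 pi r^2) so the pi*L closure per unit area is realised without
        staircase discretisation error; pass ``analytic_patches=False``
        for the raw voxel-face patches (e.g. staircase-area studies).
    plate(size, voxel_size, z)
        One-voxel-thick horizontal slab modelling an unobstructed
        horizontal sensor: only the up-facing patches are exposed, so the
        received power obeys the pi*L*A closure exactly.
    two_spheres(radius, separation, voxel_size)
        Two spheres stacked along z (centre-to-centre ``separation``); the
        upper sphere occludes part of the sky from the lower one.
    """
    if name == "sphere":
        r = params.get("radius", 0.3)
        v = params.get("voxel_size", 0.015)
        analytic = params.get("analytic_patches", True)
        n_patches = params.get("n_patches", 4000)
        center = np.array([0.0, 0.0, r + 2 * v])
        prims = [("sphere", "torso", (0.0, 0.0, center[2], r),
                  4 / 3 * math.pi * r**3, 4 * math.pi * r**2)]
        labels, origin = _rasterise(prims, v)
        body = VoxelBody(labels > 0, labels, v, origin,
                         analytic_volume=prims[0][3], analytic_area=prims[0][4])
        if analytic:
            normals = _fibonacci_sphere(n_patches)
            centers = center[None, :] + r * normals
            areas = np.full(n_patches, 4.0 * math.pi * r * r / n_patches)
            parts = np.full(n_patches, "torso", dtype=object)
            body.patch_override = PatchSet(
                centers, normals, areas, parts,
                np.ones(n_patches, dtype=bool), v, origin,
                offset_voxels=math.sqrt(3.0),
            )
        return body
    if name == "plate":
        size = params.get("size", 1.0)
        v = params.get("voxel_size", 0.02)
        z0 = params.get("z", 0.5)
        prims = [("box", "torso", (-size / 2, size / 2, -size / 2, size / 2,
                                   z0, z0 + v), size * size * v,
                  2 * size * size + 4 * size * v)]
        labels, origin = _rasterise(prims, v)
        body = VoxelBody(labels > 0, labels, v, origin,
                         analytic_volume=prims[0][3], analytic_area=prims[0][4])
        body.patch_filter = lambda ps: ps.normals[:, 2] > 0.5
        return body
    if name == "two_spheres":
        r = params.get("radius", 0.2)
        sep = params.get("separation", 0.5)
        v = params.get("voxel_size", 0.02)
        z_low = r + 2 * v
        prims = [
            ("sphere", "torso", (0.0, 0.0, z_low, r), 4 / 3 * math.pi * r**3,
             4 * math.pi * r**2),
            ("sphere", "head", (0.0, 0.0, z_low + sep, r), 4 / 3 * math.pi * r**3,
             4 * math.pi * r**2),
        ]
        labels, origin = _rasterise(prims, v)
        return VoxelBody(labels > 0, labels, v, origin,
                         analytic_volume=sum(p[3] for p in prims),
                         analytic_area=sum(p[4] for p in prims))
    raise ValueError(f"unknown fixture {name!r}")


def _fibonacci_sphere(n: int) -> np.ndarray:
    """Near-uniform unit vectors on the sphere (golden-spiral lattice)."""
    i = np.arange(n) + 0.5
    z = 1.0 - 2.0 * i / n
    rho = np.sqrt(np.clip(1.0 - z * z, 0.0, 1.0))
    phi = math.pi * (1.0 + math.sqrt(5.0)) * i
    return np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])


def export_obj(body: VoxelBody, path) -> None:
    """Write the surface patch set as a triangulated Wavefront OBJ."""
    ps = extract_patches(body)
    h = ps.voxel_size / 2.0
    lines = ["# uvbody voxel surface export"]
    for c, n in zip(ps.centers, ps.normals):
        ax = int(np.argmax(np.abs(n)))
        u = np.zeros(3); u[(ax + 1) % 3] = h
        w = np.zeros(3); w[(ax + 2) % 3] = h
        for corner in (c - u - w, c + u - w, c + u + w, c - u + w):
            lines.append(f"v {corner[0]:.5f} {corner[1]:.5f} {corner[2]:.5f}")
    for i in range(len(ps)):
        b = 4 * i + 1
        lines.append(f"f {b} {b+1} {b+2}")
        lines.append(f"f {b} {b+2} {b+3}")
    Path(path).write_text("\n".join(lines) + "\n")
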