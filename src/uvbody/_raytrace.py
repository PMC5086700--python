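"""Voxel-grid ray traversal for self-shadowing.

Amanatides-Woo 3-D DDA through the occupancy lattice, JIT-compiled with
numba when available (a pure-Python fallback keeps the package importable
without it, at reduced speed).  All coordinates are in voxel units with
the grid spanning [0, n) along each axis.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True)
def _ray_blocked(occ, ox, oy, oz, dx, dy, dz):
    """True if a ray from (ox,oy,oz) along (dx,dy,dz) hits an occupied voxel."""
    nx, ny, nz = occ.shape
    big = 1e30

    ix = int(np.floor(ox))
    iy = int(np.floor(oy))
    iz = int(np.floor(oz))

    step_x = 1 if dx > 0 else -1
    step_y = 1 if dy > 0 else -1
    step_z = 1 if dz > 0 else -1

    if dx != 0.0:
        t_delta_x = abs(1.0 / dx)
        nxt = ix + 1 if dx > 0 else ix
        t_max_x = (nxt - ox) / dx
    else:
        t_delta_x = big
        t_max_x = big
    if dy != 0.0:
        t_delta_y = abs(1.0 / dy)
        nxt = iy + 1 if dy > 0 else iy
        t_max_y = (nxt - oy) / dy
    else:
        t_delta_y = big
        t_max_y = big
    if dz != 0.0:
        t_delta_z = abs(1.0 / dz)
        nxt = iz + 1 if dz > 0 else iz
        t_max_z = (nxt - oz) / dz
    else:
        t_delta_z = big
        t_max_z = big

    while 0 <= ix < nx and 0 <= iy < ny and 0 <= iz < nz:
        if occ[ix, iy, iz]:
            return True
        if t_max_x <= t_max_y and t_max_x <= t_max_z:
            ix += step_x
            t_max_x += t_delta_x
        elif t_max_y <= t_max_z:
            iy += step_y
            t_max_y += t_delta_y
        else:
            iz += step_z
            t_max_z += t_delta_z
    return False


@njit(cache=True)
def visibility_matrix_kernel(occ, starts, dirs, relevant, out):
    """Fill out[p, d] = ray from starts[p] toward dirs[d] escapes the grid.

    ``relevant`` masks (patch, direction) pairs worth tracing (positive
    incidence cosine); others stay False.
    """
    n_p = starts.shape[0]
    n_d = dirs.shape[0]
    for p in range(n_p):
        for d in range(n_d):
            if relevant[p, d]:
                out[p, d] = not _ray_blocked(
                    occ,
                    starts[p, 0], starts[p, 1], starts[p, 2],
                    dirs[d, 0], dirs[d, 1], dirs[d, 2],
                )


def visibility_matrix(occ: np.ndarray, starts: np.ndarray, dirs: np.ndarray,
                      relevant: np.ndarray | None = None) -> np.ndarray:
    """Visibility of each direction from each ray start, through ``occ``.

    Parameters are in voxel coordinates; ``occ`` is a boolean occupancy
    lattice.  Returns a boolean (n_starts, n_dirs) matrix.
    """
    occ8 = np.ascontiguousarray(occ.astype(np.uint8))
    starts = np.ascontiguousarray(starts, dtype=np.float64)
    dirs = np.ascontiguousarray(dirs, dtype=np.float64)
    if relevant is None:
        relevant = np.ones((starts.shape[0], dirs.shape[0]), dtype=bool)
    out = np.zeros((starts.shape[0], dirs.shape[0]), dtype=bool)
    visibility_matrix_kernel(occ8, starts, dirs, np.ascontiguousarray(relevant), out)
    return out


def ray_visible(occ: np.ndarray, start_vox: np.ndarray, direction: np.ndarray) -> bool:
    """Single-ray convenience wrapper around the DDA kernel."""
    occ8 = np.ascontiguousarray(occ.astype(np.uint8))
    s = np.asarray(start_vox, dtype=float)
    d = np.asarray(direction, dtype=float)
    return not _ray_blocked(occ8, s[0], s[1], s[2], d[0], d[1], d[2])
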