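"""Wavelength grids, action spectra and the solar source spectrum.

Every spectral quantity in the package lives on a common uniform wavelength
grid covering the UV range 250-400 nm.  Spectral irradiances are expressed
in mW m^-2 nm^-1 and spectral radiances in mW m^-2 nm^-1 sr^-1 throughout;
biologically weighted integrals therefore come out in mW m^-2 (irradiance)
or mW m^-2 sr^-1 (radiance).

The erythema (sunburn) action spectrum follows the CIE (1998) reference
piecewise form, the standard weighting in UV climatology:

    w(lambda) = 1                          for lambda <= 298 nm
    w(lambda) = 10^(0.094 (298 - lambda))  for 298 < lambda <= 328 nm
    w(lambda) = 10^(0.015 (140 - lambda))  for 328 < lambda <= 400 nm

The bundled extraterrestrial spectrum is a deterministic analytic
surrogate (a diluted 5778 K Planck curve); only spectral ratios and
integral closures matter downstream, not absolute top-of-atmosphere
values, so a smooth surrogate suffices and keeps the package
self-contained.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Callable, Union

import numpy as np

__all__ = [
    "UV_MIN_NM",
    "UV_MAX_NM",
    "SpectralGrid",
    "Spectrum",
    "ActionSpectrum",
    "ERYTHEMAL",
    "UNIT_ACTION",
    "get_action_spectrum",
    "erythemal_weight",
    "weight_spectrum",
    "extraterrestrial_spectrum",
    "read_spectrum",
    "write_spectrum",
    "bundled_extraterrestrial_path",
]

UV_MIN_NM = 250.0
UV_MAX_NM = 400.0


@dataclass(frozen=True)
class SpectralGrid:
    """Uniform, strictly increasing wavelength grid covering 250-400 nm.

    Parameters
    ----------
    wavelengths : array of float
        Wavelengths in nm.  Must be uniform, strictly increasing, and span
        the full 250-400 nm UV support.
    """

    wavelengths: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        if wl.ndim != 1 or wl.size < 2:
            raise ValueError("wavelength grid must be a 1-D array with >= 2 points")
        steps = np.diff(wl)
        if np.any(steps <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if not np.allclose(steps, steps[0], rtol=1e-8, atol=1e-10):
            raise ValueError("wavelength grid must have a uniform step")
        if wl[0] > UV_MIN_NM + 1e-9 or wl[-1] < UV_MAX_NM - 1e-9:
            raise ValueError(
                f"grid must cover {UV_MIN_NM:.0f}-{UV_MAX_NM:.0f} nm, "
                f"got {wl[0]:g}-{wl[-1]:g} nm"
            )

    @property
    def step(self) -> float:
        """Grid spacing in nm."""
        return float(self.wavelengths[1] - self.wavelengths[0])

    def __len__(self) -> int:
        return self.wavelengths.size

    @classmethod
    def default(cls, step: float = 1.0) -> "SpectralGrid":
        """250-400 nm at the given step (default 1 nm)."""
        n = int(round((UV_MAX_NM - UV_MIN_NM) / step))
        return cls(np.linspace(UV_MIN_NM, UV_MAX_NM, n + 1))


_SPECTRUM_KINDS = ("irradiance", "radiance", "dimensionless")


@dataclass(frozen=True)
class Spectrum:
    """Non-negative per-wavelength values on a :class:`SpectralGrid`.

    ``kind`` tags the physical quantity: ``"irradiance"``
    (mW m^-2 nm^-1), ``"radiance"`` (mW m^-2 nm^-1 sr^-1) or
    ``"dimensionless"``.
    """

    grid: SpectralGrid
    values: np.ndarray
    kind: str = "irradiance"

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        if vals.shape != self.grid.wavelengths.shape:
            raise ValueError(
                f"values length {vals.shape} does not match grid length "
                f"{self.grid.wavelengths.shape}"
            )
        if np.any(vals < 0) or not np.all(np.isfinite(vals)):
            raise ValueError("spectrum values must be finite and non-negative")
        if self.kind not in _SPECTRUM_KINDS:
            raise ValueError(f"unknown spectrum kind {self.kind!r}")

    def scaled(self, factor: float, kind: str | None = None) -> "Spectrum":
        """Return a copy multiplied by a non-negative scalar."""
        return Spectrum(self.grid, self.values * factor, kind or self.kind)


@dataclass(frozen=True)
class ActionSpectrum:
    """Named biological weighting function, dimensionless in [0, 1]."""

    name: str
    weight: Callable[[np.ndarray], np.ndarray]

    def weights(self, grid: SpectralGrid) -> np.ndarray:
        w = np.asarray(self.weight(grid.wavelengths), dtype=float)
        if np.any(w < 0) or np.any(w > 1 + 1e-12):
            raise ValueError(f"action spectrum {self.name!r} left [0, 1]")
        return w


def erythemal_weight(wavelength: Union[float, np.ndarray]) -> Union[float, np.ndarray]:
    """CIE reference erythema weight at ``wavelength`` (nm).

    Piecewise: 1 up to 298 nm, then two exponential decays (see module
    docstring).  Raises ``ValueError`` outside 250-400 nm.
    """
    wl = np.asarray(wavelength, dtype=float)
    if np.any(wl < UV_MIN_NM - 1e-9) or np.any(wl > UV_MAX_NM + 1e-9):
        raise ValueError("erythemal weight is defined on 250-400 nm only")
    w = np.where(
        wl <= 298.0,
        1.0,
        np.where(
            wl <= 328.0,
            10.0 ** (0.094 * (298.0 - wl)),
            10.0 ** (0.015 * (140.0 - wl)),
        ),
    )
    return float(w) if w.ndim == 0 else w


ERYTHEMAL = ActionSpectrum("erythemal", erythemal_weight)
#: Flat unit weighting; handy for unweighted integrals and oracle tests.
UNIT_ACTION = ActionSpectrum("unit", lambda wl: np.ones_like(np.asarray(wl, float)))

_ACTION_REGISTRY: dict[str, ActionSpectrum] = {
    ERYTHEMAL.name: ERYTHEMAL,
    UNIT_ACTION.name: UNIT_ACTION,
}


def get_action_spectrum(name: str) -> ActionSpectrum:
    """Look up a registered action spectrum by name."""
    try:
        return _ACTION_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown action spectrum {name!r}; known: {sorted(_ACTION_REGISTRY)}"
        ) from None


def register_action_spectrum(action: ActionSpectrum) -> None:
    """Register a pluggable action spectrum (e.g. other biological weightings)."""
    _ACTION_REGISTRY[action.name] = action


def weight_spectrum(spectrum: Spectrum, action: ActionSpectrum = ERYTHEMAL) -> float:
    """Biologically weighted integral of a spectrum over its grid.

    Trapezoidal quadrature of ``spectrum(lambda) * w(lambda) dlambda``;
    the result carries the spectrum's units times nm (e.g. mW m^-2 for an
    irradiance spectrum).
    """
    w = action.weights(spectrum.grid)
    return float(np.trapezoid(spectrum.values * w, spectrum.grid.wavelengths))


# Planck constants (SI) and the solar dilution factor (R_sun / 1 AU)^2.
_H = 6.62607015e-34
_C = 2.99792458e8
_KB = 1.380649e-23
_T_SUN = 5778.0
_DILUTION = 2.1646e-5


def extraterrestrial_spectrum(grid: SpectralGrid) -> Spectrum:
    """Deterministic synthetic top-of-atmosphere solar spectrum.

    A diluted blackbody at the solar effective temperature, returned as a
    spectral irradiance in mW m^-2 nm^-1.  Smooth, strictly positive, and
    identical for identical grids.
    """
    lam_m = grid.wavelengths * 1e-9
    planck = 2.0 * _H * _C**2 / lam_m**5 / np.expm1(_H * _C / (lam_m * _KB * _T_SUN))
    e_si = np.pi * _DILUTION * planck  # W m^-2 m^-1
    return Spectrum(grid, e_si * 1e3 * 1e-9, kind="irradiance")


def read_spectrum(path: Union[str, Path], kind: str = "irradiance") -> Spectrum:
    """Read a two-column plain-text spectrum (wavelength nm, value).

    Lines beginning with ``#`` are comments.  Columns are
    whitespace-separated.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (wavelength, value)")
    return Spectrum(SpectralGrid(data[:, 0]), data[:, 1], kind=kind)


def write_spectrum(path: Union[str, Path], spectrum: Spectrum,
                   comment: str | None = None) -> None:
    """Write a spectrum in the two-column plain-text format."""
    path = Path(path)
    with path.open("w") as fh:
        if comment:
            for line in comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("# wavelength_nm value\n")
        for wl, v in zip(spectrum.grid.wavelengths, spectrum.values):
            fh.write(f"{wl:.4f} {v:.8e}\n")


def bundled_extraterrestrial_path() -> Path:
    """Path of the bundled synthetic extraterrestrial spectrum table."""
    return Path(resources.files("uvbody").joinpath("data/extraterrestrial_synthetic.txt"))
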