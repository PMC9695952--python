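"""CIE colorimetry for reflectance spectra: XYZ, xy chromaticity, CIELAB,
and the two distance metrics used throughout the pipeline (CIE76 delta-E*
and delta-xy).

Tristimulus integration uses the CIE 1931 2-degree observer and illuminant
D65 by default, tabulated on the 67-point visible grid (400-730 nm) and
shipped as package data.  Because the enhanced spectra only cover 400-730 nm,
the summation is truncated to that range; the normalization constant k is
computed over the same range, so the perfect reflector maps to Y = 100 and
L* = 100 exactly.  Absolute coordinates therefore differ slightly from
full-range colorimetry, but every comparative quantity (delta-E*, delta-xy)
is computed with the same convention on both sides and is unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources

import numpy as np

from .spectra_io import (
    ReflectanceSpectrum,
    WavelengthRangeError,
    resample,
    visible_grid,
)

__all__ = [
    "ColorXYZ",
    "Chromaticity",
    "ColorLab",
    "UndefinedChromaticityError",
    "spectrum_to_xyz",
    "xyz_to_xy",
    "xyz_to_lab",
    "delta_e_lab",
    "delta_xy",
    "white_point",
    "spectrum_to_lab",
]


class UndefinedChromaticityError(ValueError):
    """Chromaticity requested for an all-zero tristimulus."""


@dataclass(frozen=True)
class ColorXYZ:
    """CIE tristimulus values; Y = 100 for the perfect reflector."""

    X: float
    Y: float
    Z: float

    def __post_init__(self) -> None:
        if self.X < 0 or self.Y < 0 or self.Z < 0:
            raise ValueError("tristimulus values must be non-negative")


@dataclass(frozen=True)
class Chromaticity:
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0 or self.x + self.y > 1 + 1e-9:
            raise ValueError("chromaticity must satisfy x, y >= 0 and x + y <= 1")


@dataclass(frozen=True)
class ColorLab:
    L_star: float
    a_star: float
    b_star: float


# ---------------------------------------------------------------------------
# tabulated observer / illuminant data

_TABLE_FILE = "cie1931_2deg_d65_visible67.csv"
_table_cache: dict[tuple[str, str], dict[str, np.ndarray]] = {}


def _load_tables(illuminant: str = "D65", observer: str = "CIE1931_2deg"):
    key = (illuminant, observer)
    if key in _table_cache:
        return _table_cache[key]
    if observer != "CIE1931_2deg":
        raise ValueError(f"unknown observer {observer!r}")
    import pandas as pd

    with resources.files("skinspec.data").joinpath(_TABLE_FILE).open("r") as fh:
        data = pd.read_csv(fh, comment="#")
    tables = {
        "wavelength": data["wavelength_nm"],
        "xbar": data["xbar"],
        "ybar": data["ybar"],
        "zbar": data["zbar"],
    }
    if illuminant == "D65":
        tables["S"] = data["d65"]
    elif illuminant == "E":  # equal-energy illuminant
        tables["S"] = np.full_like(tables["xbar"], 100.0)
    else:
        raise ValueError(f"unknown illuminant {illuminant!r}")
    _table_cache[key] = tables
    return tables


def spectrum_to_xyz(
    spectrum: ReflectanceSpectrum,
    illuminant: str = "D65",
    observer: str = "CIE1931_2deg",
) -> ColorXYZ:
    """Integrate R(lambda)*S(lambda)*cmf(lambda) over 400-730 nm.

    The spectrum must cover the full visible grid; it is resampled to the
    67-point grid before summation.
    """
    vg = visible_grid()
    if spectrum.grid.min_nm > vg.min_nm or spectrum.grid.max_nm < vg.max_nm:
        raise WavelengthRangeError(
            "spectrum must cover 400-730 nm for colorimetry "
            f"(covers {spectrum.grid.min_nm}-{spectrum.grid.max_nm} nm)"
        )
    r = resample(spectrum, vg).values
    t = _load_tables(illuminant, observer)
    s = t["S"]
    k = 100.0 / float(np.sum(s * t["ybar"]))
    return ColorXYZ(
        X=k * float(np.sum(r * s * t["xbar"])),
        Y=k * float(np.sum(r * s * t["ybar"])),
        Z=k * float(np.sum(r * s * t["zbar"])),
    )


def white_point(
    illuminant: str = "D65", observer: str = "CIE1931_2deg"
) -> ColorXYZ:
    """Tristimulus of the perfect reflector under the given convention."""
    t = _load_tables(illuminant, observer)
    s = t["S"]
    k = 100.0 / float(np.sum(s * t["ybar"]))
    return ColorXYZ(
        X=k * float(np.sum(s * t["xbar"])),
        Y=100.0,
        Z=k * float(np.sum(s * t["zbar"])),
    )


def xyz_to_xy(xyz: ColorXYZ) -> Chromaticity:
    total = xyz.X + xyz.Y + xyz.Z
    if total <= 0:
        raise UndefinedChromaticityError(
            "chromaticity undefined for zero tristimulus"
        )
    return Chromaticity(xyz.X / total, xyz.Y / total)


def _lab_f(t: np.ndarray) -> np.ndarray:
    # CIE 1976 cube-root function with the linear segment below (6/29)^3
    delta = 6.0 / 29.0
    t = np.asarray(t, dtype=float)
    return np.where(
        t > delta**3,
        np.cbrt(t),
        t / (3 * delta**2) + 4.0 / 29.0,
    )


def xyz_to_lab(xyz: ColorXYZ, white: ColorXYZ | None = None) -> ColorLab:
    """Standard CIELAB forward transform relative to *white* (default D65)."""
    if white is None:
        white = white_point()
    if white.X <= 0 or white.Y <= 0 or white.Z <= 0:
        raise ValueError("white point components must be strictly positive")
    fx, fy, fz = _lab_f(
        np.array([xyz.X / white.X, xyz.Y / white.Y, xyz.Z / white.Z])
    )
    return ColorLab(
        L_star=float(116.0 * fy - 16.0),
        a_star=float(500.0 * (fx - fy)),
        b_star=float(200.0 * (fy - fz)),
    )


def delta_e_lab(c1: ColorLab, c2: ColorLab) -> float:
    """CIE76 color difference: Euclidean distance in (L*, a*, b*)."""
    return math.sqrt(
        (c1.L_star - c2.L_star) ** 2
        + (c1.a_star - c2.a_star) ** 2
        + (c1.b_star - c2.b_star) ** 2
    )


def delta_xy(p1: Chromaticity, p2: Chromaticity) -> float:
    """Euclidean distance in the xy chromaticity plane."""
    return math.hypot(p1.x - p2.x, p1.y - p2.y)


def spectrum_to_lab(
    spectrum: ReflectanceSpectrum,
    illuminant: str = "D65",
    observer: str = "CIE1931_2deg",
) -> ColorLab:
    """Convenience: reflectance spectrum straight to CIELAB."""
    xyz = spectrum_to_xyz(spectrum, illuminant, observer)
    return xyz_to_lab(xyz, white_point(illuminant, observer))
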