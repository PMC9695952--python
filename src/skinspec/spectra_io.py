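"""Reflectance spectra: containers, wavelength grids, file I/O, resampling.

A reflectance spectrum is the fraction of incident light a surface reflects
as a function of wavelength.  Everything downstream — the CNN enhancer, the
colorimetry, the dermatological indices — consumes the
:class:`ReflectanceSpectrum` defined here.

Two named grids matter:

* ``visible67`` — 67 points, 400–730 nm inclusive, 5 nm step.  This is the
  range the spectral enhancer operates on.
* ``full`` — 400–1000 nm, the range of the low-cost sensor; the
  near-infrared tail (>730 nm) feeds the melanin index and body-fat lookups.

File dialects (see :func:`read_spectrum` / :func:`write_spectrum`):

* CSV with header ``wavelength_nm,reflectance``, one row per grid point.
* JSON object with keys ``label``, ``wavelength_nm``, ``reflectance``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "WavelengthGrid",
    "ReflectanceSpectrum",
    "SpectrumFormatError",
    "SpectrumValidationError",
    "WavelengthRangeError",
    "GridMismatchError",
    "visible_grid",
    "full_grid",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "value_at",
]

VISIBLE_MIN_NM = 400.0
VISIBLE_MAX_NM = 730.0
VISIBLE_N_POINTS = 67
SENSOR_MAX_NM = 1000.0


class SpectrumFormatError(ValueError):
    """A spectrum file does not parse in the declared dialect."""


class SpectrumValidationError(ValueError):
    """Spectrum data violates a structural invariant (ordering, length, sign)."""


class WavelengthRangeError(ValueError):
    """A wavelength lookup or resampling target falls outside the source range."""


class GridMismatchError(ValueError):
    """An operation received spectra on incompatible wavelength grids."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelengths in nm with an identifying name."""

    points: np.ndarray
    name: str = "custom"

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size == 0:
            raise SpectrumValidationError("grid must be a non-empty 1D array")
        if not np.all(np.isfinite(pts)):
            raise SpectrumValidationError("grid contains non-finite wavelengths")
        if np.any(pts <= 0):
            raise SpectrumValidationError("wavelengths must be positive")
        if np.any(np.diff(pts) <= 0):
            raise SpectrumValidationError("wavelengths must be strictly increasing")

    def __len__(self) -> int:
        return int(self.points.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, WavelengthGrid):
            return NotImplemented
        return self.points.shape == other.points.shape and bool(
            np.array_equal(self.points, other.points)
        )

    def __hash__(self) -> int:
        return hash((self.name, self.points.tobytes()))

    @property
    def min_nm(self) -> float:
        return float(self.points[0])

    @property
    def max_nm(self) -> float:
        return float(self.points[-1])


def visible_grid() -> WavelengthGrid:
    """The canonical 67-point visible grid: 400–730 nm, 5 nm step."""
    pts = np.linspace(VISIBLE_MIN_NM, VISIBLE_MAX_NM, VISIBLE_N_POINTS)
    return WavelengthGrid(pts, name="visible67")


def full_grid(step_nm: float = 5.0) -> WavelengthGrid:
    """The full sensor-range grid, 400–1000 nm (default 5 nm step)."""
    n = int(round((SENSOR_MAX_NM - VISIBLE_MIN_NM) / step_nm)) + 1
    pts = np.linspace(VISIBLE_MIN_NM, SENSOR_MAX_NM, n)
    return WavelengthGrid(pts, name="full")


@dataclass
class ReflectanceSpectrum:
    """Reflectance fractions (dimensionless, ~[0, 1]) on a wavelength grid.

    Values above 1 are physically suspect (calibration overshoot) and raise a
    warning, not an error; negative or non-finite values are rejected.
    """

    grid: WavelengthGrid
    values: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        self.values = vals
        if vals.ndim != 1 or vals.size != len(self.grid):
            raise SpectrumValidationError(
                f"values length {vals.size} != grid length {len(self.grid)}"
            )
        if not np.all(np.isfinite(vals)):
            raise SpectrumValidationError("reflectance values must be finite")
        if np.any(vals < 0):
            raise SpectrumValidationError("reflectance values must be >= 0")
        if np.any(vals > 1):
            warnings.warn(
                f"spectrum {self.label!r}: reflectance exceeds 1 "
                f"(max {vals.max():.4g}); calibration overshoot?",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def wavelengths(self) -> np.ndarray:
        return self.grid.points

    def on_visible67(self) -> bool:
        g = self.grid
        return len(g) == VISIBLE_N_POINTS and np.allclose(
            g.points, visible_grid().points
        )

    def copy(self, label: str | None = None) -> "ReflectanceSpectrum":
        return ReflectanceSpectrum(
            self.grid, self.values.copy(), self.label if label is None else label
        )


# ---------------------------------------------------------------------------
# file I/O

_CSV_HEADER = "wavelength_nm,reflectance"


def read_spectrum(path: str | Path, format: str | None = None) -> ReflectanceSpectrum:
    """Read a spectrum from CSV or JSON.  Format inferred from suffix if omitted."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        return _read_csv(path)
    if fmt == "json":
        return _read_json(path)
    raise SpectrumFormatError(f"unknown format {fmt!r} (expected 'csv' or 'json')")


def _read_csv(path: Path) -> ReflectanceSpectrum:
    wl: list[float] = []
    vals: list[float] = []
    with open(path, encoding="utf-8") as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise SpectrumFormatError(f"{path}: empty file")
    if lines[0].strip() != _CSV_HEADER:
        raise SpectrumFormatError(
            f"{path}:1: expected header {_CSV_HEADER!r}, got {lines[0]!r}"
        )
    for i, line in enumerate(lines[1:], start=2):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise SpectrumFormatError(f"{path}:{i}: expected 2 fields, got {line!r}")
        try:
            wl.append(float(parts[0]))
            vals.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumFormatError(f"{path}:{i}: {exc}") from exc
    grid = WavelengthGrid(np.array(wl))
    return ReflectanceSpectrum(grid, np.array(vals), label=path.stem)


def _read_json(path: Path) -> ReflectanceSpectrum:
    try:
        obj = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise SpectrumFormatError(f"{path}: invalid JSON at line {exc.lineno}") from exc
    for key in ("wavelength_nm", "reflectance"):
        if key not in obj:
            raise SpectrumFormatError(f"{path}: missing key {key!r}")
    grid = WavelengthGrid(np.array(obj["wavelength_nm"], dtype=float))
    return ReflectanceSpectrum(
        grid, np.array(obj["reflectance"], dtype=float), label=str(obj.get("label", ""))
    )


def write_spectrum(
    spectrum: ReflectanceSpectrum, path: str | Path, format: str | None = None
) -> None:
    """Write a spectrum; values serialized with 12 significant digits."""
    path = Path(path)
    fmt = format or ("json" if path.suffix.lower() == ".json" else "csv")
    if fmt == "csv":
        rows = [_CSV_HEADER]
        rows += [
            f"{w:.12g},{v:.12g}"
            for w, v in zip(spectrum.wavelengths, spectrum.values)
        ]
        path.write_text("\n".join(rows) + "\n", encoding="utf-8")
    elif fmt == "json":
        obj = {
            "label": spectrum.label,
            "wavelength_nm": [float(w) for w in spectrum.wavelengths],
            "reflectance": [float(v) for v in spectrum.values],
        }
        path.write_text(json.dumps(obj, indent=1) + "\n", encoding="utf-8")
    else:
        raise SpectrumFormatError(f"unknown format {fmt!r} (expected 'csv' or 'json')")


# ---------------------------------------------------------------------------
# resampling

def resample(
    spectrum: ReflectanceSpectrum, target: WavelengthGrid
) -> ReflectanceSpectrum:
    """Linearly interpolate a spectrum onto *target*.  No extrapolation ever:
    every target point must lie within the source wavelength range."""
    src = spectrum.grid
    if target.min_nm < src.min_nm or target.max_nm > src.max_nm:
        raise WavelengthRangeError(
            f"target grid [{target.min_nm}, {target.max_nm}] nm exceeds source "
            f"range [{src.min_nm}, {src.max_nm}] nm; extrapolation is not allowed"
        )
    vals = np.interp(target.points, src.points, spectrum.values)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # overshoot already warned at source
        return ReflectanceSpectrum(target, vals, label=spectrum.label)


def value_at(spectrum: ReflectanceSpectrum, wavelength_nm: float) -> float:
    """Reflectance at one wavelength (linear interpolation between grid points)."""
    src = spectrum.grid
    if not (src.min_nm <= wavelength_nm <= src.max_nm):
        raise WavelengthRangeError(
            f"{wavelength_nm} nm outside spectrum range "
            f"[{src.min_nm}, {src.max_nm}] nm"
        )
    return float(np.interp(wavelength_nm, src.points, spectrum.values))
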