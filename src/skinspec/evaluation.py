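"""Enhancer evaluation: MSE, CIE76 delta-E* and delta-xy between candidate
and reference spectra, aggregated over a dataset into the off/on comparison
table (degraded-vs-reference against enhanced-vs-reference)."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .colorimetry import (
    delta_e_lab,
    delta_xy,
    spectrum_to_xyz,
    white_point,
    xyz_to_lab,
    xyz_to_xy,
)
from .enhancement import EnhancerModel, enhance
from .spectra_io import GridMismatchError, ReflectanceSpectrum
from .synthetic import SpectrumPair

__all__ = [
    "EvaluationReport",
    "spectral_mse",
    "compare_pair",
    "aggregate",
    "evaluate_model",
]


@dataclass(frozen=True)
class EvaluationReport:
    mse: float
    delta_e: float
    delta_xy: float
    n: int

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if min(self.mse, self.delta_e, self.delta_xy) < 0:
            raise ValueError("metrics must be non-negative")


def spectral_mse(s1: ReflectanceSpectrum, s2: ReflectanceSpectrum) -> float:
    """Mean squared reflectance difference over the (shared) grid."""
    if s1.grid != s2.grid:
        raise GridMismatchError("spectral_mse requires spectra on the same grid")
    return float(np.mean((s1.values - s2.values) ** 2))


def compare_pair(
    candidate: ReflectanceSpectrum,
    reference: ReflectanceSpectrum,
    illuminant: str = "D65",
    observer: str = "CIE1931_2deg",
) -> EvaluationReport:
    """Single-spectrum report: MSE, delta-E*76 and delta-xy, same convention
    on both sides so the illuminant/observer choice cancels."""
    mse = spectral_mse(candidate, reference)
    white = white_point(illuminant, observer)
    xyz_c = spectrum_to_xyz(candidate, illuminant, observer)
    xyz_r = spectrum_to_xyz(reference, illuminant, observer)
    de = delta_e_lab(xyz_to_lab(xyz_c, white), xyz_to_lab(xyz_r, white))
    dxy = delta_xy(xyz_to_xy(xyz_c), xyz_to_xy(xyz_r))
    return EvaluationReport(mse=mse, delta_e=de, delta_xy=dxy, n=1)


def aggregate(reports: Sequence[EvaluationReport]) -> EvaluationReport:
    """Unweighted mean of each metric; n sums the counts."""
    if not reports:
        raise ValueError("cannot aggregate an empty report list")
    return EvaluationReport(
        mse=float(np.mean([r.mse for r in reports])),
        delta_e=float(np.mean([r.delta_e for r in reports])),
        delta_xy=float(np.mean([r.delta_xy for r in reports])),
        n=int(sum(r.n for r in reports)),
    )


def evaluate_model(
    model: EnhancerModel,
    pairs: Sequence[SpectrumPair],
    illuminant: str = "D65",
    observer: str = "CIE1931_2deg",
) -> tuple[EvaluationReport, EvaluationReport]:
    """(report_off, report_on): degraded vs reference, enhanced vs reference."""
    if not pairs:
        raise ValueError("cannot evaluate on an empty pair list")
    off = [
        compare_pair(p.degraded, p.reference, illuminant, observer) for p in pairs
    ]
    on = [
        compare_pair(enhance(model, p.degraded), p.reference, illuminant, observer)
        for p in pairs
    ]
    return aggregate(off), aggregate(on)
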