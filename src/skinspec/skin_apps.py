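"""Closed-form skin analyses computed from a reflectance spectrum.

Five analyses, all standard in dermatological optics:

* **Erythema / melanin index (EI/MI)** — base-10 log-ratio measures of skin
  redness (hemoglobin) and pigmentation (melanin):
  ``index = (500 / log10 5) * (log10(R_a / R_b) + log10 5)``, which equals
  500 at unit ratio and 1000 at ratio 5.  The default EI wavelength pair is
  (880, 570) nm as used by the source app; note 880 nm is infrared — the
  classical erythema convention uses red ~660 nm, so the pair is a
  parameter.
* **Individual typology angle (ITA) and Fitzpatrick class** — ITA in degrees
  is ``arctan((L* - 50) / b*) * 180 / pi`` from the CIELAB coordinates of
  the skin tone; six threshold bands (55, 41, 28, 10, -30) map ITA to the
  labels Very light ... Dark.
* **Palette matching** — nearest entry of a user-supplied Lab palette (e.g.
  a commercial skin-tone guide) by CIE76 delta-E*.
* **Sun-exposure estimation** — time required to synthesize vitamin D
  (TRSVD) = standard vitamin D dose SDD [J/m^2] / UV irradiance [W/m^2];
  the recommended maximum sun-exposure time RMSET is 4 x TRSVD.  SDD by
  skin phototype: I 37.2, II 46.5, III 55.8, IV 83.6, V 111.4, VI 185.1.
* **Body fat** — a near-infrared regression on reflectance at 937/947 nm
  plus weight, height, sex and exercise-level terms.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .colorimetry import (
    ColorLab,
    ColorXYZ,
    delta_e_lab,
    spectrum_to_xyz,
    white_point,
    xyz_to_lab,
    xyz_to_xy,
)
from .enhancement import EnhancerModel, enhance
from .spectra_io import (
    ReflectanceSpectrum,
    WavelengthGrid,
    WavelengthRangeError,
    resample,
    value_at,
    visible_grid,
)

__all__ = [
    "SkinIndices",
    "ITAResult",
    "SunExposure",
    "BodyFatInputs",
    "BodyFatConstants",
    "PaletteEntry",
    "AnalysisReport",
    "SubjectMetadata",
    "PaletteError",
    "FITZPATRICK_LABELS",
    "SDD_J_PER_M2",
    "LABEL_TO_SKIN_TYPE",
    "DEFAULT_BODY_FAT_K",
    "erythema_index",
    "melanin_index",
    "ita_degrees",
    "classify_fitzpatrick",
    "match_palette",
    "read_palette",
    "sun_exposure",
    "body_fat_percent",
    "analyze",
]

_LOG10_5 = math.log10(5.0)

FITZPATRICK_LABELS = ("Very light", "Light", "Intermediate", "Tan", "Brown", "Dark")

# standard vitamin D dose (erythemally effective J/m^2) per skin phototype
SDD_J_PER_M2 = {
    "I": 37.2,
    "II": 46.5,
    "III": 55.8,
    "IV": 83.6,
    "V": 111.4,
    "VI": 185.1,
}

# ITA class -> phototype used for sun-exposure timing (documented assumption)
LABEL_TO_SKIN_TYPE = {
    "Very light": "I",
    "Light": "II",
    "Intermediate": "III",
    "Tan": "IV",
    "Brown": "V",
    "Dark": "VI",
}

SEX_CODES = {"male": 0.01, "female": -0.01}
EXERCISE_CODES = {"none": 0.0, "mild": 0.02, "moderate": 0.05, "severe": 0.08}


class PaletteError(ValueError):
    """Empty palette or malformed palette file."""


@dataclass(frozen=True)
class SkinIndices:
    EI: float
    MI: float
    wavelengths_used: tuple[float, float, float, float]  # EI red/green, MI ir/red


@dataclass(frozen=True)
class ITAResult:
    ita_deg: float
    label: str
    b_star_negative: bool = False  # outside the validity domain for skin


@dataclass(frozen=True)
class SunExposure:
    trsvd_s: float
    rmset_s: float
    skin_type: str
    sdd_j_per_m2: float
    uv_irradiance_w_per_m2: float


@dataclass(frozen=True)
class BodyFatConstants:
    K0: float = 84.2
    K2A: float = -16.3
    K2B: float = -6.2
    K3: float = 8.1
    K4: float = -13.7
    K5: float = -124.2
    K6: float = -81.4


DEFAULT_BODY_FAT_K = BodyFatConstants()


@dataclass(frozen=True)
class BodyFatInputs:
    l1: float  # reflectance fraction at 937 nm
    l2: float  # reflectance fraction at 947 nm
    weight_lbs: float
    height_in: float
    sex_code: float  # male 0.01, female -0.01
    exercise_code: float  # none 0, mild 0.02, moderate 0.05, severe 0.08
    K: BodyFatConstants = DEFAULT_BODY_FAT_K

    def __post_init__(self) -> None:
        if not (0 < self.l1 <= 1) or not (0 < self.l2 <= 1):
            raise ValueError("l1 and l2 must be reflectance fractions in (0, 1]")
        if self.weight_lbs <= 0 or self.height_in <= 0:
            raise ValueError("weight and height must be positive")


@dataclass(frozen=True)
class PaletteEntry:
    id: str
    color: ColorLab


@dataclass(frozen=True)
class SubjectMetadata:
    weight_lbs: float
    height_in: float
    sex: str  # "male" | "female"
    exercise: str = "none"  # none | mild | moderate | severe

    def __post_init__(self) -> None:
        if self.sex not in SEX_CODES:
            raise ValueError(f"sex must be one of {sorted(SEX_CODES)}")
        if self.exercise not in EXERCISE_CODES:
            raise ValueError(f"exercise must be one of {sorted(EXERCISE_CODES)}")


# ---------------------------------------------------------------------------
# EI / MI

def _log_ratio_index(r_num: float, r_den: float) -> float:
    if r_num <= 0 or r_den <= 0:
        raise ValueError("reflectance operands must be strictly positive")
    return (500.0 / _LOG10_5) * (math.log10(r_num / r_den) + _LOG10_5)


def erythema_index(
    spectrum: ReflectanceSpectrum, red_nm: float = 880.0, green_nm: float = 570.0
) -> float:
    """EI = (500/log10 5) * (log10(R(red)/R(green)) + log10 5).

    500 at unit ratio; increases with relative red reflectance.  The default
    red wavelength follows the source convention (880 nm); pass ``red_nm=660``
    for the classical visible-red variant.
    """
    return _log_ratio_index(value_at(spectrum, red_nm), value_at(spectrum, green_nm))


def melanin_index(
    spectrum: ReflectanceSpectrum, ir_nm: float = 880.0, red_nm: float = 660.0
) -> float:
    """MI with operands R(infrared 880 nm) / R(red 660 nm); 500 at unit ratio."""
    return _log_ratio_index(value_at(spectrum, ir_nm), value_at(spectrum, red_nm))


# ---------------------------------------------------------------------------
# ITA / Fitzpatrick

def ita_degrees(lab: ColorLab) -> float:
    """Individual typology angle: arctan((L* - 50) / b*) in degrees.

    b* = 0 degenerates to +/-90 (sign of L* - 50) or 0 when L* = 50.
    Negative b* is evaluated with the same formula (principal arctangent);
    callers should treat it as outside the skin-tone validity domain.
    """
    num = lab.L_star - 50.0
    if lab.b_star == 0.0:
        return 90.0 if num > 0 else (-90.0 if num < 0 else 0.0)
    return math.degrees(math.atan(num / lab.b_star))


def classify_fitzpatrick(ita_deg: float) -> str:
    """Map ITA degrees to the six-class skin-type label.

    Bands: >55 Very light; (41, 55] Light; (28, 41] Intermediate;
    (10, 28] Tan; (-30, 10] Brown; <= -30 Dark.  Boundary values go to the
    darker class (the published strict inequalities leave ties unassigned).
    """
    if not math.isfinite(ita_deg):
        raise ValueError("ITA must be finite")
    if ita_deg > 55:
        return "Very light"
    if ita_deg > 41:
        return "Light"
    if ita_deg > 28:
        return "Intermediate"
    if ita_deg > 10:
        return "Tan"
    if ita_deg > -30:
        return "Brown"
    return "Dark"


# ---------------------------------------------------------------------------
# palette matching

def match_palette(
    color: ColorLab, palette: Sequence[PaletteEntry]
) -> tuple[PaletteEntry, float]:
    """Nearest palette entry by CIE76 delta-E*; ties break to the smallest id."""
    if not palette:
        raise PaletteError("palette is empty")
    best = min(palette, key=lambda e: (delta_e_lab(color, e.color), e.id))
    return best, delta_e_lab(color, best.color)


def read_palette(path: str | Path) -> list[PaletteEntry]:
    """Read a palette CSV with header ``id,L,a,b``."""
    df = pd.read_csv(path, comment="#")
    expected = ["id", "L", "a", "b"]
    if list(df.columns) != expected:
        raise PaletteError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    if df["id"].astype(str).duplicated().any():
        raise PaletteError(f"{path}: duplicate palette ids")
    return [
        PaletteEntry(str(row.id), ColorLab(float(row.L), float(row.a), float(row.b)))
        for row in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# sun exposure

def sun_exposure(skin_type: str, uv_irradiance_w_per_m2: float) -> SunExposure:
    """TRSVD = SDD(type)/irradiance [s]; RMSET = 4 x TRSVD."""
    if skin_type not in SDD_J_PER_M2:
        raise KeyError(
            f"unknown skin type {skin_type!r}; expected one of {sorted(SDD_J_PER_M2)}"
        )
    if uv_irradiance_w_per_m2 <= 0:
        raise ValueError("UV irradiance must be > 0")
    sdd = SDD_J_PER_M2[skin_type]
    trsvd = sdd / uv_irradiance_w_per_m2
    return SunExposure(
        trsvd_s=trsvd,
        rmset_s=4.0 * trsvd,
        skin_type=skin_type,
        sdd_j_per_m2=sdd,
        uv_irradiance_w_per_m2=uv_irradiance_w_per_m2,
    )


# ---------------------------------------------------------------------------
# body fat

def body_fat_percent(inputs: BodyFatInputs) -> float:
    """NIR body-fat regression.

    percent = K0 + K2A*log10(1/l1) + K2B*log10(1/l2) + K3*W/100 + K4*H/100
              + K5*S + K6*EL
    with l1, l2 the reflectance fractions at 937 and 947 nm, W weight in lbs,
    H height in inches, S the sex code and EL the exercise-level code.
    """
    k = inputs.K
    return (
        k.K0
        + k.K2A * math.log10(1.0 / inputs.l1)
        + k.K2B * math.log10(1.0 / inputs.l2)
        + k.K3 * inputs.weight_lbs / 100.0
        + k.K4 * inputs.height_in / 100.0
        + k.K5 * inputs.sex_code
        + k.K6 * inputs.exercise_code
    )


# ---------------------------------------------------------------------------
# full analysis

BODY_FAT_NM = (937.0, 947.0)


@dataclass
class AnalysisReport:
    """Everything the app surfaces for one measured spectrum."""

    xyz: ColorXYZ
    chromaticity: "tuple[float, float]"
    lab: ColorLab
    indices: SkinIndices | None
    ita: ITAResult
    palette_match: tuple[str, float] | None
    sun: SunExposure | None
    body_fat_pct: float | None
    enhanced: bool
    missing: dict[str, str] = field(default_factory=dict)  # output -> reason

    def to_json(self) -> str:
        def enc(o):
            if hasattr(o, "__dict__"):
                return o.__dict__
            return o

        return json.dumps(
            {
                "xyz": self.xyz.__dict__,
                "chromaticity": {"x": self.chromaticity[0], "y": self.chromaticity[1]},
                "lab": self.lab.__dict__,
                "indices": None if self.indices is None else {
                    "EI": self.indices.EI,
                    "MI": self.indices.MI,
                    "wavelengths_used": list(self.indices.wavelengths_used),
                },
                "ita": self.ita.__dict__,
                "palette_match": None
                if self.palette_match is None
                else {"id": self.palette_match[0], "delta_e": self.palette_match[1]},
                "sun_exposure": None if self.sun is None else self.sun.__dict__,
                "body_fat_pct": self.body_fat_pct,
                "enhanced": self.enhanced,
                "missing": self.missing,
            },
            indent=1,
            default=enc,
        )


def _splice_enhanced(
    spectrum: ReflectanceSpectrum, model: EnhancerModel
) -> ReflectanceSpectrum:
    """Enhance the 400-730 nm portion, keep the raw spectrum above 730 nm."""
    vis = enhance(model, resample(spectrum, visible_grid()))
    tail_mask = spectrum.wavelengths > visible_grid().max_nm
    wl = np.concatenate([vis.wavelengths, spectrum.wavelengths[tail_mask]])
    vals = np.concatenate([vis.values, spectrum.values[tail_mask]])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return ReflectanceSpectrum(WavelengthGrid(wl), vals, label=spectrum.label)


def analyze(
    spectrum: ReflectanceSpectrum,
    metadata: SubjectMetadata | None = None,
    palette: Sequence[PaletteEntry] | None = None,
    uv_irradiance_w_per_m2: float | None = None,
    model: EnhancerModel | None = None,
    skin_type_override: str | None = None,
    ei_red_nm: float = 880.0,
    use_enhanced_for_indices: bool = True,
    illuminant: str = "D65",
    observer: str = "CIE1931_2deg",
) -> AnalysisReport:
    """Run the full analysis pipeline on one spectrum.

    The spectrum must cover at least 400-730 nm; NIR-dependent outputs
    (EI/MI at 880 nm, body fat at 937/947 nm) additionally need coverage up
    to ~950 nm and are reported as missing — with the reason — when the
    spectrum stops short.  When an enhancer model is supplied, the visible
    portion is enhanced and spliced with the raw NIR tail.
    """
    working = spectrum
    if model is not None:
        working = _splice_enhanced(spectrum, model)

    xyz = spectrum_to_xyz(working, illuminant, observer)
    lab = xyz_to_lab(xyz, white_point(illuminant, observer))
    chroma = xyz_to_xy(xyz)
    ita_val = ita_degrees(lab)
    ita = ITAResult(ita_val, classify_fitzpatrick(ita_val), lab.b_star < 0)

    missing: dict[str, str] = {}
    index_source = working if use_enhanced_for_indices else spectrum

    indices = None
    needed_nm = (880.0, 570.0, 660.0)
    if spectrum.grid.max_nm >= max(needed_nm):
        # NIR lookups always come from the raw spectrum (enhancement covers
        # only the visible range); 570/660 nm follow index_source.
        nir_source = spectrum
        ei = _log_ratio_index(
            value_at(nir_source, ei_red_nm) if ei_red_nm > 730 else value_at(index_source, ei_red_nm),
            value_at(index_source, 570.0),
        )
        mi = _log_ratio_index(
            value_at(nir_source, 880.0), value_at(index_source, 660.0)
        )
        indices = SkinIndices(ei, mi, (ei_red_nm, 570.0, 880.0, 660.0))
    else:
        missing["indices"] = (
            f"spectrum ends at {spectrum.grid.max_nm} nm; EI/MI need 880 nm"
        )

    pal_match = None
    if palette is not None:
        entry, de = match_palette(lab, palette)
        pal_match = (entry.id, de)

    sun = None
    if uv_irradiance_w_per_m2 is not None:
        skin_type = skin_type_override or LABEL_TO_SKIN_TYPE[ita.label]
        sun = sun_exposure(skin_type, uv_irradiance_w_per_m2)

    body_fat = None
    if metadata is not None:
        if spectrum.grid.max_nm >= max(BODY_FAT_NM):
            body_fat = body_fat_percent(
                BodyFatInputs(
                    l1=min(value_at(spectrum, BODY_FAT_NM[0]), 1.0),
                    l2=min(value_at(spectrum, BODY_FAT_NM[1]), 1.0),
                    weight_lbs=metadata.weight_lbs,
                    height_in=metadata.height_in,
                    sex_code=SEX_CODES[metadata.sex],
                    exercise_code=EXERCISE_CODES[metadata.exercise],
                )
            )
        else:
            missing["body_fat_pct"] = (
                f"spectrum ends at {spectrum.grid.max_nm} nm; body fat needs "
                f"{BODY_FAT_NM[1]} nm"
            )

    return AnalysisReport(
        xyz=xyz,
        chromaticity=(chroma.x, chroma.y),
        lab=lab,
        indices=indices,
        ita=ita,
        palette_match=pal_match,
        sun=sun,
        body_fat_pct=body_fat,
        enhanced=model is not None,
        missing=missing,
    )
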