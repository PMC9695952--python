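"""Erythema/melanin indices, ITA and Fitzpatrick bands, palette matching,
sun-exposure timing, body-fat regression, and the combined analysis report."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from skinspec import (
    ColorLab,
    PaletteEntry,
    ReflectanceSpectrum,
    SubjectMetadata,
    WavelengthGrid,
    analyze,
    body_fat_percent,
    classify_fitzpatrick,
    erythema_index,
    ita_degrees,
    match_palette,
    melanin_index,
    read_palette,
    sun_exposure,
)
from skinspec.skin_apps import (
    BodyFatConstants,
    BodyFatInputs,
    LABEL_TO_SKIN_TYPE,
    PaletteError,
    SDD_J_PER_M2,
    delta_e_lab,
)


def two_band_spectrum(r_880, r_570, r_660=None):
    """Spectrum engineered to hit target reflectances at the index bands."""
    wl = np.array([400.0, 570.0, 660.0, 880.0, 1000.0])
    r_660 = r_570 if r_660 is None else r_660
    vals = np.array([r_570, r_570, r_660, r_880, r_880])
    return ReflectanceSpectrum(WavelengthGrid(wl), vals)


class TestIndices:
    def test_unit_ratio_gives_500(self, flat_full):
        assert erythema_index(flat_full) == pytest.approx(500.0)
        assert melanin_index(flat_full) == pytest.approx(500.0)

    def test_ratio_five_gives_1000(self):
        s = two_band_spectrum(r_880=0.5, r_570=0.1, r_660=0.1)
        assert erythema_index(s) == pytest.approx(1000.0)
        assert melanin_index(s) == pytest.approx(1000.0)

    def test_ratio_one_fifth_gives_0(self):
        s = two_band_spectrum(r_880=0.1, r_570=0.5, r_660=0.5)
        assert erythema_index(s) == pytest.approx(0.0)

    def test_nonpositive_reflectance_rejected(self):
        s = two_band_spectrum(r_880=0.0, r_570=0.5)
        with pytest.raises(ValueError):
            melanin_index(s)

    def test_configurable_red_wavelength(self, flat_full):
        assert erythema_index(flat_full, red_nm=660.0) == pytest.approx(500.0)

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.floats(0.05, 0.95), st.floats(0.05, 0.95))
    def test_log_symmetry_about_500(self, ra, rb):
        """EI(ratio r) + EI(ratio 1/r) = 1000."""
        fwd = erythema_index(two_band_spectrum(r_880=ra, r_570=rb))
        rev = erythema_index(two_band_spectrum(r_880=rb, r_570=ra))
        assert fwd + rev == pytest.approx(1000.0)

    def test_strictly_increasing_in_ratio(self):
        ratios = np.linspace(0.2, 5.0, 15)
        vals = [
            erythema_index(two_band_spectrum(r_880=0.19 * r, r_570=0.19))
            for r in ratios
        ]
        assert np.all(np.diff(vals) > 0)


class TestITA:
    @pytest.mark.parametrize(
        "L,b,expected",
        [(50, 10, 0.0), (60, 10, 45.0), (40, 10, -45.0)],
    )
    def test_worked_angles(self, L, b, expected):
        assert ita_degrees(ColorLab(L, 0, b)) == pytest.approx(expected)

    @pytest.mark.parametrize("L,expected", [(60, 90.0), (40, -90.0), (50, 0.0)])
    def test_degenerate_b_zero(self, L, expected):
        assert ita_degrees(ColorLab(L, 0, 0)) == expected

    def test_increasing_in_lightness(self):
        angles = [ita_degrees(ColorLab(L, 0, 15)) for L in np.linspace(20, 90, 20)]
        assert np.all(np.diff(angles) > 0)


class TestFitzpatrick:
    @pytest.mark.parametrize(
        "ita,label",
        [
            (60, "Very light"),
            (50, "Light"),
            (35, "Intermediate"),
            (20, "Tan"),
            (0, "Brown"),
            (-40, "Dark"),
        ],
    )
    def test_band_examples(self, ita, label):
        assert classify_fitzpatrick(ita) == label

    @pytest.mark.parametrize(
        "boundary,label",
        [(55, "Light"), (41, "Intermediate"), (28, "Tan"), (10, "Brown"), (-30, "Dark")],
    )
    def test_boundaries_go_to_darker_class(self, boundary, label):
        assert classify_fitzpatrick(boundary) == label

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(-90, 90, allow_nan=False))
    def test_every_angle_gets_exactly_one_label(self, ita):
        assert classify_fitzpatrick(ita) in (
            "Very light", "Light", "Intermediate", "Tan", "Brown", "Dark",
        )

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_fitzpatrick(float("nan"))


class TestPalette:
    def test_exact_hit(self, fixture_palette):
        target = fixture_palette[7]
        entry, de = match_palette(target.color, fixture_palette)
        assert entry.id == target.id and de == 0.0

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.integers(0, 2**31 - 1))
    def test_equals_brute_force_argmin(self, seed):
        rng = np.random.default_rng(seed)
        palette = [
            PaletteEntry(f"P{i}", ColorLab(*rng.uniform([20, 0, 5], [80, 25, 35])))
            for i in range(5)
        ]
        query = ColorLab(*rng.uniform([20, 0, 5], [80, 25, 35]))
        entry, de = match_palette(query, palette)
        brute = min(delta_e_lab(query, e.color) for e in palette)
        assert de == pytest.approx(brute)
        assert delta_e_lab(query, entry.color) == de

    def test_tie_breaks_to_smallest_id(self):
        same = ColorLab(50, 10, 20)
        palette = [PaletteEntry("B", same), PaletteEntry("A", same)]
        entry, _ = match_palette(ColorLab(60, 10, 20), palette)
        assert entry.id == "A"

    def test_empty_palette_rejected(self):
        with pytest.raises(PaletteError):
            match_palette(ColorLab(50, 0, 0), [])

    def test_fixture_palette_loads(self, fixture_palette):
        assert len(fixture_palette) == 30
        ids = [e.id for e in fixture_palette]
        assert len(set(ids)) == 30


class TestSunExposure:
    def test_type_I_at_unit_irradiance(self):
        assert sun_exposure("I", 1.0).trsvd_s == pytest.approx(37.2)

    def test_type_VI_at_unit_irradiance(self):
        res = sun_exposure("VI", 1.0)
        assert res.trsvd_s == pytest.approx(185.1)
        assert res.rmset_s == pytest.approx(740.4)

    def test_type_III_hand_derived(self):
        assert sun_exposure("III", 0.558).trsvd_s == pytest.approx(100.0)

    @pytest.mark.parametrize("stype", list(SDD_J_PER_M2))
    def test_rmset_is_four_trsvd_and_halves_with_doubled_irradiance(self, stype):
        lo = sun_exposure(stype, 0.7)
        hi = sun_exposure(stype, 1.4)
        assert lo.rmset_s == pytest.approx(4 * lo.trsvd_s)
        assert hi.trsvd_s == pytest.approx(lo.trsvd_s / 2)

    def test_bad_inputs(self):
        with pytest.raises(KeyError):
            sun_exposure("VII", 1.0)
        with pytest.raises(ValueError):
            sun_exposure("I", 0.0)


class TestBodyFat:
    def test_zero_constants_give_zero(self):
        k = BodyFatConstants(0, 0, 0, 0, 0, 0, 0)
        inputs = BodyFatInputs(0.5, 0.5, 150, 70, 0.01, 0.02, K=k)
        assert body_fat_percent(inputs) == 0.0

    def test_canonical_hand_derived_value(self):
        # 84.2 + 8.1 - 13.7 - 1.242 with unit reflectances (log terms vanish)
        inputs = BodyFatInputs(1.0, 1.0, 100, 100, 0.01, 0.0)
        assert body_fat_percent(inputs) == pytest.approx(77.358)

    def test_monotone_in_l1_given_negative_slope(self):
        vals = [
            body_fat_percent(BodyFatInputs(l1, 0.8, 150, 66, 0.01, 0.0))
            for l1 in np.linspace(0.05, 1.0, 12)
        ]
        # K2A < 0: log10(1/l1) shrinks as l1 rises, so body fat increases
        assert np.all(np.diff(vals) > 0)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            BodyFatInputs(0.0, 0.5, 150, 70, 0.01, 0.0)
        with pytest.raises(ValueError):
            BodyFatInputs(0.5, 0.5, -1, 70, 0.01, 0.0)


class TestAnalyze:
    def test_flat_reflector_neutral_everything(self, flat_full, fixture_palette):
        rep = analyze(
            flat_full,
            metadata=SubjectMetadata(150, 70, "male"),
            palette=fixture_palette,
            uv_irradiance_w_per_m2=1.0,
        )
        assert rep.indices.EI == pytest.approx(500.0)
        assert rep.indices.MI == pytest.approx(500.0)
        assert rep.lab.a_star == pytest.approx(0.0, abs=1e-9)
        assert rep.lab.b_star == pytest.approx(0.0, abs=1e-9)
        assert rep.body_fat_pct is not None
        assert not rep.missing

    def test_zero_residual_model_changes_nothing(self, flat_full):
        from skinspec import EnhancerSpec, build_model

        model = build_model(EnhancerSpec(n_layers=3, filters_per_hidden_layer=4), 0)
        w, b = model.weights[-1]
        w[:] = 0
        b[:] = 0
        plain = analyze(flat_full)
        enhanced = analyze(flat_full, model=model)
        assert enhanced.indices.EI == pytest.approx(plain.indices.EI, abs=1e-4)
        assert enhanced.lab.L_star == pytest.approx(plain.lab.L_star, abs=1e-4)
        assert enhanced.enhanced and not plain.enhanced

    def test_report_internally_consistent(self, flat_full):
        rep = analyze(flat_full, uv_irradiance_w_per_m2=2.0)
        assert classify_fitzpatrick(rep.ita.ita_deg) == rep.ita.label
        assert rep.sun.skin_type == LABEL_TO_SKIN_TYPE[rep.ita.label]

    def test_missing_nir_reported_not_silent(self, flat_visible):
        rep = analyze(flat_visible, metadata=SubjectMetadata(150, 70, "female"))
        assert rep.indices is None
        assert "indices" in rep.missing and "880" in rep.missing["indices"]
        assert rep.body_fat_pct is None
        assert "body_fat_pct" in rep.missing

    def test_report_serializes_to_json(self, flat_full):
        import json

        rep = analyze(flat_full, uv_irradiance_w_per_m2=1.0)
        obj = json.loads(rep.to_json())
        assert obj["sun_exposure"]["trsvd_s"] > 0
        assert obj["indices"]["EI"] == pytest.approx(500.0)
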