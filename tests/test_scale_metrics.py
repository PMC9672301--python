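"""Imprecision, inaccuracy, tonic normalization, scale summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vocalscales.scale_metrics import (
    IMPRECISION_OUTLIER_CENTS,
    T12ET,
    SongAnalysis,
    TuningTemplate,
    assign_tonic,
    imprecision,
    inaccuracy,
    interval_spacing,
    max_pitch_classes,
    normalize_to_tonic,
    parse_template,
    scale_series,
    song_summary,
)
from vocalscales.segmentation import PitchClass, PitchClassSet


def _pcs(class_values, tonic=None):
    classes = [
        PitchClass(label=f"PC{i+1}", values=np.asarray(v, float))
        for i, v in enumerate(class_values)
    ]
    means = [c.mean_cents for c in classes]
    bounds = [(a + b) / 2 for a, b in zip(means[:-1], means[1:])]
    pcs = PitchClassSet(boundaries=np.array(bounds), classes=classes)
    return assign_tonic(pcs, tonic)


class TestNormalizeToTonic:
    def test_shift_by_tonic_mean(self):
        pcs = _pcs([[4310, 4315], [4510, 4515]], tonic="PC1")
        out = normalize_to_tonic(pcs)
        assert out.class_by_label("PC1").mean_cents == pytest.approx(0.0, abs=1e-12)
        assert out.class_by_label("PC2").mean_cents == pytest.approx(200.0)
        assert out.meta["tonic_shift_cents"] == pytest.approx(4312.5)

    def test_two_classes_lower_tonic(self):
        pcs = _pcs([[100], [300]], tonic="PC1")
        out = normalize_to_tonic(pcs)
        assert [c.mean_cents for c in out.classes] == [0.0, 200.0]

    def test_pitches_below_tonic_negative(self):
        pcs = _pcs([[100], [300]], tonic="PC2")
        out = normalize_to_tonic(pcs)
        assert out.class_by_label("PC1").mean_cents == pytest.approx(-200.0)

    def test_single_class_centers_on_zero(self):
        out = normalize_to_tonic(_pcs([[10, 20, 30]], tonic="PC1"))
        assert out.classes[0].mean_cents == pytest.approx(0.0, abs=1e-12)

    def test_absent_tonic_rejected(self):
        pcs = _pcs([[0], [200]])
        pcs.tonic_label = None
        with pytest.raises(ValueError, match="tonic"):
            normalize_to_tonic(pcs)

    def test_heuristic_tonic_is_most_used_and_flagged(self):
        pcs = _pcs([[0, 1], [200, 201, 202]])  # PC2 has more annotations
        assert pcs.tonic_label == "PC2"
        assert pcs.tonic_heuristic


class TestImprecision:
    def test_single_annotation_has_zero_range(self):
        out = imprecision(PitchClass("x", [0.0]))
        assert out.range_cents == 0.0 and not out.outlier

    def test_range_is_max_minus_min(self):
        out = imprecision(PitchClass("x", [-80.0, 0.0, 75.0]))
        assert out.range_cents == pytest.approx(155.0)

    def test_range_above_400_flagged_outlier(self):
        out = imprecision(PitchClass("x", [-210.0, 210.0]))
        assert out.range_cents == pytest.approx(420.0)
        assert out.outlier
        assert IMPRECISION_OUTLIER_CENTS == 400.0

    def test_translation_invariance(self, rng):
        vals = rng.normal(0, 40, 200)
        a = imprecision(PitchClass("x", vals))
        b = imprecision(PitchClass("x", vals + 4321.0))
        assert a.range_cents == pytest.approx(b.range_cents)
        assert a.iqr_cents == pytest.approx(b.iqr_cents)

    def test_uniform_width_recovery(self, rng):
        # uniform scatter of total width W, n >= 500 -> range in [0.97 W, W]
        for w in (100.0, 150.0, 200.0):
            vals = rng.uniform(-w / 2, w / 2, 500)
            r = imprecision(PitchClass("x", vals)).range_cents
            assert 0.97 * w <= r <= w


class TestInaccuracy:
    @pytest.mark.parametrize(
        "mean, expected",
        [(200.0, 0.0), (170.0, 30.0), (-250.0, 50.0), (45.0, 45.0), (1199.0, 1.0)],
    )
    def test_twelve_et_fold(self, mean, expected):
        assert inaccuracy(mean, T12ET) == pytest.approx(expected)

    @given(st.floats(min_value=-6000, max_value=6000, allow_nan=False))
    @settings(max_examples=200, deadline=None)
    def test_octave_periodicity_and_symmetry(self, m):
        assert inaccuracy(m + 1200.0) == pytest.approx(inaccuracy(m), abs=1e-8)
        assert inaccuracy(-m) == pytest.approx(inaccuracy(m), abs=1e-8)
        assert 0.0 <= inaccuracy(m) <= 50.0

    def test_uniform_offsets_mean_approaches_25(self, rng):
        # E[min(U, 100-U)] = 25 for U ~ Uniform(0, 100)
        vals = [inaccuracy(m) for m in rng.uniform(0, 100, 10_000)]
        assert np.mean(vals) == pytest.approx(25.0, abs=1.0)


class TestTemplates:
    def test_fold_max_is_half_step(self):
        assert T12ET.fold_max == 50.0
        assert TuningTemplate.equal_temperament(24).fold_max == 25.0

    def test_just_intonation_targets(self):
        ji = TuningTemplate.just_intonation()
        assert 0.0 in ji.targets
        assert any(abs(t - 701.955) < 0.01 for t in ji.targets)  # 3/2
        assert inaccuracy(702.0, ji) == pytest.approx(0.045, abs=0.01)

    def test_parse_template(self):
        assert parse_template("12tet").name == "12tet"
        assert parse_template("Ntet:24").step == pytest.approx(50.0)
        assert parse_template("ji").name == "ji"
        with pytest.raises(ValueError):
            parse_template("pythagorean")


class TestSongSummary:
    def test_means_over_classes(self):
        pcs = normalize_to_tonic(
            _pcs([np.linspace(-50, 50, 11), 170 + np.linspace(-100, 100, 11)], "PC1")
        )
        a = song_summary(pcs, song_id="s")
        assert a.mean_imprecision == pytest.approx(150.0)
        assert a.mean_inaccuracy == pytest.approx(30.0)  # only PC2 contributes

    def test_outlier_class_excluded_from_imprecision_only(self):
        pcs = normalize_to_tonic(
            _pcs(
                [
                    np.linspace(-50, 50, 11),          # range 100
                    np.array([250.0, 260.0]),          # range 10
                    600 + np.linspace(-210, 210, 11),  # range 420 -> outlier
                ],
                "PC1",
            )
        )
        a = song_summary(pcs)
        assert a.mean_imprecision == pytest.approx(55.0)  # mean of 100 and 10
        # outlier class still contributes to inaccuracy (non-tonic classes: 2)
        assert a.per_class["inaccuracy_cents"].notna().sum() == 2

    def test_tonic_only_song_has_nan_inaccuracy(self):
        a = song_summary(normalize_to_tonic(_pcs([[0, 10]], "PC1")))
        assert np.isnan(a.mean_inaccuracy)
        assert a.interval_spacings.size == 0

    def test_requires_normalization(self):
        pcs = _pcs([[100], [300]], "PC1")
        with pytest.raises(ValueError, match="normalized"):
            song_summary(pcs)


class TestIntervalSpacing:
    @pytest.mark.parametrize(
        "means, diffs, mean",
        [
            ([0, 200, 400], [200, 200], 200.0),
            ([0, 155, 465], [155, 310], 232.5),
            ([0], [], np.nan),
        ],
    )
    def test_successive_differences(self, means, diffs, mean):
        d, m = interval_spacing(means)
        assert np.allclose(d, diffs)
        assert m == pytest.approx(mean, nan_ok=True)


class TestMaxPitchClasses:
    @pytest.mark.parametrize(
        "imp, expected", [(1200.0, 1.0), (100.0, 12.0), (200.0, 6.0)]
    )
    def test_octave_quotient(self, imp, expected):
        assert max_pitch_classes(imp) == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            max_pitch_classes(0.0)


class TestScaleSeries:
    def _analysis(self, means, tonic_idx=0):
        classes = [np.array([m - 1.0, m + 1.0]) for m in means]
        pcs = _pcs(classes, f"PC{tonic_idx+1}")
        return song_summary(normalize_to_tonic(pcs))

    def test_nearest_note_names(self):
        series = scale_series(self._analysis([0, 200, 500]), tonic_name="A")
        assert [s["note"] for s in series] == ["A*", "B", "D"]

    def test_halfway_classes_get_slash_names(self):
        series = scale_series(self._analysis([0, 45]), tonic_name="A")
        assert series[1]["note"] == "A/Bb"

    def test_single_tonic_class(self):
        series = scale_series(self._analysis([0]), tonic_name="A")
        assert series == [{"note": "A*", "mean_cents": 0.0, "tonic": True}]

    def test_sharp_tonic_respelled(self):
        series = scale_series(self._analysis([0, 300]), tonic_name="C#")
        assert series[0]["note"] == "Db*"
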