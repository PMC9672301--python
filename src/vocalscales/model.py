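"""Model/Results interface tying the pipeline stages together.

:class:`SongModel` is built from the pitch annotations of one song (or a
trace CSV / WAV file) plus its analysis configuration; ``fit()`` runs
segmentation, tonic normalization and the imprecision/inaccuracy metrics
and returns a :class:`SongResults` with the per-class estimates and a
``summary()`` table.  :class:`GroupComparison` is built from a corpus
table of song-level means; ``fit()`` returns the robust pairwise
comparison results.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import scale_metrics, segmentation, stats
from .pitch_extraction import (
    CentAnnotationSet,
    PitchTrace,
    read_pitch_csv,
    select_excerpt,
)
from .scale_metrics import SongAnalysis, T12ET, TuningTemplate

__all__ = ["SongModel", "SongResults", "GroupComparison", "GroupComparisonResults"]


class SongModel:
    """Pitch-class analysis model for one song excerpt.

    Parameters
    ----------
    annotations : CentAnnotationSet
        Voiced pitch annotations of the excerpt, in cents.
    song_id, group : str
        Identification and group label (region / instrument) of the song.
    tonic_label : str, optional
        Label of the tonic pitch-class (normally a by-ear judgement from
        the song config, e.g. ``"PC2"``).  When omitted the most-used
        class is taken as a heuristic tonic and flagged as such.
    template : TuningTemplate
        Tuning template for the inaccuracy metric (12-ET by default).
    min_gap, peak_factor, min_class_frac, min_class_size
        Segmentation peak criterion and small-class merge rule.
    boundary_overrides : sequence of float, optional
        Manual boundary cent values replacing the detected ones verbatim.
    excluded_classes : sequence of str, optional
        Labels of non-discrete classes to remove before the metrics.
    """

    def __init__(
        self,
        annotations: CentAnnotationSet,
        song_id: str = "",
        group: str | None = None,
        tonic_label: str | None = None,
        template: TuningTemplate = T12ET,
        min_gap: float = segmentation.DEFAULT_MIN_GAP,
        peak_factor: float = segmentation.DEFAULT_PEAK_FACTOR,
        min_class_frac: float = segmentation.DEFAULT_MIN_CLASS_FRAC,
        min_class_size: int = segmentation.DEFAULT_MIN_CLASS_SIZE,
        boundary_overrides=None,
        excluded_classes=None,
    ) -> None:
        self.annotations = annotations
        self.song_id = song_id or annotations.source_id
        self.group = group
        self.tonic_label = tonic_label
        self.template = template
        self.min_gap = min_gap
        self.peak_factor = peak_factor
        self.min_class_frac = min_class_frac
        self.min_class_size = min_class_size
        self.boundary_overrides = boundary_overrides
        self.excluded_classes = excluded_classes

    @classmethod
    def from_csv(
        cls,
        path,
        window=None,
        pitch_band=None,
        **kwargs,
    ) -> "SongModel":
        """Build from a ``time_s,f0_hz`` pitch-trace CSV."""
        trace = read_pitch_csv(path)
        return cls.from_trace(trace, window=window, pitch_band=pitch_band, **kwargs)

    @classmethod
    def from_trace(
        cls,
        trace: PitchTrace,
        window=None,
        pitch_band=None,
        **kwargs,
    ) -> "SongModel":
        ann = select_excerpt(trace, window=window, pitch_band=pitch_band)
        kwargs.setdefault("song_id", trace.source_id)
        return cls(ann, **kwargs)

    def fit(self) -> "SongResults":
        """Segment, normalize to the tonic and compute the metrics."""
        gf = segmentation.gap_function(self.annotations)
        detected = segmentation.detect_boundaries(
            gf,
            min_gap=self.min_gap,
            peak_factor=self.peak_factor,
            min_class_frac=self.min_class_frac,
            min_class_size=self.min_class_size,
        )
        pcs = segmentation.apply_boundaries(
            self.annotations,
            detected,
            overrides=self.boundary_overrides,
            exclusions=self.excluded_classes,
        )
        pcs = scale_metrics.assign_tonic(pcs, self.tonic_label)
        pcs = scale_metrics.normalize_to_tonic(pcs)
        analysis = scale_metrics.song_summary(
            pcs,
            song_id=self.song_id,
            group=self.group,
            template=self.template,
        )
        return SongResults(
            model=self,
            pitch_classes=pcs,
            analysis=analysis,
            detected_boundaries=np.asarray(detected, dtype=float),
        )


@dataclass
class SongResults:
    """Fitted per-song results: pitch-classes, metrics, exports."""

    model: SongModel = field(repr=False)
    pitch_classes: segmentation.PitchClassSet = field(repr=False)
    analysis: SongAnalysis = field(repr=False)
    detected_boundaries: np.ndarray = field(repr=False)

    @property
    def per_class(self) -> pd.DataFrame:
        return self.analysis.per_class

    @property
    def mean_imprecision(self) -> float:
        return self.analysis.mean_imprecision

    @property
    def mean_inaccuracy(self) -> float:
        return self.analysis.mean_inaccuracy

    def scale_series(self, tonic_name: str = "A") -> list[dict]:
        return scale_metrics.scale_series(self.analysis, tonic_name=tonic_name)

    def to_row(self) -> dict:
        """One corpus-summary row of song-level means."""
        a = self.analysis
        return {
            "song_id": a.song_id,
            "group": a.group,
            "n_classes": a.n_classes,
            "mean_imprecision": a.mean_imprecision,
            "mean_iqr": a.mean_iqr,
            "mean_inaccuracy": a.mean_inaccuracy,
            "mean_interval_cents": a.mean_interval_cents,
            "noise_removed": a.noise_removed,
            "tonic_heuristic": a.tonic_heuristic,
        }

    def summary(self) -> str:
        a = self.analysis
        cols = [
            "class_label", "mean_cents", "count", "imprecision_cents",
            "iqr_cents", "inaccuracy_cents", "outlier_flag", "tonic_flag",
        ]
        table = a.per_class[cols].round(1)
        lines = [
            f"Song {a.song_id!r}"
            + (f" [{a.group}]" if a.group else "")
            + f" — {a.n_classes} pitch-classes, template {a.template}"
            + (", heuristic tonic" if a.tonic_heuristic else ""),
            table.to_string(index=False),
            (
                f"M imprecision = {a.mean_imprecision:.1f} cents, "
                f"M inaccuracy = "
                + (
                    "n/a"
                    if np.isnan(a.mean_inaccuracy)
                    else f"{a.mean_inaccuracy:.1f} cents"
                )
            ),
        ]
        if a.interval_spacings.size:
            lines.append(
                f"interval spacing: "
                + ", ".join(f"{s:.1f}" for s in a.interval_spacings)
                + f" (mean {a.mean_interval_cents:.1f} cents"
                f" = {a.mean_interval_cents / 100:.1f} semitones)"
            )
        return "\n".join(lines)


class GroupComparison:
    """Group comparison model over a table of song-level values.

    Parameters
    ----------
    data : DataFrame
        One row per song.
    value : str
        Column holding the dependent variable (e.g. ``mean_imprecision``).
    group : str
        Column holding the group label.
    method : {"games-howell", "trimmed"}
        Robust pairwise procedure.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        value: str = "mean_imprecision",
        group: str = "group",
        method: str = "games-howell",
        alpha: float = 0.05,
    ) -> None:
        if value not in data.columns or group not in data.columns:
            raise ValueError(f"data must have columns {value!r} and {group!r}")
        self.data = data
        self.value = value
        self.group = group
        self.method = method
        self.alpha = alpha

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "GroupComparison":
        return cls(data, **kwargs)

    def _groups(self) -> dict[str, np.ndarray]:
        return {
            str(name): sub[self.value].to_numpy(float)
            for name, sub in self.data.groupby(self.group, sort=True)
        }

    def fit(self) -> "GroupComparisonResults":
        res = stats.robust_pairwise(
            self._groups(),
            alpha=self.alpha,
            method=self.method,
            variable=self.value,
        )
        var = stats.variance_tests(self._groups())
        return GroupComparisonResults(model=self, comparison=res, variance=var)


@dataclass
class GroupComparisonResults:
    """Fitted group-comparison results with variance diagnostics."""

    model: GroupComparison = field(repr=False)
    comparison: stats.GroupComparisonResult = field(repr=False)
    variance: dict = field(repr=False)

    @property
    def pairwise(self) -> pd.DataFrame:
        return self.comparison.pairwise

    @property
    def describe(self) -> pd.DataFrame:
        return self.comparison.describe

    def kde_export(self, n_points: int = 128) -> pd.DataFrame:
        """Per-group Gaussian kernel density estimates (Scott bandwidth).

        Returns tidy rows (group, value, density) suitable for mirrored
        violin plotting; each group's density integrates to ~1.
        """
        from scipy.stats import gaussian_kde

        rows = []
        for name, v in self.model._groups().items():
            if v.size < 2 or np.std(v) == 0:
                continue
            kde = gaussian_kde(v)  # Scott's rule
            lo, hi = v.min() - 2 * v.std(), v.max() + 2 * v.std()
            xs = np.linspace(lo, hi, n_points)
            dens = kde(xs)
            rows.extend(
                {"group": name, "value": x, "density": d} for x, d in zip(xs, dens)
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        v = self.variance["overall"]
        return (
            self.comparison.summary()
            + "\n\n"
            + f"Variance homogeneity (Levene, {v['center']}-centered): "
            f"F = {v['f']:.3f}, df = {v['df']}, p = {v['p']:.3g}"
        )
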