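"""Pitch-class imprecision, tuning inaccuracy, and scale summaries.

Two dependent variables are computed per discrete pitch-class:

* **imprecision** — the range (max - min, in cents) of the class's
  annotation distribution.  Ranges above 400 cents (a whole tone on
  either side of the centre) are flagged as outliers and excluded from
  the imprecision analysis; the inter-quartile range is carried alongside
  as a less outlier-sensitive alternative.
* **inaccuracy** — the folded absolute distance (0-50 cents for 12-ET) of
  the class's tonic-relative mean from the nearest target of a tuning
  template.  The tonic itself is the tuning reference and has no
  inaccuracy value.

All class means are expressed relative to the mean of the tonic
pitch-class, which is assigned 0 cents; pitches below the tonic are
negative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .segmentation import PitchClass, PitchClassSet

__all__ = [
    "TuningTemplate",
    "SongAnalysis",
    "IMPRECISION_OUTLIER_CENTS",
    "assign_tonic",
    "normalize_to_tonic",
    "imprecision",
    "inaccuracy",
    "song_summary",
    "interval_spacing",
    "max_pitch_classes",
    "scale_series",
]

#: Pitch-class ranges above this are treated as outliers (whole tone either side).
IMPRECISION_OUTLIER_CENTS = 400.0

#: Standard 12-tone just-intonation ratio set (tonic-relative).
DEFAULT_JI_RATIOS = (
    Fraction(1, 1), Fraction(16, 15), Fraction(9, 8), Fraction(6, 5),
    Fraction(5, 4), Fraction(4, 3), Fraction(45, 32), Fraction(3, 2),
    Fraction(8, 5), Fraction(5, 3), Fraction(16, 9), Fraction(15, 8),
)


@dataclass(frozen=True)
class TuningTemplate:
    """A set of target pitch offsets (cents from the tonic) per octave.

    ``step`` is set for equal-temperament templates, enabling the exact
    modular fold; otherwise distances are measured to the octave-replicated
    target set.  0 cents (the tonic) is always a target.
    """

    name: str
    targets: tuple[float, ...]
    step: float | None = None

    def __post_init__(self) -> None:
        t = tuple(sorted(set(float(x) % 1200.0 for x in self.targets)))
        if 0.0 not in t:
            t = (0.0,) + t
        object.__setattr__(self, "targets", t)

    @classmethod
    def equal_temperament(cls, n: int = 12) -> "TuningTemplate":
        """N equal divisions of the octave (12-ET by default)."""
        if n < 1:
            raise ValueError("need at least one division per octave")
        step = 1200.0 / n
        return cls(
            name="12tet" if n == 12 else f"{n}tet",
            targets=tuple(step * i for i in range(n)),
            step=step,
        )

    @classmethod
    def just_intonation(cls, ratios=DEFAULT_JI_RATIOS) -> "TuningTemplate":
        """Just-intonation targets ``1200*log2(ratio)``, octave-replicated."""
        cents = tuple(1200.0 * math.log2(float(r)) for r in ratios)
        return cls(name="ji", targets=cents)

    @property
    def fold_max(self) -> float:
        """Largest attainable inaccuracy: half the widest target gap."""
        if self.step is not None:
            return self.step / 2.0
        t = np.asarray(self.targets + (self.targets[0] + 1200.0,))
        return float(np.max(np.diff(t)) / 2.0)

    def distance(self, cents: float) -> float:
        """Folded distance from ``cents`` to the nearest template target."""
        if self.step is not None:
            d = float(cents) % self.step
            return min(d, self.step - d)
        m = float(cents) % 1200.0
        t = np.asarray(self.targets)
        d = np.abs(t - m)
        return float(min(d.min(), 1200.0 - d.max()))


T12ET = TuningTemplate.equal_temperament(12)


def parse_template(spec: str) -> TuningTemplate:
    """Parse a template name: ``12tet``, ``Ntet:<N>`` or ``ji``."""
    s = spec.strip().lower()
    if s in ("12tet", "12-et", "12et"):
        return TuningTemplate.equal_temperament(12)
    if s.startswith("ntet:"):
        return TuningTemplate.equal_temperament(int(s.split(":", 1)[1]))
    if s == "ji":
        return TuningTemplate.just_intonation()
    raise ValueError(f"unknown tuning template {spec!r}")


# ---------------------------------------------------------------------------
# Tonic handling
# ---------------------------------------------------------------------------

def assign_tonic(pcs: PitchClassSet, tonic_label: str | None = None) -> PitchClassSet:
    """Record the tonic class on a segmentation.

    When no label is supplied (the tonic is normally a by-ear judgement
    recorded in the song config), fall back to the heuristic of taking the
    class with the greatest annotation count, and flag the result as
    heuristic.
    """
    if tonic_label is not None:
        pcs.class_by_label(tonic_label)  # raises KeyError if absent
        pcs.tonic_label = tonic_label
        pcs.tonic_heuristic = False
    else:
        pcs.tonic_label = max(pcs.classes, key=lambda c: c.count).label
        pcs.tonic_heuristic = True
    return pcs


def normalize_to_tonic(pcs: PitchClassSet, tonic_label: str | None = None) -> PitchClassSet:
    """Shift every annotation so the tonic class mean is exactly 0 cents."""
    label = tonic_label if tonic_label is not None else pcs.tonic_label
    if label is None:
        raise ValueError("no tonic label set; pass tonic_label or call assign_tonic")
    try:
        tonic = pcs.class_by_label(label)
    except KeyError as e:
        raise ValueError(f"tonic class {label!r} absent or excluded") from e
    shift = tonic.mean_cents
    out = PitchClassSet(
        boundaries=pcs.boundaries - shift,
        classes=[
            PitchClass(label=c.label, values=c.values - shift, discrete=c.discrete)
            for c in pcs.classes
        ],
        noise_removed=pcs.noise_removed,
        tonic_label=label,
        tonic_heuristic=pcs.tonic_heuristic,
        meta=dict(pcs.meta, tonic_shift_cents=shift),
    )
    return out


# ---------------------------------------------------------------------------
# The two dependent variables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Imprecision:
    range_cents: float
    iqr_cents: float
    outlier: bool


def imprecision(pc: PitchClass, outlier_cents: float = IMPRECISION_OUTLIER_CENTS) -> Imprecision:
    """Pitch-class range in cents (max - min), with the outlier rule.

    Ranges above ``outlier_cents`` are flagged as outliers; flagged classes
    are excluded from imprecision means downstream but keep their value
    here.  The inter-quartile range is computed alongside.
    """
    if pc.count < 1:
        raise ValueError(f"pitch-class {pc.label!r} is empty")
    rng = pc.max_cents - pc.min_cents
    q75, q25 = np.percentile(pc.values, [75, 25])
    return Imprecision(
        range_cents=float(rng),
        iqr_cents=float(q75 - q25),
        outlier=bool(rng > outlier_cents),
    )


def inaccuracy(tonic_relative_mean: float, template: TuningTemplate = T12ET) -> float:
    """Folded distance of a tonic-relative class mean to the template.

    For 12-ET: ``d = mean mod 100; min(d, 100 - d)``, so the value lies in
    [0, 50] with 50 the halfway point between adjacent targets.  Assumes
    tonic normalization has been applied.
    """
    return template.distance(tonic_relative_mean)


# ---------------------------------------------------------------------------
# Song-level summary
# ---------------------------------------------------------------------------

@dataclass
class SongAnalysis:
    """Per-class metrics and song-level means for one analysed excerpt."""

    song_id: str
    group: str | None
    per_class: pd.DataFrame = field(repr=False)
    mean_imprecision: float
    mean_iqr: float
    mean_inaccuracy: float  # NaN when no non-tonic class exists
    tonic_label: str
    template: str
    interval_spacings: np.ndarray
    noise_removed: int = 0
    tonic_heuristic: bool = False

    @property
    def n_classes(self) -> int:
        return int(len(self.per_class))

    @property
    def mean_interval_cents(self) -> float:
        if self.interval_spacings.size == 0:
            return float("nan")
        return float(np.mean(self.interval_spacings))


def song_summary(
    pcs: PitchClassSet,
    song_id: str = "",
    group: str | None = None,
    template: TuningTemplate = T12ET,
    outlier_cents: float = IMPRECISION_OUTLIER_CENTS,
) -> SongAnalysis:
    """Summarize a tonic-normalized segmentation into a :class:`SongAnalysis`.

    * ``mean_imprecision`` — unweighted mean of class ranges over classes
      not flagged as range outliers;
    * ``mean_inaccuracy`` — unweighted mean over non-tonic classes (the
      tonic is the tuning reference, inaccuracy n/a); outlier classes are
      retained here (the outlier rule scopes to the range variable only);
    * per-class table mirrors the scale-analysis report layout.
    """
    if pcs.tonic_label is None:
        raise ValueError("segmentation has no tonic; call assign_tonic first")
    tonic = pcs.class_by_label(pcs.tonic_label)
    if abs(tonic.mean_cents) > 1e-6:
        raise ValueError("segmentation is not tonic-normalized")

    rows = []
    for c in pcs.classes:
        imp = imprecision(c, outlier_cents=outlier_cents)
        is_tonic = c.label == pcs.tonic_label
        rows.append(
            {
                "class_label": c.label,
                "mean_cents": c.mean_cents,
                "count": c.count,
                "imprecision_cents": imp.range_cents,
                "iqr_cents": imp.iqr_cents,
                "inaccuracy_cents": (
                    np.nan if is_tonic else inaccuracy(c.mean_cents, template)
                ),
                "outlier_flag": imp.outlier,
                "tonic_flag": is_tonic,
            }
        )
    table = pd.DataFrame(rows).sort_values("mean_cents", ignore_index=True)

    kept = table.loc[~table["outlier_flag"]]
    if kept.empty:
        raise ValueError(f"song {song_id!r}: every class excluded as range outlier")
    mean_imp = float(kept["imprecision_cents"].mean())
    mean_iqr = float(kept["iqr_cents"].mean())
    nontonic = table.loc[~table["tonic_flag"], "inaccuracy_cents"]
    mean_inacc = float(nontonic.mean()) if len(nontonic) else float("nan")

    spac, _ = interval_spacing(table["mean_cents"].to_numpy())
    return SongAnalysis(
        song_id=song_id,
        group=group,
        per_class=table,
        mean_imprecision=mean_imp,
        mean_iqr=mean_iqr,
        mean_inaccuracy=mean_inacc,
        tonic_label=pcs.tonic_label,
        template=template.name,
        interval_spacings=spac,
        noise_removed=pcs.noise_removed,
        tonic_heuristic=pcs.tonic_heuristic,
    )


def interval_spacing(class_means) -> tuple[np.ndarray, float]:
    """Successive differences of sorted class means, plus their mean (cents).

    Returns an empty array (and NaN mean) for fewer than two classes.
    """
    m = np.sort(np.asarray(class_means, dtype=float))
    if m.size < 2:
        return np.empty(0), float("nan")
    d = np.diff(m)
    return d, float(np.mean(d))


def max_pitch_classes(mean_imprecision: float) -> float:
    """Upper bound on pitch-classes per octave implied by imprecision.

    If adjacent scale degrees must sit at least one mean pitch-class width
    apart to stay distinguishable, an octave can hold at most
    ``1200 / mean_imprecision`` classes.  Reported to one decimal.
    """
    if mean_imprecision <= 0:
        raise ValueError("mean imprecision must be positive")
    return 1200.0 / float(mean_imprecision)


# ---------------------------------------------------------------------------
# Scale-series export
# ---------------------------------------------------------------------------

_CHROMA_FLAT = ["C", "Db", "D", "Eb", "E", "F", "Gb", "G", "Ab", "A", "Bb", "B"]
#: Inaccuracy band (cents) in which a note is named with a slash (e.g. Eb/E).
SLASH_BAND = (40.0, 50.0)


def _note_name(tonic_index: int, semis: int) -> str:
    return _CHROMA_FLAT[(tonic_index + semis) % 12]


def scale_series(
    analysis: SongAnalysis,
    tonic_name: str = "A",
) -> list[dict]:
    """Ordered scale series with nearest-12-ET note names.

    Each entry carries the note name, the tonic-relative mean in cents and
    a tonic marker.  Classes whose 12-ET fold distance falls in the
    ``SLASH_BAND`` — i.e. roughly halfway between keyboard notes — are
    named with a slash between the two flanking notes ("A/Bb").  This is a
    deterministic convenience mapping from cents, not a transcription.
    """
    if tonic_name not in _CHROMA_FLAT:
        # accept sharps by enharmonic respelling
        sharps = {"C#": "Db", "D#": "Eb", "F#": "Gb", "G#": "Ab", "A#": "Bb"}
        tonic_name = sharps.get(tonic_name, tonic_name)
    try:
        t_idx = _CHROMA_FLAT.index(tonic_name)
    except ValueError:
        raise ValueError(f"unknown tonic note name {tonic_name!r}") from None

    out = []
    for _, row in analysis.per_class.iterrows():
        m = float(row["mean_cents"])
        fold = T12ET.distance(m)
        if SLASH_BAND[0] < fold <= SLASH_BAND[1]:
            lo = math.floor(m / 100.0)
            name = f"{_note_name(t_idx, lo)}/{_note_name(t_idx, lo + 1)}"
        else:
            name = _note_name(t_idx, round(m / 100.0))
        is_tonic = bool(row["tonic_flag"])
        out.append(
            {
                "note": name + ("*" if is_tonic else ""),
                "mean_cents": round(m, 1),
                "tonic": is_tonic,
            }
        )
    return out
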