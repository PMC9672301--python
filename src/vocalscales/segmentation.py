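"""Pitch-class segmentation of cent-annotation sets.

A sung melody's pitch annotations, sorted from lowest to highest cent
value, form clusters separated by large jumps.  The first difference of
the sorted annotations (the "gap function") peaks at cluster boundaries;
a boundary is placed at the midpoint of each peak gap.  Classes that are
too small to be real scale degrees are merged into their nearest
neighbour, and manual boundary overrides / class exclusions emulate the
by-hand adjustment of melograph boundary lines.

The peak criterion is relative: a gap is a peak when it exceeds
``max(min_gap, k * median positive gap)``.  Within-class gaps shrink as
annotation density grows, so the multiplicative part adapts to density
while the absolute floor prevents spurious splits in sparse traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .pitch_extraction import CentAnnotationSet

__all__ = [
    "GapFunction",
    "PitchClass",
    "PitchClassSet",
    "gap_function",
    "detect_boundaries",
    "apply_boundaries",
    "segment",
]

#: Default absolute peak floor in cents.
DEFAULT_MIN_GAP = 30.0
#: Default multiple of the median positive gap defining a peak.
DEFAULT_PEAK_FACTOR = 8.0
#: Classes below this fraction of the annotations are merged away.
DEFAULT_MIN_CLASS_FRAC = 0.02
#: ... subject to this absolute floor on class size.
DEFAULT_MIN_CLASS_SIZE = 5


@dataclass
class GapFunction:
    """Sorted annotations and their first differences."""

    sorted_cents: np.ndarray
    gaps: np.ndarray

    def __post_init__(self) -> None:
        self.sorted_cents = np.asarray(self.sorted_cents, dtype=float)
        self.gaps = np.asarray(self.gaps, dtype=float)


@dataclass
class PitchClass:
    """One discrete pitch-class: its member annotations and summary."""

    label: str
    values: np.ndarray
    discrete: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def mean_cents(self) -> float:
        return float(np.mean(self.values))

    @property
    def count(self) -> int:
        return int(self.values.size)

    @property
    def min_cents(self) -> float:
        return float(np.min(self.values))

    @property
    def max_cents(self) -> float:
        return float(np.max(self.values))


@dataclass
class PitchClassSet:
    """Segmented, labelled pitch-classes for one song excerpt.

    ``boundaries`` are the cent values separating classes (ascending);
    annotation ``v`` belongs to class ``k`` iff
    ``boundaries[k-1] < v <= boundaries[k]`` (upper-inclusive).
    ``noise_removed`` counts annotations excluded as non-discrete/noise.
    """

    boundaries: np.ndarray
    classes: list[PitchClass]
    noise_removed: int = 0
    tonic_label: str | None = None
    tonic_heuristic: bool = False
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        means = [c.mean_cents for c in self.classes]
        if any(b >= a for a, b in zip(means[1:], means[:-1])):
            raise ValueError("class means must be strictly increasing")

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.classes]

    def class_by_label(self, label: str) -> PitchClass:
        for c in self.classes:
            if c.label == label:
                return c
        raise KeyError(f"no pitch-class labelled {label!r}")

    @property
    def n_annotations(self) -> int:
        return sum(c.count for c in self.classes) + self.noise_removed


def _as_cents(annotations) -> np.ndarray:
    if isinstance(annotations, CentAnnotationSet):
        return annotations.cents
    return np.asarray(annotations, dtype=float)


def gap_function(annotations) -> GapFunction:
    """Sort the annotations ascending and take first differences.

    Requires at least two annotations; deterministic (numpy stable sort).
    """
    cents = _as_cents(annotations)
    if cents.size < 2:
        raise ValueError("gap function requires at least 2 annotations")
    s = np.sort(cents, kind="stable")
    return GapFunction(sorted_cents=s, gaps=np.diff(s))


def detect_boundaries(
    gf: GapFunction,
    min_gap: float = DEFAULT_MIN_GAP,
    peak_factor: float = DEFAULT_PEAK_FACTOR,
    min_class_frac: float = DEFAULT_MIN_CLASS_FRAC,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
) -> np.ndarray:
    """Propose pitch-class boundaries from the gap function.

    A gap is a peak when it is at least ``max(min_gap, peak_factor *
    median positive gap)``; the boundary sits at the midpoint of the two
    annotations flanking the peak.  Classes smaller than
    ``max(min_class_size, min_class_frac * n)`` are merged into the
    neighbouring class across the smaller of their flanking gaps.

    May return an empty array (a single class).
    """
    s = gf.sorted_cents
    gaps = gf.gaps
    n = s.size
    pos = gaps[gaps > 0]
    crit = min_gap if pos.size == 0 else max(min_gap, peak_factor * float(np.median(pos)))
    peak_idx = np.flatnonzero(gaps >= crit)

    # class sizes induced by the peak cuts
    cuts = list(peak_idx)  # class k = s[cut_{k-1}+1 : cut_k + 1]
    min_size = max(int(min_class_size), int(np.ceil(min_class_frac * n)))

    def sizes(cut_list):
        edges = [-1] + list(cut_list) + [n - 1]
        return [edges[i + 1] - edges[i] for i in range(len(edges) - 1)]

    # merge undersized classes into the nearest neighbour (smaller flanking gap)
    while cuts:
        sz = sizes(cuts)
        small = [i for i, c in enumerate(sz) if c < min_size]
        if not small:
            break
        i = min(small, key=lambda j: sz[j])
        left_gap = gaps[cuts[i - 1]] if i > 0 else np.inf
        right_gap = gaps[cuts[i]] if i < len(cuts) else np.inf
        if left_gap <= right_gap:
            cuts.pop(i - 1)
        else:
            cuts.pop(i)

    return np.array([(s[i] + s[i + 1]) / 2.0 for i in cuts], dtype=float)


def _default_labels(k: int) -> list[str]:
    return [f"PC{i + 1}" for i in range(k)]


def apply_boundaries(
    annotations,
    boundaries,
    overrides=None,
    exclusions=None,
    labels: list[str] | None = None,
) -> PitchClassSet:
    """Bin annotations into pitch-classes given boundary cent values.

    ``overrides``, when given, replace the detected boundaries verbatim
    (must be ascending).  ``exclusions`` is a list of class labels to flag
    non-discrete and remove; their annotation counts accumulate in
    ``noise_removed``.  Annotations exactly on a boundary go to the lower
    class (half-open intervals, upper-inclusive).
    """
    cents = _as_cents(annotations)
    if cents.size == 0:
        raise ValueError("cannot segment an empty annotation set")
    b = np.asarray(boundaries, dtype=float)
    if overrides is not None:
        b = np.asarray(overrides, dtype=float)
    if b.size > 1 and not np.all(np.diff(b) > 0):
        raise ValueError("boundaries must be strictly ascending")

    # value v in class k iff b[k-1] < v <= b[k]
    idx = np.searchsorted(b, cents, side="left")
    k = b.size + 1
    if labels is None:
        labels = _default_labels(k)
    elif len(labels) != k:
        raise ValueError(f"expected {k} labels, got {len(labels)}")

    classes: list[PitchClass] = []
    noise = 0
    exclusions = set(exclusions or ())
    unknown = exclusions - set(labels)
    if unknown:
        raise ValueError(f"excluded labels not present: {sorted(unknown)}")
    for j in range(k):
        vals = cents[idx == j]
        if vals.size == 0:
            continue
        lab = labels[j]
        if lab in exclusions:
            noise += vals.size
            continue
        classes.append(PitchClass(label=lab, values=vals))
    if not classes:
        raise ValueError("all pitch-classes were excluded or empty")
    return PitchClassSet(boundaries=b, classes=classes, noise_removed=noise)


def segment(
    annotations,
    min_gap: float = DEFAULT_MIN_GAP,
    peak_factor: float = DEFAULT_PEAK_FACTOR,
    min_class_frac: float = DEFAULT_MIN_CLASS_FRAC,
    min_class_size: int = DEFAULT_MIN_CLASS_SIZE,
    overrides=None,
    exclusions=None,
) -> PitchClassSet:
    """Full segmentation: gap function -> boundary detection -> binning."""
    gf = gap_function(annotations)
    b = detect_boundaries(
        gf,
        min_gap=min_gap,
        peak_factor=peak_factor,
        min_class_frac=min_class_frac,
        min_class_size=min_class_size,
    )
    return apply_boundaries(annotations, b, overrides=overrides, exclusions=exclusions)
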