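"""Recovery and calibration experiments.

Self-contained experiments that exercise the pipeline against known
ground truth: corpus-level parameter recovery, segmentation against an
exhaustive oracle, family-wise error calibration of the robust pairwise
procedure, instrument-ordering recovery, and YIN tracking accuracy.
Each returns plain numbers so results can be asserted in tests or
reported by reproduction scripts.
"""

from __future__ import annotations

import itertools

import numpy as np

from .model import SongModel
from .pitch_extraction import hz_to_cents, yin_f0
from .segmentation import detect_boundaries, gap_function
from .stats import games_howell
from .synthetic import GroupProfile, INSTRUMENT_PRESETS, generate_corpus

__all__ = [
    "recovery_experiment",
    "exhaustive_min_range_split",
    "segmentation_oracle_agreement",
    "fwe_experiment",
    "instrument_ordering_experiment",
    "yin_accuracy_experiment",
]


def recovery_experiment(
    n_songs: int = 100,
    width: float = 150.0,
    offset_scale: float = 50.0,
    seed: int = 0,
) -> dict:
    """Corpus-level recovery of imprecision and inaccuracy.

    Generates ``n_songs`` synthetic songs with uniform class scatter of
    total width ``width`` around 12-ET centres (spaced 300 cents) whose
    tuning offsets are uniform over ``+-offset_scale`` cents, runs the
    full pipeline with the ground-truth tonic (the lowest class), and
    returns the corpus means of song-level mean imprecision and mean
    inaccuracy.

    With offsets uniform over +-50 cents the folded distance of a class
    mean from the 12-ET grid is uniform on [0, 50], so the expected
    corpus mean inaccuracy is 25 cents; the expected range of a uniform
    sample of width W is W*(n-1)/(n+1), just under W.
    """
    profile = GroupProfile(
        name="recovery",
        width_mean=width,
        width_sd=0.0,
        offset_scale=offset_scale,
    )
    corpus = generate_corpus({"recovery": profile}, songs_per_group=n_songs, seed=seed)
    imps, inaccs = [], []
    for _, _, ann, _ in corpus.songs:
        res = SongModel(ann, tonic_label="PC1").fit()
        imps.append(res.mean_imprecision)
        inaccs.append(res.mean_inaccuracy)
    return {
        "mean_imprecision": float(np.mean(imps)),
        "mean_inaccuracy": float(np.nanmean(inaccs)),
        "n_songs": n_songs,
    }


def exhaustive_min_range_split(sorted_vals: np.ndarray, k: int) -> list[np.ndarray]:
    """Oracle segmentation: best split into k contiguous groups.

    Enumerates every placement of k-1 cuts between consecutive sorted
    values and returns the partition minimizing the sum of within-group
    ranges.  Exponential in k; intended for tiny instances only.
    """
    n = sorted_vals.size
    best, best_cost = None, np.inf
    for cuts in itertools.combinations(range(n - 1), k - 1):
        edges = (-1,) + cuts + (n - 1,)
        cost = 0.0
        parts = []
        for a, b in zip(edges[:-1], edges[1:]):
            grp = sorted_vals[a + 1 : b + 1]
            parts.append(grp)
            cost += grp[-1] - grp[0]
        if cost < best_cost:
            best_cost, best = cost, parts
    return best


def segmentation_oracle_agreement(
    n_instances: int = 200,
    seed: int = 0,
) -> dict:
    """Compare detect_boundaries with the exhaustive range-sum oracle.

    Each instance has <= 30 annotations in 1-3 well-separated clusters
    (centre separation > 3x the within-cluster scatter).  Agreement means
    the detected partition of the sorted values is identical to the
    oracle's minimum-range-sum partition at the true class count.
    """
    rng = np.random.default_rng(seed)
    agree = 0
    for _ in range(n_instances):
        k = int(rng.integers(1, 4))
        half = float(rng.uniform(10.0, 40.0))  # within-cluster half-width
        # separation strictly greater than 3x the full scatter width
        sep = float(rng.uniform(6.2 * half, 9.0 * half) + 40.0)
        centers = np.cumsum(np.concatenate([[0.0], rng.uniform(1.0, 1.5, k - 1) * sep]))
        sizes = rng.integers(5, 11, k)
        while sizes.sum() > 30:
            sizes[np.argmax(sizes)] -= 1
        vals = np.concatenate(
            [c + rng.uniform(-half, half, s) for c, s in zip(centers, sizes)]
        )
        s = np.sort(vals)
        oracle = exhaustive_min_range_split(s, k)
        b = detect_boundaries(gap_function(vals))
        detected = np.split(s, np.searchsorted(s, b))
        same = len(detected) == len(oracle) and all(
            len(d) == len(o) and np.allclose(d, o)
            for d, o in zip(detected, oracle)
        )
        agree += bool(same)
    return {"agreement": agree / n_instances, "n_instances": n_instances}


def fwe_experiment(
    n_reps: int = 1000,
    n_groups: int = 5,
    n_per_group: int = 40,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Family-wise type-I error of Games–Howell under heteroscedasticity.

    Equal-mean normal groups with SDs spread over 1-4; a replicate counts
    as a family-wise rejection when any pairwise adjusted p falls below
    ``alpha``.
    """
    rng = np.random.default_rng(seed)
    sds = np.linspace(1.0, 4.0, n_groups)
    rejections = 0
    for _ in range(n_reps):
        groups = {
            f"g{i}": rng.normal(0.0, sds[i], n_per_group) for i in range(n_groups)
        }
        pw = games_howell(groups, alpha=alpha)
        rejections += bool((pw["p_adj"] < alpha).any())
    return {"fwe": rejections / n_reps, "n_reps": n_reps, "alpha": alpha}


def instrument_ordering_experiment(
    n_seeds: int = 50,
    songs_per_group: int = 8,
    seed: int = 0,
) -> dict:
    """Recovery of the imprecision gradient across instrument presets.

    For each corpus seed, generates the four instrument groups (eight
    songs each, as in the controlled recording study), runs the pipeline
    and checks that group mean imprecision is strictly ordered
    organ < flute < trombone < voice.
    """
    master = np.random.default_rng(seed)
    order = ["organ", "flute", "trombone", "voice"]
    hits = 0
    for _ in range(n_seeds):
        cseed = int(master.integers(0, 2**31 - 1))
        corpus = generate_corpus(
            INSTRUMENT_PRESETS, songs_per_group=songs_per_group, seed=cseed
        )
        means: dict[str, list[float]] = {g: [] for g in order}
        for _, group, ann, _ in corpus.songs:
            res = SongModel(ann, tonic_label="PC1").fit()
            means[group].append(res.mean_imprecision)
        m = [float(np.mean(means[g])) for g in order]
        hits += bool(all(a < b for a, b in zip(m, m[1:])))
    return {"ordering_rate": hits / n_seeds, "n_seeds": n_seeds}


def yin_accuracy_experiment(
    freqs=None,
    sample_rate: int = 44100,
    duration_s: float = 0.5,
) -> dict:
    """Absolute cent error of the YIN tracker on clean sine tones."""
    if freqs is None:
        freqs = np.geomspace(80.0, 1000.0, 12)
    errs = []
    for f in freqs:
        t = np.arange(int(sample_rate * duration_s)) / sample_rate
        x = np.sin(2.0 * np.pi * f * t)
        trace = yin_f0(x, sample_rate)
        est = float(np.median(trace.f0_hz[trace.voiced]))
        errs.append(abs(hz_to_cents(est, f)))
    return {"max_error_cents": float(np.max(errs)), "n_tones": len(list(freqs))}
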