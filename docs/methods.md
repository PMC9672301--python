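# Methods

## The measurement model

`vocalscales` treats a monophonic melody as a stream of fundamental-frequency
annotations and asks two questions about each scale degree the singer (or
player) uses: how wide is the cloud of produced pitches around it, and how
close does its centre sit to a mathematical tuning template?

All analysis is carried out in cents (100 cents = one equal-tempered
semitone; `cents(f, ref) = 1200·log2(f/ref)`). The absolute cent reference
(MIDI note 0, 8.1758 Hz) is arbitrary: every song is eventually
re-referenced to the mean of its tonic pitch-class, which is assigned
0 cents, so only relative values matter.

### Segmentation into pitch-classes

The annotations of an excerpt are sorted from lowest to highest cent value
and first-differenced. Within a pitch-class these gaps are small and shrink
as annotation density grows; between classes they are large. A gap is
declared a boundary peak when it is at least

```
max(min_gap, k · median positive gap)      min_gap = 30 cents, k = 8
```

and the boundary is placed at the midpoint of the two annotations flanking
the peak. The multiplicative term adapts to annotation density; the
absolute floor prevents spurious splits in sparse traces. Classes smaller
than `max(5, 0.02·n)` annotations are merged into the neighbour across the
smaller flanking gap — transient ornaments and stray annotations are not
scale degrees. Annotations exactly on a boundary go to the lower class
(half-open, upper-inclusive intervals). Classes are per sounding pitch;
there is no octave folding.

Manual judgement enters in two places, mirroring practice with a melograph:
boundary overrides replace the detected boundaries verbatim, and named
classes can be excluded as non-discrete (glides, noise); excluded
annotation counts are logged in `noise_removed` so that retained + removed
always equals the input count.

The detector was validated against an exhaustive oracle: on small instances
(≤ 30 annotations, ≤ 3 classes) whose cluster separation comfortably
exceeds the within-cluster scatter, it reproduces the partition minimizing
the sum of within-class ranges in ≥ 99% of instances (200-instance suite).

### Tonic

The tonic is a perceptual judgement and is therefore a config input
(`tonic_class`). When omitted, the class with the greatest annotation count
is used and the result is flagged `tonic_heuristic` — a fallback, not a
claim about perception.

### Imprecision

Per class, imprecision = max − min of the member cent values. Ranges above
400 cents (a whole tone either side of the centre) are flagged as outliers
and excluded from song-level imprecision means; the inter-quartile range is
computed alongside as a less range-sensitive check. The outlier rule scopes
to the range variable only: outlier classes still contribute to inaccuracy
and to the scale series. For uniform scatter of total width *W* and *n*
annotations, the sample range has expectation `W·(n−1)/(n+1)`, so recovered
imprecision sits just below the generative width at realistic densities.

### Inaccuracy

Per non-tonic class, inaccuracy = folded absolute distance of the
tonic-relative class mean from the nearest template target. For 12-ET
(targets at all integer multiples of 100 cents from the tonic):
`d = mean mod 100; inaccuracy = min(d, 100 − d) ∈ [0, 50]`. The value 50 —
exactly halfway between adjacent targets — is admitted (closed interval):
the fold attains it, and excluding it would leave the metric undefined
there. The tonic's inaccuracy is n/a by construction and excluded from
song means. Alternative templates: `Ntet:<N>` (fold maximum `600/N`) and
`ji`, a standard 12-tone just-intonation ratio set
(1/1 16/15 9/8 6/5 5/4 4/3 45/32 3/2 8/5 5/3 16/9 15/8), octave-replicated.

Under tuning that is random with respect to the template, the folded
distance is uniform on [0, 50] and its expectation is 25 cents — the
benchmark against which "random tuning" is judged.

### Song and corpus summaries

Song-level means are unweighted across classes (a class is one scale
degree regardless of how often it is sung); the per-class table, interval
spacings (successive differences of sorted class means) and a scale series
(nearest-12-ET note names, slash-named when the fold distance falls in
(40, 50], tonic starred) are attached. The constraint arithmetic
`1200 / mean imprecision` gives the implied upper bound on pitch-classes
per octave.

## Statistics

Imprecision/inaccuracy distributions across groups are typically
non-normal and heteroscedastic, so group comparison defaults to
Games–Howell: pairwise Welch statistics with Welch–Satterthwaite degrees
of freedom referred to the studentized-range distribution (k = number of
groups), which controls the family-wise error rate without assuming equal
variances. A trimmed-means Welch alternative (Yuen-type, 20% trim, same
studentized-range adjustment) is available as `method="trimmed"`; output
always records which method was used. Calibration: over 1000 equal-mean
heteroscedastic replicates (5 groups, n = 40, SDs 1–4) the measured
family-wise error at nominal α = 0.05 is ≈ 0.05 (asserted ≤ 0.07).

Variance homogeneity uses the Brown–Forsythe (median-centered) Levene
variant by default, mean-centered optionally, with Bonferroni correction
over pairwise tests. Descriptives report sample SD (n−1) and adjusted
Fisher–Pearson skew (defined as 0 for constant groups). Correlations are
Pearson product-moment with `t = r·√(df/(1−r²))`, df = n−2, and the
companion OLS fit reports adjusted R² and the slope standard error. All
tests are two-sided at α = 0.05 by default.

## The synthetic-song generator

Because field recordings cannot be redistributed, every stage is tested
against generated songs with stored ground truth. A song spec fixes: the
scale (class centres in cents from the tonic), per-class scatter width,
scatter shape, per-class tuning offsets, a note sequence with durations,
annotation rate, and optional drift, glides and noise annotations. A
single seeded RNG stream drives generation; identical spec + seed is
bit-reproducible.

Choices and what they emulate:

* **Scatter** defaults to uniform over `centre ± width/2` so the range
  statistic has ground truth exactly the width; normal (SD = width/4) and
  bimodal options exercise the IQR alternative and two-lobed "interval
  island" shapes.
* **Note sequences** are repeated random permutations of the scale degrees
  with exponential durations (mean 0.6 s, floor 0.15 s): every degree
  recurs throughout the song and receives a comparable share of the
  melody, as singers use all of their scale degrees. Class occupancy is
  proportional to note duration.
* **Excerpt durations** are drawn N(20.5 s, 8.5 s), clipped to [8, 60] s,
  matching the analysed-excerpt statistics; **annotation rate** defaults
  to 50/s, a practical annotation density for sung melodies.
* **Drift** defaults to 0 (excerpts are chosen to avoid drift); nonzero
  drift is reserved for robustness tests.
* **Recovery-experiment scale**: centres at 0/300/600/900 cents
  (12-ET positions spaced three semitones). With tuning offsets uniform
  on ±50 cents the worst-case effective spacing is 200 cents, which still
  exceeds a 150-cent class width; a 100-cent-spaced scale would make
  adjacent vocal-width classes overlap by construction and the
  segmentation problem ill-posed.
* **Group presets.** Regional profiles span width means 121 cents
  (Middle East-North Africa) to 170 cents (Insular Pacific, Circumpolar),
  with the remaining regions set near the 150–160 global level following
  the reported regional ordering; offsets are uniform ±50 cents (random
  with respect to 12-ET). Instrument profiles encode a tuning-fixedness
  gradient: organ (width 10, offsets ±2), flute (30, ±8), trombone
  (120, ±35), voice (180, ±12 — wide but, as for a trained singer,
  modestly offset).

What the generator does **not** emulate: vibrato and portamento
microstructure, voiced/unvoiced alternation, breath noise, reverberation,
heavy-tailed annotation errors of real trackers, or genuinely ambiguous
tonics. Passing recovery tests therefore shows the pipeline is correct and
calibrated under its stated model — not that field recordings satisfy that
model.

## YIN frontend

The optional audio frontend implements the standard YIN recipe: squared
difference function over a fixed half-frame integration window (computed
by FFT), cumulative-mean normalization, absolute-threshold lag selection
(first dip below 0.15, descended to its local minimum), parabolic
interpolation of the difference function for sub-sample lag, f0 =
rate/lag. Frames whose normalized minimum never drops below the threshold
are unvoiced; annotation times are frame centres. Defaults (frame 2048,
hop 256, threshold 0.15 at 44.1 kHz) cover f0 from ~43 Hz to well above
vocal range; measured error on clean tones 80–1000 Hz is < 0.01 cents.
There is no octave-error post-correction — the manual pitch-band selection
in `select_excerpt` plays that role. Polyphony and probabilistic voicing
are out of scope.

## Numerical conventions and degenerate inputs

Cents are carried at full double precision; reports round to 0.1 cent.
Sorting is stable, so annotation order never affects results. Degenerate
cases: fewer than 2 annotations cannot be segmented (error); a
single-class song has imprecision but n/a inaccuracy and an empty interval
list; a constant group has SD 0 and skew 0; zero-variance correlation
inputs are an error rather than NaN. Empty excerpt selections raise an
error naming the window and band.

## Problem sizes

The validation experiments run at: 100 songs (≈ 1000 annotations each) for
corpus recovery; 200 instances for the segmentation oracle; 1000
replicates for family-wise error; 50 corpus seeds × 4 instruments ×
8 songs for the ordering experiment; 12 tones for YIN accuracy. These
sizes give Monte-Carlo standard errors well inside the asserted bands
(e.g. ≈ 0.7 cents for the corpus mean inaccuracy) while keeping a full run
around a minute on one CPU.

## Known limitations

* Boundary detection reproduces a by-eye procedure with an explicit rule;
  the peak criterion's constants (30 cents, k = 8) are exposed parameters,
  not claims about any analyst's judgement.
* A single boundary separates adjacent classes, so overlapping pitch-class
  distributions cannot be represented; strongly overlapping classes merge.
* The tonic heuristic (most-used class) is a fallback for synthetic data
  and quick looks; real analyses should supply the tonic.
* Games–Howell is one member of the family of heteroscedasticity-robust
  FWE-controlling procedures; results tables name the method so that the
  trimmed-means alternative can be compared like for like.
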