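# Methods

This note documents the models, conventions and design choices behind
`cagetrack`, in the spirit of a statistical-software methods appendix: what
is computed, under which assumptions, and what the synthetic validation does
and does not demonstrate.

## Trajectory reconstruction

The raw log is a stream of `(timestamp, antenna ID, tag ID)` events, one per
line, whitespace- or tab-delimited, with ISO-8601 timestamps and optional
fractional seconds. The exact dialect of commercial loggers varies; the
parser accepts both space and `T` date/time separators and ignores `#`
comment lines, and is deliberately the single place to adapt for another
logger. Malformed lines are counted and logged (or abort in strict mode).

Cleaning is three exact, order-insensitive rules:

1. **Truncation**: fractional seconds are *floored* away, never rounded —
   the detection belongs to the second in which it occurred.
2. **First-detection-wins**: within one `(tag, second)` cell only the
   earliest event by file order is kept. Sub-second ordering is already
   discarded by truncation, so file order is the only defensible tie-break.
3. **Forward fill**: missing seconds take the immediately preceding
   position, flagged `observed=False`. There is no back-fill: seconds before
   a tag's first detection have no preceding value and are absent. By
   default filling stops at the tag's last detection; `fill_to_session_end`
   extends it to the session boundary, and `max_fill_gap` caps how long a
   stale position may be carried (useful when a transponder detaches
   mid-experiment; `drop_tags` excludes such an animal entirely, which is
   how a detached-tag animal is conventionally handled).

Timestamps are treated as a naive, monotonic local wall clock (loggers are
synchronized to local standard time); epoch seconds are derived timezone-free
so results are identical on any machine. Non-monotonic input triggers a
warning and a stable sort.

## Grid geometry

The default board is 12 × 8 tiles of 5 cm pitch, 96 antenna IDs, numbered
row-major with `x` varying fastest (`id = (y − 1)·12 + x`, antenna 1 at tile
(1, 1)). Commercial boards do not document their numbering order; the mapping
is isolated in one function so a serpentine or transposed layout is a
one-line change. Coordinates are 1-based tile indices; all physical
distances are tile-index Euclidean distances times the pitch.

Pair proximity uses four concentric categories (Same / Close / Intermediate
/ Away). Because tile offsets are integers, classification is implemented on
the *squared* index distance (0; 1–2; 4–8; > 8), which makes the category
boundaries exact — no floating-point tolerance exists anywhere in the
classification. For realizable integer offsets the rule coincides with
Chebyshev rings 0, 1, 2, ≥ 3, and the test suite verifies this equivalence
by brute force over all 96² coordinate pairs.

## Activity metrics

Step distances are computed on the forward-filled per-second trajectory;
filled spans contribute zero distance by construction (position constant). A
step from second `t` to `t + 1` is attributed to the window containing its
arrival second `t + 1`, so a window of `T` samples sums exactly `T − 1`
steps and windowed distances are additive over any partition of the session.

Windows are anchored at the first lights-on at or after session start
(08:00 under the default 12:12 cycle; a warning is emitted if the session
does not begin at the boundary). Trailing partial bins are dropped. The 2-h
bin is the default time-course resolution and also the bin on which
relative activity is defined: each animal's bin distance divided by that
animal's maximum bin over the whole recording, × 100 (an all-zero animal is
set to 0 with a warning rather than dividing by zero). Per-window coverage
is reported as the fraction of window seconds with step rows; an animal
observed from its first detection has `T − 1` of `T` steps in its first
window, so coverage marginally below 1 there is expected.

Distances are reported in centimetres throughout (doubling the pitch doubles
every distance and leaves relative activity unchanged — a tested
equivariance).

## Proximity and CCR

Pair series are defined only on seconds where both animals have trajectory
rows. The CCR over a window is the percentage of *covered* seconds with
`L ≤ 5√2` cm (Chebyshev ≤ 1). With full coverage the divisor is the window
length `T`; with partial coverage (late first detection, tag loss) using
covered seconds keeps CCR a proportion and the coverage fraction is always
reported alongside so downweighting is possible downstream.

Group-level category proportions pool seconds across pairs rather than
averaging per-pair ratios; the two differ only under unequal coverage, and
pooled counts are also the correct input to the chi-square tests. The
pooled value is necessarily a convex combination of the per-pair
proportions (tested).

Per-animal sociability is the mean of an animal's pair CCRs over its
partners — the aggregation used for the per-animal heat-map rows and the
SL/SD features. It is isolated in one function (`per_animal_ccr`) so an
alternative (e.g. median) is a local change.

Two computation paths exist deliberately: a per-second long-form series
(inspection, small data) and an aligned-array counting path
(`pair_window_table`) for multi-day cohorts. The CCR in the counting path is
computed from its own close-contact indicator, not from the category
counts, so the identity `CCR = 100·(p_same + p_close)` is a genuine
cross-check, and the series-vs-table agreement is itself tested.

## Networks

Edge weight is pair CCR divided by 10, giving weights in [0, 10] used for
edge thickness. The export keeps the exact header `Source / Target / Edge
betweenness` for Cytoscape compatibility although the value is not
graph-theoretic betweenness; internally the field is named `weight` to avoid
propagating the misnomer. Zero-weight edges are emitted by default
(flag-controlled), since dropping them changes graph density summaries. The
canonical comparison windows are the day-1 light and day-3 dark 12-h
periods, but any window can be exported.

## Phenotyping

AL/AD are computed by first averaging each 2-h time-of-day slot across days
(so a recording of `d` days contributes one value per slot) and then
averaging slots within the light (resp. dark) phase; for balanced recordings
this equals the plain mean over phase bins, and for identical day profiles
the day-averaging is the identity (tested). SL/SD are per-animal CCR over
seconds pooled within each phase. The 2-h bin width is a configuration knob.

Features are z-scored before PCA by default: AL/AD and SL/SD share a 0–100
scale but very different variances, and standardization keeps the loading
balance interpretable; it is flag-controllable. PCA signs are fixed by
making each component's largest-magnitude loading positive. Zero-variance
features raise an error naming the feature.

Cluster-count selection automates the usual elbow-plus-silhouette
inspection with a deterministic rule: k-means (50 restarts, fixed seed) on
the leading PC scores for each candidate k, choose the k with maximal mean
silhouette, and report the inertia curve for manual elbow reading.
Reproducibility is bit-for-bit for a fixed seed (tested).

The chi-square helper is Pearson's test without continuity correction
(df = (r−1)(c−1); 3 for the light/dark × four-category layout) on pooled
category-seconds. Holm–Šidák is the step-down closed form
`1 − (1 − p_(i))^(m − i + 1)` with monotonicity enforcement, validated
against the closed form and against `statsmodels`. The omnibus two-way
ANOVAs that typically precede the adjustment are deliberately delegated to
standard statistical software — the tidy CSV exports are the interface —
and only the adjustment layer is native. The coefficient of variation uses
the sample standard deviation (ddof = 1).

## The simulator

The simulator emulates the recording regime, not mouse physiology: `n` mice
on the board, one move opportunity per second with phase-dependent
probability (defaults 0.2 light / 0.8 dark — a strong nocturnal contrast
typical of group-housed mice), and a social step with probability
`p_social` (default 0.3, a moderate attraction) that moves one tile toward
the nearest conspecific by Chebyshev distance (ties broken uniformly at
random), otherwise a uniform 8-neighbour step clipped at the walls. The
sensor model drops each detection with `p_miss` (default 0.02), adds a
spurious adjacent-tile same-second detection with `p_dup` (default 0.01),
and can silence a tag from a given second (`tag_loss`) to reproduce the
detached-transponder scenario. Presets cover group sizes 4/8/16, a stronger
nocturnal contrast, an asocial control and the tag-loss scenario.

All randomness flows from one seeded PCG64 generator consumed in a fixed
order (initial positions, then whole-array draws for movement, social
choice, direction, tie-break, dropout, duplicates and timestamp fractions),
so a given seed reproduces the log byte-for-byte across platforms.

What the simulator validates — and what it does not: it provides exact
ground truth for channel-recovery, conservation and parameter-recovery
tests (dark/light activity ratio recovered within a few percent; CCR
monotone in `p_social`; at `p_social = 0` pair CCR matches the
product-of-marginals independence baseline). It does **not** contain
huddling bouts, nest sites, feeding zones, wall-following or identity-swap
artifacts, so passing these tests demonstrates correctness of the
*computations*, not that the pipeline's biological summaries are robust to
every property of real cage data.

## Problem sizes and numerical choices

The validation suite exercises the pipeline at the full recording scale —
72-h, 16-animal cohorts (≈ 4.1 million trajectory rows, 120 pairs) — for
the conservation and channel-recovery checks, and at 12–24 h for the
parameter- and phenotype-recovery checks, sizes chosen so the whole suite
runs in a couple of minutes on one CPU while still covering the multi-day,
largest-group regime. Proximity aggregation is exact integer counting
(`bincount` on window × category codes); the only floating-point step in
CCR is the final division, so the conservation identities hold to machine
precision rather than to a tolerance. Degenerate inputs are handled
explicitly rather than propagating NaN: zero-coverage windows report
missing proportions, all-zero activity normalizes to 0 with a warning, and
zero-variance features or identical points raise informative errors.

## Known limitations

* Spatial resolution is the 5-cm tile; two mice in one tile are `Same`
  regardless of orientation, and no sub-tile interpolation is attempted.
* CCR measures spatial proximity, not specific social acts; high CCR can
  reflect affiliation, thermoregulatory huddling or simple inactivity.
* Forward fill assumes the animal stayed at its last tile; long undetected
  spans (sleep on a weak antenna, tag failure) bias positions toward the
  last detection — `max_fill_gap` bounds this at the cost of coverage.
* A single board is assumed; multi-board stitching and live acquisition are
  out of scope.
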