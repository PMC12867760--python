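# cagetrack

Home-cage RFID floor-plate analytics for group-housed rodents: from raw
antenna detection logs to per-second multi-animal trajectories, locomotor
activity, pairwise social proximity, social-interaction networks and
group-level behavioral phenotyping — with a built-in home-cage simulator so
the whole pipeline can be validated end to end without animal data.

## The problem

RFID floor plates track many tagged mice at once in their home cage: a 12 × 8
board of 5 × 5 cm antenna tiles reports `(time, antenna ID, tag ID)` events
whenever a subcutaneous transponder passes over a tile. This gives unbiased,
continuous multi-day recordings of whole groups — but the raw event stream is
irregular (multiple hits per second, dropped detections) and needs careful
reconstruction before any behavioral quantity can be computed. `cagetrack`
implements that reconstruction and the standard analytics stack on top of it.

## The core quantities

**Trajectory reconstruction.** Timestamps are truncated to whole seconds
(floored, never rounded); if a tag fires more than once within a second only
the first detection is kept; seconds with no detection carry the last
observed position forward (no back-fill before a tag's first detection). The
result is one `(x, y)` tile per animal per second.

**Travel distance.** With positions `(X_t, Y_t)` on the tile grid and pitch
5 cm, the per-second step is

    D_{t+1} = 5 · √((X_{t+1} − X_t)² + (Y_{t+1} − Y_t)²)   [cm]

and the distance over a window of `T` samples is the sum of its `T − 1`
steps (canonical windows: 2 h, `T` = 7 200 s, and 12 h, `T` = 43 200 s,
anchored at lights-on 08:00 of the 12:12 light–dark cycle). Relative
activity normalizes each animal's windowed distance to its own maximum
(× 100).

**Social proximity.** For each pair (i, j) the interindividual distance
`L_t = 5 · √((X_t^i − X_t^j)² + (Y_t^i − Y_t^j)²)` is classified into four
concentric categories — `Same` (L = 0), `Close` (L = 5 or 5√2),
`Intermediate` (L = 10, 5√5 or 10√2), `Away` (L > 10√2) — equivalent to
Chebyshev rings 0, 1, 2, ≥ 3. The **Close Contact Ratio** is the percentage
of time a pair spends in close contact:

    CCR^(i,j) = 100/T · Σ_t δ(L_t ≤ 5√2)   [%]

**Networks.** Each window's pair CCRs become an undirected weighted graph
(weight = CCR/10) exported as the tab-delimited `Source / Target / Edge
betweenness` table Cytoscape imports.

**Phenotyping.** Each animal is summarised by four features — normalized
activity in the light (AL) and dark (AD) phases, and per-animal CCR in the
light (SL) and dark (SD) phases — which feed a PCA and k-means clustering
with the cluster count chosen by maximal mean silhouette (the inertia curve
is reported for elbow inspection). Helpers cover the chi-square test on
pooled category-seconds contingencies, step-down Holm–Šidák p-value
adjustment and coefficient-of-variation summaries.

## Worked example

Simulate a 16-mouse, 24-h cohort, run the full pipeline and cluster the
phenotypes (all via the `cagetrack` console script):

```bash
cagetrack simulate --preset large-group --hours 24 --seed 5 --out raw.txt
cagetrack preprocess raw.txt --out traj.csv \
    --session-start 2023-01-10T08:00:00 --session-hours 24
cagetrack locomotion traj.csv --session-start 2023-01-10T08:00:00 \
    --session-hours 24 --out-dir loco
cagetrack proximity traj.csv --session-start 2023-01-10T08:00:00 \
    --session-hours 24 --out-dir prox
cagetrack network prox/pair_phase_windows.csv --window "day1 light" --out edges.tsv
cagetrack phenotype loco/activity.csv prox/per_animal_ccr.csv \
    --k-min 2 --k-max 5 --seed 17 --out-dir pheno
```

which prints

```
wrote raw.txt (1368326 detections, 16 mice, 24 h)
wrote traj.csv (16 tags, 1382398 rows)
wrote activity tables to loco
wrote proximity tables to prox
wrote edges.tsv (120 edges, window 'day1 light')
wrote phenotype outputs to pheno (chosen k = 3)
```

`traj.csv` holds one row per animal per second (16 × 86 400, minus two
leading seconds before two tags' first detections — there is no back-fill).
`pheno/features.csv` starts

```
tag_id,AL,AD,SL,SD
M05,25.09504519248455,99.46468137445423,12.94971248119884,13.70094728130138
M02,25.226496294487376,99.54379865502362,13.63381914490476,13.861439836713185
```

AD ≈ 100 and AL ≈ 25 reflect the simulated nocturnal activity contrast
(`p_move` 0.2 light vs 0.8 dark: every animal peaks in a dark bin, and light
bins carry about a quarter of the movement); SL/SD ≈ 13 % is the close-contact
level of a 16-mouse group with moderate social attraction. `edges.tsv` begins

```
Source	Target	Edge betweenness
M05	M02	1.3134
M05	M10	1.2301
```

i.e. pair CCRs of ≈ 13 % scaled by 1/10 for Cytoscape edge thickness.

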