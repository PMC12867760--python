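"""Pairwise social-proximity analytics and the Close Contact Ratio (CCR).

For every unordered pair of animals (i, j) and every second t where both
have a trajectory row, the interindividual distance is

    L_t = pitch_cm * sqrt((X_t^i - X_t^j)^2 + (Y_t^i - Y_t^j)^2)

and the pair is classified into Same / Close / Intermediate / Away
(see :mod:`cagetrack.geometry`).  The CCR of a pair over a window of T
samples is the percentage of covered seconds in which the pair is within
close contact (L <= pitch * sqrt(2), i.e. Same or Close):

    CCR = 100 / T_covered * sum_t delta(L_t <= pitch * sqrt(2))

With full coverage the divisor is the window length T; with partial
coverage (late introduction, tag loss) it is the number of covered
seconds, and the coverage fraction is always reported alongside.

Group-level category proportions pool seconds across pairs (a convex
combination of per-pair proportions weighted by covered seconds), not a
mean of per-pair ratios; the pooled counts are also what the light/dark
chi-square tests consume.

Two computation paths are provided: :func:`pair_series` materialises the
per-second series (convenient for inspection and small data) while
:func:`pair_window_table` aggregates counts per window directly from the
aligned position arrays and is the production path for long recordings.
"""

from __future__ import annotations

import itertools
import logging
import math

import numpy as np
import pandas as pd

from .geometry import (
    CATEGORIES,
    CLOSE_D2_MAX,
    DEFAULT_GEOMETRY,
    GridGeometry,
    category_codes_from_d2,
)
from .locomotion import AnalysisWindow

logger = logging.getLogger("cagetrack.proximity")

__all__ = [
    "align_positions",
    "pair_series",
    "category_proportions",
    "group_proportions",
    "ccr",
    "pair_window_table",
    "phase_pooled_ccr",
    "ccr_matrix",
    "per_animal_ccr",
]

_PROP_COLS = ["p_same", "p_close", "p_intermediate", "p_away"]
_COUNT_COLS = ["n_same", "n_close", "n_intermediate", "n_away"]


def align_positions(traj: pd.DataFrame):
    """Align trajectories on a common per-second timeline.

    Returns ``(tags, t0, X, Y, present)`` where X and Y are
    ``(n_tags, n_seconds)`` int16 arrays starting at epoch second ``t0``
    and ``present`` marks seconds with a trajectory row.
    """
    tags = list(dict.fromkeys(traj["tag_id"]))
    if not tags:
        raise ValueError("empty trajectory table")
    t0 = int(traj["second"].min())
    t1 = int(traj["second"].max())
    n = t1 - t0 + 1
    X = np.zeros((len(tags), n), dtype=np.int16)
    Y = np.zeros((len(tags), n), dtype=np.int16)
    present = np.zeros((len(tags), n), dtype=bool)
    for k, tag in enumerate(tags):
        g = traj[traj["tag_id"] == tag]
        idx = g["second"].to_numpy(dtype=np.int64) - t0
        X[k, idx] = g["x"].to_numpy(dtype=np.int16)
        Y[k, idx] = g["y"].to_numpy(dtype=np.int16)
        present[k, idx] = True
    return tags, t0, X, Y, present


def _normalize_pair(tag_i: str, tag_j: str, tags: list[str]) -> tuple[str, str]:
    order = {t: k for k, t in enumerate(tags)}
    return (tag_i, tag_j) if order[tag_i] < order[tag_j] else (tag_j, tag_i)


def pair_series(
    traj: pd.DataFrame,
    geom: GridGeometry = DEFAULT_GEOMETRY,
    pairs: list[tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-second distance and category series for every unordered pair.

    Returns a long DataFrame with columns ``tag_i, tag_j, second, l_cm,
    category`` restricted to seconds where both animals are present.
    N animals yield N(N-1)/2 pair series.
    """
    tags, t0, X, Y, present = align_positions(traj)
    if len(tags) < 2:
        raise ValueError("need at least two animals for pair analysis")
    if pairs is None:
        pairs = list(itertools.combinations(tags, 2))
    else:
        pairs = [_normalize_pair(a, b, tags) for a, b in pairs]
    k_of = {t: k for k, t in enumerate(tags)}
    pieces = []
    for a, b in pairs:
        i, j = k_of[a], k_of[b]
        both = present[i] & present[j]
        sec = np.nonzero(both)[0]
        dx = X[i, sec].astype(np.int32) - X[j, sec]
        dy = Y[i, sec].astype(np.int32) - Y[j, sec]
        d2 = dx * dx + dy * dy
        codes = category_codes_from_d2(d2)
        pieces.append(
            pd.DataFrame(
                {
                    "tag_i": a,
                    "tag_j": b,
                    "second": (sec + t0).astype(np.int64),
                    "l_cm": geom.pitch_cm * np.sqrt(d2.astype(np.float64)),
                    "category": pd.Categorical.from_codes(
                        codes, categories=list(CATEGORIES)
                    ),
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


def _window_index(seconds: np.ndarray, windows: list[AnalysisWindow]) -> np.ndarray:
    """Map epoch seconds to window ordinals (-1 outside every window)."""
    starts = np.array([w.start_second for w in windows], dtype=np.int64)
    ends = np.array([w.end_second for w in windows], dtype=np.int64)
    order = np.argsort(starts)
    starts_s, ends_s = starts[order], ends[order]
    pos = np.searchsorted(starts_s, seconds, side="right") - 1
    pos_c = np.clip(pos, 0, len(windows) - 1)
    inside = (pos >= 0) & (seconds < ends_s[pos_c])
    out = np.where(inside, order[pos_c], -1)
    return out


def category_proportions(
    series: pd.DataFrame, windows: list[AnalysisWindow]
) -> pd.DataFrame:
    """Per-pair, per-window category proportions from a pair series.

    Counts each category's seconds and divides by the pair's covered
    seconds in the window.  Windows with zero coverage get NaN
    proportions (never NaN propagation from a 0/0).
    """
    win_idx = _window_index(series["second"].to_numpy(dtype=np.int64), windows)
    codes = series["category"].cat.codes.to_numpy()
    rows = []
    for (a, b), g_idx in series.groupby(["tag_i", "tag_j"], sort=False).indices.items():
        wi = win_idx[g_idx]
        cd = codes[g_idx]
        for w_ord, w in enumerate(windows):
            sel = wi == w_ord
            n_cov = int(sel.sum())
            counts = np.bincount(cd[sel], minlength=4) if n_cov else np.zeros(4, int)
            row = {
                "tag_i": a,
                "tag_j": b,
                "window_start": w.start,
                "label": w.label,
                "phase": w.phase,
                "t_samples": w.t_samples,
                "n_covered": n_cov,
                "coverage": n_cov / w.t_samples,
            }
            for name, c in zip(_COUNT_COLS, counts):
                row[name] = int(c)
            for name, c in zip(_PROP_COLS, counts):
                row[name] = c / n_cov if n_cov else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def group_proportions(
    series: pd.DataFrame, windows: list[AnalysisWindow]
) -> pd.DataFrame:
    """Group-level proportions per window: seconds pooled across all pairs."""
    per_pair = category_proportions(series, windows)
    agg = per_pair.groupby(["window_start", "label", "phase", "t_samples"], sort=True)[
        _COUNT_COLS + ["n_covered"]
    ].sum().reset_index()
    for p_col, n_col in zip(_PROP_COLS, _COUNT_COLS):
        agg[p_col] = np.where(
            agg["n_covered"] > 0, agg[n_col] / agg["n_covered"], np.nan
        )
    return agg


def ccr(
    series: pd.DataFrame,
    window: AnalysisWindow,
    geom: GridGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """CCR per pair for one window, from the per-second distance series.

    Applies the close-contact indicator delta(L <= pitch*sqrt(2)) to the
    distance column directly (an independent route from the category
    counts).  Returns columns ``tag_i, tag_j, ccr_pct, coverage``; pairs
    with zero coverage in the window get NaN CCR.
    """
    sec = series["second"].to_numpy(dtype=np.int64)
    in_win = (sec >= window.start_second) & (sec < window.end_second)
    sub = series.loc[in_win]
    threshold = geom.pitch_cm * math.sqrt(2) + 1e-9
    rows = []
    for (a, b), g in sub.groupby(["tag_i", "tag_j"], sort=False):
        n_cov = len(g)
        close = g["l_cm"].to_numpy(dtype=np.float64) <= threshold
        rows.append(
            {
                "tag_i": a,
                "tag_j": b,
                "ccr_pct": 100.0 * close.sum() / n_cov,
                "coverage": n_cov / window.t_samples,
            }
        )
    # pairs absent from the window entirely
    seen = {(r["tag_i"], r["tag_j"]) for r in rows}
    for (a, b) in series.groupby(["tag_i", "tag_j"], sort=False).groups:
        if (a, b) not in seen:
            rows.append({"tag_i": a, "tag_j": b, "ccr_pct": np.nan, "coverage": 0.0})
    return pd.DataFrame(rows)


def pair_window_table(
    traj: pd.DataFrame,
    geom: GridGeometry = DEFAULT_GEOMETRY,
    windows: list[AnalysisWindow] | None = None,
) -> pd.DataFrame:
    """Per-pair, per-window proximity summary computed from aligned arrays.

    The production path for long recordings: for every unordered pair and
    window it reports covered seconds, per-category counts and
    proportions, and ``ccr_pct`` (computed from its own close-contact
    indicator on the squared distance, cross-checkable against
    ``p_same + p_close``).
    """
    if windows is None or not windows:
        raise ValueError("windows must be supplied")
    tags, t0, X, Y, present = align_positions(traj)
    if len(tags) < 2:
        raise ValueError("need at least two animals for pair analysis")
    n_sec = X.shape[1]
    win_idx = _window_index(np.arange(t0, t0 + n_sec, dtype=np.int64), windows)
    n_win = len(windows)
    rows = []
    for i, j in itertools.combinations(range(len(tags)), 2):
        both = present[i] & present[j] & (win_idx >= 0)
        sel = np.nonzero(both)[0]
        wi = win_idx[sel]
        dx = X[i, sel].astype(np.int32) - X[j, sel]
        dy = Y[i, sel].astype(np.int32) - Y[j, sel]
        d2 = dx * dx + dy * dy
        codes = category_codes_from_d2(d2)
        counts = np.bincount(wi * 4 + codes, minlength=n_win * 4).reshape(n_win, 4)
        close_n = np.bincount(wi, weights=(d2 <= CLOSE_D2_MAX), minlength=n_win)
        cov = counts.sum(axis=1)
        for w_ord, w in enumerate(windows):
            n_cov = int(cov[w_ord])
            row = {
                "tag_i": tags[i],
                "tag_j": tags[j],
                "window_start": w.start,
                "label": w.label,
                "phase": w.phase,
                "t_samples": w.t_samples,
                "n_covered": n_cov,
                "coverage": n_cov / w.t_samples,
                "n_close_contact": int(close_n[w_ord]),
            }
            for name, c in zip(_COUNT_COLS, counts[w_ord]):
                row[name] = int(c)
            for name, c in zip(_PROP_COLS, counts[w_ord]):
                row[name] = c / n_cov if n_cov else np.nan
            row["ccr_pct"] = 100.0 * close_n[w_ord] / n_cov if n_cov else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def phase_pooled_ccr(pair_table: pd.DataFrame) -> pd.DataFrame:
    """Pool a pair-window table over lighting phase.

    Sums close-contact and covered seconds over all (pure) light windows
    and all dark windows per pair, giving one CCR per pair per phase.
    """
    sub = pair_table[pair_table["phase"].isin(["light", "dark"])]
    agg = sub.groupby(["tag_i", "tag_j", "phase"], sort=False).agg(
        n_close_contact=("n_close_contact", "sum"),
        n_covered=("n_covered", "sum"),
        t_samples=("t_samples", "sum"),
    ).reset_index()
    agg["ccr_pct"] = np.where(
        agg["n_covered"] > 0, 100.0 * agg["n_close_contact"] / agg["n_covered"], np.nan
    )
    agg["coverage"] = agg["n_covered"] / agg["t_samples"]
    return agg


def per_animal_phase_ccr(
    phase_pooled: pd.DataFrame, tags: list[str] | None = None
) -> pd.DataFrame:
    """Per-animal sociability by phase: columns ``tag_id, phase, ccr_pct``.

    For each phase, builds the pair CCR matrix from the pooled table and
    averages each animal over its partners (the SL/SD features).
    """
    rows = []
    for phase in ("light", "dark"):
        sub = phase_pooled[phase_pooled["phase"] == phase]
        if sub.empty:
            continue
        score = per_animal_ccr(ccr_matrix(sub, tags=tags))
        for tag, v in score.items():
            rows.append({"tag_id": tag, "phase": phase, "ccr_pct": v})
    return pd.DataFrame(rows)


def ccr_matrix(
    ccr_values: pd.DataFrame, tags: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric animals x animals CCR matrix (diagonal NaN).

    ``ccr_values`` must hold one row per pair with columns ``tag_i,
    tag_j, ccr_pct`` (e.g. one window's slice of a pair table).
    """
    if tags is None:
        tags = list(dict.fromkeys(
            list(ccr_values["tag_i"]) + list(ccr_values["tag_j"])
        ))
    mat = pd.DataFrame(np.nan, index=tags, columns=tags, dtype=float)
    for _, r in ccr_values.iterrows():
        mat.loc[r["tag_i"], r["tag_j"]] = r["ccr_pct"]
        mat.loc[r["tag_j"], r["tag_i"]] = r["ccr_pct"]
    return mat


def per_animal_ccr(matrix: pd.DataFrame) -> pd.Series:
    """Per-animal sociability: mean of off-diagonal CCRs, ignoring missing."""
    if matrix.shape[0] < 2:
        raise ValueError("need at least two animals")
    return matrix.mean(axis=1, skipna=True)
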