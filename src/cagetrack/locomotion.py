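"""Per-animal locomotor activity metrics.

Travel distance follows the standard step-sum definition on per-second
grid positions: the step at second t+1 is

    D_{t+1} = pitch_cm * sqrt((X_{t+1} - X_t)^2 + (Y_{t+1} - Y_t)^2)

and the total distance over a window of T one-second samples is the sum
of its T-1 steps.  A step from second t to t+1 is attributed to the
window containing its *arrival* second t+1, so a full window of T samples
contributes exactly T-1 steps and windowed sums are additive over
partitions of the session.

Windows are anchored at the first lights-on at or after session start
(8:00 by default); the canonical bins are 2 h (T = 7,200 s) for activity
time courses and 12 h (T = 43,200 s) for light/dark comparisons.

Relative (normalized) activity is each animal's windowed distance divided
by that animal's maximum windowed distance over the whole recording,
times 100, so every animal that moved at all peaks at 100.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, GridGeometry
from .ingest import SessionConfig, from_epoch, to_epoch

logger = logging.getLogger("cagetrack.locomotion")

__all__ = [
    "AnalysisWindow",
    "make_windows",
    "make_phase_windows",
    "step_distances",
    "windowed_distance",
    "normalize_activity",
    "light_dark_totals",
    "activity_heatmap_matrix",
]


@dataclass(frozen=True)
class AnalysisWindow:
    """A contiguous block of one-second samples on the session clock."""

    start: datetime
    t_samples: int
    phase: str  # "light" | "dark" | "mixed"
    label: str

    @property
    def start_second(self) -> int:
        return to_epoch(self.start)

    @property
    def end_second(self) -> int:
        """First second after the window (exclusive)."""
        return self.start_second + self.t_samples


def _window_phase(start_s: int, t_samples: int, config: SessionConfig) -> str:
    # phase can only change at lighting boundaries; sample both ends and
    # every boundary strictly inside the window
    secs = [start_s, start_s + t_samples - 1]
    for anchor_time in (config.lights_on, config.lights_off):
        tod = anchor_time.hour * 3600 + anchor_time.minute * 60 + anchor_time.second
        day0 = (start_s // 86400) * 86400
        for k in range(int(t_samples // 86400) + 2):
            b = day0 + k * 86400 + tod
            if start_s < b < start_s + t_samples:
                secs.append(b)
    light = config.light_mask(np.array(secs, dtype=np.int64))
    if light.all():
        return "light"
    if not light.any():
        return "dark"
    return "mixed"


def _anchor_second(config: SessionConfig) -> int:
    """First lights-on at or after session start (warns if not the start itself)."""
    start = config.session_start
    anchor = start.replace(
        hour=config.lights_on.hour,
        minute=config.lights_on.minute,
        second=config.lights_on.second,
        microsecond=0,
    )
    if anchor < start:
        anchor += timedelta(days=1)
    if anchor != start:
        logger.warning(
            "session does not start at lights-on; windows anchored at %s", anchor
        )
    return to_epoch(anchor)


def make_windows(config: SessionConfig, bin_seconds: int = 7200) -> list[AnalysisWindow]:
    """Contiguous fixed-width windows covering the session.

    Windows are anchored at lights-on and truncated to full bins: a
    trailing partial bin is dropped.  Labels read ``day<d> HH:MM``.
    """
    if bin_seconds <= 0:
        raise ValueError("bin_seconds must be positive")
    anchor = _anchor_second(config)
    windows = []
    s = anchor
    while s + bin_seconds <= config.end_second:
        start_dt = from_epoch(s)
        day = (s - anchor) // 86400 + 1
        label = f"day{day} {start_dt.strftime('%H:%M')}"
        windows.append(
            AnalysisWindow(start_dt, bin_seconds, _window_phase(s, bin_seconds, config), label)
        )
        s += bin_seconds
    return windows


def make_phase_windows(config: SessionConfig) -> list[AnalysisWindow]:
    """Successive 12-h light/dark half-days: day1 light, day1 dark, ...

    Assumes a 12:12 cycle anchored at lights-on (the default schedule).
    """
    windows = make_windows(config, bin_seconds=43200)
    out = []
    for i, w in enumerate(windows):
        day = i // 2 + 1
        label = f"day{day} {w.phase}"
        out.append(AnalysisWindow(w.start, w.t_samples, w.phase, label))
    return out


def step_distances(
    traj: pd.DataFrame, geom: GridGeometry = DEFAULT_GEOMETRY
) -> pd.DataFrame:
    """Per-second step distances from a forward-filled trajectory table.

    Returns one row per (tag, arrival second) with column ``step_cm``;
    each tag's first second has no step.  Raises if any tag's seconds are
    not contiguous (the preprocessing contract).
    """
    pieces = []
    for tag, g in traj.groupby("tag_id", sort=False):
        g = g.sort_values("second")
        secs = g["second"].to_numpy(dtype=np.int64)
        if len(secs) > 1 and np.any(np.diff(secs) != 1):
            raise ValueError(
                f"trajectory for tag {tag!r} has non-contiguous seconds; "
                "run forward_fill first"
            )
        dx = np.diff(g["x"].to_numpy(dtype=np.float64))
        dy = np.diff(g["y"].to_numpy(dtype=np.float64))
        step = geom.pitch_cm * np.hypot(dx, dy)
        pieces.append(
            pd.DataFrame({"tag_id": tag, "second": secs[1:], "step_cm": step})
        )
    if not pieces:
        return pd.DataFrame(
            {
                "tag_id": pd.Series([], dtype=object),
                "second": pd.Series([], dtype=np.int64),
                "step_cm": pd.Series([], dtype=float),
            }
        )
    return pd.concat(pieces, ignore_index=True)


def windowed_distance(
    steps: pd.DataFrame, windows: list[AnalysisWindow]
) -> pd.DataFrame:
    """Sum step distances per (tag, window); step attributed by arrival second.

    Returns the long-format activity table with columns ``tag_id,
    window_start, label, phase, t_samples, distance_cm, coverage`` where
    coverage is the fraction of the window's seconds the animal has rows
    for.  Animals absent from a window get distance 0 and coverage 0.
    """
    if not windows:
        raise ValueError("no analysis windows supplied")
    starts = np.array([w.start_second for w in windows], dtype=np.int64)
    ends = np.array([w.end_second for w in windows], dtype=np.int64)
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    wins = [windows[i] for i in order]
    if np.any(starts[1:] < ends[:-1]):
        raise ValueError("analysis windows overlap")

    tags = list(dict.fromkeys(steps["tag_id"])) if len(steps) else []
    rows = []
    for tag in tags:
        g = steps[steps["tag_id"] == tag]
        secs = g["second"].to_numpy(dtype=np.int64)
        vals = g["step_cm"].to_numpy(dtype=np.float64)
        idx = np.searchsorted(starts, secs, side="right") - 1
        inside = (idx >= 0) & (secs < ends[np.clip(idx, 0, len(wins) - 1)])
        dist = np.zeros(len(wins))
        count = np.zeros(len(wins))
        np.add.at(dist, idx[inside], vals[inside])
        np.add.at(count, idx[inside], 1)
        for i, w in enumerate(wins):
            rows.append(
                {
                    "tag_id": tag,
                    "window_start": w.start,
                    "label": w.label,
                    "phase": w.phase,
                    "t_samples": w.t_samples,
                    "distance_cm": dist[i],
                    "coverage": count[i] / w.t_samples,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "tag_id", "window_start", "label", "phase",
            "t_samples", "distance_cm", "coverage",
        ],
    )


def normalize_activity(activity: pd.DataFrame) -> pd.DataFrame:
    """Add ``relative_activity``: 100 * distance / per-animal maximum.

    An animal that never moved gets 0 everywhere (with a warning) instead
    of dividing by zero.
    """
    out = activity.reset_index(drop=True).copy()
    rel = np.zeros(len(out))
    for tag, g in out.groupby("tag_id", sort=False):
        mx = g["distance_cm"].max()
        if mx > 0:
            rel[g.index] = 100.0 * g["distance_cm"] / mx
        else:
            logger.warning("tag %r has zero total distance; relative activity set to 0", tag)
    out["relative_activity"] = rel
    return out


def light_dark_totals(steps: pd.DataFrame, config: SessionConfig) -> pd.DataFrame:
    """Travel-distance totals per successive 12-h light/dark interval."""
    return windowed_distance(steps, make_phase_windows(config))


def activity_heatmap_matrix(
    activity: pd.DataFrame,
    tag_order: list[str] | None = None,
    value: str = "relative_activity",
) -> pd.DataFrame:
    """Dense animals x windows matrix of (relative) activity.

    Rows follow ``tag_order`` when given; columns follow window start
    time; windows an animal is absent from are NaN.
    """
    if value not in activity.columns:
        raise KeyError(f"activity table has no column {value!r}")
    mat = activity.pivot(index="tag_id", columns="window_start", values=value)
    mat = mat.sort_index(axis=1)
    if tag_order is not None:
        mat = mat.reindex(tag_order)
    else:
        mat = mat.reindex(list(dict.fromkeys(activity["tag_id"])))
    labels = activity.drop_duplicates("window_start").set_index("window_start")["label"]
    mat.columns = [labels.get(c, str(c)) for c in mat.columns]
    return mat
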