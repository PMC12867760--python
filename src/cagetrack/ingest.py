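"""Raw RFID log ingestion and per-second trajectory reconstruction.

The floor-plate logger emits one detection event per line: a wall-clock
timestamp (optionally with fractional seconds), the antenna ID that fired
and the transponder (tag) ID of the animal.  This module parses that log,
downsamples it to one position per animal per second and produces the
cleaned trajectory table every downstream metric consumes.

Log dialect
-----------
One event per line, whitespace- or tab-delimited::

    2023-01-10 08:00:00.41<TAB>13<TAB>TAG_A

* timestamp: ISO-8601 local wall clock; a space or ``T`` date/time
  separator is accepted; fractional seconds are optional,
* antenna ID: integer in ``1..n_antennas`` (96 on the default board),
* tag ID: opaque string,
* lines starting with ``#`` and blank lines are ignored.

Cleaning rules
--------------
1. Timestamps are truncated (floored, never rounded) to whole seconds.
2. If one tag is detected more than once within a second, only the first
   detection in file order is kept; detections of *different* tags in the
   same second are all kept.
3. Seconds with no detection are filled with the animal's most recent
   observed position (last observation carried forward).  There is no
   back-fill: seconds before a tag's first detection are absent.

The result is a :class:`pandas.DataFrame` ("trajectory table") with one
row per ``(tag_id, second)`` and columns ``tag_id, second, antenna_id, x,
y, observed`` where ``second`` is integer epoch seconds of the naive local
wall clock and ``observed`` is False on forward-filled rows.
"""

from __future__ import annotations

import calendar
import logging
from dataclasses import dataclass, field
from datetime import datetime, time, timedelta
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, GridGeometry, antennas_to_xy

logger = logging.getLogger("cagetrack.ingest")

__all__ = [
    "RawDetection",
    "SessionConfig",
    "to_epoch",
    "from_epoch",
    "parse_raw_log",
    "parse_raw_log_frame",
    "truncate_to_seconds",
    "dedupe_first_wins",
    "forward_fill",
    "preprocess",
    "write_processed_csv",
    "read_processed_csv",
    "TRAJECTORY_COLUMNS",
]

TRAJECTORY_COLUMNS = ["tag_id", "second", "antenna_id", "x", "y", "observed"]


def to_epoch(dt: datetime) -> int:
    """Naive wall-clock datetime -> integer epoch seconds (floored).

    The wall clock is treated as a fixed offset-free timeline (the logger
    clock is assumed monotonic local time), so the conversion is
    timezone-independent and deterministic.
    """
    return calendar.timegm(dt.timetuple())


def from_epoch(second: int) -> datetime:
    """Inverse of :func:`to_epoch` (whole seconds)."""
    return datetime(1970, 1, 1) + timedelta(seconds=int(second))


@dataclass(frozen=True)
class RawDetection:
    """One sensor event before any cleaning."""

    timestamp: datetime
    antenna_id: int
    tag_id: str
    line_no: int


@dataclass(frozen=True)
class SessionConfig:
    """Recording-session clock and housekeeping parameters.

    Parameters
    ----------
    session_start:
        Wall-clock start of the recording (animals introduced).
    session_hours:
        Total recording length in hours (default 72 h, i.e. three
        light/dark cycles).
    lights_on, lights_off:
        Daily lighting schedule; the default 08:00 / 20:00 gives a
        12:12 h light-dark cycle with lights-on at 8:00.
    expected_tags:
        Optional list of tag IDs that should appear; tags listed here but
        never detected trigger a warning and are omitted.
    fill_to_session_end:
        If True, forward-fill extends from each tag's last detection to
        the end of the session; otherwise filling stops at the tag's last
        observed second.
    max_fill_gap:
        Optional cap (seconds) on how long a position may be carried
        forward; seconds farther than this from the last observation are
        dropped.  ``None`` (default) means unlimited.
    drop_tags:
        Tag IDs excluded from the output entirely (e.g. an animal whose
        tag detached mid-experiment).
    """

    session_start: datetime
    session_hours: float = 72.0
    lights_on: time = time(8, 0)
    lights_off: time = time(20, 0)
    expected_tags: Sequence[str] | None = None
    fill_to_session_end: bool = False
    max_fill_gap: int | None = None
    drop_tags: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.lights_on == self.lights_off:
            raise ValueError("lights_on and lights_off must differ")
        if self.session_hours <= 0:
            raise ValueError("session_hours must be positive")
        if self.max_fill_gap is not None and self.max_fill_gap < 0:
            raise ValueError("max_fill_gap must be non-negative")

    @property
    def session_end(self) -> datetime:
        return self.session_start + timedelta(hours=self.session_hours)

    @property
    def start_second(self) -> int:
        return to_epoch(self.session_start)

    @property
    def end_second(self) -> int:
        """First epoch second *after* the session."""
        return self.start_second + int(round(self.session_hours * 3600))

    def light_mask(self, seconds: np.ndarray) -> np.ndarray:
        """Boolean array: True where the epoch second falls in the light phase."""
        tod = np.asarray(seconds, dtype=np.int64) % 86400
        on = self.lights_on.hour * 3600 + self.lights_on.minute * 60 + self.lights_on.second
        off = self.lights_off.hour * 3600 + self.lights_off.minute * 60 + self.lights_off.second
        if on < off:
            return (tod >= on) & (tod < off)
        return (tod >= on) | (tod < off)


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _parse_line(line: str) -> tuple[datetime, int, str]:
    """Parse one event line; raises ValueError on malformed input."""
    tokens = line.split()
    if len(tokens) == 4:
        ts_str = tokens[0] + " " + tokens[1]
        ant_str, tag = tokens[2], tokens[3]
    elif len(tokens) == 3:
        ts_str, ant_str, tag = tokens
    else:
        raise ValueError(f"expected 3 or 4 fields, got {len(tokens)}")
    ts = datetime.fromisoformat(ts_str)
    return ts, int(ant_str), tag


def parse_raw_log(
    path: str | Path,
    strict: bool = False,
    geom: GridGeometry = DEFAULT_GEOMETRY,
) -> list[RawDetection]:
    """Parse a raw log file into :class:`RawDetection` records, in file order.

    Malformed lines and out-of-range antenna IDs are counted and logged
    (or, with ``strict=True``, abort with the offending line number).
    Intended for moderate files; the bulk pipeline uses
    :func:`parse_raw_log_frame`.
    """
    path = Path(path)
    out: list[RawDetection] = []
    n_rejected = 0
    with path.open("r", encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            try:
                ts, antenna, tag = _parse_line(line)
                if not 1 <= antenna <= geom.n_antennas:
                    raise ValueError(
                        f"antenna_id {antenna} outside 1..{geom.n_antennas}"
                    )
            except ValueError as exc:
                if strict:
                    raise ValueError(f"{path}:{line_no}: {exc}") from exc
                n_rejected += 1
                logger.warning("%s:%d: rejected line (%s)", path, line_no, exc)
                continue
            out.append(RawDetection(ts, antenna, tag, line_no))
    if n_rejected:
        logger.warning("%s: rejected %d malformed line(s)", path, n_rejected)
    return out


def parse_raw_log_frame(
    path: str | Path,
    strict: bool = False,
    geom: GridGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Vectorised parser: raw log -> DataFrame.

    Columns: ``timestamp`` (datetime64[ns], fractional seconds preserved),
    ``antenna_id`` (int32), ``tag_id`` (str), ``line_no`` (int64).
    Same dialect and rejection rules as :func:`parse_raw_log`.
    """
    path = Path(path)
    with path.open("r", encoding="utf-8") as fh:
        lines = pd.Series(fh.read().splitlines(), dtype="object")
    line_no = pd.RangeIndex(1, len(lines) + 1)
    stripped = lines.str.strip()
    keep = (stripped.str.len() > 0) & ~stripped.str.startswith("#")
    stripped = stripped[np.asarray(keep)]
    line_no = line_no[np.asarray(keep)]
    if stripped.empty:
        return pd.DataFrame(
            {
                "timestamp": pd.Series([], dtype="datetime64[ns]"),
                "antenna_id": pd.Series([], dtype=np.int32),
                "tag_id": pd.Series([], dtype="object"),
                "line_no": pd.Series([], dtype=np.int64),
            }
        )
    parts = stripped.str.rsplit(n=2, expand=True)
    if parts.shape[1] < 3:  # every line malformed
        parts = parts.reindex(columns=range(3))
    ts = pd.to_datetime(parts[0], format="ISO8601", errors="coerce")
    antenna = pd.to_numeric(parts[1], errors="coerce")
    tag = parts[2]
    valid = (
        ts.notna()
        & antenna.notna()
        & (antenna == antenna.round())
        & (antenna >= 1)
        & (antenna <= geom.n_antennas)
        & tag.notna()
    )
    if not valid.all():
        bad_line = int(np.asarray(line_no)[~np.asarray(valid)][0])
        if strict:
            raise ValueError(f"{path}:{bad_line}: malformed or out-of-range line")
        logger.warning(
            "%s: rejected %d malformed line(s), first at line %d",
            path,
            int((~valid).sum()),
            bad_line,
        )
    mask = np.asarray(valid)
    return pd.DataFrame(
        {
            "timestamp": ts[mask].to_numpy(),
            "antenna_id": antenna[mask].to_numpy(dtype=np.int32),
            "tag_id": tag[mask].to_numpy(),
            "line_no": np.asarray(line_no)[mask].astype(np.int64),
        }
    )


# ---------------------------------------------------------------------------
# Cleaning (record-level API)
# ---------------------------------------------------------------------------

def truncate_to_seconds(detections: Iterable[RawDetection]) -> list[RawDetection]:
    """Drop fractional seconds (floor truncation, not rounding)."""
    return [
        RawDetection(d.timestamp.replace(microsecond=0), d.antenna_id, d.tag_id, d.line_no)
        for d in detections
    ]


def dedupe_first_wins(detections: Sequence[RawDetection]) -> list[RawDetection]:
    """Keep, per ``(tag_id, second)``, only the earliest detection by line_no.

    Timestamps must already be truncated to whole seconds.  Detections of
    different tags within the same second are all retained.
    """
    seen: set[tuple[str, datetime]] = set()
    out: list[RawDetection] = []
    for d in sorted(detections, key=lambda d: d.line_no):
        key = (d.tag_id, d.timestamp)
        if key in seen:
            continue
        seen.add(key)
        out.append(d)
    return out


def _detections_to_frame(detections: Iterable[RawDetection]) -> pd.DataFrame:
    rows = [(d.timestamp, d.antenna_id, d.tag_id, d.line_no) for d in detections]
    return pd.DataFrame(rows, columns=["timestamp", "antenna_id", "tag_id", "line_no"])


def forward_fill(
    deduped: Sequence[RawDetection] | pd.DataFrame,
    config: SessionConfig,
    geom: GridGeometry = DEFAULT_GEOMETRY,
) -> pd.DataFrame:
    """Build the per-second trajectory table from deduplicated detections.

    Gaps between a tag's first and last covered second are filled with the
    most recent observed position (``observed=False`` on filled rows).
    With ``config.fill_to_session_end`` the fill horizon extends to the
    session end; ``config.max_fill_gap`` caps the carry-forward length.
    """
    if isinstance(deduped, pd.DataFrame):
        det = deduped.copy()
    else:
        det = _detections_to_frame(deduped)
    return _fill_frame(det, config, geom)


def _fill_frame(det: pd.DataFrame, config: SessionConfig, geom: GridGeometry) -> pd.DataFrame:
    if det.empty:
        return pd.DataFrame(
            {
                "tag_id": pd.Series([], dtype="object"),
                "second": pd.Series([], dtype=np.int64),
                "antenna_id": pd.Series([], dtype=np.int64),
                "x": pd.Series([], dtype=np.int64),
                "y": pd.Series([], dtype=np.int64),
                "observed": pd.Series([], dtype=bool),
            }
        )
    # epoch seconds, floored
    ts = pd.to_datetime(det["timestamp"])
    det = det.assign(second=ts.values.astype("datetime64[s]").astype(np.int64))

    tags_seen = list(dict.fromkeys(det["tag_id"]))
    if config.expected_tags is not None:
        missing = [t for t in config.expected_tags if t not in tags_seen]
        for t in missing:
            logger.warning("expected tag %r has zero detections; omitted", t)
        tag_order = [t for t in config.expected_tags if t in tags_seen]
        extra = [t for t in tags_seen if t not in tag_order]
        tag_order += extra
    else:
        tag_order = tags_seen
    tag_order = [t for t in tag_order if t not in set(config.drop_tags)]

    end_second = config.end_second  # exclusive
    pieces = []
    for tag in tag_order:
        g = det.loc[det["tag_id"] == tag, ["second", "antenna_id"]]
        g = g.drop_duplicates("second").sort_values("second")
        secs = g["second"].to_numpy(dtype=np.int64)
        ants = g["antenna_id"].to_numpy(dtype=np.int64)
        first = secs[0]
        last = int(end_second - 1) if config.fill_to_session_end else int(secs[-1])
        if last < first:
            last = int(secs[-1])
        full = np.arange(first, last + 1, dtype=np.int64)
        idx = np.searchsorted(secs, full, side="right") - 1
        filled_ant = ants[idx]
        observed = np.zeros(full.shape, dtype=bool)
        observed[np.searchsorted(full, secs)] = True
        if config.max_fill_gap is not None:
            age = full - secs[idx]
            keep = age <= config.max_fill_gap
            full, filled_ant, observed = full[keep], filled_ant[keep], observed[keep]
        x, y = antennas_to_xy(filled_ant, geom)
        pieces.append(
            pd.DataFrame(
                {
                    "tag_id": tag,
                    "second": full,
                    "antenna_id": filled_ant,
                    "x": x,
                    "y": y,
                    "observed": observed,
                }
            )
        )
    return pd.concat(pieces, ignore_index=True)


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess(
    source: str | Path | pd.DataFrame,
    config: SessionConfig,
    geom: GridGeometry = DEFAULT_GEOMETRY,
    strict: bool = False,
) -> pd.DataFrame:
    """Raw log (path or parsed frame) -> cleaned per-second trajectory table.

    Applies, in order: parsing, second truncation, first-detection-wins
    deduplication and forward fill.  Non-monotonic timestamps trigger a
    warning and a stable sort by (timestamp, line order).
    """
    if isinstance(source, pd.DataFrame):
        det = source.copy()
    else:
        det = parse_raw_log_frame(source, strict=strict, geom=geom)
    if det.empty:
        return _fill_frame(det, config, geom)
    ts = pd.to_datetime(det["timestamp"])
    if not ts.is_monotonic_increasing:
        logger.warning("non-monotonic timestamps; applying stable sort")
        det = det.assign(timestamp=ts).sort_values(
            ["timestamp", "line_no"], kind="stable"
        )
    # first-wins per (tag, second): earliest line_no
    det = det.assign(
        second=pd.to_datetime(det["timestamp"]).values.astype("datetime64[s]").astype(np.int64)
    )
    det = det.sort_values("line_no", kind="stable").drop_duplicates(
        ["tag_id", "second"], keep="first"
    )
    return _fill_frame(det, config, geom)


# ---------------------------------------------------------------------------
# Processed-CSV dialect
# ---------------------------------------------------------------------------

def write_processed_csv(
    traj: pd.DataFrame, path: str | Path, iso_timestamps: bool = False
) -> None:
    """Write a trajectory table as CSV (header ``tag_id,second,antenna_id,x,y,observed``).

    With ``iso_timestamps=True`` the ``second`` column is written as an ISO
    wall-clock timestamp instead of integer epoch seconds.
    """
    out = traj[TRAJECTORY_COLUMNS].copy()
    if iso_timestamps:
        out["second"] = pd.to_datetime(out["second"], unit="s").dt.strftime(
            "%Y-%m-%dT%H:%M:%S"
        )
    out.to_csv(path, index=False)


def read_processed_csv(path: str | Path) -> pd.DataFrame:
    """Read a trajectory table written by :func:`write_processed_csv`."""
    df = pd.read_csv(
        path,
        dtype={"tag_id": "object", "antenna_id": np.int64, "x": np.int64, "y": np.int64},
    )
    if df["second"].dtype == object:  # ISO timestamps
        df["second"] = (
            pd.to_datetime(df["second"]).values.astype("datetime64[s]").astype(np.int64)
        )
    df["second"] = df["second"].astype(np.int64)
    df["observed"] = df["observed"].astype(bool)
    return df[TRAJECTORY_COLUMNS]
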