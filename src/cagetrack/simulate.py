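"""Synthetic home-cage cohort generator.

Emulates the recording regime the pipeline is built for -- several
RFID-tagged mice on a 12 x 8 board of 5 x 5 cm antennas under a 12:12
light-dark cycle (lights-on 08:00) over a multi-day session -- so every
pipeline stage can be exercised and validated without animal data.

Movement model (one step per second, synchronous update):

* each mouse moves with a phase-dependent probability (``p_move_light`` /
  ``p_move_dark``; mice are nocturnal, so the dark value is higher);
* a moving mouse steps *socially* with probability ``p_social``: one
  tile toward its nearest conspecific (reducing Chebyshev distance, ties
  among equally-near partners broken uniformly at random); otherwise it
  steps to a uniformly chosen 8-neighbour, clipped to the board.

Sensor model: each second each mouse's true tile is emitted as one log
line with a random two-digit fractional-second timestamp, unless dropped
(``p_miss``); with probability ``p_dup`` an extra spurious same-second
detection at an adjacent tile is emitted.  An optional ``tag_loss`` map
silences a tag from a given second onward (a detached transponder).

All randomness comes from one seeded generator consumed in a fixed,
documented order (initial positions, then per-array draws: movement,
social choice, direction, tie-break, miss, duplicate, duplicate
direction, fractions), so runs are bit-reproducible for a given seed.
The simulator validates the pipeline; it does not model mouse
physiology (no feeding zones, no wall-following).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import DEFAULT_GEOMETRY, GridGeometry
from .ingest import SessionConfig

__all__ = [
    "SimParams",
    "SimResult",
    "simulate_cohort",
    "scenario_presets",
    "write_raw_log",
    "PRESETS",
]

# 8-neighbour offsets, fixed order (E, W, S, N, SE, NE, SW, NW is *not*
# the order; row-major over dy, dx excluding (0,0))
_OFFSETS = np.array(
    [(dx, dy) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dx, dy) != (0, 0)],
    dtype=np.int64,
)


@dataclass(frozen=True)
class SimParams:
    """Cohort and sensor parameters.

    Defaults describe a typical wild-type cohort on the default board: a
    group of 8 over 72 h, nocturnal activity contrast 0.2 (light) vs 0.8
    (dark) moves per second, moderate social attraction, and a small
    sensor dropout/duplicate rate.
    """

    n_mice: int = 8
    hours: float = 72.0
    p_move_light: float = 0.2
    p_move_dark: float = 0.8
    p_social: float = 0.3
    p_miss: float = 0.02
    p_dup: float = 0.01
    tag_loss: dict[str, int] | None = None  # tag_id -> first silent second (offset)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_move_light", "p_move_dark", "p_social", "p_miss", "p_dup"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.n_mice < 1:
            raise ValueError("n_mice must be >= 1")
        if self.hours <= 0:
            raise ValueError("hours must be positive")


PRESETS: dict[str, SimParams] = {
    "small-group": SimParams(n_mice=4),
    "large-group": SimParams(n_mice=16),
    "nocturnal": SimParams(p_move_light=0.1, p_move_dark=0.9),
    "asocial": SimParams(p_social=0.0),
    "tag-loss": SimParams(n_mice=16, tag_loss={"M16": 24 * 3600}),
}


def scenario_presets(name: str) -> SimParams:
    """Named parameter bundles for the canonical cohort scenarios."""
    try:
        return PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(PRESETS)}"
        ) from None


def _tag_ids(n: int) -> list[str]:
    return [f"M{k + 1:02d}" for k in range(n)]


@dataclass
class SimResult:
    """Simulated raw detections plus the ground-truth trajectory.

    ``detections`` has one row per emitted log line (``second`` offset,
    ``frac`` two-digit fraction, ``antenna_id``, ``tag_id``), sorted by
    emission time.  ``ground_truth`` is a trajectory table giving every
    mouse's true tile each second (``observed=True`` throughout; for a
    lost tag the true positions continue even though nothing is
    emitted).
    """

    params: SimParams
    config: SessionConfig
    geom: GridGeometry
    detections: pd.DataFrame
    ground_truth: pd.DataFrame
    tag_ids: list[str] = field(default_factory=list)

    def raw_lines(self) -> list[str]:
        """Render the detections as raw log lines in the ingest dialect."""
        if self.detections.empty:
            return []
        t0 = self.config.session_start
        secs = self.detections["second"].to_numpy(dtype=np.int64)
        smin = int(secs.min())
        uniq = np.arange(smin, secs.max() + 1)
        base = (pd.to_datetime(t0) + pd.to_timedelta(uniq, unit="s")).strftime(
            "%Y-%m-%d %H:%M:%S"
        )
        ts = pd.Series(np.asarray(base, dtype=object)[secs - smin])
        frac = pd.Series(self.detections["frac"].to_numpy()).astype(str).str.zfill(2)
        ant = pd.Series(self.detections["antenna_id"].to_numpy()).astype(str)
        tag = pd.Series(self.detections["tag_id"].to_numpy())
        return list(ts + "." + frac + "\t" + ant + "\t" + tag)


def _walk(params: SimParams, config: SessionConfig, geom: GridGeometry, rng):
    """Simulate positions; returns (S, N) int16 arrays X, Y (1-based tiles)."""
    s_total = int(round(params.hours * 3600))
    n = params.n_mice
    x = rng.integers(1, geom.n_x + 1, size=n).astype(np.int64)
    y = rng.integers(1, geom.n_y + 1, size=n).astype(np.int64)

    seconds = config.start_second + np.arange(s_total, dtype=np.int64)
    light = config.light_mask(seconds)
    p_move = np.where(light, params.p_move_light, params.p_move_dark)
    mv = rng.random((s_total, n)) < p_move[:, None]
    soc = rng.random((s_total, n)) < params.p_social
    dir_idx = rng.integers(0, 8, size=(s_total, n))
    tie_u = rng.random((s_total, n))

    X = np.empty((s_total, n), dtype=np.int16)
    Y = np.empty((s_total, n), dtype=np.int16)
    for t in range(s_total):
        X[t] = x
        Y[t] = y
        movers = mv[t]
        if not movers.any():
            continue
        step_x = np.zeros(n, dtype=np.int64)
        step_y = np.zeros(n, dtype=np.int64)
        social = movers & soc[t]
        rand_m = movers & ~soc[t]
        if rand_m.any():
            off = _OFFSETS[dir_idx[t, rand_m]]
            step_x[rand_m] = off[:, 0]
            step_y[rand_m] = off[:, 1]
        if social.any() and n > 1:
            dx = x[None, :] - x[:, None]
            dy = y[None, :] - y[:, None]
            cheb = np.maximum(np.abs(dx), np.abs(dy)).astype(np.float64)
            np.fill_diagonal(cheb, np.inf)
            for i in np.nonzero(social)[0]:
                row = cheb[i]
                mn = row.min()
                cand = np.flatnonzero(row == mn)
                j = cand[int(tie_u[t, i] * len(cand)) % len(cand)]
                step_x[i] = np.sign(x[j] - x[i])
                step_y[i] = np.sign(y[j] - y[i])
        x = np.clip(x + step_x, 1, geom.n_x)
        y = np.clip(y + step_y, 1, geom.n_y)
    return X, Y


def simulate_cohort(
    params: SimParams,
    config: SessionConfig | None = None,
    geom: GridGeometry = DEFAULT_GEOMETRY,
) -> SimResult:
    """Run the cohort simulation; returns detections plus ground truth.

    When ``config`` is None a session starting 2023-01-10 08:00 (lights
    on) of ``params.hours`` hours is used.
    """
    if config is None:
        config = SessionConfig(
            session_start=datetime(2023, 1, 10, 8, 0, 0), session_hours=params.hours
        )
    rng = np.random.default_rng(params.seed)
    tags = _tag_ids(params.n_mice)
    X, Y = _walk(params, config, geom, rng)
    s_total, n = X.shape

    miss = rng.random((s_total, n)) < params.p_miss
    dup = rng.random((s_total, n)) < params.p_dup
    dup_dir = rng.integers(0, 8, size=(s_total, n))
    frac = rng.integers(0, 100, size=(s_total, n))
    dup_frac = rng.integers(0, 100, size=(s_total, n))

    lost = np.zeros((s_total, n), dtype=bool)
    if params.tag_loss:
        for tag, first_silent in params.tag_loss.items():
            if tag not in tags:
                raise ValueError(f"tag_loss references unknown tag {tag!r}")
            lost[int(first_silent):, tags.index(tag)] = True

    antenna = (Y.astype(np.int64) - 1) * geom.n_x + X.astype(np.int64)

    emit = ~miss & ~lost
    t_idx, m_idx = np.nonzero(emit)
    det = {
        "second": t_idx.astype(np.int64),
        "frac": frac[t_idx, m_idx].astype(np.int64),
        "antenna_id": antenna[t_idx, m_idx],
        "mouse": m_idx,
    }
    dup_emit = dup & emit
    td, md = np.nonzero(dup_emit)
    if len(td):
        off = _OFFSETS[dup_dir[td, md]]
        dxq = np.clip(X[td, md].astype(np.int64) + off[:, 0], 1, geom.n_x)
        dyq = np.clip(Y[td, md].astype(np.int64) + off[:, 1], 1, geom.n_y)
        det = {
            "second": np.concatenate([det["second"], td.astype(np.int64)]),
            "frac": np.concatenate([det["frac"], dup_frac[td, md].astype(np.int64)]),
            "antenna_id": np.concatenate([det["antenna_id"], (dyq - 1) * geom.n_x + dxq]),
            "mouse": np.concatenate([det["mouse"], md]),
        }
    detections = pd.DataFrame(det)
    detections["tag_id"] = pd.Categorical.from_codes(
        detections["mouse"].to_numpy(), categories=tags
    ).astype(str)
    detections = detections.drop(columns="mouse")
    detections = detections.sort_values(
        ["second", "frac", "tag_id"], kind="stable"
    ).reset_index(drop=True)

    t0 = config.start_second
    truth = pd.DataFrame(
        {
            "tag_id": np.repeat(tags, s_total),
            "second": np.tile(t0 + np.arange(s_total, dtype=np.int64), n)
            .reshape(n, s_total)
            .ravel(),
            "antenna_id": antenna.T.ravel(),
            "x": X.T.ravel().astype(np.int64),
            "y": Y.T.ravel().astype(np.int64),
            "observed": True,
        }
    )
    return SimResult(
        params=params,
        config=config,
        geom=geom,
        detections=detections,
        ground_truth=truth,
        tag_ids=tags,
    )


def write_raw_log(result: SimResult, path: str | Path) -> None:
    """Write the simulated detections as a raw log file in the ingest dialect."""
    lines = result.raw_lines()
    with Path(path).open("w", encoding="utf-8") as fh:
        fh.write("# simulated RFID floor-plate log\n")
        fh.write("\n".join(lines))
        if lines:
            fh.write("\n")


def with_overrides(params: SimParams, **kwargs) -> SimParams:
    """Convenience: copy params with field overrides."""
    return replace(params, **kwargs)
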