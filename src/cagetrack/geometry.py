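"""Floor-plate grid geometry and pairwise proximity classification.

The sensing surface is a board of square antenna tiles -- by default 12
columns by 8 rows of 5 x 5 cm tiles, i.e. 96 antenna IDs.  Animal positions
are 1-based tile indices ``(x, y)``; physical distances are tile-index
Euclidean distances scaled by the tile pitch.

Proximity between two animals is classified into four concentric
categories around the focal animal:

* ``Same``          -- both animals on the same tile (L = 0 cm)
* ``Close``         -- adjacent tiles, including diagonals (L = 5 or 5*sqrt(2) cm)
* ``Intermediate``  -- the second ring (L = 10, 5*sqrt(5) or 10*sqrt(2) cm)
* ``Away``          -- anything farther (L > 10*sqrt(2) cm)

For integer tile offsets these rings coincide exactly with Chebyshev
distance 0, 1, 2 and >= 3.  Classification is computed on the *squared*
integer tile distance, so category boundaries are exact and no floating
point tolerance is involved; centimetre values are presentation only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GridGeometry",
    "DEFAULT_GEOMETRY",
    "CATEGORIES",
    "antenna_to_xy",
    "xy_to_antenna",
    "antennas_to_xy",
    "pair_distance_cm",
    "classify_proximity",
    "category_codes_from_d2",
    "CLOSE_D2_MAX",
    "INTERMEDIATE_D2_MAX",
]

#: Proximity category labels, ordered from closest to farthest.
CATEGORIES: tuple[str, ...] = ("Same", "Close", "Intermediate", "Away")

# Squared tile-index distance bounds of the rings (exact integers).
CLOSE_D2_MAX = 2          # dx^2 + dy^2 in {1, 2}
INTERMEDIATE_D2_MAX = 8   # dx^2 + dy^2 in {4, 5, 8}


@dataclass(frozen=True)
class GridGeometry:
    """Physical layout of the antenna board.

    Parameters
    ----------
    n_x, n_y:
        Number of tile columns and rows.  The default 12 x 8 board exposes
        96 antenna IDs.
    pitch_cm:
        Edge length of one square tile in centimetres.
    """

    n_x: int = 12
    n_y: int = 8
    pitch_cm: float = 5.0

    def __post_init__(self) -> None:
        if self.n_x < 1 or self.n_y < 1:
            raise ValueError("grid dimensions must be positive")
        if self.pitch_cm <= 0:
            raise ValueError("pitch_cm must be positive")

    @property
    def n_antennas(self) -> int:
        return self.n_x * self.n_y

    def in_bounds(self, x: int, y: int) -> bool:
        return 1 <= x <= self.n_x and 1 <= y <= self.n_y


DEFAULT_GEOMETRY = GridGeometry()


def antenna_to_xy(antenna_id: int, geom: GridGeometry = DEFAULT_GEOMETRY) -> tuple[int, int]:
    """Map an antenna ID to its 1-based ``(x, y)`` tile coordinate.

    Numbering is row-major with ``x`` varying fastest: antenna 1 is tile
    (1, 1), antenna ``n_x`` is (n_x, 1), antenna ``n_x + 1`` is (1, 2) and
    so on, i.e. ``id = (y - 1) * n_x + x``.
    """
    if not 1 <= antenna_id <= geom.n_antennas:
        raise ValueError(
            f"antenna_id {antenna_id} outside valid range 1..{geom.n_antennas}"
        )
    y, x = divmod(antenna_id - 1, geom.n_x)
    return x + 1, y + 1


def xy_to_antenna(x: int, y: int, geom: GridGeometry = DEFAULT_GEOMETRY) -> int:
    """Inverse of :func:`antenna_to_xy`."""
    if not geom.in_bounds(x, y):
        raise ValueError(
            f"coordinate ({x}, {y}) outside grid 1..{geom.n_x} x 1..{geom.n_y}"
        )
    return (y - 1) * geom.n_x + x


def antennas_to_xy(
    antenna_ids: np.ndarray, geom: GridGeometry = DEFAULT_GEOMETRY
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised :func:`antenna_to_xy` for integer arrays."""
    ids = np.asarray(antenna_ids, dtype=np.int64)
    if ids.size and (ids.min() < 1 or ids.max() > geom.n_antennas):
        bad = ids[(ids < 1) | (ids > geom.n_antennas)][0]
        raise ValueError(
            f"antenna_id {bad} outside valid range 1..{geom.n_antennas}"
        )
    y, x = np.divmod(ids - 1, geom.n_x)
    return x + 1, y + 1


def pair_distance_cm(
    a: tuple[int, int], b: tuple[int, int], geom: GridGeometry = DEFAULT_GEOMETRY
) -> float:
    """Euclidean distance in cm between two tile coordinates.

    ``L = pitch_cm * sqrt((ax - bx)^2 + (ay - by)^2)``.
    """
    for p in (a, b):
        if not geom.in_bounds(*p):
            raise ValueError(f"coordinate {p} outside grid bounds")
    return geom.pitch_cm * math.hypot(a[0] - b[0], a[1] - b[1])


def category_codes_from_d2(d2: np.ndarray) -> np.ndarray:
    """Proximity category codes (0=Same .. 3=Away) from squared tile distance.

    ``d2`` must be the integer squared tile-index distance
    ``(dx^2 + dy^2)``; the ring boundaries are then exact.
    """
    d2 = np.asarray(d2)
    codes = np.full(d2.shape, 3, dtype=np.int8)
    codes[d2 <= INTERMEDIATE_D2_MAX] = 2
    codes[d2 <= CLOSE_D2_MAX] = 1
    codes[d2 == 0] = 0
    return codes


def classify_proximity(
    a: tuple[int, int], b: tuple[int, int], geom: GridGeometry = DEFAULT_GEOMETRY
) -> str:
    """Classify a pair of tile coordinates into Same/Close/Intermediate/Away."""
    for p in (a, b):
        if not geom.in_bounds(*p):
            raise ValueError(f"coordinate {p} outside grid bounds")
    d2 = (a[0] - b[0]) ** 2 + (a[1] - b[1]) ** 2
    return CATEGORIES[int(category_codes_from_d2(np.array(d2)))]
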