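"""Calibrated measurement phantom and displacement-pair datasets.

Electromagnetic tracking (EMT) accuracy is assessed on a stud-grid phantom
whose seat positions are known to high accuracy (repeatability ~0.02 mm).
Because absolute sensor positions in the tracker frame are not known without
a second measurement standard, error is defined on *relative displacements*:

    e = ||x2 - x1|| - y

where x1, x2 are two measured sensor positions and y is the ground-truth
distance between their phantom seats.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

#: Height of one brick, mm — the elevation step between phantom levels.
BRICK_HEIGHT_MM = 9.6
#: In-plane stud pitch of the board, mm.
STUD_PITCH_MM = 8.0


class ConfigurationError(ValueError):
    """Invalid phantom/model configuration."""


class DataError(ValueError):
    """Inconsistent or unusable measurement data."""


@dataclass(frozen=True)
class CalibratedPhantom:
    """A calibrated grid phantom with seats at several elevations.

    ``grid_positions`` holds the planar (x, y) seat coordinates in mm,
    centred on the board origin; a seat's 3D ground-truth position is its
    planar position at ``elevation_level * brick_height``.
    """

    grid_positions: np.ndarray          # (n_points, 2), mm
    stud_pitch: float = STUD_PITCH_MM
    brick_height: float = BRICK_HEIGHT_MM
    n_elevations: int = 3
    repeatability: float = 0.02         # mm, treated as negligible

    def __post_init__(self) -> None:
        pos = np.asarray(self.grid_positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 2 or pos.shape[0] < 2:
            raise ConfigurationError("need at least two planar seat positions")
        if self.stud_pitch <= 0 or self.brick_height <= 0:
            raise ConfigurationError("pitch and brick height must be positive")
        if self.n_elevations < 1:
            raise ConfigurationError("need at least one elevation")
        # seats must be distinct, otherwise ground-truth distances degenerate
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        if np.any(d[~np.eye(len(pos), dtype=bool)] <= 0):
            raise ConfigurationError("duplicate seat positions")
        object.__setattr__(self, "grid_positions", pos)

    @property
    def n_points(self) -> int:
        return int(self.grid_positions.shape[0])

    def elevations(self) -> np.ndarray:
        return np.arange(self.n_elevations) * self.brick_height

    def position(self, grid_index: int, elevation_level: int = 0) -> np.ndarray:
        """3D ground-truth position (mm) of a seat at an elevation level."""
        if not 0 <= grid_index < self.n_points:
            raise DataError(f"unknown grid index {grid_index}")
        if not 0 <= elevation_level < self.n_elevations:
            raise DataError(f"unknown elevation level {elevation_level}")
        x, y = self.grid_positions[grid_index]
        return np.array([x, y, elevation_level * self.brick_height])

    def ground_truth_distance(
        self, i: int, elev_i: int, j: int, elev_j: int
    ) -> float:
        return float(
            np.linalg.norm(self.position(i, elev_i) - self.position(j, elev_j))
        )


def build_phantom(
    n_points: int,
    pitch: float = STUD_PITCH_MM,
    n_elevations: int = 3,
    spacing_studs: int = 4,
    brick_height: float = BRICK_HEIGHT_MM,
) -> CalibratedPhantom:
    """Deterministic phantom layout: seats on a near-square sub-lattice.

    Seats are placed row-major on a lattice with ``spacing_studs`` studs
    between neighbouring seats, centred on the board origin, replicated at
    ``n_elevations`` levels separated by ``brick_height``.
    """
    if n_points < 2:
        raise ConfigurationError("n_points must be >= 2")
    if pitch <= 0:
        raise ConfigurationError("pitch must be positive")
    ncol = math.ceil(math.sqrt(n_points))
    step = spacing_studs * pitch
    seats = []
    for k in range(n_points):
        r, c = divmod(k, ncol)
        seats.append((c * step, r * step))
    seats_arr = np.asarray(seats, dtype=float)
    seats_arr -= seats_arr.mean(axis=0)  # centre on board origin
    return CalibratedPhantom(
        grid_positions=seats_arr,
        stud_pitch=pitch,
        brick_height=brick_height,
        n_elevations=n_elevations,
    )


@dataclass
class Measurement:
    """One (possibly distorted) sensor reading at a phantom seat."""

    scenario_id: str
    grid_index: int
    elevation_level: int
    rotation: float                      # degrees about board azimuth, 0 or 180
    position: np.ndarray                 # measured (x, y, z), mm
    quality: float                       # tracker quality indicator Q
    compensated: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.rotation not in (0, 180, 0.0, 180.0):
            raise DataError("rotation must be 0 or 180 degrees")
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class DisplacementPair:
    """The training atom: two measurements plus their ground-truth distance."""

    m1: Measurement
    m2: Measurement
    ground_truth: float                  # y, mm

    def __post_init__(self) -> None:
        if self.m1.scenario_id != self.m2.scenario_id:
            raise DataError("pair must come from one scenario")
        if self.ground_truth <= 0:
            raise DataError("ground-truth displacement must be positive")


def pair_dataset(
    measurements: Sequence[Measurement], phantom: CalibratedPhantom
) -> list[DisplacementPair]:
    """All unordered same-scenario, same-rotation measurement pairs.

    Pairs are formed across elevations but never across the two azimuth
    rotations, since seat correspondence between the rotated acquisitions is
    not defined on the board. Ground truth comes from ideal grid geometry.
    Repeat measurements of one seat (zero ground-truth distance) carry no
    displacement information and are skipped.
    """
    for m in measurements:
        if not 0 <= m.grid_index < phantom.n_points:
            raise DataError(f"unknown grid index {m.grid_index}")
    keyed: dict[tuple[str, float], list[Measurement]] = {}
    for m in measurements:
        keyed.setdefault((m.scenario_id, float(m.rotation)), []).append(m)
    pairs: list[DisplacementPair] = []
    for group in keyed.values():
        for m1, m2 in itertools.combinations(group, 2):
            if (m1.grid_index, m1.elevation_level) == (m2.grid_index, m2.elevation_level):
                continue
            y = phantom.ground_truth_distance(
                m1.grid_index, m1.elevation_level, m2.grid_index, m2.elevation_level
            )
            pairs.append(DisplacementPair(m1, m2, y))
    return pairs


def displacement_error(p1: np.ndarray, p2: np.ndarray, y: float) -> float:
    """Signed displacement error e = ||p2 - p1|| - y (mm)."""
    if y < 0:
        raise DataError("ground truth distance must be non-negative")
    return float(np.linalg.norm(np.asarray(p2, float) - np.asarray(p1, float)) - y)


def pair_errors(
    pairs: Sequence[DisplacementPair],
    positions: Literal["measured", "compensated"] = "measured",
) -> np.ndarray:
    """Signed displacement errors for a pair list, vectorised."""
    if not pairs:
        raise DataError("empty pair list")

    def point(m: Measurement) -> np.ndarray:
        if positions == "measured":
            return m.position
        if m.compensated is None:
            raise DataError("measurement has no compensated position")
        return m.compensated

    p1 = np.stack([point(p.m1) for p in pairs])
    p2 = np.stack([point(p.m2) for p in pairs])
    y = np.array([p.ground_truth for p in pairs])
    return np.linalg.norm(p2 - p1, axis=1) - y


def dataset_rmse(
    pairs: Sequence[DisplacementPair],
    positions: Literal["measured", "compensated"] = "measured",
) -> tuple[float, float]:
    """Displacement RMSE and maximum absolute displacement error (mm)."""
    e = pair_errors(pairs, positions)
    return float(np.sqrt(np.mean(e**2))), float(np.max(np.abs(e)))
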