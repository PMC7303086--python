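"""Synthetic EMT distortion: smooth, distance-decaying field plus sensor noise.

The real datasets this package emulates were acquired near a mobile c-arm
whose metal mass systematically bends the tracker's magnetic field. No field
physics is modelled here; the generator only has to reproduce the *summary
statistics* of such acquisitions (per-scenario displacement RMSE between
roughly 0.6 and 1.4 mm, a near-clean laboratory scenario, and a quality
indicator that carries local-distortion information).

Model: the displacement applied to a true position p is

    w(p) = strength * g(||p - c||) * u(p),      g(d) = 1 / (1 + (d/L)^2)

where c is the virtual distorter (c-arm source) position, L a decay length,
and u a *unit* direction field — a room-fixed axis smoothly perturbed by a
seeded low-order polynomial. Scenarios of one suite share the direction
field and differ in distorter distance and strength, mirroring one c-arm
moved around one room. ||w(p)|| is exactly monotone in the distance to the
distorter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize

from .phantom import (
    CalibratedPhantom,
    DataError,
    Measurement,
    dataset_rmse,
    pair_dataset,
)


class CalibrationError(RuntimeError):
    """Strength calibration could not bracket the target RMSE."""


@dataclass(frozen=True)
class DistortionScenario:
    """One acquisition condition: a virtual distorter plus residual noise.

    ``noise_sd`` is the per-axis standard deviation (mm) of the random error
    that survives median filtering of raw samples; ``strength`` is the peak
    field displacement in mm at the distorter itself.
    """

    scenario_id: str
    distorter_position: tuple[float, float, float]
    strength: float
    decay_length: float = 60.0           # mm
    field_seed: int = 7
    noise_sd: float = 0.05               # mm, post-median residual
    direction_wobble: float = 0.5        # relative size of the seeded perturbation
    wobble_scale: float = 40.0           # mm, spatial scale of direction variation

    def __post_init__(self) -> None:
        if self.strength < 0:
            raise DataError("strength must be non-negative")
        if self.decay_length <= 0:
            raise DataError("decay length must be positive")

    def _direction_basis(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        # room-fixed base axis: from the distorter toward the board origin
        c = np.asarray(self.distorter_position, dtype=float)
        u0 = -c / max(np.linalg.norm(c), 1e-12)
        rng = np.random.default_rng(self.field_seed)
        a0 = rng.standard_normal(3)
        A = rng.standard_normal((3, 3))
        return u0, a0, A

    def field(self, points: np.ndarray) -> np.ndarray:
        """Displacement vectors w(p) for an (n, 3) array of positions, mm."""
        p = np.atleast_2d(np.asarray(points, dtype=float))
        c = np.asarray(self.distorter_position, dtype=float)
        d = np.linalg.norm(p - c, axis=1)
        mag = self.strength / (1.0 + (d / self.decay_length) ** 2)
        u0, a0, A = self._direction_basis()
        # smooth unit direction: fixed axis + seeded linear wobble, normalised
        v = u0 + self.direction_wobble * (a0 + (p / self.wobble_scale) @ A.T)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        return mag[:, None] * v

    def field_magnitude(self, points: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(points, dtype=float))
        d = np.linalg.norm(p - np.asarray(self.distorter_position, float), axis=1)
        return self.strength / (1.0 + (d / self.decay_length) ** 2)


def distort_point(p: np.ndarray, scenario: DistortionScenario) -> np.ndarray:
    """Systematically distorted position p + w(p); noise is applied separately."""
    p = np.asarray(p, dtype=float)
    return p + scenario.field(p[None, :])[0]


@dataclass(frozen=True)
class QualityModel:
    """Tracker quality indicator Q = S * (eps - (b + m * r)).

    ``eps`` is the tracker's internal error indication, modelled here as an
    affine function of the local distortion magnitude, and ``r`` the
    sensor-transmitter range. Raw quality corresponds to S=1, b=0, m=0.
    """

    S: float = 1.0
    b: float = 0.0
    m: float = 0.0
    transmitter_position: tuple[float, float, float] = (0.0, -300.0, 150.0)
    eps_offset: float = 0.5              # indicator noise floor
    eps_slope: float = 2.0               # per mm of local distortion
    eps_noise_sd: float = 0.02
    epsilon_fn: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None

    def epsilon(self, local_mag: np.ndarray, r: np.ndarray) -> np.ndarray:
        if self.epsilon_fn is not None:
            return np.asarray(self.epsilon_fn(local_mag, r), dtype=float)
        return self.eps_offset + self.eps_slope * np.asarray(local_mag, float)


def quality_value(
    p: np.ndarray,
    scenario: DistortionScenario,
    qm: QualityModel = QualityModel(),
    rng: np.random.Generator | None = None,
) -> float:
    """Quality indicator at a true position under a scenario."""
    p = np.asarray(p, dtype=float)
    mag = scenario.field_magnitude(p[None, :])
    r = np.linalg.norm(p - np.asarray(qm.transmitter_position, float))
    eps = qm.epsilon(mag, np.array([r]))[0]
    if rng is not None:
        eps = eps + rng.normal(0.0, qm.eps_noise_sd)
    return float(qm.S * (eps - (qm.b + qm.m * r)))


def _rotate_planar(xy: np.ndarray, rotation_deg: float) -> np.ndarray:
    """Rotate planar seat positions about the board azimuth (z) axis."""
    th = math.radians(rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    return xy @ rot.T


def generate_scenario_dataset(
    phantom: CalibratedPhantom,
    scenario: DistortionScenario,
    qm: QualityModel = QualityModel(),
    seed: int = 0,
    rotations: Sequence[float] = (0.0, 180.0),
) -> list[Measurement]:
    """One measurement per (seat, elevation, rotation) under a scenario.

    The phantom is virtually rotated about its azimuth axis before the field
    is applied, so the two rotations sample the field at different places.
    Deterministic for fixed (scenario, seed).
    """
    rng = np.random.default_rng(seed)
    out: list[Measurement] = []
    for rotation in rotations:
        xy = _rotate_planar(phantom.grid_positions, rotation)
        for elev in range(phantom.n_elevations):
            z = elev * phantom.brick_height
            true = np.column_stack([xy, np.full(len(xy), z)])
            distorted = true + scenario.field(true)
            noise = rng.normal(0.0, scenario.noise_sd, size=true.shape)
            mags = scenario.field_magnitude(true)
            ranges = np.linalg.norm(
                true - np.asarray(qm.transmitter_position, float), axis=1
            )
            eps = qm.epsilon(mags, ranges) + rng.normal(
                0.0, qm.eps_noise_sd, size=len(true)
            )
            q = qm.S * (eps - (qm.b + qm.m * ranges))
            for i in range(phantom.n_points):
                out.append(
                    Measurement(
                        scenario_id=scenario.scenario_id,
                        grid_index=i,
                        elevation_level=elev,
                        rotation=rotation,
                        position=distorted[i] + noise[i],
                        quality=float(q[i]),
                    )
                )
    return out


def scenario_rmse(
    phantom: CalibratedPhantom,
    scenario: DistortionScenario,
    qm: QualityModel = QualityModel(),
    seed: int = 0,
) -> float:
    """Displacement RMSE of the pair dataset a scenario generates."""
    ms = generate_scenario_dataset(phantom, scenario, qm, seed=seed)
    rmse, _ = dataset_rmse(pair_dataset(ms, phantom))
    return rmse


def calibrate_strength(
    phantom: CalibratedPhantom,
    template: DistortionScenario,
    target_rmse: float,
    qm: QualityModel = QualityModel(),
    seed: int = 0,
    rtol: float = 0.10,
) -> DistortionScenario:
    """Find the field strength whose generated displacement RMSE hits a target.

    Monotone 1D root find (Brent) on strength; the noise realisation is held
    fixed by the seed so the objective is deterministic.
    """
    if target_rmse < 0:
        raise CalibrationError("target RMSE must be non-negative")

    def f(s: float) -> float:
        return scenario_rmse(phantom, replace(template, strength=s), qm, seed) - target_rmse

    base = f(0.0)
    if target_rmse == 0.0 and template.noise_sd == 0.0:
        return replace(template, strength=0.0)
    if base >= 0:
        if abs(base) <= rtol * max(target_rmse, 1e-12):
            return replace(template, strength=0.0)
        raise CalibrationError(
            f"target {target_rmse} mm below the noise floor {base + target_rmse:.3f} mm"
        )
    hi = max(template.strength, 1.0)
    for _ in range(40):
        if f(hi) > 0:
            break
        hi *= 2.0
    else:
        raise CalibrationError("could not bracket target RMSE")
    s = optimize.brentq(f, 0.0, hi, xtol=1e-4, rtol=1e-6)
    out = replace(template, strength=float(s))
    achieved = scenario_rmse(phantom, out, qm, seed)
    if abs(achieved - target_rmse) > rtol * target_rmse:
        raise CalibrationError(
            f"calibrated RMSE {achieved:.3f} misses target {target_rmse:.3f}"
        )
    return out


def calibrate_strengths(
    phantom: CalibratedPhantom,
    templates: Sequence[DistortionScenario],
    targets: Sequence[tuple[str, float]],
    qm: QualityModel = QualityModel(),
    seed: int = 0,
    rtol: float = 0.10,
) -> list[DistortionScenario]:
    """Calibrate a list of scenario templates to per-scenario RMSE targets."""
    by_id = {t.scenario_id: t for t in templates}
    out = []
    for sid, target in targets:
        if sid not in by_id:
            raise CalibrationError(f"no template for scenario {sid!r}")
        out.append(calibrate_strength(phantom, by_id[sid], target, qm, seed, rtol))
    return out
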