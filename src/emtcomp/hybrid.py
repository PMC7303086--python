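"""Simulated hybrid navigation: error/uncertainty accumulation and recalibration.

A virtual sensor travels along an aorta-like piecewise path whose segment
endpoints are measured board positions. Per segment the compensated
displacement error is accumulated; per waypoint the MC-dropout sigma is
accumulated as a root-sum-square,

    sigma_acc = sqrt(sum_i sigma_i^2),

until a recalibration (an on-demand X-ray snapshot, the radiation proxy)
resets both to zero. Two trigger policies are compared: adaptive (accumulated
sigma exceeds a threshold tau) and static (fixed travelled distance between
recalibrations). Sweeping both families yields the radiation-versus-error
Pareto trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .models import CompensationModel
from .phantom import ConfigurationError, DataError


@dataclass(frozen=True)
class TrajectorySpec:
    """An ordered lattice path with ground-truth segment lengths."""

    lattice_indices: np.ndarray          # (m, 2) stud indices of waypoints
    true_positions: np.ndarray           # (m, d) ground-truth positions, mm
    segment_lengths: np.ndarray          # (m-1,) ground-truth lengths, mm

    @property
    def n_waypoints(self) -> int:
        return len(self.true_positions)

    @property
    def total_length(self) -> float:
        return float(np.sum(self.segment_lengths))


@dataclass(frozen=True)
class RecalibrationPolicy:
    """Adaptive (uncertainty threshold tau, mm) or static (interval, mm)."""

    kind: Literal["adaptive", "static"]
    tau: float | None = None
    interval: float | None = None

    def __post_init__(self) -> None:
        if self.kind == "adaptive":
            if self.tau is None or self.tau <= 0:
                raise ConfigurationError("adaptive policy needs tau > 0")
        elif self.kind == "static":
            if self.interval is None or self.interval < 0:
                raise ConfigurationError("static policy needs interval >= 0")
        else:
            raise ConfigurationError(f"unknown policy kind {self.kind!r}")


@dataclass
class SimTrace:
    """Per-waypoint record of a simulated insertion."""

    traveled: np.ndarray                 # (m,) cumulative ground-truth distance
    segment_error: np.ndarray            # (m,) |comp. distance - truth|, 0 at start
    accumulated_error: np.ndarray        # (m,) RSS since last recalibration
    accumulated_sigma: np.ndarray        # (m,)
    recalibrated: np.ndarray             # (m,) bool flags
    n_recalibrations: int
    path_rmse: float                     # RMS of accumulated error over waypoints


def accumulate_uncertainty(sigmas: Sequence[float]) -> float:
    """Root-sum-square accumulation of per-waypoint sigmas."""
    s = np.asarray(list(sigmas), dtype=float)
    if s.size == 0:
        return 0.0
    if np.any(s < 0):
        raise DataError("sigmas must be non-negative")
    return float(np.sqrt(np.sum(s**2)))


def build_trajectory(
    lattice_indices: np.ndarray,
    positions: np.ndarray,
    total_length: float = 219.0,
    seed: int = 0,
) -> TrajectorySpec:
    """Aorta-like lattice path of roughly ``total_length`` mm.

    A biased walk over the available stud set: predominantly upward with
    lateral jogs, no immediate backtracking, chaining measured board seats
    until the ground-truth length reaches the target within half a pitch.
    Deterministic per seed.
    """
    idx = np.asarray(lattice_indices, dtype=int)
    pos = np.atleast_2d(np.asarray(positions, dtype=float))
    if len(idx) != len(pos):
        raise DataError("indices and positions misaligned")
    lookup = {tuple(ij): k for k, ij in enumerate(idx)}
    pitch_vecs = {}
    # infer pitch from the two nearest distinct lattice points
    d01 = np.linalg.norm(pos[1:] - pos[0], axis=1).min() if len(pos) > 1 else 0.0
    pitch = d01 if d01 > 0 else 8.0
    if total_length < pitch:
        raise DataError("requested path shorter than one grid pitch")
    rng = np.random.default_rng(seed)

    jmin, jmax = idx[:, 1].min(), idx[:, 1].max()
    bottom = idx[idx[:, 1] == jmin]
    # entry point varies over the central half of the bottom row
    cols = bottom[np.argsort(bottom[:, 0])]
    lo, hi = len(cols) // 4, max(len(cols) // 4 + 1, 3 * len(cols) // 4)
    start = tuple(cols[int(rng.integers(lo, hi))])

    # candidate moves: mostly up, some lateral/diagonal; weights bias upward
    moves = [((0, 1), 3.0), ((1, 1), 2.0), ((-1, 1), 2.0),
             ((1, 0), 1.5), ((-1, 0), 1.5), ((0, 2), 1.0),
             ((2, 1), 0.5), ((-2, 1), 0.5)]
    path = [start]
    total = 0.0
    prev = None
    guard = 0
    while total < total_length - pitch / 2:
        guard += 1
        if guard > 100 * len(idx):
            raise DataError("insufficient board coverage to reach requested length")
        here = path[-1]
        allowed = total_length - total + pitch / 2
        cands, weights = [], []
        for (di, dj), wgt in moves:
            nxt = (here[0] + di, here[1] + dj)
            if nxt not in lookup or nxt == prev:
                continue
            step = np.linalg.norm(pos[lookup[nxt]] - pos[lookup[here]])
            if step > allowed:
                continue
            # reflect downward bias at the top edge back into the board
            cands.append((nxt, step))
            weights.append(wgt)
        if not cands:
            # dead end (e.g. top edge): turn around by dropping the
            # no-backtrack constraint and flipping the vertical bias
            moves = [((di, -dj), w) for (di, dj), w in moves]
            prev = None
            continue
        w = np.asarray(weights) / np.sum(weights)
        pick = rng.choice(len(cands), p=w)
        nxt, step = cands[pick]
        path.append(nxt)
        total += step
        prev = here
    rows = np.array([lookup[p] for p in path])
    tp = pos[rows]
    seg = np.linalg.norm(np.diff(tp, axis=0), axis=1)
    return TrajectorySpec(
        lattice_indices=np.array(path), true_positions=tp, segment_lengths=seg
    )


@dataclass
class SimContext:
    """Everything a policy sweep needs for one trajectory realisation."""

    trajectory: TrajectorySpec
    measured: np.ndarray                 # (m, d) measured waypoint positions
    qualities: np.ndarray | None
    sigmas: np.ndarray                   # (m,) per-waypoint MC-dropout sigma
    model: CompensationModel | None      # None -> uncompensated run


def run_simulation(
    context: SimContext, policy: RecalibrationPolicy | None
) -> SimTrace:
    """Walk the trajectory under a recalibration policy (None: never).

    Recorded values are pre-reset; the recalibration flag marks waypoints
    where the reset fires. Recalibration is instantaneous and perfect (the
    X-ray snapshot restores ground truth), so error and accumulated sigma
    restart at zero. The final waypoint never triggers (there is no further
    travel to protect).
    """
    traj = context.trajectory
    m = traj.n_waypoints
    if context.model is not None:
        positions = context.model.predict(context.measured, context.qualities)
    else:
        positions = np.atleast_2d(context.measured)[
            :, : traj.true_positions.shape[1]
        ]
    seg_err = np.zeros(m)
    d = np.linalg.norm(np.diff(positions, axis=0), axis=1)
    seg_err[1:] = np.abs(d - traj.segment_lengths)

    traveled = np.concatenate([[0.0], np.cumsum(traj.segment_lengths)])
    acc_err = np.zeros(m)
    acc_sig = np.zeros(m)
    flags = np.zeros(m, dtype=bool)
    span_err2 = 0.0
    span_sig2 = 0.0
    since_recal = 0.0
    n_recal = 0
    for k in range(1, m):
        since_recal += traj.segment_lengths[k - 1]
        span_err2 += seg_err[k] ** 2
        span_sig2 += context.sigmas[k] ** 2
        acc_err[k] = math.sqrt(span_err2)
        acc_sig[k] = math.sqrt(span_sig2)
        trigger = False
        if policy is not None and k < m - 1:
            if policy.kind == "adaptive":
                trigger = acc_sig[k] > policy.tau
            else:
                trigger = since_recal >= policy.interval
        if trigger:
            flags[k] = True
            n_recal += 1
            span_err2 = span_sig2 = 0.0
            since_recal = 0.0
    return SimTrace(
        traveled=traveled,
        segment_error=seg_err,
        accumulated_error=acc_err,
        accumulated_sigma=acc_sig,
        recalibrated=flags,
        n_recalibrations=n_recal,
        path_rmse=float(np.sqrt(np.mean(acc_err[1:] ** 2))),
    )


@dataclass(frozen=True)
class OperatingPoint:
    """Mean performance of one policy setting across seeds."""

    family: str
    parameter: float
    mean_recalibrations: float
    mean_path_rmse: float


def pareto_front(
    contexts: Sequence[SimContext],
    tau_grid: Sequence[float],
    interval_grid: Sequence[float],
) -> dict[str, list[OperatingPoint]]:
    """Sweep both policy families over trajectory realisations.

    Returns per-family operating points averaged over contexts, sorted by
    mean recalibration count, plus their non-dominated subsets under the
    keys ``"adaptive_front"`` / ``"static_front"``.
    """
    if not len(tau_grid) or not len(interval_grid):
        raise ConfigurationError("policy grids must be non-empty")
    out: dict[str, list[OperatingPoint]] = {"adaptive": [], "static": []}
    for family, grid in (("adaptive", tau_grid), ("static", interval_grid)):
        for param in grid:
            policy = (
                RecalibrationPolicy("adaptive", tau=param)
                if family == "adaptive"
                else RecalibrationPolicy("static", interval=param)
            )
            recs, errs = [], []
            for ctx in contexts:
                trace = run_simulation(ctx, policy)
                recs.append(trace.n_recalibrations)
                errs.append(trace.path_rmse)
            out[family].append(
                OperatingPoint(family, float(param),
                               float(np.mean(recs)), float(np.mean(errs)))
            )
        out[family].sort(key=lambda p: p.mean_recalibrations)
    out["adaptive_front"] = non_dominated(out["adaptive"])
    out["static_front"] = non_dominated(out["static"])
    return out


def non_dominated(points: Sequence[OperatingPoint]) -> list[OperatingPoint]:
    """Points not dominated in (recalibration count, path error)."""
    front = []
    for p in points:
        dominated = any(
            (q.mean_recalibrations <= p.mean_recalibrations
             and q.mean_path_rmse <= p.mean_path_rmse
             and (q.mean_recalibrations < p.mean_recalibrations
                  or q.mean_path_rmse < p.mean_path_rmse))
            for q in points
        )
        if not dominated:
            front.append(p)
    return sorted(front, key=lambda p: p.mean_recalibrations)
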