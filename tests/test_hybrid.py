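import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import emtcomp as ec
from emtcomp.hybrid import OperatingPoint


class TestAccumulateUncertainty:
    @pytest.mark.parametrize(
        "sigmas,expected", [([3, 4], 5.0), ([], 0.0), ([2, 2, 2, 2], 4.0)]
    )
    def test_examples(self, sigmas, expected):
        assert ec.accumulate_uncertainty(sigmas) == pytest.approx(expected)

    def test_negative_rejected(self):
        with pytest.raises(ec.DataError):
            ec.accumulate_uncertainty([1.0, -0.5])

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 10), max_size=20))
    def test_root_sum_square(self, sigmas):
        expected = float(np.sqrt(sum(s * s for s in sigmas)))
        assert ec.accumulate_uncertainty(sigmas) == pytest.approx(expected)


class TestPolicyValidation:
    def test_adaptive_needs_positive_tau(self):
        with pytest.raises(ec.ConfigurationError):
            ec.RecalibrationPolicy("adaptive", tau=0.0)

    def test_static_allows_zero_interval(self):
        ec.RecalibrationPolicy("static", interval=0.0)

    def test_unknown_kind(self):
        with pytest.raises(ec.ConfigurationError):
            ec.RecalibrationPolicy("sometimes")


def _lattice(n=20, pitch=8.0):
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel()])
    return idx, (idx - (n - 1) / 2.0) * pitch


class TestBuildTrajectory:
    def test_total_length_within_half_pitch(self):
        idx, pos = _lattice()
        traj = ec.build_trajectory(idx, pos, total_length=219.0, seed=0)
        assert abs(traj.total_length - 219.0) <= 4.0 + 1e-9
        assert traj.total_length == pytest.approx(np.sum(traj.segment_lengths))
        assert np.all(traj.segment_lengths > 0)

    def test_deterministic_per_seed(self):
        idx, pos = _lattice()
        a = ec.build_trajectory(idx, pos, 219.0, seed=7)
        b = ec.build_trajectory(idx, pos, 219.0, seed=7)
        assert np.array_equal(a.lattice_indices, b.lattice_indices)

    def test_waypoints_are_board_seats(self):
        idx, pos = _lattice()
        seats = {tuple(ij) for ij in idx}
        traj = ec.build_trajectory(idx, pos, 219.0, seed=3)
        assert all(tuple(ij) in seats for ij in traj.lattice_indices)

    def test_too_short_request_rejected(self):
        idx, pos = _lattice()
        with pytest.raises(ec.DataError):
            ec.build_trajectory(idx, pos, total_length=2.0, seed=0)


def _context(seed=0, n_wp=20):
    """Synthetic context: raw positions with known per-waypoint noise."""
    rng = np.random.default_rng(seed)
    idx = np.column_stack([np.zeros(n_wp, dtype=int), np.arange(n_wp)])
    true = idx * 8.0
    seg = np.full(n_wp - 1, 8.0)
    traj = ec.TrajectorySpec(idx, true.astype(float), seg)
    measured = true + rng.normal(scale=0.3, size=true.shape)
    sigmas = rng.uniform(0.1, 0.5, size=n_wp)
    return ec.SimContext(traj, measured, None, sigmas, model=None)


class TestRunSimulation:
    def test_infinite_tau_never_recalibrates(self):
        ctx = _context()
        trace = ec.run_simulation(ctx, ec.RecalibrationPolicy("adaptive", tau=1e9))
        assert trace.n_recalibrations == 0

    def test_tiny_tau_recalibrates_every_waypoint(self):
        ctx = _context()
        trace = ec.run_simulation(ctx, ec.RecalibrationPolicy("adaptive", tau=1e-9))
        m = ctx.trajectory.n_waypoints
        assert trace.n_recalibrations == m - 2  # all but start and final
        # accumulated error equals the instantaneous segment error throughout
        assert np.allclose(trace.accumulated_error[1:], trace.segment_error[1:])

    def test_full_interval_matches_no_policy_run(self):
        ctx = _context()
        free = ec.run_simulation(ctx, None)
        full = ec.run_simulation(
            ctx, ec.RecalibrationPolicy("static", interval=ctx.trajectory.total_length)
        )
        assert full.n_recalibrations == 0
        assert np.array_equal(free.accumulated_error, full.accumulated_error)

    def test_zero_interval_recalibrates_every_waypoint(self):
        ctx = _context()
        trace = ec.run_simulation(ctx, ec.RecalibrationPolicy("static", interval=0.0))
        assert trace.n_recalibrations == ctx.trajectory.n_waypoints - 2

    def test_accumulated_sigma_matches_oracle_per_span(self):
        """Accumulated sigma equals root-sum-square over each reset span."""
        ctx = _context(seed=2)
        trace = ec.run_simulation(ctx, ec.RecalibrationPolicy("adaptive", tau=0.6))
        assert trace.n_recalibrations >= 2
        span: list[float] = []
        for k in range(1, ctx.trajectory.n_waypoints):
            span.append(ctx.sigmas[k])
            assert trace.accumulated_sigma[k] == pytest.approx(
                ec.accumulate_uncertainty(span)
            )
            if trace.recalibrated[k]:
                span = []

    def test_recalibration_count_monotone_in_policy_parameter(self):
        ctx = _context(seed=3)
        taus = [0.2, 0.4, 0.8, 1.6, 3.2]
        counts = [
            ec.run_simulation(ctx, ec.RecalibrationPolicy("adaptive", tau=t)).n_recalibrations
            for t in taus
        ]
        assert np.all(np.diff(counts) <= 0)
        intervals = [0.0, 16.0, 40.0, 80.0, 160.0]
        counts = [
            ec.run_simulation(ctx, ec.RecalibrationPolicy("static", interval=i)).n_recalibrations
            for i in intervals
        ]
        assert np.all(np.diff(counts) <= 0)


class TestParetoFront:
    def test_sweep_and_dominance(self):
        contexts = [_context(seed=s) for s in range(6)]
        res = ec.pareto_front(contexts, tau_grid=(0.3, 0.8, 2.0), interval_grid=(0.0, 40.0, 152.0))
        assert set(res) >= {"adaptive", "static", "adaptive_front", "static_front"}
        for fam in ("adaptive", "static"):
            pts = res[fam]
            most = max(pts, key=lambda p: p.mean_recalibrations)
            none = min(pts, key=lambda p: p.mean_recalibrations)
            assert most.mean_path_rmse <= none.mean_path_rmse

    def test_non_dominated_subset(self):
        pts = [
            OperatingPoint("f", 1, 0.0, 1.0),
            OperatingPoint("f", 2, 1.0, 0.5),
            OperatingPoint("f", 3, 2.0, 0.7),   # dominated by the 1-recal point
            OperatingPoint("f", 4, 3.0, 0.2),
        ]
        front = ec.non_dominated(pts)
        assert [p.parameter for p in front] == [1, 2, 4]

    def test_empty_grid_rejected(self):
        with pytest.raises(ec.ConfigurationError):
            ec.pareto_front([_context()], tau_grid=(), interval_grid=(1.0,))
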