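import numpy as np
import pytest

import emtcomp as ec


class TestCombineSigma:
    def test_pythagorean(self):
        assert ec.combine_sigma(np.array([3.0, 4.0])) == pytest.approx(5.0)

    def test_axis_relabeling_invariant(self):
        s = np.array([0.2, 0.7, 0.1])
        assert ec.combine_sigma(s) == pytest.approx(ec.combine_sigma(s[::-1]))

    def test_negative_rejected(self):
        with pytest.raises(ec.DataError):
            ec.combine_sigma(np.array([-1.0, 2.0]))


class TestMcDropout:
    def test_requires_dropout_trained_model(self, identity_model):
        model, _ = identity_model
        with pytest.raises(ec.StateError):
            ec.mc_dropout_estimate(model, np.zeros(3), 1.0, n=10)

    def test_estimate_fields(self, dropout_model):
        est = ec.mc_dropout_estimate(
            dropout_model, np.array([5.0, 5.0]), 1.0, n=500, seed=0
        )
        assert est.n_samples == 500
        assert est.dropout_rate == pytest.approx(0.10)
        assert np.all(est.sigma_per_axis >= 0)
        assert est.sigma_combined == pytest.approx(
            ec.combine_sigma(est.sigma_per_axis)
        )

    def test_reproducible_for_fixed_seed(self, dropout_model):
        a = ec.mc_dropout_estimate(dropout_model, np.array([5.0, 5.0]), 1.0, 300, seed=4)
        b = ec.mc_dropout_estimate(dropout_model, np.array([5.0, 5.0]), 1.0, 300, seed=4)
        assert np.array_equal(a.sigma_per_axis, b.sigma_per_axis)

    def test_sampling_depth_converged(self, dropout_model):
        """Sigma at the default depth is stable: doubling changes it <5%."""
        pts = np.array([[0.0, 0.0], [30.0, 40.0], [-50.0, 20.0]])
        q = np.array([1.0, 1.2, 0.8])
        _, s1 = ec.mc_dropout_samples(dropout_model, pts, q, n=3000, seed=1)
        _, s2 = ec.mc_dropout_samples(dropout_model, pts, q, n=6000, seed=2)
        c1 = np.sqrt(np.sum(s1**2, axis=1))
        c2 = np.sqrt(np.sum(s2**2, axis=1))
        assert np.all(np.abs(c1 - c2) / c2 < 0.05)


class TestNearestTrainingDistances:
    def test_matches_brute_force_exactly(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(-50, 50, size=(40, 2))
        train = rng.uniform(-50, 50, size=(17, 2))
        fast = ec.nearest_training_distances(pts, train)
        slow = np.array(
            [np.sqrt(min(((p - t) ** 2).sum() for t in train)) for p in pts]
        )
        assert np.array_equal(fast, slow)

    def test_coincident_point_has_zero_distance(self):
        train = np.array([[1.0, 2.0], [5.0, 5.0]])
        d = ec.nearest_training_distances(np.array([[5.0, 5.0]]), train)
        assert d[0] == 0.0


def _lattice(n):
    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    idx = np.column_stack([ii.ravel(), jj.ravel()])
    return idx, idx * 8.0


class TestMooreNeighborhoodError:
    def test_perfect_compensation_zero_everywhere(self):
        idx, gt = _lattice(8)
        err = ec.moore_neighborhood_error(idx, gt.astype(float), gt, r=3)
        assert np.allclose(err, 0.0)

    def test_translation_invariance(self):
        idx, gt = _lattice(8)
        shifted = gt + np.array([13.0, -7.0])
        err = ec.moore_neighborhood_error(idx, shifted, gt, r=3)
        assert np.allclose(err, 0.0, atol=1e-9)

    def test_rotation_invariance(self):
        """Distances are preserved under rigid rotation of the point set."""
        idx, gt = _lattice(6)
        th = 0.3
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        err = ec.moore_neighborhood_error(idx, gt @ rot.T, gt, r=3)
        assert np.allclose(err, 0.0, atol=1e-9)

    def test_matches_brute_force_oracle(self):
        idx, gt = _lattice(7)
        rng = np.random.default_rng(5)
        comp = gt + rng.normal(scale=0.5, size=gt.shape)
        r = 3
        fast = ec.moore_neighborhood_error(idx, comp, gt, r=r)
        lookup = {tuple(ij): k for k, ij in enumerate(idx)}
        for k, (i, j) in enumerate(idx):
            errs = []
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if (di, dj) == (0, 0) or (i + di, j + dj) not in lookup:
                        continue
                    nb = lookup[(i + di, j + dj)]
                    errs.append(
                        abs(np.linalg.norm(comp[k] - comp[nb])
                            - np.linalg.norm(gt[k] - gt[nb]))
                    )
            assert fast[k] == pytest.approx(np.mean(errs))

    def test_interior_point_uses_48_neighbours(self):
        # uniformly scaling the lattice perturbs every pairwise distance by
        # the same relative amount; an interior point's Moore error is then
        # the mean over its full (2r+1)^2 - 1 = 48 neighbour distances
        idx, gt = _lattice(9)
        comp = gt * 1.01
        err = ec.moore_neighborhood_error(idx, comp, gt, r=3)
        lookup = {tuple(ij): k for k, ij in enumerate(idx)}
        centre = lookup[(4, 4)]
        dists = [
            0.01 * np.linalg.norm(gt[centre] - gt[lookup[(4 + di, 4 + dj)]])
            for di in range(-3, 4) for dj in range(-3, 4)
            if (di, dj) != (0, 0)
        ]
        assert len(dists) == 48
        assert err[centre] == pytest.approx(np.mean(dists))

    def test_isolated_point_flagged_nan(self):
        idx = np.array([[0, 0], [10, 10]])
        pos = idx * 8.0
        err = ec.moore_neighborhood_error(idx, pos.astype(float), pos, r=3)
        assert np.all(np.isnan(err))


class TestUncertaintyErrorRegression:
    def test_exact_linear_relation(self):
        sigma = np.linspace(0.1, 1.0, 20)
        slope, intercept, r = ec.uncertainty_error_regression(sigma, 2.0 * sigma)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ec.DataError):
            ec.uncertainty_error_regression(np.ones(10), np.arange(10.0))


class TestUncertaintyMap:
    def test_map_fields_aligned(self, dropout_model):
        pts = np.array([[0.0, 0.0], [10.0, 10.0], [40.0, -20.0]])
        q = np.ones(3)
        train = np.array([[0.0, 0.0], [-30.0, 5.0]])
        umap = ec.build_uncertainty_map(dropout_model, pts, q, train, n=200, seed=0)
        assert umap.sigma.shape == (3,)
        assert umap.nearest_train[0] == 0.0
        assert np.all(umap.sigma >= 0)
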