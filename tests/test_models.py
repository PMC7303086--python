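import numpy as np
import pytest

import emtcomp as ec
from emtcomp.models import NormalizationSpec, _pair_arrays, displacement_loss


class TestNormalization:
    def test_min_maps_to_zero_max_to_one(self):
        x = np.array([[0.0, -5.0], [10.0, 5.0], [4.0, 0.0]])
        spec = NormalizationSpec.fit(x)
        n = spec.normalize(x)
        assert n.min(axis=0) == pytest.approx([0.0, 0.0])
        assert n.max(axis=0) == pytest.approx([1.0, 1.0])

    def test_round_trip_identity(self):
        rng = np.random.default_rng(0)
        x = rng.normal(scale=50, size=(40, 4))
        spec = NormalizationSpec.fit(x)
        assert np.allclose(spec.denormalize(spec.normalize(x)), x, rtol=1e-9)

    def test_out_of_range_maps_linearly_without_clipping(self):
        spec = NormalizationSpec(mins=np.array([0.0]), maxs=np.array([10.0]))
        assert spec.normalize(np.array([[20.0]]))[0, 0] == pytest.approx(2.0)
        assert spec.normalize(np.array([[-10.0]]))[0, 0] == pytest.approx(-1.0)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ec.ConfigurationError):
            NormalizationSpec(mins=np.array([1.0, 0.0]), maxs=np.array([1.0, 2.0]))


class TestSiameseTraining:
    def test_identity_recovered_on_clean_data(self, identity_model):
        """Clean pairs train to a near-identity map (<= 0.05 mm)."""
        model, pairs = identity_model
        assert model.history["best_val_rmse"] <= 0.05
        pts = np.stack([p.m1.position for p in pairs[:50]])
        q = np.array([p.m1.quality for p in pairs[:50]])
        comp = model.predict(pts, q)
        assert np.max(np.linalg.norm(comp - pts, axis=1)) <= 0.05

    def test_loss_descends_in_first_epoch(self, suite):
        pairs = suite.pairs["c-arm 7 cm"]
        cfg = ec.SiameseConfig(max_epochs=3, patience=3, seed=2)
        model = ec.train_siamese(pairs[:600], pairs[600:700], cfg)
        # loss at initialization: untrained residual net is near-identity,
        # so the initial loss is close to the raw mean squared error
        p1, p2, q1, q2, y = _pair_arrays(pairs[:600], cfg)
        init_net = ec.models.MLP(
            [cfg.input_dims] + [cfg.units_per_layer] * cfg.n_hidden_layers
            + [cfg.output_dims],
            alpha=cfg.alpha, seed=cfg.seed,
        )
        c1 = p1 + init_net.forward(model.normalization.normalize(np.column_stack([p1, q1])))
        c2 = p2 + init_net.forward(model.normalization.normalize(np.column_stack([p2, q2])))
        init_loss = displacement_loss(c1, c2, y)
        assert model.history["train_loss"][0] < init_loss

    def test_weight_sharing_deterministic_branches(self, identity_model):
        model, pairs = identity_model
        x = np.array([[1.0, 2.0, 3.0]])
        q = np.array([0.5])
        assert np.array_equal(model.predict(x, q), model.predict(x, q))

    def test_serialization_round_trip_bit_identical(self, identity_model, tmp_path):
        model, pairs = identity_model
        path = tmp_path / "model.json"
        model.save(path)
        loaded = ec.CompensationModel.load(path)
        pts = np.stack([p.m1.position for p in pairs[:20]])
        q = np.array([p.m1.quality for p in pairs[:20]])
        assert np.array_equal(model.predict(pts, q), loaded.predict(pts, q))

    def test_missing_quality_rejected(self, identity_model):
        model, _ = identity_model
        with pytest.raises(ec.StateError):
            model.predict(np.zeros((1, 3)), None)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ec.DataError):
            ec.train_siamese([], [], ec.SiameseConfig())


class TestLossOracle:
    def test_displacement_loss_matches_brute_force(self, identity_model):
        """Vectorised loss equals a per-pair recomputation (<=1e-6 relative)."""
        model, pairs = identity_model
        batch = pairs[:64]
        cfg = model.config
        p1, p2, q1, q2, y = _pair_arrays(batch, cfg)
        c1 = model.predict(p1, q1)
        c2 = model.predict(p2, q2)
        fast = displacement_loss(c1, c2, y)
        slow = 0.0
        for a, b, yy in zip(c1, c2, y):
            r = np.sqrt(sum((b[i] - a[i]) ** 2 for i in range(3))) - yy
            slow += r * r
        slow /= len(batch)
        assert fast == pytest.approx(slow, rel=1e-6)


class TestPolynomial:
    def test_degree_one_exactly_inverts_affine_distortion(self, phantom):
        """Closed-form oracle: an affine warp is invertible by degree 1."""
        A = np.array([[1.05, 0.02, 0.0], [0.0, 0.97, 0.01], [0.01, 0.0, 1.02]])
        t = np.array([2.0, -1.0, 0.5])
        ms = []
        for rot in (0.0,):
            for e in range(3):
                for i in range(phantom.n_points):
                    p = phantom.position(i, e)
                    ms.append(ec.Measurement("aff", i, e, rot, A @ p + t, 1.0))
        pairs = ec.pair_dataset(ms, phantom)
        model = ec.fit_polynomial(pairs, degree=1)
        comp = ec.compensate_pairs(model, pairs)
        rmse, _ = ec.dataset_rmse(comp, "compensated")
        assert rmse < 1e-6

    def test_degree_zero_rejected(self, suite):
        with pytest.raises(ec.ConfigurationError):
            ec.fit_polynomial(suite.pairs["c-arm 7 cm"], degree=0)

    def test_underdetermined_rejected(self, suite):
        with pytest.raises(ec.ConfigurationError):
            ec.fit_polynomial(suite.pairs["c-arm 7 cm"][:10], degree=3)


class TestErrorReduction:
    @pytest.mark.parametrize(
        "before,after,expected", [(1.0, 0.3, 70.0), (1.0, 1.0, 0.0), (1.0, 1.2, -20.0)]
    )
    def test_examples(self, before, after, expected):
        assert ec.error_reduction(before, after) == pytest.approx(expected)

    def test_zero_before_rejected(self):
        with pytest.raises(ec.DataError):
            ec.error_reduction(0.0, 0.5)
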