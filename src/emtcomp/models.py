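"""Error-compensation models trained on relative displacements.

The central object is the weight-shared ("siamese") network: during training
two copies of one compensation function f(x, q; w) process the two ends of a
displacement pair, and the loss penalises the squared mismatch between the
compensated distance and the calibrated ground-truth distance y:

    L = mean_i ( ||f(x2_i, q2_i) - f(x1_i, q1_i)||_2 - y_i )^2

Training therefore never needs absolute ground-truth positions in the
tracker frame — only inter-seat distances, which the phantom provides. At
inference a single branch maps an absolute measured point to a compensated
point.

f is parameterised as a residual map f(x, q) = x + d(x, q): the displacement
loss constrains f only up to a rigid motion, and the residual head pins that
gauge to the identity so absolute compensated points remain meaningful. The
head's output is in mm; inputs are min-max normalised to [0, 1].
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
from scipy import optimize

from .nn import MLP, Adam
from .phantom import ConfigurationError, DataError, DisplacementPair, Measurement

log = logging.getLogger(__name__)


class TrainingError(RuntimeError):
    """Training diverged or produced a non-finite loss."""


class StateError(RuntimeError):
    """Operation requires a trained / differently-configured model."""


@dataclass(frozen=True)
class SiameseConfig:
    """Hyperparameters of the weight-shared compensation network.

    Defaults follow the grid-searched full-volume setup: three hidden layers
    of 32 units, leaky ReLU (alpha=0.01), batch size 512, Adam at lr 0.01,
    inputs (x, y, z, Q). The planar variant uses two hidden layers of 64
    units on (x, y, Q) with two outputs.
    """

    n_hidden_layers: int = 3
    units_per_layer: int = 32
    alpha: float = 0.01
    batch_size: int = 512
    learning_rate: float = 0.01
    spatial_dims: int = 3                # 3 for full volume, 2 for planar
    use_quality: bool = True
    dropout_rate: float = 0.0            # 0.10 for the uncertainty variant
    max_epochs: int = 800
    patience: int = 200
    restore_best: bool = True            # model selection at best validation RMSE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ConfigurationError("dropout rate must lie in [0, 1)")
        if self.n_hidden_layers < 1 or self.units_per_layer < 1:
            raise ConfigurationError("layers and units must be positive")
        if self.spatial_dims not in (2, 3):
            raise ConfigurationError("spatial_dims must be 2 or 3")

    @property
    def input_dims(self) -> int:
        return self.spatial_dims + (1 if self.use_quality else 0)

    @property
    def output_dims(self) -> int:
        return self.spatial_dims


def planar_config(**overrides) -> SiameseConfig:
    """The 2-layer / 64-unit planar (x, y) variant used for uncertainty maps."""
    base = dict(n_hidden_layers=2, units_per_layer=64, spatial_dims=2)
    base.update(overrides)
    return SiameseConfig(**base)


@dataclass(frozen=True)
class NormalizationSpec:
    """Per-input min-max ranges fitted on the training set."""

    mins: np.ndarray
    maxs: np.ndarray

    def __post_init__(self) -> None:
        mins = np.asarray(self.mins, dtype=float)
        maxs = np.asarray(self.maxs, dtype=float)
        if np.any(maxs <= mins):
            raise ConfigurationError("degenerate normalization range (max <= min)")
        object.__setattr__(self, "mins", mins)
        object.__setattr__(self, "maxs", maxs)
        object.__setattr__(self, "_warned", False)

    @classmethod
    def fit(cls, x: np.ndarray) -> "NormalizationSpec":
        x = np.asarray(x, dtype=float)
        return cls(mins=x.min(axis=0), maxs=x.max(axis=0))

    def normalize(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = (x - self.mins) / (self.maxs - self.mins)
        if not self._warned and (np.any(out < -1e-9) or np.any(out > 1 + 1e-9)):
            log.warning("inputs outside the fitted normalization range")
            object.__setattr__(self, "_warned", True)
        return out

    def denormalize(self, u: np.ndarray) -> np.ndarray:
        return np.asarray(u, dtype=float) * (self.maxs - self.mins) + self.mins


@dataclass
class CompensationModel:
    """A trained compensation map, ANN or polynomial, plus its preprocessing."""

    kind: Literal["ann", "polynomial"]
    normalization: NormalizationSpec
    config: SiameseConfig
    net: MLP | None = None
    coefficients: np.ndarray | None = None   # (n_monomials, spatial_dims)
    degree: int | None = None
    history: dict = field(default_factory=dict)

    # -- inference ---------------------------------------------------------
    def _inputs(self, points: np.ndarray, qualities: np.ndarray | None) -> np.ndarray:
        pts = np.atleast_2d(np.asarray(points, dtype=float))[:, : self.config.spatial_dims]
        if self.config.use_quality:
            if qualities is None:
                raise StateError("model expects a quality input")
            q = np.atleast_1d(np.asarray(qualities, dtype=float))
            feats = np.column_stack([pts, q])
        else:
            feats = pts
        return self.normalization.normalize(feats)

    def predict(
        self,
        points: np.ndarray,
        qualities: np.ndarray | None = None,
        dropout_rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        """Compensated positions for measured points (deterministic without rng)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        x = self._inputs(pts, qualities)
        if self.kind == "ann":
            if self.net is None:
                raise StateError("model is not trained")
            delta = self.net.forward(x, dropout_rng=dropout_rng)
        else:
            if self.coefficients is None:
                raise StateError("model is not trained")
            delta = _monomials(x, self.degree) @ self.coefficients
        return pts[:, : self.config.spatial_dims] + delta

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "kind": self.kind,
            "config": asdict(self.config),
            "normalization": {
                "mins": self.normalization.mins.tolist(),
                "maxs": self.normalization.maxs.tolist(),
            },
            "history": self.history,
        }
        if self.kind == "ann":
            d["net"] = {
                "layer_sizes": list(self.net.layer_sizes),
                "alpha": self.net.alpha,
                "dropout_rate": self.net.dropout_rate,
                "weights": [w.tolist() for w in self.net.weights],
                "biases": [b.tolist() for b in self.net.biases],
            }
        else:
            d["coefficients"] = self.coefficients.tolist()
            d["degree"] = self.degree
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CompensationModel":
        config = SiameseConfig(**d["config"])
        norm = NormalizationSpec(
            mins=np.array(d["normalization"]["mins"]),
            maxs=np.array(d["normalization"]["maxs"]),
        )
        if d["kind"] == "ann":
            nd = d["net"]
            net = MLP(
                layer_sizes=nd["layer_sizes"],
                alpha=nd["alpha"],
                dropout_rate=nd["dropout_rate"],
                weights=[np.array(w) for w in nd["weights"]],
                biases=[np.array(b) for b in nd["biases"]],
            )
            return cls("ann", norm, config, net=net, history=d.get("history", {}))
        return cls(
            "polynomial",
            norm,
            config,
            coefficients=np.array(d["coefficients"]),
            degree=d["degree"],
            history=d.get("history", {}),
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "CompensationModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# pair -> array plumbing


def _pair_arrays(
    pairs: Sequence[DisplacementPair], config: SiameseConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Positions (mm), qualities and ground truths stacked from pairs."""
    sd = config.spatial_dims
    p1 = np.stack([p.m1.position[:sd] for p in pairs])
    p2 = np.stack([p.m2.position[:sd] for p in pairs])
    q1 = np.array([p.m1.quality for p in pairs])
    q2 = np.array([p.m2.quality for p in pairs])
    y = np.array([p.ground_truth for p in pairs])
    return p1, p2, q1, q2, y


def displacement_loss(c1: np.ndarray, c2: np.ndarray, y: np.ndarray) -> float:
    """Mean squared displacement residual over compensated pairs."""
    r = np.linalg.norm(c2 - c1, axis=1) - y
    return float(np.mean(r**2))


def _displacement_rmse(c1: np.ndarray, c2: np.ndarray, y: np.ndarray) -> float:
    r = np.linalg.norm(c2 - c1, axis=1) - y
    return float(np.sqrt(np.mean(r**2)))


def train_siamese(
    pairs: Sequence[DisplacementPair],
    val_pairs: Sequence[DisplacementPair],
    config: SiameseConfig = SiameseConfig(),
) -> CompensationModel:
    """Train the weight-shared compensation network on displacement pairs.

    Minimises the mean squared displacement residual with Adam; model
    selection restores the weights with the best validation displacement
    RMSE (early stopping on ``config.patience`` stalled epochs).
    """
    if not pairs:
        raise DataError("no training pairs")
    if not val_pairs:
        raise DataError("no validation pairs")
    p1, p2, q1, q2, y = _pair_arrays(pairs, config)
    vp1, vp2, vq1, vq2, vy = _pair_arrays(val_pairs, config)

    feats = np.concatenate(
        [
            np.column_stack([p1, q1]) if config.use_quality else p1,
            np.column_stack([p2, q2]) if config.use_quality else p2,
        ]
    )
    norm = NormalizationSpec.fit(feats)

    sizes = (
        [config.input_dims]
        + [config.units_per_layer] * config.n_hidden_layers
        + [config.output_dims]
    )
    net = MLP(sizes, alpha=config.alpha, dropout_rate=config.dropout_rate,
              seed=config.seed)
    model = CompensationModel("ann", norm, config, net=net)
    opt = Adam(net, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    drop_rng = np.random.default_rng(config.seed + 2) if config.dropout_rate > 0 else None

    x1 = model._inputs(p1, q1)
    x2 = model._inputs(p2, q2)
    n = len(pairs)

    def val_rmse() -> float:
        c1 = model.predict(vp1, vq1)
        c2 = model.predict(vp2, vq2)
        return _displacement_rmse(c1, c2, vy)

    best = (val_rmse(), net.copy_parameters(), 0)
    train_curve, val_curve = [], []
    for epoch in range(1, config.max_epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            b1, b2 = x1[idx], x2[idx]
            out1, cache1 = net.forward(b1, dropout_rng=drop_rng, keep_cache=True)
            out2, cache2 = net.forward(b2, dropout_rng=drop_rng, keep_cache=True)
            c1 = p1[idx] + out1
            c2 = p2[idx] + out2
            diff = c2 - c1
            dist = np.linalg.norm(diff, axis=1)
            r = dist - y[idx]
            loss = float(np.mean(r**2))
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            epoch_loss += loss * len(idx)
            # dL/dc2 = 2 r / m * unit(diff); dL/dc1 = -dL/dc2
            unit = diff / np.maximum(dist, 1e-12)[:, None]
            g = (2.0 * r / len(idx))[:, None] * unit
            grads2 = net.backward(g, cache2)
            grads1 = net.backward(-g, cache1)
            grads = [(gw1 + gw2, gb1 + gb2)
                     for (gw1, gb1), (gw2, gb2) in zip(grads1, grads2)]
            opt.step(grads)
        train_curve.append(epoch_loss / n)
        v = val_rmse()
        val_curve.append(v)
        if v < best[0] - 1e-12:
            best = (v, net.copy_parameters(), epoch)
        elif config.restore_best and epoch - best[2] >= config.patience:
            break
    if config.restore_best:
        net.set_parameters(best[1])
    model.history = {
        "train_loss": train_curve,
        "val_rmse": val_curve,
        "best_val_rmse": best[0],
        "best_epoch": best[2],
        "epochs_run": len(train_curve),
    }
    return model


def compensate(
    model: CompensationModel,
    point: np.ndarray,
    quality: float | np.ndarray | None = None,
) -> np.ndarray:
    """Deterministic compensated position(s) for measured point(s)."""
    pts = np.asarray(point, dtype=float)
    single = pts.ndim == 1
    out = model.predict(pts, None if quality is None else np.asarray(quality))
    return out[0] if single else out


def compensate_pairs(
    model: CompensationModel, pairs: Sequence[DisplacementPair]
) -> list[DisplacementPair]:
    """Pairs with ``compensated`` positions filled in on copies of the data.

    For planar models the untouched axes are carried through unchanged.
    """
    sd = model.config.spatial_dims
    out = []
    for p in pairs:
        new = DisplacementPair(
            m1=replace_measurement(p.m1), m2=replace_measurement(p.m2),
            ground_truth=p.ground_truth,
        )
        for m in (new.m1, new.m2):
            comp = model.predict(m.position[None, :], np.array([m.quality]))[0]
            full = m.position.copy()
            full[:sd] = comp
            m.compensated = full
        out.append(new)
    return out


def replace_measurement(m: Measurement) -> Measurement:
    return Measurement(
        scenario_id=m.scenario_id,
        grid_index=m.grid_index,
        elevation_level=m.elevation_level,
        rotation=m.rotation,
        position=m.position.copy(),
        quality=m.quality,
    )


# ---------------------------------------------------------------------------
# polynomial baseline


def _monomial_exponents(dims: int, degree: int) -> list[tuple[int, ...]]:
    exps = []
    def rec(prefix, remaining, dims_left):
        if dims_left == 0:
            exps.append(tuple(prefix))
            return
        for e in range(remaining + 1):
            rec(prefix + [e], remaining - e, dims_left - 1)
    rec([], degree, dims)
    return sorted(exps)


def _monomials(x: np.ndarray, degree: int) -> np.ndarray:
    x = np.atleast_2d(x)
    cols = []
    for exp in _monomial_exponents(x.shape[1], degree):
        col = np.ones(len(x))
        for d, e in enumerate(exp):
            if e:
                col = col * x[:, d] ** e
        cols.append(col)
    return np.column_stack(cols)


def fit_polynomial(
    pairs: Sequence[DisplacementPair],
    degree: int = 2,
    spatial_dims: int = 3,
) -> CompensationModel:
    """Mixed-term polynomial compensator fitted on the displacement residual.

    Per-axis polynomials in the normalised coordinates (total degree up to
    ``degree``; the quality indicator is not an input) minimise the same
    residual (||g(x2) - g(x1)|| - y)^2 by nonlinear least squares, starting
    from the identity map (all correction coefficients zero).
    """
    if degree < 1:
        raise ConfigurationError("polynomial degree must be >= 1")
    if not pairs:
        raise DataError("no training pairs")
    config = SiameseConfig(spatial_dims=spatial_dims, use_quality=False)
    p1, p2, _, _, y = _pair_arrays(pairs, config)
    norm = NormalizationSpec.fit(np.concatenate([p1, p2]))
    x1 = norm.normalize(p1)
    x2 = norm.normalize(p2)
    m1 = _monomials(x1, degree)
    m2 = _monomials(x2, degree)
    n_mono = m1.shape[1]
    n_params = n_mono * spatial_dims
    if n_params > len(pairs):
        raise ConfigurationError(
            f"{n_params} coefficients but only {len(pairs)} pairs"
        )

    def residuals(theta: np.ndarray) -> np.ndarray:
        coef = theta.reshape(n_mono, spatial_dims)
        c1 = p1 + m1 @ coef
        c2 = p2 + m2 @ coef
        return np.linalg.norm(c2 - c1, axis=1) - y

    sol = optimize.least_squares(residuals, np.zeros(n_params), method="trf")
    model = CompensationModel(
        "polynomial",
        norm,
        config,
        coefficients=sol.x.reshape(n_mono, spatial_dims),
        degree=degree,
        history={"cost": float(sol.cost), "nfev": int(sol.nfev)},
    )
    return model


def error_reduction(rmse_before: float, rmse_after: float) -> float:
    """Percentage of displacement RMSE removed by compensation."""
    if rmse_before <= 0:
        raise DataError("rmse_before must be positive")
    return 100.0 * (1.0 - rmse_after / rmse_before)
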