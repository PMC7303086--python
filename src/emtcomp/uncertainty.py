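"""Monte-Carlo-dropout spatial uncertainty and absolute-error estimation.

A compensation network trained with dropout can be sampled at inference by
keeping the dropout masks active (Monte Carlo dropout): the spread of the
sampled compensated positions approximates the model's epistemic
uncertainty at that location. For the planar model the combined spread is
sigma = sqrt(sigma_x^2 + sigma_y^2). The sampled distribution is not
Gaussian, so sigma is used ordinally (maps, thresholds, accumulation), never
to build confidence intervals.

Absolute positional error has no direct ground truth in the tracker frame;
it is estimated from pairwise distances to lattice neighbours in a Moore
neighbourhood (Chebyshev radius r), averaging the absolute distance error.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .models import CompensationModel, StateError
from .phantom import DataError


@dataclass(frozen=True)
class UncertaintyEstimate:
    """MC-dropout summary at one point."""

    mean_position: np.ndarray
    sigma_per_axis: np.ndarray
    sigma_combined: float
    n_samples: int
    dropout_rate: float


@dataclass
class UncertaintyMap:
    """Per-point uncertainty, training-point distance and error estimate."""

    points: np.ndarray                    # (m, d) evaluation positions, mm
    sigma: np.ndarray                     # (m,) combined MC-dropout sigma, mm
    sigma_per_axis: np.ndarray            # (m, d)
    mean_positions: np.ndarray            # (m, d) MC mean compensated positions
    nearest_train: np.ndarray             # (m,) distance to nearest training point
    nbhd_error: np.ndarray | None = None  # (m,) Moore-neighbourhood error, mm


def combine_sigma(sigma_per_axis: np.ndarray) -> float:
    """Root-sum-square of per-axis standard deviations."""
    s = np.asarray(sigma_per_axis, dtype=float)
    if np.any(s < 0):
        raise DataError("sigmas must be non-negative")
    return float(np.sqrt(np.sum(s**2)))


def mc_dropout_samples(
    model: CompensationModel,
    points: np.ndarray,
    qualities: np.ndarray | None,
    n: int = 3000,
    seed: int = 0,
    chunk: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-point MC mean and per-axis sigma over n stochastic passes.

    Returns ``(means (m, d), sigmas (m, d))``. Dropout masks are independent
    across points and samples; results are reproducible for a fixed seed.
    """
    if model.kind != "ann" or model.net is None:
        raise StateError("MC dropout requires a trained ANN")
    if model.net.dropout_rate <= 0.0:
        raise StateError("model was trained without dropout; nothing to sample")
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    m = len(pts)
    d = model.config.spatial_dims
    rng = np.random.default_rng(seed)
    # accumulate running moments to keep memory flat
    s1 = np.zeros((m, d))
    s2 = np.zeros((m, d))
    done = 0
    while done < n:
        k = min(chunk, n - done)
        tiled = np.repeat(pts, k, axis=0)
        q = None if qualities is None else np.repeat(np.atleast_1d(qualities), k)
        out = model.predict(tiled, q, dropout_rng=rng).reshape(m, k, d)
        s1 += out.sum(axis=1)
        s2 += (out**2).sum(axis=1)
        done += k
    mean = s1 / n
    var = np.maximum(s2 / n - mean**2, 0.0)
    return mean, np.sqrt(var)


def mc_dropout_estimate(
    model: CompensationModel,
    point: np.ndarray,
    quality: float | None = None,
    n: int = 3000,
    seed: int = 0,
) -> UncertaintyEstimate:
    """MC-dropout uncertainty at a single measured point."""
    q = None if quality is None else np.array([quality])
    mean, sig = mc_dropout_samples(model, np.asarray(point)[None, :], q, n, seed)
    return UncertaintyEstimate(
        mean_position=mean[0],
        sigma_per_axis=sig[0],
        sigma_combined=combine_sigma(sig[0]),
        n_samples=n,
        dropout_rate=model.net.dropout_rate,
    )


def nearest_training_distances(
    points: np.ndarray, training_points: np.ndarray
) -> np.ndarray:
    """Distance from each point to its nearest training point (exhaustive)."""
    p = np.atleast_2d(np.asarray(points, dtype=float))
    t = np.atleast_2d(np.asarray(training_points, dtype=float))
    d2 = ((p[:, None, :] - t[None, :, :]) ** 2).sum(axis=-1)
    return np.sqrt(d2.min(axis=1))


def build_uncertainty_map(
    model: CompensationModel,
    grid_points: np.ndarray,
    qualities: np.ndarray | None,
    training_points: np.ndarray,
    n: int = 3000,
    seed: int = 0,
) -> UncertaintyMap:
    """Evaluate MC-dropout sigma and training-point distance over a grid."""
    pts = np.atleast_2d(np.asarray(grid_points, dtype=float))
    if len(pts) == 0:
        raise DataError("empty evaluation grid")
    mean, sig = mc_dropout_samples(model, pts, qualities, n=n, seed=seed)
    sigma = np.sqrt(np.sum(sig**2, axis=1))
    nearest = nearest_training_distances(
        pts[:, : model.config.spatial_dims],
        np.atleast_2d(training_points)[:, : model.config.spatial_dims],
    )
    return UncertaintyMap(
        points=pts,
        sigma=sigma,
        sigma_per_axis=sig,
        mean_positions=mean,
        nearest_train=nearest,
    )


def moore_neighborhood_error(
    lattice_indices: np.ndarray,
    compensated: np.ndarray,
    ground_truth: np.ndarray,
    r: int = 3,
) -> np.ndarray:
    """Per-point absolute-error estimate from Moore-neighbourhood distances.

    For each lattice point, the mean absolute difference between compensated
    and ground-truth distances to every neighbour within Chebyshev radius r
    (itself excluded). Boundary points use the neighbours that exist; a point
    with no neighbour yields NaN.
    """
    idx = np.asarray(lattice_indices, dtype=int)
    comp = np.asarray(compensated, dtype=float)
    gt = np.asarray(ground_truth, dtype=float)
    if not (len(idx) == len(comp) == len(gt)):
        raise DataError("misaligned lattice/compensated/ground-truth arrays")
    lookup = {tuple(ij): k for k, ij in enumerate(idx)}
    out = np.full(len(idx), np.nan)
    for k, (i, j) in enumerate(idx):
        errs = []
        for di in range(-r, r + 1):
            for dj in range(-r, r + 1):
                if di == 0 and dj == 0:
                    continue
                nb = lookup.get((i + di, j + dj))
                if nb is None:
                    continue
                d_comp = np.linalg.norm(comp[k] - comp[nb])
                d_true = np.linalg.norm(gt[k] - gt[nb])
                errs.append(abs(d_comp - d_true))
        if errs:
            out[k] = float(np.mean(errs))
    return out


def uncertainty_error_regression(
    sigma: np.ndarray, error: np.ndarray
) -> tuple[float, float, float]:
    """OLS line of estimated error on sigma: (slope, intercept, Pearson r)."""
    s = np.asarray(sigma, dtype=float)
    e = np.asarray(error, dtype=float)
    keep = np.isfinite(s) & np.isfinite(e)
    s, e = s[keep], e[keep]
    if len(s) < 3:
        raise DataError("need at least three points for a regression")
    if np.std(s) == 0:
        raise DataError("degenerate fit: sigma has zero variance")
    res = stats.linregress(s, e)
    return float(res.slope), float(res.intercept), float(res.rvalue)
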