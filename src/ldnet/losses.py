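"""Discrepancy metrics, regularization, loss assembly, evaluation metrics.

The training loss is the nested average over samples, observation times and
points of a per-observation discrepancy (quadratic by default, optionally
goal-oriented with a flow-direction term), plus L2 penalties on the mean
squared weights of each network.  Samples contribute equally regardless of
their observation counts (the outer average is over samples).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .data import Dataset, resample_input
from .integrator import integrate_latent, interp_latent
from .model import LDNet
from .nets import FCNN

__all__ = [
    "LossConfig",
    "discrepancy_quadratic",
    "discrepancy_goal_oriented",
    "l2_regularization",
    "total_loss",
    "nrmse",
    "pearson_dissimilarity",
    "default_y_norm",
]


@dataclass
class LossConfig:
    metric: str = "quadratic"  # "quadratic" | "goal_oriented"
    y_norm: np.ndarray | float = 1.0  # per-channel normalization factor
    alpha_dyn: float = 0.0
    alpha_rec: float = 0.0
    gamma: float = 1.0  # goal-oriented direction-term weight
    eps: float = 1e-3  # goal-oriented small regularizer
    v_norm: float = 1.0  # goal-oriented reference magnitude
    point_subsample: int | None = None  # points drawn per time step per epoch

    def __post_init__(self) -> None:
        if self.metric not in ("quadratic", "goal_oriented"):
            raise ValueError(f"unknown metric '{self.metric}'")
        if np.any(np.asarray(self.y_norm) <= 0):
            raise ValueError("y_norm must be positive")
        if self.alpha_dyn < 0 or self.alpha_rec < 0:
            raise ValueError("regularization weights must be nonnegative")
        if self.metric == "goal_oriented" and self.eps <= 0:
            raise ValueError("goal-oriented metric needs eps > 0")


def default_y_norm(dataset: Dataset) -> np.ndarray:
    """Per-channel half-range of the training observations (max - min)/2."""
    d_y = dataset.d_y
    lo = np.full(d_y, np.inf)
    hi = np.full(d_y, -np.inf)
    for s in dataset.samples:
        for v in s.observations.values:
            lo = np.minimum(lo, v.min(axis=0))
            hi = np.maximum(hi, v.max(axis=0))
    half = 0.5 * (hi - lo)
    if np.any(half <= 0):
        raise ValueError("constant output channel; supply y_norm explicitly")
    return half


def discrepancy_quadratic(y_hat, y, y_norm=1.0):
    """||y_hat - y||^2 / y_norm^2 summed over channels (per row)."""
    r = (np.asarray(y_hat, dtype=float) - np.asarray(y, dtype=float)) / np.asarray(y_norm, dtype=float)
    return np.sum(np.atleast_2d(r) ** 2, axis=-1) if r.ndim > 1 else float(np.sum(r**2))


def discrepancy_goal_oriented(v_hat, v, gamma, eps, v_norm):
    """Magnitude error plus a direction-mismatch term for vector fields."""
    v = np.atleast_2d(np.asarray(v, dtype=float))
    v_hat = np.atleast_2d(np.asarray(v_hat, dtype=float))
    mag = np.sum((v - v_hat) ** 2, axis=1) / v_norm**2
    nv = np.linalg.norm(v, axis=1, keepdims=True)
    nh = np.linalg.norm(v_hat, axis=1, keepdims=True)
    dirterm = np.sum((v / (eps + nv) - v_hat / (eps + nh)) ** 2, axis=1)
    out = mag + gamma * dirterm
    return float(out[0]) if out.size == 1 and np.asarray(v).ndim == 1 else out


def l2_regularization(net: FCNN) -> float:
    """Mean of the squared trainable parameters of the network."""
    theta = net.get_params_vector()
    return float(np.mean(theta**2))


def _sample_discrepancy(model: LDNet, sample, cfg: LossConfig, T: float, rng=None) -> float:
    obs = sample.observations
    if obs.obs_times.size == 0:
        return np.nan
    traj = integrate_latent(model, sample.signal, T)
    per_time = []
    for k, tau in enumerate(obs.obs_times):
        pts, vals = obs.points[k], obs.values[k]
        if cfg.point_subsample is not None and rng is not None and pts.shape[0] > cfg.point_subsample:
            idx = rng.choice(pts.shape[0], size=cfg.point_subsample, replace=False)
            pts, vals = pts[idx], vals[idx]
        s = interp_latent(traj, min(tau, traj.horizon))
        u = resample_input(sample.signal, min(tau, sample.signal.times[-1]))
        y_hat = model.reconstruct(np.tile(s, (pts.shape[0], 1)), np.tile(u, (pts.shape[0], 1)), pts)
        if cfg.metric == "quadratic":
            e = discrepancy_quadratic(y_hat, vals, cfg.y_norm)
        else:
            e = discrepancy_goal_oriented(y_hat, vals, cfg.gamma, cfg.eps, cfg.v_norm)
        per_time.append(float(np.mean(e)))
    return float(np.mean(per_time))


def total_loss(model: LDNet, dataset: Dataset, cfg: LossConfig, epoch_seed: int | None = None) -> float:
    """Nested-average data discrepancy plus L2 regularization terms.

    This reference implementation goes through the public prediction path
    sample by sample; the training engine computes the same quantity (and
    its gradient) in a vectorized way.
    """
    rng = np.random.default_rng(epoch_seed) if epoch_seed is not None else None
    per_sample = []
    for sample in dataset.samples:
        v = _sample_discrepancy(model, sample, cfg, dataset.horizon, rng)
        if np.isnan(v):
            import warnings

            warnings.warn(f"sample {sample.id} has no observations; excluded", stacklevel=2)
            continue
        per_sample.append(v)
    data_term = float(np.mean(per_sample)) if per_sample else 0.0
    return data_term + cfg.alpha_dyn * l2_regularization(model.dyn) + cfg.alpha_rec * l2_regularization(model.rec)


def nrmse(predictions, observations, y_norm=1.0) -> float:
    """Root-mean-square of normalized residuals over all entries."""
    p = np.asarray(predictions, dtype=float)
    o = np.asarray(observations, dtype=float)
    if p.shape != o.shape:
        raise ValueError("shape mismatch")
    r = (p - o) / np.asarray(y_norm, dtype=float)
    return float(np.sqrt(np.mean(r**2)))


def pearson_dissimilarity(predictions, observations) -> float:
    """1 - Pearson correlation of the flattened prediction/observation pairs."""
    p = np.asarray(predictions, dtype=float).ravel()
    o = np.asarray(observations, dtype=float).ravel()
    if p.size != o.size or p.size < 2:
        raise ValueError("need at least two paired values")
    if np.std(p) == 0 or np.std(o) == 0:
        raise ValueError("zero variance; Pearson correlation undefined")
    return float(1.0 - sps.pearsonr(p, o).statistic)
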