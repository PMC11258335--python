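"""Scikit-learn-style estimator wrapping LDNet construction and training.

:class:`LDNetRegressor` exposes the whole pipeline (normalization fitting,
Glorot initialization, Adam + BFGS training, meshless prediction) through
the familiar ``fit`` / ``predict`` / ``get_params`` / ``set_params``
surface, so it composes with scikit-learn model selection utilities.  The
``X`` it consumes is a :class:`~ldnet.data.Dataset` rather than a feature
matrix: samples are whole input-signal/field-observation pairs.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .data import Dataset, InputSignal, fit_normalization
from .integrator import predict_field
from .losses import LossConfig, default_y_norm
from .model import LDNet
from .nets import FCNN
from .training import TrainConfig, evaluate, train

__all__ = ["LDNetRegressor"]


class LDNetRegressor(BaseEstimator):
    """Latent dynamics network regressor for spatio-temporal fields.

    Parameters mirror the method's hyperparameters: latent dimension
    ``d_s``, hidden widths of the two networks, the latent Euler step
    ``dt``, the characteristic time scale ``dt_ref``, L2 regularization
    weights, and the two-stage optimizer budgets.
    """

    def __init__(
        self,
        d_s: int = 2,
        dyn_hidden=(10,),
        rec_hidden=(12, 12),
        rec_uses_u: bool = False,
        dt: float = 0.05,
        dt_ref: float = 1.0,
        alpha_dyn: float = 0.0,
        alpha_rec: float = 0.0,
        adam_epochs: int = 300,
        adam_lr: float = 1e-2,
        bfgs_max_iter: int = 500,
        bfgs_gtol: float = 1e-9,
        point_subsample: int | None = None,
        bfgs_point_subsample: int | None = None,
        u_eq=None,
        tail_beta=None,
        u_bounds=None,
        y_bounds=None,
        y_norm=None,
        seed: int = 0,
    ):
        self.d_s = d_s
        self.dyn_hidden = dyn_hidden
        self.rec_hidden = rec_hidden
        self.rec_uses_u = rec_uses_u
        self.dt = dt
        self.dt_ref = dt_ref
        self.alpha_dyn = alpha_dyn
        self.alpha_rec = alpha_rec
        self.adam_epochs = adam_epochs
        self.adam_lr = adam_lr
        self.bfgs_max_iter = bfgs_max_iter
        self.bfgs_gtol = bfgs_gtol
        self.point_subsample = point_subsample
        self.bfgs_point_subsample = bfgs_point_subsample
        self.u_eq = u_eq
        self.tail_beta = tail_beta
        self.u_bounds = u_bounds
        self.y_bounds = y_bounds
        self.y_norm = y_norm
        self.seed = seed

    def _build_model(self, dataset: Dataset) -> LDNet:
        if self.d_s < 1:
            raise ValueError("latent dimension d_s must be >= 1")
        stats = fit_normalization(
            dataset,
            u_bounds=self.u_bounds,
            y_bounds=self.y_bounds,
            dt_ref=self.dt_ref,
            beta=self.tail_beta,
        )
        dyn = FCNN([self.d_s + dataset.d_u, *self.dyn_hidden, self.d_s])
        rec_in = self.d_s + (dataset.d_u if self.rec_uses_u else 0) + dataset.dim
        rec = FCNN([rec_in, *self.rec_hidden, dataset.d_y])
        model = LDNet(
            dyn=dyn,
            rec=rec,
            d_s=self.d_s,
            stats=stats,
            dt=self.dt,
            rec_uses_u=self.rec_uses_u,
            u_eq=self.u_eq,
        )
        return model.init_weights(self.seed)

    def fit(self, X: Dataset, y=None) -> "LDNetRegressor":
        """Fit normalization and both networks on a training Dataset."""
        dataset = X
        if self.d_s < 1:
            raise ValueError("latent dimension d_s must be >= 1")
        self.y_norm_ = np.asarray(self.y_norm if self.y_norm is not None else default_y_norm(dataset), dtype=float)
        self.model_ = self._build_model(dataset)
        loss_cfg = LossConfig(
            y_norm=self.y_norm_,
            alpha_dyn=self.alpha_dyn,
            alpha_rec=self.alpha_rec,
            point_subsample=self.point_subsample,
        )
        cfg = TrainConfig(
            adam_epochs=self.adam_epochs,
            adam_lr=self.adam_lr,
            bfgs_max_iter=self.bfgs_max_iter,
            bfgs_gtol=self.bfgs_gtol,
            bfgs_point_subsample=self.bfgs_point_subsample,
            seed=self.seed,
            loss=loss_cfg,
        )
        self.model_, self.report_ = train(self.model_, dataset, cfg)
        self.horizon_ = dataset.horizon
        return self

    def predict(self, signal: InputSignal, points, times, T: float | None = None) -> np.ndarray:
        """Predict the output field at query (x, tau) pairs for one signal."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        T = self.horizon_ if T is None else T
        return predict_field(self.model_, signal, points, times, T)

    def evaluate(self, dataset: Dataset, horizon: float | None = None) -> dict:
        """NRMSE/Pearson-dissimilarity report on a dataset (no mutation)."""
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        return evaluate(self.model_, dataset, y_norm=self.y_norm_, horizon=horizon)

    def score(self, X: Dataset, y=None) -> float:
        """Negative aggregate NRMSE (greater is better)."""
        return -self.evaluate(X)["nrmse"]
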