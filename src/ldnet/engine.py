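"""Vectorized loss/gradient engine for LDNet training.

Gradients with respect to all trainable parameters are computed by
combining backpropagation-through-time for the unrolled forward-Euler
latent recursion with plain backpropagation for the reconstruction
network.  The forward pass batches the Euler recursion across samples and
the reconstruction across every observation row of the dataset; the
adjoint of the latent path is accumulated by scattering the
reconstruction-input gradients onto the two Euler nodes bracketing each
observation time and sweeping the recursion in reverse.

The data term computed here is identical (up to round-off) to the
reference implementation in :func:`ldnet.losses.total_loss`; a test pins
that equivalence and a finite-difference check pins the gradient.
"""

from __future__ import annotations

import numpy as np

from .data import Dataset, resample_input
from .losses import LossConfig
from .model import LDNet
from .nets import tail_compress, tail_compress_derivative

__all__ = ["TrainingProblem"]


class TrainingProblem:
    """Precomputed observation layout for fast loss/gradient evaluation."""

    def __init__(self, model: LDNet, dataset: Dataset, cfg: LossConfig):
        if cfg.metric != "quadratic":
            raise NotImplementedError(
                "the vectorized engine supports the quadratic discrepancy; "
                "goal-oriented training uses the reference loss path"
            )
        self.model = model
        self.cfg = cfg
        self.dt = model.dt
        self.T = dataset.horizon
        self.n_steps = int(round(self.T / self.dt))
        if self.n_steps < 1:
            raise ValueError("horizon shorter than one latent step")
        self.n_samples = len(dataset)
        self.d_s = model.d_s

        # inputs at Euler node times, normalized once
        node_times = self.dt * np.arange(self.n_steps)
        U = np.empty((self.n_steps, self.n_samples, model.d_u))
        for i, s in enumerate(dataset.samples):
            tq = np.minimum(node_times, s.signal.times[-1])
            U[:, i, :] = resample_input(s.signal, tq)
        self.U_nodes = model.stats.u.normalize(U)

        # flatten observations: one "pair" per (sample, observation time)
        pair_sample, pair_node, pair_frac, pair_w = [], [], [], []
        pair_u = []
        counts = []
        x_rows, y_rows = [], []
        n_eff = sum(1 for s in dataset.samples if s.observations.obs_times.size > 0)
        for i, s in enumerate(dataset.samples):
            obs = s.observations
            m_times = obs.obs_times.size
            if m_times == 0:
                import warnings

                warnings.warn(f"sample {s.id} has no observations; excluded", stacklevel=2)
                continue
            for k, tau in enumerate(obs.obs_times):
                if obs.points[k].shape[0] == 0:
                    continue
                pos = min(max(tau / self.dt, 0.0), self.n_steps)
                node = min(int(pos), self.n_steps - 1)
                pair_sample.append(i)
                pair_node.append(node)
                pair_frac.append(pos - node)
                pair_w.append(1.0 / (n_eff * m_times))
                pair_u.append(resample_input(s.signal, min(tau, s.signal.times[-1])))
                counts.append(obs.points[k].shape[0])
                x_rows.append(obs.points[k])
                y_rows.append(obs.values[k])
        self.pair_sample = np.asarray(pair_sample, dtype=int)
        self.pair_node = np.asarray(pair_node, dtype=int)
        self.pair_frac = np.asarray(pair_frac)
        self.pair_w = np.asarray(pair_w)
        self.pair_u_norm = model.stats.u.normalize(np.asarray(pair_u))
        self.counts = np.asarray(counts, dtype=int)
        self.n_pairs = self.counts.size
        self.X = np.concatenate(x_rows, axis=0)
        self.Y = np.concatenate(y_rows, axis=0)
        self.Xn = model.stats.x.normalize(self.X)
        self.row_ptr = np.concatenate([[0], np.cumsum(self.counts)])
        self.y_norm = np.broadcast_to(np.asarray(cfg.y_norm, dtype=float), (model.d_y,)).copy()
        if model.dirichlet is not None:
            self.lift_rows = model.dirichlet.lift(self.X)
            self.mask_rows = model.dirichlet.mask(self.X)[:, None]
        self.u_eq_feat = (
            np.concatenate([np.zeros(self.d_s), model.stats.u.normalize(model.u_eq)])
            if model.u_eq is not None
            else None
        )

    # -- parameter vector --------------------------------------------------
    @property
    def n_params(self) -> int:
        return self.model.dyn.n_params + self.model.rec.n_params

    def get_theta(self) -> np.ndarray:
        return np.concatenate([self.model.dyn.get_params_vector(), self.model.rec.get_params_vector()])

    def set_theta(self, theta: np.ndarray) -> None:
        nd = self.model.dyn.n_params
        self.model.dyn.set_params_vector(theta[:nd])
        self.model.rec.set_params_vector(theta[nd:])

    # -- subsampling -------------------------------------------------------
    def freeze_subsample(self, m: int, rng) -> None:
        """Fix one random point subset for all subsequent full-batch calls.

        Used by the deterministic second optimization stage: the loss stays
        a fixed function of the parameters while retaining the cost saving
        of spatial subsampling.
        """
        saved = self.cfg.point_subsample
        self.cfg.point_subsample = int(m)
        self._frozen = self._select_rows(rng)
        self.cfg.point_subsample = saved

    def thaw_subsample(self) -> None:
        self._frozen = None

    def _select_rows(self, rng):
        """Per-pair random point subset; returns (row_idx, sel_counts)."""
        if rng is None and getattr(self, "_frozen", None) is not None:
            return self._frozen
        m = self.cfg.point_subsample
        if m is None or rng is None:
            return np.arange(self.X.shape[0]), self.counts
        idx_parts = []
        sel_counts = np.empty(self.n_pairs, dtype=int)
        for p in range(self.n_pairs):
            lo, hi = self.row_ptr[p], self.row_ptr[p + 1]
            c = hi - lo
            if c <= m:
                idx_parts.append(np.arange(lo, hi))
                sel_counts[p] = c
            else:
                idx_parts.append(lo + rng.choice(c, size=m, replace=False))
                sel_counts[p] = m
        return np.concatenate(idx_parts), sel_counts

    # -- loss and gradient -------------------------------------------------
    def loss_and_grad(self, theta: np.ndarray, rng=None):
        """Total loss and its gradient with respect to the packed parameters."""
        model = self.model
        cfg = self.cfg
        self.set_theta(theta)
        dyn, rec = model.dyn, model.rec
        dt_over_ref = self.dt / model.stats.dt_ref

        # ---- forward Euler (batched over samples), keeping caches --------
        n, d_s = self.n_samples, self.d_s
        S = np.zeros((self.n_steps + 1, n, d_s))
        caches = []
        if self.u_eq_feat is not None:
            eq_out, eq_cache = dyn.forward_cache(self.u_eq_feat)
        else:
            eq_out = None
        for k in range(self.n_steps):
            feat = np.concatenate([S[k], self.U_nodes[k]], axis=1)
            out, cache = dyn.forward_cache(feat)
            caches.append(cache)
            if eq_out is not None:
                out = out - eq_out
            S[k + 1] = S[k] + dt_over_ref * out
            if not np.all(np.isfinite(S[k + 1])):
                raise FloatingPointError(f"latent state blew up at Euler step {k + 1}")

        # ---- reconstruction over (subsampled) observation rows ----------
        row_idx, sel_counts = self._select_rows(rng)
        sel_ptr = np.concatenate([[0], np.cumsum(sel_counts)])
        w_rows = np.repeat(self.pair_w / sel_counts, sel_counts)

        w_left = (1.0 - self.pair_frac)[:, None]
        w_right = self.pair_frac[:, None]
        s_pair = w_left * S[self.pair_node, self.pair_sample] + w_right * S[self.pair_node + 1, self.pair_sample]
        s_rows = np.repeat(s_pair, sel_counts, axis=0)
        parts = [s_rows]
        if model.rec_uses_u:
            parts.append(np.repeat(self.pair_u_norm, sel_counts, axis=0))
        parts.append(self.Xn[row_idx])
        feat_rows = np.concatenate(parts, axis=1)

        raw, rec_cache = rec.forward_cache(feat_rows)
        raw = np.atleast_2d(raw)
        if model.stats.beta is not None:
            y_net = tail_compress(raw, model.stats.beta)
        else:
            y_net = raw
        y_hat = model.stats.y.denormalize(y_net)
        if model.dirichlet is not None:
            y_hat = self.lift_rows[row_idx] + y_hat * self.mask_rows[row_idx]

        r = (y_hat - self.Y[row_idx]) / self.y_norm
        loss_data = float(np.sum(w_rows[:, None] * r**2))

        theta_dyn = dyn.get_params_vector()
        theta_rec = rec.get_params_vector()
        loss = (
            loss_data
            + cfg.alpha_dyn * float(np.mean(theta_dyn**2))
            + cfg.alpha_rec * float(np.mean(theta_rec**2))
        )
        if not np.isfinite(loss):
            raise FloatingPointError("non-finite training loss")

        # ---- backward: reconstruction ------------------------------------
        dY = 2.0 * w_rows[:, None] * r / self.y_norm
        if model.dirichlet is not None:
            dY = dY * self.mask_rows[row_idx]
        dY = dY * model.stats.y.width
        if model.stats.beta is not None:
            dY = dY * tail_compress_derivative(raw, model.stats.beta)
        dFeat, gW_rec, gb_rec = rec.backward(rec_cache, dY)

        # latent-state adjoint at observation pairs -> Euler-node adjoint
        ds_rows = dFeat[:, :d_s]
        ds_pair = np.add.reduceat(ds_rows, sel_ptr[:-1], axis=0)
        ds_pair[sel_counts == 0] = 0.0  # reduceat artifact guard
        Lam = np.zeros((self.n_steps + 1, n, d_s))
        np.add.at(Lam, (self.pair_node, self.pair_sample), w_left * ds_pair)
        np.add.at(Lam, (self.pair_node + 1, self.pair_sample), w_right * ds_pair)

        # ---- backward through time (reverse Euler sweep) -----------------
        gW_dyn = [np.zeros_like(W) for W in dyn.weights]
        gb_dyn = [np.zeros_like(b) for b in dyn.biases]
        lam = Lam[self.n_steps].copy()
        eq_upstream = np.zeros(d_s)
        for k in range(self.n_steps - 1, -1, -1):
            upstream = dt_over_ref * lam
            dF, gW, gb = dyn.backward(caches[k], upstream)
            for l in range(len(gW_dyn)):
                gW_dyn[l] += gW[l]
                gb_dyn[l] += gb[l]
            if eq_out is not None:
                eq_upstream += upstream.sum(axis=0)
            lam = lam + dF[:, :d_s] + Lam[k]
        if eq_out is not None:
            _, gW, gb = dyn.backward(eq_cache, -eq_upstream)
            for l in range(len(gW_dyn)):
                gW_dyn[l] += gW[l]
                gb_dyn[l] += gb[l]

        g_dyn = np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(gW_dyn, gb_dyn)])
        g_rec = np.concatenate([np.concatenate([W.ravel(), b]) for W, b in zip(gW_rec, gb_rec)])
        g_dyn += cfg.alpha_dyn * 2.0 * theta_dyn / theta_dyn.size
        g_rec += cfg.alpha_rec * 2.0 * theta_rec / theta_rec.size
        return loss, np.concatenate([g_dyn, g_rec])
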