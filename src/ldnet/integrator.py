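"""Forward-Euler latent integration and meshless field prediction.

The latent ODE is advanced with a uniform explicit Euler step from the
exact initial condition s(0) = 0; latent states at arbitrary observation
times are recovered by piecewise-linear interpolation between Euler nodes,
consistent with the scheme's first-order accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import InputSignal, resample_input
from .model import LDNet

__all__ = ["LatentTrajectory", "integrate_latent", "interp_latent", "predict_field"]


@dataclass
class LatentTrajectory:
    """Euler-discretized latent path on the uniform grid 0, dt, ..., n*dt."""

    grid_times: np.ndarray
    states: np.ndarray  # (n_steps + 1, d_s)

    def __post_init__(self) -> None:
        self.grid_times = np.asarray(self.grid_times, dtype=float)
        self.states = np.atleast_2d(np.asarray(self.states, dtype=float))
        if self.states.shape[0] != self.grid_times.size:
            raise ValueError("states/grid length mismatch")

    @property
    def dt(self) -> float:
        return float(self.grid_times[1] - self.grid_times[0])

    @property
    def horizon(self) -> float:
        return float(self.grid_times[-1])


def integrate_latent(model: LDNet, signal: InputSignal, T: float, dt: float | None = None) -> LatentTrajectory:
    """Advance s' = NN_dyn(s, u(t)) with forward Euler, s(0) = 0.

    The horizon T may exceed the training horizon (time extrapolation); the
    input is resampled by piecewise-linear interpolation at each step time.
    """
    dt = model.dt if dt is None else float(dt)
    if dt <= 0 or T < dt:
        raise ValueError("need dt > 0 and T >= dt")
    n_steps = int(round(T / dt))
    times = dt * np.arange(n_steps + 1)
    U = resample_input(signal, np.minimum(times[:-1], signal.times[-1]))
    states = np.zeros((n_steps + 1, model.d_s))
    for k in range(n_steps):
        rhs = model.dyn_rhs(states[k], U[k])
        states[k + 1] = states[k] + dt * rhs
        if not np.all(np.isfinite(states[k + 1])):
            raise FloatingPointError(f"latent state blew up at step {k + 1} (t={times[k + 1]:g})")
    return LatentTrajectory(times, states)


def interp_latent(traj: LatentTrajectory, tau):
    """Latent state at time(s) tau by linear interpolation; exact on nodes."""
    tau = np.asarray(tau, dtype=float)
    scalar = tau.ndim == 0
    tq = np.atleast_1d(tau)
    if np.any(tq < -1e-12) or np.any(tq > traj.horizon * (1 + 1e-12)):
        raise ValueError("interpolation time outside the integrated trajectory")
    dt = traj.dt
    pos = np.clip(tq / dt, 0.0, traj.states.shape[0] - 1)
    k = np.minimum(pos.astype(int), traj.states.shape[0] - 2)
    frac = pos - k
    out = (1.0 - frac)[:, None] * traj.states[k] + frac[:, None] * traj.states[k + 1]
    return out[0] if scalar else out


def predict_field(model: LDNet, signal: InputSignal, points, times, T: float, dt: float | None = None):
    """Predicted output at query (x, tau) pairs; one latent solve per signal.

    ``points`` is (n, d) and ``times`` is (n,); row i is the query
    (points[i], times[i]).  Equivalent to composing integrate_latent,
    interp_latent, resample_input and reconstruct per query, but the latent
    trajectory is computed once regardless of the number of queries.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if points.shape[0] != times.size:
        raise ValueError("points and times must have matching row counts")
    traj = integrate_latent(model, signal, T, dt)
    s = interp_latent(traj, times)
    u = resample_input(signal, np.minimum(times, signal.times[-1]))
    return model.reconstruct(s, u, points)
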