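"""1D monodomain Aliev-Panfilov solver with square-impulse pacing.

The model couples a reaction-diffusion equation for the transmembrane
potential z with an ODE for the recovery variable w:

    dz/dt - D d2z/dx2 = K z (1 - z)(z - a) - z w + I_stim(x, t),
    dw/dt = (gamma + mu1 w / (mu2 + z)) (-w - K z (z - b - 1)),

on (0, L) with homogeneous Neumann boundaries (electrical insulation) and
zero initial conditions; (z, w) = (0, 0) is the resting equilibrium.
Square current impulses are applied at the two pacing sites x = L/4 and
x = 3L/4.  Reaction parameters default to the classical Aliev-Panfilov
parameterization (K=8, a=0.15, b=0.15, gamma=0.002, mu1=0.2, mu2=0.3,
dimensionless time); time marching uses the fine fixed step required by
the stiff upstroke, with either a fully explicit step (subject to the
diffusive CFL bound) or operator splitting with implicit diffusion.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.integrate import solve_ivp

from ..data import Dataset, FieldObservations, InputSignal, Sample, SpatialDomain

__all__ = [
    "APConfig",
    "StimulusProtocol",
    "APSolution",
    "make_stimulus",
    "solve_ap_1d",
    "solve_single_cell_reference",
    "sample_protocols",
    "generate_dataset_tc3",
]


@dataclass
class APConfig:
    L: float = 1.0
    D: float = 1e-3
    K: float = 8.0
    a: float = 0.15  # excitation threshold (0 < a < 1)
    b: float = 0.15
    gamma_ap: float = 0.002
    mu1_ap: float = 0.2
    mu2_ap: float = 0.3
    h: float = 0.01  # mesh spacing -> 101 nodes on [0, L]
    dt: float = 5e-6  # fine fixed step imposed by the stiff reaction
    T: float = 50.0
    n_obs_times: int = 100
    method: str = "semi_implicit"  # or "explicit" (CFL-checked)

    def __post_init__(self) -> None:
        if min(self.D, self.K, self.h, self.dt, self.T) <= 0:
            raise ValueError("D, K, h, dt, T must be positive")
        if not 0.0 < self.a < 1.0:
            raise ValueError("threshold a must lie in (0, 1)")
        if self.method not in ("semi_implicit", "explicit"):
            raise ValueError("method must be 'semi_implicit' or 'explicit'")

    @property
    def grid(self) -> np.ndarray:
        n = int(round(self.L / self.h)) + 1
        return np.linspace(0.0, self.L, n)

    @property
    def obs_times(self) -> np.ndarray:
        return self.T * np.arange(1, self.n_obs_times + 1) / self.n_obs_times


# Default impulse amplitude: roughly twice the excitation threshold of the
# default tissue configuration for a 1-time-unit pulse on a 2-cell support
# (in-tissue threshold ~ 0.45 by bisection; diffusive loading raises it
# well above the space-clamped single-cell value of ~ 0.18).
DEFAULT_AMPLITUDE = 0.9
DEFAULT_DURATION = 1.0


@dataclass
class StimulusProtocol:
    """Square impulses at the two pacing sites x = L/4 and x = 3L/4.

    ``impulses[site]`` is an (n_impulses, 3) array of rows
    (onset, duration, amplitude); ``half_width`` is the spatial half-width
    of each site's support (defaults to two mesh cells).
    """

    L: float = 1.0
    impulses: tuple = (np.zeros((0, 3)), np.zeros((0, 3)))
    half_width: float = 0.02

    def __post_init__(self) -> None:
        self.impulses = tuple(np.atleast_2d(np.asarray(im, dtype=float)).reshape(-1, 3) for im in self.impulses)
        for im in self.impulses:
            if im.size and np.any(im[:, 2] < 0):
                raise ValueError("impulse amplitudes must be nonnegative")
            if im.size and np.any(im[:, 0] < 0):
                raise ValueError("impulse onsets must be nonnegative")

    @property
    def sites(self) -> tuple:
        return (self.L / 4.0, 3.0 * self.L / 4.0)

    def amplitude_at(self, site_idx: int, t) -> np.ndarray:
        """Per-site stimulus amplitude time series (piecewise constant)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.zeros_like(t)
        for onset, dur, amp in self.impulses[site_idx]:
            out = np.where((t >= onset) & (t < onset + dur), amp, out)
        return out

    def to_signal(self, T: float, spacing: float = 0.1) -> InputSignal:
        """Sample the two per-site amplitude series as a d_u=2 input signal."""
        times = np.arange(0.0, T + spacing / 2, spacing)
        vals = np.column_stack([self.amplitude_at(0, times), self.amplitude_at(1, times)])
        return InputSignal(times=times, values=vals)


def make_stimulus(protocol: StimulusProtocol, x, t: float) -> np.ndarray:
    """I_stim(x, t): piecewise-constant in both space and time."""
    x = np.atleast_1d(np.asarray(x, dtype=float))
    out = np.zeros_like(x)
    for site_idx, site in enumerate(protocol.sites):
        amp = float(protocol.amplitude_at(site_idx, t)[0])
        if amp > 0:
            out = np.where(np.abs(x - site) <= protocol.half_width + 1e-12, out + amp, out)
    return out


@dataclass
class APSolution:
    x: np.ndarray
    times: np.ndarray
    z: np.ndarray  # potential, (n_obs, n_x)
    w: np.ndarray  # recovery variable, (n_obs, n_x)


@njit(cache=True)
def _march(z, w, n_steps, dt, rx, K, a, b, gam, mu1, mu2,
           site_mask0, site_mask1, imp0, imp1, out_steps, Z_out, W_out, semi_implicit):
    n = z.size
    # Thomas factorization of (I - dt*D/h^2 * Lap) with Neumann rows
    cp = np.empty(n)
    if semi_implicit:
        # diag: 1 + 2 rx (interior), 1 + 2 rx boundary with mirrored ghost
        # off-diagonals: -rx (interior), -2 rx at the two boundary rows
        cp[0] = (-2.0 * rx) / (1.0 + 2.0 * rx)
        for i in range(1, n - 1):
            cp[i] = -rx / (1.0 + 2.0 * rx + rx * cp[i - 1])
    out_idx = 0
    d = np.empty(n)
    for step in range(1, n_steps + 1):
        t = (step - 1) * dt
        amp0 = 0.0
        for j in range(imp0.shape[0]):
            if imp0[j, 0] <= t < imp0[j, 0] + imp0[j, 1]:
                amp0 = imp0[j, 2]
        amp1 = 0.0
        for j in range(imp1.shape[0]):
            if imp1[j, 0] <= t < imp1[j, 0] + imp1[j, 1]:
                amp1 = imp1[j, 2]
        # reaction + stimulus (explicit)
        for i in range(n):
            zi = z[i]
            wi = w[i]
            rz = K * zi * (1.0 - zi) * (zi - a) - zi * wi
            rw = (gam + mu1 * wi / (mu2 + zi)) * (-wi - K * zi * (zi - b - 1.0))
            stim = amp0 * site_mask0[i] + amp1 * site_mask1[i]
            d[i] = zi + dt * (rz + stim)
            w[i] = wi + dt * rw
        if semi_implicit:
            # solve (I - dt*D Lap_h) z_new = d   (Thomas algorithm)
            dp0 = d[0] / (1.0 + 2.0 * rx)
            z[0] = dp0
            prev = dp0
            for i in range(1, n):
                lower = -2.0 * rx if i == n - 1 else -rx
                denom = (1.0 + 2.0 * rx) - lower * cp[i - 1]
                prev = (d[i] - lower * prev) / denom
                z[i] = prev
            for i in range(n - 2, -1, -1):
                z[i] = z[i] - cp[i] * z[i + 1]
        else:
            # explicit diffusion with mirrored ghost nodes
            z[0] = d[0] + 2.0 * rx * (d[1] - d[0]) if n > 1 else d[0]
            for i in range(1, n - 1):
                z[i] = d[i] + rx * (d[i - 1] - 2.0 * d[i] + d[i + 1])
            z[n - 1] = d[n - 1] + 2.0 * rx * (d[n - 2] - d[n - 1])
        if out_idx < out_steps.size and step == out_steps[out_idx]:
            for i in range(n):
                Z_out[out_idx, i] = z[i]
                W_out[out_idx, i] = w[i]
            out_idx += 1
        if not np.isfinite(z[0]):
            return -step
    return 0


def solve_ap_1d(cfg: APConfig, protocol: StimulusProtocol) -> APSolution:
    """March the monodomain AP system at the fine fixed step.

    Reaction and stimulus are stepped explicitly; diffusion is treated
    implicitly (default) or explicitly, in which case the diffusive CFL
    bound dt <= h^2 / (2 D) is enforced.
    """
    x = cfg.grid
    rx = cfg.D * cfg.dt / cfg.h**2
    if cfg.method == "explicit" and cfg.dt > cfg.h**2 / (2.0 * cfg.D):
        raise ValueError(
            f"explicit diffusion unstable: dt={cfg.dt:g} exceeds the stable "
            f"bound h^2/(2D) = {cfg.h**2 / (2 * cfg.D):g}"
        )
    n_steps = int(round(cfg.T / cfg.dt))
    out_steps = np.unique(np.round(cfg.obs_times / cfg.dt).astype(np.int64))
    masks = [
        (np.abs(x - site) <= protocol.half_width + 1e-12).astype(float)
        for site in protocol.sites
    ]
    z = np.zeros_like(x)
    w = np.zeros_like(x)
    Z_out = np.empty((out_steps.size, x.size))
    W_out = np.empty((out_steps.size, x.size))
    status = _march(
        z, w, n_steps, cfg.dt, rx, cfg.K, cfg.a, cfg.b, cfg.gamma_ap, cfg.mu1_ap,
        cfg.mu2_ap, masks[0], masks[1], protocol.impulses[0], protocol.impulses[1],
        out_steps, Z_out, W_out, cfg.method == "semi_implicit",
    )
    if status < 0:
        raise FloatingPointError(f"AP solution blew up at step {-status}")
    times = out_steps * cfg.dt
    return APSolution(x=x, times=times, z=Z_out, w=W_out)


def solve_single_cell_reference(cfg: APConfig, impulses, T: float | None = None, t_eval=None):
    """Independent adaptive stiff ODE reference for the space-clamped cell.

    Integrates the pure reaction system (D = 0, uniform stimulus given by
    the (onset, duration, amplitude) rows) with an adaptive implicit
    scheme; used as the oracle against which the fixed-step marching
    scheme is validated.
    """
    T = cfg.T if T is None else T
    imp = np.atleast_2d(np.asarray(impulses, dtype=float)).reshape(-1, 3)

    def amp(t):
        a_ = 0.0
        for onset, dur, A in imp:
            if onset <= t < onset + dur:
                a_ += A
        return a_

    def rhs(t, yv):
        z, w = yv
        rz = cfg.K * z * (1.0 - z) * (z - cfg.a) - z * w + amp(t)
        rw = (cfg.gamma_ap + cfg.mu1_ap * w / (cfg.mu2_ap + z)) * (-w - cfg.K * z * (z - cfg.b - 1.0))
        return [rz, rw]

    edges = np.unique(np.concatenate([[0.0, T], imp[:, 0], imp[:, 0] + imp[:, 1]]))
    edges = edges[(edges >= 0) & (edges <= T)]
    sol = solve_ivp(
        rhs, (0.0, T), [0.0, 0.0],
        t_eval=np.clip(np.asarray(t_eval), 0.0, T) if t_eval is not None else cfg.obs_times[cfg.obs_times <= T],
        method="LSODA", rtol=1e-10, atol=1e-12, max_step=float(np.min(np.diff(edges)).clip(1e-6)) if edges.size > 1 else np.inf,
    )
    if not sol.success:
        raise RuntimeError(f"single-cell reference integration failed: {sol.message}")
    return sol.t, sol.y[0], sol.y[1]


def sample_protocols(cfg: APConfig, n: int, seed, amplitude: float = DEFAULT_AMPLITUDE,
                     duration: float = DEFAULT_DURATION, max_impulses: int = 2,
                     onset_window: float | None = None) -> list[StimulusProtocol]:
    """Random impulse schedules: per site, 1..max_impulses square impulses
    with onsets uniform in [0, onset_window] (default 0.6 T)."""
    rng = np.random.default_rng(seed)
    window = 0.6 * cfg.T if onset_window is None else onset_window
    protocols = []
    for _ in range(n):
        per_site = []
        for _site in range(2):
            k = int(rng.integers(1, max_impulses + 1))
            onsets = np.sort(rng.uniform(0.0, window, size=k))
            per_site.append(np.column_stack([onsets, np.full(k, duration), np.full(k, amplitude)]))
        protocols.append(StimulusProtocol(L=cfg.L, impulses=tuple(per_site), half_width=2.0 * cfg.h))
    return protocols


def generate_dataset_tc3(cfg: APConfig, n_train: int, n_test: int, seed: int,
                         protocols_train=None, protocols_test=None) -> tuple[Dataset, Dataset]:
    """Train/test datasets: inputs are the two per-site stimulus time
    series (d_u = 2), outputs the potential z on the observation grid."""

    def build(protocols, split):
        samples = []
        points = cfg.grid[:, None]
        for i, proto in enumerate(protocols):
            sol = solve_ap_1d(cfg, proto)
            obs = FieldObservations(
                obs_times=sol.times,
                points=[points] * sol.times.size,
                values=[sol.z[k][:, None] for k in range(sol.times.size)],
            )
            samples.append(Sample(id=f"ap1d_{split}_{i:04d}", signal=proto.to_signal(cfg.T), observations=obs))
        return Dataset(
            samples=samples,
            domain=SpatialDomain([[0.0, cfg.L]]),
            horizon=cfg.T,
            metadata={"generator": "ap1d", "seed": seed, "split": split},
        )

    if protocols_train is None:
        protocols_train = sample_protocols(cfg, n_train, np.random.default_rng([seed, 0]))
    if protocols_test is None:
        protocols_test = sample_protocols(cfg, n_test, np.random.default_rng([seed, 1]))
    return build(protocols_train, "train"), build(protocols_test, "test")
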