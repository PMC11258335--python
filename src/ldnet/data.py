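"""Sample and dataset containers, normalization statistics, and HDF5 I/O.

A *sample* pairs one time-dependent input signal ``u(t)`` (constant
parameters are encoded as a single-row signal) with scattered space-time
observations ``y(x, t)`` of the output field.  A :class:`Dataset` is a
homogeneous collection of samples over a common spatial domain and time
horizon; it is the unit that training, evaluation and the full-order-model
generators exchange on disk (one HDF5 file per dataset).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
from sklearn.model_selection import KFold

__all__ = [
    "InputSignal",
    "FieldObservations",
    "Sample",
    "SpatialDomain",
    "Dataset",
    "ChannelStats",
    "NormalizationStats",
    "SchemaError",
    "fit_normalization",
    "resample_input",
    "split_kfold",
    "save_dataset",
    "load_dataset",
]


class SchemaError(ValueError):
    """Raised when an on-disk dataset container is malformed."""


def _as_2d(a, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = a[:, None]
    if a.ndim != 2:
        raise ValueError(f"{name} must be 1- or 2-dimensional, got shape {a.shape}")
    return a


@dataclass
class InputSignal:
    """Time-stamped input trajectory ``u(t)`` with ``d_u`` channels.

    A single row encodes a constant parameter vector: resampling then holds
    that value at every query time.
    """

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.atleast_1d(np.asarray(self.times, dtype=float))
        self.values = _as_2d(self.values, "values")
        if self.times.ndim != 1 or self.times.size < 1:
            raise ValueError("signal needs at least one sample time")
        if self.values.shape[0] != self.times.size:
            raise ValueError("times and values row counts differ")
        if self.times.size > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("signal times must be strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("signal contains non-finite entries")

    @property
    def d_u(self) -> int:
        return self.values.shape[1]


@dataclass
class FieldObservations:
    """Scattered observations of the ``d_y``-dimensional output field.

    ``points[k]`` and ``values[k]`` hold the coordinates and readings at
    observation time ``obs_times[k]``; the per-time point sets may be ragged.
    """

    obs_times: np.ndarray
    points: list[np.ndarray]
    values: list[np.ndarray]

    def __post_init__(self) -> None:
        self.obs_times = np.atleast_1d(np.asarray(self.obs_times, dtype=float))
        self.points = [_as_2d(p, "points") for p in self.points]
        self.values = [_as_2d(v, "values") for v in self.values]
        if not (len(self.points) == len(self.values) == self.obs_times.size):
            raise ValueError("per-time lists must match obs_times length")
        for k, (p, v) in enumerate(zip(self.points, self.values)):
            if p.shape[0] != v.shape[0]:
                raise ValueError(f"point/value count mismatch at time index {k}")
            if not (np.all(np.isfinite(p)) and np.all(np.isfinite(v))):
                raise ValueError(f"non-finite observation at time index {k}")

    @property
    def d_y(self) -> int:
        return self.values[0].shape[1] if self.values else 0

    @property
    def dim(self) -> int:
        return self.points[0].shape[1] if self.points else 0

    def n_points(self) -> np.ndarray:
        return np.array([p.shape[0] for p in self.points])


@dataclass
class Sample:
    id: str
    signal: InputSignal
    observations: FieldObservations


@dataclass
class SpatialDomain:
    """Bounding box for the spatial domain Omega, shape (d, 2)."""

    bounds: np.ndarray

    def __post_init__(self) -> None:
        self.bounds = np.atleast_2d(np.asarray(self.bounds, dtype=float))
        if self.bounds.shape[1] != 2 or np.any(self.bounds[:, 0] >= self.bounds[:, 1]):
            raise ValueError("bounds must be (d, 2) with min < max per axis")

    @property
    def dim(self) -> int:
        return self.bounds.shape[0]

    def contains(self, x: np.ndarray, rtol: float = 1e-9) -> np.ndarray:
        x = _as_2d(x, "x")
        width = self.bounds[:, 1] - self.bounds[:, 0]
        lo = self.bounds[:, 0] - rtol * width
        hi = self.bounds[:, 1] + rtol * width
        return np.all((x >= lo) & (x <= hi), axis=1)


@dataclass
class Dataset:
    samples: list[Sample]
    domain: SpatialDomain
    horizon: float
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("horizon must be positive")
        for s in self.samples:
            if s.signal.times.max() > self.horizon * (1 + 1e-12):
                raise ValueError(f"sample {s.id}: signal times exceed horizon")
            if s.observations.obs_times.size and s.observations.obs_times.max() > self.horizon * (1 + 1e-12):
                raise ValueError(f"sample {s.id}: observation times exceed horizon")
            if s.observations.points and s.observations.dim != self.domain.dim:
                raise ValueError(f"sample {s.id}: spatial dimension mismatch")
            for p in s.observations.points:
                if not np.all(self.domain.contains(p)):
                    raise ValueError(f"sample {s.id}: observation point outside domain")
        dus = {s.signal.d_u for s in self.samples}
        dys = {s.observations.d_y for s in self.samples if s.observations.values}
        if len(dus) > 1 or len(dys) > 1:
            raise ValueError("samples disagree on channel counts")

    def __len__(self) -> int:
        return len(self.samples)

    @property
    def d_u(self) -> int:
        return self.samples[0].signal.d_u

    @property
    def d_y(self) -> int:
        return self.samples[0].observations.d_y

    @property
    def dim(self) -> int:
        return self.domain.dim


@dataclass
class ChannelStats:
    """Per-channel affine normalization x -> (x - center) / width."""

    center: np.ndarray
    width: np.ndarray
    strategy: list[str]

    def __post_init__(self) -> None:
        self.center = np.atleast_1d(np.asarray(self.center, dtype=float))
        self.width = np.atleast_1d(np.asarray(self.width, dtype=float))
        if np.any(self.width <= 0):
            raise ValueError("normalization width must be positive")

    def normalize(self, a: np.ndarray) -> np.ndarray:
        return (np.asarray(a, dtype=float) - self.center) / self.width

    def denormalize(self, a: np.ndarray) -> np.ndarray:
        return np.asarray(a, dtype=float) * self.width + self.center


@dataclass
class NormalizationStats:
    """Normalization state embedded in the model's non-trainable layers.

    Latent states are deliberately left without statistics: their
    distribution is unknown before training and well-tuned runs produce
    approximately normalized latents on their own.
    """

    u: ChannelStats
    y: ChannelStats
    x: ChannelStats
    dt_ref: float = 1.0
    beta: np.ndarray | None = None  # per-output tail-compression strength

    def __post_init__(self) -> None:
        if self.dt_ref <= 0:
            raise ValueError("dt_ref must be positive")
        if self.beta is not None:
            self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
            if np.any(self.beta <= 0):
                raise ValueError("tail-compression strength beta must be positive")


def _fit_channels(columns: list[np.ndarray], bounds, what: str) -> ChannelStats:
    n = len(columns)
    if bounds is None:
        bounds = [None] * n
    center = np.empty(n)
    width = np.empty(n)
    strategy = []
    for j, col in enumerate(columns):
        b = bounds[j]
        if b is not None:
            lo, hi = float(b[0]), float(b[1])
            if not lo < hi:
                raise ValueError(f"{what} channel {j}: declared bounds need min < max")
            center[j] = 0.5 * (lo + hi)
            width[j] = 0.5 * (hi - lo)
            strategy.append("bounded")
        else:
            std = float(np.std(col))
            if std == 0.0:
                raise ValueError(
                    f"{what} channel {j} has zero variance; declare explicit bounds "
                    "or drop the channel"
                )
            center[j] = float(np.mean(col))
            width[j] = 3.0 * std
            strategy.append("unbounded")
    return ChannelStats(center, width, strategy)


def fit_normalization(
    dataset: Dataset,
    u_bounds=None,
    y_bounds=None,
    x_bounds=None,
    dt_ref: float = 1.0,
    beta=None,
) -> NormalizationStats:
    """Fit per-channel affine normalization maps from training data.

    Channels with declared ``[min, max]`` bounds are mapped exactly onto
    [-1, 1]; unbounded channels use (sample mean, 3 x sample std).  Spatial
    coordinates default to the domain bounding box.
    """
    if len(dataset) == 0:
        raise ValueError("cannot fit normalization on an empty dataset")
    u_cols = [
        np.concatenate([s.signal.values[:, j] for s in dataset.samples])
        for j in range(dataset.d_u)
    ]
    y_cols = [
        np.concatenate(
            [np.concatenate([v[:, j] for v in s.observations.values]) for s in dataset.samples]
        )
        for j in range(dataset.d_y)
    ]
    if x_bounds is None:
        x_bounds = [tuple(dataset.domain.bounds[j]) for j in range(dataset.dim)]
    x_cols = [np.zeros(1)] * dataset.dim  # bounded path ignores data
    return NormalizationStats(
        u=_fit_channels(u_cols, u_bounds, "u"),
        y=_fit_channels(y_cols, y_bounds, "y"),
        x=_fit_channels(x_cols, x_bounds, "x"),
        dt_ref=dt_ref,
        beta=beta,
    )


def resample_input(signal: InputSignal, t) -> np.ndarray:
    """Piecewise-linear resampling of the input signal at time(s) ``t``.

    Exact at stored sample times; outside the recorded window the nearest
    endpoint value is held (with a warning), so time extrapolation of the
    latent dynamics always has a defined input.
    """
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tq = np.atleast_1d(t)
    lo, hi = signal.times[0], signal.times[-1]
    if np.any(tq < lo) or np.any(tq > hi):
        warnings.warn(
            "query time outside recorded input window; holding endpoint value",
            stacklevel=2,
        )
    out = np.empty((tq.size, signal.d_u))
    for j in range(signal.d_u):
        out[:, j] = np.interp(tq, signal.times, signal.values[:, j])
    return out[0] if scalar else out


def split_kfold(dataset: Dataset, K: int, seed: int):
    """K-fold partition of sample indices (list of (train, validation))."""
    n = len(dataset)
    if K < 2:
        raise ValueError("K must be at least 2")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    kf = KFold(n_splits=K, shuffle=True, random_state=seed)
    return [(tr.copy(), va.copy()) for tr, va in kf.split(np.arange(n))]


# ---------------------------------------------------------------------------
# HDF5 container: /samples/<id>/{signal_times, signal_values, obs_times,
# obs_points_<k>, obs_values_<k>}; root attributes d, d_u, d_y, T, bounds.
# ---------------------------------------------------------------------------

def save_dataset(dataset: Dataset, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["schema"] = "ldnet-dataset-v1"
        f.attrs["T"] = dataset.horizon
        f.attrs["d"] = dataset.dim
        f.attrs["d_u"] = dataset.d_u if dataset.samples else 0
        f.attrs["d_y"] = dataset.d_y if dataset.samples else 0
        f.create_dataset("bounds", data=dataset.domain.bounds)
        import json

        f.attrs["metadata"] = json.dumps(dataset.metadata)
        g = f.create_group("samples")
        for i, s in enumerate(dataset.samples):
            gs = g.create_group(s.id)
            gs.attrs["order"] = i
            gs.create_dataset("signal_times", data=s.signal.times)
            gs.create_dataset("signal_values", data=s.signal.values)
            gs.create_dataset("obs_times", data=s.observations.obs_times)
            for k in range(s.observations.obs_times.size):
                gs.create_dataset(f"obs_points_{k}", data=s.observations.points[k])
                gs.create_dataset(f"obs_values_{k}", data=s.observations.values[k])


def load_dataset(path) -> Dataset:
    import json

    with h5py.File(path, "r") as f:
        for key in ("T", "d"):
            if key not in f.attrs:
                raise SchemaError(f"dataset container missing root attribute '{key}'")
        if "bounds" not in f:
            raise SchemaError("dataset container missing 'bounds' dataset")
        if "samples" not in f:
            raise SchemaError("dataset container missing 'samples' group")
        domain = SpatialDomain(f["bounds"][...])
        metadata = json.loads(f.attrs.get("metadata", "{}"))
        samples = []
        for sid in sorted(f["samples"], key=lambda s: (int(f["samples"][s].attrs.get("order", 0)), s)):
            gs = f["samples"][sid]
            for key in ("signal_times", "signal_values", "obs_times"):
                if key not in gs:
                    raise SchemaError(f"sample '{sid}' missing group '{key}'")
            obs_times = gs["obs_times"][...]
            points, values = [], []
            for k in range(obs_times.size):
                for key in (f"obs_points_{k}", f"obs_values_{k}"):
                    if key not in gs:
                        raise SchemaError(f"sample '{sid}' missing group '{key}'")
                points.append(gs[f"obs_points_{k}"][...])
                values.append(gs[f"obs_values_{k}"][...])
            samples.append(
                Sample(
                    id=sid,
                    signal=InputSignal(gs["signal_times"][...], gs["signal_values"][...]),
                    observations=FieldObservations(obs_times, points, values),
                )
            )
        return Dataset(samples=samples, domain=domain, horizon=float(f.attrs["T"]), metadata=metadata)
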