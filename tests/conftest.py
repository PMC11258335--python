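import numpy as np
import pytest

from ldnet.data import (
    Dataset,
    FieldObservations,
    InputSignal,
    Sample,
    SpatialDomain,
    fit_normalization,
)
from ldnet.model import LDNet
from ldnet.nets import FCNN


def make_scattered_dataset(rng, n_samples=3, d_u=2, d_y=1, T=1.0):
    """Small dataset with ragged per-time observation sets."""
    samples = []
    for i in range(n_samples):
        sig = InputSignal(np.linspace(0, T, 5), rng.normal(size=(5, d_u)))
        obs_t = np.sort(rng.uniform(0, T, 3))
        pts = [rng.uniform(-1, 1, size=(int(rng.integers(2, 6)), 1)) for _ in obs_t]
        vals = [rng.normal(size=(p.shape[0], d_y)) for p in pts]
        samples.append(Sample(f"s{i}", sig, FieldObservations(obs_t, pts, vals)))
    return Dataset(samples, SpatialDomain([[-1, 1]]), T)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def scattered_dataset(rng):
    return make_scattered_dataset(rng)


def make_model(dataset, d_s=2, dyn_hidden=(6,), rec_hidden=(7,), seed=1, **kw):
    stats = fit_normalization(
        dataset,
        dt_ref=kw.pop("dt_ref", 1.0),
        beta=kw.pop("beta", None),
        y_bounds=kw.pop("y_bounds", None),
    )
    d_u, d_y, d = dataset.d_u, dataset.d_y, dataset.dim
    rec_in = d_s + (d_u if kw.get("rec_uses_u") else 0) + d
    model = LDNet(
        dyn=FCNN([d_s + d_u, *dyn_hidden, d_s]),
        rec=FCNN([rec_in, *rec_hidden, d_y]),
        d_s=d_s,
        stats=stats,
        dt=kw.pop("dt", 0.05),
        **kw,
    )
    return model.init_weights(seed)


@pytest.fixture
def toy_model(scattered_dataset):
    return make_model(scattered_dataset)
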