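import numpy as np
import pytest

from ldnet.data import (
    Dataset,
    FieldObservations,
    InputSignal,
    Sample,
    SchemaError,
    SpatialDomain,
    fit_normalization,
    load_dataset,
    resample_input,
    save_dataset,
    split_kfold,
)

from conftest import make_scattered_dataset


class TestNormalization:
    def test_bounded_channel_maps_declared_interval_to_unit(self, scattered_dataset):
        stats = fit_normalization(scattered_dataset, u_bounds=[(0.0, 2.0), None])
        assert stats.u.center[0] == 1.0 and stats.u.width[0] == 1.0
        assert stats.u.strategy[0] == "bounded"
        # every value inside the declared bounds lands exactly in [-1, 1]
        vals = np.linspace(0, 2, 11)
        assert np.all(np.abs((vals - stats.u.center[0]) / stats.u.width[0]) <= 1.0)

    def test_unbounded_channel_uses_mean_and_three_std(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(5.0, 1.0, size=400)
        sig = InputSignal(np.arange(400, dtype=float), raw[:, None])
        obs = FieldObservations([0.0], [np.zeros((1, 1))], [np.ones((1, 1))])
        ds = Dataset(
            [Sample("a", sig, obs)], SpatialDomain([[-1, 1]]), horizon=400.0
        )
        stats = fit_normalization(ds, y_bounds=[(0.0, 2.0)])
        assert stats.u.center[0] == pytest.approx(np.mean(raw))
        assert stats.u.width[0] == pytest.approx(3.0 * np.std(raw))

    def test_constant_channel_rejected(self, scattered_dataset):
        with pytest.raises(ValueError, match="min < max"):
            fit_normalization(scattered_dataset, u_bounds=[(3.0, 3.0), None])

    def test_zero_variance_unbounded_channel_rejected(self):
        sig = InputSignal([0.0, 1.0], np.full((2, 1), 7.0))
        obs = FieldObservations([0.5], [np.zeros((1, 1))], [np.ones((1, 1))])
        ds = Dataset([Sample("a", sig, obs)], SpatialDomain([[-1, 1]]), 1.0)
        with pytest.raises(ValueError, match="zero variance"):
            fit_normalization(ds, y_bounds=[(0, 2)])

    def test_empty_dataset_rejected(self):
        ds = Dataset([], SpatialDomain([[-1, 1]]), 1.0)
        with pytest.raises(ValueError, match="empty"):
            fit_normalization(ds)


class TestResampleInput:
    @pytest.mark.parametrize(
        "times, values, t, expected",
        [
            ([0, 1], [0.0, 2.0], 0.5, 1.0),
            ([0, 1, 2], [0.0, 1.0, 0.0], 1.5, 0.5),
            ([0, 1, 2], [0.0, 1.0, 0.0], 1.0, 1.0),
        ],
    )
    def test_linear_interpolation(self, times, values, t, expected):
        sig = InputSignal(times, np.asarray(values)[:, None])
        assert resample_input(sig, t)[0] == pytest.approx(expected, abs=0)

    def test_exact_on_nodes_and_continuous(self, rng):
        sig = InputSignal(np.sort(rng.uniform(0, 1, 8)), rng.normal(size=(8, 2)))
        for k, tk in enumerate(sig.times):
            assert np.array_equal(resample_input(sig, tk), sig.values[k])
        tq = np.sort(rng.uniform(sig.times[0], sig.times[-1], 1000))
        vals = resample_input(sig, tq)
        # continuity: small time steps give small value jumps
        jumps = np.abs(np.diff(vals, axis=0)).max(axis=1)
        slopes = np.abs(np.diff(sig.values, axis=0) / np.diff(sig.times)[:, None]).max()
        assert np.all(jumps <= slopes * np.diff(tq) + 1e-12)

    def test_extrapolation_holds_endpoint_with_warning(self):
        sig = InputSignal([0.0, 1.0], np.array([[1.0], [3.0]]))
        with pytest.warns(UserWarning, match="endpoint"):
            assert resample_input(sig, 2.0)[0] == 3.0

    def test_constant_parameter_single_row(self):
        sig = InputSignal([0.0], np.array([[4.0, 5.0]]))
        with pytest.warns(UserWarning):
            assert np.array_equal(resample_input(sig, 0.7), [4.0, 5.0])


class TestKFold:
    def test_partition_covers_all_indices_once(self, rng):
        ds = make_scattered_dataset(rng, n_samples=10)
        folds = split_kfold(ds, 5, seed=3)
        assert len(folds) == 5
        val_all = np.concatenate([v for _, v in folds])
        assert sorted(val_all) == list(range(10))
        for tr, va in folds:
            assert set(tr) | set(va) == set(range(10))
            assert not set(tr) & set(va)
            assert len(va) == 2

    def test_deterministic_under_seed(self, rng):
        ds = make_scattered_dataset(rng, n_samples=7)
        f1 = split_kfold(ds, 3, seed=9)
        f2 = split_kfold(ds, 3, seed=9)
        for (a, b), (c, d) in zip(f1, f2):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_too_many_folds_rejected(self, scattered_dataset):
        with pytest.raises(ValueError, match="exceeds"):
            split_kfold(scattered_dataset, 99, seed=0)


class TestRoundTrip:
    def test_lossless_round_trip(self, tmp_path, scattered_dataset):
        path = tmp_path / "ds.h5"
        save_dataset(scattered_dataset, path)
        loaded = load_dataset(path)
        assert loaded.horizon == scattered_dataset.horizon
        assert np.array_equal(loaded.domain.bounds, scattered_dataset.domain.bounds)
        assert len(loaded) == len(scattered_dataset)
        for a, b in zip(loaded.samples, scattered_dataset.samples):
            assert a.id == b.id
            assert np.array_equal(a.signal.times, b.signal.times)
            assert np.array_equal(a.signal.values, b.signal.values)
            assert np.array_equal(a.observations.obs_times, b.observations.obs_times)
            for p, q in zip(a.observations.points, b.observations.points):
                assert np.array_equal(p, q)
            for p, q in zip(a.observations.values, b.observations.values):
                assert np.array_equal(p, q)

    def test_missing_group_gives_schema_error(self, tmp_path, scattered_dataset):
        import h5py

        path = tmp_path / "ds.h5"
        save_dataset(scattered_dataset, path)
        with h5py.File(path, "a") as f:
            del f["samples/s1/obs_values_0"]
        with pytest.raises(SchemaError, match="obs_values_0"):
            load_dataset(path)

    def test_empty_dataset_round_trips(self, tmp_path):
        ds = Dataset([], SpatialDomain([[0, 1]]), 2.0, metadata={"k": "v"})
        path = tmp_path / "empty.h5"
        save_dataset(ds, path)
        loaded = load_dataset(path)
        assert len(loaded) == 0 and loaded.metadata == {"k": "v"}


class TestInvariants:
    def test_signal_times_must_increase(self):
        with pytest.raises(ValueError, match="increasing"):
            InputSignal([0.0, 0.0], np.zeros((2, 1)))

    def test_observation_point_outside_domain_rejected(self):
        sig = InputSignal([0.0], np.zeros((1, 1)))
        obs = FieldObservations([0.5], [np.array([[5.0]])], [np.ones((1, 1))])
        with pytest.raises(ValueError, match="outside"):
            Dataset([Sample("a", sig, obs)], SpatialDomain([[-1, 1]]), 1.0)
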