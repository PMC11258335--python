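import numpy as np
import pytest

from ldnet.data import Dataset, FieldObservations, InputSignal, Sample, SpatialDomain
from ldnet.integrator import predict_field
from ldnet.losses import (
    LossConfig,
    default_y_norm,
    discrepancy_goal_oriented,
    discrepancy_quadratic,
    l2_regularization,
    nrmse,
    pearson_dissimilarity,
    total_loss,
)
from ldnet.nets import FCNN

from conftest import make_model, make_scattered_dataset


class TestDiscrepancies:
    def test_quadratic_examples(self):
        assert discrepancy_quadratic(np.zeros(3), np.zeros(3)) == 0.0
        assert discrepancy_quadratic(np.array([3.0, 4.0]), np.zeros(2), 5.0) == pytest.approx(1.0)
        v = discrepancy_quadratic(np.array([1.0, 1.0]), np.zeros(2), 1.0)
        assert discrepancy_quadratic(np.array([1.0, 1.0]), np.zeros(2), 2.0) == pytest.approx(v / 4)

    def test_goal_oriented_examples(self):
        assert discrepancy_goal_oriented(np.array([1.0, 0]), np.array([1.0, 0]), 1, 1e-3, 1) == 0.0
        assert discrepancy_goal_oriented(np.array([2.0, 0]), np.array([1.0, 0]), 1.0, 0.0, 1.0) == pytest.approx(1.0)
        assert discrepancy_goal_oriented(np.array([-1.0, 0]), np.array([1.0, 0]), 1.0, 0.0, 1.0) == pytest.approx(8.0)

    def test_goal_oriented_reduces_to_quadratic_at_zero_gamma(self, rng):
        v, vh = rng.normal(size=(2, 6))
        got = discrepancy_goal_oriented(vh, v, gamma=0.0, eps=1e-3, v_norm=1.7)
        assert got == pytest.approx(discrepancy_quadratic(vh, v, 1.7), rel=1e-14)


class TestRegularization:
    def test_examples(self):
        net = FCNN([1, 1])
        assert l2_regularization(net) == 0.0
        net.weights[0][0, 0] = 1.0
        net.biases[0][0] = -1.0
        # parameters {1, -1}: mean square 1; add a layer value via widths change
        assert l2_regularization(net) == pytest.approx(1.0)

    def test_quadratic_scaling(self, rng):
        net = FCNN([2, 3, 1])
        theta = rng.normal(size=net.n_params)
        net.set_params_vector(theta)
        base = l2_regularization(net)
        net.set_params_vector(3.0 * theta)
        assert l2_regularization(net) == pytest.approx(9.0 * base, rel=1e-12)


class TestTotalLoss:
    def test_perfect_predictions_leave_only_regularization(self, rng):
        ds = make_scattered_dataset(rng)
        m = make_model(ds, seed=3)
        # replace observations by the model's own predictions
        samples = []
        for s in ds.samples:
            vals = []
            for k, tau in enumerate(s.observations.obs_times):
                pts = s.observations.points[k]
                vals.append(predict_field(m, s.signal, pts, np.full(pts.shape[0], tau), ds.horizon))
            samples.append(Sample(s.id, s.signal, FieldObservations(s.observations.obs_times, s.observations.points, vals)))
        ds2 = Dataset(samples, ds.domain, ds.horizon)
        cfg = LossConfig(alpha_dyn=0.1, alpha_rec=0.2)
        expected = 0.1 * l2_regularization(m.dyn) + 0.2 * l2_regularization(m.rec)
        assert total_loss(m, ds2, cfg) == pytest.approx(expected, abs=1e-18)

    def test_matches_flat_triple_loop_oracle(self, rng):
        """Samples weigh equally regardless of observation counts."""
        ds = make_scattered_dataset(rng, n_samples=4)
        m = make_model(ds, seed=6)
        cfg = LossConfig(y_norm=np.array([1.3]))
        got = total_loss(m, ds, cfg)
        # independent flat implementation of the nested averages
        acc = []
        for s in ds.samples:
            times_acc = []
            for k, tau in enumerate(s.observations.obs_times):
                pts = s.observations.points[k]
                pt_acc = []
                for j in range(pts.shape[0]):
                    pred = predict_field(m, s.signal, pts[j : j + 1], [tau], ds.horizon)[0]
                    pt_acc.append(np.sum(((pred - s.observations.values[k][j]) / 1.3) ** 2))
                times_acc.append(np.mean(pt_acc))
            acc.append(np.mean(times_acc))
        assert got == pytest.approx(np.mean(acc), rel=1e-12)

    def test_subsampled_loss_is_unbiased(self, rng):
        ds = make_scattered_dataset(rng, n_samples=2)
        m = make_model(ds, seed=9)
        full = total_loss(m, ds, LossConfig())
        cfg = LossConfig(point_subsample=2)
        draws = np.array([total_loss(m, ds, cfg, epoch_seed=i) for i in range(400)])
        se = draws.std(ddof=1) / np.sqrt(draws.size)
        assert abs(draws.mean() - full) <= 3 * se + 1e-12


class TestMetrics:
    def test_nrmse_examples_and_oracle(self, rng):
        a = rng.normal(size=(40, 2))
        assert nrmse(a, a) == 0.0
        assert nrmse(a + 0.5, a, 1.0) == pytest.approx(0.5)
        b = rng.normal(size=(40, 2))
        direct = np.sqrt(np.mean(((a - b) / 2.0) ** 2))
        assert nrmse(a, b, 2.0) == pytest.approx(direct, abs=1e-12)

    def test_pearson_dissimilarity_affine_and_negation(self, rng):
        y = rng.normal(size=300)
        assert pearson_dissimilarity(2 * y + 3, y) == pytest.approx(0.0, abs=1e-12)
        assert pearson_dissimilarity(-y, y) == pytest.approx(2.0, abs=1e-12)

    def test_pearson_dissimilarity_independent_noise_near_one(self):
        rng = np.random.default_rng(7)
        a, b = rng.normal(size=(2, 100000))
        assert 0.99 <= pearson_dissimilarity(a, b) <= 1.01

    def test_pearson_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_dissimilarity(np.ones(5), np.arange(5.0))

    def test_default_y_norm_is_half_range(self, rng):
        ds = make_scattered_dataset(rng)
        all_vals = np.concatenate([v for s in ds.samples for v in s.observations.values])
        assert default_y_norm(ds)[0] == pytest.approx(0.5 * (all_vals.max() - all_vals.min()))


class TestLossConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(metric="bogus")
        with pytest.raises(ValueError):
            LossConfig(y_norm=0.0)
        with pytest.raises(ValueError):
            LossConfig(metric="goal_oriented", eps=0.0)
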