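import numpy as np
import pytest

from ldnet.model import DirichletConstraint, box_boundary_mask, load_checkpoint, save_checkpoint

from conftest import make_model, make_scattered_dataset


class TestDynRhs:
    def test_equilibrium_is_exact_fixed_point_for_random_weights(self, scattered_dataset):
        u_eq = np.array([0.3, -0.5])
        residuals = []
        for seed in range(30):
            m = make_model(scattered_dataset, u_eq=u_eq, seed=seed)
            residuals.append(np.linalg.norm(m.dyn_rhs(np.zeros(m.d_s), u_eq)))
        assert max(residuals) == 0.0

    def test_zero_weights_give_zero_rhs(self, scattered_dataset):
        m = make_model(scattered_dataset)
        for l in range(len(m.dyn.weights)):
            m.dyn.weights[l][:] = 0.0
            m.dyn.biases[l][:] = 0.0
        assert np.array_equal(m.dyn_rhs(np.ones(2), np.ones(2)), np.zeros(2))

    def test_doubling_dt_ref_halves_rhs(self, scattered_dataset, rng):
        m1 = make_model(scattered_dataset, dt_ref=1.0, seed=4)
        m2 = make_model(scattered_dataset, dt_ref=2.0, seed=4)
        s, u = rng.normal(size=2), rng.normal(size=2)
        assert np.allclose(m1.dyn_rhs(s, u), 2.0 * m2.dyn_rhs(s, u), rtol=1e-14)

    def test_non_finite_inputs_rejected(self, toy_model):
        with pytest.raises(ValueError, match="finite"):
            toy_model.dyn_rhs(np.array([np.nan, 0.0]), np.zeros(2))


class TestReconstruct:
    def test_dirichlet_returns_lift_exactly_on_masked_region(self, scattered_dataset, rng):
        lift = lambda X: np.column_stack([np.sin(X[:, 0])])
        mask = box_boundary_mask([[-1, 1]])
        boundary = np.array([[-1.0], [1.0]])
        for seed in range(20):
            m = make_model(
                scattered_dataset,
                seed=seed,
                dirichlet=DirichletConstraint(lift=lift, mask=mask),
            )
            out = m.reconstruct(np.tile(rng.normal(size=2), (2, 1)), np.zeros((2, 2)), boundary)
            assert np.array_equal(out, lift(boundary))

    def test_zero_weights_give_constant_center(self, scattered_dataset):
        m = make_model(scattered_dataset)
        for l in range(len(m.rec.weights)):
            m.rec.weights[l][:] = 0.0
            m.rec.biases[l][:] = 0.0
        out = m.reconstruct(np.zeros((3, 2)), np.zeros((3, 2)), np.array([[0.1], [0.5], [-0.9]]))
        assert np.allclose(out, m.stats.y.center, rtol=0, atol=0)

    def test_pure_function_bit_identical(self, toy_model, rng):
        s = rng.normal(size=(4, 2))
        x = rng.uniform(-1, 1, size=(4, 1))
        a = toy_model.reconstruct(s, np.zeros((4, 2)), x)
        b = toy_model.reconstruct(s, np.zeros((4, 2)), x)
        assert np.array_equal(a, b)

    def test_point_outside_bounding_box_rejected(self, toy_model):
        with pytest.raises(ValueError, match="bounding box"):
            toy_model.reconstruct(np.zeros(2), np.zeros(2), np.array([2.5]))

    def test_tail_compression_applied_as_final_layer(self, scattered_dataset, rng):
        m_plain = make_model(scattered_dataset, seed=8)
        m_tail = make_model(scattered_dataset, seed=8, beta=np.array([2.0]))
        s = rng.normal(size=(3, 2))
        u = np.zeros((3, 2))
        x = rng.uniform(-1, 1, size=(3, 1))
        raw = (m_plain.reconstruct(s, u, x) - m_plain.stats.y.center) / m_plain.stats.y.width
        expected = m_tail.stats.y.denormalize((raw**3 + 2.0 * raw) / 3.0)
        assert np.allclose(m_tail.reconstruct(s, u, x), expected, rtol=1e-14)


class TestParameterBudget:
    def test_cardiac_benchmark_configuration_parameter_count(self, rng):
        """The excitation-propagation configuration (12 latent states, two
        stimulus channels, width-8 dynamics net) has a parameter count fixed
        by the dense-layer formula; pinned as a regression."""
        from ldnet.nets import FCNN

        dyn = FCNN([12 + 2, 8, 12])
        assert dyn.n_params == 228
        rec = FCNN([12 + 1, 20, 20, 1])
        assert rec.n_params == (13 * 20 + 20) + (20 * 20 + 20) + (20 + 1)


class TestMask:
    def test_box_mask_vanishes_only_on_boundary(self):
        psi = box_boundary_mask([[0, 1], [0, 2]])
        edge = np.array([[0.0, 1.0], [1.0, 0.5], [0.3, 0.0], [0.7, 2.0]])
        interior = np.array([[0.5, 1.0], [0.01, 1.99]])
        assert np.all(psi(edge) == 0.0)
        assert np.all(psi(interior) > 0.0)
        assert psi(np.array([[0.5, 1.0]]))[0] == pytest.approx(1.0)


class TestCheckpoint:
    def test_round_trip_preserves_predictions(self, tmp_path, scattered_dataset, rng):
        m = make_model(scattered_dataset, rec_uses_u=True, u_eq=np.zeros(2), beta=np.array([1.5]))
        path = tmp_path / "ckpt.h5"
        save_checkpoint(m, path)
        m2 = load_checkpoint(path)
        s = rng.normal(size=(5, 2))
        u = rng.normal(size=(5, 2))
        x = rng.uniform(-1, 1, size=(5, 1))
        assert np.array_equal(m.reconstruct(s, u, x), m2.reconstruct(s, u, x))
        assert np.array_equal(m.dyn_rhs(s, u), m2.dyn_rhs(s, u))
        assert m2.dt == m.dt and m2.stats.dt_ref == m.stats.dt_ref

    def test_wrong_file_rejected(self, tmp_path):
        import h5py

        path = tmp_path / "x.h5"
        with h5py.File(path, "w") as f:
            f.attrs["schema"] = "something-else"
        with pytest.raises(ValueError, match="schema"):
            load_checkpoint(path)
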