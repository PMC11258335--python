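import numpy as np
import pytest

from ldnet.fom.ap import (
    DEFAULT_AMPLITUDE,
    APConfig,
    StimulusProtocol,
    generate_dataset_tc3,
    make_stimulus,
    sample_protocols,
    solve_ap_1d,
    solve_single_cell_reference,
)

# property checks run the marching scheme at a coarsened fixed step (still
# within the semi-implicit stability range) to keep runtimes modest; the
# single-cell oracle in the acceptance suite uses the fine default step.
COARSE = dict(dt=2e-5)


def single_site_protocol(amp=DEFAULT_AMPLITUDE, onset=0.5, dur=1.0, hw=0.02):
    return StimulusProtocol(L=1.0, impulses=(np.array([[onset, dur, amp]]), np.zeros((0, 3))), half_width=hw)


class TestStimulus:
    def test_zero_before_onset_and_between_sites(self):
        proto = single_site_protocol(onset=2.0)
        x = np.linspace(0, 1, 101)
        assert np.all(make_stimulus(proto, x, 1.0) == 0.0)
        mid = make_stimulus(proto, np.array([0.5]), 2.5)
        assert mid[0] == 0.0

    def test_amplitude_inside_window_at_site(self):
        proto = single_site_protocol(amp=0.7, onset=1.0, dur=2.0)
        assert make_stimulus(proto, np.array([0.25]), 1.5)[0] == 0.7
        assert make_stimulus(proto, np.array([0.25]), 3.5)[0] == 0.0

    def test_signal_encoding_has_two_channels(self):
        proto = single_site_protocol()
        sig = proto.to_signal(T=10.0)
        assert sig.d_u == 2
        assert sig.values[:, 1].max() == 0.0  # quiescent second site


class TestSolver:
    def test_rest_state_is_exact_equilibrium(self):
        cfg = APConfig(T=2.0, **COARSE)
        proto = StimulusProtocol(L=1.0)
        sol = solve_ap_1d(cfg, proto)
        assert np.all(sol.z == 0.0) and np.all(sol.w == 0.0)

    def test_space_clamped_solution_matches_stiff_ode_reference(self):
        # D -> 0 with a spatially uniform stimulus: every grid point follows
        # the single-cell kinetics; validated against an adaptive reference.
        cfg = APConfig(D=1e-14, T=30.0, **COARSE)
        imp = np.array([[1.0, 1.0, 0.36]])
        proto = StimulusProtocol(L=1.0, impulses=(imp, np.zeros((0, 3))), half_width=2.0)
        sol = solve_ap_1d(cfg, proto)
        t, z_ref, w_ref = solve_single_cell_reference(cfg, imp, T=30.0, t_eval=sol.times)
        rel = np.linalg.norm(sol.z[:, 50] - z_ref) / np.linalg.norm(z_ref)
        assert rel <= 1e-3

    def test_activation_time_increases_with_distance(self):
        cfg = APConfig(T=20.0, **COARSE)
        sol = solve_ap_1d(cfg, single_site_protocol(amp=0.9))
        act = np.full(sol.x.size, np.nan)
        for i in range(sol.x.size):
            idx = np.nonzero(sol.z[:, i] > 0.5)[0]
            if idx.size:
                act[i] = sol.times[idx[0]]
        site = 25  # x = L/4
        right = act[site:][np.isfinite(act[site:])]
        left = act[: site + 1][::-1]
        left = left[np.isfinite(left)]
        assert right.size > 20 and left.size > 10  # the wave propagated
        assert np.all(np.diff(right) >= 0)
        assert np.all(np.diff(left) >= 0)

    def test_colliding_waves_annihilate_without_reexcitation(self):
        cfg = APConfig(T=25.0, **COARSE)
        imp = np.array([[0.5, 1.0, 0.9]])
        proto = StimulusProtocol(L=1.0, impulses=(imp, imp.copy()), half_width=0.02)
        sol = solve_ap_1d(cfg, proto)
        mid = sol.z[:, sol.x.size // 2]
        upward = np.sum((mid[1:] > 0.5) & (mid[:-1] <= 0.5))
        assert upward == 1

    def test_grid_refinement_changes_activation_time_little(self):
        prot = single_site_protocol(amp=0.9)
        acts = []
        for h in (0.01, 0.005):
            cfg = APConfig(T=12.0, h=h, **COARSE)
            sol = solve_ap_1d(cfg, prot)
            i_mid = int(round(0.5 / h))
            idx = np.nonzero(sol.z[:, i_mid] > 0.5)[0]
            assert idx.size
            acts.append(sol.times[idx[0]])
        assert abs(acts[1] - acts[0]) / acts[0] < 0.02

    def test_explicit_mode_rejects_cfl_violation(self):
        cfg = APConfig(D=0.5, dt=1e-3, method="explicit")
        with pytest.raises(ValueError, match="h\\^2"):
            solve_ap_1d(cfg, single_site_protocol())

    def test_potential_stays_in_physiological_range(self):
        cfg = APConfig(T=20.0, **COARSE)
        sol = solve_ap_1d(cfg, single_site_protocol(amp=0.9))
        assert sol.z.min() >= -0.1 and sol.z.max() <= 1.2


class TestDatasetGeneration:
    def test_smoke_run_layout_and_equilibrium_sample(self):
        cfg = APConfig(T=5.0, dt=5e-5, n_obs_times=10)
        quiet = StimulusProtocol(L=1.0)
        active = single_site_protocol(amp=0.9, onset=0.5)
        train, test = generate_dataset_tc3(
            cfg, 2, 1, seed=0, protocols_train=[quiet, active], protocols_test=[active]
        )
        assert len(train) == 2 and len(test) == 1
        assert train.d_u == 2
        # the unstimulated sample stays identically at rest
        quiet_vals = np.concatenate(train.samples[0].observations.values)
        assert np.all(quiet_vals == 0.0)

    def test_protocol_sampling_deterministic(self):
        cfg = APConfig(T=10.0)
        a = sample_protocols(cfg, 3, seed=4)
        b = sample_protocols(cfg, 3, seed=4)
        for p, q in zip(a, b):
            assert np.array_equal(p.impulses[0], q.impulses[0])
            assert np.array_equal(p.impulses[1], q.impulses[1])
        for p in a:
            for site in range(2):
                assert np.all(p.impulses[site][:, 0] <= 0.6 * cfg.T)
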