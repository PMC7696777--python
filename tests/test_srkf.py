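"""Square-root filter core: factorizations, updates, oracle equivalence."""

import numpy as np
import pytest
from scipy.linalg import expm

from eegda import (ChannelSelection, EEGRecording, SqrtState, SynthSpec,
                   estimate_transition, generate_recording, givens_rotation,
                   givens_time_update, ldlt_sqrt, potter_update, run_filter)
from eegda.srkf import SqrtKalmanFilter, StateSpaceModel

from kf_oracle import kf_predict, kf_update, random_system


class TestLdltSqrt:
    def test_identity(self):
        np.testing.assert_allclose(ldlt_sqrt(np.eye(3)), np.eye(3))

    def test_two_by_two_reconstruction(self):
        P = np.array([[4.0, 2.0], [2.0, 3.0]])
        S = ldlt_sqrt(P)
        np.testing.assert_allclose(S @ S.T, P, atol=1e-12)

    def test_random_spd_reconstruction(self, rng):
        for _ in range(20):
            A = rng.standard_normal((5, 5))
            P = A @ A.T + 0.1 * np.eye(5)
            S = ldlt_sqrt(P)
            np.testing.assert_allclose(S @ S.T, P, atol=1e-10)

    def test_rank_deficient_psd(self):
        v = np.array([1.0, 2.0, -1.0])
        P = np.outer(v, v)  # rank-1 PSD
        S = ldlt_sqrt(P)
        np.testing.assert_allclose(S @ S.T, P, atol=1e-10)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            ldlt_sqrt(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_indefinite_rejected(self):
        with pytest.raises(ValueError, match="indefinite"):
            ldlt_sqrt(np.diag([1.0, -1.0]))


class TestGivensRotation:
    def test_pythagorean_triple(self):
        c, s, r = givens_rotation(3.0, 4.0)
        assert (c, s, r) == (0.6, -0.8, 5.0)
        G = np.array([[c, -s], [s, c]])
        np.testing.assert_allclose(G @ [3.0, 4.0], [5.0, 0.0], atol=1e-15)

    def test_zero_pair_is_identity(self):
        assert givens_rotation(0.0, 0.0) == (1.0, 0.0, 0.0)

    def test_zero_pivot_nonzero_eliminand(self):
        c, s, r = givens_rotation(0.0, 2.0)
        G = np.array([[c, -s], [s, c]])
        np.testing.assert_allclose(G @ [0.0, 2.0], [2.0, 0.0], atol=1e-15)


class TestGivensTimeUpdate:
    def test_no_dynamics_no_noise_preserves_covariance(self, rng):
        A = rng.standard_normal((4, 4))
        P = A @ A.T + np.eye(4)
        S = ldlt_sqrt(P)
        S_pred = givens_time_update(S, np.eye(4), np.zeros((4, 4)))
        np.testing.assert_allclose(S_pred @ S_pred.T, P, atol=1e-10)

    def test_matches_dense_propagation_on_random_instances(self, rng):
        for _ in range(100):
            m = rng.integers(2, 6)
            A = rng.standard_normal((m, m))
            P = A @ A.T + 0.5 * np.eye(m)
            F = rng.standard_normal((m, m)) * 0.5
            B = rng.standard_normal((m, m))
            Q = B @ B.T * 0.2
            S_pred = givens_time_update(ldlt_sqrt(P), F, Q)
            np.testing.assert_allclose(S_pred @ S_pred.T, F @ P @ F.T + Q,
                                       atol=1e-10)

    def test_accumulated_rotation_is_orthogonal(self, rng):
        m = 5
        A = rng.standard_normal((m, m))
        P = A @ A.T + np.eye(m)
        F = rng.standard_normal((m, m)) * 0.4
        Q = np.eye(m) * 0.3
        _, B = givens_time_update(ldlt_sqrt(P), F, Q, return_B=True)
        np.testing.assert_allclose(B @ B.T, np.eye(2 * m), atol=1e-12)

    def test_result_is_lower_triangular(self, rng):
        m = 4
        A = rng.standard_normal((m, m))
        S_pred = givens_time_update(ldlt_sqrt(A @ A.T + np.eye(m)),
                                    0.5 * np.eye(m), np.eye(m))
        np.testing.assert_allclose(S_pred, np.tril(S_pred), atol=1e-12)


class TestPotterUpdate:
    def test_zero_observation_matrix_leaves_state_unchanged(self, rng):
        m = 3
        A = rng.standard_normal((m, m))
        st = SqrtState(rng.standard_normal(m), ldlt_sqrt(A @ A.T + np.eye(m)))
        out = potter_update(st, np.array([1.0]), np.zeros((1, m)),
                            np.array([[0.5]]))
        np.testing.assert_allclose(out.x, st.x, atol=1e-12)
        np.testing.assert_allclose(out.P, st.P, atol=1e-12)

    def test_uninformative_measurement_limit(self, rng):
        m = 3
        A = rng.standard_normal((m, m))
        st = SqrtState(rng.standard_normal(m), ldlt_sqrt(A @ A.T + np.eye(m)))
        H = rng.standard_normal((2, m))
        out = potter_update(st, rng.standard_normal(2), H, 1e12 * np.eye(2))
        np.testing.assert_allclose(out.x, st.x, atol=1e-6)
        np.testing.assert_allclose(out.P, st.P, rtol=1e-6, atol=1e-6)

    def test_matches_dense_kalman_update(self, rng):
        for _ in range(100):
            m = int(rng.integers(2, 6))
            p = int(rng.integers(1, 4))
            F, Q, H, R, x0, P0 = random_system(rng, m, p)
            y = rng.standard_normal(p)
            out = potter_update(SqrtState(x0, ldlt_sqrt(P0)), y, H, R)
            x_kf, P_kf = kf_update(x0, P0, y, H, R)
            np.testing.assert_allclose(out.x, x_kf, atol=1e-8)
            np.testing.assert_allclose(out.P, P_kf, atol=1e-8)

    def test_correlated_noise_diagonalized(self, rng):
        m, p = 4, 3
        F, Q, H, _, x0, P0 = random_system(rng, m, p)
        B = rng.standard_normal((p, p))
        R = B @ B.T + 0.5 * np.eye(p)  # deliberately correlated
        y = rng.standard_normal(p)
        out = potter_update(SqrtState(x0, ldlt_sqrt(P0)), y, H, R)
        x_kf, P_kf = kf_update(x0, P0, y, H, R)
        np.testing.assert_allclose(out.x, x_kf, atol=1e-8)
        np.testing.assert_allclose(out.P, P_kf, atol=1e-8)

    def test_updated_covariance_stays_psd(self, rng):
        for _ in range(25):
            m, p = 4, 2
            F, Q, H, R, x0, P0 = random_system(rng, m, p)
            out = potter_update(SqrtState(x0, ldlt_sqrt(P0)),
                                rng.standard_normal(p), H, R * 1e-6)
            assert np.linalg.eigvalsh(out.P).min() >= -1e-12

    def test_non_psd_noise_rejected(self):
        st = SqrtState(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="positive semidefinite"):
            potter_update(st, np.zeros(1), np.ones((1, 2)),
                          np.array([[-1.0]]))

    def test_dimension_mismatch_rejected(self):
        st = SqrtState(np.zeros(2), np.eye(2))
        with pytest.raises(ValueError, match="rows of H"):
            potter_update(st, np.zeros(2), np.ones((1, 2)), np.eye(1))


class TestEstimateTransition:
    def test_recovers_matrix_exponential_of_linear_sde(self):
        rng = np.random.default_rng(2)
        fs, n = 128.0, 10000
        A = np.array([[-5.0, 2.0, 0.0], [0.0, -8.0, 3.0], [1.0, 0.0, -4.0]])
        Fd = expm(A / fs)
        x = np.zeros((3, n))
        x[:, 0] = rng.standard_normal(3)
        for t in range(1, n):
            x[:, t] = Fd @ x[:, t - 1] + 0.05 * rng.standard_normal(3)
        rec = EEGRecording(x, fs, ["a", "b", "c"])
        F = estimate_transition(rec, taylor_order=2)
        assert np.linalg.norm(F - Fd) / np.linalg.norm(Fd) < 0.1

    def test_order_zero_is_identity(self, small_recording):
        np.testing.assert_array_equal(
            estimate_transition(small_recording, taylor_order=0), np.eye(6))

    def test_white_noise_gives_decoupled_transition(self, rng):
        x = rng.standard_normal((4, 5000))
        rec = EEGRecording(x * 10, 128.0, list("abcd"))
        F = estimate_transition(rec, taylor_order=2)
        off = F - np.diag(np.diag(F))
        assert np.abs(off).max() < 0.05

    def test_spectral_radius_bounded(self, alpha_recording):
        F = estimate_transition(alpha_recording, taylor_order=2)
        assert np.abs(np.linalg.eigvals(F)).max() <= 1.0 + 1e-6


class TestStateSpaceModel:
    def test_dimension_checks(self):
        with pytest.raises(ValueError, match="Q must be"):
            StateSpaceModel(np.eye(3), np.eye(3), np.eye(2), np.eye(3))

    def test_asymmetric_noise_rejected(self):
        Q = np.eye(3)
        Q[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            StateSpaceModel(np.eye(3), np.eye(3), Q, np.eye(3))


def _planted_run(seed, duration=20.0, scenario="wc"):
    spec = SynthSpec(coupling=0.9, duration=duration, seed=seed)
    rec = generate_recording(spec)
    winners = tuple(rec.labels[i] for i in spec.coherent_triplet)
    sel = ChannelSelection(winners=winners, counts={}, tied=[])
    return rec, sel, run_filter(rec, sel, scenario)


class TestRunFilter:
    def test_all_scenario_tracks_input(self):
        rec, sel, _ = _planted_run(3, scenario="wc")
        run = run_filter(rec, sel, "all")
        assert run.tracking_correlation(rec.data).min() > 0.95

    def test_perfect_observation_limit_converges_to_signal(self, rng):
        # F = I, Q -> 0, near-noiseless observations of all channels:
        # the filtered states converge to the observations themselves.
        x = np.cumsum(rng.standard_normal((3, 512)), axis=1)
        rec = EEGRecording(x + 100, 128.0, list("abc"))
        run = run_filter(rec, None, "all", F=np.eye(3),
                         Q=np.eye(3) * 1e-12, R=np.zeros((3, 3)))
        np.testing.assert_allclose(run.filtered[:, 10:], rec.data[:, 10:],
                                   rtol=1e-8, atol=1e-8)

    def test_matches_dense_kf_over_full_trajectory(self, rng):
        from kf_oracle import kf_run
        m, p, n = 4, 2, 200
        F, Q, H, _, x0, P0 = random_system(rng, m, p)
        # row-selection H, matching the EEG observation structure
        Hsel = np.zeros((p, m))
        Hsel[0, 1] = Hsel[1, 3] = 1.0
        R = np.diag([0.3, 0.6])
        data = rng.standard_normal((m, n))
        ref, _ = kf_run(data, F, Q, Hsel, R, x0, P0)

        # run the jitted sweep directly against the oracle
        from eegda.srkf import _filter_sweep, ldlt_sqrt as lsq
        states, _ = _filter_sweep(data, F, np.ascontiguousarray(lsq(Q).T),
                                  np.array([1, 3], dtype=np.int64),
                                  np.array([0.3, 0.6]), x0, lsq(P0))
        np.testing.assert_allclose(states, ref, atol=1e-8)

    def test_wc_exceeds_nwc_in_band(self):
        from eegda import scenario_psd
        rec, sel, run_wc = _planted_run(5)
        run_nwc = run_filter(rec, sel, "nwc")
        wc = scenario_psd(run_wc).band_mean((8.0, 12.0))
        nwc = scenario_psd(run_nwc).band_mean((8.0, 12.0))
        assert wc > nwc

    def test_scenario_channel_sets_partition(self):
        rec, sel, run_wc = _planted_run(6)
        run_nwc = run_filter(rec, sel, "nwc")
        wc = set(run_wc.observed_idx.tolist())
        nwc = set(run_nwc.observed_idx.tolist())
        assert wc | nwc == set(range(rec.n_channels))
        assert wc & nwc == set()

    def test_wc_without_selection_rejected(self, small_recording):
        with pytest.raises(ValueError, match="selection"):
            run_filter(small_recording, None, "wc")

    def test_summary_reports_scenario_and_channels(self):
        _, _, run = _planted_run(7, duration=5.0)
        text = run.summary()
        assert "wc" in text and "F4" in text

    def test_save_round_trip(self, tmp_path):
        _, _, run = _planted_run(8, duration=5.0)
        csv_path, meta_path = run.save(tmp_path / "run_wc")
        assert csv_path.exists() and meta_path.exists()
        import json
        import pandas as pd
        frame = pd.read_csv(csv_path)
        assert frame.shape == run.filtered.T.shape
        meta = json.loads(meta_path.read_text())
        assert meta["scenario"] == "wc"

    def test_ensemble_mode_tracks_like_exact_filter(self):
        spec = SynthSpec(coupling=0.9, duration=5.0, seed=9)
        rec = generate_recording(spec)
        run = run_filter(rec, None, "all", ensemble_size=60, seed=1)
        assert run.tracking_correlation(rec.data).min() > 0.9
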