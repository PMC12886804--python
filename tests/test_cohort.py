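"""Synthetic-cohort generator: determinism, calibration and consistency."""

import numpy as np
import pytest

from hapticlab.cohort import (
    FS_EMG,
    FS_IMU,
    FS_POSE,
    SubjectParams,
    SynergyGroundTruth,
    TaskReference,
    generate_emg,
    generate_kinematics,
    generate_pose_trace,
    generate_trial,
    iter_session_trials,
    minimum_jerk_profile,
)


class TestPoseTrace:
    def test_determinism(self, short_reference):
        subj = SubjectParams()
        a = generate_pose_trace("GV", short_reference, subj, 5, repetitions=2)
        b = generate_pose_trace("GV", short_reference, subj, 5, repetitions=2)
        for xa, xb in zip(a[:4], b[:4]):
            np.testing.assert_array_equal(xa, xb)

    def test_nh_bias_endpoint(self):
        """Noise-free no-haptics run ends a guided phase at ref + bias."""
        ref = TaskReference(grasp_ref=0.5)
        subj = SubjectParams(
            nh_bias_grasp=0.1,
            sigma_grasp={"V": 0.0, "C": 0.0, "NH": 0.0},
            sigma_pronation={"V": 0.0, "C": 0.0, "NH": 0.0},
            tremor_grasp=0.0,
            tremor_pronation=0.0,
        )
        t, grasp, _, phase, _ = generate_pose_trace("NH", ref, subj, 1)
        end_of_phase3 = np.nonzero(phase == 3)[0][-1]
        assert grasp[end_of_phase3] == pytest.approx(0.6, abs=0.01)

    def test_grasp_ratio_clipped(self, short_reference):
        subj = SubjectParams(nh_bias_grasp=0.6)  # drives the target above 1
        _, grasp, _, _, _ = generate_pose_trace("NH",
                                                TaskReference(grasp_ref=0.8),
                                                subj, 3)
        assert grasp.min() >= 0.0 and grasp.max() <= 1.0

    def test_phase_labels_cycle(self, short_reference):
        _, _, _, phase, events = generate_pose_trace(
            "GC", short_reference, SubjectParams(), 2, repetitions=3
        )
        assert set(phase) == {1, 2, 3, 4, 5}
        assert len(events) == 3
        # labels are non-decreasing within a repetition and reset after it
        rep_len = int(round(short_reference.repetition_duration * FS_POSE))
        one = phase[:rep_len]
        assert np.all(np.diff(one) >= 0)
        assert phase[rep_len] == 1

    def test_generative_error_ordering(self, short_reference):
        """Mean |endpoint error| and endpoint SD obey V <= C <= NH (grasp)."""
        ref = short_reference
        endpoints = {}
        for cond in ("GV", "GC", "NH"):
            vals = []
            for s in range(12):
                _, grasp, _, phase, _ = generate_pose_trace(
                    cond, ref, SubjectParams(), 100 + s, repetitions=2
                )
                idx = np.nonzero(phase == 3)[0]
                vals.append(np.mean(grasp[idx[-20:]]))
            endpoints[cond] = np.asarray(vals)
        err = {c: np.mean(np.abs(v - ref.grasp_ref)) for c, v in endpoints.items()}
        sd = {c: np.std(v) for c, v in endpoints.items()}
        assert err["GV"] <= err["GC"] <= err["NH"]
        assert sd["GV"] <= sd["NH"] and sd["GC"] <= sd["NH"]

    def test_sigma_ordering_enforced(self):
        with pytest.raises(ValueError):
            SubjectParams(sigma_grasp={"V": 0.2, "C": 0.1, "NH": 0.05})


class TestKinematics:
    def test_minimum_jerk_peak_speed(self):
        t = np.linspace(0, 1, 2001)
        _, vel, _ = minimum_jerk_profile(0.3, 1.0, t)
        assert vel.max() == pytest.approx(1.875 * 0.3 / 1.0, rel=1e-6)

    def test_stationary_phase_zero_velocity(self, short_reference):
        subj = SubjectParams(imu_pos_noise=0.0, imu_angle_noise=0.0,
                             tremor_grasp=0.0, tremor_pronation=0.0)
        t, g, p, ph, _ = generate_pose_trace("NH", short_reference, subj, 4)
        t_imu, imu, ph_imu = generate_kinematics(t, p, short_reference, subj, 4)
        rest = ph_imu == 5
        # the rest phase has no transport: velocity identically zero
        assert np.allclose(imu["hand_vel"][rest], 0.0)

    def test_velocity_integral_matches_position(self, small_trial):
        dt = 1.0 / FS_IMU
        for seg in ("hand", "forearm", "upper_arm"):
            pos = small_trial.imu[f"{seg}_pos"]
            vel = small_trial.imu[f"{seg}_vel"]
            assert np.sum(vel) * dt == pytest.approx(pos[-1] - pos[0], abs=1e-6)

    def test_wrist_angle_follows_pronation(self, small_trial):
        wrist = small_trial.imu["wrist_pronosupination"]
        pron = np.interp(small_trial.imu_time, small_trial.pose_time,
                         small_trial.pronation)
        assert np.corrcoef(wrist, pron)[0, 1] > 0.99


class TestEmg:
    def test_zero_activation_yields_silence(self, short_reference):
        truth = SynergyGroundTruth(
            phase_levels=np.zeros((3, 5)), noise_sd=0.0, artifact_rate=0.0
        )
        t, g, p, ph, _ = generate_pose_trace("NH", short_reference,
                                             SubjectParams(), 9)
        _, raw, _, env, _ = generate_emg(t, short_reference, truth, 1.0, 9)
        assert np.allclose(raw, 0.0) and np.allclose(env, 0.0)

    def test_muscle_permutation_equivariance(self, short_reference):
        """Permuting the rows of the synergy basis permutes the generated
        envelopes identically (the raw carriers stay channel-bound)."""
        truth = SynergyGroundTruth(noise_sd=0.0, artifact_rate=0.0)
        perm = np.random.default_rng(0).permutation(truth.W_true.shape[0])
        truth_p = SynergyGroundTruth(
            W_true=truth.W_true[perm], noise_sd=0.0, artifact_rate=0.0
        )
        t, g, p, ph, _ = generate_pose_trace("NH", short_reference,
                                             SubjectParams(), 11)
        _, _, _, env_a, _ = generate_emg(t, short_reference, truth, 1.0, 123)
        _, _, _, env_b, _ = generate_emg(t, short_reference, truth_p, 1.0, 123)
        np.testing.assert_allclose(env_b, env_a[:, perm])

    def test_envelope_nonnegative(self, small_trial):
        assert small_trial.envelope_true.min() >= 0.0

    def test_pipeline_recovers_envelope_zero_noise(self):
        from hapticlab.metrics import preprocess_emg

        truth = SynergyGroundTruth(noise_sd=0.0, artifact_rate=0.0)
        trial = generate_trial("GC", 1, 1, 21,
                               truth=truth, repetitions=1, with_imu=False)
        env = preprocess_emg(trial.emg, 1.0)
        for j in range(env.envelopes.shape[1]):
            r = np.corrcoef(env.envelopes[:, j], trial.envelope_true[:, j])[0, 1]
            assert r > 0.99


class TestStreamAlignment:
    def test_phase_boundaries_aligned_across_rates(self, small_trial):
        """Boundaries land at the same wall-clock time in all three streams
        to within one sample of the coarsest (100 Hz) rate."""
        tol = 1.0 / FS_POSE
        for fs, phase in (
            (FS_POSE, small_trial.pose_phase),
            (FS_IMU, small_trial.imu_phase),
            (FS_EMG, small_trial.emg_phase),
        ):
            switches = np.nonzero(np.diff(phase))[0] + 1
            times = switches / fs
            expected = np.cumsum(small_trial.reference.phase_durations)[:-1]
            for t_b in times:
                assert np.min(np.abs(expected - t_b)) <= tol

    def test_streams_cover_same_span(self, small_trial):
        span = small_trial.reference.repetition_duration
        assert small_trial.pose_time[-1] == pytest.approx(span - 1 / FS_POSE)
        assert small_trial.imu_time[-1] == pytest.approx(span, abs=1.5 / FS_IMU)
        assert small_trial.emg_time[-1] == pytest.approx(span, abs=1.5 / FS_EMG)


class TestSession:
    def test_trial_counting_and_determinism(self, short_reference):
        kwargs = dict(
            ref=short_reference, repetitions=1, with_emg=False, with_imu=False
        )
        trials = list(iter_session_trials(3, 2, 7, **kwargs))
        assert len(trials) == 3 * 5 * 2
        again = list(iter_session_trials(3, 2, 7, **kwargs))
        for a, b in zip(trials, again):
            assert a.condition == b.condition and a.seed == b.seed
            np.testing.assert_array_equal(a.grasp, b.grasp)
        # per-subject condition orders are shuffles of the full set
        conds_s1 = [t.condition for t in trials if t.subject_id == 1][::2]
        assert sorted(conds_s1) == ["GC", "GV", "NH", "RC", "RV"]

    def test_refuses_nonempty_dir(self, tmp_path, short_reference):
        from hapticlab.cohort import generate_session

        (tmp_path / "leftover.txt").write_text("x")
        with pytest.raises(FileExistsError):
            generate_session(
                tmp_path, n_subjects=1, n_trials_per_condition=1,
                master_seed=0, ref=short_reference, repetitions=1,
                with_emg=False, with_imu=False,
            )
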