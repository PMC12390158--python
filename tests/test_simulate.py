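import numpy as np
import pytest

from spineimu import quat
from spineimu.simulate import (
    CohortSpec,
    EarthField,
    ParticipantParams,
    SensorParams,
    build_task_script,
    make_cohort,
    simulate_free_living,
    simulate_kinematics,
    synthesize_imu,
    write_cohort,
)
from spineimu.simulate.imu import BiasSpec, Disturbance, disturbed_sample_mask
from spineimu.simulate.protocol import PROTOCOL, TaskDef

RATE = 20.0


class TestBuildTaskScript:
    def test_default_twelve_tasks(self, script):
        assert len(script) == 12
        rom = [s for s in script.segments if s.task.kind == "rom"]
        timed = [s for s in script.segments if s.task.kind in ("static", "timed")]
        assert len(rom) == 9
        assert len(timed) == 3
        for s in timed:
            assert s.t_end - s.t_start == pytest.approx(10.0)
        for s in rom:
            assert len(s.reps) == 3

    def test_hops_precede_every_task(self, script):
        for seg in script.segments:
            assert len(seg.hop_times) == 5
            assert seg.hop_window[1] < seg.t_start

    def test_segments_ordered_non_overlapping(self, script):
        prev = -np.inf
        for seg in script.segments:
            assert seg.hop_window[0] >= prev
            prev = seg.t_end

    def test_zero_tasks_empty(self):
        s = build_task_script({"tasks": []})
        assert len(s) == 0
        assert s.duration_s == 0.0

    def test_deterministic(self):
        a = build_task_script(seed=5)
        b = build_task_script(seed=5)
        assert [s.t_start for s in a.segments] == [s.t_start for s in b.segments]

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            build_task_script({"static_duration_s": -1.0})
        bad = (TaskDef("x", "static", "flexext", duration_s=0.0),)
        with pytest.raises(ValueError):
            build_task_script({"tasks": bad})


class TestSimulateKinematics:
    def test_scripted_amplitude_by_construction(self, script, session_truth):
        axis_col = {"latflex": 0, "flexext": 1, "rot": 2}
        for seg in script.segments:
            if seg.task.kind != "rom":
                continue
            col = axis_col[seg.task.axis]
            for (rs, re) in seg.reps:
                sel = (session_truth.t >= rs) & (session_truth.t < re)
                a = session_truth.joint_deg[sel, col]
                assert a.max() - a.min() == pytest.approx(seg.task.amplitude_deg, abs=0.1)

    def test_zero_amplitude_constant_angle(self):
        tasks = tuple(
            TaskDef(td.task_id, td.kind, td.axis, td.sign, td.duration_s, td.n_reps, 0.0, "standing")
            for td in PROTOCOL
        )
        script = build_task_script({"tasks": tasks}, seed=0)
        truth = simulate_kinematics(
            script,
            ParticipantParams(sitting_flex_offset_deg=0.0, walking_wobble_deg=0.0),
            seed=0,
        )
        assert np.allclose(truth.joint_deg, truth.joint_deg[0], atol=1e-9)
        assert truth.joint_deg[0, 1] == pytest.approx(8.0)

    def test_seeded_amplitude_noise(self, script):
        p = ParticipantParams(amplitude_sd_deg=2.0)
        a = simulate_kinematics(script, p, seed=1)
        b = simulate_kinematics(script, p, seed=2)
        assert not np.allclose(a.joint_deg, b.joint_deg)
        # same task order regardless of seed
        assert [s.task_id for s in a.script.segments] == [s.task_id for s in b.script.segments]

    def test_orientation_consistency_invariant(self, session_truth):
        """Joint angle reconstructed from the orientations matches the
        stored truth to < 1e-6 deg."""
        recon = session_truth.joint_from_orientations()
        assert np.abs(recon - session_truth.joint_deg).max() < 1e-6

    def test_hops_visible_in_vertical_acceleration(self, session_truth):
        for seg in session_truth.script.segments:
            h = seg.hop_times[0]
            sel = (session_truth.t >= h - 0.075) & (session_truth.t <= h + 0.075)
            assert session_truth.lin_acc_earth[sel, 2].max() > 1.0

    def test_unit_norm_orientations(self, session_truth):
        assert np.allclose(np.linalg.norm(session_truth.q_upper, axis=1), 1.0, atol=1e-9)
        assert np.allclose(np.linalg.norm(session_truth.q_lower, axis=1), 1.0, atol=1e-9)


class TestSynthesizeImu:
    def test_stationary_gravity_only(self):
        truth = simulate_free_living(60.0, seed=0)
        # zero all motion: constant orientation, no lin acc
        truth.q_lower[:] = quat.identity()
        truth.q_upper[:] = quat.identity()
        truth.lin_acc_earth[:] = 0.0
        stream = synthesize_imu(truth, SensorParams(sensor_id="lower"))
        assert np.allclose(stream.acc_magnitude(), 1.0, atol=1e-12)
        assert np.allclose(stream.gyr, 0.0, atol=1e-9)

    def test_injected_constant_bias_recovered_in_mean(self):
        truth = simulate_free_living(120.0, seed=1)
        truth.q_lower[:] = quat.identity()
        truth.q_upper[:] = quat.identity()
        bias = BiasSpec(knot_t=np.array([0.0]), knot_values=np.array([[0.5, 0.0, 0.0]]))
        stream = synthesize_imu(
            truth, SensorParams(sensor_id="lower", bias=bias, noise_gyr_dps=0.1), seed=3
        )
        n = len(stream)
        ci = 3 * 0.1 / np.sqrt(n)
        assert stream.gyr[:, 0].mean() == pytest.approx(0.5, abs=ci)

    def test_field_step_scales_magnitude(self):
        truth = simulate_free_living(100.0, seed=2)
        d = Disturbance(30.0, 60.0, "step", 0.4)
        stream = synthesize_imu(truth, SensorParams(sensor_id="lower"), disturbances=[d])
        inside = (stream.t >= 30.0) & (stream.t < 60.0 - 1 / RATE)
        outside = stream.t < 29.0
        assert np.allclose(stream.mag_magnitude()[inside], 1.4, atol=1e-6)
        assert np.allclose(stream.mag_magnitude()[outside], 1.0, atol=1e-6)

    def test_disturbance_manifest_matches_deviating_samples(self):
        truth = simulate_free_living(100.0, seed=3)
        d = Disturbance(20.0, 50.0, "step", 0.4)
        stream = synthesize_imu(truth, SensorParams(sensor_id="lower"), disturbances=[d])
        deviating = np.abs(stream.mag_magnitude() - 1.0) > 0.01
        expected = disturbed_sample_mask(stream.t, "lower", [d])
        assert np.array_equal(deviating, expected)

    def test_timestamps_strictly_increasing_and_drift(self):
        truth = simulate_free_living(600.0, seed=4)
        skew = 0.0015
        stream = synthesize_imu(truth, SensorParams(sensor_id="upper", clock_skew_samples_per_s=skew))
        assert np.all(np.diff(stream.t) > 0)
        # total drift over T seconds = skew * T within one sample
        T = truth.t[-1] - truth.t[0]
        extra_samples = len(stream) - len(truth)
        assert abs(extra_samples - skew * T) <= 1.0

    def test_non_unit_mounting_rejected(self):
        with pytest.raises(ValueError):
            SensorParams(sensor_id="lower", mounting_quat=np.array([2.0, 0, 0, 0]))


class TestFreeLiving:
    def test_labels_cover_recording(self):
        truth = simulate_free_living(300.0, seed=5)
        assert len(truth.labels) == 300
        allowed = {"sitting", "standing", "stepping", "lying", "transport"}
        assert set(truth.labels.labels) <= allowed

    def test_deterministic(self):
        a = simulate_free_living(120.0, seed=6)
        b = simulate_free_living(120.0, seed=6)
        assert np.array_equal(a.joint_deg, b.joint_deg)
        assert list(a.labels.labels) == list(b.labels.labels)


class TestCohort:
    def test_single_participant_rejected(self):
        with pytest.raises(ValueError):
            make_cohort(CohortSpec(n_participants=1, day_duration_s=800))

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            CohortSpec(between_sd_deg=-1)
        with pytest.raises(ValueError):
            CohortSpec(disturbance_density=1.5)

    def test_population_icc_closed_forms(self):
        assert CohortSpec(between_sd_deg=10, within_sd_deg=0, day_duration_s=800).population_icc_a1() == 1.0
        spec = CohortSpec(between_sd_deg=1.0, within_sd_deg=1.0, day_duration_s=800)
        assert spec.population_icc_a1() == pytest.approx(0.5)
        assert spec.population_icc_ak(k=3) == pytest.approx(0.75)

    def test_cohort_files_byte_identical(self, tmp_path):
        spec = CohortSpec(n_participants=2, day_duration_s=800, seed=9, disturbance_density=0.05)
        for d in ("a", "b"):
            write_cohort(make_cohort(spec), tmp_path / d)
        files_a = sorted((tmp_path / "a").rglob("*.*"))
        files_b = sorted((tmp_path / "b").rglob("*.*"))
        assert [f.name for f in files_a] == [f.name for f in files_b]
        for fa, fb in zip(files_a, files_b):
            assert fa.read_bytes() == fb.read_bytes(), fa.name

    def test_recording_structure(self):
        spec = CohortSpec(n_participants=2, day_duration_s=800, seed=10, disturbance_density=0.1)
        cohort = make_cohort(spec)
        p = cohort.participants[0]
        assert set(p.recordings) == {"lab", "rw"}
        rw = p.recordings["rw"]
        assert len(rw.day_bounds) == 2
        assert {w.condition for w in rw.task_windows} == {"rw1", "rw2"}
        assert len(rw.task_windows) == 24
        lab = p.recordings["lab"]
        assert lab.flags is not None and len(lab.flags) == 24  # start+end per task
        for d in rw.disturbances:
            assert 0.0 <= d.start_s < d.end_s
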