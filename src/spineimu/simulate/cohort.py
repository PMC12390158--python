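"""Cohort-level simulation: lab session plus two real-world "days" per
participant, with known posture variance components, clock skews, gyro
bias drift, mounting offsets and magnetic disturbances.

Starting postures follow a two-way random-effects model: participant
neutral postures are drawn from a between-participant distribution and
per-condition offsets from a within-participant distribution, so the
population ICC of true starting postures is known analytically from the
spec variances.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ..core import ActivityLabels, SensorStream, TaskWindow
from .. import io as sio
from .. import quat
from .imu import BiasSpec, Disturbance, EarthField, SensorParams, synthesize_imu
from .kinematics import (
    GroundTruth,
    ParticipantParams,
    concat_truth,
    simulate_free_living,
    simulate_kinematics,
)
from .protocol import PROTOCOL, TaskScript, build_task_script

SPINE_SENSORS = ("upper", "lower")
ALL_SENSORS = ("upper", "lower", "thigh")


@dataclass
class CohortSpec:
    """Parameters of a simulated cohort (desk-scale defaults)."""

    n_participants: int = 2
    between_sd_deg: float = 8.0  # between-participant posture s.d.
    within_sd_deg: float = 3.0  # within-participant between-condition s.d.
    task_noise_sd_deg: float = 1.0  # rep-level execution noise
    mounting_sd_deg: float = 3.0  # per-axis mounting-offset s.d. per sensor set
    clock_skew_range: float = 0.002  # samples/s, uniform +/- range
    bias_drift_dps: float = 0.3  # gyro-bias random-walk step per knot
    disturbance_density: float = 0.1  # target corrupted fraction of rw time
    seed: int = 0
    rate_hz: float = 20.0
    day_duration_s: float = 1200.0
    n_days: int = 2
    lab_filler_s: float = 90.0
    redraw_mounting_per_day: bool = False
    noise_acc_g: float = 0.01
    noise_gyr_dps: float = 0.2
    noise_mag: float = 0.01
    earth_inclination_deg: float = -60.0
    neutral_mean_deg: float = 8.0
    # stable per-participant "postural style" (constant across conditions):
    # keeps between-participant variance alive after per-recording
    # reference normalization, as in real cohorts
    style_sitting_sd_deg: float = 5.0
    style_amplitude_sd: float = 0.2

    def __post_init__(self):
        for name in ("between_sd_deg", "within_sd_deg", "task_noise_sd_deg", "mounting_sd_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.disturbance_density <= 1.0:
            raise ValueError("disturbance density must be in [0, 1]")
        if self.day_duration_s < 700:
            raise ValueError("day duration too short to hold a task session plus filler")

    def population_icc_a1(self) -> float:
        b, w = self.between_sd_deg**2, self.within_sd_deg**2
        return b / (b + w) if (b + w) else float("nan")

    def population_icc_ak(self, k: int | None = None) -> float:
        k = k or (1 + self.n_days)
        b, w = self.between_sd_deg**2, self.within_sd_deg**2
        return b / (b + w / k) if b or w else float("nan")


@dataclass
class Recording:
    rec_id: str  # 'lab' | 'rw'
    streams: dict[str, SensorStream]
    labels: ActivityLabels
    truth: GroundTruth
    task_windows: list[TaskWindow]
    disturbances: list[Disturbance] = field(default_factory=list)
    flags: pd.DataFrame | None = None
    day_bounds: list[tuple[float, float]] = field(default_factory=list)
    sensor_params: dict[str, SensorParams] = field(default_factory=dict)
    mounting: dict = field(default_factory=dict)  # (set/day) -> sensor -> quat list


@dataclass
class Participant:
    pid: str
    neutral_deg: np.ndarray
    condition_offsets: dict[str, float]
    recordings: dict[str, Recording]


@dataclass
class Cohort:
    spec: CohortSpec
    participants: list[Participant]
    earth: EarthField

    @property
    def analytic(self) -> dict:
        return {
            "population_icc_a1": self.spec.population_icc_a1(),
            "population_icc_ak": self.spec.population_icc_ak(),
            "k_conditions": 1 + self.spec.n_days,
        }


def _mounting_quat(rng: np.random.Generator, sd_deg: float) -> np.ndarray:
    rv = np.radians(rng.normal(0.0, sd_deg, 3))
    return quat.from_rotvec(rv)


def _bias_spec(rng: np.random.Generator, duration_s: float, drift_dps: float,
               knot_interval_s: float = 600.0) -> BiasSpec:
    kt = np.arange(0.0, duration_s + knot_interval_s, knot_interval_s)
    steps = rng.normal(0.0, drift_dps, (kt.size, 3))
    steps[0] = rng.normal(0.0, 0.3, 3)
    return BiasSpec(knot_t=kt, knot_values=np.cumsum(steps, axis=0))


def _schedule_disturbances(
    rng: np.random.Generator, t0: float, t1: float, density: float
) -> list[Disturbance]:
    if density <= 0:
        return []
    total = (t1 - t0) * density
    covered = 0.0
    out: list[Disturbance] = []
    occupied: list[tuple[float, float]] = []
    attempts = 0
    while covered < total and attempts < 2000:
        attempts += 1
        dur = float(np.clip(rng.lognormal(np.log(60.0), 0.8), 10.0, 600.0))
        dur = min(dur, total - covered + 10.0)
        start = float(rng.uniform(t0, t1 - dur))
        if any(start < e + 5.0 and start + dur > s - 5.0 for s, e in occupied):
            continue
        kind = rng.choice(["step", "tilt", "ramp"], p=[0.6, 0.25, 0.15])
        if kind == "step":
            magnitude = float(rng.uniform(0.35, 0.7) * rng.choice([-1, 1]))
        elif kind == "ramp":
            magnitude = float(rng.uniform(0.4, 0.7))
        else:
            # tilt toward the horizontal: tilting past vertical folds the
            # dip angle back and can evade the 30 degree inclination rule
            magnitude = float(rng.uniform(35.0, 60.0))
        scope_draw = rng.random()
        sensors: tuple[str, ...] | str
        if scope_draw < 0.7:
            sensors = "all"
        elif scope_draw < 0.85:
            sensors = ("upper",)
        else:
            sensors = ("lower",)
        out.append(Disturbance(start_s=start, end_s=start + dur, kind=kind,
                               magnitude=magnitude, sensors=sensors))
        occupied.append((start, start + dur))
        covered += dur
    out.sort(key=lambda d: d.start_s)
    return out


def _guarded_labels(
    duration_s: float,
    rng: np.random.Generator,
    guard_head_s: float = 0.0,
    guard_tail_s: float = 0.0,
) -> ActivityLabels:
    from .kinematics import _markov_labels

    labels = _markov_labels(int(round(duration_s)), rng)
    lab = labels.labels
    n = lab.size
    head = min(n, int(round(guard_head_s)))
    tail = min(n, int(round(guard_tail_s)))
    for sl in (slice(0, head), slice(n - tail, n) if tail else slice(0, 0)):
        lab[sl] = np.where(lab[sl] == "transport", "sitting", lab[sl])
    return ActivityLabels(t=labels.t, labels=lab)


def _windows_from_script(script: TaskScript, condition: str) -> list[TaskWindow]:
    return [
        TaskWindow(
            task_id=seg.task_id,
            condition=condition,
            start_s=seg.t_start,
            end_s=seg.t_end,
            reps=list(seg.reps),
            provenance="manual",
        )
        for seg in script.segments
    ]


def _mounted_truth(truth: GroundTruth, mounts: list[dict[str, np.ndarray]],
                   day_bounds: list[tuple[float, float]]) -> GroundTruth:
    """Compose (possibly per-day) mounting offsets into the segment
    orientations that the sensors will actually report."""
    q_upper = truth.q_upper.copy()
    q_lower = truth.q_lower.copy()
    q_thigh = truth.q_thigh.copy() if truth.q_thigh is not None else None
    for (b0, b1), m in zip(day_bounds, mounts):
        sel = (truth.t >= b0) & (truth.t < b1)
        q_upper[sel] = quat.qmul(q_upper[sel], m["upper"])
        q_lower[sel] = quat.qmul(q_lower[sel], m["lower"])
        if q_thigh is not None:
            q_thigh[sel] = quat.qmul(q_thigh[sel], m["thigh"])
    return dataclasses.replace(truth, q_upper=q_upper, q_lower=q_lower, q_thigh=q_thigh)


def _simulate_recording(
    spec: CohortSpec,
    pp: ParticipantParams,
    rec_id: str,
    rng: np.random.Generator,
    session_offsets: dict[str, float],
    earth: EarthField,
) -> Recording:
    rate = spec.rate_hz
    if rec_id == "lab":
        conditions = ["lab"]
    else:
        conditions = [f"rw{d + 1}" for d in range(spec.n_days)]

    parts: list[GroundTruth] = []
    day_bounds: list[tuple[float, float]] = []
    offset = 0.0
    scripts: list[tuple[str, float]] = []  # (condition, local t0 within its part)
    for cond in conditions:
        p_cond = dataclasses.replace(
            pp,
            neutral_deg=pp.neutral_deg + np.array([0.0, session_offsets[cond], 0.0]),
            amplitude_sd_deg=spec.task_noise_sd_deg,
        )
        script = build_task_script(seed=int(rng.integers(2**31)))
        session_truth = simulate_kinematics(
            script, p_cond, seed=int(rng.integers(2**31)), rate_hz=rate
        )
        session_dur = len(session_truth) / rate
        if rec_id == "lab":
            pre = post = spec.lab_filler_s
        else:
            pre = round(0.4 * (spec.day_duration_s - session_dur))
            post = spec.day_duration_s - session_dur - pre
        # keep seated transport away from the task session so its +/- 5 min
        # exclusion pad cannot swallow the standardized tasks at desk scale
        guard = 330.0
        pre_truth = simulate_free_living(
            pre, p_cond, seed=int(rng.integers(2**31)), rate_hz=rate,
            labels=_guarded_labels(pre, rng, guard_tail_s=guard),
        )
        post_truth = simulate_free_living(
            post, p_cond, seed=int(rng.integers(2**31)), rate_hz=rate,
            labels=_guarded_labels(post, rng, guard_head_s=guard),
        )
        parts += [pre_truth, session_truth, post_truth]
        scripts.append((cond, offset + pre))
        day_len = (len(pre_truth) + len(session_truth) + len(post_truth)) / rate
        day_bounds.append((offset, offset + day_len))
        offset += day_len

    truth = concat_truth(parts)
    # locate shifted scripts in the concatenated clock
    task_windows: list[TaskWindow] = []
    cond_scripts: list[tuple[str, TaskScript]] = []
    for (cond, t_local), script in zip(scripts, getattr(truth, "scripts", [])):
        task_windows += _windows_from_script(script, cond)
        cond_scripts.append((cond, script))

    duration = len(truth) / rate
    disturbances = (
        _schedule_disturbances(rng, 0.0, duration, spec.disturbance_density)
        if rec_id == "rw"
        else []
    )

    # mounting: one set per recording, optionally re-drawn each day
    n_sets = len(day_bounds) if (rec_id == "rw" and spec.redraw_mounting_per_day) else 1
    mounts = []
    for _ in range(n_sets):
        mounts.append({s: _mounting_quat(rng, spec.mounting_sd_deg) for s in ALL_SENSORS})
    bounds_for_mount = day_bounds if n_sets > 1 else [(0.0, duration)]
    sensor_truth = _mounted_truth(truth, mounts, bounds_for_mount)

    streams = {}
    sensor_params = {}
    for sid in ALL_SENSORS:
        skew = 0.0 if sid == "lower" else float(rng.uniform(-spec.clock_skew_range, spec.clock_skew_range))
        sp = SensorParams(
            sensor_id=sid,
            noise_acc_g=spec.noise_acc_g,
            noise_gyr_dps=spec.noise_gyr_dps,
            noise_mag=spec.noise_mag,
            clock_skew_samples_per_s=skew,
            bias=_bias_spec(rng, duration, spec.bias_drift_dps),
        )
        sensor_params[sid] = sp
        streams[sid] = synthesize_imu(
            sensor_truth, sp, earth=earth, disturbances=disturbances,
            seed=int(rng.integers(2**31)),
        )

    flags = None
    if rec_id == "lab":
        rows = []
        for w in task_windows:
            rows.append({"event_time_s": w.start_s, "flag_type": "start"})
            rows.append({"event_time_s": w.end_s, "flag_type": "end"})
        flags = pd.DataFrame(rows)

    mounting_record = {
        f"set{k}": {s: m[s].tolist() for s in ALL_SENSORS} for k, m in enumerate(mounts)
    }
    return Recording(
        rec_id=rec_id,
        streams=streams,
        labels=truth.labels,
        truth=truth,
        task_windows=task_windows,
        disturbances=disturbances,
        flags=flags,
        day_bounds=day_bounds,
        sensor_params=sensor_params,
        mounting=mounting_record,
    )


def make_cohort(spec: CohortSpec) -> Cohort:
    """Draw and simulate a full cohort; deterministic given ``spec.seed``."""
    if spec.n_participants < 2:
        raise ValueError("an ICC-bearing cohort needs at least 2 participants")
    root = np.random.default_rng(spec.seed)
    earth = EarthField(magnitude=1.0, inclination_deg=spec.earth_inclination_deg)
    conditions = ["lab"] + [f"rw{d + 1}" for d in range(spec.n_days)]
    participants = []
    for i in range(spec.n_participants):
        rng = np.random.default_rng(root.integers(2**63))
        neutral_flex = spec.neutral_mean_deg + rng.normal(0.0, spec.between_sd_deg)
        offsets = {c: float(rng.normal(0.0, spec.within_sd_deg)) for c in conditions}
        amp_scale = max(0.3, 1.0 + rng.normal(0.0, spec.style_amplitude_sd))
        from .protocol import PROTOCOL as _PROTOCOL

        pp = ParticipantParams(
            neutral_deg=np.array([0.0, neutral_flex, 0.0]),
            amplitude_sd_deg=spec.task_noise_sd_deg,
            heading_deg=float(rng.uniform(-180, 180)),
            sitting_flex_offset_deg=12.0 + rng.normal(0.0, spec.style_sitting_sd_deg),
            amplitudes_deg={td.task_id: td.amplitude_deg * amp_scale for td in _PROTOCOL},
        )
        recs = {
            "lab": _simulate_recording(spec, pp, "lab", rng, offsets, earth),
            "rw": _simulate_recording(spec, pp, "rw", rng, offsets, earth),
        }
        participants.append(
            Participant(
                pid=f"P{i + 1:02d}",
                neutral_deg=pp.neutral_deg,
                condition_offsets=offsets,
                recordings=recs,
            )
        )
    return Cohort(spec=spec, participants=participants, earth=earth)


def _truth_manifest(p: Participant, rec: Recording) -> dict:
    return {
        "neutral_deg": p.neutral_deg.tolist(),
        "condition_offsets": p.condition_offsets,
        "day_bounds": [list(b) for b in rec.day_bounds],
        "mounting": rec.mounting,
        "clock_skew_samples_per_s": {
            sid: sp.clock_skew_samples_per_s for sid, sp in rec.sensor_params.items()
        },
        "gyro_bias": {sid: sp.bias.to_dict() for sid, sp in rec.sensor_params.items()},
        "disturbances": [d.to_dict() for d in rec.disturbances],
        "task_windows": [
            {
                "task_id": w.task_id,
                "condition": w.condition,
                "start_s": w.start_s,
                "end_s": w.end_s,
                "reps": [list(r) for r in w.reps],
            }
            for w in rec.task_windows
        ],
    }


def write_cohort(cohort: Cohort, out_dir) -> list[Path]:
    """Write raw files plus truth manifests; returns all written paths."""
    out_dir = Path(out_dir)
    written: list[Path] = []
    for p in cohort.participants:
        for rec_id, rec in p.recordings.items():
            base = out_dir / p.pid / rec_id
            for sid, stream in rec.streams.items():
                written.append(sio.write_sensor_table(stream, base / f"{sid}.csv"))
            written.append(sio.write_labels(rec.labels, base / "labels.csv"))
            if rec.flags is not None:
                base.mkdir(parents=True, exist_ok=True)
                rec.flags.to_csv(base / "flags.csv", index=False, float_format="%.8g")
                written.append(base / "flags.csv")
            joint = pd.DataFrame(
                np.column_stack([rec.truth.t, rec.truth.joint_deg]),
                columns=sio.JOINT_COLUMNS,
            )
            joint.to_csv(base / "truth_joint.csv", index=False, float_format="%.8g")
            written.append(base / "truth_joint.csv")
            written.append(sio.write_json(_truth_manifest(p, rec), base / "truth.json"))
    manifest = {
        "spec": dataclasses.asdict(cohort.spec),
        "participants": [p.pid for p in cohort.participants],
        "analytic": cohort.analytic,
        "earth": {"magnitude": cohort.earth.magnitude, "inclination_deg": cohort.earth.inclination_deg},
    }
    written.append(sio.write_json(manifest, out_dir / "manifest.json"))
    return written
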