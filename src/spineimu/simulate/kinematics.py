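"""Ground-truth kinematics: scripted task trajectories and free-living
filler.

Joint-angle trajectories are built from minimum-jerk pulses on top of a
smooth posture baseline, so every scripted repetition has an exactly known
amplitude.  The two spine-segment orientations are constructed to be
consistent with the joint angle at every sample by definition
(``q_upper = q_lower (x) q_joint``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from ..core import ACTIVITIES, ActivityLabels
from .. import quat
from .protocol import (
    HOP_DURATION_S,
    HOP_PEAK_G,
    MOVE_S,
    TaskScript,
)


@dataclass
class ParticipantParams:
    """Per-participant kinematic parameters.

    ``neutral_deg`` is the standing neutral joint angle (latflex, flexext,
    rot); ``amplitude_sd_deg`` is the rep-to-rep execution noise on ROM
    amplitudes; ``amplitudes_deg`` overrides per-task mean amplitudes.
    """

    neutral_deg: np.ndarray = field(default_factory=lambda: np.array([0.0, 8.0, 0.0]))
    amplitudes_deg: dict = field(default_factory=dict)
    amplitude_sd_deg: float = 0.0
    sitting_flex_offset_deg: float = 12.0
    lower_share: float = 0.3  # fraction of joint motion taken up by the pelvis segment
    heading_deg: float = 0.0
    walking_wobble_deg: float = 3.0

    def __post_init__(self):
        self.neutral_deg = np.asarray(self.neutral_deg, dtype=float).reshape(3)
        if self.amplitude_sd_deg < 0:
            raise ValueError("amplitude s.d. must be >= 0")


@dataclass
class GroundTruth:
    """Everything downstream stages are later asked to recover."""

    t: np.ndarray
    joint_deg: np.ndarray  # (n, 3) latflex, flexext, rot
    q_lower: np.ndarray  # (n, 4) lower spine segment -> Earth
    q_upper: np.ndarray
    lin_acc_earth: np.ndarray  # (n, 3) g, shared trunk linear acceleration
    labels: ActivityLabels
    rate_hz: float = 20.0
    script: TaskScript | None = None
    q_thigh: np.ndarray | None = None

    def __len__(self) -> int:
        return self.t.size

    def joint_from_orientations(self) -> np.ndarray:
        """Recompute joint angles from the stored orientations (consistency
        oracle)."""
        qj = quat.qmul(quat.qconj(self.q_lower), self.q_upper)
        e = quat.to_euler_zyx(qj)
        return np.column_stack([e[:, 2], e[:, 1], e[:, 0]])


def minimum_jerk(u: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile on u in [0, 1]."""
    u = np.clip(u, 0.0, 1.0)
    return 10 * u**3 - 15 * u**4 + 6 * u**5


def _rom_pulse(t: np.ndarray, start: float, end: float, move_s: float) -> np.ndarray:
    """Unit-amplitude out-hold-back profile over a repetition window."""
    out = np.zeros_like(t)
    sel = (t >= start) & (t <= end)
    ts = t[sel]
    rise = minimum_jerk((ts - start) / move_s)
    fall = minimum_jerk((end - ts) / move_s)
    out[sel] = np.minimum(rise, fall)
    return out


def _hop_acc(t: np.ndarray, hop_times: list[float], peak_g: float = HOP_PEAK_G) -> np.ndarray:
    a = np.zeros_like(t)
    half = HOP_DURATION_S / 2
    for h in hop_times:
        sel = (t >= h - half) & (t <= h + half)
        a[sel] += peak_g * np.sin(np.pi * (t[sel] - (h - half)) / HOP_DURATION_S)
    return a


def _orientations(
    joint_deg: np.ndarray, params: ParticipantParams
) -> tuple[np.ndarray, np.ndarray]:
    dev = joint_deg - joint_deg[0]
    pitch_lower = params.lower_share * dev[:, 1]
    roll_lower = params.lower_share * dev[:, 0]
    heading = np.full(len(joint_deg), params.heading_deg)
    q_lower = quat.from_euler_zyx(heading, pitch_lower, roll_lower)
    q_joint = quat.from_euler_zyx(joint_deg[:, 2], joint_deg[:, 1], joint_deg[:, 0])
    q_upper = quat.qmul(q_lower, q_joint)
    return q_lower, q_upper


def _thigh_orientation(labels_per_sample: np.ndarray, rate: float) -> np.ndarray:
    pitch_target = np.zeros(labels_per_sample.size)
    for act, pitch in (("sitting", 80.0), ("transport", 80.0), ("lying", 85.0)):
        pitch_target[labels_per_sample == act] = pitch
    pitch = gaussian_filter1d(pitch_target, sigma=max(1.0, rate))
    return quat.from_euler_zyx(np.zeros_like(pitch), pitch, np.zeros_like(pitch))


def _labels_from_script(script: TaskScript, n_seconds: int, t0: float) -> ActivityLabels:
    lab = np.full(n_seconds, "standing", dtype=object)
    secs = t0 + np.arange(n_seconds, dtype=float)
    for seg in script.segments:
        sel = (secs >= seg.t_start) & (secs < seg.t_end)
        lab[sel] = seg.task.activity
    return ActivityLabels(t=secs, labels=lab)


def simulate_kinematics(
    script: TaskScript,
    params: ParticipantParams | None = None,
    seed: int = 0,
    rate_hz: float = 20.0,
    duration_s: float | None = None,
) -> GroundTruth:
    """Realize one scripted session as smooth ground-truth kinematics."""
    params = params or ParticipantParams()
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = float(np.ceil(script.duration_s + 2.0))
    n = int(round(duration_s * rate_hz))
    t = script.t0 + np.arange(n) / rate_hz

    joint = np.tile(params.neutral_deg, (n, 1))

    # posture baseline: sitting tasks shift the flexion baseline; the
    # posture persists until the next task's hop burst so transitions fall
    # outside repetition windows, then the whole track is smoothed
    baseline_shift = np.zeros(n)
    segs = script.segments
    for k, seg in enumerate(segs):
        if seg.task.activity in ("sitting", "transport"):
            until = segs[k + 1].hop_window[0] - 1.0 if k + 1 < len(segs) else seg.t_end + 1.0
            sel = (t >= seg.hop_window[0] - 1.0) & (t < until)
            baseline_shift[sel] = params.sitting_flex_offset_deg
    baseline_shift = gaussian_filter1d(baseline_shift, sigma=0.6 * rate_hz)
    joint[:, 1] += baseline_shift

    axis_index = {"latflex": 0, "flexext": 1, "rot": 2}
    for seg in script.segments:
        td = seg.task
        if td.kind == "rom":
            amp_mean = params.amplitudes_deg.get(td.task_id, td.amplitude_deg)
            j = axis_index[td.axis]
            for (rs, re) in seg.reps:
                amp = amp_mean + rng.normal(0.0, params.amplitude_sd_deg)
                joint[:, j] += td.sign * amp * _rom_pulse(t, rs, re, MOVE_S)
        elif td.task_id == "walking":
            sel = (t >= seg.t_start) & (t < seg.t_end)
            phase = 2 * np.pi * 1.5 * (t[sel] - seg.t_start)
            ramp = np.minimum(1.0, (t[sel] - seg.t_start) / 1.0) * np.minimum(
                1.0, (seg.t_end - t[sel]) / 1.0
            )
            joint[sel, 1] += params.walking_wobble_deg * np.sin(phase) * ramp

    lin_acc = np.zeros((n, 3))
    for seg in script.segments:
        lin_acc[:, 2] += _hop_acc(t, seg.hop_times)
        if seg.task.task_id == "walking":
            sel = (t >= seg.t_start) & (t < seg.t_end)
            bob = rng.standard_normal(int(sel.sum()))
            lin_acc[sel, 2] += 0.2 * gaussian_filter1d(bob, sigma=1.5)

    q_lower, q_upper = _orientations(joint, params)
    labels = _labels_from_script(script, int(np.ceil(duration_s)), float(np.floor(t[0])))
    from ..segmentation import upsample_labels

    per_sample = upsample_labels(labels, t, rate_hz)
    return GroundTruth(
        t=t,
        joint_deg=joint,
        q_lower=q_lower,
        q_upper=q_upper,
        lin_acc_earth=lin_acc,
        labels=labels,
        rate_hz=rate_hz,
        script=script,
        q_thigh=_thigh_orientation(per_sample, rate_hz),
    )


#: per-activity flexion target (deg relative to neutral) and vertical
#: movement-noise amplitude (g) for free-living filler
_ACTIVITY_POSTURE = {
    "sitting": 15.0,
    "standing": 0.0,
    "stepping": 3.0,
    "lying": -25.0,
    "transport": 15.0,
}
_ACTIVITY_ACC = {
    "sitting": 0.01,
    "standing": 0.01,
    "stepping": 0.25,
    "lying": 0.003,
    "transport": 0.06,
}


def _markov_labels(n_seconds: int, rng: np.random.Generator, t0: float = 0.0,
                   stay: float = 0.995) -> ActivityLabels:
    acts = list(ACTIVITIES)
    weights = np.array([0.35, 0.25, 0.20, 0.10, 0.10])
    lab = np.empty(n_seconds, dtype=object)
    state = rng.choice(len(acts), p=weights / weights.sum())
    for i in range(n_seconds):
        lab[i] = acts[state]
        if rng.random() > stay:
            others = [k for k in range(len(acts)) if k != state]
            w = weights[others]
            state = int(rng.choice(others, p=w / w.sum()))
    return ActivityLabels(t=t0 + np.arange(n_seconds, dtype=float), labels=lab)


def simulate_free_living(
    duration_s: float,
    params: ParticipantParams | None = None,
    seed: int = 0,
    rate_hz: float = 20.0,
    labels: ActivityLabels | None = None,
) -> GroundTruth:
    """Unscripted filler: a Markov chain over the five activity labels with
    per-activity posture targets and movement-noise levels."""
    params = params or ParticipantParams()
    rng = np.random.default_rng(seed)
    n_seconds = int(round(duration_s))
    n = int(round(duration_s * rate_hz))
    t = np.arange(n) / rate_hz
    if labels is None:
        labels = _markov_labels(n_seconds, rng)
    from ..segmentation import upsample_labels

    per_sample = upsample_labels(labels, t, rate_hz)

    flex_target = np.array([_ACTIVITY_POSTURE.get(a, 0.0) for a in per_sample])
    acc_amp = np.array([_ACTIVITY_ACC.get(a, 0.01) for a in per_sample])
    flex = gaussian_filter1d(flex_target, sigma=1.5 * rate_hz)
    # slow postural wander, a few degrees over minutes
    wander = gaussian_filter1d(rng.standard_normal(n), sigma=30 * rate_hz)
    wander *= 3.0 / max(1e-9, wander.std())
    joint = np.tile(params.neutral_deg, (n, 1))
    joint[:, 1] += flex + wander
    joint[:, 0] += 0.3 * gaussian_filter1d(rng.standard_normal(n), sigma=20 * rate_hz) / max(
        1e-9, 1.0
    )

    lin_acc = np.zeros((n, 3))
    lin_acc[:, 2] = acc_amp * gaussian_filter1d(rng.standard_normal(n), sigma=1.5)

    q_lower, q_upper = _orientations(joint, params)
    return GroundTruth(
        t=t,
        joint_deg=joint,
        q_lower=q_lower,
        q_upper=q_upper,
        lin_acc_earth=lin_acc,
        labels=labels,
        rate_hz=rate_hz,
        script=None,
        q_thigh=_thigh_orientation(per_sample, rate_hz),
    )


def concat_truth(parts: list[GroundTruth]) -> GroundTruth:
    """Chain ground-truth segments end to end on one continuous clock."""
    if not parts:
        raise ValueError("nothing to concatenate")
    rate = parts[0].rate_hz
    offset = 0.0
    ts, joints, qls, qus, qts, accs = [], [], [], [], [], []
    lab_t, lab_v = [], []
    scripts = []
    for p in parts:
        if p.rate_hz != rate:
            raise ValueError("all parts must share one rate")
        shift = offset - p.t[0]
        ts.append(p.t + shift)
        joints.append(p.joint_deg)
        qls.append(p.q_lower)
        qus.append(p.q_upper)
        qts.append(p.q_thigh if p.q_thigh is not None else quat.identity(len(p)))
        accs.append(p.lin_acc_earth)
        lab_t.append(p.labels.t + shift)
        lab_v.append(p.labels.labels)
        if p.script is not None:
            scripts.append(p.script.shifted(shift))
        offset += len(p) / rate
    out = GroundTruth(
        t=np.concatenate(ts),
        joint_deg=np.vstack(joints),
        q_lower=np.vstack(qls),
        q_upper=np.vstack(qus),
        lin_acc_earth=np.vstack(accs),
        labels=ActivityLabels(t=np.concatenate(lab_t), labels=np.concatenate(lab_v)),
        rate_hz=rate,
        script=scripts[0] if len(scripts) == 1 else None,
        q_thigh=np.vstack(qts),
    )
    out.scripts = scripts  # type: ignore[attr-defined]
    return out
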