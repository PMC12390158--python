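"""The 12-task standardized protocol and scripted session timing.

Twelve tasks in fixed order: standing, four standing ROM tasks, sitting,
three sitting ROM tasks, sit-to-stand, object pick-up, and walking.  Timed
tasks last 10 s; ROM tasks have three repetitions with a 5 s hold each.
Every task is preceded by a burst of five gentle hops used for
segmentation in unscripted recordings.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

HOPS_PER_BURST = 5
HOP_PEAK_G = 2.0
HOP_DURATION_S = 0.15
HOP_SPACING_S = 0.5
BURST_QUIET_S = 2.5

MOVE_S = 2.0  # min-jerk move out / back
HOLD_S = 5.0  # hold each posture
REP_PAUSE_S = 1.0


@dataclass(frozen=True)
class TaskDef:
    task_id: str
    kind: str  # 'static' | 'rom' | 'timed'
    axis: str  # primary angle axis: 'latflex' | 'flexext' | 'rot'
    sign: float = 1.0
    duration_s: float = 10.0  # static / timed tasks
    n_reps: int = 1
    amplitude_deg: float = 0.0  # default scripted amplitude for ROM tasks
    activity: str = "standing"  # dominant activity label during the task


#: protocol order and defaults
PROTOCOL: tuple[TaskDef, ...] = (
    TaskDef("standing", "static", "flexext", duration_s=10.0, activity="standing"),
    TaskDef("bend_forwards", "rom", "flexext", sign=+1, n_reps=3, amplitude_deg=40.0),
    TaskDef("bend_backwards", "rom", "flexext", sign=-1, n_reps=3, amplitude_deg=20.0),
    TaskDef("left_bend", "rom", "latflex", sign=+1, n_reps=3, amplitude_deg=25.0),
    TaskDef("right_bend", "rom", "latflex", sign=-1, n_reps=3, amplitude_deg=25.0),
    TaskDef("sitting", "static", "flexext", duration_s=10.0, activity="sitting"),
    TaskDef("slumping", "rom", "flexext", sign=+1, n_reps=3, amplitude_deg=30.0, activity="sitting"),
    TaskDef("right_rotation", "rom", "rot", sign=-1, n_reps=3, amplitude_deg=30.0, activity="sitting"),
    TaskDef("left_rotation", "rom", "rot", sign=+1, n_reps=3, amplitude_deg=30.0, activity="sitting"),
    TaskDef("sit_to_stand", "rom", "flexext", sign=+1, n_reps=3, amplitude_deg=20.0, activity="sitting"),
    TaskDef("object_pickup", "rom", "flexext", sign=+1, n_reps=3, amplitude_deg=45.0),
    TaskDef("walking", "timed", "flexext", duration_s=10.0, activity="stepping"),
)

TASK_IDS = tuple(td.task_id for td in PROTOCOL)


def nominal_duration_s(td: TaskDef, hold_s: float = HOLD_S, move_s: float = MOVE_S) -> float:
    """Scripted duration of a task: timed/static tasks use their stated
    duration, ROM tasks three repetitions plus inter-rep pauses."""
    if td.kind == "rom":
        return td.n_reps * (2 * move_s + hold_s) + (td.n_reps - 1) * REP_PAUSE_S
    return td.duration_s


@dataclass
class TaskSegment:
    task: TaskDef
    hop_times: list[float]  # peak times of the 5 hops
    hop_window: tuple[float, float]
    t_start: float  # task start (after the burst's trailing quiet margin)
    t_end: float
    reps: list[tuple[float, float]] = field(default_factory=list)

    @property
    def task_id(self) -> str:
        return self.task.task_id


@dataclass
class TaskScript:
    segments: list[TaskSegment]
    t0: float = 0.0

    def __post_init__(self):
        prev_end = -np.inf
        for seg in self.segments:
            if seg.hop_window[0] < prev_end:
                raise ValueError("task segments overlap or are out of order")
            if seg.task.kind == "rom" and len(seg.reps) != 3:
                raise ValueError(f"ROM task {seg.task_id} must have exactly 3 repetitions")
            if len(seg.hop_times) != HOPS_PER_BURST:
                raise ValueError(f"task {seg.task_id} must be preceded by exactly 5 hops")
            prev_end = seg.t_end

    def __len__(self) -> int:
        return len(self.segments)

    @property
    def duration_s(self) -> float:
        return (self.segments[-1].t_end + BURST_QUIET_S - self.t0) if self.segments else 0.0

    @property
    def end_s(self) -> float:
        return self.t0 + self.duration_s

    def shifted(self, dt: float) -> "TaskScript":
        segs = [
            TaskSegment(
                task=s.task,
                hop_times=[h + dt for h in s.hop_times],
                hop_window=(s.hop_window[0] + dt, s.hop_window[1] + dt),
                t_start=s.t_start + dt,
                t_end=s.t_end + dt,
                reps=[(a + dt, b + dt) for a, b in s.reps],
            )
            for s in self.segments
        ]
        return TaskScript(segments=segs, t0=self.t0 + dt)


def build_task_script(
    protocol_params: dict | None = None,
    seed: int = 0,
    t0: float = 0.0,
) -> TaskScript:
    """Lay out one scripted session: per task a 5-hop burst (quiet margins
    on both sides) followed by the task itself; small seeded jitter on the
    inter-task pauses.

    ``protocol_params`` may override ``tasks`` (list of :class:`TaskDef`),
    ``static_duration_s``, ``hold_s``, ``move_s``.
    """
    params = dict(protocol_params or {})
    tasks: tuple[TaskDef, ...] = tuple(params.pop("tasks", PROTOCOL))
    static_duration = float(params.pop("static_duration_s", 10.0))
    hold_s = float(params.pop("hold_s", HOLD_S))
    move_s = float(params.pop("move_s", MOVE_S))
    if params:
        raise ValueError(f"unknown protocol params: {sorted(params)}")
    if static_duration <= 0 or hold_s <= 0 or move_s <= 0:
        raise ValueError("durations must be > 0")
    for td in tasks:
        if td.duration_s <= 0:
            raise ValueError(f"task {td.task_id}: duration must be > 0")

    rng = np.random.default_rng(seed)
    segments: list[TaskSegment] = []
    t = t0
    for td in tasks:
        t += BURST_QUIET_S
        hop_times = [t + k * HOP_SPACING_S for k in range(HOPS_PER_BURST)]
        hop_window = (hop_times[0] - HOP_DURATION_S / 2, hop_times[-1] + HOP_DURATION_S / 2)
        t = hop_window[1] + BURST_QUIET_S
        t_start = t
        reps: list[tuple[float, float]] = []
        if td.kind == "rom":
            rep_dur = 2 * move_s + hold_s
            for _ in range(td.n_reps):
                reps.append((t, t + rep_dur))
                t += rep_dur + REP_PAUSE_S
            t -= REP_PAUSE_S
        else:
            dur = td.duration_s if td.duration_s != 10.0 else static_duration
            t += dur
        segments.append(
            TaskSegment(
                task=replace(td, duration_s=td.duration_s),
                hop_times=hop_times,
                hop_window=hop_window,
                t_start=t_start,
                t_end=t,
                reps=reps,
            )
        )
        t += float(rng.uniform(2.0, 4.0))  # natural inter-task pause
    return TaskScript(segments=segments, t0=t0)
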