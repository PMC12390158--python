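"""Task segmentation: hop-burst detection, session finding, task windows,
and activity-label up-sampling.

In the laboratory, experimenter flags bracket each standardized task.  In
the real world, each task is preceded by five gentle hops; bursts in which
the acceleration deviation crosses a threshold at least four times, with
two quiet seconds on each side, mark candidate task boundaries, and a run
of at least ten such bursts within an hour marks a candidate task session.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ACTIVITIES, UNKNOWN_LABEL, ActivityLabels, TaskWindow
from .errors import ContractError

log = logging.getLogger(__name__)


@dataclass
class HopEvent:
    start_s: float
    end_s: float
    n_crossings: int

    @property
    def midpoint_s(self) -> float:
        return 0.5 * (self.start_s + self.end_s)


def detect_hops(
    t: np.ndarray,
    accel_mag: np.ndarray,
    thresh_g: float = 0.5,
    quiet_s: float = 2.0,
    min_crossings: int = 4,
) -> list[HopEvent]:
    """Find hop bursts in an acceleration-magnitude series.

    The rectified deviation ``|accel_mag - 1|`` is thresholded; contiguous
    groups of supra-threshold activity separated by less than ``quiet_s``
    are one candidate burst.  A burst qualifies if the deviation crosses
    the threshold at least ``min_crossings`` times (both directions count)
    and the signal stays sub-threshold for ``quiet_s`` before and after.
    """
    if thresh_g <= 0:
        raise ContractError("hop threshold must be > 0")
    t = np.asarray(t, dtype=float)
    dev = np.abs(np.asarray(accel_mag, dtype=float) - 1.0)
    above = dev > thresh_g
    if not above.any():
        return []
    idx = np.flatnonzero(above)
    # group supra-threshold samples into bursts separated by >= quiet_s
    gaps = np.flatnonzero(np.diff(t[idx]) >= quiet_s)
    group_bounds = np.split(idx, gaps + 1)
    events: list[HopEvent] = []
    for g in group_bounds:
        i0, i1 = int(g[0]), int(g[-1])
        # quiet margins must exist inside the recording
        if t[i0] - t[0] < quiet_s or t[-1] - t[i1] < quiet_s:
            continue
        seg_above = above[i0 : i1 + 1]
        # threshold crossings: transitions between below and above
        crossings = int(np.abs(np.diff(seg_above.astype(np.int8))).sum()) + 2
        # +2 accounts for the entry and exit crossings at the burst edges
        if crossings < min_crossings:
            continue
        events.append(HopEvent(start_s=float(t[i0]), end_s=float(t[i1]), n_crossings=crossings))
    return events


def find_task_sessions(
    hops: list[HopEvent],
    min_bursts: int = 10,
    span_s: float = 3600.0,
) -> list[tuple[float, float]]:
    """Maximal windows containing >= ``min_bursts`` hop bursts whose
    extremes lie within ``span_s``.  Overlapping candidates are merged."""
    if len(hops) < min_bursts:
        return []
    mids = np.array([h.midpoint_s for h in hops])
    if not np.all(np.diff(mids) >= 0):
        raise ContractError("hop events must be time-ordered")
    candidates = []
    n = len(hops)
    for i in range(n):
        j = int(np.searchsorted(mids, mids[i] + span_s, side="right")) - 1
        if j - i + 1 >= min_bursts:
            candidates.append((hops[i].start_s, hops[j].end_s))
    if not candidates:
        return []
    merged = [list(candidates[0])]
    for s, e in candidates[1:]:
        if s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(float(s), float(e)) for s, e in merged]


def _attach_reps(task_def, start: float, end: float) -> list[tuple[float, float]]:
    if task_def.n_reps <= 1:
        return []
    edges = np.linspace(start, end, task_def.n_reps + 1)
    return [(float(edges[k]), float(edges[k + 1])) for k in range(task_def.n_reps)]


def segment_tasks(
    session: tuple[float, float],
    condition: str,
    hops: list[HopEvent] | None = None,
    markers: pd.DataFrame | None = None,
    flags: pd.DataFrame | None = None,
    protocol=None,
    quiet_s: float = 2.0,
) -> list[TaskWindow]:
    """Split a candidate session into per-task windows.

    Exactly one of ``markers`` / ``flags`` / ``hops`` drives the split:

    * markers: reviewer-style table (task_id, start_s, end_s[, rep_index]);
    * flags: experimenter events, paired start/end per task in protocol order;
    * hops (auto mode): each task occupies the interval between consecutive
      hop bursts (minus quiet margins, capped at the task's nominal
      scripted duration), in protocol order, with 3-rep tasks split into
      equal thirds.
    """
    from .simulate.protocol import PROTOCOL, nominal_duration_s

    protocol = protocol if protocol is not None else PROTOCOL
    by_id = {td.task_id: td for td in protocol}
    s0, s1 = session

    if markers is not None:
        out: list[TaskWindow] = []
        unknown = set(markers["task_id"]) - set(by_id)
        if unknown:
            raise ContractError(f"markers contain unknown tasks: {sorted(unknown)}")
        if set(markers["task_id"]) != set(by_id):
            raise ContractError(
                f"marker file covers {markers['task_id'].nunique()} tasks, protocol has {len(by_id)}"
            )
        for task_id, grp in markers.groupby("task_id", sort=False):
            td = by_id[task_id]
            rep_rows = grp[np.isfinite(grp["rep_index"].astype(float))]
            start = float(grp["start_s"].min())
            end = float(grp["end_s"].max())
            if len(rep_rows):
                reps = [
                    (float(r.start_s), float(r.end_s))
                    for r in rep_rows.sort_values("rep_index").itertuples()
                ]
            else:
                reps = _attach_reps(td, start, end)
            out.append(
                TaskWindow(
                    task_id=task_id, condition=condition, start_s=start, end_s=end,
                    reps=reps, provenance="manual",
                )
            )
        out.sort(key=lambda w: w.start_s)
        return out

    if flags is not None:
        times = np.sort(flags["event_time_s"].to_numpy(float))
        if times.size != 2 * len(protocol):
            raise ContractError(
                f"expected {2 * len(protocol)} flags for {len(protocol)} tasks, got {times.size}"
            )
        out = []
        for k, td in enumerate(protocol):
            start, end = float(times[2 * k]), float(times[2 * k + 1])
            out.append(
                TaskWindow(
                    task_id=td.task_id, condition=condition, start_s=start, end_s=end,
                    reps=_attach_reps(td, start, end), provenance="flag",
                )
            )
        return out

    if hops is None:
        raise ContractError("segment_tasks needs markers, flags, or hops")
    in_session = [h for h in hops if s0 - 1e-9 <= h.midpoint_s <= s1 + 1e-9]
    if len(in_session) != len(protocol):
        raise ContractError(
            f"auto mode needs exactly {len(protocol)} hop bursts in the session, got {len(in_session)}"
        )
    out = []
    for k, td in enumerate(protocol):
        start = in_session[k].end_s + quiet_s
        nominal_end = start + nominal_duration_s(td) + 1.0
        if k + 1 < len(in_session):
            end = min(in_session[k + 1].start_s - quiet_s, nominal_end)
        else:
            end = min(s1, nominal_end)
        if end <= start:
            raise ContractError(f"degenerate auto window for task {td.task_id}")
        out.append(
            TaskWindow(
                task_id=td.task_id, condition=condition, start_s=start, end_s=end,
                reps=_attach_reps(td, start, end), provenance="hop",
            )
        )
    return out


def upsample_labels(
    labels: ActivityLabels,
    t: np.ndarray,
    rate_hz: float = 20.0,
) -> np.ndarray:
    """Repeat each second's label across that second's samples.

    ``t`` is the sample grid to label.  Seconds not covered by the label
    track are filled with ``"unknown"`` and logged.
    """
    t = np.asarray(t, dtype=float)
    out = np.full(t.size, UNKNOWN_LABEL, dtype=object)
    if len(labels) == 0:
        if t.size:
            log.warning("empty label track: %d samples labelled unknown", t.size)
        return out
    sec = np.floor(t + 1e-9).astype(np.int64)
    lab_sec = np.floor(labels.t + 1e-9).astype(np.int64)
    lut = dict(zip(lab_sec.tolist(), labels.labels.tolist()))
    misses = 0
    for i, s in enumerate(sec.tolist()):
        lab = lut.get(s)
        if lab is None:
            misses += 1
        else:
            out[i] = lab
    if misses:
        log.warning("label track gaps: %d samples labelled unknown", misses)
    return out


def label_durations(per_sample: np.ndarray, rate_hz: float) -> dict[str, float]:
    """Total seconds per activity in an up-sampled label track."""
    vals, counts = np.unique(np.asarray(per_sample, dtype=object), return_counts=True)
    return {str(v): float(c) / rate_hz for v, c in zip(vals, counts)}


__all__ = [
    "HopEvent",
    "detect_hops",
    "find_task_sessions",
    "segment_tasks",
    "upsample_labels",
    "label_durations",
    "ACTIVITIES",
]
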