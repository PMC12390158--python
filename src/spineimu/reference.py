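"""Reference-posture ("zero") strategies.

Five methods define the posture subtracted from all angle estimates of a
scope:

* ``lab`` -- mean angle over the laboratory standardized standing task,
  applied to every recording;
* ``session`` -- the same statistic from each recording's own standing task;
* ``day`` -- per-day standing task;
* ``composite`` -- median over all samples inside all standardized task
  windows of the recording;
* ``median_standing`` -- median over all samples labelled standing in the
  recording (stepping and masked samples excluded).

Only absolute angles are affected; any range-of-motion measure is exactly
invariant to the choice of method.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .core import JointAngleSeries, TaskWindow, window_mask
from .errors import ContractError, MethodUnavailableError

log = logging.getLogger(__name__)

METHODS = ("lab", "session", "day", "composite", "median_standing")

STANDING_TASK = "standing"


@dataclass
class ReferencePosture:
    method: str
    scope: str  # e.g. "all", "lab", "rw", "rw:day0"
    offsets_deg: np.ndarray  # (3,) per angle axis
    n_samples: int

    def __post_init__(self):
        if self.method not in METHODS:
            raise ContractError(f"unknown reference method {self.method!r}")
        self.offsets_deg = np.asarray(self.offsets_deg, dtype=float).reshape(3)
        if not np.all(np.isfinite(self.offsets_deg)):
            raise ContractError("reference offsets must be finite")


def _unmasked(values: np.ndarray, keep: np.ndarray) -> np.ndarray:
    return values[keep]


def _standing_offsets(
    joint: JointAngleSeries, window: TaskWindow, mask: np.ndarray | None
) -> tuple[np.ndarray, int]:
    sel = window_mask(joint.t, window.start_s, window.end_s)
    if mask is not None:
        sel &= ~mask
    n = int(sel.sum())
    if n == 0:
        raise MethodUnavailableError("standing", "standing window fully masked")
    return joint.angles[sel].mean(axis=0), n


def standing_reference(
    method: str,
    joint: JointAngleSeries,
    windows: list[TaskWindow],
    mask: np.ndarray | None = None,
    scope: str = "session",
) -> ReferencePosture:
    """Mean joint angle over the standardized standing task (lab / session /
    day methods, which differ only in scope)."""
    standing = [w for w in windows if w.task_id == STANDING_TASK]
    if not standing:
        raise MethodUnavailableError(method, "no standing task window in scope")
    try:
        offsets, n = _standing_offsets(joint, standing[0], mask)
    except MethodUnavailableError:
        raise MethodUnavailableError(method, "standing window fully masked") from None
    return ReferencePosture(method=method, scope=scope, offsets_deg=offsets, n_samples=n)


def composite_reference(
    joint: JointAngleSeries,
    windows: list[TaskWindow],
    mask: np.ndarray | None = None,
    scope: str = "session",
) -> ReferencePosture:
    """Median over all samples inside all standardized task windows."""
    if not windows:
        raise MethodUnavailableError("composite", "no task windows in scope")
    sel = np.zeros(len(joint), dtype=bool)
    for w in windows:
        sel |= window_mask(joint.t, w.start_s, w.end_s)
    if mask is not None:
        sel &= ~mask
    n = int(sel.sum())
    if n == 0:
        raise MethodUnavailableError("composite", "all task samples masked")
    return ReferencePosture(
        method="composite",
        scope=scope,
        offsets_deg=np.median(joint.angles[sel], axis=0),
        n_samples=n,
    )


def median_standing_reference(
    joint: JointAngleSeries,
    labels_per_sample: np.ndarray,
    mask: np.ndarray | None = None,
    scope: str = "session",
) -> ReferencePosture:
    """Median over all samples labelled standing in the recording."""
    lab = np.asarray(labels_per_sample, dtype=object)
    if lab.size != len(joint):
        raise ContractError("label track length must match joint series")
    sel = lab == "standing"
    if mask is not None:
        sel &= ~mask
    n = int(sel.sum())
    if n == 0:
        raise MethodUnavailableError("median_standing", "no unmasked standing samples")
    return ReferencePosture(
        method="median_standing",
        scope=scope,
        offsets_deg=np.median(joint.angles[sel], axis=0),
        n_samples=n,
    )


def compute_reference(
    method: str,
    joint: JointAngleSeries,
    windows: list[TaskWindow] | None = None,
    labels_per_sample: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    scope: str = "session",
) -> ReferencePosture:
    """Dispatch to the named strategy (scope bookkeeping is the caller's)."""
    if method not in METHODS:
        raise ContractError(f"unknown reference method {method!r}; choose from {METHODS}")
    if method in ("lab", "session", "day"):
        if windows is None:
            raise MethodUnavailableError(method, "task windows required")
        return standing_reference(method, joint, windows, mask, scope)
    if method == "composite":
        if windows is None:
            raise MethodUnavailableError(method, "task windows required")
        return composite_reference(joint, windows, mask, scope)
    if labels_per_sample is None:
        raise MethodUnavailableError(method, "label track required")
    return median_standing_reference(joint, labels_per_sample, mask, scope)


def apply_reference(joint: JointAngleSeries, ref: ReferencePosture) -> JointAngleSeries:
    """Per-axis subtraction of the reference offsets."""
    return joint.shifted(ref.offsets_deg)


def reference_table_rows(participant: str, refs: list[ReferencePosture]) -> list[dict]:
    """Rows for the serialized reference table."""
    from .core import ANGLE_AXES

    rows = []
    for r in refs:
        for j, ax in enumerate(ANGLE_AXES):
            rows.append(
                {
                    "participant": participant,
                    "method": r.method,
                    "scope": r.scope,
                    "axis": ax,
                    "offset_deg": float(r.offsets_deg[j]),
                    "n_samples": r.n_samples,
                }
            )
    return rows
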