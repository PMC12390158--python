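"""Data-quality flags: magnetic disturbance, seated transport, and
non-physiological joint angles.

Magnetic rules (applied per spine sensor, joint samples excluded when
either sensor is flagged): instantaneous field-strength deviation > 30%,
sustained deviation > 15% lasting at least 30 s, or inclination deviation
> 30 degrees from the expected Earth-field reference.  All thresholds are
strict inequalities, so boundary values survive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .bias import StillnessInterval
from .core import JointAngleSeries, SensorStream
from .errors import ConfigurationError, ContractError

log = logging.getLogger(__name__)

REASONS = ("magnetic", "transport", "nonphysiological")


@dataclass
class FieldReference:
    """Expected Earth-field magnitude and inclination (dip angle, deg;
    negative = field pointing above the horizontal)."""

    magnitude: float
    inclination_deg: float
    source: str = "stillness"

    def __post_init__(self):
        if self.magnitude <= 0:
            raise ContractError("field magnitude must be > 0")
        if not -90.0 <= self.inclination_deg <= 90.0:
            raise ContractError("inclination must be within [-90, 90] deg")


@dataclass
class MagneticFlags:
    """Per-sample magnetic-disturbance flags with per-rule attribution."""

    instantaneous: np.ndarray
    sustained: np.ndarray
    inclination: np.ndarray

    @property
    def any(self) -> np.ndarray:
        return self.instantaneous | self.sustained | self.inclination


@dataclass
class QualityMask:
    """Union exclusion mask with per-reason bookkeeping."""

    flags: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self):
        lengths = {k: v.size for k, v in self.flags.items()}
        if len(set(lengths.values())) > 1:
            raise ContractError(f"flag series length mismatch: {lengths}")

    @property
    def n(self) -> int:
        return next(iter(self.flags.values())).size if self.flags else 0

    @property
    def union(self) -> np.ndarray:
        out = np.zeros(self.n, dtype=bool)
        for v in self.flags.values():
            out |= v
        return out

    def fraction(self, reason: str) -> float:
        return float(self.flags[reason].mean()) if self.n else 0.0

    @property
    def union_fraction(self) -> float:
        return float(self.union.mean()) if self.n else 0.0

    def overlap_share(self, of: str, with_: str) -> float:
        """Share of ``of``-flagged samples that are also ``with_``-flagged."""
        a = self.flags[of]
        b = self.flags[with_]
        denom = int(a.sum())
        return float((a & b).sum() / denom) if denom else float("nan")

    def report(self) -> dict:
        rep = {
            "n_samples": int(self.n),
            "fractions": {k: self.fraction(k) for k in self.flags},
            "union_fraction": self.union_fraction,
        }
        if "transport" in self.flags and "magnetic" in self.flags:
            rep["transport_also_magnetic"] = self.overlap_share("transport", "magnetic")
        return rep


def _lowpass_gravity(acc: np.ndarray, rate_hz: float, cutoff_hz: float = 0.5) -> np.ndarray:
    """Low-passed accelerometer as a gravity-direction estimate.

    Deliberately independent of the orientation filter (which already
    consumes the magnetometer) to avoid circularity.
    """
    if acc.shape[0] < 15 or cutoff_hz >= rate_hz / 2:
        return acc.copy()
    b, a = sp_signal.butter(2, cutoff_hz / (rate_hz / 2))
    return sp_signal.filtfilt(b, a, acc, axis=0)


def inclination_series(
    stream: SensorStream, cutoff_hz: float = 0.5
) -> np.ndarray:
    """Per-sample magnetic dip angle (deg) against the low-passed gravity
    direction."""
    up = _lowpass_gravity(stream.acc, stream.rate_hz, cutoff_hz)
    nu = np.linalg.norm(up, axis=1)
    nm = np.linalg.norm(stream.mag, axis=1)
    ok = (nu > 0) & (nm > 0)
    cosang = np.zeros(len(stream))
    cosang[ok] = np.einsum("ij,ij->i", up[ok], stream.mag[ok]) / (nu[ok] * nm[ok])
    return -np.degrees(np.arcsin(np.clip(cosang, -1.0, 1.0)))


def estimate_field_reference(
    stream: SensorStream,
    stillness: list[StillnessInterval],
    min_total_s: float = 30.0,
    user_reference: FieldReference | None = None,
) -> FieldReference:
    """Robust Earth-field reference from stillness periods.

    Magnitude is the median field magnitude over stillness samples;
    inclination is the median dip angle against the accelerometer gravity
    estimate.  A user-supplied reference is returned verbatim.
    """
    if user_reference is not None:
        return user_reference
    total = sum(iv.duration_s for iv in stillness)
    if total < min_total_s:
        raise ConfigurationError(
            f"only {total:.1f} s of stillness (< {min_total_s} s) and no user field reference"
        )
    incl = inclination_series(stream)
    magmag = stream.mag_magnitude()
    sel = np.zeros(len(stream), dtype=bool)
    for iv in stillness:
        sel |= (stream.t >= iv.start_s) & (stream.t <= iv.end_s)
    return FieldReference(
        magnitude=float(np.median(magmag[sel])),
        inclination_deg=float(np.median(incl[sel])),
        source="stillness",
    )


def check_reference_consistency(
    ref_a: FieldReference, ref_b: FieldReference, tol_frac: float = 0.10
) -> bool:
    """Cross-check two spine sensors' field references; a disagreement
    beyond ``tol_frac`` in magnitude suggests stillness fell inside a
    disturbance.  Returns True when consistent; logs a warning otherwise."""
    rel = abs(ref_a.magnitude - ref_b.magnitude) / max(ref_a.magnitude, ref_b.magnitude)
    if rel > tol_frac:
        log.warning(
            "field references disagree by %.0f%% (possible disturbed stillness)", 100 * rel
        )
        return False
    return True


def detect_magnetic_disturbance(
    stream: SensorStream,
    ref: FieldReference,
    instantaneous_frac: float = 0.30,
    sustained_frac: float = 0.15,
    sustained_s: float = 30.0,
    inclination_deg: float = 30.0,
) -> MagneticFlags:
    """Apply the three magnetic-disturbance rules to one sensor."""
    magmag = stream.mag_magnitude()
    rel = np.abs(magmag - ref.magnitude) / ref.magnitude
    inst = rel > instantaneous_frac

    over = rel > sustained_frac
    sust = np.zeros(len(stream), dtype=bool)
    if over.any():
        padded = np.r_[0, over.astype(np.int8), 0]
        starts = np.flatnonzero(np.diff(padded) == 1)
        ends = np.flatnonzero(np.diff(padded) == -1) - 1
        for i0, i1 in zip(starts, ends):
            if stream.t[i1] - stream.t[i0] >= sustained_s:
                sust[i0 : i1 + 1] = True

    incl = inclination_series(stream)
    incl_flag = np.abs(incl - ref.inclination_deg) > inclination_deg
    return MagneticFlags(instantaneous=inst, sustained=sust, inclination=incl_flag)


def joint_magnetic_flags(upper: MagneticFlags, lower: MagneticFlags) -> np.ndarray:
    """A joint-angle sample is excluded if either spine sensor is flagged."""
    a = upper.any
    b = lower.any
    if a.size != b.size:
        raise ContractError("magnetic flag series length mismatch")
    return a | b


def exclude_transport(
    labels_per_sample: np.ndarray,
    rate_hz: float,
    pad_s: float = 300.0,
) -> np.ndarray:
    """Flag seated-transport samples, dilated by ``pad_s`` on each side
    (clamped at the recording bounds)."""
    lab = np.asarray(labels_per_sample, dtype=object)
    flag = lab == "transport"
    if not flag.any():
        return flag
    pad = int(round(pad_s * rate_hz))
    idx = np.flatnonzero(flag)
    out = np.zeros(lab.size, dtype=bool)
    # dilate run-wise to stay O(runs)
    run_starts = idx[np.r_[True, np.diff(idx) > 1]]
    run_ends = idx[np.r_[np.diff(idx) > 1, True]]
    for s, e in zip(run_starts, run_ends):
        out[max(0, s - pad) : min(lab.size, e + pad + 1)] = True
    return out


def exclude_nonphysiological(
    joint: JointAngleSeries,
    flexion_max_deg: float = 70.0,
    extension_min_deg: float = -50.0,
) -> np.ndarray:
    """Flag impossible spinal curvatures (flexion beyond +70 deg or
    extension beyond -50 deg, strict)."""
    fe = joint.flexext
    return (fe > flexion_max_deg) | (fe < extension_min_deg)


def combine_masks(**flags: np.ndarray) -> QualityMask:
    """Element-wise union with per-reason bookkeeping."""
    clean = {k: np.asarray(v, dtype=bool) for k, v in flags.items()}
    return QualityMask(flags=clean)


def flags_to_intervals(t: np.ndarray, flag: np.ndarray) -> list[tuple[float, float]]:
    """Contiguous flagged runs as (start_s, end_s) pairs."""
    flag = np.asarray(flag, dtype=bool)
    if not flag.any():
        return []
    padded = np.r_[0, flag.astype(np.int8), 0]
    starts = np.flatnonzero(np.diff(padded) == 1)
    ends = np.flatnonzero(np.diff(padded) == -1) - 1
    return [(float(t[i0]), float(t[i1])) for i0, i1 in zip(starts, ends)]
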