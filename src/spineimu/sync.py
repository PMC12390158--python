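"""Inter-sensor clock synchronization.

Each sensor runs on its own clock, so its sample index drifts linearly
against the others over long recordings.  The lag between two sensors is
estimated by cross-correlating their (orientation-invariant) acceleration
magnitudes in windows placed at regular checkpoints; a straight line fitted
to lag-vs-time gives the relative clock-speed error, which is removed by
linear interpolation onto the reference sensor's grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sp_signal

from .core import SensorStream
from .errors import ContractError, InsufficientDataError, UndefinedLagError

log = logging.getLogger(__name__)


@dataclass
class SensorDrift:
    slope: float  # samples per second of reference time
    intercept: float  # samples at t = 0
    checkpoints: list[tuple[float, float]] = field(default_factory=list)

    def lag_samples(self, t) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)


@dataclass
class DriftModel:
    reference: str
    sensors: dict[str, SensorDrift] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "reference": self.reference,
            "sensors": {
                k: {
                    "slope": v.slope,
                    "intercept": v.intercept,
                    "checkpoints": [list(c) for c in v.checkpoints],
                }
                for k, v in self.sensors.items()
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DriftModel":
        return cls(
            reference=d["reference"],
            sensors={
                k: SensorDrift(
                    slope=v["slope"],
                    intercept=v["intercept"],
                    checkpoints=[tuple(c) for c in v.get("checkpoints", [])],
                )
                for k, v in d["sensors"].items()
            },
        )


def cross_correlate(a: np.ndarray, b: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """Normalized cross-correlation of ``b`` against ``a`` over
    ``lags in [-max_lag, max_lag]``.

    A positive lag means ``b`` starts later than ``a`` (``b[n] ~ a[n-lag]``).
    Returns ``(lags, r)`` with ``r`` approximately in ``[-1, 1]``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    a = a - a.mean()
    b = b - b.mean()
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise UndefinedLagError("constant input signal: lag undefined")
    full = sp_signal.correlate(b, a, mode="full")
    lags = sp_signal.correlation_lags(b.size, a.size, mode="full")
    sel = np.abs(lags) <= max_lag
    return lags[sel], full[sel] / (na * nb)


def estimate_lag(
    a: np.ndarray,
    b: np.ndarray,
    max_lag: int,
    min_peak: float | None = None,
) -> int:
    """Integer lag of ``b`` relative to ``a`` (positive: ``b`` later).

    Both series should be at least ``2 * max_lag`` long.  If ``min_peak``
    is given, a normalized correlation peak below it raises
    :class:`UndefinedLagError`.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 * max_lag or b.size < 2 * max_lag:
        raise ContractError("series must be at least 2 * max_lag long")
    lags, r = cross_correlate(a, b, max_lag)
    i = int(np.argmax(r))
    if min_peak is not None and r[i] < min_peak:
        raise UndefinedLagError(f"correlation peak {r[i]:.3f} below threshold {min_peak}")
    return int(lags[i])


def _sync_signal(stream: SensorStream) -> np.ndarray:
    # magnitude of acceleration minus 1 g: orientation-invariant and zero at rest
    return stream.acc_magnitude() - 1.0


def estimate_clock_drift(
    streams: dict[str, SensorStream],
    reference: str,
    checkpoint_interval_s: float = 3600.0,
    window_s: float = 60.0,
    max_lag_s: float = 10.0,
    min_peak: float = 0.5,
) -> DriftModel:
    """Fit a per-sensor linear lag-vs-time model against ``reference``.

    The lag at each hourly checkpoint is tracked incrementally: the search
    window for checkpoint *k* is centered on the lag found at checkpoint
    *k-1*, so total drift may exceed ``max_lag_s`` as long as it grows by
    less than that between checkpoints.  Checkpoints whose correlation peak
    falls below ``min_peak`` (e.g. motionless periods) are discarded.
    """
    if reference not in streams:
        raise ContractError(f"reference sensor {reference!r} not among streams")
    ref = streams[reference]
    rate = ref.rate_hz
    max_lag = int(round(max_lag_s * rate))
    win = int(round(window_s * rate))
    model = DriftModel(reference=reference)

    ref_sig = _sync_signal(ref)
    for sid, st in streams.items():
        if sid == reference:
            continue
        if st.rate_hz != rate:
            raise ContractError("all streams must share the nominal rate")
        sig = _sync_signal(st)
        t0 = max(ref.t[0], st.t[0])
        t1 = min(ref.t[-1], st.t[-1])
        if t1 - t0 < 2 * checkpoint_interval_s:
            raise InsufficientDataError(
                f"recording of {sid} too short for {checkpoint_interval_s} s checkpoints"
            )
        centers = np.arange(t0 + 0.5 * checkpoint_interval_s, t1, checkpoint_interval_s)
        checkpoints: list[tuple[float, float]] = []
        lag_pred = 0
        for tc in centers:
            i0 = int(np.searchsorted(ref.t, tc - window_s / 2))
            i1 = i0 + win
            if i1 > ref.t.size:
                continue
            j0 = int(np.searchsorted(st.t, tc - window_s / 2)) + lag_pred
            j1 = j0 + win
            if j0 < 0 or j1 > st.t.size:
                continue
            try:
                resid = estimate_lag(ref_sig[i0:i1], sig[j0:j1], max_lag, min_peak=min_peak)
            except UndefinedLagError:
                log.debug("sensor %s: checkpoint at %.0f s discarded (no peak)", sid, tc)
                continue
            total = lag_pred + resid
            checkpoints.append((float(tc), float(total)))
            lag_pred = total
        if len(checkpoints) < 2:
            raise InsufficientDataError(
                f"sensor {sid}: only {len(checkpoints)} valid checkpoints, need >= 2"
            )
        ts = np.array([c[0] for c in checkpoints])
        ls = np.array([c[1] for c in checkpoints])
        slope, intercept = np.polyfit(ts, ls, 1)
        model.sensors[sid] = SensorDrift(
            slope=float(slope), intercept=float(intercept), checkpoints=checkpoints
        )
    return model


def estimate_constant_lag(
    streams: dict[str, SensorStream],
    reference: str,
    max_lag_s: float = 10.0,
    min_peak: float = 0.3,
) -> DriftModel:
    """Single whole-recording lag per sensor (short-recording fallback).

    Used for laboratory sessions that are too short to expose clock drift;
    the model is constant (slope 0).
    """
    if reference not in streams:
        raise ContractError(f"reference sensor {reference!r} not among streams")
    ref = streams[reference]
    max_lag = int(round(max_lag_s * ref.rate_hz))
    model = DriftModel(reference=reference)
    ref_sig = _sync_signal(ref)
    for sid, st in streams.items():
        if sid == reference:
            continue
        n = min(ref_sig.size, len(st))
        lag = estimate_lag(ref_sig[:n], _sync_signal(st)[:n], max_lag, min_peak=min_peak)
        model.sensors[sid] = SensorDrift(slope=0.0, intercept=float(lag), checkpoints=[])
    return model


def resynchronize(stream: SensorStream, model: DriftModel) -> SensorStream:
    """Interpolate all channels onto the reference clock grid.

    The drift model gives this sensor's lag (in samples) as a function of
    its own claimed time; subtracting it maps claimed timestamps to
    reference time, after which every channel is linearly interpolated onto
    the uniform reference grid.
    """
    sid = stream.sensor_id
    if sid == model.reference or sid not in model.sensors:
        if sid not in model.sensors and sid != model.reference:
            raise ContractError(f"drift model does not cover sensor {sid!r}")
        return stream.copy()
    drift = model.sensors[sid]
    if drift.slope == 0.0 and drift.intercept == 0.0:
        return stream.copy()
    rate = stream.rate_hz
    master_t = stream.t - drift.lag_samples(stream.t) / rate
    dt = 1.0 / rate
    k0 = int(np.ceil(master_t[0] / dt))
    k1 = int(np.floor(master_t[-1] / dt))
    grid = np.arange(k0, k1 + 1) * dt
    channels = {}
    for name in ("acc", "gyr", "mag"):
        arr = getattr(stream, name)
        channels[name] = np.column_stack(
            [np.interp(grid, master_t, arr[:, j]) for j in range(3)]
        )
    return SensorStream(
        sensor_id=sid,
        t=grid,
        acc=channels["acc"],
        gyr=channels["gyr"],
        mag=channels["mag"],
        rate_hz=rate,
    )


def align_streams(streams: dict[str, SensorStream]) -> dict[str, SensorStream]:
    """Trim synchronized streams to their common time span on one grid."""
    t0 = max(s.t[0] for s in streams.values())
    t1 = min(s.t[-1] for s in streams.values())
    out = {}
    for sid, s in streams.items():
        i0 = int(np.searchsorted(s.t, t0 - 1e-9))
        i1 = int(np.searchsorted(s.t, t1 + 1e-9, side="right"))
        out[sid] = s.slice(i0, i1)
    n = min(len(s) for s in out.values())
    return {sid: s.slice(0, n) for sid, s in out.items()}
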