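"""Per-task outcome measures and ICC repeatability.

For each standardized task the outcomes are the range of motion
(max - min over the task window) and the starting posture (mean over the
first five unmasked samples).  Repeatability across conditions (lab and
the two real-world days; the sensor set and time point jointly form the
condition factor) is quantified with the two-way random-effects,
absolute-agreement, average-measures intraclass correlation ICC(A,k),
with listwise deletion of participants missing any condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import ANGLE_AXES
from .errors import ContractError, InsufficientDataError

log = logging.getLogger(__name__)

CONDITIONS = ("lab", "rw1", "rw2")
MEASURES = ("rom", "start")


def range_of_motion(values: np.ndarray, mask: np.ndarray | None = None) -> float | None:
    """Max minus min over unmasked samples; ``None`` (missing) when fewer
    than two unmasked samples remain."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        v = v[~np.asarray(mask, dtype=bool)]
    if v.size < 2:
        return None
    return float(v.max() - v.min())


def starting_posture(
    values: np.ndarray, mask: np.ndarray | None = None, n_first: int = 5
) -> float | None:
    """Mean over the first ``n_first`` unmasked samples of the window.

    Masked leading samples are skipped (the window effectively extends to
    the first five usable samples); fewer than five usable samples in the
    whole window yields a missing value."""
    v = np.asarray(values, dtype=float)
    if mask is not None:
        m = np.asarray(mask, dtype=bool)
        if m[: min(n_first, m.size)].any():
            log.debug("starting posture: leading masked samples skipped")
        v = v[~m]
    if v.size < n_first:
        return None
    return float(v[:n_first].mean())


def aggregate_reps(values: list[float | None]) -> tuple[float | None, int]:
    """Mean of available repetition values and how many contributed."""
    avail = [v for v in values if v is not None]
    if not avail:
        return None, 0
    if len(avail) < len(values):
        log.debug("aggregate_reps: %d of %d reps missing", len(values) - len(avail), len(values))
    return float(np.mean(avail)), len(avail)


@dataclass
class IccResult:
    value: float
    msr: float  # rows (targets) mean square
    msc: float  # columns (conditions) mean square
    mse: float  # error mean square
    n: int  # targets
    k: int  # conditions
    band: str
    method: str = "ICC(A,k)"
    ci95: tuple[float, float] | None = None


def interpret_icc(value: float) -> str:
    """Interpretation bands: poor < 0.5 <= moderate <= 0.75 < good <= 0.9
    < excellent."""
    if not np.isfinite(value):
        return "undefined"
    if value < 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def _icc2k_ci(icc2: float, msr: float, msc: float, mse: float, n: int, k: int,
              alpha: float = 0.05) -> tuple[float, float] | None:
    """F-based confidence interval for ICC(A,k) (single-measures interval
    stepped up with Spearman-Brown).  Reported for context only."""
    try:
        a = (k * icc2) / (n * (1 - icc2))
        b = 1 + (k * icc2 * (n - 1)) / (n * (1 - icc2))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f2u = stats.f.ppf(1 - alpha / 2, n - 1, v)
        f2l = stats.f.ppf(1 - alpha / 2, v, n - 1)
        lo1 = n * (msr - f2u * mse) / (
            f2u * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi1 = n * (f2l * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f2l * msr)
        lo = lo1 * k / (1 + (k - 1) * lo1)
        hi = hi1 * k / (1 + (k - 1) * hi1)
        return float(lo), float(hi)
    except (ZeroDivisionError, FloatingPointError, ValueError):
        return None


def icc_2k(matrix: np.ndarray, with_ci: bool = False) -> IccResult:
    """ICC(A,k) from a participants x conditions matrix.

    Rows with any missing value are deleted listwise.  Mean squares come
    from the two-way ANOVA decomposition; the estimate is
    ``(MSR - MSE) / (MSR + (MSC - MSE) / n)``.  Zero total variance yields
    an undefined (NaN) ICC, reported as such.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ContractError("ICC input must be a 2-D matrix")
    complete = np.isfinite(x).all(axis=1)
    x = x[complete]
    n, k = x.shape
    if k < 2:
        raise InsufficientDataError("ICC needs at least 2 conditions")
    if n < 2:
        raise InsufficientDataError(
            f"ICC needs at least 2 complete rows after listwise deletion, got {n}"
        )
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * float(((row_means - grand) ** 2).sum())
    ssc = n * float(((col_means - grand) ** 2).sum())
    sst = float(((x - grand) ** 2).sum())
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    denom = msr + (msc - mse) / n
    if sst == 0.0 or denom == 0.0:
        value = float("nan")
    else:
        value = (msr - mse) / denom
    ci = None
    if with_ci and np.isfinite(value):
        denom1 = msr + (k - 1) * mse + k * (msc - mse) / n
        icc2 = (msr - mse) / denom1 if denom1 else float("nan")
        if np.isfinite(icc2) and icc2 < 1:
            ci = _icc2k_ci(icc2, msr, msc, mse, n, k)
    return IccResult(
        value=float(value), msr=msr, msc=msc, mse=mse, n=n, k=k,
        band=interpret_icc(value), ci95=ci,
    )


def population_icc_ak(
    between_var: float, within_var: float, k: int
) -> float:
    """Closed-form population ICC(A,k) for a cohort with between-target
    variance ``between_var`` and total within-target (condition + error)
    variance ``within_var``, averaged over ``k`` conditions."""
    return between_var / (between_var + within_var / k)


def outcome_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble an outcome table (participant, task, condition, measure,
    axis, value_deg) enforcing at most one row per key."""
    df = pd.DataFrame(rows, columns=["participant", "task", "condition", "measure", "axis", "value_deg"])
    key = ["participant", "task", "condition", "measure", "axis"]
    if df.duplicated(subset=key).any():
        raise ContractError("outcome table has duplicate (participant, task, condition, measure, axis) rows")
    bad_axis = set(df["axis"]) - set(ANGLE_AXES)
    if bad_axis:
        raise ContractError(f"unknown angle axes in outcome table: {sorted(bad_axis)}")
    return df


def task_matrix(
    outcomes: pd.DataFrame,
    task: str,
    measure: str,
    axis: str,
    conditions: tuple[str, ...] = CONDITIONS,
) -> np.ndarray:
    """Participants x conditions matrix for one (task, measure, axis)."""
    sub = outcomes[
        (outcomes["task"] == task)
        & (outcomes["measure"] == measure)
        & (outcomes["axis"] == axis)
    ]
    pivot = sub.pivot_table(
        index="participant", columns="condition", values="value_deg", aggfunc="first"
    )
    pivot = pivot.reindex(columns=list(conditions))
    return pivot.to_numpy(dtype=float)


def repeatability_report(
    outcomes: pd.DataFrame,
    measure: str = "start",
    axis: str = "flexext",
    conditions: tuple[str, ...] = CONDITIONS,
) -> pd.DataFrame:
    """One ICC per task plus the unweighted mean and s.d. across tasks.

    Tasks with insufficient complete data are omitted from the per-task
    rows and listed in the ``skipped`` attribute of the returned frame.
    """
    tasks = list(dict.fromkeys(outcomes["task"]))
    rows = []
    skipped = []
    for task in tasks:
        mat = task_matrix(outcomes, task, measure, axis, conditions)
        try:
            res = icc_2k(mat)
        except InsufficientDataError as exc:
            skipped.append((task, str(exc)))
            continue
        rows.append(
            {"task": task, "icc": res.value, "band": res.band, "n": res.n, "k": res.k}
        )
    df = pd.DataFrame(rows, columns=["task", "icc", "band", "n", "k"])
    if len(df):
        vals = df["icc"].to_numpy(float)
        mean_row = {
            "task": "mean",
            "icc": float(np.nanmean(vals)),
            "band": interpret_icc(float(np.nanmean(vals))),
            "n": int(df["n"].min()),
            "k": int(df["k"].max()),
        }
        df = pd.concat([df, pd.DataFrame([mean_row])], ignore_index=True)
        df.attrs["icc_sd"] = float(np.nanstd(vals, ddof=1)) if len(vals) > 1 else float("nan")
    df.attrs["skipped"] = skipped
    return df
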