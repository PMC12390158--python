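import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings, strategies as st

from spineimu.errors import ContractError, InsufficientDataError
from spineimu.outcomes import (
    aggregate_reps,
    icc_2k,
    interpret_icc,
    outcome_table,
    population_icc_ak,
    range_of_motion,
    repeatability_report,
    starting_posture,
)


def icc_ak_anova_oracle(x):
    """Brute-force two-way ANOVA by definition (explicit loops)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / (n * k)
    ssr = 0.0
    for i in range(n):
        ssr += k * (x[i, :].sum() / k - grand) ** 2
    ssc = 0.0
    for j in range(k):
        ssc += n * (x[:, j].sum() / n - grand) ** 2
    sst = 0.0
    for i in range(n):
        for j in range(k):
            sst += (x[i, j] - grand) ** 2
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (msc - mse) / n)


class TestRangeOfMotion:
    def test_constant_zero(self):
        assert range_of_motion(np.full(10, 3.3)) == 0.0

    def test_sinusoid_amplitude(self):
        t = np.linspace(0, 10, 2000)
        v = 15.0 * np.sin(2 * np.pi * 0.5 * t)
        assert range_of_motion(v) == pytest.approx(30.0, abs=0.1)

    def test_masked_spike_excluded(self):
        v = np.concatenate([np.linspace(0, 20, 50), [200.0], np.linspace(20, 0, 50)])
        mask = np.zeros(v.size, bool)
        mask[50] = True
        clean = np.delete(v, 50)
        assert range_of_motion(v, mask) == clean.max() - clean.min()

    def test_too_few_samples_missing(self):
        assert range_of_motion(np.array([1.0]), None) is None
        mask = np.ones(10, bool)
        mask[0] = False
        assert range_of_motion(np.arange(10.0), mask) is None

    def test_non_negative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert range_of_motion(rng.normal(0, 5, 30)) >= 0.0


class TestStartingPosture:
    def test_constant(self):
        assert starting_posture(np.full(20, 12.0)) == 12.0

    def test_ramp_mean(self):
        assert starting_posture(np.arange(10.0)) == pytest.approx(2.0)

    def test_leading_masked_skipped(self):
        v = np.arange(20.0)
        mask = np.zeros(20, bool)
        mask[:3] = True  # skip 0,1,2 -> use 3..7
        assert starting_posture(v, mask) == pytest.approx(np.mean([3, 4, 5, 6, 7]))

    def test_insufficient_missing(self):
        mask = np.ones(10, bool)
        mask[:4] = False
        assert starting_posture(np.arange(10.0), mask) is None


class TestAggregateReps:
    def test_mean(self):
        assert aggregate_reps([10.0, 12.0, 14.0]) == (12.0, 3)

    def test_one_missing(self):
        val, n = aggregate_reps([10.0, None, 14.0])
        assert val == 12.0 and n == 2

    def test_all_missing(self):
        assert aggregate_reps([None, None, None]) == (None, 0)


class TestIcc2k:
    def test_identical_columns_unity(self):
        col = np.array([1.0, 5.0, 9.0, 2.0])
        x = np.column_stack([col, col, col])
        assert icc_2k(x).value == pytest.approx(1.0)

    def test_3x3_matches_oracle(self):
        x = np.array([[1.0, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert icc_2k(x).value == pytest.approx(icc_ak_anova_oracle(x), abs=1e-12)

    def test_thousand_random_matrices_vs_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            n = int(rng.integers(3, 21))
            k = int(rng.integers(2, 5))
            x = (
                rng.normal(0, 1, (n, k))
                + rng.normal(0, 1.5, (n, 1))
                + rng.normal(0, 0.5, (1, k))
            )
            assert icc_2k(x).value == pytest.approx(icc_ak_anova_oracle(x), abs=1e-10)

    def test_against_pingouin(self):
        rng = np.random.default_rng(8)
        for _ in range(10):
            n, k = 9, 3
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 1, (n, 1))
            df = pd.DataFrame(
                {
                    "t": np.repeat(np.arange(n), k),
                    "r": np.tile(np.arange(k), n),
                    "y": x.ravel(),
                }
            )
            expected = pg.intraclass_corr(df, "t", "r", "y").set_index("Type").loc["ICC(A,k)", "ICC"]
            assert icc_2k(x).value == pytest.approx(float(expected), abs=1e-9)

    def test_listwise_deletion(self):
        x = np.array([[1.0, 2, 3], [4, 5, 6], [7, np.nan, 9], [2, 3, 4]])
        res = icc_2k(x)
        assert res.n == 3
        assert res.value == pytest.approx(icc_ak_anova_oracle(np.delete(x, 2, axis=0)), abs=1e-12)

    def test_insufficient_rows(self):
        with pytest.raises(InsufficientDataError):
            icc_2k(np.array([[1.0, 2.0]]))
        with pytest.raises(InsufficientDataError):
            icc_2k(np.array([[1.0], [2.0]]))

    def test_zero_variance_undefined(self):
        res = icc_2k(np.full((4, 3), 2.0))
        assert np.isnan(res.value)
        assert res.band == "undefined"

    @settings(max_examples=30, deadline=None)
    @given(c=st.floats(-50, 50))
    def test_whole_matrix_shift_invariance(self, c):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, (8, 3)) + rng.normal(0, 2, (8, 1))
        assert icc_2k(x + c).value == pytest.approx(icc_2k(x).value, abs=1e-9)

    def test_column_shift_lowers_absolute_agreement(self):
        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, (12, 3)) + rng.normal(0, 3, (12, 1))
        base = icc_2k(x).value
        shifted = x.copy()
        shifted[:, 0] += 5.0
        assert icc_2k(shifted).value <= base + 1e-12

    def test_monte_carlo_calibration(self):
        """Cohorts at sigma_b^2 = 1, sigma_w^2 = 1, k = 3 have population
        ICC(A,k) = 0.75; a large-n estimate concentrates there."""
        rng = np.random.default_rng(13)
        n, k = 200, 3
        vals = [
            icc_2k(
                rng.standard_normal((n, 1))
                + np.sqrt(0.3) * rng.standard_normal((1, k))
                + np.sqrt(0.7) * rng.standard_normal((n, k))
            ).value
            for _ in range(60)
        ]
        assert population_icc_ak(1.0, 1.0, 3) == pytest.approx(0.75)
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert np.mean(vals) == pytest.approx(0.75, abs=max(4 * se, 0.02))


class TestInterpretation:
    @pytest.mark.parametrize(
        "value,band",
        [
            (0.67, "moderate"),
            (0.72, "moderate"),
            (0.49, "poor"),
            (0.5, "moderate"),
            (0.75, "moderate"),
            (0.76, "good"),
            (0.9, "good"),
            (0.95, "excellent"),
            (-0.32, "poor"),
        ],
    )
    def test_bands(self, value, band):
        assert interpret_icc(value) == band


class TestOutcomeTable:
    def _rows(self):
        rows = []
        for p in ("P01", "P02", "P03"):
            for c in ("lab", "rw1", "rw2"):
                rows.append(
                    {
                        "participant": p,
                        "task": "standing",
                        "condition": c,
                        "measure": "start",
                        "axis": "flexext",
                        "value_deg": hash((p, c)) % 10,
                    }
                )
        return rows

    def test_duplicate_rejected(self):
        rows = self._rows()
        rows.append(rows[0])
        with pytest.raises(ContractError):
            outcome_table(rows)

    def test_report_shape(self):
        df = outcome_table(self._rows())
        rep = repeatability_report(df, measure="start", axis="flexext")
        assert list(rep["task"]) == ["standing", "mean"]

    def test_insufficient_tasks_listed(self):
        rows = self._rows()[:3]  # single participant
        df = outcome_table(rows)
        rep = repeatability_report(df)
        assert len(rep) == 0
        assert rep.attrs["skipped"][0][0] == "standing"
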