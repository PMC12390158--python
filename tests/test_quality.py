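import numpy as np
import pytest

from spineimu.bias import detect_stillness
from spineimu.core import JointAngleSeries, SensorStream
from spineimu.errors import ConfigurationError, ContractError
from spineimu.quality import (
    FieldReference,
    check_reference_consistency,
    combine_masks,
    detect_magnetic_disturbance,
    estimate_field_reference,
    exclude_nonphysiological,
    exclude_transport,
    flags_to_intervals,
    joint_magnetic_flags,
)
from spineimu.simulate.imu import EarthField

RATE = 20.0
EARTH = EarthField()


def _mag_stream(scale=None, tilt_deg=None, n_s=120.0, noise=0.0, seed=0):
    """Upright still stream whose field magnitude/inclination can be
    manipulated per sample."""
    rng = np.random.default_rng(seed)
    n = int(n_s * RATE)
    t = np.arange(n) / RATE
    acc = np.tile([0.0, 0.0, 1.0], (n, 1))
    e = np.tile(EARTH.vector(), (n, 1))
    if scale is not None:
        e = e * np.asarray(scale)[:, None]
    if tilt_deg is not None:
        th = np.radians(np.asarray(tilt_deg))
        base = EARTH.vector()
        # rotate about the west (y) axis per sample
        e = np.column_stack(
            [
                base[0] * np.cos(th) + base[2] * np.sin(th),
                np.zeros(n),
                -base[0] * np.sin(th) + base[2] * np.cos(th),
            ]
        )
    if noise:
        e = e + rng.normal(0, noise, (n, 3))
        acc = acc + rng.normal(0, noise, (n, 3))
    return SensorStream("m", t, acc, np.zeros((n, 3)), e, rate_hz=RATE)


REF = FieldReference(1.0, -60.0, source="user")


class TestFieldReference:
    def test_clean_simulation_recovery(self):
        stream = _mag_stream(noise=0.005, seed=1)
        stillness = detect_stillness(stream, 3.0, 5.0)
        ref = estimate_field_reference(stream, stillness)
        assert ref.magnitude == pytest.approx(1.0, abs=0.01)
        assert ref.inclination_deg == pytest.approx(-60.0, abs=0.5)

    def test_user_reference_passthrough(self):
        out = estimate_field_reference(_mag_stream(), [], user_reference=REF)
        assert out is REF

    def test_insufficient_stillness(self):
        stream = _mag_stream(n_s=10.0)
        with pytest.raises(ConfigurationError):
            estimate_field_reference(stream, [])

    def test_disturbed_stillness_cross_check_warns(self, caplog):
        # both references computed, but one sensor saw a +40% field: the
        # two-sensor consistency check flags the disagreement
        a = FieldReference(1.0, -60.0)
        b = FieldReference(1.4, -60.0)
        with caplog.at_level("WARNING"):
            ok = check_reference_consistency(a, b)
        assert not ok
        assert check_reference_consistency(a, FieldReference(1.02, -61.0))


class TestMagneticRules:
    def test_instantaneous_step_flagged_from_first_sample(self):
        scale = np.ones(int(120 * RATE))
        i0, i1 = int(40 * RATE), int(50 * RATE)
        scale[i0:i1] = 1.4
        flags = detect_magnetic_disturbance(_mag_stream(scale=scale), REF)
        assert flags.instantaneous[i0]
        assert flags.instantaneous[i0:i1].all()
        assert not flags.instantaneous[:i0].any()
        assert not flags.sustained[:i0].any()

    def test_sustained_rule_duration_gate(self):
        # +20%: below the instantaneous rule; flagged only when >= 30 s
        n = int(200 * RATE)
        for dur_s, expect in ((10.0, False), (35.0, True)):
            scale = np.ones(n)
            i0 = int(60 * RATE)
            i1 = i0 + int(dur_s * RATE)
            scale[i0:i1] = 1.2
            flags = detect_magnetic_disturbance(_mag_stream(scale=scale, n_s=200.0), REF)
            assert not flags.instantaneous.any()
            assert flags.sustained[i0:i1].all() == expect
            if expect:  # whole run flagged
                assert not flags.sustained[: i0 - 1].any()
                assert not flags.sustained[i1 + 1 :].any()

    def test_inclination_rule(self):
        n = int(120 * RATE)
        tilt = np.zeros(n)
        i0, i1 = int(30 * RATE), int(60 * RATE)
        tilt[i0:i1] = 35.0
        flags = detect_magnetic_disturbance(_mag_stream(tilt_deg=tilt), REF)
        # constant magnitude: only the inclination rule fires
        assert not flags.instantaneous.any() and not flags.sustained.any()
        inner = slice(i0 + int(2 * RATE), i1 - int(2 * RATE))
        assert flags.inclination[inner].all()
        assert not flags.inclination[: i0 - int(2 * RATE)].any()

    def test_boundary_strictness(self):
        scale = np.full(int(60 * RATE), 1.30)  # exactly 30%: survives
        flags = detect_magnetic_disturbance(_mag_stream(scale=scale, n_s=60.0), REF)
        assert not flags.instantaneous.any()

    def test_clean_stream_no_false_positives(self):
        flags = detect_magnetic_disturbance(_mag_stream(noise=0.005, seed=2), REF)
        assert not flags.any.any()

    def test_either_sensor_rule(self):
        a = detect_magnetic_disturbance(_mag_stream(), REF)
        scale = np.ones(int(120 * RATE))
        scale[100:200] = 1.5
        b = detect_magnetic_disturbance(_mag_stream(scale=scale), REF)
        joint = joint_magnetic_flags(a, b)
        assert joint[100:200].all()
        assert joint.sum() == b.any.sum()


class TestTransport:
    def test_pad_dilation(self):
        n = int(1800 * RATE)
        lab = np.full(n, "sitting", dtype=object)
        i0, i1 = int(600 * RATE), int(1200 * RATE)
        lab[i0:i1] = "transport"
        flag = exclude_transport(lab, RATE, pad_s=300.0)
        assert flag.sum() == (i1 - i0) + 2 * int(300 * RATE)
        assert flag[i0 - int(300 * RATE)]
        assert not flag[i0 - int(300 * RATE) - 1]

    def test_clamped_at_start(self):
        n = int(600 * RATE)
        lab = np.full(n, "standing", dtype=object)
        lab[: int(60 * RATE)] = "transport"
        flag = exclude_transport(lab, RATE, pad_s=300.0)
        assert flag[0]
        assert flag.sum() == int(60 * RATE) + int(300 * RATE)

    def test_no_transport_no_flags(self):
        lab = np.full(100, "standing", dtype=object)
        assert exclude_transport(lab, RATE).sum() == 0


class TestNonPhysiological:
    def _joint(self, flex):
        flex = np.asarray(flex, dtype=float)
        return JointAngleSeries(
            t=np.arange(flex.size) / RATE,
            angles=np.column_stack([np.zeros_like(flex), flex, np.zeros_like(flex)]),
        )

    def test_constant_75_all_flagged(self):
        assert exclude_nonphysiological(self._joint(np.full(50, 75.0))).all()

    def test_minus_50_boundary_survives(self):
        assert not exclude_nonphysiological(self._joint(np.full(50, -50.0))).any()

    def test_sleep_extension_beyond_minus_50_flagged(self):
        flex = np.full(100, -40.0)
        flex[30:60] = -55.0  # far more extended than standing
        flag = exclude_nonphysiological(self._joint(flex))
        assert flag[30:60].all() and flag.sum() == 30


class TestCombineMasks:
    def test_disjoint_additivity(self):
        a = np.zeros(100, bool)
        b = np.zeros(100, bool)
        a[:10] = True
        b[50:60] = True
        mask = combine_masks(magnetic=a, transport=b)
        assert mask.union_fraction == pytest.approx(0.2)

    def test_idempotence(self):
        a = np.zeros(100, bool)
        a[:10] = True
        mask = combine_masks(magnetic=a, transport=a.copy())
        assert mask.union_fraction == pytest.approx(0.1)

    def test_length_mismatch(self):
        with pytest.raises(ContractError):
            combine_masks(magnetic=np.zeros(5, bool), transport=np.zeros(6, bool))

    def test_union_bounds_property(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            flags = {
                k: rng.random(200) < p
                for k, p in (("magnetic", 0.3), ("transport", 0.1), ("nonphysiological", 0.05))
            }
            mask = combine_masks(**flags)
            per = [mask.fraction(k) for k in flags]
            assert max(per) <= mask.union_fraction <= min(1.0, sum(per)) + 1e-12

    def test_overlap_share(self):
        a = np.zeros(100, bool)
        b = np.zeros(100, bool)
        a[:20] = True
        b[10:30] = True
        mask = combine_masks(magnetic=a, transport=b)
        assert mask.overlap_share("transport", "magnetic") == pytest.approx(0.5)


def test_flags_to_intervals():
    flag = np.zeros(100, bool)
    flag[10:20] = True
    flag[50:51] = True
    t = np.arange(100) / RATE
    ivs = flags_to_intervals(t, flag)
    assert len(ivs) == 2
    assert ivs[0] == (t[10], t[19])
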