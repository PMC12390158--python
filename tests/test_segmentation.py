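import numpy as np
import pandas as pd
import pytest

from spineimu.core import ActivityLabels, UNKNOWN_LABEL
from spineimu.errors import ContractError
from spineimu.segmentation import (
    HopEvent,
    detect_hops,
    find_task_sessions,
    label_durations,
    segment_tasks,
    upsample_labels,
)
from spineimu.simulate.protocol import PROTOCOL, build_task_script

RATE = 20.0


def _hop_signal(burst_times, n_s=120.0, peak=2.0, n_hops=5, spacing=0.5):
    """1 g baseline plus half-sine hop bursts."""
    n = int(n_s * RATE)
    t = np.arange(n) / RATE
    mag = np.ones(n)
    for b in burst_times:
        for k in range(n_hops):
            h = b + k * spacing
            sel = (t >= h - 0.075) & (t <= h + 0.075)
            mag[sel] += peak * np.sin(np.pi * (t[sel] - (h - 0.075)) / 0.15)
    return t, mag


class TestDetectHops:
    def test_five_hop_burst_is_one_event(self):
        t, mag = _hop_signal([10.0])
        events = detect_hops(t, mag, 0.5)
        assert len(events) == 1
        assert events[0].n_crossings >= 4
        assert 9.5 < events[0].start_s < 10.0

    def test_single_spike_too_few_crossings(self):
        t, mag = _hop_signal([10.0], n_hops=1)
        assert detect_hops(t, mag, 0.5) == []

    def test_no_quiet_margin_rejected(self):
        # continuous high-rate oscillation: no 2 s quiet margins anywhere
        n = int(60 * RATE)
        t = np.arange(n) / RATE
        mag = 1.0 + 1.0 * np.sin(2 * np.pi * 2.0 * t)
        assert detect_hops(t, mag, 0.5) == []

    def test_burst_at_recording_edge_rejected(self):
        t, mag = _hop_signal([0.5])
        assert detect_hops(t, mag, 0.5) == []

    def test_two_bursts_two_events(self):
        t, mag = _hop_signal([10.0, 40.0])
        assert len(detect_hops(t, mag, 0.5)) == 2

    def test_simulated_session_recall_precision(self, session_truth, clean_spine_streams):
        """Recall and precision both 1.0 for scripted bursts at 2x threshold."""
        stream = clean_spine_streams["lower"]
        events = detect_hops(stream.t, stream.acc_magnitude(), 0.5)
        script = session_truth.script
        true_bursts = [seg.hop_window for seg in script.segments]
        assert len(events) == len(true_bursts)  # precision: no spurious events
        for ev, (b0, b1) in zip(events, true_bursts):
            assert abs(ev.midpoint_s - 0.5 * (b0 + b1)) < 1.0  # recall: all found


def brute_force_sessions(mids, min_bursts, span_s):
    """O(n^2) window-scan oracle for burst clustering."""
    hits = []
    for i in range(len(mids)):
        for j in range(i + min_bursts - 1, len(mids)):
            if mids[j] - mids[i] <= span_s:
                hits.append((i, j))
    merged = []
    for i, j in hits:
        if merged and i <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], j))
        else:
            merged.append((i, j))
    return merged


class TestFindSessions:
    def _hops(self, times):
        return [HopEvent(t - 1.0, t + 1.0, 10) for t in times]

    def test_twelve_bursts_in_twenty_minutes(self):
        times = np.linspace(100, 1300, 12)
        sessions = find_task_sessions(self._hops(times))
        assert len(sessions) == 1

    def test_nine_bursts_no_candidate(self):
        times = np.linspace(100, 1300, 9)
        assert find_task_sessions(self._hops(times)) == []

    def test_two_separated_clusters_vs_oracle(self):
        times = np.concatenate([np.linspace(100, 800, 12), np.linspace(18100, 18800, 12)])
        hops = self._hops(times)
        sessions = find_task_sessions(hops)
        oracle = brute_force_sessions(times, 10, 3600.0)
        assert len(sessions) == len(oracle) == 2
        for (s, e), (i, j) in zip(sessions, oracle):
            assert s == hops[i].start_s and e == hops[j].end_s


class TestSegmentTasks:
    def test_auto_mode_twelve_windows_in_order(self, session_truth, clean_spine_streams):
        stream = clean_spine_streams["lower"]
        hops = detect_hops(stream.t, stream.acc_magnitude(), 0.5)
        assert len(hops) == 12
        sess = (hops[0].start_s, float(stream.t[-1]))
        windows = segment_tasks(sess, "rw1", hops=hops, quiet_s=2.0)
        assert [w.task_id for w in windows] == [td.task_id for td in PROTOCOL]
        # Jaccard overlap with the simulator's true windows
        for w, seg in zip(windows, session_truth.script.segments):
            inter = min(w.end_s, seg.t_end) - max(w.start_s, seg.t_start)
            union = max(w.end_s, seg.t_end) - min(w.start_s, seg.t_start)
            assert inter / union >= 0.8, w.task_id

    def test_flags_passthrough(self):
        script = build_task_script(seed=3)
        rows = []
        for seg in script.segments:
            rows.append({"event_time_s": seg.t_start, "flag_type": "start"})
            rows.append({"event_time_s": seg.t_end, "flag_type": "end"})
        flags = pd.DataFrame(rows)
        windows = segment_tasks((0.0, script.end_s), "lab", flags=flags)
        for w, seg in zip(windows, script.segments):
            assert w.start_s == seg.t_start and w.end_s == seg.t_end
            assert w.provenance == "flag"

    def test_marker_count_mismatch(self):
        markers = pd.DataFrame(
            {
                "task_id": [td.task_id for td in PROTOCOL[:-1]],
                "start_s": np.arange(11) * 30.0,
                "end_s": np.arange(11) * 30.0 + 20.0,
                "rep_index": np.nan,
            }
        )
        with pytest.raises(ContractError):
            segment_tasks((0.0, 400.0), "lab", markers=markers)

    def test_marker_mode_with_reps(self):
        rows = []
        t = 0.0
        for td in PROTOCOL:
            if td.n_reps == 3:
                for r in range(3):
                    rows.append({"task_id": td.task_id, "start_s": t + 10 * r,
                                 "end_s": t + 10 * r + 9, "rep_index": r})
                t += 40
            else:
                rows.append({"task_id": td.task_id, "start_s": t, "end_s": t + 10,
                             "rep_index": np.nan})
                t += 20
        windows = segment_tasks((0.0, t), "lab", markers=pd.DataFrame(rows))
        assert len(windows) == 12
        rom = [w for w in windows if len(w.reps) == 3]
        assert len(rom) == 9


class TestUpsampleLabels:
    def test_constant_fill(self):
        labels = ActivityLabels(np.arange(3.0), np.array(["standing"] * 3, dtype=object))
        t = np.arange(60) / RATE
        out = upsample_labels(labels, t, RATE)
        assert np.all(out == "standing")
        assert out.size == 60

    def test_alternating_blocks(self):
        labels = ActivityLabels(np.arange(4.0), np.array(
            ["sitting", "standing", "sitting", "standing"], dtype=object))
        t = np.arange(80) / RATE
        out = upsample_labels(labels, t, RATE)
        assert np.all(out[:20] == "sitting")
        assert np.all(out[20:40] == "standing")

    def test_gap_becomes_unknown(self, caplog):
        labels = ActivityLabels(np.array([0.0, 2.0]), np.array(["sitting", "sitting"], dtype=object))
        t = np.arange(60) / RATE
        with caplog.at_level("WARNING"):
            out = upsample_labels(labels, t, RATE)
        assert np.all(out[20:40] == UNKNOWN_LABEL)
        assert (out == UNKNOWN_LABEL).sum() == 20

    def test_duration_conservation(self):
        rng = np.random.default_rng(0)
        acts = np.array(["sitting", "standing", "stepping", "lying", "transport"], dtype=object)
        labels = ActivityLabels(np.arange(50.0), rng.choice(acts, 50))
        t = np.arange(1000) / RATE
        out = upsample_labels(labels, t, RATE)
        durations = label_durations(out, RATE)
        for a in acts:
            assert durations.get(str(a), 0.0) == pytest.approx(float((labels.labels == a).sum()))
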