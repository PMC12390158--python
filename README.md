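# spineimu

Lumbar spine posture analysis from paired trunk-worn inertial sensors.

The package implements a complete, testable analysis chain for multi-day
recordings from two spine-mounted IMUs (T12/L1 and L5/S1) plus a thigh
sensor and a per-second activity-label track:

1. **Synchronization** (`spineimu.sync`) — inter-sensor lag estimation by
   cross-correlating acceleration magnitudes at hourly checkpoints, linear
   clock-drift fitting, and resampling onto one master clock.
2. **Gyro bias** (`spineimu.bias`) — stillness detection by gyroscope
   thresholding (runs ≥ 5 s), a piecewise-linear per-axis bias model, and
   subtraction before fusion.
3. **Orientation** (`spineimu.orientation`) — a gradient-descent MARG
   complementary filter (gain 0.1 at 20 Hz) producing unit quaternions per
   sensor, and lumbar joint Euler angles
   (`conj(q_lower) ⊗ q_upper`, intrinsic z–y′–x″: axial rotation,
   flexion–extension, lateral flexion).
4. **Segmentation** (`spineimu.segmentation`) — hop-burst detection
   (≥ 4 threshold crossings with 2 s quiet margins), task-session finding
   (≥ 10 bursts within an hour), task/repetition windows from experimenter
   flags, marker files, or automatic protocol-order splitting, plus 1 Hz →
   20 Hz label up-sampling.
5. **Quality** (`spineimu.quality`) — magnetic-disturbance rules
   (> 30 % instantaneous, > 15 % sustained ≥ 30 s, > 30° inclination,
   either-sensor exclusion), seated-transport padding (± 5 min), and
   non-physiological joint angles (> 70° flexed / > 50° extended), with
   per-reason and union exclusion fractions.
6. **Reference postures** (`spineimu.reference`) — the five zeroing
   strategies: lab, session, day, composite (median over all task
   windows), and median standing.
7. **Outcomes** (`spineimu.outcomes`) — range of motion and starting
   posture per task, repetition averaging, and ICC(A,k) (two-way random
   effects, absolute agreement, average measures) with interpretation
   bands.
8. **Simulation** (`spineimu.simulate`) — synthetic cohorts with ground
   truth for every stage: the 12-task scripted protocol with 5-hop bursts,
   Markov-chain free-living filler, clock skews, drifting gyro bias,
   mounting offsets, and scripted magnetic disturbances, with analytically
   known population ICCs.

## CLI

```bash
# generate a synthetic cohort with truth manifests
spineimu simulate --n 4 --seed 1 --out cohort/

# run the full pipeline (sync → bias → orient → segment → qc → reference → ICC)
spineimu run --in cohort/ --out run/ --seed 1

# repeatability report from an outcome table
spineimu icc --in run/outcomes.csv --out icc.csv --measure start

# quality report for a single raw stream
spineimu qc --in cohort/P01/rw/lower.csv --labels cohort/P01/rw/labels.csv --out qc.json
```

All artifacts are plain text (CSV / JSON); `run/manifest.json` lists every
file written together with the configuration, seed, and per-stage sample
counts. Runs are fully deterministic given a seed.

## Data formats

Sensor tables: CSV with columns
`time_s, ax_g, ay_g, az_g, gx_dps, gy_dps, gz_dps, mx, my, mz`
(acceleration in g, rate in deg/s, magnetometer normalized to unit
undisturbed field). Labels: `time_s, activity` at 1 Hz with activities
`sitting, standing, stepping, lying, transport`. Markers:
`task_id, start_s, end_s[, rep_index]`. Flags: `event_time_s, flag_type`.
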