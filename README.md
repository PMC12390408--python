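# freezekin

Foot-mounted IMU gait analysis: gait-event detection from the sagittal
gyroscope, four-phase stride segmentation, Gait Phase Quality Index (GPQI),
ZUPT-based stride length / walking speed / foot clearance, method-agreement
statistics against an optoelectronic reference trajectory, and the two-group
comparison machinery used for cohort studies — all driven by a ground-truthed
synthetic gait generator.

## What it computes

Given a trial of synchronized accelerometer (m/s²), gyroscope (°/s) and
orientation-quaternion streams from a foot-worn IMU sampled at 100 Hz:

1. **Events** — heel strike (HS), toe strike (TS), heel off (HO) and toe off
   (TO) from the low-pass-filtered sagittal angular velocity. Stride cycles
   are delimited by consecutive dominant swing peaks; HS/TO are the
   stance-adjacent maxima and TS/HO the 30 °/s threshold crossings of |ω|.
2. **Temporal parameters** — stride time (HS→HS), loading-response /
   midstance / pre-swing / swing percentages of stride time, cadence
   (strides/min, floored), and GPQI, the squared discrepancy between a
   subject's phase distribution and a healthy-reference distribution
   (`as_printed` and `per_foot_sqrt` variants).
3. **Spatial parameters** — zero-velocity-update (ZUPT) dead reckoning:
   specific force rotated to the global frame via the quaternions, gravity
   removed, velocity zeroed on flat-foot (TS→HO) intervals and integrated per
   moving span with a linear detrend; stride length is the peak horizontal
   displacement between consecutive HS events, speed is SL/ST, and foot
   clearance is the relative vertical displacement with landmarks Max1 / Min /
   Max2 inside each swing.
4. **Agreement** — per-stride clearance landmarks compared against a
   marker-based reference: mean absolute and relative errors, and
   Bland–Altman bias with 95 % limits of agreement (IMU − reference, so a
   negative bias is IMU underestimation).
5. **Group statistics** — Shapiro–Wilk normality gating, then two-sided
   Mann–Whitney U (non-normal) or independent-samples t-tests (normal) on the
   standard eight group comparisons (HC vs the parkinsonian OFF/ON and
   FOG/no-FOG subgroups).

Because no real recordings ship with the package, the `synthetic` module is a
first-class citizen: it builds C² foot trajectories with exact, analytically
known events, stride lengths and clearance landmarks, synthesizes IMU and
marker streams from them (with configurable noise and bias), and draws
multi-group cohorts with prescribed between-subject distributions.

## CLI

```sh
# write a synthetic trial (IMU csv, marker csv, ground-truth table)
freezekin simulate --out trial/ --seed 1 --n-strides 12

# per-stride spatiotemporal metrics
freezekin extract trial/imu.csv --config config.yml --out metrics.csv

# clearance agreement against a reference marker track
freezekin validate trial/imu.csv trial/markers.csv --out report/
```

`config.yml` mirrors `freezekin.PipelineConfig`; every default is
overridable. Field defaults follow the published processing choices
(order-2 Butterworth, 3 Hz gyro / 10 Hz accel cutoffs, 30 °/s threshold,
10 central strides per walking bout). For synthetic trials use
`freezekin.synthetic.analysis_config()`, which raises the cutoffs to match
the template bandwidth and switches to spline integration (see the module
docstrings for rationale).

```python
import freezekin as fk

params = fk.GaitModelParams(n_strides=20, gyro_noise_dps=2.0, seed=0)
truth, traj = fk.generate_trajectory(params)
rec = fk.simulate_imu(traj, params)
result = fk.run_trial(rec, fk.synthetic.analysis_config())
print(result.to_frame())
```

## Layout

| module | contents |
|---|---|
| `freezekin.io_config` | file readers/writers, `PipelineConfig`, zero-phase Butterworth |
| `freezekin.events` | stride windowing, HS/TS/HO/TO detection, central-stride selection |
| `freezekin.temporal` | stride time, phase percentages, cadence, GPQI |
| `freezekin.spatial` | gravity removal, ZUPT velocity, stride length, speed, clearance |
| `freezekin.agreement` | reference normalization, landmark pairing, error metrics, Bland–Altman |
| `freezekin.group_stats` | normality gate, two-group tests, comparison grid |
| `freezekin.synthetic` | ground-truthed gait generator, IMU/marker simulation, cohorts |
| `freezekin.pipeline` | per-trial orchestration used by the CLI |
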