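# magdist

Magnetic distance estimation for wearable human-motion tracking.

Clinical gait analysis needs accurate *relative* (point-to-point) distances
between the lower extremities, but wearable IMU setups struggle to deliver
them. One alternative is active magnetic tracking: body-worn triaxial coil
actuators emit AC dipole fields near 7.5 kHz, and triaxial magnetoelectric
(ME) cantilever magnetometers — body-worn and stationary — measure them.
Magnetic fields pass through the body (no line-of-sight problem) but decay
with 1/r³, and early-stage ME sensors are sharply resonant and imperfectly
orthogonal, so the signal chain and calibration do the heavy lifting.
`magdist` implements that full chain in software, validated end-to-end on a
bundled synthetic-data simulator standing in for the hardware and the
optical reference system.

## The estimator

Each actuator–sensor pair yields a 3×3 normalized field matrix Θ (rows =
sensor axes, columns = actuator coils). For an ideal dipole source,

```
Θ(r⃗, R) = (1/r³) · R · Φ(e⃗ᵣ),     Φ(e⃗) = ½ (3 e⃗ e⃗ᵀ − I)
```

The directivity matrix Φ is symmetric, traceless, and has ‖Φ‖²_F = 3/2 for
*every* unit direction, while the rotation R cannot change a Frobenius
norm. Distance therefore follows in closed form:

```
r̂ = ( √(3/2) / ‖Θ‖_F )^(1/3)
```

Real sensors distort the measured matrix Θ̃ (sensitive-axis tilt, gain
errors, assembly misalignment). The *spatial calibration* corrects each
column θ̃ᵢ with its own 3×3 weighting matrix Wᵢ — 27 weights per pair,
estimated by gradient descent on the mean squared distance error against
ground truth, with an Armijo backtracking line search (α₀ = 1000, ρ = 0.8,
σ = 10⁻⁴, tolerance 10⁻¹⁵ m², ≤ 2000 iterations).

Upstream, the package provides the FDMA measurement chain: six excitation
tones (7425–7675 Hz, 50 Hz spacing, one per actuator coil), a resonant
band-pass sensor model, amplitude-response characterization from
band-limited-noise recordings (|H| = √(S_yy/S_vv), Welch-averaged),
parametric peak-filter equalizer design (coarse bandpass fit refined by an
exhaustive 61×121×16 parameter sweep minimizing the dB-domain MAE over
7.4–7.7 kHz), and matched-filter demodulation (40 ms quadrature correlation
per 512-sample frame at 48 kHz → signed tone amplitudes at 93.75 Hz).

## Worked example

```python
import numpy as np
from magdist import (PoseSample, field_matrix, estimate_distance,
                     calibrate, estimate_trace, error_metrics)
from magdist.synthetic import TrajectoryConfig, DistortionConfig, build_dataset

# closed-form inversion of an ideal pose
pose = PoseSample(position=[0.25, 0.10, -0.05])
print(f"true {pose.r:.4f} m, estimated {estimate_distance(field_matrix(pose)):.4f} m")

# calibrate one gait pair on distorted, noisy synthetic data and validate
dist = DistortionConfig(seed=7)
train = build_dataset(TrajectoryConfig(scenario="B", duration_s=120.0, seed=21),
                      dist, "train")
val = build_dataset(TrajectoryConfig(scenario="B", duration_s=120.0,
                                     walking_speed_m_s=1.0, seed=21),
                    dist, "validation")
res = calibrate(train.pairs["A0-S0"])
tr = val.pairs["A0-S0"]
before = error_metrics(estimate_trace(tr.theta, time_s=tr.time_s, r_true_m=tr.r))
after = error_metrics(estimate_trace(tr.theta, w=res.w, time_s=tr.time_s, r_true_m=tr.r))
print(f"{res.iterations} iterations, MAE {100*before.mae_m:.2f} -> {100*after.mae_m:.2f} cm")
```

prints

```
true 0.2739 m, estimated 0.2739 m
824 iterations, MAE 0.16 -> 0.01 cm
```

The first line shows the noiseless closed form is exact; the second shows
the 27-weight calibration removing the systematic error of a simulated
tilted/mis-gained sensor during treadmill-gait motion (training at 0.5 m/s,
validation at 1 m/s), leaving only the noise-floor residual.

The same workflow is available from the shell:

```sh
magdist simulate --scenario B --speed 0.5 --seed 21 --distortion-seed 7 -o data/train_B
magdist calibrate --dataset data/train_B --pair A0-S0 -o calib.json
magdist estimate --dataset data/val_B --weights calib.json -o traces/
magdist evaluate --traces traces/ -o report.json
```

(plus `characterize`, `equalize`, `demodulate` for the raw signal chain and
`crossval` for the full train/validate table).

## Scope

The package covers the software chain only: hardware (coils, PCBs,
amplifiers), optical motion-capture processing, real-time runtimes, and
acoustic/mechanical noise suppression are out of scope. The synthetic gait
model is a deliberately minimal kinematic toy that reproduces the signal
morphology relevant to the estimator, not subject biomechanics — see
`docs/methods.md` for the model details and its limits.
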