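# Methods

This note documents the models, parameter choices and numerical decisions
behind `magdist`, and what the synthetic validation does and does not show.

## Dipole forward model (`magdist.dipole`)

A triaxial coil actuator is modelled as three orthogonal point dipoles at a
common origin. The normalized field matrix of a pair is
Θ(r⃗, R) = (1/r³) R Φ(e⃗ᵣ) with Φ(e⃗) = ½(3 e⃗e⃗ᵀ − I). Θ is emitted in
units where the per-pair actuator-moment constant is exactly 1 — the
absolute scale linking drive current to field is not needed for distance
estimation (it cancels in no way, but the spatial-calibration weights
absorb any residual per-pair gain, and for real voltage data a scalar gain
from the sensitivity characterization must be supplied in config).

Conventions: actuator-centered right-handed frame; e⃗ᵣ points from actuator
to sensor; Θ rows index sensor axes, columns index actuator coils. Unit
directions are validated (|‖e‖² − 1| ≤ 1e-9) and never silently
renormalized. Ranges below 1 mm log a warning (model validity) rather than
raising; r = 0 raises.

## Distance estimator (`magdist.estimator`)

r̂ = (√(3/2)/‖Θ‖_F)^(1/3), exact on noiseless model data at any distance
and invariant to sensor orientation. The weighted variant multiplies column
i of Θ̃ by Wᵢ before taking the norm.

Weight-vector layout: `w.reshape(3, 3, 3)` has axes `[coil, row, column]` —
elements 0–8 are W_x row-major (applied to the x-coil column), then W_y,
then W_z. With identity weights the weighted path returns the unweighted
result bit-identically (each inner product is the original entry plus exact
zeros), which is pinned by a unit test. All distances are meters
internally; centimeters appear only in report formatting.

`estimate_trace` flags frames with non-finite or all-zero matrices as
invalid instead of raising, so one corrupt frame cannot abort a trace.

## Spatial calibration (`magdist.calibration`)

Cost: c(w) = (1/N) Σₙ (r(n) − r̂(n, w))² in m², over valid frames (invalid
frames are excluded with a logged count and N reduced). Optimization is
plain gradient descent with Armijo backtracking, defaults α₀ = 1000,
ρ = 0.8, σ = 10⁻⁴, improvement tolerance 10⁻¹⁵ m² (applied to c itself, in
m², matching the tolerance's printed unit), cap 2000 iterations,
initialization at identity weights so iteration 0 *is* the uncalibrated
estimator and training can only improve on it.

The analytic gradient uses the chain rule through
r̂ = (3/2)^{1/6} u^{−1/6}, u(n) = Σᵢ‖Wᵢθ̃ᵢ(n)‖²:

∂c/∂W[c,r,j] = −(2/3N) Σₙ (r̂−r) (r̂/u) v[n,c,r] θ̃[n,j,c],
v[n,c,·] = W_c θ̃_c(n).

It is verified against central finite differences (h = 10⁻⁶, relative
error < 10⁻⁶) on random instances; a finite-difference mode is also
available as an option.

Performance: along a descent line w − αg the weighted squared norm is an
exact quadratic in α, u(α) = u₀ − 2αs₁ + α²s₂, so every backtracking trial
costs three vector operations instead of a full re-weighting. Trials are
evaluated in blocks of 24 ladder steps; the mathematics (first accepted
α₀ρᵐ) is unchanged. A full calibration on 11 250 frames takes a few
seconds.

Identifiability: the cost depends on w only through norms, so weights are
recoverable at most up to per-column-block orthogonal transformations.
Calibration quality is therefore always judged on distances, never on raw
weight values.

Termination labels: `converged` (improvement below tolerance),
`max_iterations`, `zero_gradient`. Armijo acceptance guarantees the cost
history is non-increasing; a line search that exhausts the ladder below
10⁻³⁰ raises (pathological scaling). Multi-dataset training concatenates
traces with uniform sample weights, so the merged MSE is the N-weighted
mean of per-set MSEs.

## Signal chain (`magdist.signal_chain`)

**FDMA plan.** Six tones, 7425–7675 Hz at 50 Hz spacing (three per
actuator), 25 Hz channel bandwidth — spacing exactly twice the channel
bandwidth. Envelopes (motion) above half the tone spacing are rejected.
With the 40 ms matched-filter window every tone and every 50 Hz offset
completes an integer number of cycles, so channels are mutually orthogonal
over the window and adjacent-channel leakage is at the numerical floor.

**Resonator model.** One ME sensor axis is a second-order band-pass
H(s) = S(ω₀/Q)s/(s² + (ω₀/Q)s + ω₀²), Q = f_res/bw: peak gain exactly S at
f_res and −3 dB bandwidth exactly bw. It is applied in the frequency
domain (rfft multiply with the analog response) rather than as a
bilinear-discretized IIR: at 7.4–7.8 kHz and 48 kHz sampling, bilinear
frequency warping would shift the resonance by far more than the ~30 Hz
bandwidth unless prewarped, and the exact complex response is needed by
the phase-aware equalizer anyway. The wrap-around transient affects only
the first ~Q/(πf₀) ≈ 10 ms, which demodulation settling skips.

**Characterization.** |H| = √(S_yy/S_vv) from band-limited-noise (6–9 kHz)
records, Welch-averaged periodograms with 50 % overlap and a default
segment length of 48 000 samples (1 Hz resolution). Because numerator and
denominator share the same excitation realization their fluctuations
largely cancel in the ratio, so ~10 s records already give < 0.5 dB
accuracy. The quoted sensor noise floor ("10 pT/Hz at resonance" for the
hardware) is exposed as an amplitude-spectral-density parameter of the
simulator without asserting the unit interpretation.

**Peak-filter parametrization.** The equalizer model is the audio
parametric-EQ peaking biquad (gain-symmetric: negating the dB gain gives
the exact inverse). Its bandwidth parameter is defined as the **−3 dB-below-
peak width**: solving |H| = peak/√2 for the digital biquad gives a width of
exactly 2·arctan(αA/√(A⁴−2)) rad, which is inverted for α. This matches
what the coarse bandpass fit measures on a spectrum, so the sweep ranges
centered on that fit actually bracket the optimum — with the common
mid-gain convention the two bandwidth notions differ by a gain-dependent
factor larger than the sweep span. For |gain| ≤ 3.01 dB such a width does
not exist and the conventional mid-gain form is used (identical filters at
0 dB). Fitted sensor gains are tens of dB, far from that regime.

**Sweep fit.** Exhaustive refinement over f₀ ± 3 Hz (0.1 Hz), Δf₀ ± 6 Hz
(0.1 Hz) and G₀ − 15…G₀ dB (1 dB) around the bandpass-fit init — 118 096
combinations, vectorized per gain — minimizing the mean absolute error in
dB over 7.4–7.7 kHz. The init is rounded onto the sweep resolution so it is
itself a grid member, guaranteeing the sweep never does worse. Because the
measured spectrum carries an arbitrary absolute scale while the model is
referenced to a 0 dB floor, each combination is compared at its L1-optimal
dB offset (the median difference); this makes on-grid generating
parameters exactly recoverable. Ties break toward the init center
frequency, then init bandwidth, then larger gain.

**Demodulation.** Per tone, the trailing 1920-sample (40 ms) rectangular
window — the matched filter for a sinusoid in white noise — is correlated
against quadrature references once per 512-sample frame (73 % window
overlap between successive frames), giving signed amplitudes at exactly
93.75 Hz. Frames are timestamped at the window end; the first three frames
(incomplete window) are dropped. Sign comes from the known excitation
phase. Two output projections: `inphase` (Re(z·e^{−jφ}); unbiased under
noise, needs phase-accurate equalization) and `magnitude`
(sign(Re)·|z|; robust to the residual phase error of amplitude-only
equalization). Default is `inphase`.

**Equalizer application.** Corrections are applied per tone in the
frequency domain (divide the demodulated complex amplitude by the model
response at the tone frequency) rather than filtering the raw stream —
equivalent for fixed narrowband tones and much cheaper. Two equalizer
classes: the fitted peak-filter inverse (amplitude plus model phase — the
true sensor phase is unobservable from the amplitude-only
characterization), optionally rescaled by the measured peak sensitivity to
convert volts to field units; and the exact resonator inverse for
simulation, where drive and demodulator are phase-locked. For real
recordings a phase-alignment preprocessing step would be required before
the `inphase` projection is meaningful; this is intentionally not modelled.

## Synthetic data (`magdist.synthetic`)

**Scenario A** (arbitrary motion): distance, direction angles and Euler
orientation angles are independent sums of five sinusoids with random
frequencies ≤ 2 Hz, normalized by the sum of amplitudes so corridor
containment (default 0.15–0.60 m) and a finite-difference speed bound hold
*analytically*, not per-sample. Deterministic per seed.

**Scenario B** (gait): a deliberately minimal planar two-leg pendulum.
Hips oscillate at the stride frequency with legs phase-opposed; a smooth
once-per-cycle knee flexion (A(½−½cos(φ−δ))²) is superimposed; step
frequency is walking_speed / step_length (0.5 m default step → 1 Hz at
0.5 m/s). Geometry: hip height 0.85 m, hip half-width 0.10 m, thigh and
shank 0.40 m, actuators at shank midpoints, sensors at thigh midpoints,
stationary stands 0.50 m high at ±0.30 m lateral and 0.20 m anterior
offset. The anterior stand offset is what makes the stand-to-shank
distance fundamental sit at the stride frequency (the lateral term enters
squared and would otherwise frequency-double). The model reproduces the
morphology that matters downstream — contralateral shank–thigh distances
at twice the stride frequency, knee flexion on the ipsilateral pair, exact
left/right symmetry under a half-cycle shift, reduced modulation for the
far stand — and nothing else: no double support, no pelvis motion, no
ground contact. A per-recording random phase and a ±5 % amplitude jitter
(shared by both legs) stand in for subject variability.

**Distortion.** Per sensor: each nominal axis tilted by a uniform random
angle up to 3° about a random perpendicular axis, per-axis gains uniform in
[0.9, 1.1], cross-coupling I + N(0, 0.02) off-diagonals; composed as
D = C·diag(g)·T and applied to the rows (sensor side) of Θ. Additive
Gaussian frame noise with σ = 0.01 normalized field units — constant in
field units, so SNR falls as 1/r³ like the signal. Body-worn (thigh)
sensors additionally get motion-artifact bursts (probability 0.005 per
frame, amplitude 0.05). The burst statistics are an assumption — real
artifact statistics are not characterized — and all of these defaults were
chosen once as plausible magnitudes for hand-assembled early-stage sensor
arrays; they are configuration, not fit parameters. Noise is injected at
frame level by default; the raw-stream path (tone synthesis → resonator →
demodulation) exists for end-to-end consistency tests.

**Determinism.** Trajectory randomness derives from (trajectory seed,
split, pair); the distortion matrices derive from (distortion seed, sensor)
only — hardware identity is shared across splits, which is what makes
calibration transfer from training to validation. Measurement noise is
drawn per split and pair. Datasets carry a manifest from which they
regenerate bit-identically.

## Evaluation (`magdist.evaluation`)

Metrics per trace: MAE, RMSE, signed mean error and population std (so
RMSE² = mean² + std²), plus per-distance-bin mean ± std summaries (2 cm
bins) for estimated-versus-true plots. The cross-validation table rows are
training conditions (none, A, B, A+B-pooled), columns validation
scenarios; cells hold the unweighted mean of per-pair MAEs and the
worst-pair MAE. Calibration runs independently per actuator–sensor pair;
pairs missing from a set are warned about and excluded. Formatting is in
centimeters with one decimal.

## Problem sizes

The bundled validation uses Scenario A with 80 s training / 60 s
validation per pair and Scenario B with 120 s per split (0.5 m/s training,
1.0 m/s validation), all eight pairs, at 93.75 Hz — 5 625–11 250 frames
per trace and 24 calibrations for the full table. These sizes were chosen
as representative recording lengths for this kind of experiment; the full
harness runs in a few minutes on one CPU.

## What the synthetic validation shows — and does not

Passing tests demonstrate that the estimator is an exact inverse of the
dipole model, that the signal chain reconstructs field matrices from raw
voltages to numerical precision under phase-locked equalization, and that
the calibration removes recoverable (invertible, per-column) linear
distortions to the noise floor, with the qualitative cross-validation
pattern — training on matching data strictly reduces validation error —
reproduced. They do *not* establish hardware-level accuracy: real sensors
add unmodelled position offsets of the sensing elements, environmental
soft/hard-iron distortion, acoustic/mechanical pickup with unknown
statistics, and optical-reference alignment error. Absolute MAE values on
synthetic data depend directly on the assumed distortion and noise
magnitudes and are not comparable to measurements on real recordings.

## Known limitations

- The 27-weight model corrects only column-wise linear distortions; sensor
  element position offsets and field nonidealities are outside its class.
- Amplitude-only characterization leaves the sensor phase unknown; signed
  demodulation of real data needs a phase-alignment step (stubbed).
- Gradient descent with backtracking is deliberately simple; no
  regularization, minibatching, or joint multi-pair calibration.
- The gait generator is a signal-morphology toy, unsuitable for any
  biomechanical inference.
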