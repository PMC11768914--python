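"""Synthetic trajectory, distortion and dataset generation.

Every downstream stage (estimation, calibration, evaluation) is exercised on
data from this module: smooth arbitrary motion of an actuator around a sensor
("Scenario A", the technical-calibration style of recording) and a gait-like
setup of two shank-mounted actuators with two thigh-worn and two stationary
sensors on a treadmill ("Scenario B").

The gait generator is a deliberately minimal planar two-leg pendulum toy —
hips oscillate at stride frequency with the two legs phase-opposed, and a
smooth once-per-cycle knee flexion is superimposed.  It reproduces the
qualitative structure of real traces (contralateral shank-thigh distances at
twice the stride frequency, knee flexion on the ipsilateral pair, left/right
symmetry under a half-cycle shift, reduced modulation for the far stationary
stand) without claiming biomechanical fidelity.

Measurement distortion composes, per sensor, a sensitive-axis tilt of each
nominal axis, per-axis gain errors and a near-identity cross-coupling
matrix, plus frame-level additive noise (constant in normalized field units,
so the SNR falls with r^3 like the signal) and optional motion-artifact
bursts on body-worn sensors.  Datasets carry a generation manifest and are
regenerable bit-identically from it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Mapping

import numpy as np
from scipy.spatial.transform import Rotation

from . import __version__
from .calibration import PairedTrace
from .dipole import field_matrices
from .signal_chain import ExcitationConfig, ResonatorModel, apply_resonator

__all__ = [
    "PoseSeries",
    "TrajectoryConfig",
    "DistortionConfig",
    "DistortionModel",
    "SyntheticDataset",
    "gen_arbitrary_trajectory",
    "gen_gait_trajectories",
    "apply_distortion",
    "build_dataset",
    "dataset_from_manifest",
    "resample_truth",
    "render_sensor_voltage",
    "GAIT_PAIR_IDS",
    "BODY_WORN_SENSORS",
    "SENSOR_IDS",
]

SENSOR_IDS = ("S0", "S1", "S2", "S3")
ACTUATOR_IDS = ("A0", "A1")
#: Thigh-mounted sensors (subject to motion-artifact bursts).
BODY_WORN_SENSORS = ("S0", "S1")
GAIT_PAIR_IDS = tuple(f"{a}-{s}" for a in ACTUATOR_IDS for s in SENSOR_IDS)

_SPLIT_CODES = {"train": 1, "validation": 2}

# Scenario-A trajectory construction constants (exported for the analytic
# speed bound: |velocity| <= hw*2*pi*f_max + r_max*(POLAR + pi)*2*pi*f_max).
SCENARIO_A_COMPONENTS = 5
SCENARIO_A_POLAR_AMP = 0.9  # rad, polar-angle excursion about the equator
SCENARIO_A_EULER_AMP = np.pi / 2  # rad, orientation Euler-angle excursion

# Gait-model geometry (meters) and kinematic amplitudes (radians).  The
# values are round numbers for an adult on a treadmill; only the signal
# morphology matters downstream.
_HIP_HEIGHT = 0.85
_HIP_HALF_WIDTH = 0.10
_L_THIGH = 0.40
_L_SHANK = 0.40
_A_HIP = 0.30
_A_KNEE = 1.00
_KNEE_LAG = 0.5
_STAND_LATERAL = 0.30
_STAND_FORWARD = 0.20
_STAND_HEIGHT = 0.50


@dataclass
class PoseSeries:
    """Time series of actuator-relative sensor poses."""

    time_s: np.ndarray
    position: np.ndarray  # (N, 3) meters
    rotation: np.ndarray  # (N, 3, 3)

    @property
    def distances(self) -> np.ndarray:
        return np.linalg.norm(self.position, axis=1)

    def __len__(self) -> int:
        return self.time_s.size


@dataclass
class TrajectoryConfig:
    """Scenario selection and motion parameters.

    Scenario ``"A"``: smooth arbitrary motion (band-limited below
    ``max_band_hz``) confined to the distance corridor, with smoothly
    varying orientation.  Scenario ``"B"``: treadmill gait at
    ``walking_speed_m_s`` with step frequency ``speed / step_length``.
    """

    scenario: str = "A"
    duration_s: float = 120.0
    frame_rate_hz: float = 93.75
    corridor_m: tuple[float, float] = (0.15, 0.60)
    max_band_hz: float = 2.0
    walking_speed_m_s: float = 0.5
    step_length_m: float = 0.5
    pairs: tuple[str, ...] = GAIT_PAIR_IDS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scenario not in ("A", "B"):
            raise ValueError("scenario must be 'A' or 'B'")
        if self.duration_s <= 0:
            raise ValueError("duration must be positive")
        if self.corridor_m[0] <= 0 or self.corridor_m[1] <= self.corridor_m[0]:
            raise ValueError("corridor must satisfy 0 < min < max")
        self.corridor_m = tuple(float(c) for c in self.corridor_m)
        self.pairs = tuple(self.pairs)


def _smooth_signal(
    rng: np.random.Generator, t: np.ndarray, f_hi: float, f_lo: float = 0.05
) -> np.ndarray:
    """Random smooth signal bounded to [-1, 1] with |derivative| <= 2 pi f_hi.

    Sum of ``SCENARIO_A_COMPONENTS`` sinusoids with random frequencies in
    [f_lo, f_hi], normalized by the sum of amplitudes (an amplitude bound,
    not a per-sample normalization, so the derivative bound is analytic).
    """
    a = rng.uniform(0.5, 1.0, SCENARIO_A_COMPONENTS)
    f = rng.uniform(f_lo, f_hi, SCENARIO_A_COMPONENTS)
    phi = rng.uniform(0.0, 2.0 * np.pi, SCENARIO_A_COMPONENTS)
    s = np.sum(
        a[:, None] * np.sin(2.0 * np.pi * f[:, None] * t[None, :] + phi[:, None]),
        axis=0,
    )
    return s / np.sum(a)


def gen_arbitrary_trajectory(
    cfg: TrajectoryConfig, rng: np.random.Generator | None = None
) -> PoseSeries:
    """Scenario-A pose series: smooth random motion inside the corridor.

    Deterministic for a given seed (``cfg.seed`` unless an rng is passed).
    """
    if cfg.scenario != "A":
        raise ValueError("arbitrary trajectories require scenario 'A'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n) / cfg.frame_rate_hz
    lo, hi = cfg.corridor_m
    mid, hw = 0.5 * (lo + hi), 0.5 * (hi - lo)
    r = mid + hw * _smooth_signal(rng, t, cfg.max_band_hz)
    polar = np.pi / 2 + SCENARIO_A_POLAR_AMP * _smooth_signal(rng, t, cfg.max_band_hz)
    azim = np.pi * _smooth_signal(rng, t, cfg.max_band_hz)
    e = np.stack(
        [np.sin(polar) * np.cos(azim), np.sin(polar) * np.sin(azim), np.cos(polar)],
        axis=1,
    )
    pos = r[:, None] * e
    angles = np.stack(
        [SCENARIO_A_EULER_AMP * _smooth_signal(rng, t, cfg.max_band_hz) for _ in range(3)],
        axis=1,
    )
    rot = Rotation.from_euler("xyz", angles).as_matrix()
    return PoseSeries(time_s=t, position=pos, rotation=rot)


def _rot_x(angle: np.ndarray) -> np.ndarray:
    """Batch rotation matrices about the lateral (x) axis."""
    c, s = np.cos(angle), np.sin(angle)
    n = angle.size
    out = np.zeros((n, 3, 3))
    out[:, 0, 0] = 1.0
    out[:, 1, 1] = c
    out[:, 1, 2] = -s
    out[:, 2, 1] = s
    out[:, 2, 2] = c
    return out


def gen_gait_trajectories(
    cfg: TrajectoryConfig, rng: np.random.Generator | None = None
) -> dict[str, PoseSeries]:
    """Scenario-B pose series for all eight actuator-sensor pairs.

    Frame: x lateral (right positive), y anterior, z up; treadmill center at
    the origin.  A0/A1 are the right/left shank actuators, S0/S1 the
    left/right thigh sensors, S2/S3 the right/left stationary stands.  Step
    frequency is ``walking_speed / step_length`` and each leg swings at the
    stride frequency (half of it), legs phase-opposed — so contralateral
    relative distances oscillate at the step frequency, twice the stride
    frequency seen by the stationary stands.
    """
    if cfg.scenario != "B":
        raise ValueError("gait trajectories require scenario 'B'")
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = int(round(cfg.duration_s * cfg.frame_rate_hz))
    t = np.arange(n) / cfg.frame_rate_hz
    f_step = cfg.walking_speed_m_s / cfg.step_length_m
    f_stride = f_step / 2.0
    phase0 = rng.uniform(0.0, 2.0 * np.pi)
    amp_scale = rng.uniform(0.95, 1.05)
    a_hip = _A_HIP * amp_scale
    a_knee = _A_KNEE * amp_scale

    def leg(side: float, phase: float):
        phi = 2.0 * np.pi * f_stride * t + phase0 + phase
        th_h = a_hip * np.sin(phi)
        th_k = a_knee * (0.5 - 0.5 * np.cos(phi - _KNEE_LAG)) ** 2
        hip = np.column_stack(
            [np.full(n, side * _HIP_HALF_WIDTH), np.zeros(n), np.full(n, _HIP_HEIGHT)]
        )
        thigh_dir = np.column_stack([np.zeros(n), np.sin(th_h), -np.cos(th_h)])
        knee = hip + _L_THIGH * thigh_dir
        sh = th_h - th_k
        shank_dir = np.column_stack([np.zeros(n), np.sin(sh), -np.cos(sh)])
        actuator_pos = knee + 0.5 * _L_SHANK * shank_dir
        thigh_pos = hip + 0.5 * _L_THIGH * thigh_dir
        return {
            "actuator_pos": actuator_pos,
            "actuator_rot": _rot_x(sh),
            "thigh_pos": thigh_pos,
            "thigh_rot": _rot_x(th_h),
        }

    right = leg(+1.0, 0.0)
    left = leg(-1.0, np.pi)
    eye = np.broadcast_to(np.eye(3), (n, 3, 3)).copy()
    nodes = {
        "A0": (right["actuator_pos"], right["actuator_rot"]),
        "A1": (left["actuator_pos"], left["actuator_rot"]),
        "S0": (left["thigh_pos"], left["thigh_rot"]),
        "S1": (right["thigh_pos"], right["thigh_rot"]),
        "S2": (
            np.broadcast_to(
                [_STAND_LATERAL, _STAND_FORWARD, _STAND_HEIGHT], (n, 3)
            ).copy(),
            eye,
        ),
        "S3": (
            np.broadcast_to(
                [-_STAND_LATERAL, _STAND_FORWARD, _STAND_HEIGHT], (n, 3)
            ).copy(),
            eye,
        ),
    }
    out: dict[str, PoseSeries] = {}
    for act in ACTUATOR_IDS:
        p_a, r_a = nodes[act]
        r_a_t = np.swapaxes(r_a, 1, 2)
        for sen in SENSOR_IDS:
            p_s, r_s = nodes[sen]
            rel_pos = np.einsum("nij,nj->ni", r_a_t, p_s - p_a)
            rel_rot = r_a_t @ r_s
            out[f"{act}-{sen}"] = PoseSeries(
                time_s=t.copy(), position=rel_pos, rotation=rel_rot
            )
    return out


# ---------------------------------------------------------------------------
# Distortion
# ---------------------------------------------------------------------------


@dataclass
class DistortionConfig:
    """Statistical description of per-sensor measurement distortion."""

    max_tilt_deg: float = 3.0
    gain_range: tuple[float, float] = (0.9, 1.1)
    cross_coupling_std: float = 0.02
    noise_floor: float = 0.01  # normalized field units per frame, additive
    artifact_prob: float = 0.005  # per frame, body-worn sensors only
    artifact_amp: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_floor < 0:
            raise ValueError("noise floor must be nonnegative")
        self.gain_range = tuple(float(g) for g in self.gain_range)


@dataclass
class DistortionModel:
    """One realized distortion: ``theta_tilde = D @ theta + noise (+ bursts)``."""

    matrix: np.ndarray
    noise_floor: float = 0.0
    artifact_prob: float = 0.0
    artifact_amp: float = 0.0

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float).reshape(3, 3)

    @classmethod
    def draw(
        cls,
        cfg: DistortionConfig,
        rng: np.random.Generator,
        body_worn: bool = False,
    ) -> "DistortionModel":
        """Sample a distortion realization: tilt, gains, cross-coupling."""
        rows = np.empty((3, 3))
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            # random tilt of the sensitive axis away from nominal
            perp = rng.standard_normal(3)
            perp -= (perp @ e) * e
            perp /= np.linalg.norm(perp)
            angle = np.deg2rad(rng.uniform(0.0, cfg.max_tilt_deg))
            v = np.cos(angle) * e + np.sin(angle) * perp
            rows[i] = v
        gains = rng.uniform(*cfg.gain_range, 3)
        coupling = np.eye(3)
        off = ~np.eye(3, dtype=bool)
        coupling[off] += rng.normal(0.0, cfg.cross_coupling_std, 6)
        d = coupling @ np.diag(gains) @ rows
        return cls(
            matrix=d,
            noise_floor=cfg.noise_floor,
            artifact_prob=cfg.artifact_prob if body_worn else 0.0,
            artifact_amp=cfg.artifact_amp if body_worn else 0.0,
        )


def apply_distortion(
    theta: np.ndarray,
    model: DistortionModel,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Distort an ideal field-matrix series: ``D @ Theta`` plus noise/bursts.

    With the identity model and zero noise the input is returned unchanged
    (bitwise).  A singular distortion matrix raises (not invertible, the
    calibration model could never undo it).
    """
    th = np.asarray(theta, dtype=float)
    d = model.matrix
    if abs(np.linalg.det(d)) < 1e-12:
        raise ValueError("distortion matrix is singular")
    if np.array_equal(d, np.eye(3)):
        out = th.copy()
    else:
        out = np.einsum("ij,...jk->...ik", d, th)
    needs_rng = model.noise_floor > 0 or (
        model.artifact_prob > 0 and model.artifact_amp > 0
    )
    if needs_rng:
        if rng is None:
            raise ValueError("stochastic distortion requires an rng")
        if model.noise_floor > 0:
            out = out + rng.normal(0.0, model.noise_floor, out.shape)
        if model.artifact_prob > 0 and model.artifact_amp > 0:
            flat = out.reshape(-1, 3, 3)
            bursts = rng.random(flat.shape[0]) < model.artifact_prob
            n_b = int(np.count_nonzero(bursts))
            if n_b:
                flat[bursts] += model.artifact_amp * rng.standard_normal((n_b, 3, 3))
    return out


# ---------------------------------------------------------------------------
# Dataset assembly
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDataset:
    """Per-pair paired traces plus pose series and a generation manifest."""

    pairs: dict[str, PairedTrace]
    poses: dict[str, PoseSeries] = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def _derived_rng(*keys: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(keys))


def build_dataset(
    traj_cfg: TrajectoryConfig,
    distortion_cfg: DistortionConfig | None = None,
    split: str = "train",
) -> SyntheticDataset:
    """Generate a full synthetic dataset for one split.

    Trajectory randomness is derived from ``(traj_cfg.seed, split, pair)``,
    so train and validation splits differ by construction; the distortion
    matrices are derived from ``(distortion_cfg.seed, sensor)`` only — they
    describe the hardware and are therefore identical across splits, which
    is what makes calibration transfer from training to validation data.
    Measurement noise is drawn per split and pair.
    """
    if split not in _SPLIT_CODES:
        raise ValueError(f"split must be one of {sorted(_SPLIT_CODES)}")
    code = _SPLIT_CODES[split]

    if traj_cfg.scenario == "A":
        poses = {
            pid: gen_arbitrary_trajectory(
                traj_cfg, rng=_derived_rng(traj_cfg.seed, code, i)
            )
            for i, pid in enumerate(traj_cfg.pairs)
        }
    else:
        all_poses = gen_gait_trajectories(
            traj_cfg, rng=_derived_rng(traj_cfg.seed, code)
        )
        poses = {pid: all_poses[pid] for pid in traj_cfg.pairs}

    models: dict[str, DistortionModel] = {}
    if distortion_cfg is not None:
        for s_idx, sensor in enumerate(SENSOR_IDS):
            models[sensor] = DistortionModel.draw(
                distortion_cfg,
                _derived_rng(distortion_cfg.seed, s_idx),
                body_worn=sensor in BODY_WORN_SENSORS,
            )

    pairs: dict[str, PairedTrace] = {}
    for i, (pid, pose) in enumerate(poses.items()):
        theta = field_matrices(pose.position, pose.rotation)
        if distortion_cfg is not None:
            sensor = pid.split("-")[1]
            theta = apply_distortion(
                theta,
                models[sensor],
                rng=_derived_rng(distortion_cfg.seed, code, i, 7),
            )
        pairs[pid] = PairedTrace(
            theta=theta, r=pose.distances, time_s=pose.time_s, pair_id=pid
        )

    manifest = {
        "generator": "magdist.synthetic.build_dataset",
        "version": __version__,
        "split": split,
        "trajectory": asdict(traj_cfg),
        "distortion": asdict(distortion_cfg) if distortion_cfg is not None else None,
    }
    return SyntheticDataset(pairs=pairs, poses=poses, manifest=manifest)


def dataset_from_manifest(manifest: Mapping) -> SyntheticDataset:
    """Regenerate a dataset bit-identically from its manifest."""
    traj = dict(manifest["trajectory"])
    traj["corridor_m"] = tuple(traj["corridor_m"])
    traj["pairs"] = tuple(traj["pairs"])
    traj_cfg = TrajectoryConfig(**traj)
    dist_cfg = None
    if manifest.get("distortion") is not None:
        dist = dict(manifest["distortion"])
        dist["gain_range"] = tuple(dist["gain_range"])
        dist_cfg = DistortionConfig(**dist)
    return build_dataset(traj_cfg, dist_cfg, split=manifest["split"])


def resample_truth(
    time_src_s: np.ndarray, r_src_m: np.ndarray, time_target_s: np.ndarray
) -> np.ndarray:
    """Linear-interpolation resampler for ground truth onto the frame grid."""
    return np.interp(
        np.asarray(time_target_s, float),
        np.asarray(time_src_s, float),
        np.asarray(r_src_m, float),
    )


def render_sensor_voltage(
    theta: np.ndarray,
    frame_time_s: np.ndarray,
    excitation: ExcitationConfig,
    resonators: list[ResonatorModel],
    coil_tone_indices: tuple[int, int, int],
    duration_s: float | None = None,
) -> np.ndarray:
    """Raw 48 kHz voltage streams of one triaxial sensor node.

    The per-coil ideal field components (columns of ``theta``, given on the
    frame grid) amplitude-modulate the coil's excitation tone; each sensor
    axis then passes through its resonator model.  Returns ``(3, n_samples)``.
    """
    th = np.asarray(theta, dtype=float).reshape(-1, 3, 3)
    frame_time_s = np.asarray(frame_time_s, dtype=float)
    fs = excitation.sample_rate_hz
    if duration_s is None:
        duration_s = float(frame_time_s[-1])
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    field_sig = np.zeros((3, n))
    for col, tone_idx in enumerate(coil_tone_indices):
        f_tone = excitation.tone_frequencies_hz[tone_idx]
        amp = excitation.amplitudes[tone_idx]
        ph = excitation.phases_rad[tone_idx]
        carrier = amp * np.cos(2.0 * np.pi * f_tone * t + ph)
        for row in range(3):
            env = np.interp(t, frame_time_s, th[:, row, col])
            field_sig[row] += env * carrier
    if len(resonators) != 3:
        raise ValueError("one resonator model per sensor axis required")
    return np.stack(
        [apply_resonator(field_sig[i], resonators[i], fs) for i in range(3)]
    )
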