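import numpy as np
import pytest

from magdist.calibration import PairedTrace
from magdist.dipole import field_matrices
from magdist.synthetic import (
    DistortionConfig,
    DistortionModel,
    TrajectoryConfig,
    apply_distortion,
    gen_arbitrary_trajectory,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_poses(rng, n, r_range=(0.1, 0.8)):
    """Random poses: positions with |r| in r_range, proper random rotations."""
    from scipy.spatial.transform import Rotation

    e = rng.standard_normal((n, 3))
    e /= np.linalg.norm(e, axis=1)[:, None]
    r = rng.uniform(*r_range, n)
    rot = Rotation.random(n, rng=rng).as_matrix()
    return r[:, None] * e, rot, r


def make_distorted_trace(
    seed=3,
    duration_s=5.0,
    noise_floor=0.0,
    max_tilt_deg=3.0,
    gain_range=(0.9, 1.1),
    pair_id="A0-S0",
):
    """Short scenario-A paired trace with a drawn distortion (no artifacts)."""
    cfg = TrajectoryConfig(scenario="A", duration_s=duration_s, seed=seed)
    pose = gen_arbitrary_trajectory(cfg)
    theta = field_matrices(pose.position, pose.rotation)
    dcfg = DistortionConfig(
        seed=seed,
        noise_floor=noise_floor,
        artifact_prob=0.0,
        max_tilt_deg=max_tilt_deg,
        gain_range=gain_range,
    )
    model = DistortionModel.draw(dcfg, np.random.default_rng(seed))
    rng = np.random.default_rng(seed + 1) if noise_floor > 0 else None
    tilde = apply_distortion(theta, model, rng=rng)
    return PairedTrace(theta=tilde, r=pose.distances, time_s=pose.time_s, pair_id=pair_id)
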