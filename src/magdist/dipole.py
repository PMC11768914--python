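"""Ideal dipole forward model for a triaxial coil actuator and triaxial point sensor.

A triaxial magnetic actuator (three orthogonal coils on a common body) driven
with AC currents produces, at a point sensor a relative position ``r_vec``
away, a 3x3 *normalized field matrix* ``Theta``: column ``i`` holds the x/y/z
field components (in the sensor frame) generated by coil ``i``.  For an ideal
dipole source the matrix factorizes into a ``1/r^3`` decay, the sensor
orientation matrix ``R`` and a purely directional part ``Phi``::

    Theta(r_vec, R) = (1 / r**3) * R @ Phi(e_r),   e_r = r_vec / r

``Phi`` (the *directivity matrix*) is symmetric, traceless and has constant
squared Frobenius norm 3/2 for every unit direction — the property that makes
a closed-form distance estimate possible downstream.

Units: positions in meters; ``Theta`` in normalized field units where the
per-pair actuator-moment constant is absorbed into the normalization (a
scalar gain must be supplied in config when ingesting real voltages; the
spatial-calibration weights absorb any residual gain).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PoseSample",
    "directivity",
    "field_matrix",
    "field_matrices",
    "frobenius_norm",
    "DIRECTIVITY_NORM_SQ",
]

logger = logging.getLogger(__name__)

#: Squared Frobenius norm of the directivity matrix, identical for every
#: unit direction.
DIRECTIVITY_NORM_SQ = 1.5

_UNIT_TOL = 1e-9
_ORTHO_TOL = 1e-10
_MIN_RANGE_WARN_M = 1e-3


@dataclass
class PoseSample:
    """Actuator-relative sensor pose.

    Parameters
    ----------
    position:
        Relative position ``r_s - r_a`` in meters (actuator-centered,
        right-handed frame; the unit direction points from actuator to
        sensor).
    rotation:
        Sensor orientation as a proper rotation matrix (orthogonal,
        determinant +1).
    time_s:
        Timestamp in seconds (bookkeeping only).
    """

    position: np.ndarray
    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    time_s: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float).reshape(3)
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        r = float(np.linalg.norm(self.position))
        if r == 0.0:
            raise ValueError("pose position must be nonzero (|r| > 0)")
        if r < _MIN_RANGE_WARN_M:
            # Dipole model validity: warn, do not reject.
            logger.warning(
                "pose range %.2e m is below 1 mm; dipole model may not be valid", r
            )
        err = np.max(np.abs(self.rotation.T @ self.rotation - np.eye(3)))
        if err > _ORTHO_TOL or np.linalg.det(self.rotation) < 0:
            raise ValueError(
                "rotation must be orthogonal with determinant +1 "
                f"(orthogonality error {err:.2e})"
            )

    @property
    def r(self) -> float:
        """Actuator-sensor distance in meters."""
        return float(np.linalg.norm(self.position))


def directivity(e: np.ndarray) -> np.ndarray:
    """Directivity matrix ``Phi`` of the dipole field for unit direction ``e``.

    ``Phi = 1/2 * (3 e e^T - I)`` — symmetric, traceless, and with squared
    Frobenius norm 3/2 for any unit ``e``.

    Raises
    ------
    ValueError
        If ``e`` is not unit-norm within tolerance.  No silent
        renormalization is performed; callers must normalize explicitly.
    """
    e = np.asarray(e, dtype=float).reshape(3)
    nrm2 = float(e @ e)
    if abs(nrm2 - 1.0) > _UNIT_TOL:
        raise ValueError(f"direction must be unit-norm (|e|^2 = {nrm2!r})")
    return 0.5 * (3.0 * np.outer(e, e) - np.eye(3))


def field_matrix(pose: PoseSample) -> np.ndarray:
    """Normalized field matrix ``Theta`` of an ideal dipole actuator.

    ``Theta = (1/r^3) * R @ Phi(r_vec / r)``; rows index sensor axes,
    columns index actuator coils.
    """
    r = pose.r
    e = pose.position / r
    return (pose.rotation @ directivity(e)) / r**3


def field_matrices(positions: np.ndarray, rotations: np.ndarray | None = None) -> np.ndarray:
    """Vectorized :func:`field_matrix` over a pose series.

    Parameters
    ----------
    positions:
        ``(N, 3)`` relative positions in meters (all nonzero).
    rotations:
        ``(N, 3, 3)`` rotation matrices, or ``None`` for identity.

    Returns
    -------
    ``(N, 3, 3)`` array of field matrices.
    """
    p = np.asarray(positions, dtype=float).reshape(-1, 3)
    r = np.linalg.norm(p, axis=1)
    if np.any(r == 0.0):
        raise ValueError("all positions must be nonzero")
    e = p / r[:, None]
    # Phi = 1/2 (3 e e^T - I), batched.
    phi = 1.5 * np.einsum("ni,nj->nij", e, e) - 0.5 * np.eye(3)
    theta = phi / (r**3)[:, None, None]
    if rotations is not None:
        rot = np.asarray(rotations, dtype=float).reshape(-1, 3, 3)
        theta = rot @ theta
    return theta


def frobenius_norm(m: np.ndarray) -> float | np.ndarray:
    """Frobenius norm (square root of the sum of squared entries).

    Accepts a single matrix or a batch with matrices in the last two axes.
    """
    m = np.asarray(m, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix entries must be finite")
    out = np.sqrt(np.sum(m * m, axis=(-2, -1)))
    return float(out) if out.ndim == 0 else out
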