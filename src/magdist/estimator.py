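"""Closed-form distance estimation from a (possibly weighted) field matrix.

Because the directivity matrix has constant Frobenius norm sqrt(3/2) and the
rotation matrix does not change the norm, the actuator-sensor distance
follows directly from the field-matrix norm::

    r_hat = ( sqrt(3/2) / ||Theta||_F )**(1/3)

Real sensors distort the measured matrix ``Theta_tilde`` (sensitive-axis
tilt, gain errors, assembly misalignment).  The weighted estimator corrects
each column ``theta_tilde_i`` (the field vector of one actuator coil) with
its own 3x3 weighting matrix ``W_i`` before taking the norm.  The three
weighting matrices are carried as a single 27-element weight vector ``w``
so the spatial calibration can treat them as one parameter vector.

Weight-vector layout (fixed package convention): ``w.reshape(3, 3, 3)`` has
axes ``[coil, row, column]`` — elements 0..8 are ``W_x`` row-major (the
matrix applied to the x-coil column), 9..17 ``W_y``, 18..26 ``W_z``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "N_WEIGHTS",
    "identity_weights",
    "weights_as_matrices",
    "apply_weights",
    "estimate_distance",
    "estimate_distance_weighted",
    "estimate_trace",
    "DistanceTrace",
]

#: Number of calibration weights per actuator-sensor pair (three 3x3 matrices).
N_WEIGHTS = 27

_SQRT_3_2 = float(np.sqrt(1.5))


def identity_weights() -> np.ndarray:
    """Weight vector whose three weighting matrices are all identity."""
    return np.tile(np.eye(3), (3, 1, 1)).reshape(N_WEIGHTS).copy()


def weights_as_matrices(w: np.ndarray) -> np.ndarray:
    """Reshape a 27-vector into the ``(3, 3, 3)`` stack ``[W_x, W_y, W_z]``."""
    w = np.asarray(w, dtype=float)
    if w.size != N_WEIGHTS:
        raise ValueError(f"weight vector must have exactly {N_WEIGHTS} elements")
    if not np.all(np.isfinite(w)):
        raise ValueError("weight vector must be finite")
    return w.reshape(3, 3, 3)


def apply_weights(theta: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Column-wise weighting: column ``i`` of ``theta`` is replaced by ``W_i @ theta[:, i]``.

    Works on a single matrix or a batch ``(..., 3, 3)``.  With identity
    weights the input is returned bit-identically (each sum is the original
    entry plus exact zeros), so the weighted estimator with ``w = identity``
    follows the same formula path as the unweighted one.
    """
    wm = weights_as_matrices(w)
    th = np.asarray(theta, dtype=float)
    cols = np.moveaxis(th, -1, -2)  # (..., coil, row)
    corrected = np.einsum("crj,...cj->...cr", wm, cols)
    return np.moveaxis(corrected, -1, -2)


def estimate_distance(theta: np.ndarray) -> float | np.ndarray:
    """Distance estimate ``(sqrt(3/2) / ||Theta||_F)**(1/3)`` in meters.

    Accepts a single 3x3 matrix or a batch ``(..., 3, 3)``.

    Raises
    ------
    ValueError
        If any matrix has zero Frobenius norm (the estimate would be
        infinite) or non-finite entries.
    """
    th = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(th)):
        raise ValueError("field matrix entries must be finite")
    nrm = np.sqrt(np.sum(th * th, axis=(-2, -1)))
    if np.any(nrm == 0.0):
        raise ValueError("field matrix is all-zero; distance is undefined")
    out = (_SQRT_3_2 / nrm) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


def estimate_distance_weighted(theta_tilde: np.ndarray, w: np.ndarray) -> float | np.ndarray:
    """Weighted distance estimate: columns corrected by ``W_x, W_y, W_z`` first."""
    corrected = apply_weights(theta_tilde, w)
    return estimate_distance(corrected)


@dataclass
class DistanceTrace:
    """Per-frame distance estimates with an optional ground-truth track.

    ``valid`` flags frames whose field matrix allowed an estimate; invalid
    frames carry ``nan`` estimates but are never dropped silently.
    """

    time_s: np.ndarray
    r_est_m: np.ndarray
    r_true_m: np.ndarray | None = None
    valid: np.ndarray | None = None
    pair_id: str = ""

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.r_est_m = np.asarray(self.r_est_m, dtype=float)
        if self.valid is None:
            self.valid = np.isfinite(self.r_est_m)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.r_true_m is not None:
            self.r_true_m = np.asarray(self.r_true_m, dtype=float)
            if self.r_true_m.shape != self.r_est_m.shape:
                raise ValueError("truth and estimate must have equal length")
        if self.time_s.shape != self.r_est_m.shape:
            raise ValueError("time and estimate must have equal length")

    def __len__(self) -> int:
        return self.r_est_m.size


def estimate_trace(
    thetas: np.ndarray,
    w: np.ndarray | None = None,
    time_s: np.ndarray | None = None,
    r_true_m: np.ndarray | None = None,
    pair_id: str = "",
) -> DistanceTrace:
    """Apply the (weighted) estimator frame by frame to a field-matrix series.

    Frames with non-finite or all-zero matrices are flagged invalid instead
    of raising, so a single corrupt frame cannot abort a whole trace.
    """
    th = np.asarray(thetas, dtype=float).reshape(-1, 3, 3)
    n = th.shape[0]
    if n == 0:
        raise ValueError("field-matrix series is empty")
    if w is not None:
        wm = weights_as_matrices(w)
    r_est = np.full(n, np.nan)
    finite = np.all(np.isfinite(th), axis=(1, 2))
    work = np.where(finite[:, None, None], th, 0.0)
    if w is not None:
        cols = np.moveaxis(work, -1, -2)
        work = np.moveaxis(np.einsum("crj,ncj->ncr", wm, cols), -1, -2)
    nrm = np.sqrt(np.sum(work * work, axis=(1, 2)))
    valid = finite & (nrm > 0.0)
    r_est[valid] = (_SQRT_3_2 / nrm[valid]) ** (1.0 / 3.0)
    if time_s is None:
        time_s = np.arange(n, dtype=float)
    return DistanceTrace(
        time_s=time_s, r_est_m=r_est, r_true_m=r_true_m, valid=valid, pair_id=pair_id
    )
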