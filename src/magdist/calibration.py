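"""Spatial calibration: gradient descent on the 27-element weight vector.

The calibration estimates, for one actuator-sensor pair, the weight vector
``w`` (three 3x3 column-weighting matrices) that minimizes the mean squared
error between the weighted distance estimate and a ground-truth distance
track::

    c(w) = (1/N) * sum_n ( r(n) - r_hat(n, w) )**2        [m^2]

Minimization is plain gradient descent with an Armijo backtracking line
search: each outer iteration starts the step size at ``alpha0`` (default
1000) and shrinks it geometrically by ``rho`` (default 0.8) until the
sufficient-decrease condition

    c(w - alpha * g) <= c(w) - sigma * alpha * g.T @ g      (sigma = 1e-4)

holds.  The loop terminates when the cost improvement drops below the
tolerance (default 1e-15 m^2) or after ``max_iterations`` (default 2000).
Every accepted step strictly decreases the cost, so the recorded cost
history is monotonically non-increasing.

The analytic gradient uses the chain rule through
``r_hat = (3/2)**(1/6) * u**(-1/6)`` with
``u(n) = sum_i || W_i theta_tilde_i(n) ||^2``:

    dc/dW[c, r, j] = -(2 / 3N) * sum_n (r_hat - r) * r_hat / u
                       * v[n, c, r] * theta[n, j, c]

where ``v[n, c, :] = W_c @ theta_tilde[n, :, c]``.  A central
finite-difference gradient is available as an independent mode.

Note: the cost depends on ``w`` only through the norms ``u(n)``, so weights
are identifiable at most up to per-column-block orthogonal transformations.
Calibration quality must be judged on distances, never on raw weights.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .estimator import N_WEIGHTS, identity_weights, weights_as_matrices

__all__ = [
    "PairedTrace",
    "CalibrationOptions",
    "CalibrationResult",
    "cost",
    "cost_gradient",
    "finite_difference_gradient",
    "armijo_backtracking",
    "backtracking_search",
    "calibrate",
    "merge_training",
]

logger = logging.getLogger(__name__)

_SIXTH_ROOT_3_2 = float(1.5 ** (1.0 / 6.0))


@dataclass
class PairedTrace:
    """Time-aligned measured field matrices and ground-truth distances.

    The unit of training/validation data for one actuator-sensor pair.
    Ground truth is assumed to be resampled to the demodulator's frame grid
    already (the simulator emits aligned truth; see
    :func:`magdist.synthetic.resample_truth` for real data).
    """

    theta: np.ndarray  # (N, 3, 3) measured field matrices
    r: np.ndarray  # (N,) ground-truth distance, meters
    time_s: np.ndarray | None = None
    pair_id: str = ""

    def __post_init__(self) -> None:
        self.theta = np.asarray(self.theta, dtype=float).reshape(-1, 3, 3)
        self.r = np.asarray(self.r, dtype=float).reshape(-1)
        if self.theta.shape[0] != self.r.size:
            raise ValueError("theta series and truth must have equal length")
        if self.time_s is None:
            self.time_s = np.arange(self.r.size, dtype=float)
        self.time_s = np.asarray(self.time_s, dtype=float).reshape(-1)
        if self.time_s.size != self.r.size:
            raise ValueError("time axis must match trace length")
        if np.any(~np.isfinite(self.r)) or np.any(self.r <= 0):
            raise ValueError("ground-truth distances must be finite and > 0")
        if self.r.size < N_WEIGHTS:
            logger.warning(
                "paired trace %s has only %d samples (< %d weights); "
                "calibration may be under-determined",
                self.pair_id or "<unnamed>",
                self.r.size,
                N_WEIGHTS,
            )

    def __len__(self) -> int:
        return self.r.size

    def valid_mask(self) -> np.ndarray:
        """Frames usable for calibration (finite, not all-zero)."""
        finite = np.all(np.isfinite(self.theta), axis=(1, 2))
        nonzero = np.sum(self.theta * self.theta, axis=(1, 2)) > 0
        return finite & nonzero


def _clean(data: PairedTrace) -> tuple[np.ndarray, np.ndarray]:
    """Valid-frame arrays ``(theta_cols (N, coil, row), r)``; logs exclusions."""
    mask = data.valid_mask()
    n_excluded = int(np.count_nonzero(~mask))
    if n_excluded:
        logger.warning(
            "excluding %d invalid frame(s) of %d from cost for pair %s",
            n_excluded,
            len(data),
            data.pair_id or "<unnamed>",
        )
    if not np.any(mask):
        raise ValueError("no valid frames in paired trace")
    cols = np.moveaxis(data.theta[mask], -1, -2).copy()  # (N, coil, row)
    return cols, data.r[mask]


def _u_of(wm: np.ndarray, cols: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Weighted column stack ``v`` and squared norm ``u`` per frame."""
    v = np.einsum("crj,ncj->ncr", wm, cols)
    u = np.einsum("ncr,ncr->n", v, v)
    return v, u


def cost(w: np.ndarray, data: PairedTrace) -> float:
    """Distance-MSE cost in m^2 over the valid frames of ``data``."""
    cols, r = _clean(data)
    _, u = _u_of(weights_as_matrices(w), cols)
    if np.any(u == 0.0):
        raise ValueError("weighted field matrix vanished for some frame")
    r_hat = _SIXTH_ROOT_3_2 * u ** (-1.0 / 6.0)
    d = r - r_hat
    return float(np.mean(d * d))


def cost_gradient(w: np.ndarray, data: PairedTrace) -> np.ndarray:
    """Analytic gradient of :func:`cost` with respect to the 27 weights."""
    cols, r = _clean(data)
    wm = weights_as_matrices(w)
    v, u = _u_of(wm, cols)
    if np.any(u == 0.0):
        raise ValueError("weighted field matrix vanished for some frame")
    r_hat = _SIXTH_ROOT_3_2 * u ** (-1.0 / 6.0)
    f = (r_hat - r) * r_hat / u
    n = r.size
    grad = -(2.0 / (3.0 * n)) * np.einsum("n,ncr,ncj->crj", f, v, cols)
    return grad.reshape(N_WEIGHTS)


def finite_difference_gradient(
    w: np.ndarray, data: PairedTrace, h: float = 1e-6
) -> np.ndarray:
    """Central finite-difference gradient (independent check of the analytic one)."""
    w = np.asarray(w, dtype=float).reshape(N_WEIGHTS).copy()
    g = np.empty(N_WEIGHTS)
    for i in range(N_WEIGHTS):
        wp = w.copy()
        wp[i] += h
        wmns = w.copy()
        wmns[i] -= h
        g[i] = (cost(wp, data) - cost(wmns, data)) / (2.0 * h)
    return g


@dataclass
class CalibrationOptions:
    """Gradient-descent and line-search settings.

    Defaults follow the published tuning of the method: initial step 1000,
    backtracking factor 0.8, Armijo constant 1e-4, improvement tolerance
    1e-15 m^2, at most 2000 iterations.
    """

    alpha0: float = 1000.0
    rho: float = 0.8
    sigma: float = 1e-4
    tolerance_m2: float = 1e-15
    max_iterations: int = 2000
    gradient_mode: str = "analytic"  # "analytic" | "finite-difference"
    fd_step: float = 1e-6
    min_alpha: float = 1e-30

    def __post_init__(self) -> None:
        if not (0.0 < self.rho < 1.0):
            raise ValueError("rho must lie in (0, 1)")
        if not (0.0 < self.sigma < 1.0):
            raise ValueError("sigma must lie in (0, 1)")
        if self.tolerance_m2 <= 0:
            raise ValueError("tolerance must be positive")
        if self.gradient_mode not in ("analytic", "finite-difference"):
            raise ValueError(f"unknown gradient mode {self.gradient_mode!r}")


@dataclass
class CalibrationResult:
    """Outcome of :func:`calibrate`: weights, history and termination info."""

    w: np.ndarray
    cost_history_m2: np.ndarray
    iterations: int
    termination: str
    step_sizes: np.ndarray
    pair_id: str = ""

    @property
    def final_cost_m2(self) -> float:
        return float(self.cost_history_m2[-1])


def armijo_backtracking(
    fun: Callable[[np.ndarray], float],
    w: np.ndarray,
    grad: np.ndarray,
    c0: float | None = None,
    alpha0: float = 1000.0,
    rho: float = 0.8,
    sigma: float = 1e-4,
    min_alpha: float = 1e-30,
) -> tuple[float, float]:
    """Generic Armijo backtracking line search along ``-grad``.

    Returns the first accepted step size and the cost at the new point.

    Raises
    ------
    ValueError
        If the gradient is zero (no descent direction).
    RuntimeError
        If the step underflows below ``min_alpha`` without acceptance
        (signals pathological scaling of the problem).
    """
    grad = np.asarray(grad, dtype=float)
    gg = float(grad @ grad)
    if gg == 0.0:
        raise ValueError("gradient is zero; no descent direction")
    if c0 is None:
        c0 = fun(w)
    alpha = float(alpha0)
    while alpha >= min_alpha:
        c_new = fun(w - alpha * grad)
        if c_new <= c0 - sigma * alpha * gg:
            return alpha, c_new
        alpha *= rho
    raise RuntimeError(
        f"backtracking line search underflowed below {min_alpha:g} without "
        "satisfying the Armijo condition"
    )


def backtracking_search(
    w: np.ndarray,
    gradient: np.ndarray,
    data: PairedTrace,
    opts: CalibrationOptions | None = None,
) -> tuple[float, float]:
    """Armijo backtracking on the distance-MSE cost of ``data``."""
    opts = opts or CalibrationOptions()
    return armijo_backtracking(
        lambda wt: cost(wt, data),
        np.asarray(w, dtype=float),
        gradient,
        alpha0=opts.alpha0,
        rho=opts.rho,
        sigma=opts.sigma,
        min_alpha=opts.min_alpha,
    )


def calibrate(
    data: PairedTrace,
    opts: CalibrationOptions | None = None,
    w_init: np.ndarray | None = None,
) -> CalibrationResult:
    """Estimate the weight vector minimizing the distance MSE on ``data``.

    Initialization defaults to identity weighting so that iteration 0 equals
    the uncalibrated estimator and training can only improve on it.  The
    procedure is fully deterministic given inputs and options.
    """
    opts = opts or CalibrationOptions()
    w = identity_weights() if w_init is None else np.asarray(w_init, dtype=float).reshape(
        N_WEIGHTS
    ).copy()

    # Clean once; all inner iterations work on the valid-frame arrays.
    cols, r = _clean(data)
    n = r.size

    def _cost_from_u(u: np.ndarray) -> float:
        d = r - _SIXTH_ROOT_3_2 * u ** (-1.0 / 6.0)
        return float(np.mean(d * d))

    # Candidate step-size ladder alpha0 * rho**m, truncated at min_alpha.
    n_ladder = int(np.ceil(np.log(opts.min_alpha / opts.alpha0) / np.log(opts.rho))) + 1
    ladder = opts.alpha0 * opts.rho ** np.arange(n_ladder)

    use_fd = opts.gradient_mode == "finite-difference"

    v0, u0 = _u_of(w.reshape(3, 3, 3), cols)
    if np.any(u0 == 0.0):
        raise ValueError("weighted field matrix vanished at the initial weights")
    c = _cost_from_u(u0)
    if not np.isfinite(c):
        raise ValueError("cost is not finite at the initial weights")
    history = [c]
    steps: list[float] = []
    termination = "max_iterations"
    _BLOCK = 24
    for _ in range(opts.max_iterations):
        if use_fd:
            g = finite_difference_gradient(w, data, h=opts.fd_step)
        else:
            r_hat = _SIXTH_ROOT_3_2 * u0 ** (-1.0 / 6.0)
            f = (r_hat - r) * r_hat / u0
            g = (
                -(2.0 / (3.0 * n)) * np.einsum("n,ncr,ncj->crj", f, v0, cols)
            ).reshape(N_WEIGHTS)
        gg = float(g @ g)
        if gg == 0.0:
            termination = "zero_gradient"
            break
        # Along w - alpha*g the weighted squared norm is an exact quadratic
        # in alpha: u(alpha) = u0 - 2 alpha s1 + alpha^2 s2 — so every
        # backtracking trial costs three vector operations, not a re-weighting.
        vg = np.einsum("crj,ncj->ncr", g.reshape(3, 3, 3), cols)
        s1 = np.einsum("ncr,ncr->n", v0, vg)
        s2 = np.einsum("ncr,ncr->n", vg, vg)
        alpha = None
        c_new = None
        for blk in range(0, n_ladder, _BLOCK):
            a_blk = ladder[blk : blk + _BLOCK]
            u_blk = u0[None, :] - 2.0 * a_blk[:, None] * s1 + (a_blk**2)[:, None] * s2
            with np.errstate(invalid="ignore", divide="ignore"):
                d = r[None, :] - _SIXTH_ROOT_3_2 * u_blk ** (-1.0 / 6.0)
                c_blk = np.mean(d * d, axis=1)
            ok = np.where(
                (u_blk.min(axis=1) > 0.0)
                & np.isfinite(c_blk)
                & (c_blk <= c - opts.sigma * a_blk * gg)
            )[0]
            if ok.size:
                alpha = float(a_blk[ok[0]])
                c_new = float(c_blk[ok[0]])
                break
        if alpha is None:
            raise RuntimeError(
                f"backtracking line search underflowed below {opts.min_alpha:g} "
                "without satisfying the Armijo condition"
            )
        w = w - alpha * g
        v0, u0 = _u_of(w.reshape(3, 3, 3), cols)
        improvement = c - c_new
        c = c_new
        history.append(c)
        steps.append(alpha)
        if improvement < opts.tolerance_m2:
            termination = "converged"
            break
    return CalibrationResult(
        w=w,
        cost_history_m2=np.asarray(history),
        iterations=len(steps),
        termination=termination,
        step_sizes=np.asarray(steps),
        pair_id=data.pair_id,
    )


def merge_training(traces: Sequence[PairedTrace]) -> PairedTrace:
    """Concatenate training traces of one pair (uniform sample weighting).

    The merged MSE is therefore the N-weighted mean of the per-set MSEs.
    """
    traces = list(traces)
    if not traces:
        raise ValueError("no traces to merge")
    pair_ids = {t.pair_id for t in traces}
    if len(pair_ids) > 1:
        raise ValueError(f"cannot merge traces of different pairs: {sorted(pair_ids)}")
    if len(traces) == 1:
        return traces[0]
    return PairedTrace(
        theta=np.concatenate([t.theta for t in traces], axis=0),
        r=np.concatenate([t.r for t in traces]),
        time_s=np.concatenate([t.time_s for t in traces]),
        pair_id=traces[0].pair_id,
    )
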