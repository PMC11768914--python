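"""Error metrics and the cross-scenario train/validate harness.

Metrics are computed in meters and reported in centimeters at the formatting
layer.  The cross-validation table mirrors the standard experiment design:
rows are training conditions (no training, scenario A only, B only, A and B
pooled), columns are validation scenarios, and each cell aggregates the
mean absolute distance error over all actuator-sensor pairs (mean) plus the
worst-performing pair (max).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .calibration import CalibrationOptions, PairedTrace, calibrate, merge_training
from .estimator import estimate_trace, identity_weights
from .estimator import DistanceTrace

__all__ = ["ErrorReport", "error_metrics", "CrossValTable", "crossval", "format_table"]

logger = logging.getLogger(__name__)


@dataclass
class ErrorReport:
    """Summary error metrics of a distance trace against ground truth."""

    mae_m: float
    rmse_m: float
    mean_error_m: float
    std_error_m: float
    n_valid: int
    bin_centers_m: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_mean_m: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_std_m: np.ndarray = field(default_factory=lambda: np.empty(0))
    bin_count: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))

    def to_dict(self) -> dict:
        return {
            "mae_m": self.mae_m,
            "rmse_m": self.rmse_m,
            "mean_error_m": self.mean_error_m,
            "std_error_m": self.std_error_m,
            "n_valid": self.n_valid,
            "bins": {
                "center_m": self.bin_centers_m.tolist(),
                "mean_error_m": self.bin_mean_m.tolist(),
                "std_error_m": self.bin_std_m.tolist(),
                "count": self.bin_count.tolist(),
            },
        }


def error_metrics(trace: DistanceTrace, bin_width_m: float = 0.02) -> ErrorReport:
    """MAE, RMSE, signed mean/std error and per-distance-bin summaries.

    Errors are ``r_est - r_true`` over valid frames; the per-bin summary
    (default 2 cm bins over the true distance) supports estimated-versus-
    true plots.  Raises if the trace has no truth or no valid frame.
    """
    if trace.r_true_m is None:
        raise ValueError("trace carries no ground truth")
    mask = trace.valid & np.isfinite(trace.r_true_m)
    if not np.any(mask):
        raise ValueError("no valid frames to evaluate")
    err = trace.r_est_m[mask] - trace.r_true_m[mask]
    r_true = trace.r_true_m[mask]
    mae = float(np.mean(np.abs(err)))
    rmse = float(np.sqrt(np.mean(err * err)))
    mean = float(np.mean(err))
    std = float(np.std(err))  # population std: rmse^2 == mean^2 + std^2
    idx = np.floor(r_true / bin_width_m).astype(int)
    uniq = np.unique(idx)
    centers = (uniq + 0.5) * bin_width_m
    bmean = np.array([np.mean(err[idx == u]) for u in uniq])
    bstd = np.array([np.std(err[idx == u]) for u in uniq])
    bcount = np.array([np.count_nonzero(idx == u) for u in uniq])
    return ErrorReport(
        mae_m=mae,
        rmse_m=rmse,
        mean_error_m=mean,
        std_error_m=std,
        n_valid=int(np.count_nonzero(mask)),
        bin_centers_m=centers,
        bin_mean_m=bmean,
        bin_std_m=bstd,
        bin_count=bcount,
    )


@dataclass
class CrossValTable:
    """Mean/max MAE per (training condition, validation scenario) cell."""

    rows: tuple[str, ...]
    columns: tuple[str, ...]
    mean_mae_m: dict  # row -> col -> float
    max_mae_m: dict
    per_pair_mae_m: dict  # row -> col -> {pair_id: mae}
    weights: dict  # row -> {pair_id: list of 27 floats}

    def to_dict(self) -> dict:
        return {
            "rows": list(self.rows),
            "columns": list(self.columns),
            "mean_mae_m": self.mean_mae_m,
            "max_mae_m": self.max_mae_m,
            "per_pair_mae_m": self.per_pair_mae_m,
        }


def _pair_mae(trace: PairedTrace, w: np.ndarray) -> float:
    est = estimate_trace(
        trace.theta, w=w, time_s=trace.time_s, r_true_m=trace.r, pair_id=trace.pair_id
    )
    return error_metrics(est).mae_m


def crossval(
    train_sets: Mapping[str, Mapping[str, PairedTrace]],
    validation_sets: Mapping[str, Mapping[str, PairedTrace]],
    opts: CalibrationOptions | None = None,
) -> CrossValTable:
    """Cross-scenario train/validate harness.

    ``train_sets`` and ``validation_sets`` map scenario name -> pair_id ->
    :class:`PairedTrace`.  Rows are ``"none"``, each training scenario, and
    (with at least two scenarios) their pooled concatenation; columns are
    the validation scenarios.  Calibration runs independently per pair.
    Pairs missing from a training or validation set are reported and
    excluded from the aggregation.
    """
    opts = opts or CalibrationOptions()
    scen = list(train_sets)
    rows = ["none"] + scen + (["+".join(scen)] if len(scen) > 1 else [])
    columns = list(validation_sets)

    all_pairs: list[str] = []
    for vs in validation_sets.values():
        for pid in vs:
            if pid not in all_pairs:
                all_pairs.append(pid)

    weights: dict[str, dict[str, np.ndarray]] = {"none": {}}
    for pid in all_pairs:
        weights["none"][pid] = identity_weights()
    for row in rows[1:]:
        members = row.split("+")
        weights[row] = {}
        for pid in all_pairs:
            traces = [
                train_sets[m][pid] for m in members if pid in train_sets.get(m, {})
            ]
            if len(traces) < len(members):
                logger.warning(
                    "pair %s missing from training condition %s; excluded", pid, row
                )
                continue
            merged = merge_training(traces)
            weights[row][pid] = calibrate(merged, opts=opts).w

    mean_mae: dict[str, dict[str, float]] = {}
    max_mae: dict[str, dict[str, float]] = {}
    per_pair: dict[str, dict[str, dict[str, float]]] = {}
    for row in rows:
        mean_mae[row], max_mae[row], per_pair[row] = {}, {}, {}
        for col in columns:
            maes = {}
            for pid, trace in validation_sets[col].items():
                if pid not in weights[row]:
                    logger.warning(
                        "pair %s has no weights for condition %s; excluded", pid, row
                    )
                    continue
                maes[pid] = _pair_mae(trace, weights[row][pid])
            if not maes:
                raise ValueError(f"no evaluable pairs for cell ({row}, {col})")
            per_pair[row][col] = maes
            mean_mae[row][col] = float(np.mean(list(maes.values())))
            max_mae[row][col] = float(np.max(list(maes.values())))
    return CrossValTable(
        rows=tuple(rows),
        columns=tuple(columns),
        mean_mae_m=mean_mae,
        max_mae_m=max_mae,
        per_pair_mae_m=per_pair,
        weights={r: {p: w.tolist() for p, w in ws.items()} for r, ws in weights.items()},
    )


def format_table(table: CrossValTable) -> str:
    """Human-readable table, MAE in centimeters with one decimal."""
    head = ["training \\ validation"] + [
        f"{c}: mean | max MAE [cm]" for c in table.columns
    ]
    lines = ["\t".join(head)]
    for row in table.rows:
        cells = [row]
        for col in table.columns:
            cells.append(
                f"{100 * table.mean_mae_m[row][col]:.1f} | "
                f"{100 * table.max_mae_m[row][col]:.1f}"
            )
        lines.append("\t".join(cells))
    return "\n".join(lines)
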