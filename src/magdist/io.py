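"""File formats: dataset directories, traces, calibration results, streams.

All tabular artifacts are plain CSV (pandas), structured metadata is JSON,
raw streams are float WAV (scipy.io.wavfile) or HDF5 (datasets
``/<node>/<axis>`` with a ``sample_rate`` attribute).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .calibration import CalibrationResult, PairedTrace
from .estimator import DistanceTrace
from .signal_chain import PeakFilterParams, SpectrumEstimate
from .synthetic import SyntheticDataset

__all__ = [
    "write_dataset",
    "read_dataset",
    "write_distance_trace",
    "read_distance_trace",
    "write_calibration_results",
    "read_calibration_results",
    "write_equalizer_bank",
    "read_equalizer_bank",
    "write_spectrum",
    "read_spectrum",
    "write_stream_wav",
    "read_stream_wav",
    "write_stream_h5",
    "read_stream_h5",
]

_AXES = ("x", "y", "z")
_THETA_COLS = [f"theta_{r}{c}" for r in _AXES for c in _AXES]  # row=sensor axis


def write_dataset(ds: SyntheticDataset, path: str | Path) -> None:
    """Dataset directory: manifest.json plus one CSV of theta/truth per pair."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "manifest.json").write_text(json.dumps(ds.manifest, indent=2))
    for pid, trace in ds.pairs.items():
        df = pd.DataFrame({"time_s": trace.time_s})
        flat = trace.theta.reshape(-1, 9)
        for k, col in enumerate(_THETA_COLS):
            df[col] = flat[:, k]
        df["r_true_m"] = trace.r
        df.to_csv(path / f"pair_{pid}.csv", index=False)


def read_dataset(path: str | Path) -> SyntheticDataset:
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    pairs = {}
    for f in sorted(path.glob("pair_*.csv")):
        pid = f.stem[len("pair_"):]
        df = pd.read_csv(f)
        theta = df[_THETA_COLS].to_numpy().reshape(-1, 3, 3)
        pairs[pid] = PairedTrace(
            theta=theta,
            r=df["r_true_m"].to_numpy(),
            time_s=df["time_s"].to_numpy(),
            pair_id=pid,
        )
    if not pairs:
        raise FileNotFoundError(f"no pair_*.csv files under {path}")
    return SyntheticDataset(pairs=pairs, manifest=manifest)


def write_distance_trace(trace: DistanceTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "time_s": trace.time_s,
            "pair_id": trace.pair_id,
            "r_est_m": trace.r_est_m,
            "valid": trace.valid.astype(int),
        }
    )
    if trace.r_true_m is not None:
        df["r_true_m"] = trace.r_true_m
    df.to_csv(path, index=False)


def read_distance_trace(path: str | Path) -> DistanceTrace:
    df = pd.read_csv(path)
    return DistanceTrace(
        time_s=df["time_s"].to_numpy(),
        r_est_m=df["r_est_m"].to_numpy(),
        r_true_m=df["r_true_m"].to_numpy() if "r_true_m" in df else None,
        valid=df["valid"].to_numpy().astype(bool),
        pair_id=str(df["pair_id"].iloc[0]) if len(df) else "",
    )


def write_calibration_results(
    results: Mapping[str, CalibrationResult], path: str | Path
) -> None:
    payload = {
        pid: {
            "pair_id": pid,
            "w": res.w.tolist(),
            "cost_history_m2": res.cost_history_m2.tolist(),
            "iterations": res.iterations,
            "termination": res.termination,
        }
        for pid, res in results.items()
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_calibration_results(path: str | Path) -> dict[str, np.ndarray]:
    """Weight vectors only: {pair_id: (27,) array}."""
    payload = json.loads(Path(path).read_text())
    return {pid: np.asarray(entry["w"], dtype=float) for pid, entry in payload.items()}


def write_equalizer_bank(entries: list[dict], path: str | Path) -> None:
    """Entries: {sensor_id, axis, f0_hz, bw_hz, gain_db, peak_sensitivity_v_per_t}."""
    Path(path).write_text(json.dumps(entries, indent=2))


def read_equalizer_bank(path: str | Path) -> list[dict]:
    entries = json.loads(Path(path).read_text())
    for e in entries:
        # validates the filter parameters
        PeakFilterParams(f0_hz=e["f0_hz"], bw_hz=e["bw_hz"], gain_db=e["gain_db"])
    return entries


def write_spectrum(spec: SpectrumEstimate, path: str | Path) -> None:
    pd.DataFrame(
        {"frequency_hz": spec.frequencies_hz, "amplitude_db": spec.amplitude_db}
    ).to_csv(path, index=False)


def read_spectrum(path: str | Path) -> SpectrumEstimate:
    df = pd.read_csv(path)
    return SpectrumEstimate(
        frequencies_hz=df["frequency_hz"].to_numpy(),
        amplitude=10.0 ** (df["amplitude_db"].to_numpy() / 20.0),
    )


def write_stream_wav(stream: np.ndarray, sample_rate_hz: float, path: str | Path) -> None:
    data = np.asarray(stream, dtype=np.float32)
    if data.ndim == 2:  # (channels, samples) -> (samples, channels)
        data = data.T
    wavfile.write(path, int(round(sample_rate_hz)), data)


def read_stream_wav(path: str | Path) -> tuple[np.ndarray, float]:
    rate, data = wavfile.read(path)
    if data.ndim == 2:
        data = data.T
    return np.asarray(data, dtype=float), float(rate)


def write_stream_h5(
    streams: Mapping[str, Mapping[str, np.ndarray]],
    sample_rate_hz: float,
    path: str | Path,
) -> None:
    """``streams[node][axis]`` -> dataset ``/<node>/<axis>``."""
    with h5py.File(path, "w") as f:
        f.attrs["sample_rate"] = float(sample_rate_hz)
        for node, axes in streams.items():
            grp = f.create_group(node)
            for axis, data in axes.items():
                grp.create_dataset(axis, data=np.asarray(data, dtype=float))


def read_stream_h5(path: str | Path) -> tuple[dict[str, dict[str, np.ndarray]], float]:
    out: dict[str, dict[str, np.ndarray]] = {}
    with h5py.File(path, "r") as f:
        rate = float(f.attrs["sample_rate"])
        for node in f:
            out[node] = {axis: f[node][axis][()] for axis in f[node]}
    return out, rate
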