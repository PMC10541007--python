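"""File I/O: WAV audio, CSV event tables, YAML configs."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.io import wavfile

__all__ = [
    "write_wav",
    "read_wav",
    "read_trace",
    "load_config",
    "dump_config",
    "read_spikes",
    "spike_trains_from_table",
]


def write_wav(path: str | Path, waveform: np.ndarray, fs: float) -> None:
    """Write mono float32 PCM WAV (sampling rate from ``fs``)."""
    wavfile.write(str(path), int(fs), np.asarray(waveform, dtype=np.float32))


def read_wav(path: str | Path) -> tuple[np.ndarray, float]:
    """Read a mono WAV; integer PCM is rescaled to [-1, 1] floats."""
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.ndim > 1:
        raise ValueError(f"{path}: expected mono audio, got {data.shape[1]} channels")
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(np.float64) / np.iinfo(data.dtype).max
    return data.astype(np.float64), float(fs)


def read_trace(path: str | Path) -> np.ndarray:
    """Single-column numeric text/CSV trace (header optional)."""
    try:
        return np.loadtxt(str(path), ndmin=1)
    except ValueError:
        return pd.read_csv(path).iloc[:, 0].to_numpy(float)


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def dump_config(cfg: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)


def read_spikes(path: str | Path) -> pd.DataFrame:
    """spikes.csv with columns unit_id, time_s."""
    df = pd.read_csv(path)
    missing = {"unit_id", "time_s"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


def spike_trains_from_table(df: pd.DataFrame) -> dict[int, np.ndarray]:
    """Map unit_id -> sorted spike-time array."""
    return {int(uid): np.sort(g["time_s"].to_numpy(float)) for uid, g in df.groupby("unit_id")}
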