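"""Voltage containers: single-subject epoch stacks and averaged ERPs.

Values are microvolts.  The time axis is milliseconds on a half-open,
0-based sample grid: a window of -200..1000 ms at 500 Hz holds exactly
600 samples at -200, -198, ..., 998 ms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from .layout import SensorLayout

__all__ = ["EpochArray", "ERP", "time_axis"]


def time_axis(window_ms: tuple[float, float], rate: float) -> np.ndarray:
    """Sample times (ms) for a half-open window at the given rate."""
    start, end = window_ms
    if not start < end:
        raise ValueError("window start must precede end")
    n = int(round((end - start) * rate / 1000.0))
    return start + np.arange(n) * 1000.0 / rate


def _check(data: np.ndarray, times: np.ndarray, rate: float, layout: SensorLayout, ndim: int):
    if rate <= 0:
        raise ValueError("rate must be positive")
    if data.ndim != ndim:
        raise ValueError(f"expected {ndim}-d data, got {data.ndim}-d")
    if not np.all(np.isfinite(data)):
        raise ValueError("data must be finite")
    if data.shape[-1] != len(times):
        raise ValueError("time axis length must match the sample count")
    if data.shape[-2] != layout.n_channels:
        raise ValueError("channel count must match the layout")


@dataclass(frozen=True)
class EpochArray:
    """Trials x channels x samples for one subject and condition."""

    subject_id: str
    condition: str
    data: np.ndarray
    rate: float
    times: np.ndarray
    layout: SensorLayout

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        _check(data, times, self.rate, self.layout, 3)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def with_data(self, data, rate=None, times=None) -> "EpochArray":
        kw = {"data": data}
        if rate is not None:
            kw["rate"] = rate
        if times is not None:
            kw["times"] = times
        return replace(self, **kw)

    # -- delimited persistence: trial and time columns, then channels --

    def save(self, path) -> None:
        path = Path(path)
        n_tr, n_ch, n_s = self.data.shape
        trial_col = np.repeat(np.arange(n_tr), n_s)
        time_col = np.tile(self.times, n_tr)
        flat = self.data.transpose(0, 2, 1).reshape(n_tr * n_s, n_ch)
        body = np.column_stack([trial_col, time_col, flat])
        header = "\t".join(["trial", "time_ms", *self.layout.channel_names])
        np.savetxt(path, body, fmt="%.10g", delimiter="\t", header=header,
                   comments="")
        meta = {"subject_id": self.subject_id, "condition": self.condition,
                "rate": self.rate}
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
        self.layout.to_sidecar(path.with_suffix(path.suffix + ".layout"))

    @classmethod
    def load(cls, path) -> "EpochArray":
        path = Path(path)
        body = np.loadtxt(path, delimiter="\t", skiprows=1)
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        layout = SensorLayout.from_sidecar(path.with_suffix(path.suffix + ".layout"))
        trials = body[:, 0].astype(int)
        n_tr = trials.max() + 1
        n_s = int(len(body) / n_tr)
        times = body[:n_s, 1]
        data = body[:, 2:].reshape(n_tr, n_s, -1).transpose(0, 2, 1)
        return cls(meta["subject_id"], meta["condition"], data, meta["rate"],
                   times, layout)


@dataclass(frozen=True)
class ERP:
    """Channels x samples trial average for one subject and condition."""

    subject_id: str
    condition: str
    data: np.ndarray
    rate: float
    times: np.ndarray
    layout: SensorLayout
    n_trials_averaged: int = 1

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        times = np.asarray(self.times, dtype=float)
        _check(data, times, self.rate, self.layout, 2)
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "times", times)

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def epoch_length_s(self) -> float:
        return self.n_samples / self.rate

    def with_data(self, data) -> "ERP":
        return replace(self, data=data)

    # -- delimited persistence: samples x channels matrix + JSON sidecar --

    def save(self, path) -> None:
        path = Path(path)
        np.savetxt(path, self.data.T, fmt="%.10g", delimiter="\t",
                   header="\t".join(self.layout.channel_names), comments="")
        meta = {
            "subject_id": self.subject_id,
            "condition": self.condition,
            "rate": self.rate,
            "times": [float(t) for t in self.times],
            "n_trials_averaged": self.n_trials_averaged,
        }
        path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta))
        self.layout.to_sidecar(path.with_suffix(path.suffix + ".layout"))

    @classmethod
    def load(cls, path) -> "ERP":
        path = Path(path)
        data = np.loadtxt(path, delimiter="\t", skiprows=1).T
        meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
        layout = SensorLayout.from_sidecar(path.with_suffix(path.suffix + ".layout"))
        if data.ndim == 1:
            data = data[:, None]
        return cls(meta["subject_id"], meta["condition"], data, meta["rate"],
                   np.asarray(meta["times"]), layout, meta["n_trials_averaged"])
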