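"""Sensor montages on the unit sphere.

The built-in montage is an idealized spherical 10-10 layout with 64
channels: electrode rows (Fp, AF, F, FC, C, CP, P, PO, O) sit on arcs
between the midline and the 10% temporal circle, the head being a unit
sphere with x pointing to the nasion, y to the left ear and z to the
vertex.  Only relative geometry matters downstream (interpolation
neighborhoods and smooth synthetic topographies), not millimetre fidelity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["SensorLayout", "standard_layout_64"]

# row -> (sagittal angle from Cz, deg, +anterior; azimuth of the row's
# outermost electrode on the temporal circle, deg from the nasion)
_ROWS = {
    "Fp": (72.0, 18.0),
    "AF": (54.0, 36.0),
    "F": (36.0, 54.0),
    "FC": (18.0, 72.0),
    "C": (0.0, 90.0),
    "CP": (-18.0, 108.0),
    "P": (-36.0, 126.0),
    "PO": (-54.0, 144.0),
    "O": (-72.0, 162.0),
}

# polar angle of the temporal (10%) circle, measured from the vertex
_TEMPORAL_POLAR = 72.0

_CHANNELS_64 = (
    "Fp1 Fpz Fp2 "
    "AF7 AF3 AFz AF4 AF8 "
    "F7 F5 F3 F1 Fz F2 F4 F6 F8 "
    "FT7 FC5 FC3 FC1 FCz FC2 FC4 FC6 FT8 "
    "T7 C5 C3 C1 Cz C2 C4 C6 T8 "
    "TP7 CP5 CP3 CP1 CPz CP2 CP4 CP6 TP8 "
    "P7 P5 P3 P1 Pz P2 P4 P6 P8 "
    "PO7 PO5 PO3 POz PO4 PO6 PO8 "
    "O1 Oz O2 "
    "Iz"
).split()


@dataclass(frozen=True)
class SensorLayout:
    """A named electrode montage with unit-sphere positions."""

    channel_names: tuple[str, ...]
    positions: np.ndarray  # (n_channels, 3), unit rows
    name: str = "custom"
    _index: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = tuple(self.channel_names)
        pos = np.asarray(self.positions, dtype=float)
        if len(names) != len(set(names)):
            raise ValueError("channel names must be unique")
        if len(names) < 2:
            raise ValueError("a layout needs at least 2 channels")
        if pos.shape != (len(names), 3):
            raise ValueError(f"positions must be ({len(names)}, 3), got {pos.shape}")
        norms = np.linalg.norm(pos, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("positions must have unit norm (tol 1e-9)")
        object.__setattr__(self, "channel_names", names)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "_index", {n: i for i, n in enumerate(names)})

    @property
    def n_channels(self) -> int:
        return len(self.channel_names)

    def index(self, name: str) -> int:
        try:
            return self._index[name]
        except KeyError:
            raise ValueError(f"unknown channel {name!r}") from None

    def indices(self, names) -> np.ndarray:
        return np.array([self.index(n) for n in names], dtype=int)

    def neighbors(self, name: str, k: int = 6, exclude=()) -> list[str]:
        """The ``k`` nearest channels to ``name`` by chord distance."""
        i = self.index(name)
        excl = {name, *exclude}
        d = np.linalg.norm(self.positions - self.positions[i], axis=1)
        order = np.argsort(d, kind="stable")
        out = [self.channel_names[j] for j in order if self.channel_names[j] not in excl]
        return out[:k]

    # -- sidecar I/O (one "name x y z" line per channel, tab-separated) --

    def to_sidecar(self, path) -> None:
        lines = ["name\tx\ty\tz"]
        for n, p in zip(self.channel_names, self.positions):
            lines.append(f"{n}\t{p[0]:.10f}\t{p[1]:.10f}\t{p[2]:.10f}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_sidecar(cls, path, name: str = "custom") -> "SensorLayout":
        rows = Path(path).read_text().strip().splitlines()
        if rows and rows[0].lower().startswith("name"):
            rows = rows[1:]
        names, pos = [], []
        for row in rows:
            parts = row.split("\t")
            names.append(parts[0])
            pos.append([float(v) for v in parts[1:4]])
        p = np.asarray(pos)
        p = p / np.linalg.norm(p, axis=1, keepdims=True)  # tolerate rounding
        return cls(tuple(names), p, name=name)


def _slerp(a: np.ndarray, b: np.ndarray, f: float) -> np.ndarray:
    """Point at fraction f along the great circle from a to b (unit vectors)."""
    omega = np.arccos(np.clip(a @ b, -1.0, 1.0))
    if omega < 1e-12:
        return a.copy()
    return (np.sin((1 - f) * omega) * a + np.sin(f * omega) * b) / np.sin(omega)


def _position(label: str) -> np.ndarray:
    if label == "Iz":
        return np.array([-1.0, 0.0, 0.0])
    # split row prefix from column suffix
    for row in sorted(_ROWS, key=len, reverse=True):
        base = row
        if label.startswith(("FT", "TP")) and row in ("FC", "CP"):
            base = {"FC": "FT", "CP": "TP"}[row]
        if label.startswith(base):
            suffix = label[len(base):]
            break
    else:
        if label.startswith("T"):  # T7 / T8 live on the C row
            row, suffix = "C", label[1:]
        else:
            raise ValueError(f"cannot parse electrode label {label!r}")
    sag, outer_az = _ROWS[row]
    sag_r = np.deg2rad(sag)
    mid = np.array([np.sin(sag_r), 0.0, np.cos(sag_r)])
    if suffix == "z":
        return mid
    n = int(suffix)
    left = n % 2 == 1
    # outermost electrodes (7/8, temporal names, Fp1/2, O1/2) sit on the circle
    if base in ("FT", "TP") or label in ("T7", "T8", "Fp1", "Fp2", "O1", "O2"):
        f = 1.0
    else:
        f = ((n + 1) // 2 * 2) / 8.0
    pol = np.deg2rad(_TEMPORAL_POLAR)
    az = np.deg2rad(outer_az)
    temporal = np.array([np.sin(pol) * np.cos(az), np.sin(pol) * np.sin(az), np.cos(pol)])
    p = _slerp(mid, temporal, f)
    if not left:
        p = p * np.array([1.0, -1.0, 1.0])
    return p / np.linalg.norm(p)


def standard_layout_64() -> SensorLayout:
    """The built-in 64-channel idealized spherical 10-10 montage."""
    pos = np.array([_position(c) for c in _CHANNELS_64])
    return SensorLayout(tuple(_CHANNELS_64), pos, name="standard-10-10-64")
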