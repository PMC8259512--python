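"""Core in-memory containers shared across the analysis modules.

Axis and unit conventions used throughout the package:

* 3D volumes are indexed ``(z, row, col)``; the node axis is the row axis,
  with the superior end at row 0.  Physical distances use per-axis voxel
  sizes in micrometres.
* Voltage traces are uniformly sampled in millivolts (default 10 kHz).
* Kymographs are ``(space, time)`` grids: rows are positions along the
  scanned line (``pixel_um`` apart), columns are successive line scans
  (``line_interval_ms`` apart).  Amplitudes are raw fluorescence until
  normalized to dF/F0.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "LabeledVolume",
    "VoltageTrace",
    "Kymograph",
    "PairedRecording",
    "GroundTruth",
]


@dataclass
class LabeledVolume:
    """Two-channel 3D voxel grid (pacemaker-myocyte and vessel channels)."""

    myocyte_channel: np.ndarray
    vessel_channel: np.ndarray
    voxel_size_um: tuple[float, float, float]

    def __post_init__(self) -> None:
        if self.myocyte_channel.shape != self.vessel_channel.shape:
            raise ValueError("channel shapes differ")
        if self.myocyte_channel.ndim != 3:
            raise ValueError("volume channels must be 3D (z, row, col)")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.myocyte_channel.shape


@dataclass
class VoltageTrace:
    """Uniformly sampled membrane-potential recording in mV."""

    samples_mv: np.ndarray
    sample_rate_hz: float
    condition: str | None = None

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample rate must be positive")
        self.samples_mv = np.asarray(self.samples_mv, dtype=float)

    @property
    def n_samples(self) -> int:
        return self.samples_mv.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sample_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sample_rate_hz


@dataclass
class Kymograph:
    """Line-scan image: space (rows, um) by time (columns, line scans)."""

    data: np.ndarray
    pixel_um: float
    line_interval_ms: float
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.pixel_um <= 0 or self.line_interval_ms <= 0:
            raise ValueError("pixel size and line interval must be positive")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("kymograph must be 2D (space, time)")

    @property
    def scan_length_um(self) -> float:
        return self.data.shape[0] * self.pixel_um

    @property
    def duration_s(self) -> float:
        return self.data.shape[1] * self.line_interval_ms / 1000.0

    @property
    def positions_um(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.pixel_um

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.data.shape[1]) * self.line_interval_ms / 1000.0


@dataclass
class PairedRecording:
    """Simultaneous membrane-potential trace and line-scan kymograph.

    Both channels share a time base; ``offset_s`` is the start time of the
    kymograph relative to the start of the voltage trace.
    """

    trace: VoltageTrace
    kymograph: Kymograph
    offset_s: float = 0.0

    def __post_init__(self) -> None:
        overlap = min(self.trace.duration_s,
                      self.offset_s + self.kymograph.duration_s) - max(
                          0.0, self.offset_s)
        if overlap <= 1.0:
            raise ValueError("paired channels must overlap by more than 1 s")


@dataclass
class GroundTruth:
    """Record of every object a generator planted, in analysis coordinates."""

    kind: str
    objects: dict[str, Any] = field(default_factory=dict)

    def __getitem__(self, key: str) -> Any:
        return self.objects[key]

    def __contains__(self, key: str) -> bool:
        return key in self.objects
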