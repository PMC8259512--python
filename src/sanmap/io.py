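"""File I/O: TIFF + JSON-sidecar volumes and kymographs, CSV/NPZ traces.

Formats are deliberately plain so that exports from any microscope or
amplifier tool chain can be used: volumes are two-channel multi-page TIFF
with a JSON sidecar holding voxel size and channel names; kymographs are
single-channel TIFF with pixel size and line interval in the sidecar;
traces are two-column CSV (time_s, mV) or NPZ.  Ground truth and run
summaries are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .datatypes import GroundTruth, Kymograph, LabeledVolume, VoltageTrace

__all__ = [
    "write_volume", "read_volume",
    "write_trace", "read_trace",
    "write_kymograph", "read_kymograph",
    "write_ground_truth", "read_ground_truth",
    "write_table", "read_table",
]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__dataclass__": type(obj).__name__,
                **_jsonable(dataclasses.asdict(obj))}
    return obj


def _require(meta: dict, field: str, path: Path):
    if field not in meta:
        raise ValueError(f"metadata file {path} is missing required field "
                         f"{field!r}")
    return meta[field]


def write_volume(vol: LabeledVolume, tif_path, meta_path=None) -> None:
    """Write a two-channel volume as multi-page TIFF + JSON sidecar."""
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    stack = np.stack([vol.myocyte_channel, vol.vessel_channel]).astype(
        np.uint8)
    # pages are (channel, z); axes recorded in the sidecar
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    meta = {"voxel_size_um": list(vol.voxel_size_um),
            "channel_names": ["myocyte", "vessel"],
            "axes": "CZYX"}
    meta_path.write_text(json.dumps(meta, indent=1))


def read_volume(tif_path, meta_path=None) -> LabeledVolume:
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    voxel = tuple(_require(meta, "voxel_size_um", meta_path))
    stack = tifffile.imread(tif_path)
    if stack.ndim != 4 or stack.shape[0] != 2:
        raise ValueError(f"{tif_path} is not a two-channel volume")
    return LabeledVolume(myocyte_channel=stack[0].astype(bool)
                         if stack.dtype == np.uint8 else stack[0],
                         vessel_channel=stack[1].astype(bool)
                         if stack.dtype == np.uint8 else stack[1],
                         voxel_size_um=voxel)


def write_trace(trace: VoltageTrace, path) -> None:
    """CSV (time_s, mv) or NPZ depending on the suffix."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, samples_mv=trace.samples_mv,
                 sample_rate_hz=trace.sample_rate_hz)
    else:
        df = pd.DataFrame({"time_s": trace.times_s,
                           "mv": trace.samples_mv})
        df.to_csv(path, index=False)


def read_trace(path, sample_rate_hz: float | None = None) -> VoltageTrace:
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path)
        return VoltageTrace(samples_mv=data["samples_mv"],
                            sample_rate_hz=float(data["sample_rate_hz"]))
    df = pd.read_csv(path)
    if "mv" not in df.columns:
        raise ValueError(f"{path} has no 'mv' column")
    if sample_rate_hz is None:
        if "time_s" not in df.columns or len(df) < 2:
            raise ValueError(
                f"{path}: cannot infer the sample rate without a time_s "
                "column; pass sample_rate_hz")
        dt = np.diff(df["time_s"].to_numpy())
        sample_rate_hz = 1.0 / float(np.median(dt))
    return VoltageTrace(samples_mv=df["mv"].to_numpy(),
                        sample_rate_hz=sample_rate_hz)


def write_kymograph(kymo: Kymograph, tif_path, meta_path=None) -> None:
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    tifffile.imwrite(tif_path, kymo.data.astype(np.float32),
                     photometric="minisblack")
    meta = {"pixel_um": kymo.pixel_um,
            "line_interval_ms": kymo.line_interval_ms,
            "normalized": kymo.normalized,
            "axes": "XT"}
    meta_path.write_text(json.dumps(meta, indent=1))


def read_kymograph(tif_path, meta_path=None) -> Kymograph:
    tif_path = Path(tif_path)
    meta_path = Path(meta_path) if meta_path else tif_path.with_suffix(".json")
    meta = json.loads(meta_path.read_text())
    return Kymograph(data=tifffile.imread(tif_path).astype(float),
                     pixel_um=float(_require(meta, "pixel_um", meta_path)),
                     line_interval_ms=float(
                         _require(meta, "line_interval_ms", meta_path)),
                     normalized=bool(meta.get("normalized", False)))


def write_ground_truth(gt: GroundTruth, path) -> None:
    payload = {"kind": gt.kind, "objects": _jsonable(gt.objects)}
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(kind=payload["kind"], objects=payload["objects"])


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
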