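"""Shared fixtures: small synthetic datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from sanmap import synthetic, volumetrics


@pytest.fixture(scope="session")
def node_volume():
    """Default synthetic node volume + ground truth (seed 1)."""
    cfg = synthetic.NodeVolumeConfig(seed=1)
    return synthetic.gen_node_volume(cfg)


@pytest.fixture(scope="session")
def node_distance_map(node_volume):
    vol, _ = node_volume
    return volumetrics.distance_transform(
        vol.myocyte_channel, vol.vessel_channel, vol.voxel_size_um)


@pytest.fixture(scope="session")
def tonic_trace():
    """30 s tonic trace at the superior-cell defaults (seed 3)."""
    cfg = synthetic.TraceConfig(duration_s=30.0, seed=3)
    return synthetic.gen_voltage_trace(cfg)


@pytest.fixture(scope="session")
def spark_kymograph():
    """Kymograph with fixed-amplitude (0.30) sparks at SNR 10 (seed 0)."""
    cfg = synthetic.KymoConfig(
        spark_amp_mixture=[(1.0, 0.30, 0.0)], noise_sd_dff=0.03, seed=0)
    return synthetic.gen_kymograph(cfg)


def match_events(detected: np.ndarray, truth: np.ndarray,
                 tol: float) -> tuple[int, int, int]:
    """(true positives, false negatives, false positives) by nearest match."""
    if detected.size == 0:
        return 0, truth.size, 0
    tp = sum(np.min(np.abs(detected - t)) < tol for t in truth)
    fp = sum(np.min(np.abs(truth - d)) >= tol for d in detected)
    return tp, truth.size - tp, fp
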