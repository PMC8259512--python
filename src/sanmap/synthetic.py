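"""Ground-truth-labeled synthetic data emulating sinoatrial-node recordings.

Four generators produce the inputs the analysis modules consume, each with
a complete ground-truth record of every planted object:

* :func:`gen_node_volume` -- a two-channel 3D volume with a primary artery
  descending the node (row) axis, branch arterioles/capillaries, and a
  myocyte density field; vessel and myocyte densities step from a superior
  to an inferior level at a configurable boundary fraction, which is what
  creates the step in myocyte-to-vessel distance that the volumetric
  analysis fits with a sigmoid.
* :func:`gen_voltage_trace` -- pacemaker membrane-potential traces in five
  firing modalities (silent, subthreshold-only, tonic, irregular, burst),
  with a parametric action-potential waveform whose knobs map one-to-one
  onto the standard waveform features (MDP, take-off, peak, APD90, early
  diastolic depolarization rate) plus stochastic subthreshold bumps drawn
  from a Gaussian amplitude mixture.
* :func:`gen_kymograph` -- line-scan Ca2+ fluorescence with planted sparks
  (Gaussian in space, fast rise / exponential decay in time) and
  whole-cell transients.
* :func:`gen_paired_recording` -- a voltage trace and kymograph on a shared
  time base with sparks planted in the diastolic window before each AP at
  a configured mean count and linear ramp.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import GroundTruth, Kymograph, LabeledVolume, PairedRecording, VoltageTrace

__all__ = [
    "NodeVolumeConfig",
    "TraceConfig",
    "KymoConfig",
    "CouplingConfig",
    "gen_node_volume",
    "gen_voltage_trace",
    "gen_kymograph",
    "gen_paired_recording",
    "superior_trace_config",
    "inferior_trace_config",
]

MODALITIES = ("silent", "subthreshold_only", "tonic", "irregular", "burst")

# Reported single-cell AP waveform parameters for superior and inferior
# mouse SAN myocytes (means).  These drive the generator presets and are
# the reference values parameter-recovery checks compare against.
SUPERIOR_AP_REFERENCE: dict[str, float] = {
    "ap_frequency_hz": 4.04,
    "isi_cv": 0.46,
    "mdp_mv": -56.88,
    "takeoff_mv": -36.051,
    "early_diastolic_duration_ms": 51.36,
    "edd_rate_mv_per_s": 83.80,
    "upstroke_rate_mv_per_ms": 40.08,
    "apd90_ms": 51.56,
}
INFERIOR_AP_REFERENCE: dict[str, float] = {
    "ap_frequency_hz": 1.44,
    "isi_cv": 0.96,
    "mdp_mv": -54.63,
    "takeoff_mv": -30.99,
    "early_diastolic_duration_ms": 325.09,
    "edd_rate_mv_per_s": 36.73,
    "upstroke_rate_mv_per_ms": 29.67,
    "apd90_ms": 75.38,
}

# Reported subthreshold-fluctuation amplitude decompositions (mV):
# superior cells are two-component, inferior cells one-component.
SUPERIOR_SUBTHRESHOLD_MIXTURE = [(0.5, 2.0, 1.3), (0.5, 11.0, 1.1)]
INFERIOR_SUBTHRESHOLD_MIXTURE = [(1.0, 6.0, 2.3)]


# --------------------------------------------------------------------------
# configs
# --------------------------------------------------------------------------

@dataclass
class NodeVolumeConfig:
    """Parameters of the synthetic two-channel node volume.

    Default regional parameters follow the reported anatomy: the superior
    region spans ~60% of the node axis, is denser in both vessels and
    myocytes, and its primary artery is wider (30.6 um tapering to
    23.4 um inferiorly).  Absolute fractional-volume targets are free
    parameters (the source work shows only normalized heat maps); the
    defaults 0.10/0.04 (vessels) and 0.35/0.20 (myocytes) give regional
    mean myocyte-to-vessel distances of the observed few-micrometre scale.
    """

    shape: tuple[int, int, int] = (40, 120, 96)  # (z, row, col) voxels
    voxel_size_um: tuple[float, float, float] = (2.0, 2.0, 2.0)
    boundary_fraction: float = 0.6
    vessel_density_superior: float = 0.10
    vessel_density_inferior: float = 0.04
    myocyte_density_superior: float = 0.35
    myocyte_density_inferior: float = 0.20
    artery_diameter_superior_um: float = 30.6
    artery_diameter_inferior_um: float = 23.4
    # segments per branch order (order 1 = the primary artery, implicit)
    branch_counts: dict[int, int] = field(
        default_factory=lambda: {2: 4, 3: 6, 4: 8})
    branch_diameters_um: dict[int, float] = field(
        default_factory=lambda: {2: 10.0, 3: 6.0, 4: 4.0})
    branch_lengths_um: dict[int, float] = field(
        default_factory=lambda: {2: 30.0, 3: 20.0, 4: 12.0})
    capillaries: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("shape must be positive")
        if any(v <= 0 for v in self.voxel_size_um):
            raise ValueError("voxel sizes must be positive")
        if not 0.0 < self.boundary_fraction < 1.0:
            raise ValueError("boundary_fraction must lie in (0, 1)")
        for d in (self.vessel_density_superior, self.vessel_density_inferior,
                  self.myocyte_density_superior, self.myocyte_density_inferior):
            if not 0.0 < d < 1.0:
                raise ValueError("densities must lie in (0, 1)")


@dataclass
class TraceConfig:
    """Parameters of a synthetic membrane-potential recording.

    Waveform defaults are the superior-cell values: 4.04 Hz firing, MDP
    -56.88 mV, take-off -36.05 mV, APD90 51.56 ms, early diastolic
    depolarization at 83.80 mV/s, phase-0 upstroke 40 mV/ms.  The
    subthreshold amplitude mixture defaults to the superior two-component
    decomposition (2.0 +/- 1.3 mV and 11.0 +/- 1.1 mV, equal weights).
    Recording noise is a free parameter; 0.3 mV SD is a realistic
    perforated-patch figure.
    """

    duration_s: float = 30.0
    sample_rate_hz: float = 10_000.0
    modality: str = "tonic"
    ap_frequency_hz: float = 4.04
    isi_cv_target: float = 0.2
    mdp_mv: float = -56.88
    takeoff_mv: float = -36.05
    peak_mv: float = 15.0
    apd90_ms: float = 51.56
    edd_rate_mv_per_s: float = 83.80
    upstroke_rate_mv_per_ms: float = 40.0
    subthreshold_rate_hz: float = 2.10
    subthreshold_amp_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.5, 2.0, 1.3), (0.5, 11.0, 1.1)])
    noise_sd_mv: float = 0.3
    burst_silence_s: float = 2.0
    burst_mean_len: float = 6.0
    burst_intra_isi_ms: float = 150.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.modality not in MODALITIES:
            raise ValueError(
                f"unknown modality {self.modality!r}; one of {MODALITIES}")
        if not self.mdp_mv < self.takeoff_mv < self.peak_mv:
            raise ValueError("require MDP < take-off < peak")
        w = sum(w for w, _, _ in self.subthreshold_amp_mixture)
        if abs(w - 1.0) > 1e-6:
            raise ValueError("subthreshold mixture weights must sum to 1")


@dataclass
class KymoConfig:
    """Parameters of a synthetic line-scan Ca2+ kymograph.

    Spark amplitudes default to the superior two-population mixture
    (dF/F0 0.30 and 0.90); geometry defaults (FWHM 2 um, FDHM 30 ms) are
    typical cardiac spark dimensions, the source figures reporting only
    that they did not differ regionally.
    """

    scan_length_um: float = 50.0
    pixel_um: float = 0.5
    duration_s: float = 10.0
    line_interval_ms: float = 4.0
    spark_rate_per_100um_s: float = 4.7
    spark_amp_mixture: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.5, 0.30, 0.05), (0.5, 0.90, 0.10)])
    spark_fwhm_um: float = 2.0
    spark_fdhm_ms: float = 30.0
    transient_frequency_hz: float = 0.0
    transient_amp_dff: float = 1.37
    transient_fdhm_ms: float = 300.0
    noise_sd_dff: float = 0.03
    f0_baseline: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("scan_length_um", "pixel_um", "duration_s",
                     "line_interval_ms", "spark_fwhm_um", "spark_fdhm_ms",
                     "f0_baseline"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.spark_fwhm_um >= self.scan_length_um:
            raise ValueError("spark FWHM must be smaller than the scan length")
        if self.spark_rate_per_100um_s < 0 or self.transient_frequency_hz < 0:
            raise ValueError("event rates must be non-negative")


@dataclass
class CouplingConfig:
    """Spark-to-AP coupling in a paired recording.

    ``sparks_per_ap`` is the Poisson mean count of diastolic sparks in the
    pre-AP window; ``pre_ap_ramp`` sets a linearly increasing spark-time
    density toward the AP (0 = uniform; r means the density at the AP is
    (1+r)/1 times the density at the window start).  ``dv_per_amp_mv``
    optionally couples each spark to a small membrane depolarization.
    """

    sparks_per_ap: float = 4.5
    pre_ap_ramp: float = 1.0
    window_ms: float = 300.0
    dv_per_amp_mv: float = 0.0

    def __post_init__(self) -> None:
        if self.sparks_per_ap < 0 or self.pre_ap_ramp < 0:
            raise ValueError("coupling parameters must be non-negative")
        if self.window_ms <= 0:
            raise ValueError("window_ms must be positive")


def distance_matched_node_config(**overrides) -> NodeVolumeConfig:
    """Node-volume configuration whose regional myocyte-to-vessel distance
    means reproduce the reported values (superior 2.54 um, inferior
    4.69 um).  Vessel densities (0.15 / 0.05) were calibrated once
    against the distance transform at the default geometry and frozen."""
    return replace(NodeVolumeConfig(
        vessel_density_superior=0.15, vessel_density_inferior=0.05),
        **overrides)


def superior_trace_config(**overrides) -> TraceConfig:
    """Trace configuration with the superior-cell waveform parameters."""
    return replace(TraceConfig(), **overrides)


def inferior_trace_config(**overrides) -> TraceConfig:
    """Trace configuration with the inferior-cell waveform parameters:

    1.44 Hz irregular firing, MDP -54.63 mV, take-off -30.99 mV, APD90
    75.38 ms, EDD rate 36.73 mV/s, upstroke 29.67 mV/ms, and a
    single-component subthreshold amplitude distribution (6.0 +/- 2.3 mV).
    """
    ref = INFERIOR_AP_REFERENCE
    cfg = TraceConfig(
        modality="irregular", ap_frequency_hz=ref["ap_frequency_hz"],
        mdp_mv=ref["mdp_mv"], takeoff_mv=ref["takeoff_mv"],
        apd90_ms=ref["apd90_ms"],
        edd_rate_mv_per_s=ref["edd_rate_mv_per_s"],
        upstroke_rate_mv_per_ms=ref["upstroke_rate_mv_per_ms"],
        subthreshold_rate_hz=1.80,
        subthreshold_amp_mixture=list(INFERIOR_SUBTHRESHOLD_MIXTURE))
    return replace(cfg, **overrides)


# --------------------------------------------------------------------------
# node volume
# --------------------------------------------------------------------------

def _rasterize_capsule(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray,
                       radius_um: float,
                       voxel_size: np.ndarray) -> None:
    """Set all voxels within ``radius_um`` of segment p0-p1 (um coords)."""
    lo = np.minimum(p0, p1) - radius_um
    hi = np.maximum(p0, p1) + radius_um
    lo_idx = np.maximum(np.floor(lo / voxel_size).astype(int), 0)
    hi_idx = np.minimum(np.ceil(hi / voxel_size).astype(int) + 1,
                        np.asarray(mask.shape))
    if np.any(hi_idx <= lo_idx):
        return
    grids = np.meshgrid(*[
        (np.arange(lo_idx[a], hi_idx[a]) + 0.5) * voxel_size[a]
        for a in range(3)], indexing="ij")
    pts = np.stack(grids, axis=-1)
    d = p1 - p0
    seg_len2 = float(d @ d)
    if seg_len2 == 0:
        dist = np.linalg.norm(pts - p0, axis=-1)
    else:
        t = np.clip(((pts - p0) @ d) / seg_len2, 0.0, 1.0)
        closest = p0 + t[..., None] * d
        dist = np.linalg.norm(pts - closest, axis=-1)
    sub = mask[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
    sub |= dist <= radius_um


def gen_node_volume(cfg: NodeVolumeConfig) -> tuple[LabeledVolume, GroundTruth]:
    """Generate a two-channel synthetic node volume with ground truth.

    The vessel channel holds the branched artery tree plus, when
    ``cfg.capillaries`` is set, short randomly oriented capillary tubes
    added per region until the regional fractional-volume targets are met
    exactly.  The myocyte channel realizes its regional density targets
    exactly by sampling voxels outside the vessel mask.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = tuple(cfg.shape)
    voxel = np.asarray(cfg.voxel_size_um, dtype=float)
    nz, nrow, ncol = shape
    extent_um = voxel * np.asarray(shape)
    boundary_row = int(round(cfg.boundary_fraction * nrow))
    if not 0 < boundary_row < nrow:
        raise ValueError("boundary_fraction leaves an empty region")

    vessel = np.zeros(shape, dtype=bool)
    segments: list[dict] = []

    # -- primary artery: straight tube descending the row axis at the
    #    volume center, radius tapering superior -> inferior
    r_sup = cfg.artery_diameter_superior_um / 2.0
    r_inf = cfg.artery_diameter_inferior_um / 2.0
    if 2 * max(r_sup, r_inf) >= min(extent_um[0], extent_um[2]):
        raise ValueError("artery diameter does not fit in the volume")
    center_z = extent_um[0] / 2.0
    center_c = extent_um[2] / 2.0
    zz, rr, cc = np.meshgrid(
        (np.arange(nz) + 0.5) * voxel[0],
        (np.arange(nrow) + 0.5) * voxel[1],
        (np.arange(ncol) + 0.5) * voxel[2], indexing="ij")
    frac = rr / extent_um[1]
    radius_here = r_sup + (r_inf - r_sup) * frac
    artery = (zz - center_z) ** 2 + (cc - center_c) ** 2 <= radius_here ** 2
    vessel |= artery
    art_p0 = np.array([center_z, 0.0, center_c])
    art_p1 = np.array([center_z, extent_um[1], center_c])
    segments.append({
        "order": 1, "start_um": art_p0.tolist(), "end_um": art_p1.tolist(),
        "length_um": float(extent_um[1]),
        "diameter_um": float(r_sup + r_inf)})

    # -- branch tree: order-k segments sprout from a random point on a
    #    random order-(k-1) segment, heading laterally with jitter
    parents = {1: [(art_p0, art_p1)]}
    for order in sorted(cfg.branch_counts):
        count = cfg.branch_counts[order]
        pts = []
        parent_list = parents.get(order - 1, [])
        if count > 0 and not parent_list:
            raise ValueError(
                f"branch order {order} configured without order {order-1}")
        for _ in range(count):
            p0p, p1p = parent_list[rng.integers(len(parent_list))]
            t = rng.uniform(0.15, 0.85)
            start = p0p + t * (p1p - p0p)
            direction = rng.normal(size=3)
            direction[1] *= 0.4  # mostly lateral to the node axis
            direction /= np.linalg.norm(direction)
            length = cfg.branch_lengths_um[order] * rng.uniform(0.8, 1.2)
            end = start + direction * length
            end = np.clip(end, 1.0, extent_um - 1.0)
            length = float(np.linalg.norm(end - start))
            radius = cfg.branch_diameters_um[order] / 2.0
            _rasterize_capsule(vessel, start, end, radius, voxel)
            pts.append((start, end))
            segments.append({
                "order": order, "start_um": start.tolist(),
                "end_um": end.tolist(), "length_um": length,
                "diameter_um": float(cfg.branch_diameters_um[order])})
        parents[order] = pts

    # -- per-region capillary top-up to the vessel density targets
    region_slices = {
        "superior": (slice(None), slice(0, boundary_row), slice(None)),
        "inferior": (slice(None), slice(boundary_row, nrow), slice(None)),
    }
    row_lims_um = {
        "superior": (0.0, boundary_row * voxel[1]),
        "inferior": (boundary_row * voxel[1], extent_um[1]),
    }
    targets = {"superior": cfg.vessel_density_superior,
               "inferior": cfg.vessel_density_inferior}
    for region, sl in region_slices.items():
        if not cfg.capillaries:
            break  # tree-only volume: density targets are not enforced
        region_voxels = vessel[sl].size
        target_count = int(round(targets[region] * region_voxels))
        if int(artery[sl].sum()) > target_count * 1.1:
            raise ValueError(
                f"vessel density target {targets[region]} infeasible in the "
                f"{region} region: the primary artery alone occupies "
                f"{artery[sl].mean():.3f}")
        # capillary bed: a uniform random voxel field topping the region up
        # to its target count exactly (capillary-scale voxels; spatially
        # homogeneous, which is what the distance statistics assume).  If
        # the branch tree already overshoots, trim non-artery voxels.
        have = int(vessel[sl].sum())
        if have < target_count:
            free = np.flatnonzero(~vessel[sl].ravel())
            add = rng.choice(free, size=target_count - have, replace=False)
            flat = vessel[sl].ravel()
            flat[add] = True
            vessel[sl] = flat.reshape(vessel[sl].shape)
        elif have > target_count * 1.1:
            raise ValueError(
                f"vessel density target {targets[region]} infeasible in the "
                f"{region} region: the artery tree alone occupies "
                f"{have / region_voxels:.3f}")
        # tree overshoot within +10% of the target is accepted as-is

    # -- myocyte channel: exact-count random voxels outside the vessels
    myocyte = np.zeros(shape, dtype=bool)
    myo_targets = {"superior": cfg.myocyte_density_superior,
                   "inferior": cfg.myocyte_density_inferior}
    for region, sl in region_slices.items():
        region_voxels = myocyte[sl].size
        want = int(round(myo_targets[region] * region_voxels))
        free = np.flatnonzero(~vessel[sl].ravel())
        if free.size < want:
            raise ValueError(
                f"myocyte density target {myo_targets[region]} infeasible in "
                f"the {region} region")
        pick = rng.choice(free, size=want, replace=False)
        flat = myocyte[sl].ravel()
        flat[pick] = True
        myocyte[sl] = flat.reshape(myocyte[sl].shape)

    vol = LabeledVolume(myocyte_channel=myocyte, vessel_channel=vessel,
                        voxel_size_um=tuple(voxel))
    realized = {
        region: {
            "vessel": float(vessel[sl].mean()),
            "myocyte": float(myocyte[sl].mean()),
        } for region, sl in region_slices.items()}
    gt = GroundTruth(kind="node_volume", objects={
        "boundary_row": boundary_row,
        "boundary_fraction": cfg.boundary_fraction,
        "segments": segments,
        "realized_densities": realized,
        "artery_root_um": art_p0.tolist(),
        "config": cfg,
    })
    return vol, gt


# --------------------------------------------------------------------------
# voltage trace
# --------------------------------------------------------------------------

def _waveform_spans(cfg: TraceConfig) -> tuple[float, float]:
    """(upstroke, repolarization) durations in seconds for the AP waveform.

    Repolarization is exponential to 90% (APD90 exact) plus a 40 ms linear
    tail to the MDP, so the full AP spans ``up + apd90 + 40 ms``.
    """
    amp_up = cfg.peak_mv - cfg.takeoff_mv
    tau_u = amp_up / (4.0 * cfg.upstroke_rate_mv_per_ms) / 1000.0
    up_dur = 8.0 * tau_u
    repol_dur = (cfg.apd90_ms + 40.0) / 1000.0 - up_dur
    return up_dur, repol_dur


def _draw_isis(cfg: TraceConfig, rng: np.random.Generator,
               total_s: float) -> np.ndarray:
    """Inter-spike intervals (s) for the configured firing modality."""
    mean = 1.0 / cfg.ap_frequency_hz
    up_dur, repol_dur = _waveform_spans(cfg)
    min_isi = up_dur + repol_dur + 0.03  # full AP span + a short diastole
    isis: list[float] = []
    t = 0.0
    if cfg.modality == "tonic":
        sd = cfg.isi_cv_target * mean
        while t < total_s:
            isi = max(min_isi, rng.normal(mean, sd))
            isis.append(isi)
            t += isi
    elif cfg.modality == "irregular":
        while t < total_s:
            isi = max(min_isi, rng.exponential(mean))
            isis.append(isi)
            t += isi
    elif cfg.modality == "burst":
        while t < total_s:
            silence = rng.exponential(cfg.burst_silence_s) + min_isi
            isis.append(silence)
            t += silence
            n_in_burst = 2 + rng.poisson(max(cfg.burst_mean_len - 2, 0.0))
            for _ in range(int(n_in_burst) - 1):
                isi = max(min_isi,
                          rng.normal(cfg.burst_intra_isi_ms,
                                     0.1 * cfg.burst_intra_isi_ms) / 1000.0)
                isis.append(isi)
                t += isi
    return np.asarray(isis)


def _render_ap_train(cfg: TraceConfig, takeoff_times: np.ndarray,
                     n: int) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Render the noise-free AP train; returns (trace, diastolic spans).

    Each cycle is upstroke (logistic, peak slope = the phase-0 rate),
    repolarization (exponential decay reaching the 90% level exactly at
    APD90, then a 40 ms linear tail to the MDP), then a diastolic ramp
    rising at exactly the configured EDD rate through the first half of
    the diastolic interval -- covering the 10-50% window the feature
    extractor fits -- with a faster linear rise to the take-off potential
    after that (long burst silences fall back to a plain linear ramp).
    """
    fs = cfg.sample_rate_hz
    v = np.full(n, cfg.mdp_mv)
    amp_up = cfg.peak_mv - cfg.takeoff_mv
    up_dur, repol_dur = _waveform_spans(cfg)
    # the upstroke is a logistic rescaled to interpolate take-off -> peak
    # exactly over [t0, t0 + 8 tau] (no jump at the diastole junction);
    # the rescale slightly raises the max slope, compensated via tau
    sig_span = 1.0 / (1.0 + math.exp(-4.0)) - 1.0 / (1.0 + math.exp(4.0))
    tau_u = up_dur / 8.0 / sig_span
    v_asym = cfg.mdp_mv - 5.0
    v90 = cfg.peak_mv - 0.9 * amp_up
    # exponential decay reaching the 90%-repolarization level exactly at
    # APD90, then a linear 40 ms tail down to the MDP
    t90_after_peak = cfg.apd90_ms / 1000.0 - up_dur
    tau_r = t90_after_peak / math.log(
        (cfg.peak_mv - v_asym) / (v90 - v_asym))
    gain = cfg.takeoff_mv - cfg.mdp_mv
    diastolic_spans: list[tuple[float, float]] = []

    t_axis = np.arange(n) / fs
    for i, t0 in enumerate(takeoff_times):
        t_next = takeoff_times[i + 1] if i + 1 < takeoff_times.size else np.inf
        # upstroke
        i0 = max(int(t0 * fs), 0)
        i1 = min(int((t0 + up_dur) * fs) + 1, n)
        if i0 >= n:
            break
        tt = t_axis[i0:i1]
        sig = 1.0 / (1.0 + np.exp(-(tt - (t0 + 0.5 * up_dur)) / tau_u))
        sig0 = 1.0 / (1.0 + math.exp(0.5 * up_dur / tau_u))
        v[i0:i1] = cfg.takeoff_mv + amp_up * (sig - sig0) / (1.0 - 2.0 * sig0)
        # repolarization: exponential to the 90% level, then linear tail
        t_peak = t0 + up_dur
        t90 = t_peak + t90_after_peak
        t_mdp = min(t_peak + repol_dur, t_next)
        i2 = min(int(t_mdp * fs) + 1, n)
        if i1 < i2:
            tt = t_axis[i1:i2]
            exp_part = v_asym + (cfg.peak_mv - v_asym) * np.exp(
                -(tt - t_peak) / tau_r)
            lin_part = np.interp(tt, [t90, t_peak + repol_dur],
                                 [v90, cfg.mdp_mv])
            v[i1:i2] = np.where(tt <= t90, exp_part, lin_part)
        # diastole up to the next take-off
        if not np.isfinite(t_next) or t_mdp >= t_next:
            if not np.isfinite(t_next) and i2 < n:
                v[i2:] = cfg.mdp_mv
            continue
        dd = t_next - t_mdp
        diastolic_spans.append((t_mdp, t_next))
        i3 = min(int(t_next * fs) + 1, n)
        tt = t_axis[i2:i3]
        v2 = cfg.edd_rate_mv_per_s * 0.5 * dd
        if v2 <= 0.9 * gain:
            # linear rise at exactly the EDD rate through the first half of
            # the diastolic interval (the analysis fits 10-50% of it), then
            # a faster late rise to the take-off potential
            knots_t = np.array([t_mdp, t_mdp + 0.5 * dd, t_next])
            knots_v = cfg.mdp_mv + np.array([0.0, v2, gain])
        else:
            # diastole too long for the configured rate (burst silences):
            # plain linear ramp; the per-cycle EDD rate will not match
            knots_t = np.array([t_mdp, t_next])
            knots_v = cfg.mdp_mv + np.array([0.0, gain])
        v[i2:i3] = np.interp(tt, knots_t, knots_v)
    # leading segment before the first AP: a diastolic ramp ending at the
    # take-off potential, so the first upstroke is continuous too
    if takeoff_times.size:
        lead = int(takeoff_times[0] * fs)
        if lead > 0:
            tt = t_axis[:lead]
            ramp_start = max(0.0, takeoff_times[0] - 0.5 / max(
                cfg.ap_frequency_hz, 1e-6))
            v[:lead] = np.interp(tt, [0.0, ramp_start, takeoff_times[0]],
                                 [cfg.mdp_mv, cfg.mdp_mv, cfg.takeoff_mv])
            diastolic_spans.insert(0, (0.0, takeoff_times[0]))
    else:
        diastolic_spans.append((0.0, n / fs))
    return v, diastolic_spans


def _sample_mixture(mixture, rng: np.random.Generator, size: int) -> np.ndarray:
    weights = np.array([w for w, _, _ in mixture])
    comps = rng.choice(len(mixture), size=size, p=weights / weights.sum())
    out = np.empty(size)
    for i, c in enumerate(comps):
        _, center, width = mixture[c]
        out[i] = rng.normal(center, width)
    return out


def gen_voltage_trace(cfg: TraceConfig) -> tuple[VoltageTrace, GroundTruth]:
    """Generate a membrane-potential trace with planted APs and bumps."""
    rng = np.random.default_rng(cfg.seed)
    fs = cfg.sample_rate_hz
    n = int(round(cfg.duration_s * fs))

    if cfg.modality in ("silent", "subthreshold_only"):
        takeoffs = np.array([])
    else:
        isis = _draw_isis(cfg, rng, cfg.duration_s)
        first = 0.1 + rng.uniform(0.0, 0.5 / cfg.ap_frequency_hz)
        takeoffs = first + np.concatenate([[0.0], np.cumsum(isis)])
        takeoffs = takeoffs[takeoffs < cfg.duration_s - 0.02]

    v, diastolic_spans = _render_ap_train(cfg, takeoffs, n)

    # subthreshold bumps: Poisson process thinned to diastolic windows,
    # alpha-function shape, amplitude from the configured mixture
    bumps: list[dict] = []
    if cfg.modality != "silent" and cfg.subthreshold_rate_hz > 0:
        n_cand = rng.poisson(cfg.subthreshold_rate_hz * cfg.duration_s)
        cand_t = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_cand))
        durs = rng.uniform(5.0, 50.0, size=n_cand) / 1000.0
        amps = np.abs(_sample_mixture(cfg.subthreshold_amp_mixture, rng,
                                      n_cand))
        amps = np.maximum(amps, 0.2)
        t_axis = np.arange(n) / fs
        for t0, dur, amp in zip(cand_t, durs, amps):
            margin = 0.01
            ok = any(lo + margin <= t0 and t0 + dur <= hi - margin
                     for lo, hi in diastolic_spans)
            if not ok:
                continue
            # never exceed the AP threshold of -29 mV
            base = v[int(t0 * fs)]
            amp_eff = float(min(amp, -31.0 - base))
            if amp_eff < 0.2:
                continue
            tau = dur / 5.0
            i0 = int(t0 * fs)
            i1 = min(int((t0 + 8 * tau) * fs) + 1, n)
            tt = t_axis[i0:i1] - t0
            v[i0:i1] += amp_eff * (tt / tau) * np.exp(1.0 - tt / tau)
            bumps.append({"time_s": float(t0), "amplitude_mv": amp_eff,
                          "duration_ms": float(dur * 1000.0)})

    if cfg.noise_sd_mv > 0:
        v = v + rng.normal(0.0, cfg.noise_sd_mv, size=n)

    trace = VoltageTrace(samples_mv=v, sample_rate_hz=fs)
    gt = GroundTruth(kind="voltage_trace", objects={
        "modality": cfg.modality,
        "ap_times_s": takeoffs.tolist(),
        "isis_s": np.diff(takeoffs).tolist(),
        "bumps": bumps,
        "diastolic_spans_s": diastolic_spans,
        "config": cfg,
    })
    return trace, gt


# --------------------------------------------------------------------------
# kymograph
# --------------------------------------------------------------------------

def _add_spark(dff: np.ndarray, pos_um: float, t_s: float, amp: float,
               fwhm_um: float, fdhm_ms: float, pixel_um: float,
               line_interval_ms: float) -> None:
    n_x, n_t = dff.shape
    sigma = fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
    tau_ms = fdhm_ms / math.log(2.0)  # instant rise: FDHM = tau * ln 2
    x = (np.arange(n_x) + 0.5) * pixel_um
    spatial = np.exp(-0.5 * ((x - pos_um) / sigma) ** 2)
    j0 = int(t_s * 1000.0 / line_interval_ms)
    j1 = min(j0 + int(6 * tau_ms / line_interval_ms) + 1, n_t)
    if j0 >= n_t:
        return
    tt = (np.arange(j0, j1) - j0) * line_interval_ms
    temporal = amp * np.exp(-tt / tau_ms)
    dff[:, j0:j1] += spatial[:, None] * temporal[None, :]


def gen_kymograph(cfg: KymoConfig) -> tuple[Kymograph, GroundTruth]:
    """Generate a raw-fluorescence line-scan kymograph with ground truth."""
    rng = np.random.default_rng(cfg.seed)
    n_x = int(round(cfg.scan_length_um / cfg.pixel_um))
    n_t = int(round(cfg.duration_s * 1000.0 / cfg.line_interval_ms))
    dff = np.zeros((n_x, n_t))

    sparks: list[dict] = []
    mean_count = (cfg.spark_rate_per_100um_s * cfg.scan_length_um / 100.0
                  * cfg.duration_s)
    n_sparks = rng.poisson(mean_count) if mean_count > 0 else 0
    margin_x = cfg.spark_fwhm_um
    margin_t = 3.0 * cfg.spark_fdhm_ms / 1000.0
    for _ in range(n_sparks):
        pos = rng.uniform(margin_x, cfg.scan_length_um - margin_x)
        t = rng.uniform(0.02, cfg.duration_s - margin_t)
        amp = float(np.abs(_sample_mixture(cfg.spark_amp_mixture, rng, 1)[0]))
        amp = max(amp, 0.05)
        _add_spark(dff, pos, t, amp, cfg.spark_fwhm_um, cfg.spark_fdhm_ms,
                   cfg.pixel_um, cfg.line_interval_ms)
        sparks.append({"position_um": float(pos), "time_s": float(t),
                       "amplitude_dff": amp,
                       "fwhm_um": cfg.spark_fwhm_um,
                       "fdhm_ms": cfg.spark_fdhm_ms})

    transients: list[dict] = []
    if cfg.transient_frequency_hz > 0:
        period = 1.0 / cfg.transient_frequency_hz
        t = 0.2 + rng.uniform(0.0, 0.2 * period)
        tau_ms = cfg.transient_fdhm_ms / math.log(2.0)
        while t < cfg.duration_s - 0.05:
            j0 = int(t * 1000.0 / cfg.line_interval_ms)
            j1 = min(j0 + int(6 * tau_ms / cfg.line_interval_ms) + 1, n_t)
            tt = (np.arange(j0, j1) - j0) * cfg.line_interval_ms
            dff[:, j0:j1] += cfg.transient_amp_dff * np.exp(-tt / tau_ms)
            transients.append({"time_s": float(t),
                               "amplitude_dff": cfg.transient_amp_dff,
                               "fdhm_ms": cfg.transient_fdhm_ms})
            t += period * rng.uniform(0.95, 1.05)

    raw = cfg.f0_baseline * (1.0 + dff)
    if cfg.noise_sd_dff > 0:
        raw = raw + rng.normal(0.0, cfg.noise_sd_dff * cfg.f0_baseline,
                               size=raw.shape)
    kymo = Kymograph(data=raw, pixel_um=cfg.pixel_um,
                     line_interval_ms=cfg.line_interval_ms, normalized=False)
    gt = GroundTruth(kind="kymograph", objects={
        "sparks": sparks, "transients": transients, "config": cfg})
    return kymo, gt


# --------------------------------------------------------------------------
# paired recording
# --------------------------------------------------------------------------

def _sample_ramp_positions(rng: np.random.Generator, ramp: float,
                           size: int) -> np.ndarray:
    """Draw x in [0, 1] (1 = at the AP) with density proportional to 1+ramp*x."""
    u = rng.uniform(size=size)
    if ramp == 0:
        return u
    # inverse CDF of f(x) = (1 + ramp x) / (1 + ramp/2)
    a = ramp / 2.0
    return (-1.0 + np.sqrt(1.0 + 4.0 * a * (1.0 + a) * u)) / (2.0 * a)


def gen_paired_recording(
        cfg_trace: TraceConfig, cfg_kymo: KymoConfig,
        coupling: CouplingConfig) -> tuple[PairedRecording, GroundTruth]:
    """Simultaneous voltage trace and kymograph with coupled sparks.

    Sparks are planted in the diastolic window before each AP take-off:
    Poisson-distributed counts with mean ``coupling.sparks_per_ap`` and
    times drawn from a linearly ramping density toward the AP.  Background
    (uncoupled) sparks follow ``cfg_kymo.spark_rate_per_100um_s``.
    """
    if abs(cfg_trace.duration_s - cfg_kymo.duration_s) > 1e-9:
        raise ValueError("trace and kymograph durations must match")

    trace, trace_gt = gen_voltage_trace(cfg_trace)
    rng = np.random.default_rng(np.random.SeedSequence(
        [cfg_trace.seed, cfg_kymo.seed, 0xC0]))

    bg_kymo, bg_gt = gen_kymograph(replace(cfg_kymo, noise_sd_dff=0.0))
    dff = bg_kymo.data / cfg_kymo.f0_baseline - 1.0

    ap_times = np.asarray(trace_gt["ap_times_s"])
    coupled: list[dict] = []
    per_ap_counts: list[int] = []
    v = trace.samples_mv.copy()
    fs = trace.sample_rate_hz
    for i, t_ap in enumerate(ap_times):
        prev = ap_times[i - 1] if i > 0 else 0.0
        window_s = min(coupling.window_ms / 1000.0, t_ap - prev - 0.05)
        if window_s <= 0.01:
            per_ap_counts.append(0)
            continue
        k = rng.poisson(coupling.sparks_per_ap)
        xs = _sample_ramp_positions(rng, coupling.pre_ap_ramp, k)
        times = t_ap - window_s * (1.0 - xs)
        for t in np.sort(times):
            pos = rng.uniform(cfg_kymo.spark_fwhm_um,
                              cfg_kymo.scan_length_um - cfg_kymo.spark_fwhm_um)
            amp = float(np.abs(_sample_mixture(
                cfg_kymo.spark_amp_mixture, rng, 1)[0]))
            amp = max(amp, 0.05)
            _add_spark(dff, pos, float(t), amp, cfg_kymo.spark_fwhm_um,
                       cfg_kymo.spark_fdhm_ms, cfg_kymo.pixel_um,
                       cfg_kymo.line_interval_ms)
            coupled.append({"position_um": float(pos), "time_s": float(t),
                            "amplitude_dff": amp, "ap_index": i,
                            "rel_time_s": float(t - t_ap)})
            if coupling.dv_per_amp_mv != 0.0:
                i0 = int(t * fs)
                i1 = min(i0 + int(0.05 * fs), v.size)
                v[i0:i1] += coupling.dv_per_amp_mv * amp
        per_ap_counts.append(int(k))

    raw = cfg_kymo.f0_baseline * (1.0 + dff)
    if cfg_kymo.noise_sd_dff > 0:
        raw = raw + rng.normal(
            0.0, cfg_kymo.noise_sd_dff * cfg_kymo.f0_baseline, size=raw.shape)
    kymo = Kymograph(data=raw, pixel_um=cfg_kymo.pixel_um,
                     line_interval_ms=cfg_kymo.line_interval_ms,
                     normalized=False)
    trace = VoltageTrace(samples_mv=v, sample_rate_hz=fs)
    paired = PairedRecording(trace=trace, kymograph=kymo, offset_s=0.0)
    gt = GroundTruth(kind="paired_recording", objects={
        "ap_times_s": ap_times.tolist(),
        "coupled_sparks": coupled,
        "background_sparks": bg_gt["sparks"],
        "per_ap_counts": per_ap_counts,
        "window_ms": coupling.window_ms,
        "coupling": coupling,
        "trace_gt": trace_gt.objects,
    })
    return paired, gt
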