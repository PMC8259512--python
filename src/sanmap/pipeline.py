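"""Configuration-driven end-to-end orchestration.

A run configuration (YAML or dict) names which synthetic datasets to
generate (or which input files to load), the per-stage parameters, the
seed, and the output directory.  ``run_pipeline`` executes every stage,
writes CSV tables, PNG figures, a JSON summary and a log, and is
deterministic for a fixed config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import platform
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import yaml

from . import calcium, coupling, ephys, io, synthetic, volumetrics

__all__ = ["RunConfig", "run_pipeline", "load_config"]


@dataclass
class RunConfig:
    out_dir: str = "sanmap_out"
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: [
        "volume", "trace", "kymo", "paired"])
    volume: dict = field(default_factory=dict)    # NodeVolumeConfig overrides
    trace: dict = field(default_factory=dict)     # TraceConfig overrides
    kymo: dict = field(default_factory=dict)      # KymoConfig overrides
    coupling: dict = field(default_factory=dict)  # CouplingConfig overrides
    analysis: dict = field(default_factory=dict)  # per-stage analysis params
    inputs: dict = field(default_factory=dict)    # optional real-data paths


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**raw)


def _fig(path: Path, draw) -> None:
    fig, ax = plt.subplots(figsize=(5, 3.2), dpi=110)
    draw(ax)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _tuplify(d: dict) -> dict:
    out = dict(d)
    for key in ("shape", "voxel_size_um"):
        if key in out:
            out[key] = tuple(out[key])
    for key in ("subthreshold_amp_mixture", "spark_amp_mixture"):
        if key in out:
            out[key] = [tuple(c) for c in out[key]]
    for key in ("branch_counts", "branch_diameters_um", "branch_lengths_um"):
        if key in out:
            out[key] = {int(k): v for k, v in out[key].items()}
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run every configured stage; returns the summary dict."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log: list[str] = [
        f"sanmap pipeline, python {platform.python_version()}",
        f"seed {config.seed}",
    ]
    summary: dict = {"seed": config.seed, "stages": {}}
    ss = np.random.SeedSequence(config.seed)
    stage_seeds = {name: int(s.generate_state(1)[0] % (2 ** 31))
                   for name, s in zip(("volume", "trace", "kymo", "paired"),
                                      ss.spawn(4))}

    try:
        if "volume" in config.stages:
            summary["stages"]["volume"] = _run_volume(
                config, out, stage_seeds["volume"], log)
        if "trace" in config.stages:
            summary["stages"]["trace"] = _run_trace(
                config, out, stage_seeds["trace"], log)
        if "kymo" in config.stages:
            summary["stages"]["kymo"] = _run_kymo(
                config, out, stage_seeds["kymo"], log)
        if "paired" in config.stages:
            summary["stages"]["paired"] = _run_paired(
                config, out, stage_seeds["paired"], log)
    except Exception as exc:  # noqa: BLE001 - stage attribution then re-raise
        log.append(f"FAILED: {exc}")
        (out / "run.log").write_text("\n".join(log) + "\n")
        raise

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    (out / "run.log").write_text("\n".join(log) + "\n")
    return summary


def _run_volume(config: RunConfig, out: Path, seed: int,
                log: list[str]) -> dict:
    if "volume_tif" in config.inputs:
        vol = io.read_volume(config.inputs["volume_tif"],
                             config.inputs.get("volume_meta"))
        log.append(f"volume: loaded {config.inputs['volume_tif']}")
    else:
        cfg = synthetic.NodeVolumeConfig(
            **_tuplify(config.volume), seed=config.volume.get("seed", seed)) \
            if "seed" not in config.volume else synthetic.NodeVolumeConfig(
                **_tuplify(config.volume))
        vol, gt = synthetic.gen_node_volume(cfg)
        io.write_volume(vol, out / "volume.tif")
        io.write_ground_truth(gt, out / "volume_truth.json")
        log.append(f"volume: generated (seed {cfg.seed})")

    params = config.analysis.get("volumetrics", {})
    res = volumetrics.analyze_volume(
        vol, tile_shape=tuple(params.get("tile_shape", (32, 32))),
        threshold_method=params.get("threshold_method", "fixed"),
        threshold=params.get("threshold", 0.5))
    profile, boundary = res["profile"], res["boundary"]

    io.write_table(
        _profile_table(profile), out / "distance_profile.csv")
    np.savetxt(out / "vessel_density_map.csv",
               res["vessel_density"].values, delimiter=",")
    np.savetxt(out / "myocyte_density_map.csv",
               res["myocyte_density"].values, delimiter=",")

    _fig(out / "density_heatmaps.png", lambda ax: (
        ax.imshow(res["vessel_density"].values, aspect="auto",
                  cmap="inferno"),
        ax.set_title("vessel fractional volume"),
        ax.set_xlabel("tile col"), ax.set_ylabel("node axis (tile row)")))

    def draw_profile(ax):
        ax.errorbar(profile.rows, profile.mean_um, yerr=profile.sem_um,
                    fmt=".", ms=3, lw=0.8, label="per-row mean")
        if not boundary.degenerate:
            from .fitstats import logistic4
            xs = np.linspace(profile.rows[0], profile.rows[-1], 200)
            ax.plot(xs, logistic4(xs, boundary.d_sup_um, boundary.d_inf_um,
                                  boundary.boundary_row, boundary.steepness),
                    label="sigmoid fit")
            ax.axvline(boundary.boundary_row, ls="--", c="k", lw=0.8)
        ax.set_xlabel("node axis row (voxels)")
        ax.set_ylabel("myocyte-vessel distance (um)")
        ax.legend(fontsize=7)

    _fig(out / "distance_profile.png", draw_profile)

    stage = {
        "global_vessel_fraction": res["vessel_density"].global_fraction,
        "global_myocyte_fraction": res["myocyte_density"].global_fraction,
        "boundary_row": boundary.boundary_row,
        "boundary_converged": boundary.converged,
        "d_sup_um": boundary.d_sup_um,
        "d_inf_um": boundary.d_inf_um,
    }
    if res["ecdf"]:
        for region in ("superior", "inferior"):
            stage[f"{region}_mean_distance_um"] = res["ecdf"][region]["mean_um"]
    log.append(f"volume: boundary row {boundary.boundary_row:.1f}")
    return stage


def _profile_table(profile):
    import pandas as pd
    return pd.DataFrame({
        "row": profile.rows, "mean_um": profile.mean_um,
        "sem_um": profile.sem_um, "n_voxels": profile.n})


def _run_trace(config: RunConfig, out: Path, seed: int,
               log: list[str]) -> dict:
    if "trace_csv" in config.inputs:
        trace = io.read_trace(config.inputs["trace_csv"],
                              config.inputs.get("sample_rate_hz"))
        log.append(f"trace: loaded {config.inputs['trace_csv']}")
    else:
        overrides = _tuplify(config.trace)
        overrides.setdefault("seed", seed)
        cfg = synthetic.TraceConfig(**overrides)
        trace, gt = synthetic.gen_voltage_trace(cfg)
        io.write_trace(trace, out / "trace.csv")
        io.write_ground_truth(gt, out / "trace_truth.json")
        log.append(f"trace: generated {cfg.modality} (seed {cfg.seed})")

    aps = ephys.detect_aps(trace)
    features = ephys.ap_features(trace, aps)
    subs = ephys.detect_subthreshold(trace, aps)
    stats = ephys.interval_stats(aps["takeoff_time_s"].to_numpy())
    modality = ephys.classify_modality(aps, subs, stats)

    io.write_table(features, out / "ap_table.csv")
    io.write_table(subs, out / "subthreshold_events.csv")

    def draw_joint(ax):
        if stats.joint_pairs.size:
            ax.loglog(stats.joint_pairs[:, 0], stats.joint_pairs[:, 1],
                      ".", ms=3, alpha=0.6)
        ax.set_xlabel("ISI$_i$ (ms)")
        ax.set_ylabel("ISI$_{i+1}$ (ms)")
        ax.set_title(f"modality: {modality}, CV = {stats.cv:.2f}")

    _fig(out / "joint_isi.png", draw_joint)

    if len(subs) >= 30:
        fit = ephys.fit_amplitude_mixture(subs["amplitude_mv"].to_numpy())

        def draw_hist(ax):
            amps = subs["amplitude_mv"].to_numpy()
            ax.hist(amps, bins=30, density=True, alpha=0.6)
            xs = np.linspace(amps.min(), amps.max(), 200)
            pdf = np.zeros_like(xs)
            for w, c, s in zip(fit.weights, fit.centers, fit.widths):
                pdf += w * np.exp(-0.5 * ((xs - c) / s) ** 2) / (
                    s * np.sqrt(2 * np.pi))
            ax.plot(xs, pdf, "k")
            ax.set_xlabel("subthreshold amplitude (mV)")
            ax.set_ylabel("density")

        _fig(out / "subthreshold_amplitudes.png", draw_hist)
        mixture = {"k": fit.k, "centers_mv": fit.centers.tolist(),
                   "widths_mv": fit.widths.tolist()}
    else:
        mixture = None

    stage = {
        "n_aps": int(len(aps)),
        "ap_frequency_hz": stats.frequency_hz,
        "isi_cv": stats.cv,
        "modality": modality,
        "n_subthreshold": int(len(subs)),
        "amplitude_mixture": mixture,
    }
    log.append(f"trace: {len(aps)} APs, modality {modality}")
    return stage


def _run_kymo(config: RunConfig, out: Path, seed: int,
              log: list[str]) -> dict:
    if "kymo_tif" in config.inputs:
        kymo = io.read_kymograph(config.inputs["kymo_tif"],
                                 config.inputs.get("kymo_meta"))
        log.append(f"kymo: loaded {config.inputs['kymo_tif']}")
    else:
        overrides = _tuplify(config.kymo)
        overrides.setdefault("seed", seed)
        cfg = synthetic.KymoConfig(**overrides)
        kymo, gt = synthetic.gen_kymograph(cfg)
        io.write_kymograph(kymo, out / "kymo.tif")
        io.write_ground_truth(gt, out / "kymo_truth.json")
        log.append(f"kymo: generated (seed {cfg.seed})")

    params = config.analysis.get("calcium", {})
    norm = calcium.normalize_kymograph(kymo)
    sparks = calcium.detect_sparks(norm,
                                   criterion=params.get("criterion", 3.8))
    transients = calcium.detect_transients(norm)
    rate = calcium.spark_rate(sparks, norm.scan_length_um, norm.duration_s)

    io.write_table(sparks, out / "spark_table.csv")
    io.write_table(transients, out / "transient_table.csv")

    def draw(ax):
        ax.imshow(norm.data, aspect="auto", cmap="viridis",
                  extent=[0, norm.duration_s, norm.scan_length_um, 0])
        if len(sparks):
            ax.plot(sparks["time_s"], sparks["position_um"], "r.", ms=4)
        ax.set_xlabel("time (s)")
        ax.set_ylabel("position (um)")

    _fig(out / "kymo_overlay.png", draw)

    stage = {
        "n_sparks": int(len(sparks)),
        "spark_rate_per_100um_s": rate,
        "n_transients": int(len(transients)),
        "transient_frequency_hz": transients.attrs["frequency_hz"],
    }
    log.append(f"kymo: {len(sparks)} sparks, rate {rate:.2f}/100um*s")
    return stage


def _run_paired(config: RunConfig, out: Path, seed: int,
                log: list[str]) -> dict:
    overrides_t = _tuplify(config.trace)
    overrides_t.setdefault("seed", seed)
    overrides_k = _tuplify(config.kymo)
    overrides_k.setdefault("seed", seed + 1)
    overrides_k.setdefault("spark_rate_per_100um_s", 0.0)
    cfg_t = synthetic.TraceConfig(**overrides_t)
    cfg_k = synthetic.KymoConfig(
        **{**overrides_k, "duration_s": cfg_t.duration_s})
    cfg_c = synthetic.CouplingConfig(**config.coupling)
    paired, gt = synthetic.gen_paired_recording(cfg_t, cfg_k, cfg_c)
    log.append(f"paired: generated (seeds {cfg_t.seed}/{cfg_k.seed})")

    aps = ephys.detect_aps(paired.trace)
    norm = calcium.normalize_kymograph(paired.kymograph)
    sparks = calcium.detect_sparks(norm)
    result = coupling.analyze_coupling(
        paired, aps["takeoff_time_s"].to_numpy(), sparks,
        window_ms=cfg_c.window_ms)

    io.write_table(result.dv_table, out / "spark_dv_table.csv")

    def draw(ax):
        centers = 0.5 * (result.hist_edges_s[:-1] + result.hist_edges_s[1:])
        ax.bar(centers * 1000, result.hist_prob,
               width=np.diff(result.hist_edges_s)[0] * 900, color="0.7")
        ax.set_xlabel("time before AP take-off (ms)")
        ax.set_ylabel("spark probability / bin")
        ax.set_title(f"slope {result.slope_prob_per_bin:.4f} /bin/bin")

    _fig(out / "pre_ap_sparks.png", draw)

    stage = {
        "n_aps": result.n_aps,
        "mean_sparks_per_ap": result.mean_sparks_per_ap,
        "pre_ap_slope": result.slope_prob_per_bin,
        "amplitude_dv_r": result.amplitude_dv_r,
        "amplitude_dv_r2": result.amplitude_dv_r2,
    }
    log.append(f"paired: {result.mean_sparks_per_ap:.2f} sparks per AP")
    return stage
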