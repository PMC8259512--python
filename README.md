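# sanmap

Quantitative analysis of sinoatrial-node (SAN) microvascular anatomy and
pacemaker-myocyte excitability, with synthetic ground-truth data for every
stage.

The SAN — the heart's primary pacemaker between the venae cavae — is not
homogeneous: vessel and myocyte densities, myocyte-to-vessel distances,
action-potential (AP) firing rates and Ca²⁺ signaling all differ between
its superior and inferior regions. `sanmap` implements the analysis chain
that quantifies this regional organization from standard experimental
data, and a set of simulators that generate statistically matched inputs
with complete ground truth, so every detector and estimator can be
validated end to end.

**Who it is for:** cardiac electrophysiology and microscopy labs analyzing
two-channel 3D immunofluorescence volumes (pacemaker marker HCN4 +
endothelial marker CD31), perforated-patch current-clamp recordings, and
Fluo-4 line-scan kymographs — and anyone who needs a reproducible,
testable re-implementation of these measurements.

## What it computes

**Volumetrics** (`sanmap.volumetrics`) — from a two-channel volume:

- fractional volume per tile, `f = N_mask / N_total`, as density heat maps;
- the exact anisotropic Euclidean distance from every myocyte voxel to its
  nearest vessel voxel;
- the per-row mean distance profile along the node axis and its
  four-parameter logistic fit
  `d(x) = d_sup + (d_inf − d_sup) / (1 + e^{−k(x − x₀)})`,
  whose inflection `x₀` is an objective superior/inferior boundary;
- a skeleton graph of the vasculature: segments, polyline lengths, branch
  orders 1°–4° (widest-continuation rule from the artery root), and
  per-segment diameters `2 × EDT` along the skeleton.

**Electrophysiology** (`sanmap.ephys`) — from a 10 kHz voltage trace:

- AP take-off detection (the sample where dV/dt first reaches 10% of its
  per-AP maximum) and full waveform features: peak, maximum dV/dt, MDP,
  diastolic duration, early diastolic depolarization (EDD) rate — the
  least-squares slope over 10–50% of the diastolic interval — and APD90;
- inter-AP interval statistics (mean, SD, CV = SD/mean, joint-interval
  pairs) and firing-modality classification
  (silent / subthreshold-only / tonic / irregular / burst);
- subthreshold voltage fluctuations: events exceeding baseline mean + 3 SD
  for ≥ 1 ms whose peak stays below the −29 mV AP threshold, plus one- or
  two-component Gaussian amplitude decomposition (EM, BIC selection);
- paired before/after condition comparisons (e.g. SR Ca²⁺-pump block).

**Calcium** (`sanmap.calcium`) — from a line-scan kymograph:

- per-pixel ΔF/F₀ normalization (F₀ = quiescent 20th percentile);
- Ca²⁺ spark detection (3.8 SD criterion) with amplitude, spatial FWHM,
  temporal FDHM, and rates in events/100 µm·s;
- whole-cell transient detection on the spatially averaged trace.

**Coupling** (`sanmap.coupling`) — from paired voltage + kymograph
recordings: sparks aligned to each AP's pre-take-off window, sparks per
AP, the exposure-corrected slope of the pre-AP spark-probability
histogram, and the spark-amplitude vs ΔV correlation.

**Synthetic data** (`sanmap.synthetic`) — generators for node volumes,
voltage traces (parametric AP waveform in five firing modalities),
kymographs and coupled paired recordings. Defaults are the reported
regional parameters (e.g. superior cells: 4.04 Hz, MDP −56.88 mV,
take-off −36.05 mV, APD90 51.56 ms, EDD rate 83.80 mV/s; subthreshold
amplitude mixture 2.0 ± 1.3 and 11.0 ± 1.1 mV). Every planted object is
recorded in a ground-truth structure.

## Worked example

```python
import numpy as np
from sanmap import synthetic, ephys

cfg = synthetic.TraceConfig(duration_s=30.0, seed=3)   # superior-cell defaults
trace, truth = synthetic.gen_voltage_trace(cfg)

aps = ephys.detect_aps(trace)
feats = ephys.ap_features(trace, aps)
stats = ephys.interval_stats(aps["takeoff_time_s"].to_numpy())
subs = ephys.detect_subthreshold(trace, aps)
print(f"APs detected: {len(aps)} (planted: {len(truth['ap_times_s'])})")
print(f"frequency: {stats.frequency_hz:.2f} Hz   ISI CV: {stats.cv:.2f}")
print(f"modality: {ephys.classify_modality(aps, subs, stats)}")
print(f"MDP: {feats['mdp_mv'].mean():.1f} mV   take-off: {feats['takeoff_mv'].mean():.1f} mV")
print(f"APD90: {feats['apd90_ms'].mean():.1f} ms   EDD rate: {feats['edd_rate_mv_per_s'].mean():.1f} mV/s")
```

prints

```
APs detected: 122 (planted: 122)
frequency: 4.07 Hz   ISI CV: 0.22
modality: tonic
MDP: -57.0 mV   take-off: -35.4 mV
APD90: 50.4 ms   EDD rate: 84.3 mV/s
```

Every AP planted at 4.04 Hz was recovered; the waveform features agree
with the generator parameters (MDP −56.88 mV, take-off −36.05 mV, APD90
51.56 ms, EDD rate 83.80 mV/s) to within a few percent, the residual
coming from the 0.3 mV recording noise. The low interval CV (0.22)
classifies the cell as a tonic firer.

## Command line

```sh
sanmap simulate volume|trace|kymo|paired --seed N --out DIR
sanmap volumetrics --in vol.tif --meta vol.json --tile 32 --out DIR
sanmap ephys --in trace.csv --rate 10000 --ap-threshold -29 --out DIR
sanmap calcium --in kymo.tif --criterion 3.8 --out DIR
sanmap coupling --trace t.csv --kymo k.tif --out DIR
sanmap run-all --config cfg.yaml --seed N --out DIR
```

Volumes are two-channel multi-page TIFF + JSON sidecar (voxel size,
channel names); traces are CSV `(time_s, mv)` or NPZ; kymographs are
single-channel TIFF + JSON (`pixel_um`, `line_interval_ms`). Each run
writes CSV tables, PNG figures, `summary.json` and a log, and is
byte-identical for a fixed config + seed.

## Acceptance script

`scripts/acceptance.py` recomputes the package's headline quantities from
scratch by running the generators and analysis modules end to end: the
interval CV of a simulated memoryless spike train, the recovered centers
of the two-component (superior) and single-component (inferior)
subthreshold amplitude mixtures, the fitted superior fraction of the node
axis on a default synthetic volume, and the pooled detected spark
amplitude at the low-amplitude calibration point. Run it as

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/sanmap/
  synthetic.py    generators + ground truth (volumes, traces, kymographs, paired)
  volumetrics.py  densities, distance transform, boundary fit, vessel graph
  ephys.py        AP/subthreshold detection, features, intervals, modality
  calcium.py      dF/F0 normalization, spark & transient detection
  coupling.py     spark-to-AP alignment, counts, slope, dV correlation
  fitstats.py     logistic fits, Gaussian mixtures, group comparisons
  io.py           TIFF/CSV/NPZ/JSON readers and writers
  pipeline.py     config-driven orchestration
  cli.py          the `sanmap` command
docs/methods.md   model and algorithm notes, defaults, limitations
```
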