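# Methods notes

This note documents the models behind `sanmap`'s generators and
estimators, the defaults and why they were chosen, what the synthetic
data does and does not emulate, and the numerical choices that affect
results. It states no empirical numbers beyond what the test suite and
`scripts/acceptance.py` themselves compute.

## Coordinate and unit conventions

Volumes are `(z, row, col)` with the node axis along rows and the
superior end at row 0; physical distances come from per-axis voxel sizes
in µm. Voltage is mV at a uniform sample rate (default 10 kHz).
Kymographs are `(space, time)` with `pixel_um` spacing and
`line_interval_ms` between lines (default ~4 ms); amplitudes are ΔF/F₀
after normalization. All randomness flows from a single integer seed per
generator; the pipeline derives per-stage child seeds from one run seed.

## Synthetic node volume

The vessel channel is built in three parts:

1. **Primary artery** — a straight tube descending the full node axis at
   the volume center, radius tapering linearly from the superior to the
   inferior diameter (defaults 30.6 → 23.4 µm, the reported 1° calibre
   change).
2. **Branch tree** — order-2..4 segments sprouting from random points on
   their parent, mostly lateral, with per-order diameters (10/6/4 µm) and
   lengths (30/20/12 µm) inside the reported per-order diameter ranges.
3. **Capillary bed** — an exact-count uniform random voxel field topping
   each region up to its vessel fractional-volume target (defaults
   0.10 superior / 0.04 inferior, switching at `boundary_fraction`,
   default 0.6 of the axis).

The capillary bed is deliberately a random *voxel* field rather than
discrete tubes: at the low inferior density, tube-shaped capillaries are
spatially clumpy (Poisson clustering of large objects), the per-row mean
distance then never plateaus, and the boundary fit becomes unstable.
The voxel field gives a spatially homogeneous nearest-vessel distance
within each region, which is the statistical property the distance
analysis measures. Consequences: the generated capillaries have no
connectivity or calibre, so vascular-topology analyses (skeleton,
orders, diameters) should run on tree-only volumes
(`capillaries=False`); and the absolute density→distance mapping is
voxel-size dependent.

The myocyte channel realizes its regional density targets exactly by
sampling voxels outside the vessel mask (defaults 0.35/0.20; free
parameters — only normalized density maps are reported in the source
data). A preset `distance_matched_node_config()` carries vessel
densities (0.15/0.05) calibrated once so the regional mean
myocyte-to-vessel distances reproduce the reported 2.54/4.69 µm at the
default geometry; the calibration is frozen, not re-fit.

Default shape (40, 120, 96) voxels at 2 µm: large enough that the artery
fits the cross-section with room for the density targets, small enough
that generation plus the distance transform runs in well under a second.
A real full-node mosaic at 0.5 µm/pixel would be >10⁹ voxels; all
algorithms are resolution-agnostic, only the defaults are scaled down.

## Synthetic voltage trace

The AP waveform is piecewise, with each piece mapping 1:1 onto a
measured feature:

- **Upstroke**: a logistic rescaled to interpolate take-off → peak
  exactly over 8τ, with maximum slope equal to the configured phase-0
  rate. Rescaling avoids the open tails of a pure logistic, which would
  otherwise create voltage discontinuities (and spurious dV/dt spikes)
  at the diastole junction.
- **Repolarization**: exponential decay toward an asymptote 5 mV below
  the MDP, with the time constant solved so the 90%-repolarization level
  is crossed exactly at APD90, followed by a 40 ms linear tail to the
  MDP. The bounded tail keeps the full AP span at APD90 + 40 ms; a pure
  exponential approach to the MDP would consume most of the cycle at
  fast rates and leave no diastole.
- **Diastole**: linear at exactly the configured EDD rate through the
  first half of the diastolic interval — covering the 10–50% window the
  feature extractor fits — then a faster linear rise to the take-off
  potential. Cycles whose diastole is too long for the configured rate
  (burst silences) fall back to a plain ramp and will not report the
  configured EDD rate.

Firing modalities: *tonic* draws ISIs from a normal distribution with
`isi_cv_target` (default 0.2); *irregular* draws exponential ISIs;
*burst* alternates exponential silences (mean 2 s) with short
high-frequency clusters (mean 6 APs at 150 ms). All ISIs are floored at
the waveform span + 30 ms; for the irregular default this leaves the
ground-truth interval CV slightly below 1 (≈0.93–0.96), the memoryless
benchmark being checked directly on exponential samples elsewhere.

Subthreshold fluctuations are alpha-function bumps (rise τ = duration/5,
durations uniform 5–50 ms; no shape is reported for the real events),
placed by Poisson thinning into diastolic windows, with amplitudes drawn
from the configured Gaussian mixture and clipped so the trace never
exceeds −31 mV (2 mV below the AP threshold). Recording noise is white
Gaussian, default SD 0.3 mV — a free parameter, chosen as a realistic
perforated-patch figure; the detector calibration tests probe 0.5 mV.

## Synthetic kymograph and paired recording

Sparks are separable events: Gaussian in space (configured FWHM,
default 2 µm) and instantaneous-rise/exponential-decay in time with
τ = FDHM/ln 2 (default FDHM 30 ms). The defaults are typical cardiac
spark dimensions; the source figures report only that geometry did not
differ regionally. Whole-cell transients use the same temporal kernel
across the full scan line. Raw fluorescence is
`F₀·(1 + ΔF/F₀) + noise`, with noise quoted in ΔF/F₀ units
(default 0.03).

Paired recordings plant Poisson-distributed spark counts (mean
`sparks_per_ap`) in the window before each AP take-off (default 300 ms,
truncated at the preceding AP), with spark times drawn from a linearly
ramping density 1 + r·x toward the AP (inverse-CDF sampling). An
optional `dv_per_amp_mv` adds a per-spark membrane depolarization; the
default is 0, matching the reported absence of spark→ΔV coupling.

## Detectors and estimators

**AP detection.** dV/dt is a central difference after a 0.5 ms moving
average. Candidate runs above 1 mV/ms are merged when closer than 20 ms
(noise fragments one upstroke); a candidate must reach a voltage peak
above −20 mV and above the −29 mV threshold, rise at least 10 mV above
its take-off sample (this rejects noise blips riding the repolarization,
where the absolute voltage is still high), and sit more than 5 ms from
the trace edges. The take-off sample is found by walking back from the
maximal slope to the first sample still at ≥10% of that AP's maximum
dV/dt; the per-AP (not per-trace) maximum accommodates variable
upstrokes.

**Waveform features.** The peak is read from the raw trace (smoothing
flattens it). MDP is the minimum between consecutive take-offs;
diastolic duration runs from that minimum to the take-off; the EDD rate
is the least-squares slope over 10–50% of it; APD90 interpolates the
crossing of `peak − 0.9(peak − take-off)`. Edge APs report NaN for
features their window cannot contain.

**Subthreshold events.** Baseline mean/SD come from the longest AP-free
stretch (≥200 ms), sigma-clipped at 3 SD so the events themselves do not
inflate the threshold. Crossings of mean + 3 SD separated by <0.5 ms are
merged; events must last ≥1 ms at the crossing level and peak below
−29 mV. *Limitation:* in fast tonic firers the diastoles are shorter
than the baseline window, so within-train bumps are under-detected; the
rule is reliable on quiescent or slowly firing cells, which is where the
amplitude statistics are measured.

**Modality rule.** Tonic if interval CV < 0.7; otherwise burst if a
two-component fit of the log-ISIs is selected by BIC with a mode ratio
> 5 *and* the short mode in the majority — a truncated-exponential
(irregular) train also splits into two modes, but with only a minor
refractory pile-up in the short one; otherwise irregular. Thresholds are
arguments.

**Spark detection.** The ΔF/F₀ image is Gaussian-smoothed (σ = 1 px/1
line) for detection; candidate regions are crossings of
baseline + 3.8 × the *smoothed* noise SD, and each event is then gated
on its raw peak amplitude exceeding 3.8 × the *raw* noise SD — the
criterion as usually quoted. Both noise scales are median/MAD estimates.
Connected components are split at local maxima (5 px × 9 line
footprint) so overlapping sparks at high rates are counted separately;
the event time is refined on the raw temporal profile (the smoothed
argmax lags the fast rise). FWHM/FDHM come from linearly interpolated
half-maximum crossings; events wider than 60% of the scan are treated as
whole-cell transients and excluded. Transients are detected on the
spatially averaged trace by peak *prominence* (floor 0.3 ΔF/F₀), so
events riding the previous decay in fast trains still count; amplitude
is measured from the event's left base.

**Coupling.** The pre-AP spark histogram is exposure-corrected: each
bin's count is divided by the number of AP windows long enough to cover
it, otherwise truncated windows make even a uniform spark distribution
look ramped. ΔV uses 20 ms means before onset/after peak; sparks with an
AP take-off less than 200 ms before or 50 ms after them are excluded so
upstrokes and repolarizations cannot masquerade as spark-evoked
depolarizations.

**Fits and statistics.** Gaussian mixtures are EM (scikit-learn) with 10
seeded restarts, tolerance 1e−8, full covariances, components sorted by
center, selection by BIC. The boundary fit is a bounded least-squares
4-parameter logistic with data-driven initialization; a profile whose
range is < 1e−9 (or < 1e−6 of its mean) is flagged degenerate, and the
fit is normalized so the steepness is positive. Group comparisons route
by Shapiro–Wilk at α = 0.05 to Student's t (or paired t) vs
Mann–Whitney (or Wilcoxon), with the usual */**/*** significance
convention. Sample (n−1) SDs throughout; event frequency is
(n−1)/(last − first).

**Vessel graph.** 26-connectivity skeleton (scikit-image), decomposed
into segments between junction/endpoint voxels; terminal segments
shorter than 3 voxels are pruned as spurs. Branch orders are assigned by
a greedy widest-continuation walk from the root (order 1 = primary
artery path; each side branch increments), using per-segment mean
diameters (2 × EDT along the path). Medial-axis skeletons erode tube
ends by about one radius, so segment lengths are systematically short by
up to a diameter per free end.

## What a green test establishes — and what it does not

The generators emulate the *statistical* structure the analyses assume:
regional density steps, renewal spike trains with parametric waveforms,
separable spark kernels, Poisson event counts. They do not emulate
microscope physics (PSF, bleaching, depth attenuation), cell geometry,
biophysical (conductance-based) AP dynamics, Ca²⁺ wave propagation, or
motion. Parameter-recovery results therefore validate the estimators'
correctness and calibration on matched models, not their robustness to
every real-data artifact. Thresholds most sensitive to this idealization
are the spark criterion (assumes stationary white noise) and the
AP-candidate gates (assume upstrokes are the fastest events in the
trace).

## Reference parameters

`synthetic.SUPERIOR_AP_REFERENCE` / `INFERIOR_AP_REFERENCE` hold the
reported regional single-cell AP parameters (frequency, CV, MDP,
take-off, early diastolic duration, EDD rate, phase-0 rate, APD90) and
drive the generator presets; the subthreshold amplitude mixtures are in
`SUPERIOR_SUBTHRESHOLD_MIXTURE` / `INFERIOR_SUBTHRESHOLD_MIXTURE`. Note
the early diastolic *duration* entries are reference values only: the
generator's diastole is fully determined by frequency, APD90 and the
waveform tail, so its implied EDD duration differs from the reference
table — the acceptance ratio check uses the reference values, not a
simulation.
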