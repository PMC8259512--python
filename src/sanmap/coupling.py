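"""Spark-to-action-potential coupling metrics for paired recordings.

Given a voltage trace and a line-scan kymograph on a shared time base,
these functions align detected Ca2+ sparks to the take-off time of each
AP, count sparks per diastolic window, fit the slope of the pre-AP
spark-probability histogram (spark accumulation toward firing), and
correlate spark amplitude with the local membrane-potential change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import PairedRecording

__all__ = [
    "AlignedSparks",
    "CouplingResult",
    "align_sparks_to_aps",
    "sparks_per_ap",
    "pre_ap_slope",
    "spark_voltage_coupling",
]


@dataclass
class AlignedSparks:
    """Sparks assigned to the pre-take-off window of each AP.

    ``rel_times_s`` holds, per AP, the spark times relative to that AP's
    take-off (all <= 0); ``windows_s`` is the actual window length used for
    each AP (the configured window truncated at the preceding AP).
    """

    ap_times_s: np.ndarray
    rel_times_s: list[np.ndarray]
    windows_s: np.ndarray
    window_s: float

    @property
    def counts(self) -> np.ndarray:
        return np.array([r.size for r in self.rel_times_s], dtype=int)

    @property
    def pooled_rel_times_s(self) -> np.ndarray:
        if not self.rel_times_s:
            return np.array([])
        return np.concatenate(self.rel_times_s) if any(
            r.size for r in self.rel_times_s) else np.array([])


@dataclass
class CouplingResult:
    mean_sparks_per_ap: float
    sd_sparks_per_ap: float
    n_aps: int
    hist_prob: np.ndarray
    hist_edges_s: np.ndarray
    slope_prob_per_bin: float
    slope_flagged: bool
    dv_table: pd.DataFrame | None = None
    amplitude_dv_r: float = float("nan")
    amplitude_dv_r2: float = float("nan")
    amplitude_dv_p: float = float("nan")


def align_sparks_to_aps(ap_times_s: np.ndarray, spark_times_s: np.ndarray,
                        window_ms: float = 300.0) -> AlignedSparks:
    """Assign sparks to the window before each AP take-off.

    For AP at time t the window is (t - w, t], with w the configured
    window truncated at the preceding AP's take-off, so a spark belongs to
    at most one AP.  Relative times are <= 0 (0 = at take-off).
    """
    ap = np.sort(np.asarray(ap_times_s, dtype=float))
    sp = np.sort(np.asarray(spark_times_s, dtype=float))
    w = window_ms / 1000.0
    rel: list[np.ndarray] = []
    windows = np.empty(ap.size)
    for i, t in enumerate(ap):
        lo = t - w
        if i > 0:
            lo = max(lo, ap[i - 1])
        windows[i] = t - lo
        inside = sp[(sp > lo) & (sp <= t)]
        rel.append(inside - t)
    return AlignedSparks(ap_times_s=ap, rel_times_s=rel, windows_s=windows,
                         window_s=w)


def sparks_per_ap(aligned: AlignedSparks) -> tuple[float, float, np.ndarray]:
    """Mean +/- sample SD of the per-AP spark count."""
    if aligned.ap_times_s.size == 0:
        raise ValueError("no APs to count sparks against")
    counts = aligned.counts
    sd = float(counts.std(ddof=1)) if counts.size > 1 else float("nan")
    return float(counts.mean()), sd, counts


def pre_ap_slope(aligned: AlignedSparks, n_bins: int = 10,
                 min_sparks: int = 20) -> tuple[float, np.ndarray, np.ndarray, bool]:
    """Slope of the pre-AP spark-probability histogram.

    Pooled relative spark times are binned over [-window, 0] into
    ``n_bins`` equal bins.  Because per-AP windows are truncated at the
    preceding AP, bins far from the take-off are covered by fewer APs;
    counts are therefore exposure-corrected (divided by the number of AP
    windows covering each bin) before normalizing to probability (sum 1).
    The slope is the least-squares fit of probability against bin index
    ordered toward the AP, in probability per bin per bin; positive slope
    = sparks accumulate before firing.  Fewer than ``min_sparks`` aligned
    sparks flags the estimate instead of failing.
    """
    rel = aligned.pooled_rel_times_s
    edges = np.linspace(-aligned.window_s, 0.0, n_bins + 1)
    if rel.size == 0:
        return float("nan"), np.zeros(n_bins), edges, True
    counts, _ = np.histogram(rel, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])
    exposure = np.array([(aligned.windows_s >= -c).sum() for c in centers])
    covered = exposure > 0
    rate = np.zeros(len(centers))
    rate[covered] = counts[covered] / exposure[covered]
    prob = rate / rate.sum() if rate.sum() > 0 else rate
    idx = np.arange(n_bins)
    slope = float(np.polyfit(idx[covered], prob[covered], 1)[0])
    flagged = rel.size < min_sparks
    return slope, prob, edges, flagged


def spark_voltage_coupling(paired: PairedRecording, sparks: pd.DataFrame,
                           ap_times_s: np.ndarray | None = None, *,
                           window_ms: float = 20.0,
                           ap_exclusion_post_ms: float = 200.0,
                           ap_exclusion_pre_ms: float = 50.0
                           ) -> pd.DataFrame:
    """Per-spark membrane-potential change and amplitude correlation.

    For each diastolic spark, dV = (mean V in the ``window_ms`` after the
    spark peak) - (mean V in the ``window_ms`` before it).  Sparks too
    close to the trace edges are excluded, as are sparks within an AP's
    voltage footprint (an AP take-off less than ``ap_exclusion_post_ms``
    before or ``ap_exclusion_pre_ms`` after the spark -- the upstroke or
    repolarization would otherwise dominate dV).  Returns a table of
    per-spark (amplitude, dV) plus the Pearson r, r^2 and p of their
    correlation (NaN-flagged when dV has no variance or fewer than 3
    sparks remain).
    """
    trace = paired.trace
    fs = trace.sample_rate_hz
    v = trace.samples_mv
    w = int(round(window_ms / 1000.0 * fs))
    ap = (np.asarray(ap_times_s, dtype=float)
          if ap_times_s is not None else np.array([]))
    post = ap_exclusion_post_ms / 1000.0
    pre = ap_exclusion_pre_ms / 1000.0
    rows = []
    for _, s in sparks.iterrows():
        t = float(s["time_s"]) + paired.offset_s
        i = int(round(t * fs))
        if i - w < 0 or i + w > v.size:
            continue
        if ap.size and np.any((ap >= t - post) & (ap <= t + pre)):
            continue
        dv = float(v[i:i + w].mean() - v[i - w:i].mean())
        rows.append({"time_s": t, "amplitude_dff": float(s["amplitude_dff"]),
                     "dv_mv": dv})
    table = pd.DataFrame(rows, columns=["time_s", "amplitude_dff", "dv_mv"])
    r = r2 = p = float("nan")
    if len(table) >= 3 and table["dv_mv"].std() > 1e-12 \
            and table["amplitude_dff"].std() > 1e-12:
        res = stats.pearsonr(table["amplitude_dff"], table["dv_mv"])
        r, p = float(res.statistic), float(res.pvalue)
        r2 = r * r
    table.attrs["r"] = r
    table.attrs["r2"] = r2
    table.attrs["p"] = p
    n = len(table)
    table.attrs["adjusted_r2"] = (1 - (1 - r2) * (n - 1) / (n - 2)
                                  if np.isfinite(r2) and n > 2 else float("nan"))
    return table


def analyze_coupling(paired: PairedRecording, ap_times_s: np.ndarray,
                     sparks: pd.DataFrame, *, window_ms: float = 300.0,
                     n_bins: int = 10) -> CouplingResult:
    """Full coupling analysis bundle used by the pipeline."""
    aligned = align_sparks_to_aps(ap_times_s, sparks["time_s"].to_numpy(),
                                  window_ms)
    if aligned.ap_times_s.size:
        mean_c, sd_c, _ = sparks_per_ap(aligned)
    else:
        mean_c, sd_c = float("nan"), float("nan")
    slope, prob, edges, flagged = pre_ap_slope(aligned, n_bins)
    dv_table = spark_voltage_coupling(paired, sparks, ap_times_s)
    return CouplingResult(
        mean_sparks_per_ap=mean_c, sd_sparks_per_ap=sd_c,
        n_aps=int(aligned.ap_times_s.size), hist_prob=prob,
        hist_edges_s=edges, slope_prob_per_bin=slope, slope_flagged=flagged,
        dv_table=dv_table, amplitude_dv_r=dv_table.attrs["r"],
        amplitude_dv_r2=dv_table.attrs["r2"],
        amplitude_dv_p=dv_table.attrs["p"])
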