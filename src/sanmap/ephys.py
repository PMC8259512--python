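"""Action-potential and subthreshold-event analysis of membrane-potential traces.

Feature conventions follow the standard pacemaker definitions:

* the take-off potential is the membrane voltage at which dV/dt first
  reaches 10% of its (per-AP) phase-0 maximum; its time stamps the AP;
* the maximum diastolic potential (MDP) is the most negative voltage
  between APs;
* diastolic duration is MDP time to take-off time; the early diastolic
  depolarization (EDD) rate is the least-squares slope over 10%-50% of
  that interval, and the early diastolic duration is that 40% window;
* APD90 is the time from take-off until the voltage has repolarized by
  90% of (peak - take-off potential);
* a subthreshold voltage fluctuation is a depolarizing event exceeding
  baseline mean + 3 SD for at least 1 ms whose peak stays below the AP
  threshold (-29 mV).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fitstats
from .datatypes import VoltageTrace

__all__ = [
    "AP_THRESHOLD_MV",
    "IntervalStats",
    "detect_aps",
    "ap_features",
    "interval_stats",
    "classify_modality",
    "detect_subthreshold",
    "fit_amplitude_mixture",
    "compare_conditions",
]

AP_THRESHOLD_MV = -29.0

AP_TABLE_COLUMNS = [
    "takeoff_time_s", "takeoff_mv", "peak_mv", "max_dvdt_mv_per_ms",
    "mdp_mv", "diastolic_duration_ms", "early_diastolic_duration_ms",
    "edd_rate_mv_per_s", "apd90_ms",
]

SUBTHRESHOLD_COLUMNS = [
    "onset_time_s", "amplitude_mv", "duration_ms", "peak_mv",
]


@dataclass
class IntervalStats:
    """Inter-event interval statistics (sample SD throughout)."""

    intervals_ms: np.ndarray
    mean_ms: float
    sd_ms: float
    cv: float
    frequency_hz: float
    joint_pairs: np.ndarray  # (n-1, 2): (ISI_i, ISI_i+1) in ms

    @property
    def n_events(self) -> int:
        return self.intervals_ms.size + 1 if self.intervals_ms.size else 0


def _smooth_dvdt(trace: VoltageTrace,
                 smooth_ms: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Moving-average smoothed voltage and central-difference dV/dt (mV/ms)."""
    v = trace.samples_mv
    fs = trace.sample_rate_hz
    win = max(int(round(smooth_ms * fs / 1000.0)), 1)
    if win > 1:
        kernel = np.ones(win) / win
        vs = np.convolve(v, kernel, mode="same")
    else:
        vs = v.astype(float)
    dvdt = np.gradient(vs) * fs / 1000.0
    return vs, dvdt


def detect_aps(trace: VoltageTrace, *, dvdt_floor_mv_per_ms: float = 1.0,
               peak_floor_mv: float = -20.0,
               ap_threshold_mv: float = AP_THRESHOLD_MV,
               smooth_ms: float = 0.5) -> pd.DataFrame:
    """Detect AP take-off times.

    Candidate upstrokes are contiguous runs where the smoothed dV/dt
    exceeds an absolute floor (default 1 mV/ms); a candidate is accepted
    when the following voltage peak crosses both the AP threshold and a
    peak floor (default -20 mV), which excludes large subthreshold bumps.
    The take-off sample is the first, walking back from the maximal-slope
    sample, at which dV/dt still exceeds 10% of that AP's maximum dV/dt.
    """
    if trace.duration_s < 0.5:
        raise ValueError("need at least 0.5 s of data to detect APs")
    vs, dvdt = _smooth_dvdt(trace, smooth_ms)
    fs = trace.sample_rate_hz
    above = dvdt > dvdt_floor_mv_per_ms
    if not above.any():
        return pd.DataFrame(columns=["takeoff_time_s", "takeoff_mv",
                                     "max_dvdt_mv_per_ms"])
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])

    # merge candidate runs separated by less than 20 ms: noise fragments a
    # single upstroke (and its foot) into several supra-floor runs
    gap = int(0.02 * fs)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])

    edge = int(0.005 * fs)  # smoothing/gradient edge artifacts
    rows = []
    for s, e in merged:
        seg = slice(s, e)
        i_max = s + int(np.argmax(dvdt[seg]))
        if i_max < edge or i_max > vs.size - edge:
            continue
        max_dvdt = float(dvdt[i_max])
        # voltage peak within 20 ms after the maximal slope
        j_end = min(i_max + int(0.02 * fs), vs.size)
        v_peak = float(vs[i_max:j_end].max()) if j_end > i_max else float(vs[i_max])
        if v_peak < peak_floor_mv or v_peak < ap_threshold_mv:
            continue
        # walk back to the first sample at >= 10% of this AP's max dV/dt
        thr = 0.1 * max_dvdt
        i = i_max
        while i > 0 and dvdt[i - 1] >= thr:
            i -= 1
        if v_peak - float(vs[i]) < 10.0:
            continue  # no real upstroke above the take-off level
        rows.append({
            "takeoff_time_s": i / fs,
            "takeoff_mv": float(vs[i]),
            "max_dvdt_mv_per_ms": max_dvdt,
        })
    df = pd.DataFrame(rows, columns=["takeoff_time_s", "takeoff_mv",
                                     "max_dvdt_mv_per_ms"])
    # collapse duplicates closer than 20 ms (one upstroke split by noise)
    if len(df) > 1:
        keep = np.concatenate([[True],
                               np.diff(df["takeoff_time_s"]) > 0.02])
        df = df[keep].reset_index(drop=True)
    return df


def ap_features(trace: VoltageTrace, ap_table: pd.DataFrame, *,
                smooth_ms: float = 0.5) -> pd.DataFrame:
    """Per-AP waveform features; edge APs get NaN for diastolic features.

    Diastolic features (MDP, diastolic duration, EDD rate) describe the
    interval *preceding* each AP, so the first AP has none; APD90 needs
    the repolarization to complete inside the trace, so a final truncated
    AP reports NaN.
    """
    vs, dvdt = _smooth_dvdt(trace, smooth_ms)
    fs = trace.sample_rate_hz
    takeoffs = ap_table["takeoff_time_s"].to_numpy()
    rows = []
    for i, t0 in enumerate(takeoffs):
        i0 = int(round(t0 * fs))
        rec: dict[str, float] = {
            "takeoff_time_s": t0,
            "takeoff_mv": float(vs[i0]),
            "max_dvdt_mv_per_ms": float(
                ap_table["max_dvdt_mv_per_ms"].iloc[i])
            if "max_dvdt_mv_per_ms" in ap_table else float("nan"),
        }
        t_next = takeoffs[i + 1] if i + 1 < takeoffs.size else trace.duration_s
        i_next = int(round(t_next * fs))
        # peak after take-off, from the raw trace (smoothing flattens it)
        raw = trace.samples_mv
        j_end = min(i0 + int(0.05 * fs), i_next, vs.size)
        seg = raw[i0:j_end]
        if seg.size == 0:
            continue
        peak = float(seg.max())
        i_peak = i0 + int(np.argmax(seg))
        rec["peak_mv"] = peak
        # APD90: repolarization to 90% of (peak - takeoff) below peak
        v90 = peak - 0.9 * (peak - rec["takeoff_mv"])
        rep = vs[i_peak:i_next]
        below = np.flatnonzero(rep <= v90)
        if below.size:
            k = below[0]
            if k > 0:
                # linear interpolation between the straddling samples
                va, vb = rep[k - 1], rep[k]
                fracs = (va - v90) / (va - vb) if va != vb else 0.0
                t90 = (i_peak + k - 1 + fracs) / fs
            else:
                t90 = (i_peak + k) / fs
            rec["apd90_ms"] = (t90 - t0) * 1000.0
        else:
            rec["apd90_ms"] = float("nan")
        # diastolic features from the preceding inter-AP interval
        if i == 0:
            rec.update(mdp_mv=float("nan"), diastolic_duration_ms=float("nan"),
                       early_diastolic_duration_ms=float("nan"),
                       edd_rate_mv_per_s=float("nan"))
        else:
            t_prev = takeoffs[i - 1]
            i_prev = int(round(t_prev * fs))
            between = vs[i_prev:i0]
            i_mdp = i_prev + int(np.argmin(between))
            mdp = float(vs[i_mdp])
            dd_s = (i0 - i_mdp) / fs
            rec["mdp_mv"] = mdp
            rec["diastolic_duration_ms"] = dd_s * 1000.0
            a = i_mdp + int(round(0.1 * dd_s * fs))
            b = i_mdp + int(round(0.5 * dd_s * fs))
            if b - a >= 2:
                tt = np.arange(a, b) / fs
                slope = float(np.polyfit(tt, vs[a:b], 1)[0])
                rec["edd_rate_mv_per_s"] = slope
                rec["early_diastolic_duration_ms"] = (b - a) / fs * 1000.0
            else:
                rec["edd_rate_mv_per_s"] = float("nan")
                rec["early_diastolic_duration_ms"] = float("nan")
        rows.append(rec)
    return pd.DataFrame(rows, columns=AP_TABLE_COLUMNS)


def interval_stats(event_times_s: np.ndarray,
                   frequency_mode: str = "span") -> IntervalStats:
    """Inter-event intervals, CV (sample SD / mean) and joint-interval pairs.

    ``frequency_mode='span'`` defines frequency as (n-1)/(last-first);
    ``'duration'`` callers can divide the count by the recording length
    themselves.  Fewer than 2 events yields NaN frequency; fewer than 3
    yields NaN CV.
    """
    t = np.sort(np.asarray(event_times_s, dtype=float))
    isis = np.diff(t) * 1000.0
    if t.size >= 2 and frequency_mode == "span":
        freq = (t.size - 1) / (t[-1] - t[0]) if t[-1] > t[0] else float("nan")
    else:
        freq = float("nan")
    if isis.size >= 2:
        mean = float(isis.mean())
        sd = float(isis.std(ddof=1))
        cv = sd / mean if mean > 0 else float("nan")
    elif isis.size == 1:
        mean, sd, cv = float(isis[0]), float("nan"), float("nan")
    else:
        mean = sd = cv = float("nan")
    pairs = (np.column_stack([isis[:-1], isis[1:]])
             if isis.size >= 2 else np.empty((0, 2)))
    return IntervalStats(intervals_ms=isis, mean_ms=mean, sd_ms=sd, cv=cv,
                         frequency_hz=freq, joint_pairs=pairs)


def classify_modality(ap_table: pd.DataFrame, subthreshold: pd.DataFrame,
                      stats: IntervalStats | None = None, *,
                      tonic_cv_max: float = 0.7,
                      burst_mode_ratio: float = 5.0,
                      seed: int = 0) -> str:
    """Classify a trace's firing modality.

    silent: no APs and no subthreshold events; subthreshold_only: events
    but no APs.  With >= 3 APs, tonic when the ISI CV is below
    ``tonic_cv_max``; otherwise burst when the log-ISI distribution is
    bimodal with a mode ratio above ``burst_mode_ratio`` (long silences
    versus short intra-burst intervals -- the "L-shaped" joint-interval
    signature), else irregular.
    """
    n_aps = len(ap_table)
    if n_aps == 0:
        return "subthreshold_only" if len(subthreshold) else "silent"
    if stats is None:
        stats = interval_stats(ap_table["takeoff_time_s"].to_numpy())
    if stats.intervals_ms.size < 2 or not np.isfinite(stats.cv):
        return "irregular"
    if stats.cv < tonic_cv_max:
        return "tonic"
    log_isi = np.log(stats.intervals_ms)
    if log_isi.size >= 30:
        fit = fitstats.select_mixture(log_isi, (1, 2), seed=seed)
        if fit.k == 2:
            ratio = float(np.exp(fit.centers[1] - fit.centers[0]))
            # bursting = two well-separated ISI modes with the *short*
            # (intra-burst) mode in the majority; a heavy-tailed but
            # unimodal (Poisson-like) train instead puts most mass in the
            # long mode, with a minor pile-up at the refractory floor
            if ratio > burst_mode_ratio and fit.weights[0] > 0.5:
                return "burst"
    else:
        # small samples: fall back to a direct mode-ratio heuristic
        short = np.median(stats.intervals_ms[
            stats.intervals_ms <= np.median(stats.intervals_ms)])
        long = np.median(stats.intervals_ms[
            stats.intervals_ms > np.median(stats.intervals_ms)])
        if long / short > burst_mode_ratio:
            return "burst"
    return "irregular"


def _baseline_stats(vs: np.ndarray, free: np.ndarray, fs: float,
                    min_ms: float = 200.0) -> tuple[float, float]:
    """Mean/SD of the longest AP-free segment, sigma-clipped at 3 SD so the
    subthreshold events themselves do not inflate the baseline."""
    runs = []
    in_run = False
    start = 0
    for i, f in enumerate(free):
        if f and not in_run:
            in_run, start = True, i
        elif not f and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, free.size))
    if not runs:
        raise ValueError("no AP-free segment available for a baseline")
    s, e = max(runs, key=lambda r: r[1] - r[0])
    if (e - s) / fs * 1000.0 < min_ms:
        raise ValueError("longest AP-free segment is shorter than the "
                         f"{min_ms:.0f} ms baseline window")
    seg = vs[s:e]
    mu, sd = float(seg.mean()), float(seg.std())
    for _ in range(5):
        keep = np.abs(seg - mu) < 3.0 * sd
        if keep.all() or keep.sum() < 50:
            break
        mu, sd = float(seg[keep].mean()), float(seg[keep].std())
    return mu, max(sd, 1e-6)


def detect_subthreshold(trace: VoltageTrace, ap_table: pd.DataFrame, *,
                        ap_threshold_mv: float = AP_THRESHOLD_MV,
                        smooth_ms: float = 0.5,
                        exclusion_pre_ms: float = 10.0,
                        exclusion_post_ms: float = 150.0) -> pd.DataFrame:
    """Detect subthreshold voltage fluctuations.

    Events are contiguous runs above baseline mean + 3 SD lasting at least
    1 ms (measured at the crossing level) whose peak stays below the AP
    threshold.  Windows around each AP (10 ms before to 150 ms after the
    take-off by default) are excluded from the search, and the baseline is
    the sigma-clipped mean/SD of the longest AP-free stretch (>= 200 ms).
    """
    vs, _ = _smooth_dvdt(trace, smooth_ms)
    fs = trace.sample_rate_hz
    free = np.ones(vs.size, dtype=bool)
    for t0 in ap_table["takeoff_time_s"].to_numpy() if len(ap_table) else []:
        a = max(int((t0 - exclusion_pre_ms / 1000.0) * fs), 0)
        b = min(int((t0 + exclusion_post_ms / 1000.0) * fs), vs.size)
        free[a:b] = False
    mu, sd = _baseline_stats(vs, free, fs)
    thr = mu + 3.0 * sd

    above = (vs > thr) & free
    d = np.diff(above.astype(int))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if above[0]:
        starts = np.concatenate([[0], starts])
    if above[-1]:
        ends = np.concatenate([ends, [above.size]])
    # merge crossings separated by < 0.5 ms: noise splits one event
    gap = max(int(round(0.5e-3 * fs)), 1)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    min_samples = max(int(round(1e-3 * fs)), 1)
    rows = []
    for s, e in merged:
        if e - s < min_samples:
            continue
        peak = float(vs[s:e].max())
        if peak >= ap_threshold_mv:
            continue
        rows.append({
            "onset_time_s": s / fs,
            "amplitude_mv": peak - mu,
            "duration_ms": (e - s) / fs * 1000.0,
            "peak_mv": peak,
        })
    df = pd.DataFrame(rows, columns=SUBTHRESHOLD_COLUMNS)
    df.attrs["baseline_mean_mv"] = mu
    df.attrs["baseline_sd_mv"] = sd
    return df


def fit_amplitude_mixture(amplitudes, k_candidates=(1, 2),
                          seed: int = 0) -> fitstats.MixtureFit:
    """Decompose an event-amplitude sample into 1 or 2 Gaussian components,
    selecting the component count by BIC."""
    return fitstats.select_mixture(amplitudes, k_candidates, seed=seed)


def compare_conditions(cells_before: dict[str, dict],
                       cells_after: dict[str, dict]) -> pd.DataFrame:
    """Per-cell before/after comparison (e.g. control vs thapsigargin).

    Each cell record maps a cell id to a dict with any of the keys
    ``ap_frequency_hz``, ``subthreshold_frequency_hz``,
    ``subthreshold_amplitude_mv`` and ``resting_potential_mv``; the result
    holds the per-cell deltas (after - before) plus a ``__summary__`` row
    of group means.  Cells must match between conditions.
    """
    if set(cells_before) != set(cells_after):
        raise ValueError("condition tables cover different cells")
    keys = ["ap_frequency_hz", "subthreshold_frequency_hz",
            "subthreshold_amplitude_mv", "resting_potential_mv"]
    rows = []
    for cell in sorted(cells_before):
        rec = {"cell": cell}
        for k in keys:
            b = cells_before[cell].get(k)
            a = cells_after[cell].get(k)
            rec[f"delta_{k}"] = (a - b) if a is not None and b is not None \
                else float("nan")
        rows.append(rec)
    df = pd.DataFrame(rows)
    summary = {"cell": "__summary__"}
    for k in keys:
        col = df[f"delta_{k}"]
        summary[f"delta_{k}"] = float(col.mean())
    return pd.concat([df, pd.DataFrame([summary])], ignore_index=True)
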