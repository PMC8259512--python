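"""AP detection, waveform features, interval statistics, event detection."""

import numpy as np
import pandas as pd
import pytest

from sanmap import ephys, synthetic
from sanmap.datatypes import VoltageTrace
from sanmap.ephys import (ap_features, classify_modality, compare_conditions,
                          detect_aps, detect_subthreshold,
                          fit_amplitude_mixture, interval_stats)

from conftest import match_events

FS = 10_000.0


def _trace(v, fs=FS):
    return VoltageTrace(samples_mv=np.asarray(v, float), sample_rate_hz=fs)


class TestDetectAps:
    def test_flat_trace_no_aps(self):
        aps = detect_aps(_trace(np.full(20_000, -60.0)))
        assert len(aps) == 0

    def test_tonic_trace_count_matches_planted(self, tonic_trace):
        trace, gt = tonic_trace
        aps = detect_aps(trace)
        assert abs(len(aps) - len(gt["ap_times_s"])) <= 2

    def test_takeoff_at_ten_percent_of_max_slope(self):
        # piecewise-linear upstroke: 1 s at -60, ramp at 2 mV/ms for 10 ms,
        # then 40 mV/ms for 2 ms to +20, hold, decay.  10% of max slope =
        # 4 mV/ms, first reached where the 40 mV/ms leg begins.
        fs = FS
        t_ramp = int(0.010 * fs)
        t_fast = int(0.002 * fs)
        v = np.concatenate([
            np.full(int(fs), -60.0),
            -60.0 + 2.0 * np.arange(t_ramp) / 10.0,     # 2 mV/ms
            -40.0 + 40.0 * np.arange(t_fast) / 10.0,    # 40 mV/ms
            np.full(int(0.02 * fs), 20.0),
            np.linspace(20.0, -60.0, int(0.1 * fs)),
            np.full(int(fs), -60.0),
        ])
        aps = detect_aps(_trace(v))
        assert len(aps) == 1
        expected = 1.0 + 0.010  # start of the 40 mV/ms leg
        assert aps["takeoff_time_s"].iloc[0] == pytest.approx(expected,
                                                              abs=0.0015)

    def test_detection_invariant_to_offset_and_shift(self, tonic_trace):
        trace, _ = tonic_trace
        base = detect_aps(trace)["takeoff_time_s"].to_numpy()
        shifted = detect_aps(_trace(trace.samples_mv + 17.0))[
            "takeoff_time_s"].to_numpy()
        assert np.allclose(base, shifted)
        pad = np.concatenate([np.full(int(FS), trace.samples_mv[0]),
                              trace.samples_mv])
        padded = detect_aps(_trace(pad))["takeoff_time_s"].to_numpy()
        assert np.allclose(padded[: base.size], base + 1.0, atol=2e-3)

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_aps(_trace(np.zeros(1000)))

    @pytest.mark.parametrize("modality,freq", [("tonic", 4.04),
                                               ("irregular", 1.44),
                                               ("burst", 2.0)])
    def test_recall_and_precision_across_modalities(self, modality, freq):
        """Detection recall and precision >= 0.98 on generator traces at
        default noise, across firing modalities and seeds."""
        tps = fns = fps = 0
        for seed in range(7):
            cfg = synthetic.TraceConfig(duration_s=20.0, modality=modality,
                                        ap_frequency_hz=freq, seed=seed)
            trace, gt = synthetic.gen_voltage_trace(cfg)
            det = detect_aps(trace)["takeoff_time_s"].to_numpy()
            tp, fn, fp = match_events(det, np.asarray(gt["ap_times_s"]),
                                      tol=0.005)
            tps, fns, fps = tps + tp, fns + fn, fps + fp
        assert tps / (tps + fns) >= 0.98
        assert tps / (tps + fps) >= 0.98


class TestApFeatures:
    def test_linear_diastolic_ramp_edd_rate(self):
        # MDP hold, exactly 50 mV/s ramp for 400 ms, then a fast AP
        fs = FS
        ramp = int(0.4 * fs)
        up = int(0.002 * fs)
        cycle = np.concatenate([
            -60.0 + 50.0 * np.arange(ramp) / fs,          # 50 mV/s
            -40.0 + 60.0 * np.arange(up) / (up / 10.0),   # fast upstroke
            np.linspace(20.0, -60.0, int(0.06 * fs)),
        ])
        v = np.concatenate([np.full(int(0.2 * fs), -60.0)] + [cycle] * 4)
        trace = _trace(v)
        aps = detect_aps(trace)
        feats = ap_features(trace, aps)
        edd = feats["edd_rate_mv_per_s"].dropna()
        assert len(edd) >= 2
        assert edd.mean() == pytest.approx(50.0, abs=0.5)

    def test_triangular_ap_apd90_closed_form(self):
        # symmetric triangle: instant-ish rise 2 ms, linear fall 80 mV over
        # 40 ms; APD90 = rise + time to drop 0.9*80 = 2 + 36 ms
        fs = FS
        rise = int(0.002 * fs)
        fall = int(0.040 * fs)
        tri = np.concatenate([
            np.linspace(-60.0, 20.0, rise),
            np.linspace(20.0, -60.0, fall),
        ])
        v = np.concatenate([np.full(int(fs), -60.0), tri,
                            np.full(int(fs), -60.0)])
        trace = _trace(v)
        aps = detect_aps(trace)
        feats = ap_features(trace, aps)
        assert feats["apd90_ms"].iloc[0] == pytest.approx(38.0, abs=1.5)

    def test_generator_waveform_parameters_recovered(self, tonic_trace):
        """Mean features within 10% of the superior-cell generator values
        (take-off -36.05 mV, MDP -56.88 mV, APD90 51.56 ms, EDD rate
        83.80 mV/s, phase-0 40 mV/ms)."""
        trace, gt = tonic_trace
        cfg = gt["config"]
        feats = ap_features(trace, detect_aps(trace))
        checks = {
            "takeoff_mv": cfg.takeoff_mv,
            "mdp_mv": cfg.mdp_mv,
            "peak_mv": cfg.peak_mv,
            "apd90_ms": cfg.apd90_ms,
            "edd_rate_mv_per_s": cfg.edd_rate_mv_per_s,
            "max_dvdt_mv_per_ms": cfg.upstroke_rate_mv_per_ms,
        }
        for col, target in checks.items():
            assert feats[col].mean() == pytest.approx(target, rel=0.10), col

    def test_edge_ap_features_flagged_missing(self, tonic_trace):
        trace, _ = tonic_trace
        feats = ap_features(trace, detect_aps(trace))
        assert np.isnan(feats["mdp_mv"].iloc[0])  # no preceding diastole


class TestIntervalStats:
    def test_hand_arithmetic(self):
        st = interval_stats(np.array([0.0, 0.1, 0.3, 0.6]))
        assert st.intervals_ms == pytest.approx([100.0, 200.0, 300.0])
        assert st.mean_ms == pytest.approx(200.0)
        assert st.sd_ms == pytest.approx(100.0)
        assert st.cv == pytest.approx(0.5)
        assert st.frequency_hz == pytest.approx(3 / 0.6)

    def test_periodic_events_zero_cv(self):
        st = interval_stats(np.arange(50) * 0.25)
        assert st.cv == pytest.approx(0.0, abs=1e-12)

    def test_exponential_intervals_unit_cv(self):
        rng = np.random.default_rng(0)
        times = np.cumsum(rng.exponential(0.25, 10_000))
        st = interval_stats(times)
        assert st.cv == pytest.approx(1.0, abs=0.03)

    def test_joint_pairs_conserve_count(self):
        rng = np.random.default_rng(1)
        times = np.cumsum(rng.uniform(0.1, 0.5, 200))
        st = interval_stats(times)
        assert st.joint_pairs.shape == (st.intervals_ms.size - 1, 2)

    def test_too_few_events_flagged(self):
        st = interval_stats(np.array([0.5]))
        assert np.isnan(st.frequency_hz) and np.isnan(st.cv)


class TestClassifyModality:
    @pytest.mark.parametrize("modality,freq", [
        ("tonic", 4.04), ("irregular", 1.44), ("burst", 2.0),
        ("silent", 0.5), ("subthreshold_only", 0.5)])
    def test_generator_label_recovery(self, modality, freq):
        for seed in range(3):
            cfg = synthetic.TraceConfig(duration_s=60.0, modality=modality,
                                        ap_frequency_hz=freq, seed=seed)
            trace, _ = synthetic.gen_voltage_trace(cfg)
            aps = detect_aps(trace)
            subs = detect_subthreshold(trace, aps)
            assert classify_modality(aps, subs) == modality

    def test_no_events_is_silent(self):
        empty = pd.DataFrame(columns=["takeoff_time_s"])
        assert classify_modality(empty, pd.DataFrame()) == "silent"


class TestDetectSubthreshold:
    def test_false_positive_rate_on_pure_noise(self):
        """3-SD + 1-ms rule: < 0.1 Hz false events on Gaussian noise."""
        n_events = 0
        for seed in range(3):
            cfg = synthetic.TraceConfig(duration_s=60.0, modality="silent",
                                        noise_sd_mv=0.5, seed=seed)
            trace, _ = synthetic.gen_voltage_trace(cfg)
            n_events += len(detect_subthreshold(trace, detect_aps(trace)))
        assert n_events / 180.0 < 0.1

    def test_planted_bump_recall(self):
        cfg = synthetic.TraceConfig(
            duration_s=60.0, modality="subthreshold_only",
            subthreshold_rate_hz=2.0, noise_sd_mv=0.5,
            subthreshold_amp_mixture=[(1.0, 5.0, 0.0)], seed=5)
        trace, gt = synthetic.gen_voltage_trace(cfg)
        subs = detect_subthreshold(trace, detect_aps(trace))
        truth = np.array([b["time_s"] for b in gt["bumps"]])
        tp, fn, _ = match_events(subs["onset_time_s"].to_numpy(), truth,
                                 tol=0.03)
        assert tp / truth.size >= 0.95

    def test_event_reaching_ap_threshold_rejected(self):
        # a 35 mV depolarization from -60 peaks at -25 mV: not subthreshold
        fs = FS
        v = np.full(int(3 * fs), -60.0)
        bump = 35.0 * np.sin(np.linspace(0, np.pi, int(0.03 * fs))) ** 2
        v[int(1.5 * fs):int(1.5 * fs) + bump.size] += bump
        v += np.random.default_rng(0).normal(0, 0.3, v.size)
        subs = detect_subthreshold(_trace(v), detect_aps(_trace(v)))
        assert not ((subs["onset_time_s"] - 1.5).abs() < 0.05).any()

    def test_amplitudes_exceed_three_sd(self):
        cfg = synthetic.TraceConfig(duration_s=30.0,
                                    modality="subthreshold_only", seed=1)
        trace, _ = synthetic.gen_voltage_trace(cfg)
        subs = detect_subthreshold(trace, detect_aps(trace))
        assert (subs["amplitude_mv"]
                > 3 * subs.attrs["baseline_sd_mv"]).all()
        assert (subs["duration_ms"] >= 1.0).all()

    def test_short_trace_baseline_error(self):
        with pytest.raises(ValueError):
            detect_subthreshold(_trace(np.zeros(500)), pd.DataFrame(
                columns=["takeoff_time_s"]))


class TestAmplitudeMixture:
    def test_two_component_recovery_at_printed_parameters(self):
        rng = np.random.default_rng(11)
        comp = rng.integers(0, 2, 2000)
        x = np.where(comp == 0, rng.normal(2.0, 1.3, 2000),
                     rng.normal(11.0, 1.1, 2000))
        fit = fit_amplitude_mixture(x)
        assert fit.k == 2
        assert fit.centers[0] == pytest.approx(2.0, abs=0.2)
        assert fit.centers[1] == pytest.approx(11.0, abs=0.3)

    def test_single_component_selected_and_centered(self):
        rng = np.random.default_rng(12)
        fit = fit_amplitude_mixture(rng.normal(6.0, 2.3, 2000))
        assert fit.k == 1
        assert fit.centers[0] == pytest.approx(6.0, abs=0.2)

    def test_degenerate_sample_flagged(self):
        fit = fit_amplitude_mixture(np.full(50, 4.2))
        assert fit.degenerate

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            fit_amplitude_mixture(np.arange(20.0))


class TestCompareConditions:
    def test_identical_conditions_zero_deltas(self):
        cells = {f"c{i}": {"ap_frequency_hz": 4.0,
                           "resting_potential_mv": -60.0} for i in range(5)}
        out = compare_conditions(cells, cells)
        deltas = out[out["cell"] != "__summary__"]
        assert np.allclose(deltas["delta_ap_frequency_hz"], 0.0)

    def test_planted_baseline_shift_recovered(self):
        # a +20 mV resting-potential shift between conditions
        rng = np.random.default_rng(3)
        before = {f"c{i}": {"resting_potential_mv": -60.0 + rng.normal(0, 1)}
                  for i in range(6)}
        after = {c: {"resting_potential_mv":
                     before[c]["resting_potential_mv"] + 20.0
                     + rng.normal(0, 0.3)} for c in before}
        out = compare_conditions(before, after)
        summary = out[out["cell"] == "__summary__"].iloc[0]
        assert summary["delta_resting_potential_mv"] == pytest.approx(
            20.0, abs=1.0)

    def test_ap_suppression_with_preserved_bumps(self):
        # emulates SR Ca2+ pump block: APs vanish, bump rate unchanged
        before = {"c1": {"ap_frequency_hz": 4.0,
                         "subthreshold_frequency_hz": 2.1}}
        after = {"c1": {"ap_frequency_hz": 0.0,
                        "subthreshold_frequency_hz": 2.0}}
        out = compare_conditions(before, after)
        row = out.iloc[0]
        assert row["delta_ap_frequency_hz"] == pytest.approx(-4.0)
        assert abs(row["delta_subthreshold_frequency_hz"]) < 0.2

    def test_unmatched_cells_rejected(self):
        with pytest.raises(ValueError):
            compare_conditions({"a": {}}, {"b": {}})
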