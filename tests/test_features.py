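"""Landmark extraction: recovery against ground truth and closed forms."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from meafp.errors import (InvalidArgumentError, InvalidWindowError,
                          SchemaError, UnsupportedInputError)
from meafp.features import (DetectionParams, assemble_feature_table,
                            cluster_well_beats, detect_beats,
                            fridericia_correct, measure_fpd, measure_slope)
from meafp.simulate import RecordingBundle, preset_config, simulate_recording
from meafp.layout import make_layout


def _bundle_from(signals, fs=2000.0, layout=None):
    layout = layout or make_layout(1, signals.shape[1], 300.0)
    return RecordingBundle(signals=signals, sampling_rate=fs, layout=layout,
                           metadata={"well_id": "w", "genotype": "g",
                                     "differentiation_id": "d", "seed": 0,
                                     "preset": None})


class TestDetect:
    def test_noise_free_recovery_one_event_per_beat(self, wt_clean_bundle):
        events = detect_beats(wt_clean_bundle)
        truth = wt_clean_bundle.truth.table
        fs = wt_clean_bundle.sampling_rate
        assert len(events) == len(truth)
        m = events.merge(truth, on="electrode_id", suffixes=("", "_t"))
        m = m[m.beat_index == m.beat_index_t]
        assert len(m) == len(truth)
        assert ((m.t_spike_s - m.t_activation_s).abs() * fs <= 1.0 + 1e-9).all()

    def test_all_zero_trace_gives_no_events(self):
        b = _bundle_from(np.zeros((8000, 2)))
        assert detect_beats(b).empty

    def test_two_beats_interval_recovered(self):
        cfg = preset_config("wt", sampling_rate=2000.0, duration=2.5,
                            noise_sd=0.0, cycle_length_cov=0.0, seed=0)
        b = simulate_recording(cfg)
        ev = detect_beats(b)
        one = ev[ev.electrode_id == "E00"].sort_values("t_spike_s")
        assert len(one) == 2
        dt = np.diff(one.t_spike_s.values)[0]
        assert dt == pytest.approx(1.0, abs=1.0 / cfg.sampling_rate)

    def test_low_sampling_rate_unsupported(self):
        b = _bundle_from(np.zeros((4000, 1)), fs=500.0)
        with pytest.raises(UnsupportedInputError):
            detect_beats(b)


class TestSlope:
    def test_linear_ramp_is_exact(self):
        fs = 2000.0
        t = np.arange(2000) / fs
        x = -0.1 * 1000.0 * t          # -0.1 V/s in mV
        assert measure_slope(x, fs, 100, 1900) == pytest.approx(-0.1, rel=1e-9)

    def test_flat_baseline_is_zero(self):
        assert measure_slope(np.zeros(4000), 2000.0, 10, 3000) == 0.0

    def test_synthetic_spike_within_one_percent(self):
        cfg = preset_config("wt", duration=3.0, noise_sd=0.0, seed=1)  # 12.5 kHz
        b = simulate_recording(cfg)
        ev = detect_beats(b)
        assert (np.abs(ev.slope_v_per_s - cfg.target_max_slope)
                / abs(cfg.target_max_slope) < 0.01).all()

    def test_window_outside_trace_rejected(self):
        with pytest.raises(InvalidWindowError):
            measure_slope(np.zeros(100), 2000.0, 50, 200)


class TestFpd:
    def test_recovery_against_truth(self, wt_clean_bundle, wt_clean_features):
        truth = wt_clean_bundle.truth.table
        fs = wt_clean_bundle.sampling_rate
        m = wt_clean_features.merge(truth, on=["beat_index", "electrode_id"],
                                    suffixes=("", "_t"))
        err_samples = (m.fpd_ms - m.fpd_ms_t).abs() * fs / 1000.0
        assert (err_samples <= 1.0 + 1e-9).all()

    @pytest.mark.parametrize("preset,fpd", [("wt", 281.0), ("r403q", 318.0)])
    def test_preset_mean_fpd_recovered(self, preset, fpd):
        cfg = preset_config(preset, sampling_rate=2000.0, duration=6.0,
                            noise_sd=0.0, fpd_spatial_sd=0.0,
                            ectopic_probability=0.0, seed=3)
        b = simulate_recording(cfg)
        feats = assemble_feature_table([b])
        assert feats.fpd_ms.dropna().values == pytest.approx(
            fpd, abs=1000.0 / cfg.sampling_rate)

    def test_absent_twave_is_flagged_not_raised(self):
        cfg = preset_config("wt", sampling_rate=2000.0, duration=6.0,
                            noise_sd=0.0, twave_amplitude=0.0, seed=3)
        feats = assemble_feature_table([simulate_recording(cfg)])
        assert feats.fpd_ms.isna().all()
        assert feats.t_spike_s.notna().all()   # spikes still measured

    def test_window_before_spike_rejected(self):
        with pytest.raises(InvalidWindowError):
            measure_fpd(np.zeros(4000), 2000.0, t_spike=1.0, window=(0.5, 1.5))


class TestClustering:
    def test_one_cluster_per_true_beat(self, wt_clean_bundle):
        ev = detect_beats(wt_clean_bundle)
        beat_times, _ = cluster_well_beats(ev, 100.0)
        assert beat_times.size == wt_clean_bundle.truth.beat_times.size

    def test_single_electrode_identity(self):
        ev = pd.DataFrame({"electrode_id": ["E00"] * 3, "beat_index": range(3),
                           "t_spike_s": [0.5, 1.5, 2.5],
                           "slope_v_per_s": [-0.1] * 3, "amplitude_mv": [1.0] * 3})
        beat_times, labelled = cluster_well_beats(ev, 100.0)
        assert beat_times.tolist() == [0.5, 1.5, 2.5]
        assert labelled.well_beat.tolist() == [0, 1, 2]

    def test_pathological_window_rejected(self):
        from meafp.errors import ClusteringError
        ev = pd.DataFrame({"electrode_id": ["E00"] * 4, "beat_index": range(4),
                           "t_spike_s": [0.5, 1.5, 2.5, 3.5],
                           "slope_v_per_s": [-0.1] * 4, "amplitude_mv": [1.0] * 4})
        with pytest.raises(ClusteringError):
            cluster_well_beats(ev, window_ms=1500.0)


class TestFridericia:
    @pytest.mark.parametrize("fpd,cl,expect", [
        (300.0, 1.0, 300.0),       # identity at CL = 1 s
        (300.0, 0.512, 375.0),     # 0.512^(1/3) = 0.8
        (240.0, 8.0, 120.0),       # 8^(1/3) = 2
    ])
    def test_closed_form(self, fpd, cl, expect):
        assert fridericia_correct(fpd, cl) == pytest.approx(expect, abs=1e-9)

    @given(fpd=st.floats(1.0, 1000.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_identity_at_unit_cycle_length(self, fpd):
        assert fridericia_correct(fpd, 1.0) == fpd

    @given(fpd=st.floats(50.0, 600.0),
           cl1=st.floats(0.2, 5.0), cl2=st.floats(0.2, 5.0))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_strictly_decreasing_in_cycle_length(self, fpd, cl1, cl2):
        if abs(cl1 - cl2) < 1e-6:
            return
        lo, hi = sorted([cl1, cl2])
        assert fridericia_correct(fpd, lo) > fridericia_correct(fpd, hi)

    @pytest.mark.parametrize("fpd,cl", [(0.0, 1.0), (300.0, 0.0), (-5.0, 1.0)])
    def test_non_positive_inputs_rejected(self, fpd, cl):
        with pytest.raises(InvalidArgumentError):
            fridericia_correct(fpd, cl)


class TestAssemble:
    def test_counting_rule_first_beat_lacks_rate_correction(self):
        cfg = preset_config("wt", sampling_rate=2000.0, duration=11.0,
                            noise_sd=0.0, cycle_length_cov=0.0, seed=0)
        b = simulate_recording(cfg)
        feats = assemble_feature_table([b])
        n_beats = b.truth.beat_times.size
        assert len(feats) == n_beats * 16
        assert feats.fpdc_ms.notna().sum() == (n_beats - 1) * 16
        assert feats[feats.beat_index == 0].cl_s.isna().all()

    def test_empty_input_gives_empty_table_with_schema(self):
        from meafp.features import FEATURE_COLUMNS
        out = assemble_feature_table([])
        assert out.empty and list(out.columns) == FEATURE_COLUMNS

    def test_missing_metadata_rejected(self, wt_clean_bundle):
        broken = RecordingBundle(signals=wt_clean_bundle.signals,
                                 sampling_rate=wt_clean_bundle.sampling_rate,
                                 layout=wt_clean_bundle.layout,
                                 metadata={"well_id": "w"})
        with pytest.raises(SchemaError):
            assemble_feature_table([broken])

    def test_mean_fpd_recovered_within_1ms(self, wt_clean_bundle,
                                           wt_clean_features):
        truth_mean = wt_clean_bundle.truth.table.fpd_ms.mean()
        assert wt_clean_features.fpd_ms.mean() == pytest.approx(truth_mean, abs=1.0)

    def test_measurement_unbiased_at_default_noise(self):
        """With the default noise floor, well-mean slope and FPD remain
        unbiased (within 3 SE across wells) relative to ground truth."""
        d_slope, d_fpd = [], []
        for seed in range(20):
            cfg = preset_config("wt", duration=6.0, seed=seed)  # 12.5 kHz, default noise
            b = simulate_recording(cfg)
            f = assemble_feature_table([b])
            tr = b.truth.table
            d_slope.append(f.slope_v_per_s.mean() - tr.slope_v_per_s.mean())
            d_fpd.append(f.fpd_ms.mean() - tr.fpd_ms.mean())
        for d, tol_floor in ((np.asarray(d_slope), 0.14 * 0.015),
                             (np.asarray(d_fpd), 0.3)):
            se = d.std(ddof=1) / np.sqrt(d.size)
            # small allowance for derivative-filter attenuation and the
            # extremum bias of min-of-derivative under noise
            assert abs(d.mean()) < 3 * se + tol_floor
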