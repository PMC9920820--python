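"""AMPT decision-logic tests: update rules, classification, search-back,
localisation, and whole-detector properties (determinism, causality,
scale invariance, refractory spacing, threshold relations)."""

from collections import deque

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ampt
from ampt.ampt import (
    AMPTConfig,
    DetectorState,
    PeakEvent,
    candidate_peaks,
    local_maxima,
    qrs_slope,
)
from tests.conftest import detection_metrics


class TestUpdateRules:
    def test_fixed_point(self):
        assert ampt.update_signal_peak(3.0, 3.0) == 3.0
        assert ampt.update_noise_peak(0.5, 0.5) == 0.5

    def test_direct_arithmetic(self):
        assert ampt.update_signal_peak(0.0, 8.0) == pytest.approx(1.0)
        assert ampt.update_noise_peak(4.0, 0.0) == pytest.approx(3.5)

    def test_signal_noise_rules_symmetric(self):
        assert ampt.update_signal_peak(2.0, 5.0) == ampt.update_noise_peak(2.0, 5.0)

    def test_geometric_convergence(self):
        spkf, p = 0.0, 11.0
        for k in range(120):
            spkf = ampt.update_signal_peak(spkf, p)
            # closed form: residual decays exactly as 0.875^k
            assert abs(spkf - p) == pytest.approx(0.875 ** (k + 1) * p,
                                                  rel=1e-9)
        assert abs(spkf - p) < 1e-6 * p

    def test_negative_levels_rejected(self):
        with pytest.raises(ValueError):
            ampt.update_signal_peak(-1.0, 2.0)


class TestThresholds:
    @pytest.mark.parametrize("spkf,npkf,f1,f2", [
        (8.0, 0.0, 2.0, 0.5),
        (10.0, 2.0, 4.0, 1.0),
        (3.0, 3.0, 3.0, 0.75),
    ])
    def test_examples(self, spkf, npkf, f1, f2):
        got1, got2 = ampt.compute_thresholds(spkf, npkf)
        assert got1 == pytest.approx(f1) and got2 == pytest.approx(f2)

    @given(st.floats(0, 1e6), st.floats(0, 1e6))
    def test_sandwich_and_quarter_relation(self, spkf, npkf):
        f1, f2 = ampt.compute_thresholds(spkf, npkf)
        assert f2 == 0.25 * f1
        if spkf >= npkf:
            assert npkf <= f1 <= spkf


class TestRRAverage:
    def test_constant_buffer(self):
        stats = ampt.update_rr_average([160] * 8)
        assert stats.rr_average1 == 160
        assert stats.rr_missed_limit == pytest.approx(265.6)

    def test_eight_interval_mean(self):
        stats = ampt.update_rr_average([100, 120, 140, 160, 180, 200, 220, 240])
        assert stats.rr_average1 == pytest.approx(170.0)  # 0.125 * 1360

    def test_partial_buffer_mean(self):
        assert ampt.update_rr_average([200]).rr_average1 == 200

    def test_empty_buffer_rejected(self):
        with pytest.raises(ValueError):
            ampt.update_rr_average([])

    def test_missed_limit_ratio_exact(self):
        stats = ampt.update_rr_average([123, 171, 150])
        assert stats.rr_missed_limit / stats.rr_average1 == pytest.approx(1.66)


def _state(spkf=8.0, npkf=0.0, last_qrs=None, slope=None, rr=()):
    f1, f2 = ampt.compute_thresholds(spkf, npkf)
    return DetectorState(spkf=spkf, npkf=npkf, threshold_f1=f1,
                         threshold_f2=f2, rr_buffer=deque(rr, maxlen=8),
                         last_qrs_index=last_qrs, last_qrs_slope=slope)


class TestClassifyPeak:
    FS = 200.0

    def test_tall_peak_outside_t_zone_is_signal(self):
        st_ = _state(last_qrs=0, slope=1.0)
        ev = PeakEvent(index=120, peakf=2 * st_.threshold_f1)  # 600 ms later
        assert ampt.classify_peak(ev, st_, self.FS) == "signal"

    def test_low_slope_peak_in_t_zone_is_twave(self):
        deriv = np.zeros(400)
        deriv[0:10] = 1.0    # previous QRS slope region
        deriv[55:65] = 0.3   # candidate slope region (~0.3x)
        st_ = _state(last_qrs=0, slope=1.0)
        ev = PeakEvent(index=60, peakf=1.1 * st_.threshold_f1)  # 300 ms later
        label = ampt.classify_peak(ev, st_, self.FS, derivative=deriv,
                                   integration_delay=0.0)
        assert label == "twave"

    def test_subthreshold_peak_is_noise(self):
        st_ = _state(last_qrs=0, slope=1.0)
        ev = PeakEvent(index=120, peakf=0.5 * st_.threshold_f1)
        assert ampt.classify_peak(ev, st_, self.FS) == "noise"

    def test_refractory_peak_is_noise(self):
        st_ = _state(last_qrs=100, slope=1.0)
        ev = PeakEvent(index=120, peakf=10 * st_.threshold_f1)  # 100 ms later
        assert ampt.classify_peak(ev, st_, self.FS) == "noise"


class TestSearchBack:
    FS = 200.0

    def _integrated(self, peaks):
        x = np.zeros(800)
        for idx, h in peaks:
            x[idx - 2:idx + 3] = [0.3 * h, 0.8 * h, h, 0.8 * h, 0.3 * h]
        return x

    def test_peak_between_f2_and_f1_returned(self):
        st_ = _state(spkf=8.0, npkf=0.0)  # f1=2, f2=0.5
        x = self._integrated([(400, 1.0)])
        ev = ampt.search_back(st_, x, (100, 700), self.FS)
        assert ev is not None and ev.index == 400

    def test_all_below_f2_returns_none(self):
        st_ = _state(spkf=8.0, npkf=0.0)
        x = self._integrated([(400, 0.3)])
        assert ampt.search_back(st_, x, (100, 700), self.FS) is None

    def test_taller_candidate_wins(self):
        st_ = _state(spkf=8.0, npkf=0.0)
        for order in [[(300, 0.9), (500, 1.4)], [(300, 1.4), (500, 0.9)]]:
            x = self._integrated(order)
            ev = ampt.search_back(st_, x, (100, 700), self.FS)
            tallest = max(order, key=lambda p: p[1])[0]
            assert ev.index == tallest

    def test_equal_heights_tie_to_earlier(self):
        st_ = _state(spkf=8.0, npkf=0.0)
        x = self._integrated([(300, 1.0), (500, 1.0)])
        assert ampt.search_back(st_, x, (100, 700), self.FS).index == 300

    def test_refractory_zone_excluded(self):
        st_ = _state(spkf=8.0, npkf=0.0)
        x = self._integrated([(120, 1.0)])  # 20 samples = 100 ms after window start
        assert ampt.search_back(st_, x, (100, 700), self.FS) is None


class TestPeakCandidates:
    def test_plateau_takes_first_sample(self):
        assert list(local_maxima(np.array([0, 1, 1, 1, 0.0]))) == [1]

    def test_strict_maxima(self):
        x = np.array([0, 2, 0, 3, 0, 1, 0.0])
        assert list(local_maxima(x)) == [1, 3, 5]

    def test_thinning_keeps_tallest_within_distance(self):
        x = np.zeros(100)
        x[30], x[40] = 1.0, 2.0
        x[80] = 0.5
        assert list(candidate_peaks(x, 40)) == [40, 80]

    @given(st.lists(st.floats(0, 100), min_size=10, max_size=60))
    def test_maxima_are_strictly_increasing_and_local(self, vals):
        x = np.asarray(vals)
        peaks = local_maxima(x)
        assert np.all(np.diff(peaks) > 0)
        for p in peaks:
            assert x[p] > x[p - 1]


class TestDetect:
    def test_zero_signal_no_detections(self):
        pr = ampt.preprocess(ampt.ECGRecord(np.zeros(4000), 200.0))
        assert len(ampt.detect(pr).r_peaks) == 0

    def test_clean_60bpm_counts_and_accuracy(self, clean_sinus,
                                             clean_sinus_processed):
        res = ampt.detect(clean_sinus_processed)
        truth = clean_sinus.truth_r_peaks
        # the 2 s learning phase forfeits the first beats, nothing else
        assert len(truth) - 3 <= len(res.r_peaks) <= len(truth)
        m = ampt.match_beats(res.r_peaks, truth, 200.0)
        assert m.fp == 0
        for a, d in m.pairs:
            assert abs(d - a) <= 0.150 * 200

    def test_short_record_warns_and_is_empty(self):
        pr = ampt.preprocess(ampt.ECGRecord(np.zeros(300), 200.0))
        with pytest.warns(UserWarning):
            res = ampt.detect(pr)
        assert len(res.r_peaks) == 0

    def test_searchback_recovers_attenuated_beats(self):
        cfg = ampt.SimConfig(fs=200, duration_s=300, mean_hr_bpm=75,
                             rr_process="gaussian", rr_sd_s=0.02,
                             attenuate_every=10, attenuate_factor=0.3, seed=3)
        truth = ampt.degrade(ampt.generate(cfg), 25)
        pr = ampt.preprocess(truth.record)
        _, sens_on, _ = detection_metrics(
            ampt.detect(pr, config=AMPTConfig(searchback_enabled=True)),
            truth, 200.0)
        _, sens_off, _ = detection_metrics(
            ampt.detect(pr, config=AMPTConfig(searchback_enabled=False)),
            truth, 200.0)
        assert sens_on >= 98.0
        assert sens_on - sens_off >= 5.0

    def test_determinism(self, noisy_sinus_processed):
        a = ampt.detect(noisy_sinus_processed)
        b = ampt.detect(noisy_sinus_processed)
        assert np.array_equal(a.r_peaks, b.r_peaks)
        assert a.op_counts == b.op_counts

    def test_scale_invariance(self, noisy_sinus):
        pr1 = ampt.preprocess(noisy_sinus.record)
        scaled = ampt.ECGRecord(noisy_sinus.record.samples * 37.5, 200.0)
        pr2 = ampt.preprocess(scaled)
        assert np.array_equal(ampt.detect(pr1).r_peaks, ampt.detect(pr2).r_peaks)

    def test_causality_under_truncation(self, clean_sinus):
        full = ampt.detect(ampt.preprocess(clean_sinus.record)).r_peaks
        k = len(clean_sinus.record.samples) // 2
        trunc_rec = ampt.ECGRecord(clean_sinus.record.samples[:k], 200.0)
        trunc = ampt.detect(ampt.preprocess(trunc_rec)).r_peaks
        margin = k - 200  # one second before the cut
        assert np.array_equal(full[full < margin], trunc[trunc < margin])

    def test_refractory_spacing(self, noisy_sinus_processed):
        res = ampt.detect(noisy_sinus_processed)
        assert np.all(np.diff(res.r_peaks) >= 0.2 * 200)

    def test_threshold_trace_invariants(self, noisy_sinus_processed):
        trace = []
        ampt.detect(noisy_sinus_processed, trace=trace)
        assert len(trace) > 100
        for st_ in trace:
            assert st_.threshold_f2 == 0.25 * st_.threshold_f1
            if st_.spkf >= st_.npkf:
                assert st_.npkf <= st_.threshold_f1 <= st_.spkf
            assert len(st_.rr_buffer) <= 8


class TestMapToRaw:
    def test_clean_beat_maps_to_apex(self, clean_sinus, clean_sinus_processed):
        res = ampt.detect(clean_sinus_processed)
        m = ampt.match_beats(res.r_peaks, clean_sinus.truth_r_peaks, 200.0)
        for a, d in m.pairs:
            assert abs(d - a) <= 1

    def test_near_start_is_clipped(self):
        bp = np.random.default_rng(0).normal(size=100)
        delays = {"lowpass": 6.0, "highpass": 16.0, "derivative": 2.0,
                  "integration": 14.5}
        out = ampt.map_peak_to_raw(3, delays, bp, 200.0)
        assert 0 <= out < 100

    def test_refinement_stays_within_window(self, clean_sinus_processed):
        pr = clean_sinus_processed
        res = ampt.detect(pr)
        from ampt.ampt import BANDPASS_REFINE_DELAY
        from ampt.filters import DERIVATIVE_DELAY
        margin = round(0.025 * 200)
        for ip, rp in zip(res.integrated_peaks, res.r_peaks):
            center_raw = ip - DERIVATIVE_DELAY - BANDPASS_REFINE_DELAY
            assert center_raw - pr.window_samples - margin <= rp <= center_raw + margin


def test_op_counter_categories_all_exercised(noisy_sinus_processed):
    res = ampt.detect(noisy_sinus_processed)
    assert res.op_counts["peak_update"] > 0
    assert res.op_counts["threshold"] > 0
    assert res.op_counts["rr_update"] > 0
    assert res.op_counts["compare"] > 0
    assert res.total_ops == sum(res.op_counts.values())


def test_qrs_slope_measures_local_derivative_extreme():
    deriv = np.zeros(200)
    deriv[100] = -3.0
    assert qrs_slope(deriv, 110, 10.0, 15) == 3.0
    assert qrs_slope(deriv, 5, 0.0, 3) == 0.0
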