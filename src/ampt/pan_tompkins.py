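"""Faithful original Pan-Tompkins QRS detector (the comparison baseline).

Differences from the simplified AMPT detector in :mod:`ampt.ampt`:

* **Dual-signal analysis.**  Adaptive signal/noise estimates and threshold
  pairs are kept for *both* the moving-window-integrated signal (SPKI/NPKI,
  THRESHOLD I1/I2) and the band-passed signal (SPKF/NPKF, THRESHOLD F1/F2).
  A QRS is accepted only when the integrated-track peak and the
  corresponding band-passed peak (within one integration-window length)
  both exceed their first thresholds.
* **Dual RR averages.**  RR AVERAGE1 is the mean of the last eight RR
  intervals; RR AVERAGE2 averages the last eight intervals that fell within
  the 92%-116% band of RR AVERAGE2 itself.  The missed-beat limit is
  166% of RR AVERAGE2, and an out-of-band interval (irregular rhythm)
  halves the first thresholds to regain sensitivity.
* **Search-back coefficients.**  A beat recovered by search-back updates
  the signal estimates with 0.25/0.75 (the normal path uses 0.125/0.875),
  and the second thresholds are half - not a quarter - of the first.

The T-wave slope discrimination, 200 ms refractory period, learning-phase
initialisation and raw-coordinate localisation are shared with AMPT.

:func:`simplified_config` produces the configuration in which every one of
these extra mechanisms is switched off; the detector then reduces exactly
to the AMPT decision logic, which is verified as a program-equivalence test.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
import warnings

import numpy as np

from .filters import DERIVATIVE_DELAY, ProcessedSignal
from .ampt import (
    DetectionResult,
    OpCounter,
    _map_all,
    candidate_peaks,
    compute_thresholds,
    qrs_slope,
    update_noise_peak,
    update_rr_average,
    update_signal_peak,
)


@dataclass(frozen=True)
class PTConfig:
    """Constants of the original detector; see :class:`ampt.ampt.AMPTConfig`."""

    refractory_s: float = 0.200
    twave_window_s: float = 0.360
    twave_slope_ratio: float = 0.5
    learn_s: float = 2.0
    transient_s: float = 0.5
    threshold1_frac: float = 0.25
    threshold2_frac: float = 0.5
    peak_update: tuple[float, float] = (0.125, 0.875)
    searchback_update: tuple[float, float] = (0.25, 0.75)
    missed_factor: float = 1.66
    rr_buffer_len: int = 8
    searchback_min_rr: int = 2
    rr_low_frac: float = 0.92
    rr_high_frac: float = 1.16
    slope_halfwindow_s: float = 0.075
    twave_rule_enabled: bool = True
    searchback_enabled: bool = True
    dual_signal: bool = True
    dual_rr: bool = True
    irregular_halving: bool = True


def simplified_config() -> PTConfig:
    """The test hook of the structural-equivalence check.

    Short-circuits the band-passed-signal analysis, collapses the RR
    bookkeeping to the single buffer-1 average (no 92-116% band, no
    threshold halving), and sets the modified coefficients (search-back
    update 0.125/0.875, second threshold = 0.25 of the first).  With these
    switches the baseline implements exactly the AMPT decision logic.
    """
    return PTConfig(
        dual_signal=False,
        dual_rr=False,
        irregular_halving=False,
        threshold2_frac=0.25,
        searchback_update=(0.125, 0.875),
    )


@dataclass
class PTState:
    """Running adaptive state: both threshold sets and both RR buffers."""

    spki: float = 0.0
    npki: float = 0.0
    threshold_i1: float = 0.0
    threshold_i2: float = 0.0
    spkf: float = 0.0
    npkf: float = 0.0
    threshold_f1: float = 0.0
    threshold_f2: float = 0.0
    rr_buffer_1: deque = field(default_factory=lambda: deque(maxlen=8))
    rr_buffer_2: deque = field(default_factory=lambda: deque(maxlen=8))
    last_qrs_index: int | None = None
    last_qrs_slope: float | None = None


def _bandpassed_peak(bp: np.ndarray, integrated_index: int,
                     integration_delay: float, halfwidth: int) -> float:
    """Height of the band-passed peak corresponding to an integrated-track peak.

    Correspondence is 'on a time basis': the maximal absolute band-passed
    amplitude within one integration-window length of the delay-corrected
    location.
    """
    c = int(round(integrated_index - integration_delay - DERIVATIVE_DELAY))
    lo = max(0, c - halfwidth)
    hi = min(len(bp), c + halfwidth + 1)
    if lo >= hi:
        return 0.0
    return float(np.max(np.abs(bp[lo:hi])))


def detect_pt(processed: ProcessedSignal, fs: float | None = None,
              config: PTConfig = PTConfig(), record_id: str = "") -> DetectionResult:
    """Run the original Pan-Tompkins state machine over a preprocessed record."""
    fs = processed.fs if fs is None else fs
    integrated = processed.integrated
    bp = processed.bandpassed
    deriv = processed.derivative
    ops = OpCounter()
    learn_end = int(round(config.learn_s * fs))
    if len(integrated) <= learn_end:
        warnings.warn(
            f"record {record_id!r} shorter than the {config.learn_s} s "
            "learning phase; no detections produced"
        )
        return DetectionResult(record_id, "PanTompkins", np.array([], dtype=int),
                               np.array([], dtype=int), fs, ops.counts)

    int_delay = processed.stage_delays["integration"]
    slope_hw = int(round(config.slope_halfwindow_s * fs))
    refractory = int(round(config.refractory_s * fs))
    twave_win = int(round(config.twave_window_s * fs))
    bp_halfwidth = processed.window_samples

    # learning-phase initialisation, integrated side identical to AMPT's
    lo0 = int(round(config.transient_s * fs))
    seg_i = integrated[lo0:learn_end]
    state = PTState(
        rr_buffer_1=deque(maxlen=config.rr_buffer_len),
        rr_buffer_2=deque(maxlen=config.rr_buffer_len),
    )
    state.spki = 0.25 * float(np.max(seg_i))
    state.npki = 0.5 * float(np.mean(seg_i))
    state.threshold_i1, state.threshold_i2 = compute_thresholds(
        state.spki, state.npki, config.threshold1_frac, config.threshold2_frac)
    ops.tick("threshold")
    if config.dual_signal:
        seg_f = np.abs(bp[lo0:learn_end])
        state.spkf = 0.25 * float(np.max(seg_f))
        state.npkf = 0.5 * float(np.mean(seg_f))
        state.threshold_f1, state.threshold_f2 = compute_thresholds(
            state.spkf, state.npkf, config.threshold1_frac, config.threshold2_frac)
        ops.tick("threshold")

    accepted: list[int] = []

    def recompute_thresholds() -> None:
        state.threshold_i1, state.threshold_i2 = compute_thresholds(
            state.spki, state.npki, config.threshold1_frac, config.threshold2_frac)
        ops.tick("threshold")
        if config.dual_signal:
            state.threshold_f1, state.threshold_f2 = compute_thresholds(
                state.spkf, state.npkf, config.threshold1_frac, config.threshold2_frac)
            ops.tick("threshold")

    def rr_bookkeeping(rr: int) -> None:
        state.rr_buffer_1.append(rr)
        ops.tick("rr_update")
        if not config.dual_rr:
            return
        ops.tick("rr_update")
        if len(state.rr_buffer_2) == 0:
            state.rr_buffer_2.append(rr)
            return
        avg2 = update_rr_average(state.rr_buffer_2, config.missed_factor).rr_average1
        ops.tick("compare", 2)
        if config.rr_low_frac * avg2 <= rr <= config.rr_high_frac * avg2:
            state.rr_buffer_2.append(rr)
        elif config.irregular_halving:
            # irregular rhythm: halve the first thresholds to regain sensitivity
            state.threshold_i1 *= 0.5
            state.threshold_i2 = config.threshold2_frac * state.threshold_i1
            if config.dual_signal:
                state.threshold_f1 *= 0.5
                state.threshold_f2 = config.threshold2_frac * state.threshold_f1
            ops.tick("threshold")

    def accept(idx: int, peaki: float, peakf: float, via_searchback: bool) -> None:
        coeffs = config.searchback_update if via_searchback else config.peak_update
        state.spki = update_signal_peak(state.spki, peaki, coeffs)
        ops.tick("peak_update")
        if config.dual_signal:
            state.spkf = update_signal_peak(state.spkf, peakf, coeffs)
            ops.tick("peak_update")
        recompute_thresholds()
        if state.last_qrs_index is not None:
            rr_bookkeeping(idx - state.last_qrs_index)
        state.last_qrs_index = idx
        state.last_qrs_slope = qrs_slope(deriv, idx, int_delay, slope_hw)
        accepted.append(idx)

    def reject(peaki: float, peakf: float) -> None:
        state.npki = update_noise_peak(state.npki, peaki, config.peak_update)
        ops.tick("peak_update")
        if config.dual_signal:
            state.npkf = update_noise_peak(state.npkf, peakf, config.peak_update)
            ops.tick("peak_update")
        recompute_thresholds()

    def missed_limit():
        buf = state.rr_buffer_2 if config.dual_rr else state.rr_buffer_1
        if len(state.rr_buffer_1) < config.searchback_min_rr or len(buf) == 0:
            return None
        return update_rr_average(buf, config.missed_factor).rr_missed_limit

    def is_twave(idx: int, since: int) -> bool:
        if not (config.twave_rule_enabled and state.last_qrs_slope is not None
                and since < twave_win):
            return False
        ops.tick("compare")
        slope = qrs_slope(deriv, idx, int_delay, slope_hw)
        return slope < config.twave_slope_ratio * state.last_qrs_slope

    def maybe_search_back(current: int) -> None:
        if not config.searchback_enabled:
            return
        while state.last_qrs_index is not None:
            ops.tick("compare")
            limit = missed_limit()
            if limit is None or current - state.last_qrs_index <= limit:
                break
            lo = state.last_qrs_index
            cands = peaks[(peaks > lo) & (peaks < current)]
            best = None
            best_h = -np.inf
            for idx in cands:
                if idx <= lo or idx - lo < refractory:
                    continue
                h = float(integrated[idx])
                ops.tick("searchback")
                if h <= state.threshold_i2:
                    continue
                if config.dual_signal:
                    pf = _bandpassed_peak(bp, idx, int_delay, bp_halfwidth)
                    ops.tick("searchback")
                    if pf <= state.threshold_f2:
                        continue
                else:
                    pf = 0.0
                if is_twave(int(idx), int(idx) - lo):
                    continue
                if h > best_h:
                    best, best_h = (int(idx), pf), h
            if best is None:
                break
            accept(best[0], best_h, best[1], via_searchback=True)

    peaks = candidate_peaks(integrated, refractory)
    for idx in peaks[peaks >= learn_end]:
        idx = int(idx)
        maybe_search_back(idx)
        peaki = float(integrated[idx])
        peakf = _bandpassed_peak(bp, idx, int_delay, bp_halfwidth) \
            if config.dual_signal else 0.0
        ops.tick("compare")
        if state.last_qrs_index is not None and idx - state.last_qrs_index < refractory:
            reject(peaki, peakf)
            continue
        ops.tick("compare")
        if peaki > state.threshold_i1:
            if is_twave(idx, idx - (state.last_qrs_index if state.last_qrs_index
                                    is not None else -twave_win)):
                reject(peaki, peakf)
                continue
            if config.dual_signal:
                ops.tick("compare")
                if peakf <= state.threshold_f1:
                    reject(peaki, peakf)  # no time-coincident band-passed peak
                    continue
            accept(idx, peaki, peakf, via_searchback=False)
        else:
            reject(peaki, peakf)
    maybe_search_back(len(integrated))

    r_peaks = _map_all(accepted, processed, fs)
    return DetectionResult(record_id, "PanTompkins", r_peaks,
                           np.asarray(accepted, dtype=int), fs, ops.counts)
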