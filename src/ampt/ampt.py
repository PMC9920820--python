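"""AMPT: a simplified Pan-Tompkins QRS detector for real-time use.

The detector analyses only the final moving-window-integrated signal (the
original Pan-Tompkins runs a parallel analysis on the band-passed signal as
well) and keeps a single running RR average for missed-beat search-back
(the original keeps two, one restricted to regular rhythm).  The adaptive
state is:

    SPKF = 0.125 PEAKF + 0.875 SPKF            (signal-peak estimate)
    NPKF = 0.125 PEAKF + 0.875 NPKF            (noise-peak estimate)
    THRESHOLD F1 = NPKF + 0.25 (SPKF - NPKF)
    THRESHOLD F2 = 0.25 THRESHOLD F1

A QRS recovered by search-back updates SPKF with the same 0.125/0.875
rule.  The average of the eight most recent RR intervals defines
RR MISSED LIMIT = 1.66 * RR AVERAGE1; when the gap since the last accepted
QRS exceeds it, the interval is re-examined against the lower THRESHOLD F2.
The 200 ms refractory period and the T-wave slope test (a candidate within
360 ms of the previous QRS whose maximal slope is below half that QRS's
slope is a T wave) are retained from the original method.

The detector is a causal, deterministic state machine: no randomness, and
thresholds are relative so detections are invariant to positive rescaling
of the input.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
import warnings

import numpy as np

from .filters import (
    DERIVATIVE_DELAY,
    HIGHPASS_DELAY,
    LOWPASS_DELAY,
    ProcessedSignal,
)

# Exact group delay of the band-pass cascade used when refining a detection
# back to raw coordinates: the low-pass is FIR-equivalent to an 11-tap
# symmetric kernel (delay 5) and the high-pass is dominated by its 16-sample
# all-pass path.
BANDPASS_REFINE_DELAY = 5 + HIGHPASS_DELAY


@dataclass(frozen=True)
class AMPTConfig:
    """Tunable constants of the AMPT decision logic.

    Durations are in seconds and scaled by the sampling rate at run time.
    ``twave_rule_enabled`` and ``searchback_enabled`` are test hooks that
    switch off the corresponding rule wholesale.
    """

    refractory_s: float = 0.200
    twave_window_s: float = 0.360
    twave_slope_ratio: float = 0.5
    learn_s: float = 2.0
    transient_s: float = 0.5
    threshold1_frac: float = 0.25
    threshold2_frac: float = 0.25
    peak_update: tuple[float, float] = (0.125, 0.875)
    searchback_update: tuple[float, float] = (0.125, 0.875)
    missed_factor: float = 1.66
    rr_buffer_len: int = 8
    searchback_min_rr: int = 2
    slope_halfwindow_s: float = 0.075
    twave_rule_enabled: bool = True
    searchback_enabled: bool = True


@dataclass
class RRStats:
    """Single averaged RR interval and the derived missed-beat limit."""

    rr_average1: float
    rr_missed_limit: float


@dataclass
class PeakEvent:
    """A candidate local maximum of the integrated signal."""

    index: int
    peakf: float
    classified_as: str | None = None  # {"signal", "noise", "twave"}


@dataclass
class DetectorState:
    """Running adaptive state of the detector."""

    spkf: float = 0.0
    npkf: float = 0.0
    threshold_f1: float = 0.0
    threshold_f2: float = 0.0
    rr_buffer: deque = field(default_factory=lambda: deque(maxlen=8))
    last_qrs_index: int | None = None
    last_qrs_slope: float | None = None


@dataclass
class DetectionResult:
    """Detector output: R-peak indices in the raw record's coordinates."""

    record_id: str
    detector_name: str
    r_peaks: np.ndarray
    integrated_peaks: np.ndarray
    fs: float
    op_counts: dict[str, int]

    @property
    def total_ops(self) -> int:
        return sum(self.op_counts.values())


class OpCounter:
    """Tally of state-update and comparison operations.

    A hardware-independent proxy for computational cost: every adaptive
    update (SPK/NPK), threshold recomputation, RR-buffer update, and
    decision comparison increments a category.
    """

    CATEGORIES = ("peak_update", "threshold", "rr_update", "compare", "searchback")

    def __init__(self) -> None:
        self.counts = dict.fromkeys(self.CATEGORIES, 0)

    def tick(self, category: str, n: int = 1) -> None:
        self.counts[category] += n


# ---------------------------------------------------------------------------
# Threshold and RR update rules
# ---------------------------------------------------------------------------

def update_signal_peak(spkf: float, peakf: float,
                       coeffs: tuple[float, float] = (0.125, 0.875)) -> float:
    """SPKF <- 0.125 PEAKF + 0.875 SPKF (same rule in normal and search-back)."""
    if spkf < 0 or peakf < 0:
        raise ValueError("peak levels must be non-negative")
    return coeffs[0] * peakf + coeffs[1] * spkf


def update_noise_peak(npkf: float, peakf: float,
                      coeffs: tuple[float, float] = (0.125, 0.875)) -> float:
    """NPKF <- 0.125 PEAKF + 0.875 NPKF."""
    if npkf < 0 or peakf < 0:
        raise ValueError("peak levels must be non-negative")
    return coeffs[0] * peakf + coeffs[1] * npkf


def compute_thresholds(spkf: float, npkf: float,
                       frac1: float = 0.25,
                       frac2: float = 0.25) -> tuple[float, float]:
    """THRESHOLD F1 = NPKF + 0.25 (SPKF - NPKF); THRESHOLD F2 = 0.25 F1.

    Computed literally even if NPKF has drifted above SPKF; no clamping.
    """
    f1 = npkf + frac1 * (spkf - npkf)
    f2 = frac2 * f1
    return f1, f2


def update_rr_average(rr_buffer, missed_factor: float = 1.66) -> RRStats:
    """RR AVERAGE1 = mean of the up-to-8 most recent RR intervals.

    With a full buffer this is 0.125 times the sum; before eight intervals
    exist the mean of the available ones is used.
    """
    buf = list(rr_buffer)
    if not buf:
        raise ValueError("no RR intervals yet")
    avg = float(np.mean(buf))
    return RRStats(rr_average1=avg, rr_missed_limit=missed_factor * avg)


# ---------------------------------------------------------------------------
# Peak candidates and slope measurement
# ---------------------------------------------------------------------------

def local_maxima(x: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; a flat-topped plateau yields its first sample."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return np.array([], dtype=int)
    d = np.diff(x)
    nz = np.flatnonzero(d)
    if len(nz) == 0:
        return np.array([], dtype=int)
    peaks = []
    prev_sign = 0
    prev_idx = -1
    for i in nz:
        s = 1 if d[i] > 0 else -1
        if prev_sign > 0 and s < 0:
            # rise ended at sample prev_idx + 1 (first sample of any plateau)
            peaks.append(prev_idx + 1)
        prev_sign = s
        prev_idx = i
    return np.asarray(peaks, dtype=int)


def candidate_peaks(x: np.ndarray, distance: int) -> np.ndarray:
    """Local maxima thinned so no two candidates are closer than ``distance``.

    The integrated track of a multi-wave beat carries secondary maxima on
    the flanks of the main hump; feeding those to the noise estimate would
    inflate NPKF far above any genuine noise level.  As in the classic
    fiducial-mark step, only one candidate per hump survives: maxima are
    ranked by height (ties to the earlier index) and a maximum is kept only
    if no taller kept candidate lies within ``distance`` samples.
    """
    peaks = local_maxima(x)
    if len(peaks) == 0 or distance <= 1:
        return peaks
    heights = x[peaks]
    order = np.lexsort((peaks, -heights))
    keep = np.ones(len(peaks), dtype=bool)
    kept: list[int] = []
    import bisect
    for k in order:
        p = int(peaks[k])
        j = bisect.bisect_left(kept, p - distance + 1)
        if j < len(kept) and kept[j] <= p + distance - 1:
            keep[k] = False
        else:
            bisect.insort(kept, p)
    return peaks[keep]


def qrs_slope(derivative: np.ndarray, integrated_index: int,
              integration_delay: float, halfwindow: int) -> float:
    """Maximal absolute derivative-stage value near a peak of the integrated track."""
    c = int(round(integrated_index - integration_delay))
    lo = max(0, c - halfwindow)
    hi = min(len(derivative), c + halfwindow + 1)
    if lo >= hi:
        return 0.0
    return float(np.max(np.abs(derivative[lo:hi])))


def classify_peak(event: PeakEvent, state: DetectorState, fs: float,
                  config: AMPTConfig = AMPTConfig(),
                  derivative: np.ndarray | None = None,
                  integration_delay: float = 0.0,
                  ops: OpCounter | None = None) -> str:
    """Route a candidate peak to {"signal", "noise", "twave"}.

    Order of tests: refractory lockout, first threshold, then the T-wave
    slope discrimination for peaks within 360 ms of the previous QRS.
    """
    if ops is not None:
        ops.tick("compare")
    refractory = int(round(config.refractory_s * fs))
    if state.last_qrs_index is not None and event.index - state.last_qrs_index < refractory:
        return "noise"
    if ops is not None:
        ops.tick("compare")
    if event.peakf > state.threshold_f1:
        if (
            config.twave_rule_enabled
            and state.last_qrs_index is not None
            and state.last_qrs_slope is not None
            and event.index - state.last_qrs_index < int(round(config.twave_window_s * fs))
        ):
            if ops is not None:
                ops.tick("compare")
            slope = qrs_slope(
                derivative, event.index, integration_delay,
                int(round(config.slope_halfwindow_s * fs)),
            ) if derivative is not None else np.inf
            if slope < config.twave_slope_ratio * state.last_qrs_slope:
                return "twave"
        return "signal"
    return "noise"


def search_back(state: DetectorState, integrated: np.ndarray,
                window: tuple[int, int], fs: float,
                config: AMPTConfig = AMPTConfig(),
                derivative: np.ndarray | None = None,
                integration_delay: float = 0.0,
                ops: OpCounter | None = None,
                peaks: np.ndarray | None = None) -> PeakEvent | None:
    """Re-examine (last QRS, current) for a missed beat above THRESHOLD F2.

    Returns the tallest candidate exceeding F2 that passes the refractory
    and T-wave checks (ties broken by the earlier index), or None.  The
    caller applies the Eq-style SPKF update on acceptance.  ``peaks`` is
    the candidate list to draw from (the same refractory-thinned maxima
    the main pass uses); it is recomputed from the window if not supplied.
    """
    lo, hi = window
    refractory = int(round(config.refractory_s * fs))
    twave_win = int(round(config.twave_window_s * fs))
    if peaks is None:
        sub = np.asarray(integrated[max(lo, 0):hi], dtype=float)
        cands = candidate_peaks(sub, refractory) + max(lo, 0)
    else:
        peaks = np.asarray(peaks)
        cands = peaks[(peaks > lo) & (peaks < hi)]
    best: PeakEvent | None = None
    for idx in cands:
        if idx <= lo or idx - lo < refractory:
            continue
        h = float(integrated[idx])
        if ops is not None:
            ops.tick("searchback")
        if h <= state.threshold_f2:
            continue
        if (
            config.twave_rule_enabled
            and state.last_qrs_slope is not None
            and idx - lo < twave_win
            and derivative is not None
        ):
            slope = qrs_slope(
                derivative, idx, integration_delay,
                int(round(config.slope_halfwindow_s * fs)),
            )
            if slope < config.twave_slope_ratio * state.last_qrs_slope:
                continue
        if best is None or h > best.peakf:
            best = PeakEvent(index=int(idx), peakf=h, classified_as="signal")
    return best


def map_peak_to_raw(integrated_index: int, stage_delays: dict[str, float],
                    bandpassed: np.ndarray, fs: float) -> int:
    """Localise an integrated-track detection in raw-signal coordinates.

    The trailing-mean maximum of the integrated track occurs while the QRS
    energy burst still lies inside the window, so the band-passed QRS peak
    sits within one integration window before the derivative-corrected
    integrated index.  The detection is refined to the maximal absolute
    band-passed amplitude over that span (plus a small margin), and the
    band-pass cascade delay subtracted; the result is clipped to the
    record bounds.
    """
    d_int = stage_delays["integration"]
    n_win = int(round(2 * d_int + 1))  # integration window length
    margin = int(round(0.025 * fs))
    center = int(round(integrated_index - stage_delays["derivative"]))
    est_raw = center - BANDPASS_REFINE_DELAY
    lo = max(0, center - n_win - margin)
    hi = min(len(bandpassed), center + margin + 1)
    if lo >= hi:
        return int(np.clip(est_raw, 0, len(bandpassed) - 1))
    refined = lo + int(np.argmax(np.abs(bandpassed[lo:hi])))
    raw = refined - BANDPASS_REFINE_DELAY
    return int(np.clip(raw, 0, len(bandpassed) - 1))


# ---------------------------------------------------------------------------
# Detection state machine
# ---------------------------------------------------------------------------

def _initial_state(integrated: np.ndarray, fs: float,
                   config: AMPTConfig) -> DetectorState:
    """Learning-phase initialisation, scale-free by construction.

    SPKF starts at a quarter of the integrated-signal maximum over the
    learning span and NPKF at half its mean; the first ~0.5 s of filter
    transient is excluded.
    """
    lo = int(round(config.transient_s * fs))
    hi = int(round(config.learn_s * fs))
    seg = integrated[lo:hi]
    spkf = 0.25 * float(np.max(seg))
    npkf = 0.5 * float(np.mean(seg))
    f1, f2 = compute_thresholds(spkf, npkf, config.threshold1_frac,
                                config.threshold2_frac)
    return DetectorState(
        spkf=spkf, npkf=npkf, threshold_f1=f1, threshold_f2=f2,
        rr_buffer=deque(maxlen=config.rr_buffer_len),
    )


def detect(processed: ProcessedSignal, fs: float | None = None,
           config: AMPTConfig = AMPTConfig(), record_id: str = "",
           trace: list | None = None) -> DetectionResult:
    """Run the AMPT state machine over a preprocessed record.

    A single causal pass: candidate peaks are the local maxima of the
    integrated track; each is classified against THRESHOLD F1 (with
    refractory and T-wave rules); accepted peaks update SPKF and the RR
    buffer, rejected ones update NPKF; thresholds are recomputed after
    every update; search-back runs whenever the elapsed gap exceeds
    RR MISSED LIMIT.  Pass ``trace`` (a list) to collect state snapshots
    after every update.
    """
    fs = processed.fs if fs is None else fs
    integrated = processed.integrated
    ops = OpCounter()
    learn_end = int(round(config.learn_s * fs))
    if len(integrated) <= learn_end:
        warnings.warn(
            f"record {record_id!r} shorter than the {config.learn_s} s "
            "learning phase; no detections produced"
        )
        return DetectionResult(record_id, "AMPT", np.array([], dtype=int),
                               np.array([], dtype=int), fs, ops.counts)

    state = _initial_state(integrated, fs, config)
    ops.tick("threshold")
    int_delay = processed.stage_delays["integration"]
    slope_hw = int(round(config.slope_halfwindow_s * fs))
    deriv = processed.derivative

    def snapshot() -> None:
        if trace is not None:
            trace.append(replace(state, rr_buffer=deque(state.rr_buffer,
                                                        maxlen=config.rr_buffer_len)))

    def accept(idx: int, height: float, via_searchback: bool) -> None:
        coeffs = config.searchback_update if via_searchback else config.peak_update
        state.spkf = update_signal_peak(state.spkf, height, coeffs)
        ops.tick("peak_update")
        state.threshold_f1, state.threshold_f2 = compute_thresholds(
            state.spkf, state.npkf, config.threshold1_frac, config.threshold2_frac)
        ops.tick("threshold")
        if state.last_qrs_index is not None:
            state.rr_buffer.append(idx - state.last_qrs_index)
            ops.tick("rr_update")
        state.last_qrs_index = idx
        state.last_qrs_slope = qrs_slope(deriv, idx, int_delay, slope_hw)
        accepted.append(idx)
        snapshot()

    def reject(height: float) -> None:
        state.npkf = update_noise_peak(state.npkf, height, config.peak_update)
        ops.tick("peak_update")
        state.threshold_f1, state.threshold_f2 = compute_thresholds(
            state.spkf, state.npkf, config.threshold1_frac, config.threshold2_frac)
        ops.tick("threshold")
        snapshot()

    def maybe_search_back(current: int) -> None:
        if not config.searchback_enabled:
            return
        while (state.last_qrs_index is not None
               and len(state.rr_buffer) >= config.searchback_min_rr):
            ops.tick("compare")
            stats = update_rr_average(state.rr_buffer, config.missed_factor)
            if current - state.last_qrs_index <= stats.rr_missed_limit:
                break
            found = search_back(
                state, integrated, (state.last_qrs_index, current), fs,
                config, deriv, int_delay, ops, peaks,
            )
            if found is None:
                break
            accept(found.index, found.peakf, via_searchback=True)

    accepted: list[int] = []
    peaks = candidate_peaks(integrated, int(round(config.refractory_s * fs)))
    for idx in peaks[peaks >= learn_end]:
        maybe_search_back(int(idx))
        event = PeakEvent(index=int(idx), peakf=float(integrated[idx]))
        label = classify_peak(event, state, fs, config, deriv, int_delay, ops)
        event.classified_as = label
        if label == "signal":
            accept(event.index, event.peakf, via_searchback=False)
        else:
            reject(event.peakf)
    maybe_search_back(len(integrated))

    r_peaks = _map_all(accepted, processed, fs)
    return DetectionResult(record_id, "AMPT", r_peaks,
                           np.asarray(accepted, dtype=int), fs, ops.counts)


def _map_all(accepted: list[int], processed: ProcessedSignal,
             fs: float) -> np.ndarray:
    """Map integrated-track detections to raw coordinates, keeping them increasing."""
    raw: list[int] = []
    for idx in accepted:
        r = map_peak_to_raw(idx, processed.stage_delays, processed.bandpassed, fs)
        if raw and r <= raw[-1]:
            continue
        raw.append(r)
    return np.asarray(raw, dtype=int)
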