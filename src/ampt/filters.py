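"""Pan-Tompkins signal-conditioning chain.

The classic QRS preprocessing cascade: recursive low-pass and high-pass
filters (designed for a 200 Hz sampling rate, band roughly 5-15 Hz where
QRS energy concentrates), a five-point derivative, pointwise squaring, and
a trailing moving-window integration of ~150 ms.  The AMPT detector and
the original Pan-Tompkins baseline both consume the output of this chain.

All filters run causally with zero initial conditions; amplitude units are
arbitrary (downstream thresholds are adaptive), so no normalisation is
applied before filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal as sps

#: The sampling rate (Hz) the recursive filter coefficients were designed for.
DESIGN_FS = 200.0

#: Integration window length in seconds (~width of a QRS complex plus a margin).
INTEGRATION_WINDOW_S = 0.150

# Nominal per-stage group delays in samples at the design rate.
LOWPASS_DELAY = 6
HIGHPASS_DELAY = 16
DERIVATIVE_DELAY = 2


class FilterInputError(ValueError):
    """Raised when a filter stage receives invalid input."""


@dataclass
class ECGRecord:
    """A single-lead ECG trace with sampling metadata and beat annotations.

    Annotations are ground-truth R-peak positions as ``(sample_index, label)``
    pairs with strictly increasing indices.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""
    annotations: list[tuple[int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"sampling frequency must be positive, got {self.fs}")
        if not np.all(np.isfinite(self.samples)):
            raise FilterInputError("ECG samples contain non-finite values")
        idx = [i for i, _ in self.annotations]
        if any(b <= a for a, b in zip(idx, idx[1:])):
            raise ValueError("annotation indices must be strictly increasing")
        if idx and (idx[0] < 0 or idx[-1] >= len(self.samples)):
            raise ValueError("annotation indices out of record bounds")

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.fs

    @property
    def annotation_indices(self) -> np.ndarray:
        return np.asarray([i for i, _ in self.annotations], dtype=int)


@dataclass
class ProcessedSignal:
    """Output of the conditioning chain, aligned sample-for-sample with the input.

    ``bandpassed`` is the signal after low-pass + high-pass, ``derivative``
    after the five-point differentiator, and ``integrated`` after squaring
    and the trailing-window mean.  ``stage_delays`` records the nominal group
    delay of each stage in samples.
    """

    bandpassed: np.ndarray
    derivative: np.ndarray
    integrated: np.ndarray
    fs: float
    stage_delays: dict[str, float]
    window_samples: int

    @property
    def total_delay(self) -> float:
        return sum(self.stage_delays.values())

    def __len__(self) -> int:
        return len(self.integrated)


def _validate(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise FilterInputError(f"expected a 1-D sequence, got shape {x.shape}")
    if not np.all(np.isfinite(x)):
        raise FilterInputError("input contains non-finite values")
    return x


def lowpass_filter(x) -> np.ndarray:
    """Recursive low-pass y(n) = 2y(n-1) - y(n-2) + x(n) - 2x(n-6) + x(n-12).

    Transfer function (1 - z^-6)^2 / (1 - z^-1)^2: DC gain 36, ~11 Hz corner
    and nominal group delay of 6 samples at the 200 Hz design rate.
    """
    x = _validate(x)
    b = np.zeros(13)
    b[0], b[6], b[12] = 1.0, -2.0, 1.0
    a = np.array([1.0, -2.0, 1.0])
    return sps.lfilter(b, a, x)


def highpass_filter(x) -> np.ndarray:
    """Recursive high-pass y(n) = y(n-1) - x(n)/32 + x(n-16) - x(n-17) + x(n-32)/32.

    An all-pass delay of 16 samples minus a 32-point recursive low-pass
    (gain-normalised), giving DC gain 0, unity passband gain and nominal
    group delay of 16 samples: the ~5 Hz corner of the classic chain.
    """
    x = _validate(x)
    b = np.zeros(33)
    b[0], b[16], b[17], b[32] = -1.0 / 32.0, 1.0, -1.0, 1.0 / 32.0
    a = np.array([1.0, -1.0])
    return sps.lfilter(b, a, x)


def derivative_filter(x) -> np.ndarray:
    """Five-point derivative y(n) = (2x(n) + x(n-1) - x(n-3) - 2x(n-4)) / 8."""
    x = _validate(x)
    b = np.array([2.0, 1.0, 0.0, -1.0, -2.0]) / 8.0
    return sps.lfilter(b, [1.0], x)


def square(x) -> np.ndarray:
    """Pointwise squaring; makes all samples positive and emphasises steep slopes."""
    x = np.asarray(x, dtype=float)
    return x * x


def moving_window_integrate(x, window_samples: int) -> np.ndarray:
    """Trailing moving-window mean over ``window_samples`` samples.

    During warm-up (the first ``window_samples - 1`` samples) the mean is
    taken over the available prefix rather than dividing by the full window
    length, which avoids an artificial startup spike.
    """
    x = _validate(x)
    if window_samples < 1:
        raise FilterInputError(f"window_samples must be >= 1, got {window_samples}")
    if window_samples > len(x):
        raise FilterInputError(
            f"window_samples {window_samples} exceeds signal length {len(x)}"
        )
    css = np.concatenate([[0.0], np.cumsum(x)])
    n = len(x)
    counts = np.minimum(np.arange(1, n + 1), window_samples)
    starts = np.arange(1, n + 1) - counts
    return (css[1:] - css[starts]) / counts


def integration_window_samples(fs: float) -> int:
    """Window length N = round(150 ms * fs); 30 samples at 200 Hz."""
    return max(1, int(round(INTEGRATION_WINDOW_S * fs)))


def preprocess(record: ECGRecord) -> ProcessedSignal:
    """Run the full conditioning chain on a record.

    The recursive coefficients are applied at the record's own sampling rate
    (as in the primary analysis mode); only the integration window length is
    rescaled with fs.  Use :func:`resample_to_200hz` first to run the chain
    at its design rate.
    """
    n = integration_window_samples(record.fs)
    bp = highpass_filter(lowpass_filter(record.samples))
    deriv = derivative_filter(bp)
    integrated = moving_window_integrate(square(deriv), n)
    delays = {
        "lowpass": float(LOWPASS_DELAY),
        "highpass": float(HIGHPASS_DELAY),
        "derivative": float(DERIVATIVE_DELAY),
        "integration": (n - 1) / 2.0,
    }
    return ProcessedSignal(
        bandpassed=bp,
        derivative=deriv,
        integrated=integrated,
        fs=record.fs,
        stage_delays=delays,
        window_samples=n,
    )


def resample_to_200hz(record: ECGRecord) -> ECGRecord:
    """Resample a record to the chain's 200 Hz design rate.

    Uses polyphase FIR anti-aliased rational resampling; annotation indices
    are mapped by ``round(i * 200 / fs)``, preserving annotation times to
    within half an output sample.
    """
    if record.fs == DESIGN_FS:
        return record
    ratio = Fraction(int(round(DESIGN_FS * 1000)), int(round(record.fs * 1000)))
    up, down = ratio.numerator, ratio.denominator
    samples = sps.resample_poly(record.samples, up, down)
    scale = DESIGN_FS / record.fs
    n_out = len(samples)
    anns = [
        (min(int(round(i * scale)), n_out - 1), label)
        for i, label in record.annotations
    ]
    # collapse any duplicate indices produced by rounding at extreme ratios
    dedup: list[tuple[int, str]] = []
    for i, label in anns:
        if dedup and i <= dedup[-1][0]:
            continue
        dedup.append((i, label))
    return ECGRecord(
        samples=samples, fs=DESIGN_FS, record_id=record.record_id, annotations=dedup
    )
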