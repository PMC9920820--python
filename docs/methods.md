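# Methods

## Signal conditioning

The detector chain is the classic recursive Pan–Tompkins cascade, designed
for 200 Hz input:

- low-pass `y(n) = 2y(n−1) − y(n−2) + x(n) − 2x(n−6) + x(n−12)`
  (transfer `(1−z⁻⁶)²/(1−z⁻¹)²`: DC gain 36, ~11 Hz corner, nominal delay
  6 samples; the FIR-equivalent kernel is 11 taps with exact delay 5);
- high-pass `y(n) = y(n−1) − x(n)/32 + x(n−16) − x(n−17) + x(n−32)/32`
  (a 16-sample all-pass minus a gain-normalised 32-point low-pass: DC gain
  0, unity passband, delay 16).  Several circulating transcriptions of this
  stage place the feedback term with the wrong sign, which moves the pole
  to z = −1 and gives a DC gain of 16; the form used here satisfies the
  defining properties (DC null, unity passband, linear phase) and is the
  one the rest of the literature implements;
- five-point derivative `y(n) = (2x(n) + x(n−1) − x(n−3) − 2x(n−4))/8`
  (delay 2), squaring, and a trailing moving-window mean of
  `N = round(0.150·fs)` samples (30 at 200 Hz).  The warm-up prefix divides
  by the number of samples actually present, avoiding a startup spike.

All stages run causally from zero initial state.  In the primary ("native")
mode the 200 Hz coefficients are applied unchanged at the record's own
sampling rate — the band edges shift accordingly, which is deliberate; only
the integration window rescales with fs.  A second mode resamples every
record to 200 Hz first (polyphase FIR rational resampling; annotation
indices mapped by `round(i·200/fs)`).  Amplitudes are arbitrary units and
are never normalised: every decision threshold downstream is adaptive and
scale-free, and the tests assert exact invariance of detections under
positive rescaling.

## Candidate peaks

Candidate events are strict local maxima of the integrated track (first
sample of a flat plateau), thinned so that within any 200 ms span only the
tallest maximum survives (height priority, ties to the earlier index —
the `find_peaks(distance=...)` convention).  The thinning matters: the
squared-derivative energy of a multi-wave beat is multi-lobed, so the
trailing mean carries secondary maxima on the flanks of the main hump.
Classifying those as noise peaks inflates NPKF to ~0.7·SPKF, which pushes
THRESHOLD F1 far above any genuine noise level and starves both search-back
(F2 too high to recover attenuated beats) and the T-wave rule (T peaks can
never reach F1).  One candidate per hump restores the threshold dynamics
the update equations assume.  Search-back draws from the same thinned
candidate list; recomputing raw maxima inside the search window would let
the triggering beat's own secondary maximum be "recovered" in place of the
genuinely missed beat.

## Decision logic

AMPT maintains SPKF/NPKF (0.125/0.875 exponential updates),
`F1 = NPKF + 0.25(SPKF−NPKF)`, `F2 = 0.25·F1`, an 8-deep RR buffer with
`RR MISSED LIMIT = 1.66 × mean`, a 200 ms refractory period and the slope
T-wave test (within 360 ms of the previous QRS, maximal absolute
derivative-stage value in a ±75 ms neighbourhood below half the previous
QRS's slope → T wave, routed to the noise update).  Thresholds are
recomputed after every update and computed literally even if NPKF drifts
above SPKF (no clamping).  Search-back triggers whenever the elapsed gap
at a candidate event (or end of record) exceeds the missed limit, requires
at least two known RR intervals, accepts the tallest above-F2 candidate
passing the refractory and T-wave checks, and applies the same 0.125/0.875
update.

Initialisation is a 2 s learning phase: SPKF starts at 0.25 × the maximum
and NPKF at 0.5 × the mean of the integrated signal over the span, with
the first 0.5 s of filter transient excluded.  Both quantities scale with
the input, so initialisation preserves scale invariance.  Records shorter
than the learning phase yield an empty result with a warning.  The first
one-to-two beats of any record fall inside the learning phase and are
structurally undetectable; quality figures quoted on whole records include
this deficit.

The Pan–Tompkins baseline implements the original's extra machinery:
parallel SPKI/NPKI and SPKF/NPKF threshold pairs on the integrated and
band-passed tracks with acceptance requiring time-coincident peaks
(correspondence window = one integration window; the original description
gives no tolerance), second thresholds at 0.5 of the first, search-back updates
0.25/0.75 on both tracks, dual RR buffers where buffer 2 keeps intervals
inside the 92–116 % band of its own average, missed limit 1.66 × that
average, and threshold halving on an out-of-band (irregular) interval.
A configuration hook (`simplified_config`) disables the band-passed
analysis, collapses RR bookkeeping to buffer 1, and sets the second
threshold fraction to 0.25 and search-back coefficients to 0.125/0.875;
the test suite verifies that the baseline then emits bit-identical
detections to the independent AMPT implementation on mixed batches of
records — the structural content of the simplification, checked as program
equivalence.  Efficiency is compared by operation counts (every adaptive
update, threshold recomputation, RR update and decision comparison), a
hardware-independent proxy; wall-clock timings are logged for information
only and nothing asserts on them.

## Localisation

Detections live on the integrated track and are mapped back to raw
coordinates for the 150 ms evaluation window.  Empirically (and by
construction of the trailing mean with first-of-plateau maxima) the
integrated peak occurs while the QRS energy burst is still inside the
window, so the band-passed QRS extremum lies within one integration window
before the derivative-corrected index; the mapper takes the maximal
absolute band-passed value over that span (±25 ms margin) and subtracts
the exact band-pass cascade delay of 21 samples (5 + 16).  On clean
synthetic records this lands on the simulated R apex to the sample at all
supported rates.  A fixed ±75 ms refinement around the nominal
total-delay-corrected point was tried first and fails whenever T-wave
energy merges into the integration window and shifts the integrated peak
by up to ~20 samples.

## Beat-by-beat evaluation

Matching is greedy nearest-neighbour in annotation order, one-to-one, ties
to the earlier detection, within a 150 ms window by default.  Unmatched
detections are FP, unmatched annotations FN; TP + FN = TB holds by
construction.  Aggregation over records is reported under two bases —
pooled counts (sum TP/FP/FN/TB, then apply the formulas) and per-record
means of the percentages — because the two genuinely disagree on
heterogeneous record sizes and published tables do not always say which
was used.  The published six-dataset benchmark counts are embedded
(`PUBLISHED_BENCHMARKS`) so the error-rate arithmetic can be re-verified;
for the telehealth dataset the printed error rates are not consistent with
the same rows' counts (the failed-detection identity FP + FN still holds
there), so that dataset is excluded from the arithmetic cross-check, and
printed sensitivity/PPV/accuracy columns are not cross-checked at all for
the same reason.

## Synthetic records

Each beat is a sum of Gaussians (P, Q, R, S, T) placed on an RR point
process, R apices grid-aligned so ground truth is exact.  Defaults: R width
σ = 13 ms, T at +250 ms with σ = 45 ms and amplitude ratio 0.25; sampling
rates restricted to the benchmark set {128, 200, 250, 360, 500} Hz.  RR
processes: constant, Gaussian jitter (σ = 30 ms default), and irregular
(jitter plus premature beats at ~55 % of the nominal interval with 10 %
probability).  The paced morphology is a 4 ms-wide high-amplitude stimulus
spike followed by a broad 120 ms complex.  The prominent-T regime uses a
*peaked* T (σ = 25 ms at ratio 0.6): tall-and-steep T waves are the
canonical confounder for slope-based discrimination — a broad 45 ms T at
the same amplitude produces integrated peaks too small to cross any
plausible threshold (height scales as amplitude²/width), which would make
the T-rule untestable, while at 25 ms the slope ratio (~0.3 of the QRS)
still sits below the 0.5 rejection criterion.  Per-beat gain modulation,
deterministic every-kth-beat attenuation (for search-back studies),
baseline wander (0.3 Hz), mains (50 Hz) and white noise are available;
`degrade` adds a calibrated mixture (60 % white / 25 % baseline / 15 %
mains) to reach a stated broadband SNR, leaving truth untouched.  All draws
come from one integer-seeded generator; identical configuration and seed
reproduce records bit for bit.

What the generator does **not** emulate: real electrode-motion artefact
(non-stationary, impulsive), morphology change across arrhythmia types,
QT adaptation to rate, muscle noise spectra, or real annotation ambiguity.
Passing tests therefore demonstrate the decision logic behaves as designed
under controlled conditions, not clinical-grade performance; the optional
`scripts/physionet_bench.py` exists to run the identical pipeline on real
archived data.

## Problem sizes and numerical choices

Test and acceptance runs use synthetic records of 2–5.5 minutes
(300–500 beats) — long enough for threshold dynamics, RR buffers and
search-back to reach steady state, with 3 seeds/heart rates for the
quality checks and 6 mixed-morphology records for the equivalence batch.
Filter oracles run on 1000-sample random vectors at 1e−9 absolute
tolerance.  Durations in the decision logic (refractory 200 ms, T window
360 ms, slope neighbourhood ±75 ms, learning 2 s) are scaled by fs and
rounded to samples.  Ties are always broken toward the earlier index.
Degenerate inputs: empty RR buffer disables search-back; zero-denominator
metrics return NaN with a warning; non-finite samples are rejected at the
filter boundary.

## Known limitations

- The learning phase forfeits the first ~2 s of every record; no
  retrospective recovery of those beats is attempted.
- Native-rate mode shifts the band edges at rates other than 200 Hz by
  design; no coefficient redesign is provided.
- The baseline reconstruction follows the original method's published
  description; where that description leaves freedom (coincidence
  tolerance, initialisation, irregularity response timing) the choices
  documented here apply, and no attempt is made to replicate any specific
  third-party implementation's quirks.
- WFDB support covers headers, signal formats 16 and 212 and MIT
  annotation files — the subset this package reads and writes — not the
  full format family.
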