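# ampt

Real-time QRS detection for single-lead ECG, built for the constraints of
wearable and mobile platforms.

Continuous ECG monitoring needs a beat detector that is cheap enough to run
in real time on battery-powered hardware without giving up accuracy.  The
classic Pan–Tompkins detector runs a *dual* analysis — adaptive thresholds
on both the band-passed signal and the moving-window-integrated signal,
plus two parallel RR-interval averages — much of which is redundant.  This
package implements **AMPT** (a simplified Pan–Tompkins): the same filter
chain, but decision logic driven by a *single* set of adaptive thresholds
on the integrated signal and a *single* averaged RR interval for missed-beat
search-back.  It ships with:

- `ampt.filters` — the Pan–Tompkins conditioning chain (recursive low- and
  high-pass, five-point derivative, squaring, 150 ms moving-window
  integration) and polyphase resampling to the chain's 200 Hz design rate;
- `ampt.ampt` — the AMPT detector as a causal, deterministic state machine;
- `ampt.pan_tompkins` — a faithful original Pan–Tompkins baseline
  (dual-signal coincidence, dual RR averages with the 92–116 % band,
  0.25/0.75 search-back updates), with a configuration hook that reduces it
  exactly to AMPT;
- `ampt.evaluation` — ANSI/AAMI-style beat-by-beat scoring (one-to-one
  matching within 150 ms) and the standard correctness metrics, plus the
  published six-dataset benchmark counts for desk-checking the arithmetic;
- `ampt.synthetic` — a seeded generator of annotated ECG-like records
  (sinus, irregular/premature, paced, peaked-T morphologies; calibrated
  noise) so everything is testable without downloads;
- `ampt.pipeline` / `ampt.cli` — manifests, batch runs, and the `ampt`
  command-line tool.

## The model

All detection happens on the integrated signal `y`.  For every candidate
peak of height `PEAKF` the detector maintains

```
SPKF = 0.125·PEAKF + 0.875·SPKF          (accepted as QRS)
NPKF = 0.125·PEAKF + 0.875·NPKF          (rejected as noise)
THRESHOLD F1 = NPKF + 0.25·(SPKF − NPKF)
THRESHOLD F2 = 0.25·THRESHOLD F1
```

A peak above `F1` is a QRS unless it falls in the 200 ms refractory period,
or lies within 360 ms of the previous QRS with maximal slope below half of
that QRS's slope (then it is a T wave and treated as noise).  With
`RR AVERAGE1` the mean of the eight most recent RR intervals and
`RR MISSED LIMIT = 1.66·RR AVERAGE1`, any gap exceeding the limit is
re-searched for the tallest candidate above the lower threshold `F2`; a
recovered beat updates `SPKF` with the same 0.125/0.875 rule.  Beat-by-beat
scoring uses

```
error rate  = 100·(FN+FP)/TB     sensitivity = 100·TP/(TP+FN)
PPV         = 100·TP/(TP+FP)     accuracy    = 100·TP/(TP+FP+FN)
F1          = 100·2TP/(2TP+FP+FN)
```

## Worked example

```
$ ampt simulate demo --duration-s 120 --hr-bpm 75 --rr-process gaussian --seed 5 --snr-db 20
wrote demo (150 beats, fs=200 Hz, seed=5)
$ ampt detect demo --out demo_peaks.csv
$ ampt evaluate demo_peaks.csv demo
{
  "record_id": "demo",
  "basis": "record",
  "TP": 148,
  "FP": 0,
  "FN": 2,
  "TB": 150,
  "failed_detection": 2,
  "error_rate_pct": 1.33,
  "sensitivity_pct": 98.67,
  "ppv_pct": 100.0,
  "accuracy_pct": 98.67,
  "f1_pct": 99.33
}
```

The simulated record has 150 annotated beats at 20 dB broadband SNR.  AMPT
finds 148 of them within the 150 ms window with no false positives; the two
misses are the beats inside the detector's 2 s learning phase, before the
adaptive thresholds exist.  `ampt bench manifest.yaml --detector pt
--out-dir out/` runs the same pipeline over a whole dataset manifest and
writes per-record peak lists, metric tables under both aggregation bases
(pooled counts and per-record means) and an operation-count summary.

`scripts/physionet_bench.py` applies both detectors to locally stored
PhysioNet-style WFDB data (e.g. the MIT-BIH databases) described by a
manifest; see its module docstring.

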