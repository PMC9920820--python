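"""Beat matching and correctness-metric tests, including a brute-force
maximum-cardinality matching oracle and the published benchmark counts."""

import itertools
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ampt
from ampt.evaluation import (
    CONSISTENT_ERROR_RATE_ROWS,
    PUBLISHED_BENCHMARKS,
    MatchResult,
)


def max_cardinality_matching(det, ann, tol):
    """Brute-force oracle: maximum number of one-to-one pairs within tol."""
    best = 0
    for k in range(min(len(det), len(ann)), 0, -1):
        for ann_sub in itertools.combinations(range(len(ann)), k):
            for det_sub in itertools.permutations(range(len(det)), k):
                if all(abs(det[d] - ann[a]) <= tol
                       for a, d in zip(ann_sub, det_sub)):
                    return k
    return best


class TestMatchBeats:
    FS = 360.0

    def test_perfect_agreement(self):
        ann = [100, 500, 900]
        m = ampt.match_beats(ann, ann, self.FS)
        assert (m.tp, m.fp, m.fn) == (3, 0, 0) and m.tb == 3

    def test_just_outside_window(self):
        off = int(0.150 * self.FS) + 1
        m = ampt.match_beats([1000 + off], [1000], self.FS)
        assert (m.tp, m.fp, m.fn) == (0, 1, 1)

    def test_just_inside_window(self):
        off = int(0.150 * self.FS)
        m = ampt.match_beats([1000 + off], [1000], self.FS)
        assert (m.tp, m.fp, m.fn) == (1, 0, 0)

    def test_one_detection_two_close_annotations(self):
        m = ampt.match_beats([1030], [1000, 1060], self.FS)
        assert (m.tp, m.fp, m.fn) == (1, 0, 1)
        assert max_cardinality_matching([1030], [1000, 1060],
                                        0.150 * self.FS) == 1

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_cardinality_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        ann = np.sort(rng.choice(2000, size=5, replace=False))
        ann = ann[np.insert(np.diff(ann) > 0, 0, True)]
        det = np.sort(rng.choice(2000, size=5, replace=False))
        det = det[np.insert(np.diff(det) > 0, 0, True)]
        tol = 0.150 * self.FS
        m = ampt.match_beats(det, ann, self.FS)
        assert m.tp == max_cardinality_matching(list(det), list(ann), tol)

    def test_unsorted_rejected(self):
        with pytest.raises(ValueError):
            ampt.match_beats([5, 3], [1, 2], self.FS)

    def test_counts_identity(self):
        m = ampt.match_beats([10, 400, 800], [12, 395, 1500, 1900], self.FS)
        assert m.tp + m.fn == m.tb
        assert len(m.pairs) == m.tp

    @given(st.lists(st.integers(0, 50), min_size=1, max_size=8),
           st.lists(st.integers(0, 50), min_size=1, max_size=8))
    def test_swap_symmetry(self, a_gaps, d_gaps):
        # well-separated beats: gaps > 2x tolerance
        tol_samples = int(0.150 * self.FS)
        ann = np.cumsum(np.asarray(a_gaps) + 2 * tol_samples + 1)
        det = np.cumsum(np.asarray(d_gaps) + 2 * tol_samples + 1)
        m1 = ampt.match_beats(det, ann, self.FS)
        m2 = ampt.match_beats(ann, det, self.FS)
        assert m1.tp == m2.tp
        assert (m1.fp, m1.fn) == (m2.fn, m2.fp)

    def test_shift_below_tolerance_preserves_tp(self):
        ann = np.arange(10) * 400 + 500  # gaps far above 2x tolerance
        det = ann.copy()
        for shift in (-50, -10, 10, 50):  # 150 ms at 360 Hz = 54 samples
            m = ampt.match_beats(det + shift, ann, self.FS)
            assert m.tp == len(ann)


class TestMetricFormulas:
    def test_worked_example(self):
        m = MatchResult.from_counts(tp=90, fp=10, fn=10)
        assert ampt.sensitivity(m) == pytest.approx(90.0)
        assert ampt.ppv(m) == pytest.approx(90.0)
        assert ampt.accuracy(m) == pytest.approx(100 * 90 / 110)
        assert ampt.f1(m) == pytest.approx(90.0)
        assert ampt.total_error_rate(m) == pytest.approx(20.0)

    def test_perfect_and_degenerate(self):
        perfect = MatchResult.from_counts(tp=7, fp=0, fn=0)
        for fn in (ampt.sensitivity, ampt.ppv, ampt.accuracy, ampt.f1):
            assert fn(perfect) == 100.0
        assert ampt.total_error_rate(perfect) == 0.0
        bad = MatchResult.from_counts(tp=0, fp=3, fn=4)
        for fn in (ampt.sensitivity, ampt.ppv, ampt.accuracy, ampt.f1):
            assert fn(bad) == 0.0

    def test_undefined_flagged_as_nan(self):
        empty = MatchResult.from_counts(tp=0, fp=0, fn=0, tb=0)
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            assert math.isnan(ampt.total_error_rate(empty))
            assert math.isnan(ampt.sensitivity(empty))
        assert caught

    @given(st.integers(0, 1000), st.integers(0, 1000), st.integers(0, 1000))
    def test_f1_is_harmonic_mean_and_accuracy_bound(self, tp, fp, fn):
        m = MatchResult.from_counts(tp=tp, fp=fp, fn=fn)
        if tp + fn > 0 and tp + fp > 0 and tp > 0:
            s = ampt.sensitivity(m) / 100
            p = ampt.ppv(m) / 100
            assert ampt.f1(m) / 100 == pytest.approx(2 * s * p / (s + p),
                                                     abs=1e-12)
            assert ampt.accuracy(m) <= min(ampt.sensitivity(m), ampt.ppv(m)) + 1e-9


class TestAggregate:
    def test_single_record_equal_under_both_bases(self):
        m = MatchResult.from_counts(tp=90, fp=10, fn=10)
        pooled = ampt.aggregate([m], "pooled-counts")
        mean = ampt.aggregate([m], "per-record-mean")
        assert pooled.sensitivity == pytest.approx(mean.sensitivity)
        assert pooled.f1 == pytest.approx(mean.f1)

    def test_bases_diverge_on_unbalanced_records(self):
        ms = [MatchResult.from_counts(90, 10, 10),
              MatchResult.from_counts(10, 0, 90)]
        pooled = ampt.aggregate(ms, "pooled-counts")
        mean = ampt.aggregate(ms, "per-record-mean")
        assert pooled.sensitivity == pytest.approx(50.0)
        assert mean.sensitivity == pytest.approx(50.0)
        assert pooled.ppv == pytest.approx(100 * 100 / 110)
        assert mean.ppv == pytest.approx(95.0)

    def test_unknown_basis_rejected(self):
        with pytest.raises(ValueError):
            ampt.aggregate([MatchResult.from_counts(1, 0, 0)], "median")


class TestPublishedBenchmarks:
    def test_failed_detection_identity_all_rows(self):
        for row in PUBLISHED_BENCHMARKS.values():
            assert row["fp"] + row["fn"] == row["failed"]

    def test_error_rate_recomputes_from_counts(self):
        for key in CONSISTENT_ERROR_RATE_ROWS:
            row = PUBLISHED_BENCHMARKS[key]
            m = MatchResult.from_counts(row["tp"], row["fp"], row["fn"],
                                        tb=row["tb"])
            assert round(ampt.total_error_rate(m), 2) == row["error_rate"], key

    def test_telehealth_rows_excluded_from_consistency_set(self):
        assert all(ds != "D" for ds, _ in CONSISTENT_ERROR_RATE_ROWS)
        assert len(CONSISTENT_ERROR_RATE_ROWS) == 10


def test_write_report_round_trip(tmp_path):
    import json

    import pandas as pd

    ms = {"r1": MatchResult.from_counts(90, 10, 10),
          "r2": MatchResult.from_counts(50, 5, 2)}
    rep = ampt.aggregate(ms, "pooled-counts")
    ampt.write_report([rep], tmp_path / "m.csv", "csv")
    ampt.write_report([rep], tmp_path / "m.json", "json")
    df = pd.read_csv(tmp_path / "m.csv")
    assert list(df["record_id"]) == ["r1", "r2", "aggregate"]
    rows = json.loads((tmp_path / "m.json").read_text())
    assert rows[-1]["record_id"] == "aggregate"
    assert rows[-1]["TP"] == 140
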