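import math

import numpy as np
import pytest

import icptools as it
from icptools.evaluate import (
    baseline_noise_std,
    classification_report,
    match_events,
    metrics_from_counts,
    sigma_bn_detect,
    SigmaBaselineDetector,
)


def _event(cid, max_index, lp=0.05, above=True, discarded=False):
    return it.CandidateEvent(cid, max_index, max_index - 2, lp, 1 + lp, 1.0,
                             above_threshold=above,
                             artifact_discarded=discarded)


def _injury(frame=60, ts=3.0):
    return it.InjuryEstimate(injury_frame=frame, sample_period_s=ts)


class TestMatching:
    def test_within_tolerance_is_tp(self):
        es = it.EventSet({"c": [_event("c", 100 // 3 + 1)]})  # 102 s
        gt = it.GroundTruthMarks({"c": np.array([106.0])})
        cm = match_events(es, gt, 3.0, epsilon_s=10)
        assert (cm.tp, cm.fp, cm.fn) == (1, 0, 0)

    def test_outside_tolerance_fp_and_fn(self):
        es = it.EventSet({"c": [_event("c", 33)]})  # 99 s
        gt = it.GroundTruthMarks({"c": np.array([115.0])})
        cm = match_events(es, gt, 3.0, epsilon_s=10)
        assert (cm.tp, cm.fp, cm.fn) == (0, 1, 1)

    def test_fig8_style_accounting(self):
        # 41 candidates, 5 above threshold all coinciding with 5 marks
        evs = [_event("c", 20 * (k + 1), lp=0.05) for k in range(5)]
        evs += [_event("c", 3 + 6 * k, lp=0.01, above=False)
                for k in range(36)]
        es = it.EventSet({"c": evs})
        gt = it.GroundTruthMarks({"c": np.array([60.0 * (k + 1)
                                                 for k in range(5)])})
        cm = match_events(es, gt, 3.0, epsilon_s=10)
        assert (cm.tp, cm.tn, cm.fp, cm.fn) == (5, 36, 0, 0)

    def test_one_to_one_matching_no_double_count(self):
        # two detections near one mark: only one TP, the other is FP
        es = it.EventSet({"c": [_event("c", 33), _event("c", 35)]})
        gt = it.GroundTruthMarks({"c": np.array([102.0])})
        cm = match_events(es, gt, 3.0, epsilon_s=10)
        assert (cm.tp, cm.fp, cm.fn) == (1, 1, 0)

    def test_discarded_event_excluded_from_tp_fp(self):
        es = it.EventSet({"c": [_event("c", 34, discarded=True)]})
        gt = it.GroundTruthMarks({"c": np.array([102.0])})
        cm = match_events(es, gt, 3.0, epsilon_s=10)
        # the mark is missed; the discarded candidate absorbs it (not TN)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (0, 0, 1, 0)

    def test_widening_epsilon_monotone(self):
        rng = np.random.default_rng(3)
        evs = {f"c{i}": [_event(f"c{i}", int(m))
                         for m in np.sort(rng.choice(200, 8, replace=False))]
               for i in range(10)}
        es = it.EventSet(evs)
        gt = it.GroundTruthMarks({
            cid: np.sort(rng.choice(600, 6, replace=False)).astype(float)
            for cid in evs})
        prev_tp, prev_fn = -1, 10**9
        for eps in (0, 3, 6, 10, 15, 30):
            cm = match_events(es, gt, 3.0, epsilon_s=eps)
            assert cm.tp >= prev_tp and cm.fn <= prev_fn
            prev_tp, prev_fn = cm.tp, cm.fn


class TestMetrics:
    def test_perfect_case(self):
        m = metrics_from_counts(it.ConfusionCounts(tp=5, fn=0, tn=36, fp=0))
        assert (m.sensitivity, m.specificity, m.accuracy) == (1.0, 1.0, 1.0)

    def test_undefined_denominator_is_nan_with_warning(self):
        with pytest.warns(RuntimeWarning, match="sensitivity"):
            m = metrics_from_counts(it.ConfusionCounts(tp=0, fn=0, tn=3, fp=1))
        assert math.isnan(m.sensitivity)
        assert m.specificity == 0.75

    def test_random_counts_match_hand_formulas(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            tp, fp, tn, fn = (int(x) for x in rng.integers(1, 50, 4))
            m = metrics_from_counts(it.ConfusionCounts(tp, fp, tn, fn))
            assert m.sensitivity == pytest.approx(tp / (tp + fn))
            assert m.specificity == pytest.approx(tn / (tn + fp))
            assert m.accuracy == pytest.approx((tp + tn) / (tp + fp + tn + fn))


class TestSigmaComparator:
    def test_noiseless_trace_keeps_every_candidate(self):
        x = np.ones(120)
        x[[30, 70]] += [0.02, 0.05]
        rec = it.Recording(np.tile(x, (4, 1)), list("abcd"), 3.0)
        es = sigma_bn_detect(rec, n_sigma=10, mode="per_icp",
                             injury=_injury(20))
        assert all(e.above_threshold for e in es)

    def test_lowest_noise_uses_dataset_minimum(self):
        rng = np.random.default_rng(4)
        tr = np.vstack([0.01 * rng.standard_normal(200),
                        0.002 * rng.standard_normal(200)]) + 1.0
        rec = it.Recording(tr, ["hi", "lo"], 3.0)
        det = SigmaBaselineDetector(n_sigma=10, mode="lowest_noise",
                                    injury=_injury(60)).fit(rec)
        thr = det.thresholds_
        assert thr["hi"] == thr["lo"]
        per = SigmaBaselineDetector(n_sigma=10, mode="per_icp",
                                    injury=_injury(60)).fit(rec)
        assert per.thresholds_["hi"] > per.thresholds_["lo"]
        assert thr["hi"] == pytest.approx(per.thresholds_["lo"])

    def test_sigma_recovered_from_generator_noise(self):
        # oracle: the generator's own per-cell noise sigma; the residual-std
        # estimate from the raw traces must track it closely pre-injury
        truth = it.generate_recording(
            it.SynthConfig(seed=6, noise_sigma_range=(0.002, 0.01),
                           br_event_rate=0.0))
        rec = truth.recording
        sig = baseline_noise_std(rec, _injury(truth.injury_frame))
        rng = np.random.default_rng(6)
        expected = np.exp(rng.uniform(np.log(0.002), np.log(0.01),
                                      size=rec.n_cells))
        ratio = sig / expected
        assert 0.8 < np.median(ratio) < 1.2

    def test_short_baseline_rejected(self, default_truth):
        with pytest.raises(it.ValidationError):
            baseline_noise_std(default_truth.recording, _injury(2))


class TestClassificationReport:
    def _labels(self, codes):
        return {f"c{i}": it.ClassLabel.from_code(c)
                for i, c in enumerate(codes)}

    def test_all_correct(self):
        t = self._labels([0, 1, 2, 3])
        rep = classification_report(t, t)
        assert rep.overall_accuracy == 1.0 and rep.error_percent == 0.0

    def test_counting_matches_published_style_ratio(self):
        # 789 correct of 825 -> 0.9564
        codes = [0] * 825
        truth = self._labels(codes)
        pred = dict(truth)
        for i in range(36):
            pred[f"c{i}"] = it.ClassLabel.from_code(2)
        rep = classification_report(pred, truth)
        assert rep.n_correct == 789
        assert rep.overall_accuracy == pytest.approx(0.9564, abs=5e-5)

    def test_confusion_restricted_to_one_class(self):
        truth = self._labels([0, 0, 1, 1, 2, 2, 3, 3])
        pred = dict(truth)
        pred["c2"] = it.ClassLabel.from_code(3)  # one class-1 cell wrong
        rep = classification_report(pred, truth)
        assert rep.per_class_accuracy[1] == 0.5
        for c in (0, 2, 3):
            assert rep.per_class_accuracy[c] == 1.0

    def test_cell_set_mismatch_rejected(self):
        with pytest.raises(it.ValidationError):
            classification_report(self._labels([0]), self._labels([0, 1]))
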