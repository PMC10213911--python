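"""Evaluation protocol: tolerance matching, metrics and comparators.

Detections are scored against expert marks with a symmetric +/- epsilon
tolerance (epsilon = 10 s, about three samples at Ts = 3 s): each mark is
greedily matched nearest-first to at most one above-threshold event within
epsilon (TP); unmatched marks are FN; unmatched above-threshold events are
FP; sub-threshold candidates not absorbed by a mark are TN. Under this
accounting tp+fn = |marks|, tp+fp = |above-threshold events| and, whenever
every mark coincides with some candidate, tp+tn+fp+fn = |candidates|.

The comparator detectors replicate the common practice of thresholding at
n times the baseline-noise standard deviation (sigma_bn), either per
profile or using the quietest profile of the dataset; both threshold the
same left-prominence scores so the comparison isolates how the threshold
is constructed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datatypes import (
    ClassLabel,
    ConfusionCounts,
    EventSet,
    GroundTruthMarks,
    InjuryEstimate,
    MetricTriple,
    Recording,
    ValidationError,
)
from .detect import detect_candidates
from .preprocess import SavGolSmoother

__all__ = [
    "match_events",
    "match_events_per_cell",
    "metrics_from_counts",
    "baseline_noise_std",
    "sigma_bn_detect",
    "SigmaBaselineDetector",
    "classification_report",
    "ClassificationReport",
]

DEFAULT_EPSILON_S = 10.0


def _match_cell(
    evs,
    gt_times: np.ndarray,
    sample_period_s: float,
    epsilon_s: float,
) -> ConfusionCounts:
    det = [e for e in evs if e.is_true_event]
    rest = [e for e in evs if not e.is_true_event]
    det_t = np.array([e.report_time_s(sample_period_s) for e in det])
    rest_t = np.array([e.report_time_s(sample_period_s) for e in rest])

    def greedy(gtimes: np.ndarray, etimes: np.ndarray) -> tuple[set, set]:
        """Nearest-first one-to-one matching within epsilon."""
        pairs = [
            (abs(g - t), gi, ei)
            for gi, g in enumerate(gtimes)
            for ei, t in enumerate(etimes)
            if abs(g - t) <= epsilon_s
        ]
        pairs.sort()
        used_g: set = set()
        used_e: set = set()
        for _, gi, ei in pairs:
            if gi not in used_g and ei not in used_e:
                used_g.add(gi)
                used_e.add(ei)
        return used_g, used_e

    matched_g, matched_e = greedy(gt_times, det_t)
    tp = len(matched_g)
    fp = len(det) - len(matched_e)
    fn = len(gt_times) - tp
    # unmatched marks absorb the nearest remaining candidate (the missed
    # event itself) so it is not double-counted as a true negative
    missed = np.array([g for i, g in enumerate(gt_times) if i not in matched_g])
    _, absorbed = greedy(missed, rest_t)
    tn = len(rest) - len(absorbed)
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn, epsilon_s=epsilon_s)


def match_events_per_cell(
    events: EventSet,
    gt: GroundTruthMarks,
    sample_period_s: float = 3.0,
    epsilon_s: float = DEFAULT_EPSILON_S,
) -> dict[str, ConfusionCounts]:
    """Per-cell confusion counts under the +/- epsilon protocol."""
    if epsilon_s < 0:
        raise ValidationError("epsilon_s must be >= 0")
    out = {}
    for cid, evs in events.events.items():
        out[cid] = _match_cell(evs, gt.times_for(cid), sample_period_s, epsilon_s)
    return out


def match_events(
    events: EventSet,
    gt: GroundTruthMarks,
    sample_period_s: float = 3.0,
    epsilon_s: float = DEFAULT_EPSILON_S,
) -> ConfusionCounts:
    """Dataset-level confusion counts (sum over cells)."""
    per_cell = match_events_per_cell(events, gt, sample_period_s, epsilon_s)
    total = ConfusionCounts(epsilon_s=epsilon_s)
    for c in per_cell.values():
        total = total + c
    return total


def _safe_ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        warnings.warn(f"{name} undefined (zero denominator)", RuntimeWarning,
                      stacklevel=3)
        return float("nan")
    return num / den


def metrics_from_counts(counts: ConfusionCounts) -> MetricTriple:
    """Sensitivity, specificity, accuracy; NaN on empty denominators."""
    return MetricTriple(
        sensitivity=_safe_ratio(counts.tp, counts.tp + counts.fn, "sensitivity"),
        specificity=_safe_ratio(counts.tn, counts.tn + counts.fp, "specificity"),
        accuracy=_safe_ratio(counts.tp + counts.tn, counts.total, "accuracy"),
    )


def baseline_noise_std(
    raw: Recording,
    injury: InjuryEstimate,
    sg_window: int = 11,
    sg_polyorder: int = 3,
) -> np.ndarray:
    """Per-cell baseline noise std: residual from the smoothed trace over
    the pre-injury frames."""
    if injury.injury_frame < 3:
        raise ValidationError("pre-injury baseline shorter than 3 samples")
    smooth = SavGolSmoother(sg_window, sg_polyorder).fit(raw).transform(raw)
    resid = raw.traces[:, : injury.injury_frame] \
        - smooth.traces[:, : injury.injury_frame]
    return resid.std(axis=1)


def sigma_bn_detect(
    rec: Recording,
    n_sigma: float,
    mode: str,
    injury: InjuryEstimate,
    raw: Recording | None = None,
    sg_window: int = 11,
    sg_polyorder: int = 3,
) -> EventSet:
    """Comparator detector thresholding LP at ``n_sigma * sigma_bn``.

    ``rec`` holds the preprocessed traces candidates are scored on; ``raw``
    (default ``rec``) supplies the unsmoothed traces the baseline noise is
    measured from. ``mode``: ``per_icp`` uses each cell's own sigma,
    ``lowest_noise`` uses the dataset minimum for every cell.
    """
    if n_sigma <= 0:
        raise ValidationError("n_sigma must be positive")
    if mode not in ("per_icp", "lowest_noise"):
        raise ValidationError(f"unknown sigma mode {mode!r}")
    sigma = baseline_noise_std(raw if raw is not None else rec, injury,
                               sg_window, sg_polyorder)
    if mode == "lowest_noise":
        sigma = np.full_like(sigma, sigma.min())
    thresholds = dict(zip(rec.cell_ids, n_sigma * sigma))
    candidates = detect_candidates(rec)
    return EventSet({
        cid: [replace(e, above_threshold=e.lp >= thresholds[cid]) for e in evs]
        for cid, evs in candidates.events.items()
    })


class SigmaBaselineDetector:
    """sklearn-style wrapper for the sigma_bn comparator.

    ``fit(X)`` requires an injury estimate (pass via ``injury`` parameter);
    sets ``events_`` and ``thresholds_``.
    """

    def __init__(self, n_sigma: float = 3.0, mode: str = "per_icp",
                 injury: InjuryEstimate | None = None,
                 sg_window: int = 11, sg_polyorder: int = 3):
        self.n_sigma = n_sigma
        self.mode = mode
        self.injury = injury
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder

    def get_params(self, deep: bool = True) -> dict:
        return {"n_sigma": self.n_sigma, "mode": self.mode,
                "injury": self.injury, "sg_window": self.sg_window,
                "sg_polyorder": self.sg_polyorder}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, X: Recording, y=None, raw: Recording | None = None):
        if self.injury is None:
            raise ValidationError("SigmaBaselineDetector needs an injury estimate")
        sigma = baseline_noise_std(raw if raw is not None else X, self.injury,
                                   self.sg_window, self.sg_polyorder)
        if self.mode == "lowest_noise":
            sigma = np.full_like(sigma, sigma.min())
        self.thresholds_ = dict(zip(X.cell_ids, self.n_sigma * sigma))
        self.events_ = sigma_bn_detect(X, self.n_sigma, self.mode, self.injury,
                                       raw, self.sg_window, self.sg_polyorder)
        return self


@dataclass
class ClassificationReport:
    """Per-class and overall accuracy of the 4-class labelling."""

    per_class_accuracy: dict[int, float]
    per_class_total: dict[int, int]
    overall_accuracy: float
    error_percent: float
    n_correct: int
    n_total: int
    with_artifact_detection: bool = True


def classification_report(
    pred: dict[str, ClassLabel],
    truth: dict[str, ClassLabel],
    with_ad: bool = True,
) -> ClassificationReport:
    """Score predicted labels against ground-truth labels.

    Per-class accuracy is correct/total within each ground-truth class;
    error % = 100 * (1 - overall accuracy). Running this twice, with and
    without artifact filtering, gives the paired error comparison used to
    quantify the benefit of artifact rejection.
    """
    if set(pred) != set(truth):
        raise ValidationError("predicted and truth cell sets differ")
    per_ok: dict[int, int] = {c: 0 for c in range(4)}
    per_n: dict[int, int] = {c: 0 for c in range(4)}
    correct = 0
    for cid, t in truth.items():
        per_n[t.code] += 1
        if pred[cid].code == t.code:
            per_ok[t.code] += 1
            correct += 1
    n = len(truth)
    acc = correct / n if n else float("nan")
    return ClassificationReport(
        per_class_accuracy={
            c: (per_ok[c] / per_n[c]) if per_n[c] else float("nan")
            for c in range(4)
        },
        per_class_total=per_n,
        overall_accuracy=acc,
        error_percent=100.0 * (1.0 - acc) if n else float("nan"),
        n_correct=correct,
        n_total=n,
        with_artifact_detection=with_ad,
    )


def metrics_table(rows: list[dict]) -> pd.DataFrame:
    """Assemble a sweep of metric rows into the standard report layout:
    threshold x (sensitivity, specificity, accuracy) x (max, min, mean)."""
    return pd.DataFrame(rows).set_index(["method", "threshold"])


def sweep_metrics(
    datasets: list[tuple[EventSet, GroundTruthMarks, float]],
    method: str,
    threshold: float,
    epsilon_s: float = DEFAULT_EPSILON_S,
) -> dict:
    """One sweep row: max/min/mean of each metric across datasets."""
    triples = []
    for events, gt, ts in datasets:
        triples.append(metrics_from_counts(match_events(events, gt, ts, epsilon_s)))
    row = {"method": method, "threshold": threshold}
    for name in ("sensitivity", "specificity", "accuracy"):
        vals = np.array([getattr(t, name) for t in triples], dtype=float)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            row[f"{name}_max"] = float(np.nanmax(vals))
            row[f"{name}_min"] = float(np.nanmin(vals))
            row[f"{name}_mean"] = float(np.nanmean(vals))
    return row
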