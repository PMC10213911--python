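"""Left-prominence event detection.

A candidate Ca2+ event is a local maximum paired with the closest local
minimum strictly to its left; its left prominence

    LP_k = lmax_k - lmin_k

is the detection score, and a candidate is a true event when
``LP >= lp_threshold`` (inclusive) and it is not inside an artifact region.
Unlike baseline-noise n-sigma thresholds, LP needs no basal-noise segment,
which makes it robust when the basal stage is short or artifact-laden.

Extrema use strict comparisons with plateaus collapsed to their leftmost
sample, so maxima and minima strictly alternate and each maximum has a
unique left partner. Boundary samples are never extrema; a leading maximum
with no interior minimum to its left is ignored.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .datatypes import (
    CandidateEvent,
    EventSet,
    GroundTruthMarks,
    Recording,
    ValidationError,
)

__all__ = [
    "find_extrema",
    "pair_and_score",
    "detect_candidates",
    "threshold_events",
    "lp_histogram",
    "suggest_threshold",
    "LeftProminenceDetector",
]

DEFAULT_LP_THRESHOLD = 0.024
DEFAULT_HIST_BIN_WIDTH = 0.001


def find_extrema(trace: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interior local maxima and minima of one profile.

    Returns ``(maxima, minima)`` as int arrays of frame indices. Plateaus
    collapse to their leftmost sample; traces shorter than 3 samples have
    no extrema.
    """
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValidationError("find_extrema expects a single trace")
    if x.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)

    # collapse runs of equal values to their leftmost sample
    keep = np.ones(x.size, dtype=bool)
    keep[1:] = x[1:] != x[:-1]
    idx = np.flatnonzero(keep)
    v = x[idx]
    if v.size < 3:
        return np.empty(0, dtype=int), np.empty(0, dtype=int)
    rising = v[1:] > v[:-1]  # sign of each compressed step
    interior = slice(1, v.size - 1)
    is_max = rising[:-1] & ~rising[1:]
    is_min = ~rising[:-1] & rising[1:]
    maxima = idx[interior][is_max]
    minima = idx[interior][is_min]
    return maxima, minima


def pair_and_score(
    trace: np.ndarray,
    maxima: np.ndarray,
    minima: np.ndarray,
    cell_id: str = "cell",
) -> list[CandidateEvent]:
    """Pair each maximum with its closest left minimum and score LP.

    Maxima with no interior minimum to their left (at the recording start)
    are dropped. Candidates are returned sorted by maximum index.
    """
    x = np.asarray(trace, dtype=float)
    minima = np.asarray(minima, dtype=int)
    out: list[CandidateEvent] = []
    for m in np.sort(np.asarray(maxima, dtype=int)):
        pos = np.searchsorted(minima, m)
        if pos == 0:
            continue  # leading maximum without a left minimum
        lm = int(minima[pos - 1])
        out.append(
            CandidateEvent(
                cell_id=cell_id,
                max_index=int(m),
                min_index=lm,
                lp=float(x[m] - x[lm]),
                value_max=float(x[m]),
                value_min=float(x[lm]),
            )
        )
    return out


def detect_candidates(rec: Recording) -> EventSet:
    """All candidate events of a recording (no threshold applied yet)."""
    events = {}
    for cid, trace in zip(rec.cell_ids, rec.traces):
        maxima, minima = find_extrema(trace)
        events[cid] = pair_and_score(trace, maxima, minima, cid)
    return EventSet(events)


def threshold_events(candidates: EventSet, lp_threshold: float) -> EventSet:
    """Flag candidates with ``lp >= lp_threshold`` (inclusive).

    Every candidate is retained — sub-threshold candidates become the true
    negatives of the evaluation accounting.
    """
    if lp_threshold < 0:
        raise ValidationError("lp_threshold must be >= 0")
    return candidates.map(
        lambda e: replace(e, above_threshold=e.lp >= lp_threshold)
    )


def _match_gt_lps(
    candidates: EventSet,
    gt: GroundTruthMarks,
    sample_period_s: float,
    epsilon_s: float,
) -> np.ndarray:
    """LP of the candidate nearest (within epsilon) to each GT mark."""
    lps = []
    for cell, times in gt.marks.items():
        evs = candidates.cell(cell)
        if not evs:
            continue
        ev_t = np.array([e.max_index * sample_period_s for e in evs])
        for t in times:
            d = np.abs(ev_t - t)
            j = int(np.argmin(d))
            if d[j] <= epsilon_s:
                lps.append(evs[j].lp)
    return np.asarray(lps)


def lp_histogram(
    candidates: EventSet,
    gt: GroundTruthMarks | None = None,
    bin_width: float = DEFAULT_HIST_BIN_WIDTH,
    sample_period_s: float = 3.0,
    epsilon_s: float = 10.0,
):
    """Histogram of LP values, overall and (optionally) GT-matched.

    Returns ``(edges, counts_all, counts_gt)``; ``counts_gt`` is None when
    no ground truth is given. Overlaying the two histograms is how a
    threshold is chosen: below the GT mode the candidate histogram is
    dominated by non-events.
    """
    lps = np.array([e.lp for e in candidates])
    if lps.size == 0:
        raise ValidationError("no candidates to histogram")
    n_bins = max(1, int(np.ceil(lps.max() / bin_width)))
    edges = np.arange(n_bins + 1) * bin_width
    counts_all, _ = np.histogram(lps, bins=edges)
    counts_gt = None
    if gt is not None:
        gt_lps = _match_gt_lps(candidates, gt, sample_period_s, epsilon_s)
        counts_gt, _ = np.histogram(gt_lps, bins=edges)
    return edges, counts_all, counts_gt


def suggest_threshold(
    candidates: EventSet,
    gt: GroundTruthMarks,
    bin_width: float = DEFAULT_HIST_BIN_WIDTH,
    sample_period_s: float = 3.0,
    epsilon_s: float = 10.0,
) -> float:
    """Lower edge of the modal LP bin of ground-truth-matched candidates.

    The most frequent small true events set the working point; ties take
    the lowest bin.
    """
    edges, _, counts_gt = lp_histogram(
        candidates, gt, bin_width, sample_period_s, epsilon_s
    )
    if counts_gt is None or counts_gt.sum() == 0:
        raise ValidationError(
            "no ground-truth-matched candidates; cannot suggest a threshold")
    return float(edges[int(np.argmax(counts_gt))])


class LeftProminenceDetector(BaseEstimator):
    """Candidate detection + LP thresholding as a fit-shaped estimator.

    ``fit(X)`` computes candidates on the given (already preprocessed)
    traces and applies the inclusive LP threshold.

    Attributes
    ----------
    events_ : EventSet
        All candidates with ``above_threshold`` flags set.
    n_candidates_, n_above_threshold_ : int
    """

    def __init__(self, lp_threshold: float = DEFAULT_LP_THRESHOLD,
                 sample_period_s: float = 3.0):
        self.lp_threshold = lp_threshold
        self.sample_period_s = sample_period_s

    def _as_recording(self, X) -> Recording:
        if isinstance(X, Recording):
            return X
        mat = np.asarray(X, dtype=float)
        return Recording(mat, [f"cell_{i + 1:04d}" for i in range(mat.shape[0])],
                         self.sample_period_s)

    def fit(self, X, y=None):
        rec = self._as_recording(X)
        self.events_ = threshold_events(detect_candidates(rec), self.lp_threshold)
        self.n_candidates_ = self.events_.n_candidates
        self.n_above_threshold_ = self.events_.n_above_threshold
        self.n_features_in_ = rec.n_frames
        return self

    def predict(self, X=None) -> list[np.ndarray]:
        """Above-threshold event frames (max indices) per cell."""
        check_is_fitted(self, "events_")
        return [
            np.array([e.max_index for e in evs if e.above_threshold], dtype=int)
            for evs in self.events_.events.values()
        ]
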