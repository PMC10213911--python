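"""End-to-end analysis: preprocess -> detect -> reject artifacts -> classify.

`IcpEventClassifier` is the one-stop estimator: ``fit(X)`` runs the whole
chain on a cells x frames matrix (or :class:`Recording`) and exposes every
intermediate product as a fitted attribute; ``fit_predict`` returns the
per-cell 4-class codes, clustering-style (no supervised training is
involved).
"""

from __future__ import annotations

import logging

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import artifact as _artifact
from . import classify as _classify
from . import detect as _detect
from . import preprocess as _preprocess
from .datatypes import (
    ArtifactMask,
    EventSet,
    InjuryEstimate,
    NoInjurySignatureError,
    Recording,
)

logger = logging.getLogger(__name__)

__all__ = ["IcpEventClassifier"]


class IcpEventClassifier(BaseEstimator):
    """Detect true Ca2+ events and assign 4-class labels to every ICP.

    Stages (each switchable): Savitzky-Golay smoothing; global linear
    photobleaching compensation; left-prominence candidate detection and
    inclusive thresholding; injury-frame estimation from coherent first
    differences of the unsmoothed traces; per-frame event-frequency
    artifact rejection (disabled for 90 s after injury); 20 %-rise
    anchoring of early post-injury events; binary-coded classification
    from basal/response-region activity.

    Parameters default to the published working point: 11/3 smoother,
    lp_threshold 0.024, th_diff 0.040, shift k = 10, Ts = 3 s, 90-s
    windows, 20 % rise fraction.

    Attributes (after ``fit``)
    --------------------------
    recording_, processed_ : Recording
        Raw input and its preprocessed version.
    injury_ : InjuryEstimate
    events_ : EventSet
        All candidates with threshold/artifact/shift flags resolved.
    artifact_mask_ : ArtifactMask
    class_labels_ : dict[str, ClassLabel]
    labels_ : ndarray of int
        Class codes in input row order.
    """

    def __init__(
        self,
        sample_period_s: float = 3.0,
        sg_window: int = 11,
        sg_polyorder: int = 3,
        enable_smoothing: bool = True,
        enable_bleach_compensation: bool = True,
        bleach_n_lowest: int = 20,
        lp_threshold: float = _detect.DEFAULT_LP_THRESHOLD,
        th_diff: float = _artifact.DEFAULT_TH_DIFF,
        shift_k: int = _artifact.DEFAULT_SHIFT_K,
        injury_frame_override: int | None = None,
        enable_artifact_detection: bool = True,
        th_art: float = _artifact.DEFAULT_TH_ART_FRACTION,
        th_art_mode: str = "fraction",
        artifact_dilation: int = _artifact.DEFAULT_DILATION,
        disabled_window_s: float = _artifact.DEFAULT_DISABLED_WINDOW_S,
        rise_fraction: float = _classify.DEFAULT_RISE_FRACTION,
        shift_window_s: float = _classify.DEFAULT_SHIFT_WINDOW_S,
    ):
        self.sample_period_s = sample_period_s
        self.sg_window = sg_window
        self.sg_polyorder = sg_polyorder
        self.enable_smoothing = enable_smoothing
        self.enable_bleach_compensation = enable_bleach_compensation
        self.bleach_n_lowest = bleach_n_lowest
        self.lp_threshold = lp_threshold
        self.th_diff = th_diff
        self.shift_k = shift_k
        self.injury_frame_override = injury_frame_override
        self.enable_artifact_detection = enable_artifact_detection
        self.th_art = th_art
        self.th_art_mode = th_art_mode
        self.artifact_dilation = artifact_dilation
        self.disabled_window_s = disabled_window_s
        self.rise_fraction = rise_fraction
        self.shift_window_s = shift_window_s

    def _as_recording(self, X) -> Recording:
        if isinstance(X, Recording):
            return X
        mat = np.asarray(X, dtype=float)
        return Recording(mat, [f"cell_{i + 1:04d}" for i in range(mat.shape[0])],
                         self.sample_period_s)

    def fit(self, X, y=None):
        rec = self._as_recording(X)
        self.recording_ = rec

        proc = rec
        if self.enable_smoothing:
            proc = _preprocess.smooth_traces(proc, self.sg_window,
                                             self.sg_polyorder)
        if self.enable_bleach_compensation:
            model = _preprocess.estimate_mean_bleach_slope(
                proc, self.bleach_n_lowest)
            proc = _preprocess.compensate_bleach(proc, model)
            self.bleach_model_ = model
        self.processed_ = proc

        # the step statistic lives in single-frame differences, which the
        # smoother flattens fivefold -- estimate injury on the raw traces
        if self.injury_frame_override is not None:
            self.injury_ = InjuryEstimate(
                injury_frame=self.injury_frame_override,
                sample_period_s=rec.sample_period_s,
                th_diff=self.th_diff, shift_k=self.shift_k)
        else:
            self.injury_ = _artifact.estimate_injury_frame(
                rec, self.th_diff, self.shift_k)

        events = _detect.threshold_events(
            _detect.detect_candidates(proc), self.lp_threshold)
        logger.info("candidates: %d, above threshold: %d",
                    events.n_candidates, events.n_above_threshold)

        freq = _artifact.event_frequency_per_frame(events, rec.n_frames)
        if self.enable_artifact_detection:
            mask = _artifact.detect_artifact_frames(
                freq, self.th_art, self.injury_, rec.n_cells,
                self.th_art_mode, self.artifact_dilation,
                self.disabled_window_s)
        else:
            mask = ArtifactMask(
                flags=np.zeros(rec.n_frames, dtype=bool),
                th_art_count=float("inf"),
                disabled_window=(self.injury_.injury_frame,
                                 self.injury_.injury_frame))
        self.artifact_mask_ = mask
        self.event_frequency_ = freq

        events = _artifact.filter_artifact_events(events, mask)
        events = _classify.shift_events(proc, events, self.injury_,
                                        self.rise_fraction,
                                        self.shift_window_s)
        self.events_ = events

        self.class_labels_ = _classify.classify_cells(
            events, self.injury_, rec.n_frames)
        self.labels_ = np.array(
            [self.class_labels_[c].code for c in rec.cell_ids], dtype=int)
        n_disc = sum(e.artifact_discarded for e in events)
        logger.info("artifact frames: %d, discarded events: %d",
                    int(mask.flags.sum()), n_disc)
        self.n_features_in_ = rec.n_frames
        return self

    def fit_predict(self, X, y=None) -> np.ndarray:
        """Run the pipeline and return per-cell class codes (0-3)."""
        return self.fit(X).labels_

    def predict(self, X=None) -> np.ndarray:
        """Class codes of the fitted recording."""
        check_is_fitted(self, "labels_")
        return self.labels_
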