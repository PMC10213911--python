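"""Injury-time estimation and coherent-artifact rejection.

The mechanical lesion elicits a near-synchronous Ca2+ step across
responding cells; its onset frame is estimated from the per-frame count of
cells whose first difference exceeds ``th_diff``, taking the earliest
argmax and shifting it ``shift_k`` samples left (the experimentally
determined lag between pipette contact and the synchronized rise).

Non-biological transients (focus adjustment, perfusion switch, tissue
displacement) also hit many cells at once. Frames where the count of cells
holding an above-threshold event reaches ``th_art`` are flagged as
artifact, dilated by one frame to absorb smoothing jitter — except inside
the 90-s window after injury, where genuine responses are just as coherent
and artifact detection is disabled.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import (
    ArtifactMask,
    EventSet,
    InjuryEstimate,
    NoInjurySignatureError,
    Recording,
    ValidationError,
)

__all__ = [
    "estimate_injury_frame",
    "event_frequency_per_frame",
    "detect_artifact_frames",
    "filter_artifact_events",
    "disabled_window_frames",
    "InjuryFrameEstimator",
]

DEFAULT_TH_DIFF = 0.040
DEFAULT_SHIFT_K = 10
DEFAULT_TH_ART_FRACTION = 0.30
DEFAULT_DISABLED_WINDOW_S = 90.0
DEFAULT_DILATION = 1


def disabled_window_frames(sample_period_s: float,
                           disabled_window_s: float = DEFAULT_DISABLED_WINDOW_S) -> int:
    """Length of the post-injury disabled window in frames (90 s default)."""
    return int(round(disabled_window_s / sample_period_s))


def estimate_injury_frame(
    rec: Recording,
    th_diff: float = DEFAULT_TH_DIFF,
    shift_k: int = DEFAULT_SHIFT_K,
) -> InjuryEstimate:
    """Estimate the injury frame from coherent first-difference activity.

    ``c(i)`` counts cells with ``trace(i) - trace(i-1) > th_diff``; the
    injury frame is ``argmax_i c(i) - shift_k`` (earliest argmax on ties),
    clamped at 0.

    Raises
    ------
    NoInjurySignatureError
        If no cell ever exceeds ``th_diff`` (the caller may then supply an
        injury frame manually).
    """
    if th_diff <= 0:
        raise ValidationError("th_diff must be positive")
    diffs = np.diff(rec.traces, axis=1) > th_diff
    counts = np.zeros(rec.n_frames, dtype=int)
    counts[1:] = diffs.sum(axis=0)
    if counts.max() == 0:
        raise NoInjurySignatureError(
            "no frame shows any suprathreshold first difference")
    argmax = int(np.argmax(counts))  # earliest on ties
    frame = max(argmax - shift_k, 0)
    return InjuryEstimate(
        injury_frame=frame,
        sample_period_s=rec.sample_period_s,
        th_diff=th_diff,
        shift_k=shift_k,
        counts=counts,
    )


def event_frequency_per_frame(events: EventSet, n_frames: int) -> np.ndarray:
    """f(i) = number of cells with an above-threshold candidate peaking at i."""
    freq = np.zeros(n_frames, dtype=int)
    for cell_events in events.events.values():
        frames = {e.max_index for e in cell_events if e.above_threshold}
        for i in frames:
            freq[i] += 1
    return freq


def resolve_th_art(th_art: float, n_cells: int, mode: str = "fraction") -> float:
    """Absolute event-frequency threshold in cells per frame."""
    if th_art <= 0:
        raise ValidationError("th_art must be positive")
    if mode == "fraction":
        return th_art * n_cells
    if mode == "count":
        return th_art
    raise ValidationError(f"unknown th_art mode {mode!r}")


def detect_artifact_frames(
    freq: np.ndarray,
    th_art: float,
    injury: InjuryEstimate,
    n_cells: int,
    th_art_mode: str = "fraction",
    dilation: int = DEFAULT_DILATION,
    disabled_window_s: float = DEFAULT_DISABLED_WINDOW_S,
) -> ArtifactMask:
    """Flag frames whose event frequency reaches the artifact threshold.

    Flags are dilated by ``dilation`` frames on each side, then the
    disabled window ``[injury_frame, injury_frame + round(90 s / Ts))`` is
    cleared unconditionally.
    """
    freq = np.asarray(freq)
    n_frames = freq.size
    th_abs = resolve_th_art(th_art, n_cells, th_art_mode)
    win = disabled_window_frames(injury.sample_period_s, disabled_window_s)
    lo, hi = injury.injury_frame, min(injury.injury_frame + win, n_frames)

    flags = freq >= th_abs
    flags[lo:hi] = False
    if dilation > 0 and flags.any():
        hits = np.flatnonzero(flags)
        for h in hits:
            flags[max(h - dilation, 0): h + dilation + 1] = True
        flags[lo:hi] = False  # the disabled window is absolute
    return ArtifactMask(flags=flags, th_art_count=th_abs,
                        disabled_window=(lo, hi))


def filter_artifact_events(events: EventSet, mask: ArtifactMask) -> EventSet:
    """Mark events peaking inside artifact regions as discarded.

    Only flags change — lp values and candidate counts are preserved for
    auditability; discarded events are excluded downstream from
    classification and from true-event evaluation.
    """
    return events.map(
        lambda e: replace(e, artifact_discarded=bool(mask.flags[e.max_index]))
    )


class InjuryFrameEstimator(BaseEstimator):
    """Fit-shaped wrapper around :func:`estimate_injury_frame`.

    Attributes
    ----------
    injury_frame_ : int
    estimate_ : InjuryEstimate
    """

    def __init__(self, th_diff: float = DEFAULT_TH_DIFF,
                 shift_k: int = DEFAULT_SHIFT_K,
                 sample_period_s: float = 3.0):
        self.th_diff = th_diff
        self.shift_k = shift_k
        self.sample_period_s = sample_period_s

    def fit(self, X, y=None):
        if not isinstance(X, Recording):
            mat = np.asarray(X, dtype=float)
            X = Recording(mat, [f"cell_{i + 1:04d}" for i in range(mat.shape[0])],
                          self.sample_period_s)
        self.estimate_ = estimate_injury_frame(X, self.th_diff, self.shift_k)
        self.injury_frame_ = self.estimate_.injury_frame
        self.n_features_in_ = X.n_frames
        return self
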