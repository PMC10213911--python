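"""Core containers shared across the analysis stages.

An intracellular Ca2+ profile (ICP) is the per-cell time series of the
Fura-2 340/380 fluorescence ratio; a recording is the cells x frames matrix
of such profiles sampled at a fixed period (0.33 Hz in the motivating
mechanical-injury assay, i.e. Ts = 3 s).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "Recording",
    "GroundTruthMarks",
    "CandidateEvent",
    "EventSet",
    "InjuryEstimate",
    "ArtifactMask",
    "ClassLabel",
    "ConfusionCounts",
    "MetricTriple",
    "FormatError",
    "ValidationError",
    "NoInjurySignatureError",
]


class FormatError(ValueError):
    """A file does not conform to the expected text format."""


class ValidationError(ValueError):
    """Inputs are well-formed but semantically inconsistent."""


class NoInjurySignatureError(RuntimeError):
    """No frame shows any suprathreshold first difference in any cell."""


@dataclass
class Recording:
    """Cells x frames matrix of ratio values with its sample period.

    Parameters
    ----------
    traces : ndarray, shape (n_cells, n_frames)
        340/380 ratio values, arbitrary units. Must be finite.
    cell_ids : list of str
        Unique opaque identifiers, one per row.
    sample_period_s : float
        Seconds per frame (Ts). Frame ``i`` occurs at time ``i * Ts``.
    smoothed, bleach_compensated : bool
        Provenance flags set by the preprocessing stages.
    """

    traces: np.ndarray
    cell_ids: list[str]
    sample_period_s: float = 3.0
    smoothed: bool = False
    bleach_compensated: bool = False

    def __post_init__(self) -> None:
        self.traces = np.asarray(self.traces, dtype=float)
        if self.traces.ndim != 2:
            raise ValidationError("traces must be a 2-D cells x frames matrix")
        if self.traces.shape[1] < 2:
            raise ValidationError("a recording needs at least 2 frames")
        if not np.all(np.isfinite(self.traces)):
            raise ValidationError("traces contain non-finite values")
        if self.sample_period_s <= 0:
            raise ValidationError("sample_period_s must be positive")
        self.cell_ids = [str(c) for c in self.cell_ids]
        if len(self.cell_ids) != self.traces.shape[0]:
            raise ValidationError("cell_ids count does not match trace rows")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValidationError("cell_ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.traces.shape[0]

    @property
    def n_frames(self) -> int:
        return self.traces.shape[1]

    @property
    def duration_s(self) -> float:
        return (self.n_frames - 1) * self.sample_period_s

    def times(self) -> np.ndarray:
        """Frame times in seconds (0-based frame convention)."""
        return np.arange(self.n_frames) * self.sample_period_s

    def trace(self, cell_id: str) -> np.ndarray:
        return self.traces[self.cell_ids.index(cell_id)]


@dataclass
class GroundTruthMarks:
    """Per-cell expert marker times in seconds, sorted ascending.

    Not every profile has events; cells may map to empty arrays.
    """

    marks: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean: dict[str, np.ndarray] = {}
        for cell, t in self.marks.items():
            arr = np.sort(np.asarray(t, dtype=float))
            if arr.size and arr.min() < 0:
                raise ValidationError(f"negative marker time for cell {cell!r}")
            clean[str(cell)] = arr
        self.marks = clean

    @property
    def n_marks(self) -> int:
        return int(sum(len(t) for t in self.marks.values()))

    def times_for(self, cell_id: str) -> np.ndarray:
        return self.marks.get(cell_id, np.empty(0))

    def bind(self, rec: Recording) -> "GroundTruthMarks":
        """Validate against a recording and snap times to the frame grid.

        Expert markers were mouse-placed on continuous plots of discrete
        samples, so each time is snapped to the nearest frame time.
        """
        out: dict[str, np.ndarray] = {c: np.empty(0) for c in rec.cell_ids}
        tmax = rec.duration_s
        for cell, t in self.marks.items():
            if cell not in out:
                raise ValidationError(f"ground-truth cell {cell!r} not in recording")
            if t.size and t.max() > tmax:
                raise ValidationError(
                    f"marker at {t.max():g} s beyond recording end {tmax:g} s"
                )
            frames = np.rint(t / rec.sample_period_s).astype(int)
            out[cell] = np.unique(frames) * rec.sample_period_s
        return GroundTruthMarks(out)


@dataclass
class CandidateEvent:
    """A (left local minimum, local maximum) pair with its left prominence.

    The left prominence ``lp = value_max - value_min`` is the detection
    score; ``report_index`` is the frame used as the event's time anchor
    (the maximum, or the 20 %-rise point for early post-injury events).
    """

    cell_id: str
    max_index: int
    min_index: int
    lp: float
    value_max: float
    value_min: float
    above_threshold: bool = False
    artifact_discarded: bool = False
    shifted: bool = False
    report_index: int = -1

    def __post_init__(self) -> None:
        if self.report_index < 0:
            self.report_index = self.max_index
        if self.min_index >= self.max_index:
            raise ValidationError("left minimum must precede the maximum")
        if self.report_index > self.max_index:
            raise ValidationError("report_index cannot lie right of the maximum")

    @property
    def is_true_event(self) -> bool:
        return self.above_threshold and not self.artifact_discarded

    def report_time_s(self, sample_period_s: float) -> float:
        return self.report_index * sample_period_s


@dataclass
class EventSet:
    """Candidate events grouped per cell, sorted by maximum index."""

    events: dict[str, list[CandidateEvent]]

    def __post_init__(self) -> None:
        for cell, evs in self.events.items():
            self.events[cell] = sorted(evs, key=lambda e: e.max_index)

    def __iter__(self) -> Iterator[CandidateEvent]:
        for evs in self.events.values():
            yield from evs

    @property
    def n_candidates(self) -> int:
        return sum(len(v) for v in self.events.values())

    @property
    def n_above_threshold(self) -> int:
        return sum(e.above_threshold for e in self)

    def cell(self, cell_id: str) -> list[CandidateEvent]:
        return self.events.get(cell_id, [])

    def true_events(self, cell_id: str) -> list[CandidateEvent]:
        return [e for e in self.cell(cell_id) if e.is_true_event]

    def map(self, fn) -> "EventSet":
        """Return a new EventSet with ``fn`` applied to every event."""
        return EventSet(
            {cell: [fn(e) for e in evs] for cell, evs in self.events.items()}
        )

    def replace_flags(self, event: CandidateEvent, **kw) -> CandidateEvent:
        return replace(event, **kw)


@dataclass(frozen=True)
class InjuryEstimate:
    """Estimated onset frame of the mechanical lesion.

    Derived from the shifted argmax of the per-frame count of cells whose
    first difference exceeds ``th_diff``; ``shift_k`` samples are subtracted
    to compensate the lag between pipette contact and the synchronized
    Ca2+ rise.
    """

    injury_frame: int
    sample_period_s: float = 3.0
    th_diff: float = 0.040
    shift_k: int = 10
    counts: np.ndarray | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        if self.injury_frame < 0:
            raise ValidationError("injury_frame must be >= 0")
        if self.th_diff <= 0:
            raise ValidationError("th_diff must be positive")
        if self.shift_k < 0:
            raise ValidationError("shift_k must be >= 0")

    @property
    def injury_time_s(self) -> float:
        return self.injury_frame * self.sample_period_s


@dataclass
class ArtifactMask:
    """Per-frame artifact flags plus the post-injury disabled window.

    No frame inside ``disabled_window`` (half-open frame interval) is ever
    flagged: right after the stimulus genuine responses are as coherent as
    an artifact would be.
    """

    flags: np.ndarray
    th_art_count: float
    disabled_window: tuple[int, int]

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)
        lo, hi = self.disabled_window
        if self.flags[lo:hi].any():
            raise ValidationError("artifact flags inside the disabled window")

    @property
    def n_frames(self) -> int:
        return len(self.flags)

    def flagged_frames(self) -> np.ndarray:
        return np.flatnonzero(self.flags)


@dataclass(frozen=True)
class ClassLabel:
    """Binary-coded 4-class label from basal/response-region activity.

    code = 2 * rr_active + br_active: 0 = silent, 1 = basal only,
    2 = response only, 3 = both.
    """

    br_active: bool
    rr_active: bool

    @property
    def code(self) -> int:
        return 2 * int(self.rr_active) + int(self.br_active)

    @classmethod
    def from_code(cls, code: int) -> "ClassLabel":
        if code not in (0, 1, 2, 3):
            raise ValidationError(f"class code must be 0-3, got {code}")
        return cls(br_active=bool(code & 1), rr_active=bool(code & 2))


@dataclass
class ConfusionCounts:
    """TP/FP/TN/FN under the +/- epsilon tolerance matching."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    epsilon_s: float = 10.0

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.fp + other.fp,
            self.tn + other.tn,
            self.fn + other.fn,
            self.epsilon_s,
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricTriple:
    """Sensitivity, specificity, accuracy; NaN where the denominator is 0."""

    sensitivity: float
    specificity: float
    accuracy: float
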