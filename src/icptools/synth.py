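"""Seeded synthetic ICP recordings with known ground truth.

The generator emulates the mechanical-injury assay regime: ~150 cells and
~250 frames of 340/380 ratio at 0.33 Hz, Gaussian baseline noise, a
negative photobleaching drift, sparse basal Ca2+ transients and
oscillations, a large step-like biphasic response in a fraction of cells
triggered by the injury, and optional coherent multi-cell artifacts.

Every injected event is recorded as a ground-truth mark (at its peak, or
at its 20 %-rise point when it starts within 90 s of the injury, the way
expert marks were placed), and true 4-class labels are derived from the
placed events, so every pipeline stage can be validated without any
external data.

The labelled ``injury_frame`` is the pipette-contact time; the
synchronized Ca2+ rise of responding cells begins ``response_delay_frames``
(default 10, i.e. 30 s) later plus a per-cell propagation latency — the
same lag the injury-frame estimator's experimentally determined shift
``k`` compensates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .artifact import disabled_window_frames
from .datatypes import ClassLabel, GroundTruthMarks, Recording, ValidationError

__all__ = ["SynthConfig", "SynthEvent", "SynthTruth", "event_template",
           "generate_recording"]


@dataclass(frozen=True)
class SynthConfig:
    """Stated world of the synthetic assay. All defaults mirror the
    acquisition regime (Ts = 3 s, hundreds of cells, ~250 frames) and the
    detectability regime the method targets (injected event prominences
    from 0.03 a.u. up, smoothed-noise candidate prominences well below
    0.02 a.u.)."""

    seed: int
    n_cells: int = 150
    n_frames: int = 250
    sample_period_s: float = 3.0
    baseline_level: float = 1.0
    noise_sigma: float = 0.004
    noise_sigma_range: tuple[float, float] | None = None  # heterogeneous cells
    bleach_slope: float = -0.0002  # a.u. per second
    injury_frame: int = 60
    responder_fraction: float = 0.6
    response_delay_frames: int = 10  # lag pipette contact -> Ca2+ rise
    latency_max_s: float = 15.0  # per-cell propagation delay
    response_lp_range: tuple[float, float] = (0.12, 0.35)
    br_event_rate: float = 0.7  # mean basal events per cell
    event_lp_range: tuple[float, float] = (0.03, 0.3)
    oscillation_fraction: float = 0.2  # of basal events
    transient_rise_frames: int = 3
    transient_decay_frames: int = 10
    oscillation_period_frames: int = 12
    oscillation_cycles: int = 2
    biphasic_plateau_frames: int = 30
    biphasic_plateau_level: float = 0.6
    biphasic_decay_frames: int = 40
    artifacts: tuple[tuple[int, float, float], ...] = ()
    # each: (peak frame, affected fraction of cells, amplitude in a.u.)

    def validate(self) -> None:
        for name, frac in (("responder_fraction", self.responder_fraction),
                           ("oscillation_fraction", self.oscillation_fraction)):
            if not 0 <= frac <= 1:
                raise ValidationError(f"{name} must be in [0, 1]")
        if not 0 <= self.injury_frame and self.injury_frame + 30 < self.n_frames:
            pass
        if self.injury_frame < 0 or self.injury_frame + 30 >= self.n_frames:
            raise ValidationError("injury_frame + 30 must fit in the recording")
        for lo, hi in (self.event_lp_range, self.response_lp_range):
            if not (0 < lo <= hi):
                raise ValidationError("amplitude ranges must be positive")
        for frame, frac, amp in self.artifacts:
            if not (0 <= frame < self.n_frames):
                raise ValidationError("artifact frame outside recording")
            if not (0 < frac <= 1) or amp <= 0:
                raise ValidationError("artifact fraction/amplitude invalid")


def event_template(shape: str, lp: float, *, rise_frames: int = 3,
                   decay_frames: int = 10, period_frames: int = 12,
                   cycles: int = 2, plateau_frames: int = 30,
                   plateau_level: float = 0.6) -> np.ndarray:
    """Waveform of one event, starting and ending at exactly 0.

    ``transient``: linear rise over ``rise_frames``, exponential decay with
    time constant ``decay_frames`` (tapered to end at 0); peak equals
    ``lp``. ``biphasic``: abrupt two-frame rise to ``lp``, drop to a slowly
    decaying plateau, then exponential return. ``oscillation``: raised
    cosine with exactly ``cycles`` interior maxima of height ``lp``.
    """
    if lp <= 0:
        raise ValidationError("event amplitude must be positive")
    if shape == "transient":
        if rise_frames <= 0 or decay_frames <= 0:
            raise ValidationError("durations must be positive")
        up = np.linspace(0.0, lp, rise_frames + 1)
        n_tail = decay_frames * 5
        tail = lp * np.exp(-np.arange(1, n_tail + 1) / decay_frames)
        tail -= np.linspace(0.0, tail[-1], n_tail)
        return np.concatenate([up, tail])
    if shape == "oscillation":
        if period_frames <= 1 or cycles <= 0:
            raise ValidationError("durations must be positive")
        t = np.arange(cycles * period_frames + 1)
        return lp * 0.5 * (1.0 - np.cos(2.0 * np.pi * t / period_frames))
    if shape == "biphasic":
        if plateau_frames <= 0 or decay_frames <= 0:
            raise ValidationError("durations must be positive")
        up = np.array([0.0, 0.75 * lp, lp])  # ER-depletion step
        drop = np.linspace(lp, plateau_level * lp, 6)[1:]
        plat = plateau_level * lp * np.exp(
            -np.arange(1, plateau_frames + 1) / (plateau_frames * 6.0))
        n_tail = decay_frames * 3
        tail = plat[-1] * np.exp(-np.arange(1, n_tail + 1) / decay_frames)
        tail -= np.linspace(0.0, tail[-1], n_tail)
        return np.concatenate([up, drop, plat, tail])
    raise ValidationError(f"unknown event shape {shape!r}")


@dataclass(frozen=True)
class SynthEvent:
    """One injected event and where its ground truth was placed."""

    cell_id: str
    shape: str
    onset_frame: int
    peak_frame: int
    lp: float
    mark_frame: int  # peak, or 20%-rise frame for early post-injury events


@dataclass
class SynthTruth:
    """A generated recording together with everything that is true of it."""

    recording: Recording
    gt_marks: GroundTruthMarks
    class_labels: dict[str, ClassLabel]
    injury_frame: int
    events: list[SynthEvent]
    artifacts: tuple[tuple[int, float, float], ...]
    config: SynthConfig
    artifact_cells: dict[int, list[str]] = field(default_factory=dict)


def _basal_templates(cfg: SynthConfig, rng: np.random.Generator):
    """Draw shape + amplitude for one basal event (log-uniform amplitude,
    so near-threshold events of nearly undetectable magnitude exist)."""
    lo, hi = cfg.event_lp_range
    lp = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    if rng.random() < cfg.oscillation_fraction:
        shape = "oscillation"
        w = event_template(shape, lp, period_frames=cfg.oscillation_period_frames,
                           cycles=cfg.oscillation_cycles)
    else:
        shape = "transient"
        w = event_template(shape, lp, rise_frames=cfg.transient_rise_frames,
                           decay_frames=cfg.transient_decay_frames)
    return shape, lp, w


def _peak_frames(shape: str, onset: int, w: np.ndarray, cfg: SynthConfig) -> list[int]:
    if shape == "oscillation":
        half = cfg.oscillation_period_frames // 2
        return [onset + half + i * cfg.oscillation_period_frames
                for i in range(cfg.oscillation_cycles)]
    return [onset + int(np.argmax(w))]


def generate_recording(cfg: SynthConfig) -> SynthTruth:
    """Generate one fully labelled synthetic recording.

    Fully reproducible per ``cfg.seed``. Raises on configs whose events
    cannot fit the recording.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n, f, ts = cfg.n_cells, cfg.n_frames, cfg.sample_period_s
    t = np.arange(f) * ts
    cell_ids = [f"cell_{i + 1:04d}" for i in range(n)]

    if cfg.noise_sigma_range is not None:
        lo, hi = cfg.noise_sigma_range
        sigmas = np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))
    else:
        sigmas = np.full(n, cfg.noise_sigma)

    traces = (cfg.baseline_level
              + cfg.bleach_slope * t[None, :]
              + rng.normal(0.0, 1.0, size=(n, f)) * sigmas[:, None])

    responders = rng.random(n) < cfg.responder_fraction
    latency_max_frames = int(cfg.latency_max_s / ts)
    shift_win = disabled_window_frames(ts)
    if cfg.responder_fraction > 0:
        # the sustained tail may run past the recording end, the response
        # peak may not
        latest_peak = (cfg.injury_frame + cfg.response_delay_frames - 1
                       + latency_max_frames + 3)
        if latest_peak > f:
            raise ValidationError(
                "response events would overlap the recording end")

    events: list[SynthEvent] = []
    marks: dict[str, list[float]] = {cid: [] for cid in cell_ids}
    br_active = np.zeros(n, dtype=bool)
    rr_active = np.zeros(n, dtype=bool)

    def place(j: int, shape: str, onset: int, lp: float, w: np.ndarray) -> None:
        if onset + len(w) > f:
            raise ValidationError("event overlaps the recording end")
        traces[j, onset: onset + len(w)] += w
        for peak in _peak_frames(shape, onset, w, cfg):
            if cfg.injury_frame <= peak < cfg.injury_frame + shift_win:
                rel = np.flatnonzero(w >= 0.2 * lp)
                mark = onset + int(rel[0])
            else:
                mark = peak
            events.append(SynthEvent(cell_ids[j], shape, onset, peak, lp, mark))
            marks[cell_ids[j]].append(mark * ts)
            if peak < cfg.injury_frame:
                br_active[j] = True
            else:
                rr_active[j] = True

    # basal events: peaks kept >= 10 frames clear of the injury so a basal
    # event is never confused with the response by tolerance matching, and
    # full waveform footprints kept disjoint so no event rides the decaying
    # tail of another (overlap erodes the measured prominence)
    for j in range(n):
        n_ev = rng.poisson(cfg.br_event_rate)
        footprints: list[tuple[int, int]] = []
        attempts = 0
        while len(footprints) < n_ev and attempts < 50:
            attempts += 1
            shape, lp, w = _basal_templates(cfg, rng)
            peaks_rel = _peak_frames(shape, 0, w, cfg)
            # earliest onset 15: the smoother spreads a rise ~5 frames
            # left, and the left minimum must stay an interior extremum
            hi_onset = cfg.injury_frame - 10 - max(peaks_rel)
            if hi_onset < 15:
                break
            onset = int(rng.integers(15, hi_onset + 1))
            span = (onset, onset + len(w))
            if any(span[0] < b and a < span[1] for a, b in footprints):
                continue
            place(j, shape, onset, lp, w)
            footprints.append(span)

    # injury response: biphasic rise beginning response_delay after contact
    lo, hi = cfg.response_lp_range
    for j in np.flatnonzero(responders):
        lat = int(rng.integers(0, latency_max_frames + 1)) if latency_max_frames else 0
        lp = float(rng.uniform(lo, hi))
        w = event_template("biphasic", lp,
                           plateau_frames=cfg.biphasic_plateau_frames,
                           plateau_level=cfg.biphasic_plateau_level,
                           decay_frames=cfg.biphasic_decay_frames)
        onset = cfg.injury_frame + cfg.response_delay_frames - 1 + lat
        if onset + len(w) > f:
            w = w[: f - onset]  # plateau tail may run past the recording
        place(j, "biphasic", onset, lp, w)

    # coherent artifacts: short non-biological bumps hitting many cells;
    # the 3-frame rise keeps per-frame differences below th_diff so an
    # artifact does not mimic the injury step itself
    artifact_cells: dict[int, list[str]] = {}
    for frame, frac, amp in cfg.artifacts:
        w = event_template("transient", amp, rise_frames=3, decay_frames=4)
        onset = frame - 3  # template peaks at the scheduled frame
        if onset < 0 or onset + len(w) > f:
            raise ValidationError("artifact waveform outside recording")
        affected = rng.choice(n, size=int(round(frac * n)), replace=False)
        for j in affected:
            traces[j, onset: onset + len(w)] += w
        artifact_cells[frame] = [cell_ids[j] for j in sorted(affected)]

    rec = Recording(traces, cell_ids, ts)
    gt = GroundTruthMarks({c: np.array(v) for c, v in marks.items()})
    labels = {
        cell_ids[j]: ClassLabel(br_active=bool(br_active[j]),
                                rr_active=bool(rr_active[j]))
        for j in range(n)
    }
    return SynthTruth(
        recording=rec,
        gt_marks=gt,
        class_labels=labels,
        injury_frame=cfg.injury_frame,
        events=events,
        artifacts=cfg.artifacts,
        config=cfg,
        artifact_cells=artifact_cells,
    )
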