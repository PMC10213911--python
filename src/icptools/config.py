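"""Pipeline configuration: one flat parameter set, YAML/JSON round-trip.

Every parameter defaults to the published working point (Savitzky-Golay
11/3, lp_threshold 0.024, th_diff 0.040, k 10, Ts 3 s, epsilon 10 s,
90-s windows, 20 % rise fraction).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .datatypes import ValidationError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    sample_period_s: float = 3.0
    sg_window: int = 11
    sg_polyorder: int = 3
    enable_smoothing: bool = True
    enable_bleach_compensation: bool = True
    bleach_n_lowest: int = 20
    lp_threshold: float = 0.024
    hist_bin_width: float = 0.001
    th_diff: float = 0.040
    shift_k: int = 10
    injury_frame_override: int | None = None
    enable_artifact_detection: bool = True
    th_art: float = 0.30
    th_art_mode: str = "fraction"
    artifact_dilation: int = 1
    disabled_window_s: float = 90.0
    rise_fraction: float = 0.2
    shift_window_s: float = 90.0
    epsilon_s: float = 10.0
    n_sigma_list: tuple[float, ...] = (1, 3, 4, 7, 9, 10, 13)
    sigma_mode: str = "per_icp"
    lp_threshold_sweep: tuple[float, ...] = (
        0.020, 0.021, 0.022, 0.023, 0.024, 0.025, 0.026)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_sigma_list"] = list(self.n_sigma_list)
        d["lp_threshold_sweep"] = list(self.lp_threshold_sweep)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("n_sigma_list", "lp_threshold_sweep"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix == ".json"
                else yaml.safe_load(text)) or {}
        return cls.from_dict(data)

    def write(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix == ".json":
            path.write_text(json.dumps(self.to_dict(), indent=1))
        else:
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def estimator_kwargs(self) -> dict:
        """Keyword arguments for :class:`icptools.pipeline.IcpEventClassifier`."""
        keep = ("sample_period_s", "sg_window", "sg_polyorder",
                "enable_smoothing", "enable_bleach_compensation",
                "bleach_n_lowest", "lp_threshold", "th_diff", "shift_k",
                "injury_frame_override", "enable_artifact_detection",
                "th_art", "th_art_mode", "artifact_dilation",
                "disabled_window_s", "rise_fraction", "shift_window_s")
        d = self.to_dict()
        return {k: d[k] for k in keep}
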