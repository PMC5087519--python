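"""Pipeline configuration: defaults, validation, YAML round-trip.

Defaults mirror the acquisition protocol the pipeline emulates: 512 frames
at 12.5 Hz for biospeckle stacks, 65x65-pixel ROI patches, prefix windows
of 10/20/30/40 s, 256 gray levels, and a 2:1 train/prediction split.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # imaging geometry / acquisition
    roi_size: int = 65
    speckle_size: int = 64  # simulated stack side (single-column THSP; scaled down)
    n_frames: int = 512
    frame_rate: float = 12.5
    gray_levels: int = 256
    thsp_column: int | str = "mid"  # "mid" or explicit 0-based index
    windows: tuple = (10.0, 20.0, 30.0, 40.0)
    # synthetic-data conditions
    n_per_class: int = 20
    rho_ss: float = 0.95
    rho_is: float = 0.5
    grain_sigma: float = 1.0
    con: float = 30.9
    channel_sd: float = 8.0
    n_lenticels: int = 5
    # features & classification
    feature_families: tuple = ("color",)
    lssvm_gamma: float = 10.0
    lssvm_sigma: float = 2.0
    n_repeats: int = 50
    train_fraction: float = 2.0 / 3.0
    # reproducibility
    seed: int = 0

    _KNOWN_FAMILIES = ("color", "glcm", "gabor", "dtcwt")

    def validate(self) -> None:
        if self.roi_size < 16 and "dtcwt" in self.feature_families:
            raise ValueError("dtcwt features need roi_size >= 16")
        if self.roi_size < 9 and "gabor" in self.feature_families:
            raise ValueError("gabor features need roi_size >= 9")
        for fam in self.feature_families:
            if fam not in self._KNOWN_FAMILIES:
                raise ValueError(f"unknown feature family {fam!r}")
        if not 0 <= self.rho_ss <= 1 or not 0 <= self.rho_is <= 1:
            raise ValueError("rho values must lie in [0, 1]")
        if self.gray_levels != 256:
            raise ValueError("v1 supports 8-bit imaging only (gray_levels=256)")
        if self.thsp_column != "mid" and (
            not isinstance(self.thsp_column, int) or self.thsp_column < 0
        ):
            raise ValueError("thsp_column must be 'mid' or a non-negative index")
        if self.frame_rate <= 0 or self.n_frames < 2:
            raise ValueError("invalid acquisition settings")
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must lie in (0, 1)")
        for w in self.windows:
            if not isinstance(w, str) and w * self.frame_rate > self.n_frames:
                raise ValueError(
                    f"window {w} s exceeds the {self.n_frames}-frame recording"
                )

    @property
    def column_index(self) -> int | None:
        return None if self.thsp_column == "mid" else int(self.thsp_column)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["windows"] = list(self.windows)
        d["feature_families"] = list(self.feature_families)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("windows", "feature_families"):
            if key in data:
                data[key] = tuple(data[key])
        cfg = cls(**data)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path
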