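"""Flat run configuration with strict key checking.

Every field has a default matching the benchmark protocol: the 44-subject
four-emotion recording design at 256 Hz, db8 wavelet to level 6, 500
hidden nodes, 70/30 stratified split, train-only min-max scaling.  Config
files are flat YAML/key-value documents; unknown keys are rejected by
name rather than ignored.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError
from .experiments import ExperimentConfig
from .synthetic import (
    DEFAULT_CHANNELS,
    DEFAULT_EMOTIONS,
    DatasetDesign,
    well_separated_signatures,
)


@dataclass(frozen=True)
class RunConfig:
    # recording design
    n_subjects: int = 44
    emotions: tuple[str, ...] = DEFAULT_EMOTIONS
    videos_per_emotion: int = 3
    segments_per_video: int = 10
    channels: tuple[str, ...] = DEFAULT_CHANNELS
    sampling_rate: float = 256.0
    segment_seconds: float = 10.0
    # synthetic signatures
    preset: str = "well_separated"
    preset_channel: str = "FP1-F7"
    separation: float = 1.0
    noise_uv: float = 10.0
    subject_sd: float = 0.1
    # decomposition
    wavelet: str = "db8"
    levels: int = 6
    # feature conventions
    variance_mode: str = "population"  # or "sample"
    standardize_mode: str = "segment"  # or "subband" / "none"
    log_epsilon: float = 1e-12
    # classifier
    hidden_count: int = 500
    ridge: float | None = None
    # evaluation
    train_fraction: float = 0.70
    stratified: bool = True
    scaling: str = "train-only"  # or "full-data"
    seed: int = 0
    out_dir: str = "."

    def __post_init__(self) -> None:
        if self.variance_mode not in ("population", "sample"):
            raise ConfigurationError("variance_mode must be 'population' or 'sample'")
        if self.standardize_mode not in ("segment", "subband", "none"):
            raise ConfigurationError(
                "standardize_mode must be 'segment', 'subband' or 'none'"
            )
        if self.scaling not in ("train-only", "full-data"):
            raise ConfigurationError("scaling must be 'train-only' or 'full-data'")
        if self.preset not in ("well_separated",):
            raise ConfigurationError(f"unknown preset {self.preset!r}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown configuration key(s): {', '.join(sorted(unknown))}"
            )
        if "emotions" in data:
            data["emotions"] = tuple(data["emotions"])
        if "channels" in data:
            data["channels"] = tuple(data["channels"])
        return cls(**data)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text(encoding="utf-8")
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: config must be a flat key-value document")
        return cls.from_mapping(data)

    def design(self) -> DatasetDesign:
        return DatasetDesign(
            n_subjects=self.n_subjects,
            emotions=self.emotions,
            videos_per_emotion=self.videos_per_emotion,
            segments_per_video=self.segments_per_video,
            channels=self.channels,
            sampling_rate=self.sampling_rate,
            segment_seconds=self.segment_seconds,
        )

    def signatures(self):
        return well_separated_signatures(
            self.design(),
            channel=self.preset_channel,
            separation=self.separation,
            noise_uv=self.noise_uv,
            subject_sd=self.subject_sd,
        )

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            hidden_count=self.hidden_count,
            ridge=self.ridge,
            train_fraction=self.train_fraction,
            stratified=self.stratified,
            scaling=self.scaling,
            seed=self.seed,
        )

    @property
    def variance_ddof(self) -> int:
        return 0 if self.variance_mode == "population" else 1

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        """Stable hash of the scientific configuration (``out_dir``, a mere
        destination, excluded), for provenance blocks."""
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
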