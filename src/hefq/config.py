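"""Run configuration: strict YAML schema over the pipeline's stage settings."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from hefq.core import ScanGeometry

__all__ = ["RunConfig", "load_config"]


def _from_mapping(cls, mapping: dict, context: str):
    """Build a dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {context}: {sorted(unknown)}")
    return cls(**mapping)


@dataclass(frozen=True)
class SynthVolumeConfig:
    n_volumes: int = 3
    n_blobs: int = 12
    blob_contrast_sd: float = 6.0
    noise_sd: float = 0.04
    n_fluid: int = 2


@dataclass(frozen=True)
class SynthCohortConfig:
    n_eyes: int = 260
    visit_noise_sd: float = 0.25
    missing_rate: float = 0.10
    low_signal_rate: float = 0.05
    zero_baseline_rate: float = 0.03


@dataclass(frozen=True)
class SegmentConfig:
    method: str = "reference"  # reference | learned
    surfaces: str = "supplied"  # supplied | gradient
    k_sd: float = 3.0


@dataclass(frozen=True)
class QuantifyConfig:
    min_size: int = 3
    connectivity: int = 8
    center: str = "auto"  # "auto" or "x_mm,y_mm"


@dataclass(frozen=True)
class AnalyzeConfig:
    bonferroni_m: int = 4
    screen_threshold: float = 0.10
    entry_p: float = 0.05
    removal_p: float = 0.10
    vif_max: float = 5.0


@dataclass(frozen=True)
class RunConfig:
    """Fully-resolved configuration for one pipeline run."""

    geometry: ScanGeometry = field(default_factory=ScanGeometry)
    synth_volume: SynthVolumeConfig = field(default_factory=SynthVolumeConfig)
    synth_cohort: SynthCohortConfig = field(default_factory=SynthCohortConfig)
    segment: SegmentConfig = field(default_factory=SegmentConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    analyze: AnalyzeConfig = field(default_factory=AnalyzeConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        blocks = {
            "geometry": ScanGeometry,
            "synth_volume": SynthVolumeConfig,
            "synth_cohort": SynthCohortConfig,
            "segment": SegmentConfig,
            "quantify": QuantifyConfig,
            "analyze": AnalyzeConfig,
        }
        unknown = set(d) - set(blocks) - {"seed"}
        if unknown:
            raise ValueError(f"unknown top-level config keys: {sorted(unknown)}")
        kwargs: dict = {}
        for name, block_cls in blocks.items():
            if name in d:
                if name == "geometry":
                    kwargs[name] = _from_mapping(ScanGeometry, d[name], "geometry")
                else:
                    kwargs[name] = _from_mapping(block_cls, d[name], name)
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration (strict: unknown keys fail)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return RunConfig.from_dict(data)
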