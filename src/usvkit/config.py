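"""Run configuration: one YAML document covering every pipeline stage.

The config round-trips losslessly through YAML; every default is the
corresponding dataclass default, so an empty file is a valid config.
Outputs embed ``config_hash`` so runs are attributable to their exact
parameterization.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .calls import DetectionParams, FeatureParams
from .taxonomy import TaxonomyThresholds


@dataclass(frozen=True)
class SpectroParams:
    fft_len: int = 256
    overlap: float = 0.5
    window: str = "hamming"
    cutoff_hz: float = 20000.0


@dataclass(frozen=True)
class StatsParams:
    alpha: float = 0.05
    ss_type: str = "III"


@dataclass(frozen=True)
class SynthParams:
    """Session-simulation knobs used by the ``simulate`` command."""

    sample_rate_hz: float = 250000.0
    n_calls: int = 10
    snr_db: float = 30.0
    background_noise_rms: float = 0.01
    cohort_noise_model: str = "negbin"
    cohort_baseline_mean: float = 40.0
    cohort_dispersion: float = 8.0
    cohort_gaussian_sd: float = 12.0


@dataclass(frozen=True)
class RunConfig:
    spectro: SpectroParams = field(default_factory=SpectroParams)
    detection: DetectionParams = field(default_factory=DetectionParams)
    features: FeatureParams = field(default_factory=FeatureParams)
    taxonomy: TaxonomyThresholds = field(default_factory=TaxonomyThresholds)
    stats: StatsParams = field(default_factory=StatsParams)
    synth: SynthParams = field(default_factory=SynthParams)
    seed: int = 0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(
            spectro=SpectroParams(**d.get("spectro", {})),
            detection=DetectionParams(**d.get("detection", {})),
            features=FeatureParams(**d.get("features", {})),
            taxonomy=TaxonomyThresholds(**d.get("taxonomy", {})),
            stats=StatsParams(**d.get("stats", {})),
            synth=SynthParams(**d.get("synth", {})),
            seed=int(d.get("seed", 0)),
            log_level=str(d.get("log_level", "INFO")),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        d = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(d)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]
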