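"""Pipeline configuration: one YAML-serializable object drives every stage."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .sparcc import SparccParams

__all__ = ["ConsensusConfig", "KeystoneConfig", "TranscriptionConfig", "PipelineConfig"]


@dataclass
class ConsensusConfig:
    n_runs: int = 1000
    subsample_size: int = 50
    alpha: float = 0.05
    min_support_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must be in (0, 1]")
        if not 0 < self.min_support_fraction <= 1:
            raise ValueError("min_support_fraction must be in (0, 1]")


@dataclass
class KeystoneConfig:
    mad_factor: float = 5.0


@dataclass
class TranscriptionConfig:
    k_max: int = 10
    min_cluster_size: int = 3
    n_trees: int = 500
    n_perm: int = 100


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a run: inputs, thresholds, seed.

    The "express" profile scales the subsampling and permutation counts
    down (100 runs, 200 permutations) for quick exploratory runs; the
    canonical profile (1000 runs, 1000 permutations) is the default.
    """

    abundance_path: str | None = None
    functional_path: str | None = None
    metadata_path: str | None = None
    output_dir: str = "keystonenet_out"
    ranks: list[str] = field(default_factory=lambda: ["species"])
    min_prevalence: float = 0.20
    sparcc: SparccParams = field(default_factory=SparccParams)
    consensus: ConsensusConfig = field(default_factory=ConsensusConfig)
    keystone: KeystoneConfig = field(default_factory=KeystoneConfig)
    transcription: TranscriptionConfig = field(default_factory=TranscriptionConfig)
    seed: int = 0

    @classmethod
    def express(cls, **overrides) -> "PipelineConfig":
        cfg = cls(**overrides)
        cfg.sparcc = SparccParams(iterations=20, n_permutations=200)
        cfg.consensus = ConsensusConfig(n_runs=100, subsample_size=50)
        return cfg

    # -- serialization ---------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "sparcc" in data and isinstance(data["sparcc"], dict):
            data["sparcc"] = SparccParams(**data["sparcc"])
        if "consensus" in data and isinstance(data["consensus"], dict):
            data["consensus"] = ConsensusConfig(**data["consensus"])
        if "keystone" in data and isinstance(data["keystone"], dict):
            data["keystone"] = KeystoneConfig(**data["keystone"])
        if "transcription" in data and isinstance(data["transcription"], dict):
            data["transcription"] = TranscriptionConfig(**data["transcription"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
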