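"""Run configuration: a YAML-serializable bundle of all stage parameters."""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .metagene import MetageneConfig
from .pauses import PauseConfig
from .processing import ProcessingConfig

__all__ = ["RunConfig", "config_hash"]


@dataclass
class RunConfig:
    """Paths and stage parameters for a full pipeline run.

    Paths left empty are filled by the packaged fixtures (`fixture: human-like`
    or `fixture: toy`).
    """

    fixture: str = "human-like"
    genome_fasta: str = ""
    gene_table: str = ""
    topology_table: str = ""
    records: str = ""
    output_dir: str = "results"
    seed: int = 1
    total_reads: int = 100_000
    n_replicates: int = 3
    polya_len: int = 10
    kd_target: str = ""
    kd_scale: float = 1.0
    processing: ProcessingConfig = field(default_factory=ProcessingConfig)
    metagene: MetageneConfig = field(default_factory=MetageneConfig)
    pauses: PauseConfig = field(default_factory=PauseConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        proc = ProcessingConfig(**data.pop("processing", {}))
        mg = MetageneConfig(**data.pop("metagene", {}))
        pc = PauseConfig(**data.pop("pauses", {}))
        return cls(processing=proc, metagene=mg, pauses=pc, **data)

    def validate_paths(self) -> None:
        for name in ("genome_fasta", "gene_table", "topology_table", "records"):
            value = getattr(self, name)
            if value and not Path(value).exists():
                raise FileNotFoundError(f"{name}: {value} does not exist")


def config_hash(cfg: RunConfig) -> str:
    """Short stable hash identifying the configuration, stamped on outputs."""
    return hashlib.sha256(cfg.to_yaml().encode()).hexdigest()[:12]
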