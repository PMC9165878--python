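"""Run configuration: every tunable of the pipeline with its default.

Defaults equal the protocol's stated values where one exists (gene
detected in >3 cells; 200 < genes/cell < 5000; mito fraction >25% removed;
~2000 variable genes; PCA dims 1:10; clustering resolution 0.5; marker
test min.pct 0.25 and log-fold-change threshold 0.25; normalization scale
10,000; differential filter >2 TPM and two-fold max gap). Round-trips
losslessly through YAML.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .cluster import ClusterParams
from .qc import GeneBlacklist, QCThresholds


@dataclass
class OriginParams:
    min_cells: int = 10
    tau_detect: float = 0.05
    margin: float = 2.0


@dataclass
class DEParams:
    min_tpm: float = 2.0
    min_ratio: float = 2.0
    scale: float = 10_000.0


@dataclass
class DoubletParams:
    tau: float = 1.0
    max_iterations: int = 3


@dataclass
class RunConfig:
    input_dir: str | None = None
    pairs_file: str | None = None
    outdir: str = "graftsc_out"
    seed: int = 0
    log_level: str = "INFO"
    qc: QCThresholds = field(default_factory=QCThresholds)
    blacklist: GeneBlacklist = field(default_factory=GeneBlacklist)
    clustering: ClusterParams = field(default_factory=ClusterParams)
    origin: OriginParams = field(default_factory=OriginParams)
    de: DEParams = field(default_factory=DEParams)
    doublets: DoubletParams = field(default_factory=DoubletParams)
    parenchymal_types: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        for key, typ in (("qc", QCThresholds), ("blacklist", GeneBlacklist),
                         ("clustering", ClusterParams), ("origin", OriginParams),
                         ("de", DEParams), ("doublets", DoubletParams)):
            if key in data and isinstance(data[key], dict):
                data[key] = typ(**data[key])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})
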