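"""Pipeline configuration: validation and YAML loading."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .stoichiometry import OccupancyParams
from .synthetic import SimConfig


@dataclass
class PipelineConfig:
    """End-to-end run configuration.

    In simulate mode (the default) inputs are generated from ``simulation``;
    alternatively FASTA/PSM/PRM paths may point at existing files. All
    thresholds are validated before any computation starts.
    """

    out_dir: str = "eccquant_out"
    seed: int = 0
    experiments: tuple[str, ...] = ("EDL", "soleus", "EOM")
    n_proteins: int = 300
    mean_length: int = 300
    simulation: SimConfig = field(default_factory=SimConfig)
    q_max: float = 0.05
    fold_min: float = 0.2
    min_peptides: int = 2
    spike_fmol_per_ug: float = 10.0
    yield_ug_per_mg: float = 64.5
    oligomers: dict = field(default_factory=dict)
    occupancy: OccupancyParams = field(default_factory=OccupancyParams)
    n_prm_targets: int = 4
    fasta_path: str | None = None
    psm_paths: dict = field(default_factory=dict)
    prm_paths: dict = field(default_factory=dict)
    verbosity: str = "INFO"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if not 0 < self.q_max <= 1:
            raise ValueError(f"q_max must lie in (0, 1], got {self.q_max}")
        if self.fold_min < 0:
            raise ValueError("fold_min must be >= 0")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.spike_fmol_per_ug <= 0 or self.yield_ug_per_mg <= 0:
            raise ValueError("spike and yield must be > 0")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")
        if not self.experiments:
            raise ValueError("at least one experiment is required")
        for mapping in (self.psm_paths, self.prm_paths):
            for name, path in mapping.items():
                if not Path(path).exists():
                    raise FileNotFoundError(f"input for {name!r} not found: {path}")
        if self.fasta_path is not None and not Path(self.fasta_path).exists():
            raise FileNotFoundError(f"FASTA not found: {self.fasta_path}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["experiments"] = list(self.experiments)
        return d

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        sim = SimConfig(**payload.pop("simulation", {}))
        occ = OccupancyParams(**payload.pop("occupancy", {}))
        if "experiments" in payload:
            payload["experiments"] = tuple(payload["experiments"])
        return cls(simulation=sim, occupancy=occ, **payload)
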