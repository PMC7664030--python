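"""Pipeline configuration: thresholds, schedules, and the random seed.

Defaults mirror the published filtering and selection rules: interaction
terms kept at FDR < 0.05 with at least 30 non-zero supporting responses,
collinearity screened at VIF <= 5, STRING edges above score 700, duplicate
assays merged only above Pearson r = 0.7, small-molecule kinase inhibitors
capped at 900 Da, cancer groups kept at >= 1000 responses, and the network
escalation schedule stopping at mean cross-validated R^2 >= 0.8.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    fdr_alpha: float = 0.05
    min_nonzero: int = 30
    vif_max: float = 5.0
    ppi_score_min: float = 700.0
    duplicate_r_min: float = 0.7
    min_group_responses: int = 1000
    min_cell_line_responses: int = 30
    performance_threshold: float = 0.8
    mw_max: float = 900.0
    kinomescan_control_max: float = 5.0
    cv_folds: int = 10
    #: (architecture variant, optimizer iterations) escalation stages.
    iteration_schedule: tuple[tuple[str, int], ...] = (
        ("single", 200), ("single", 300),
        ("double", 200), ("double", 300),
        ("complex_double", 200), ("complex_double", 300),
    )
    l1_grid: tuple[float, ...] = (1e-4, 1e-3, 1e-2)
    edge_impact_cut: float = 0.05
    roc_thresholds: tuple[float, ...] = (-4.0, -3.0, -2.0, -1.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        positive = ("fdr_alpha", "min_nonzero", "vif_max", "ppi_score_min",
                    "duplicate_r_min", "min_group_responses",
                    "min_cell_line_responses", "performance_threshold",
                    "mw_max", "kinomescan_control_max", "cv_folds")
        for name in positive:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        self.iteration_schedule = tuple(
            (str(v), int(i)) for v, i in self.iteration_schedule)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Stable hash embedded in every output artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)
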