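"""Pipeline configuration: YAML-backed, with the study constants as defaults.

Every analysis constant is a config key defaulted to the value used in the
study design: k_neighbors=30, fdr_threshold=0.05, z_threshold=1.5,
wilcoxon_alpha=0.05, n_modules=7, core_fraction=0.30; the AUCell ranking
fraction (not stated by the study) defaults to 0.05.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .errors import ParameterError


@dataclass
class PipelineConfig:
    # input paths (any may be None when the pipeline simulates its inputs)
    expression_path: str | None = None
    cells_path: str | None = None
    regulons_path: str | None = None
    drivers_path: str | None = None
    cohort_expression_path: str | None = None
    cohort_survival_path: str | None = None
    programs_path: str | None = None

    # analysis parameters
    k_neighbors: int = 30
    aucell_top_fraction: float = 0.05
    z_threshold: float = 1.5
    z_mode: str = "cellwise"
    wilcoxon_alpha: float = 0.05
    fdr_threshold: float = 0.05
    n_modules: int = 7
    core_fraction: float = 0.30
    collapse_degree: bool = False
    sqrt_jsd: bool = False
    signature_fate: str = "fate2"

    # execution
    outdir: str = "regfate_results"
    seed: int = 0
    log_level: str = "INFO"
    synthetic: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ParameterError(f"k_neighbors must be ≥ 1, got {self.k_neighbors}")
        for name in ("aucell_top_fraction", "core_fraction"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.0):
                raise ParameterError(f"{name} must lie in (0, 1], got {value!r}")
        for name in ("z_threshold", "wilcoxon_alpha", "fdr_threshold"):
            value = getattr(self, name)
            if not math.isfinite(value):
                raise ParameterError(f"{name} must be finite, got {value!r}")
        if self.z_mode not in ("states", "cellwise"):
            raise ParameterError(f"z_mode must be 'states' or 'cellwise', got {self.z_mode!r}")
        if self.n_modules < 1:
            raise ParameterError(f"n_modules must be ≥ 1, got {self.n_modules}")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as handle:
            data = yaml.safe_load(handle) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
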