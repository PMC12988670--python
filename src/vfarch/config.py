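"""Pipeline configuration with defaults matching the reference analysis."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml


@dataclass
class PipelineConfig:
    """End-to-end pipeline settings.

    Defaults follow the reference settings: 10 CV folds, 100 restarts,
    archetype counts scanned from 2 to 17, family-wise alpha 0.05 over 43
    aspects.
    """

    # qc
    asym_threshold_db: float = 5.0
    corr_threshold: float = 0.6
    exclude_flagged: bool = False
    # archetypes
    k: int | None = None  # fixed K; None -> select via cross-validation
    k_min: int = 2
    k_max: int = 17
    folds: int = 10
    restarts: int = 100
    max_iter: int = 100
    tol: float = 1e-6
    penalty: float = 200.0
    # qol
    alpha: float = 0.05
    n_tests: int = 43
    foveal_adjust: bool = True
    # shared
    seed: int | None = None
    strict: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
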