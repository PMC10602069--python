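"""Pipeline configuration: paths, method choice, and thresholds with their defaults."""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

from .exceptions import InvalidInputError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Everything a full run needs; defaults are the pipeline's standard thresholds.

    Paths may be None when a stage is skipped (no enrichment without a GMT,
    non-informative priors without a bulk table).  ``counts_path`` is either
    an MTX triplet directory or a dense CSV file.
    """

    counts_path: str | None = None
    metadata_path: str | None = None
    phenotype_path: str | None = None
    bulk_prior_path: str | None = None
    gene_sets_path: str | None = None
    out_dir: str = "bfhde_out"

    method: str = "hybrid"
    gene_mean_min: float = 0.1
    mito_max: float = 0.10
    detected_pct: float = 2.0
    mito_prefix: str = "MT-"
    gene_filter_first: bool = True

    alpha: float = 0.01
    effect_min: float = 0.585
    q_max: float = 0.05

    em_tol: float = 1e-8
    em_max_iter: int = 100
    x2_log_first: bool = False  # False: average probabilities, then -log
    seed: int = 0

    def __post_init__(self):
        if self.method not in ("frequentist", "bayes", "hybrid"):
            raise InvalidInputError(f"unknown method {self.method!r}")
        if not (0 <= self.mito_max <= 1 and 0 <= self.detected_pct <= 100):
            raise InvalidInputError("mito_max in [0,1], detected_pct in [0,100] required")
        for name in ("alpha", "q_max"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InvalidInputError(f"{name} must lie in (0, 1]")
        if self.effect_min < 0 or self.em_tol <= 0 or self.em_max_iter < 1:
            raise InvalidInputError("effect_min >= 0, em_tol > 0, em_max_iter >= 1 required")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        """Load from a flat key: value YAML file; unknown keys are rejected."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise InvalidInputError("config file must be a flat key: value mapping")
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise InvalidInputError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
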