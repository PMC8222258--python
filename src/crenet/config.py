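"""Run configuration for the pipeline.

All analysis thresholds live here so that a run is fully described by one
human-editable YAML file plus a seed.  Defaults follow the conventions of the
tools they emulate: the region-gene association uses the "basal plus
extension" rule (5 kb upstream / 1 kb downstream basal window, extended up to
1 Mb until hitting a neighbouring basal domain), differential calls use
corrected p < 0.05, motif scanning uses a 1e-4 p-value threshold, and soft
clustering uses fuzziness m = 1.5 with 25 soft clusters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


class ConfigError(ValueError):
    """Raised when a configuration value violates its constraints."""


@dataclass
class PipelineConfig:
    # differential-call thresholds
    deg_alpha: float = 0.05
    docr_alpha: float = 0.05
    contrast: str = "NR23_vs_RPE23"

    # regulatory-domain model
    basal_up: int = 5000
    basal_down: int = 1000
    max_extension: int = 1_000_000
    association_mode: str = "midpoint"  # or "overlap"
    promoter_up: int = 1000
    promoter_down: int = 100

    # motif scanning
    motif_p_threshold: float = 1e-4
    max_overlap_bp: int = 3
    pseudocount: float = 0.1
    n_score_bins: int = 1000
    background: str = "empirical"  # or "uniform"

    # network statistics
    cooccupancy_rate: str = "jaccard"  # or "conditional"

    # CRE null comparison
    n_resamples: int = 1000
    exclude_tfs_from_null: bool = True

    # trajectory clustering
    variance_threshold: float = 3.0
    fuzziness: float = 1.5
    n_soft_clusters: int = 25
    n_main_clusters_tf: int = 6
    n_main_clusters_cytoskeletal: int = 8
    max_iterations: int = 300
    convergence_tol: float = 1e-6

    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not 0 < self.deg_alpha <= 1 or not 0 < self.docr_alpha <= 1:
            raise ConfigError("alpha thresholds must lie in (0, 1]")
        if self.basal_up < 0 or self.basal_down < 0:
            raise ConfigError("basal window sizes must be nonnegative")
        if self.max_extension < 0:
            raise ConfigError("max_extension must be nonnegative")
        if self.association_mode not in ("midpoint", "overlap"):
            raise ConfigError(f"unknown association_mode {self.association_mode!r}")
        if not 0 < self.motif_p_threshold <= 1:
            raise ConfigError("motif_p_threshold must lie in (0, 1]")
        if self.max_overlap_bp < 0:
            raise ConfigError("max_overlap_bp must be nonnegative")
        if self.pseudocount < 0:
            raise ConfigError("pseudocount must be nonnegative")
        if self.n_score_bins < 10:
            raise ConfigError("n_score_bins must be at least 10")
        if self.background not in ("empirical", "uniform"):
            raise ConfigError(f"unknown background {self.background!r}")
        if self.cooccupancy_rate not in ("jaccard", "conditional"):
            raise ConfigError(f"unknown cooccupancy_rate {self.cooccupancy_rate!r}")
        if self.fuzziness <= 1:
            raise ConfigError("fuzziness m must be > 1")
        if self.n_soft_clusters < 2:
            raise ConfigError("n_soft_clusters must be >= 2")
        if self.convergence_tol <= 0:
            raise ConfigError("convergence_tol must be positive")
        return self

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML run configuration.

    Unknown keys are rejected so that typos in threshold names cannot
    silently fall back to defaults.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
    return PipelineConfig(**raw).validate()


def save_config(config: PipelineConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
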