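"""Declarative pipeline configuration with schema validation.

A single YAML (or JSON) document drives a run; unknown keys, a missing
seed, or bad enum values produce named validation errors.  Defaults
mirror the study conditions the synthetic generator emulates.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SyntheticSection(_Strict):
    n_blocks: int = 6
    pots_per_block_per_treatment: int = 1
    days: list[float] = Field(default=[2, 3, 4, 6, 8, 10, 13, 14])
    diel_days: list[float] = Field(default=[3, 4, 13, 14])
    diel_times: list[str] = Field(default=["0900", "1800", "2200", "0400"])
    depth: int = 2000
    n_features: int = 150
    module_size: int = 15
    within_degree: int = 4
    partial_corr: float = 0.2
    planted: list[dict] = Field(default_factory=list)
    use_default_planted: bool = True
    target_r2: float = 0.30
    baseline: float = 100.0
    block_noise_share: float = 0.2


class InputSection(_Strict):
    counts_tsv: str | None = None
    biom_json: str | None = None
    metadata_tsv: str | None = None
    growth_tsv: str | None = None

    @model_validator(mode="after")
    def _check_paths(self):
        for name in ("counts_tsv", "biom_json", "metadata_tsv", "growth_tsv"):
            val = getattr(self, name)
            if val is not None and not Path(val).exists():
                raise ValueError(f"input path does not exist: {name}={val}")
        return self


class StabilitySection(_Strict):
    n_runs: int = 100
    threshold: int = 80
    n_folds: int = 10
    n_lambda: int = 100
    lambda_min_ratio: float | None = None
    pseudocount: float = 0.5
    top_n: int = 200
    subsample_frac: float | None = 0.8
    module_min_prevalence: float = 0.27

    @model_validator(mode="after")
    def _check(self):
        if not 1 <= self.threshold <= self.n_runs:
            raise ValueError("threshold must be in [1, n_runs]")
        return self


class BayesSection(_Strict):
    draws: int = 1000
    warmup: int = 500
    chains: int = 2
    ci_level: float = 0.95
    prior_scale: float = 2.5


class PermutationSection(_Strict):
    n_replicates: int = 1


class NetworkSection(_Strict):
    enabled: bool = True
    min_samples: int = 4
    min_mean_rel_abund: float = 0.005
    lambda_min_ratio: float = 0.01
    n_lambda: int = 20
    n_subsamples: int = 50
    subsample_ratio: float = 0.8
    instability_threshold: float = 0.05
    groups: list[str] = Field(default=["all"])  # stages to build networks for

    @field_validator("groups")
    @classmethod
    def _stages(cls, v):
        bad = set(v) - {"early", "late", "all"}
        if bad:
            raise ValueError(f"invalid network group stage(s): {sorted(bad)}")
        return v


class ModuleSection(_Strict):
    enabled: bool = True


class PipelineConfig(_Strict):
    seed: int
    output_dir: str = "rhizolink_out"
    synthetic: SyntheticSection | None = None
    inputs: InputSection | None = None
    responses: list[list[str]] | None = None  # [[stage, response], ...]
    tests: list[list[str]] | None = None  # [[treatment, stage, response], ...]
    treatments: list[str] = Field(default=["inoculated", "disrupted"])
    stability: StabilitySection = Field(default_factory=StabilitySection)
    bayes: BayesSection = Field(default_factory=BayesSection)
    permutation: PermutationSection = Field(default_factory=PermutationSection)
    network: NetworkSection = Field(default_factory=NetworkSection)
    modules: ModuleSection = Field(default_factory=ModuleSection)

    @field_validator("treatments")
    @classmethod
    def _treat(cls, v):
        bad = set(v) - {"inoculated", "disrupted"}
        if bad:
            raise ValueError(f"invalid treatment(s): {sorted(bad)}")
        return v

    @field_validator("tests")
    @classmethod
    def _tests(cls, v):
        if v is None:
            return v
        for item in v:
            if len(item) != 3:
                raise ValueError("each test must be [treatment, stage, response]")
            if item[0] not in ("inoculated", "disrupted"):
                raise ValueError(f"invalid treatment in tests: {item[0]}")
            if item[1] not in ("early", "late", "all"):
                raise ValueError(f"invalid stage in tests: {item[1]}")
        return v

    @model_validator(mode="after")
    def _source(self):
        if self.synthetic is None and self.inputs is None:
            self.synthetic = SyntheticSection()
        if self.synthetic is not None and self.inputs is not None:
            raise ValueError("specify either synthetic or inputs, not both")
        return self


def validate_config(path) -> PipelineConfig:
    """Load and schema-check a YAML/JSON pipeline config."""
    text = Path(path).read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    if "seed" not in data:
        raise ValueError("config is missing required key: seed")
    return PipelineConfig(**data)
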