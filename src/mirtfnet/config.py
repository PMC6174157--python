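"""Pipeline configuration: parsing, defaulting and validation.

Configs are YAML or JSON; unknown keys are rejected so typos fail loudly.
In ``simulate`` mode the cohort is generated from ``sim``; in ``files``
mode the input paths must exist at validation time.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .errors import ConfigError
from .synthetic import SimulationConfig


class InputPaths(BaseModel):
    model_config = ConfigDict(extra="forbid")

    mrna_counts: str | None = None
    mrna_lengths: str | None = None
    mirna_counts: str | None = None
    utr_fasta: str | None = None
    mirna_fasta: str | None = None
    tf_list: str | None = None
    go_map: str | None = None


class PipelineConfig(BaseModel):
    """Fully-defaulted, validated parameters for every stage."""

    model_config = ConfigDict(extra="forbid")

    mode: str = "simulate"  # simulate | files
    inputs: InputPaths = Field(default_factory=InputPaths)
    sim: dict = Field(default_factory=dict)

    dispersion: float = 0.1
    fc_threshold: float = 1.5
    fdr_threshold: float = 0.05
    pseudocount: float = 0.5
    cpm_threshold: float = 1.0
    cpm_min_samples: int = 1

    align_min: float | None = None
    align_min_frac: float = 0.9
    w_au: float = 0.1
    w_pos: float = 0.1

    min_pairs: int = 2

    enrich_method: str = "hypergeom"  # hypergeom | wallenius
    top_k_terms: int = 15

    rng_seed: int = 42

    @field_validator("mode")
    @classmethod
    def _mode(cls, v):
        if v not in {"simulate", "files"}:
            raise ValueError(f"mode must be 'simulate' or 'files', got {v!r}")
        return v

    @field_validator("fdr_threshold")
    @classmethod
    def _fdr(cls, v):
        if not 0 < v <= 1:
            raise ValueError(f"fdr_threshold must be in (0, 1], got {v}")
        return v

    @field_validator("fc_threshold")
    @classmethod
    def _fc(cls, v):
        if v < 1:
            raise ValueError(f"fc_threshold must be >= 1, got {v}")
        return v

    @field_validator("dispersion")
    @classmethod
    def _disp(cls, v):
        if v < 0:
            raise ValueError(f"dispersion must be >= 0, got {v}")
        return v

    @field_validator("pseudocount")
    @classmethod
    def _pseudo(cls, v):
        if v <= 0:
            raise ValueError(f"pseudocount must be positive, got {v}")
        return v

    @field_validator("min_pairs", "cpm_min_samples", "top_k_terms")
    @classmethod
    def _pos_int(cls, v, info):
        if v < 1:
            raise ValueError(f"{info.field_name} must be >= 1, got {v}")
        return v

    @field_validator("align_min_frac", "w_au", "w_pos")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0, got {v}")
        return v

    @field_validator("enrich_method")
    @classmethod
    def _enrich(cls, v):
        if v not in {"hypergeom", "wallenius"}:
            raise ValueError(f"enrich_method must be 'hypergeom' or 'wallenius', got {v!r}")
        return v

    @model_validator(mode="after")
    def _check_files(self):
        if self.mode == "files":
            required = ["mrna_counts", "mirna_counts", "utr_fasta", "mirna_fasta", "tf_list"]
            for key in required:
                path = getattr(self.inputs, key)
                if path is None:
                    raise ValueError(f"mode 'files' requires inputs.{key}")
                if not Path(path).exists():
                    raise ValueError(f"inputs.{key}: path does not exist: {path}")
        return self

    def simulation_config(self) -> SimulationConfig:
        """Build the generator config; ``sim.rng_seed`` defaults to the run seed."""
        known = {f.name for f in dataclasses.fields(SimulationConfig)}
        unknown = set(self.sim) - known
        if unknown:
            raise ConfigError(f"unknown sim keys: {sorted(unknown)}")
        params = dict(self.sim)
        params.setdefault("rng_seed", self.rng_seed)
        for key in ("utr_length_range", "baseline_log_mean", "library_size_range", "go_terms_per_gene"):
            if key in params:
                params[key] = tuple(params[key])
        cfg = SimulationConfig(**params)
        cfg.validate()
        return cfg


def validate_config(raw_text: str) -> PipelineConfig:
    """Parse YAML/JSON text into a fully-validated :class:`PipelineConfig`."""
    try:
        data = yaml.safe_load(raw_text) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"config is not valid YAML/JSON: {exc}") from exc
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping of keys to values")
    try:
        cfg = PipelineConfig(**data)
    except Exception as exc:
        raise ConfigError(str(exc)) from exc
    cfg.simulation_config()  # surface sim errors at validation time
    return cfg


def load_config(path) -> PipelineConfig:
    return validate_config(Path(path).read_text())


def dump_config(cfg: PipelineConfig) -> str:
    """Serialize a config such that re-parsing reproduces it exactly."""
    return json.dumps(cfg.model_dump(), indent=1, sort_keys=True)
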