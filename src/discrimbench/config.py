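"""Run configuration: one human-readable YAML file, validated fail-fast.

The experiment has many silent defaults (selection alpha, priors, Q mode,
categorization cutpoints) that must be auditable; everything is therefore
collected in a single ``RunConfig`` document, validated strictly (unknown
keys rejected with a path-like key name) before any computation starts, and
echoed to the log by the CLI together with its hash.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

from .cohort import CohortConfig, DurationSpec
from .experiment import ExperimentConfig


class ConfigError(ValueError):
    """Invalid run configuration."""


class CohortSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    n: int = 243
    regime: str = "logistic"
    seed: int = 0
    intercept: float = -0.6
    coefficients: dict[str, float] = Field(
        default_factory=lambda: {
            "satisfaction": -1.3,
            "family_history": 1.5,
            "duration": 0.18,
        }
    )
    binary_probs: dict[str, float] = Field(
        default_factory=lambda: {"satisfaction": 0.5, "family_history": 0.25}
    )
    duration_dist: str = "lognormal"
    duration_params: tuple[float, float] = (1.0, 0.6)
    class_prevalence: float = 0.4
    class_means: dict[int, dict[str, float]] = Field(
        default_factory=lambda: {0: {"duration": 2.8}, 1: {"duration": 3.6}}
    )
    shared_covariance: list[list[float]] = Field(default_factory=lambda: [[2.0]])
    class_binary_probs: dict[int, dict[str, float]] = Field(
        default_factory=lambda: {
            0: {"satisfaction": 0.55, "family_history": 0.20},
            1: {"satisfaction": 0.40, "family_history": 0.32},
        }
    )

    def to_cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n=self.n,
            regime=self.regime,
            seed=self.seed,
            intercept=self.intercept,
            coefficients=dict(self.coefficients),
            binary_probs=dict(self.binary_probs),
            duration=DurationSpec(self.duration_dist, tuple(self.duration_params)),
            class_prevalence=self.class_prevalence,
            class_means={k: dict(v) for k, v in self.class_means.items()},
            shared_covariance=tuple(tuple(r) for r in self.shared_covariance),
            class_binary_probs={k: dict(v) for k, v in self.class_binary_probs.items()},
        )


class ExperimentSettings(BaseModel):
    model_config = ConfigDict(extra="forbid")

    sizes: list[int] = Field(default_factory=lambda: [50, 100, 150, 200, 220])
    series: int = 2
    include_total_row: bool = True
    selection_alpha: float = 0.05
    select: bool = True
    seed: int = 0
    equal_priors: bool = False
    q_mode: str = "strict"
    replicates: int = 1
    categorize: bool = False
    cutpoints: list[float] | None = None  # None with categorize=True -> tertiles

    def to_experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            sizes=tuple(self.sizes),
            n_series=self.series,
            include_total_row=self.include_total_row,
            selection_alpha=self.selection_alpha,
            select=self.select,
            seed=self.seed,
            equal_priors=self.equal_priors,
            q_mode=self.q_mode,
            replicates=self.replicates,
            cutpoints=tuple(self.cutpoints) if self.cutpoints else None,
        )


class RunConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")

    cohort: CohortSettings = Field(default_factory=CohortSettings)
    experiment: ExperimentSettings = Field(default_factory=ExperimentSettings)
    table_out: str = "table.csv"
    log_level: str = "INFO"

    @model_validator(mode="after")
    def _sizes_fit(self) -> "RunConfig":
        too_big = [s for s in self.experiment.sizes if s > self.cohort.n]
        if too_big:
            raise ValueError(
                f"experiment.sizes: size {too_big[0]} exceeds cohort n = {self.cohort.n}"
            )
        return self


def _format_error(exc: ValidationError) -> str:
    parts = []
    for err in exc.errors():
        loc = ".".join(str(x) for x in err["loc"]) or "<root>"
        parts.append(f"{loc}: {err['msg']}")
    return "; ".join(parts)


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Unknown keys, type mismatches and out-of-range values are rejected with
    the offending key's dotted path in the message.
    """
    text = Path(path).read_text()
    doc = yaml.safe_load(text) or {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    try:
        return RunConfig.model_validate(doc)
    except ValidationError as exc:
        raise ConfigError(f"{path}: {_format_error(exc)}") from None


def dump_config(config: RunConfig) -> str:
    """Normalized YAML of the effective configuration (defaults filled)."""
    return yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True)
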