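"""Experiment-suite configuration: parsing, defaults and cross-field checks."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Optional

import yaml

from .cohort import CohortConfig
from .errors import InvalidConfigError
from .models import ModelConfig

__all__ = ["ExperimentConfig", "validate_config", "load_config"]

EXPERIMENT_FLAGS = (
    "model_comparison", "graph_sensitivity", "linearity_sensitivity",
    "data_scaling", "subject_specificity", "group_model",
    "shared_response_ablation", "dynamics",
)


@dataclasses.dataclass(frozen=True)
class ExperimentConfig:
    cohort: CohortConfig = dataclasses.field(default_factory=CohortConfig)
    cutoff_hz: float = 0.01             # high-pass cutoff, Hz
    train_fraction: float = 44 / 68     # first fraction of runs -> training set
    graph_kind: str = "functional"
    graph_density: float = 0.10
    absolute_correlation: bool = False
    model_grid: tuple = ()
    lags: tuple = (1, 2, 3, 4, 5, 6)
    experiments: tuple = ("model_comparison",)
    epochs: int = 30
    batch_size: int = 128
    learning_rate: float = 1e-2
    n_random_graph_trials: int = 5
    data_scaling_run_counts: Optional[tuple] = None
    data_scaling_repetitions: int = 5
    group_total_train_runs: Optional[int] = None
    seed_parcel: int = 0
    seed: int = 0
    output_dir: str = "neuroar_out"

    def __post_init__(self):
        if not self.model_grid:
            object.__setattr__(self, "model_grid",
                               (ModelConfig(family="linear_multi", k=1),))


def _as_model_config(entry) -> ModelConfig:
    if isinstance(entry, ModelConfig):
        return entry
    entry = dict(entry)
    if "hidden_sizes" in entry:
        entry["hidden_sizes"] = tuple(entry["hidden_sizes"])
    return ModelConfig(**entry)


def validate_config(raw) -> ExperimentConfig:
    """Normalize a raw mapping (or ExperimentConfig) into a validated config.

    Defaults are filled (graph density 0.10, high-pass 0.01 Hz, lags 1..6),
    units are sanity-checked and cross-field constraints enforced; every
    violation is collected and reported together.
    """
    if isinstance(raw, ExperimentConfig):
        cfg = raw
    else:
        raw = dict(raw or {})
        violations = []
        known = {f.name for f in dataclasses.fields(ExperimentConfig)}
        for key in raw:
            if key not in known:
                violations.append(f"unknown field {key!r}")
        if violations:
            raise InvalidConfigError("; ".join(violations))
        if "cohort" in raw and not isinstance(raw["cohort"], CohortConfig):
            cohort = dict(raw["cohort"])
            if "n_runs_per_condition" in cohort:
                cohort["n_runs_per_condition"] = dict(cohort["n_runs_per_condition"])
            raw["cohort"] = CohortConfig(**cohort)
        if "model_grid" in raw:
            raw["model_grid"] = tuple(_as_model_config(e) for e in raw["model_grid"])
        for key in ("lags", "experiments", "data_scaling_run_counts"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        cfg = ExperimentConfig(**raw)

    violations = []
    for flag in cfg.experiments:
        if flag not in EXPERIMENT_FLAGS:
            violations.append(f"experiments: unknown flag {flag!r}")
    if not cfg.experiments:
        violations.append("experiments: at least one experiment must be enabled")
    nyquist = 1.0 / (2.0 * cfg.cohort.tr)
    if cfg.cutoff_hz >= nyquist:
        violations.append(f"cutoff_hz: {cfg.cutoff_hz} >= Nyquist {nyquist:.4g} Hz")
    if not 0.0 < cfg.graph_density <= 1.0:
        violations.append("graph_density: must lie in (0, 1]")
    if not cfg.lags or min(cfg.lags) < 1:
        violations.append("lags: must be a non-empty list of lags >= 1")
    for mc in cfg.model_grid:
        if mc.k + max(cfg.lags) > cfg.cohort.run_length:
            violations.append(
                f"model_grid/k + lags: k={mc.k} + max lag {max(cfg.lags)} exceeds "
                f"cohort/run_length={cfg.cohort.run_length}")
    if not 0.0 < cfg.train_fraction < 1.0:
        violations.append("train_fraction: must lie in (0, 1)")
    if violations:
        raise InvalidConfigError("; ".join(violations))
    return cfg


def load_config(path) -> ExperimentConfig:
    """Load and validate a YAML/JSON experiment configuration file."""
    raw = yaml.safe_load(Path(path).read_text())
    return validate_config(raw)


def config_to_dict(cfg: ExperimentConfig) -> dict:
    out = dataclasses.asdict(cfg)
    out["cohort"]["n_runs_per_condition"] = dict(out["cohort"]["n_runs_per_condition"])
    out["model_grid"] = [dataclasses.asdict(m) for m in cfg.model_grid]
    return out
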