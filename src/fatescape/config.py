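"""Run configuration: validated settings with study-condition defaults.

A :class:`RunConfig` gathers everything one inference run needs — model
parameters, prior construction, simulation settings, the distance
metric, and ABC–SMC controls — and round-trips exactly through a YAML
file.  Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .distances import METRICS
from .model import PARAM_NAMES, VECTOR_FIELDS, ModelParameters

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Resolved configuration for a full generate→infer→analyze run."""

    # model / prior
    params: dict = field(
        default_factory=lambda: {k: float(getattr(ModelParameters(), k))
                                 for k in VECTOR_FIELDS}
    )
    inferred_names: list = field(default_factory=lambda: list(PARAM_NAMES))
    prior_factor: float = 10.0
    # simulation
    n_cells: int = 300
    T: int = 10
    t_end: float = 100.0
    x0: list = field(default_factory=lambda: [0.0, 1.0, 0.0, 0.0])
    # distance
    metric: str = "sinkhorn"
    metric_options: dict = field(default_factory=dict)
    # ABC-SMC
    n_particles: int = 100
    quantile_alpha: float = 0.3
    epsilon_target: float = 0.0
    max_sims: int = 10_000_000
    pilot_factor: int = 10
    # bookkeeping
    seed: int = 0
    out_dir: str = "runs"

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if self.n_cells < 1:
            raise ValueError(f"n_cells must be >= 1, got {self.n_cells}")
        if self.T < 1:
            raise ValueError(f"T must be >= 1, got {self.T}")
        if self.t_end <= 0:
            raise ValueError(f"t_end must be > 0, got {self.t_end}")
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}, got {self.metric!r}")
        if not 0 < self.quantile_alpha < 1:
            raise ValueError("quantile_alpha must be in (0, 1)")
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.max_sims < 1:
            raise ValueError("max_sims must be >= 1")
        if len(self.x0) != 4 or any(v < 0 for v in self.x0):
            raise ValueError("x0 must be 4 nonnegative values")
        unknown = set(self.params) - set(VECTOR_FIELDS)
        if unknown:
            raise ValueError(f"unknown model parameter keys {sorted(unknown)}")
        bad = set(self.inferred_names) - set(PARAM_NAMES)
        if bad:
            raise ValueError(f"cannot infer unknown parameters {sorted(bad)}")
        # materializing checks nonnegativity of every parameter
        self.model_parameters()

    def model_parameters(self) -> ModelParameters:
        return ModelParameters(**{k: float(v) for k, v in self.params.items()})


def save_config(cfg: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(asdict(cfg), sort_keys=False))


def load_config(path) -> RunConfig:
    """Load a config file; missing keys take defaults, unknown keys fail."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    known = {f.name: f for f in fields(RunConfig)}
    unknown = set(raw) - set(known)
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key, value in raw.items():
        expected = known[key].type
        if key in ("n_cells", "T", "n_particles", "max_sims", "pilot_factor",
                   "seed") and not isinstance(value, int):
            raise ValueError(f"{path}: key {key!r} must be an integer, got {value!r}")
    return RunConfig(**raw)
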