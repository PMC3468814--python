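"""Simulation configuration, config-file parsing, and run manifests.

Defaults follow the base parameterisation used throughout the experiments:
p_L = 0.6, p_H = 0.9 (theta = 1.5), alpha = 0.4, epsilon = 0.05, a
100 x 100 grid and 400 agents.  ``theta`` may be given instead of ``p_high``
(then p_high = theta * p_low); giving both is over-determined and rejected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

SCENARIOS = ("base_case", "hetero_types", "quadrants", "movement", "gradient")

#: CLI-facing scenario spellings mapped to internal names.
SCENARIO_ALIASES = {
    "base-case": "base_case",
    "hetero": "hetero_types",
    "quadrants": "quadrants",
    "movement": "movement",
    "gradient": "gradient",
}


@dataclass
class SimulationConfig:
    """Parameters of a single simulation run."""

    scenario: str = "base_case"
    width: int = 100
    height: int = 100
    n_agents: int = 400
    epsilon: float = 0.05
    p_low: float = 0.6
    p_high: float = 0.9
    alpha: float = 0.4
    equilibrium_tol: float = 1e-4
    equilibrium_window: int = 10
    max_steps: int = 5000
    seed: int = 0
    allow_stay: bool = False  # may agents stay put during the move step

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.scenario not in SCENARIOS:
            raise ValueError(
                f"unknown scenario {self.scenario!r}; expected one of {SCENARIOS}"
            )
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be positive")
        if self.n_agents < 1:
            raise ValueError("n_agents must be positive")
        if not 0.0 <= self.epsilon <= 1.0:
            raise ValueError(f"epsilon must be in [0, 1], got {self.epsilon}")
        if not self.p_low > 0 or not self.p_high >= self.p_low:
            raise ValueError(
                f"need p_high >= p_low > 0, got p_low={self.p_low}, p_high={self.p_high}"
            )
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError(f"alpha must be in (0, 1], got {self.alpha}")
        if not self.equilibrium_tol > 0:
            raise ValueError("equilibrium_tol must be > 0")
        if self.equilibrium_window < 1 or self.max_steps < 1:
            raise ValueError("equilibrium_window and max_steps must be >= 1")

    @property
    def theta(self) -> float:
        """High-to-low palatability ratio."""
        return self.p_high / self.p_low

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ExperimentSpec:
    """A named experiment plus replicate structure.

    Replicate r's RNG stream is derived from (seed, r) only, via
    ``numpy.random.SeedSequence(seed).spawn``; runs are therefore
    independent and individually reproducible.
    """

    name: str = "base_case"
    n_replicates: int = 15
    config: SimulationConfig = field(default_factory=SimulationConfig)
    time_to_learn_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if not 0 < self.time_to_learn_tol < min(self.config.p_low, self.config.p_high):
            raise ValueError("time_to_learn_tol must be in (0, min(p))")

    def replicate_seeds(self) -> list[np.random.SeedSequence]:
        return np.random.SeedSequence(self.config.seed).spawn(self.n_replicates)


_CONFIG_KEYS = {f.name for f in dataclasses.fields(SimulationConfig)}
_EXTRA_KEYS = {"theta", "n_replicates", "time_to_learn_tol"}


def load_config(
    path: str | Path | None = None, overrides: dict | None = None
) -> tuple[SimulationConfig, ExperimentSpec]:
    """Load a flat ``key: value`` config file, applying CLI overrides on top.

    Unknown keys and out-of-range values raise ``ValueError`` naming the
    offending key.  An empty (or absent) file yields all defaults.
    """
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config file {path} is not a flat key: value map")
        raw.update(loaded)
    if overrides:
        raw.update({k: v for k, v in overrides.items() if v is not None})

    unknown = set(raw) - _CONFIG_KEYS - _EXTRA_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "theta" in raw and "p_high" in raw:
        raise ValueError(
            "config is over-determined: give either theta or p_high, not both"
        )

    n_replicates = int(raw.pop("n_replicates", 15))
    ttl_tol = float(raw.pop("time_to_learn_tol", 0.01))
    theta = raw.pop("theta", None)
    cfg_kwargs = {k: v for k, v in raw.items() if k in _CONFIG_KEYS}
    config = SimulationConfig(**cfg_kwargs)
    if theta is not None:
        theta = float(theta)
        if theta < 1.0:
            raise ValueError(f"theta must be >= 1, got {theta}")
        config = config.replace(p_high=theta * config.p_low)
    spec = ExperimentSpec(
        name=config.scenario,
        n_replicates=n_replicates,
        config=config,
        time_to_learn_tol=ttl_tol,
    )
    return config, spec


@dataclass
class RunManifest:
    """Everything needed to reproduce a run bit-exactly."""

    config: dict
    master_seed: int
    replicate_seeds: list[int]
    n_replicates: int
    time_to_learn_tol: float
    version: str
    outputs: list[str] = field(default_factory=list)
    equilibrium_flags: list[bool] = field(default_factory=list)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        return cls(**json.loads(Path(path).read_text()))

    def to_spec(self) -> ExperimentSpec:
        """Rebuild the effective experiment spec (round-trip contract)."""
        return ExperimentSpec(
            name=self.config["scenario"],
            n_replicates=self.n_replicates,
            config=SimulationConfig(**self.config),
            time_to_learn_tol=self.time_to_learn_tol,
        )


def make_manifest(spec: ExperimentSpec, outputs=(), equilibrium_flags=()) -> RunManifest:
    from . import __version__

    # Informational: the first 31 bits of each replicate stream's state.
    child_seeds = [
        int(ss.generate_state(1)[0]) % (2**31) for ss in spec.replicate_seeds()
    ]
    return RunManifest(
        config=spec.config.to_dict(),
        master_seed=spec.config.seed,
        replicate_seeds=child_seeds,
        n_replicates=spec.n_replicates,
        time_to_learn_tol=spec.time_to_learn_tol,
        version=__version__,
        outputs=list(outputs),
        equilibrium_flags=list(equilibrium_flags),
    )
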