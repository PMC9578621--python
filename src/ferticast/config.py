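"""Run configuration: hyperprior bounds, MCMC and projection settings.

Every key has a default, so an empty config file (or none at all) is valid.
Configs load from YAML mappings whose top-level keys are ``priors``,
``mcmc``, ``projection`` and ``ar1``; unknown keys are rejected to catch
typos early.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

from .exceptions import ValidationError

Bounds = tuple[float, float]


@dataclass(frozen=True)
class PriorConfig:
    """Uniform hyperprior supports for all national-level parameters.

    The transition model's hyperparameters have no published priors; wide
    uniforms centred on demographically plausible ranges keep the posterior
    proper while staying diffuse.  All bounds are configurable.
    """

    chi: Bounds = (-5.0, 5.0)
    psi: Bounds = (0.01, 5.0)
    Delta4_mean: Bounds = (-5.0, 5.0)
    delta4_sd: Bounds = (0.01, 5.0)
    alpha: Bounds = (-5.0, 5.0)
    delta_sd: Bounds = (0.01, 5.0)
    sigma0: Bounds = (0.01, 0.6)
    S: Bounds = (3.5, 6.5)
    a: Bounds = (0.0, 0.2)
    b: Bounds = (0.0, 0.2)
    c1975: Bounds = (0.8, 2.0)
    m_tau: Bounds = (-1.0, 1.0)
    s_tau: Bounds = (0.01, 1.0)
    #: Upper bound of the uniform prior on the onset level U_c for regions
    #: whose transition began before the observation window.
    U_upper: float = 8.8
    #: Lower bound is min(U_lower_cap, max observed TFR of the region).
    U_lower_cap: float = 5.5


@dataclass(frozen=True)
class MCMCConfig:
    """Metropolis-within-Gibbs sampler settings."""

    chains: int = 3
    iterations: int = 20_000
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    #: Initial random-walk proposal sd per block kind.
    proposal_scale: float = 0.2
    #: Adapt proposal scales toward this acceptance rate during burn-in.
    target_acceptance: float = 0.44
    #: Adaptation window (iterations between scale updates).
    adapt_every: int = 50
    #: Parameter names clamped at fixed values (never updated); supports the
    #: fixed-distortion run mode and collapsed single-parameter checks.
    fixed_params: dict = field(default_factory=dict)
    priors: PriorConfig = field(default_factory=PriorConfig)

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.iterations):
            raise ValidationError("need 0 <= burn_in < iterations")
        if self.thin < 1 or self.chains < 1:
            raise ValidationError("thin and chains must be >= 1")


#: Reduced preset for tests and smoke runs.
TEST_MCMC = dict(chains=2, iterations=2_000, burn_in=1_000, thin=5)


@dataclass(frozen=True)
class ProjectionConfig:
    """Forward-simulation settings."""

    horizon_end_year: int = 2100
    n_trajectories: int = 2_000
    seed: int = 0
    #: Minimum simulated TFR (children per woman); Gaussian distortions can
    #: otherwise produce non-physical values.
    tfr_floor: float = 0.5
    #: Phase II -> III switch rule during simulation: "lambda" applies the
    #: in-sample two-increases-below-2 pattern online (plus a hard switch
    #: when the decrement gate closes at f <= 1); "never" keeps Phase II
    #: dynamics throughout (diagnostic mode).
    phase3_rule: str = "lambda"

    def __post_init__(self) -> None:
        if self.n_trajectories < 1:
            raise ValidationError("n_trajectories must be >= 1")
        if self.phase3_rule not in ("lambda", "never"):
            raise ValidationError(f"unknown phase3_rule {self.phase3_rule!r}")


@dataclass(frozen=True)
class AR1Config:
    mu: float = 2.1
    #: Pool Phase III pairs across all regions (else national series only).
    pool_regions: bool = True


@dataclass(frozen=True)
class RunConfig:
    priors: PriorConfig = field(default_factory=PriorConfig)
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    projection: ProjectionConfig = field(default_factory=ProjectionConfig)
    ar1: AR1Config = field(default_factory=AR1Config)

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    "priors": PriorConfig,
    "mcmc": MCMCConfig,
    "projection": ProjectionConfig,
    "ar1": AR1Config,
}


def _build(cls, data: dict):
    valid = set(cls.__dataclass_fields__)
    unknown = set(data) - valid
    if unknown:
        raise ValidationError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    coerced = {
        k: tuple(v) if isinstance(v, list) else v  # YAML lists -> bound tuples
        for k, v in data.items()
    }
    return cls(**coerced)


def load_config(path: str | Path | None) -> RunConfig:
    """Load a RunConfig from a YAML file; a missing/empty file gives defaults."""
    if path is None:
        return RunConfig()
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path} must be a YAML mapping")
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValidationError(f"unknown config sections: {sorted(unknown)}")
    sections = {name: _build(cls, raw.get(name, {}) or {}) for name, cls in _SECTIONS.items()}
    # the sampler carries its own copy of the prior bounds
    sections["mcmc"] = replace(sections["mcmc"], priors=sections["priors"])
    return RunConfig(**sections)
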