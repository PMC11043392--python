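"""Simulation parameters and named scenario presets.

The simulator models a population of ``n_total`` individuals split at time
``t_0`` into ``n_villages`` patrilocal villages, optionally structured into
patrilineal descent groups of initial size ``group_init_size``.  All the
knobs of the socio-demographic model live in :class:`SimulationConfig`;
the named scenarios (a bilateral control, the eight patrilineal variants,
the two-transition scenarios, the long/decay scenarios and the strongly
polygynous variant) are encoded as :class:`ScenarioPreset` objects made of
:class:`Phase` schedules.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Mapping

import yaml

BILATERAL = "bilateral"
PATRILINEAL = "patrilineal"

PATRILOCAL = "patrilocal"
MATRILOCAL = "matrilocal"
MULTILOCAL = "multilocal"

RANDOM_FISSION = "random"
LINEAL_FISSION = "lineal"

_DESCENT_RULES = (BILATERAL, PATRILINEAL)
_RESIDENCE_RULES = (PATRILOCAL, MATRILOCAL, MULTILOCAL)
_FISSION_TYPES = (RANDOM_FISSION, LINEAL_FISSION)


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of range."""


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameterisation of one simulation run.

    Defaults follow the reference setting used throughout the analysis:
    1500 founders in 5 villages of 300, 1% exponential growth, patrilocal
    female migration of 10%, fission threshold 150 with a 3-generation
    cooldown, and fitness-draw standard deviation sigma = 0.1 where spread
    applies.
    """

    n_total: int = 1500
    n_villages: int = 5
    village_init_size: int = 300
    group_init_size: int = 100
    growth_rate: float = 0.01
    sigma: float = 0.1
    female_mig_rate: float = 0.1
    male_mig_rate: float = 0.0
    fission_threshold: int = 150
    fission_cooldown: int = 3
    fission_type: str = RANDOM_FISSION
    post_fission_migration: bool = False
    violence_rate: float = 0.0
    violence_arena: str = "population"  # or "village": who counts as rivals
    polygyny: bool = False
    polygyny_p: float = 0.5
    mu_y: float = 2.5e-8
    mu_mt: float = 5.5e-7
    len_y: int = 1_000_000
    len_mt: int = 10_000
    sample_per_village: int = 20
    sample_interval: int = 20
    generation_time: float = 25.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for key in ("female_mig_rate", "male_mig_rate", "violence_rate"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{key}={v!r} must lie in [0, 1]")
        if self.violence_arena not in ("population", "village"):
            raise ConfigError(
                f"violence_arena={self.violence_arena!r} must be "
                "'population' or 'village'"
            )
        if not 0.0 < self.polygyny_p <= 1.0:
            raise ConfigError(f"polygyny_p={self.polygyny_p!r} must lie in (0, 1]")
        if self.sigma < 0:
            raise ConfigError(f"sigma={self.sigma!r} must be non-negative")
        for key in (
            "n_total",
            "n_villages",
            "village_init_size",
            "group_init_size",
            "fission_threshold",
            "len_y",
            "len_mt",
            "sample_per_village",
        ):
            v = getattr(self, key)
            if not (isinstance(v, int) and v > 0):
                raise ConfigError(f"{key}={v!r} must be a positive integer")
        if self.fission_cooldown < 0:
            raise ConfigError("fission_cooldown must be non-negative")
        if self.growth_rate < 0:
            raise ConfigError("growth_rate must be non-negative")
        for key in ("mu_y", "mu_mt"):
            if getattr(self, key) < 0:
                raise ConfigError(f"{key} must be non-negative")
        if self.generation_time <= 0:
            raise ConfigError("generation_time must be positive")
        if self.fission_type not in _FISSION_TYPES:
            raise ConfigError(
                f"fission_type={self.fission_type!r} must be one of {_FISSION_TYPES}"
            )
        if self.village_init_size * self.n_villages != self.n_total:
            raise ConfigError(
                "village_init_size * n_villages must equal n_total "
                f"({self.village_init_size} * {self.n_villages} != {self.n_total})"
            )
        if self.group_init_size * 3 != self.village_init_size:
            raise ConfigError(
                "villages hold 3 initial descent groups: group_init_size * 3 "
                f"must equal village_init_size ({self.group_init_size} * 3 != "
                f"{self.village_init_size})"
            )

    # -- serialisation -------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def replace(self, **overrides) -> "SimulationConfig":
        return dataclasses.replace(self, **overrides)

    def village_target_size(self, generation: int) -> int:
        """Deterministic village size round(N0 * exp(r * t)) at ``generation``."""
        return round(self.village_init_size * math.exp(self.growth_rate * generation))


_FIELD_NAMES = {f.name for f in dataclasses.fields(SimulationConfig)}


def load_config(source: str | Mapping | None = None, **overrides) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a mapping or a YAML file path.

    Unknown keys are rejected with a message naming the offending key;
    keyword ``overrides`` win over file/mapping values.
    """
    data: dict = {}
    if source is not None:
        if isinstance(source, Mapping):
            data.update(source)
        else:
            with open(source) as fh:
                loaded = yaml.safe_load(fh) or {}
            if not isinstance(loaded, Mapping):
                raise ConfigError(f"config file {source!r} must hold a key: value mapping")
            data.update(loaded)
    data.update(overrides)
    unknown = sorted(set(data) - _FIELD_NAMES)
    if unknown:
        raise ConfigError(f"unknown configuration key(s): {', '.join(unknown)}")
    return SimulationConfig(**data)


def residence_migration_rates(residence: str, config: SimulationConfig) -> tuple[float, float]:
    """(female, male) per-generation migration rates implied by a residence rule.

    Patrilocal: females move at ``female_mig_rate`` (10% by default), males at
    ``male_mig_rate`` (0 or 2%).  Matrilocal mirrors this (10% of males, no
    females); multilocal moves 5% of each sex.
    """
    if residence == PATRILOCAL:
        return config.female_mig_rate, config.male_mig_rate
    if residence == MATRILOCAL:
        return 0.0, 0.1
    if residence == MULTILOCAL:
        return 0.05, 0.05
    raise ConfigError(f"unknown residence rule {residence!r}")


@dataclass(frozen=True)
class Phase:
    """One segment of a run: a descent rule, a residence rule and overrides.

    ``start`` is the generation (counted from t_0 = 0) at which the phase's
    rules take effect; overrides may change sigma, fission_type,
    violence_rate or polygyny for the duration of the phase.
    """

    start: int
    descent: str
    residence: str
    overrides: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.descent not in _DESCENT_RULES:
            raise ConfigError(f"unknown descent rule {self.descent!r}")
        if self.residence not in _RESIDENCE_RULES:
            raise ConfigError(f"unknown residence rule {self.residence!r}")
        unknown = sorted(
            set(self.overrides)
            - {"sigma", "fission_type", "violence_rate", "polygyny", "post_fission_migration"}
        )
        if unknown:
            raise ConfigError(f"unknown phase override(s): {', '.join(unknown)}")

    def effective_config(self, config: SimulationConfig) -> SimulationConfig:
        return config.replace(**dict(self.overrides)) if self.overrides else config


@dataclass(frozen=True)
class ScenarioPreset:
    """A named scenario: an ordered phase schedule and a total duration."""

    name: str
    phases: tuple[Phase, ...]
    total_generations: int

    def __post_init__(self) -> None:
        starts = [p.start for p in self.phases]
        if not starts or starts[0] != 0:
            raise ConfigError("the first phase must start at generation 0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ConfigError("phase start generations must be strictly increasing")
        if self.total_generations <= starts[-1]:
            raise ConfigError("total_generations must exceed the last phase start")

    def active_phase(self, generation: int) -> Phase:
        """Phase governing the cycle that produces the cohort of ``generation``.

        A phase starting at t governs cycles t+1, t+2, ...; the transition
        itself is applied to the standing population once generation t is
        complete.
        """
        current = self.phases[0]
        for phase in self.phases:
            if phase.start < generation:
                current = phase
        return current

    def phase_starting_at(self, generation: int) -> Phase | None:
        for phase in self.phases:
            if phase.start == generation:
                return phase
        return None


def _variant(fission_type: str, variance: bool, violence: bool) -> Mapping:
    return {
        "fission_type": fission_type,
        "sigma": 0.1 if variance else 0.0,
        "violence_rate": 0.15 if violence else 0.0,
    }


_SCENARIO_2_SETTINGS = {
    # fission type, variance in reproductive success, violent competition
    "2a": (RANDOM_FISSION, False, False),
    "2b": (RANDOM_FISSION, False, True),
    "2c": (LINEAL_FISSION, False, False),
    "2d": (LINEAL_FISSION, False, True),
    "2e": (RANDOM_FISSION, True, False),
    "2f": (RANDOM_FISSION, True, True),
    "2g": (LINEAL_FISSION, True, False),
    "2h": (LINEAL_FISSION, True, True),
}

_2G = _variant(LINEAL_FISSION, True, False)
_2C = _variant(LINEAL_FISSION, False, False)


def scenario_names() -> tuple[str, ...]:
    return ("1",) + tuple(_SCENARIO_2_SETTINGS) + ("3a", "3b", "3c", "4a", "4b", "4c", "polygyny")


def preset(name: str) -> ScenarioPreset:
    """Return the phase schedule for a named scenario.

    ``"1"`` is the bilateral patrilocal control; ``"2a"``–``"2h"`` toggle
    fission type, between-group variance in reproductive success and violent
    competition; ``"3a"``–``"3c"`` prepend 100 generations of bilateral
    descent (patrilocal, multilocal, matrilocal) before a patrilineal phase
    with the 2g settings; ``"4a"`` extends 2g to 200 generations, ``"4b"``
    follows 100 generations of 2g with 100 bilateral generations, ``"4c"``
    with 100 patrilineal generations without variance (2c settings);
    ``"polygyny"`` is a bilateral patrilocal population with geometric
    male mating weights.
    """
    if name == "1":
        return ScenarioPreset("1", (Phase(0, BILATERAL, PATRILOCAL),), 100)
    if name in _SCENARIO_2_SETTINGS:
        fission, variance, violence = _SCENARIO_2_SETTINGS[name]
        return ScenarioPreset(
            name,
            (Phase(0, PATRILINEAL, PATRILOCAL, _variant(fission, variance, violence)),),
            100,
        )
    if name in ("3a", "3b", "3c"):
        residence = {"3a": PATRILOCAL, "3b": MULTILOCAL, "3c": MATRILOCAL}[name]
        return ScenarioPreset(
            name,
            (Phase(0, BILATERAL, residence), Phase(100, PATRILINEAL, PATRILOCAL, _2G)),
            200,
        )
    if name == "4a":
        return ScenarioPreset("4a", (Phase(0, PATRILINEAL, PATRILOCAL, _2G),), 200)
    if name == "4b":
        return ScenarioPreset(
            "4b",
            (Phase(0, PATRILINEAL, PATRILOCAL, _2G), Phase(100, BILATERAL, PATRILOCAL)),
            200,
        )
    if name == "4c":
        return ScenarioPreset(
            "4c",
            (
                Phase(0, PATRILINEAL, PATRILOCAL, _2G),
                Phase(100, PATRILINEAL, PATRILOCAL, _2C),
            ),
            200,
        )
    if name == "polygyny":
        return ScenarioPreset(
            "polygyny",
            (Phase(0, BILATERAL, PATRILOCAL, {"polygyny": True}),),
            100,
        )
    raise ConfigError(f"unknown scenario {name!r}; known: {', '.join(scenario_names())}")
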