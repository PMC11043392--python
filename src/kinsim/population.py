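"""Agent state and the per-generation cycle.

The living cohort is held as flat numpy arrays (struct-of-arrays) for
speed: generations do not overlap, so parents are replaced wholesale by
their children each cycle.  Parent links of every individual ever born are
kept in a growing :class:`Pedigree`, which is what the uniparental
genealogy extraction later walks.

The cycle, applied once per generation, is: individual migration ->
reproduction (villages grow deterministically as round(N0 * exp(r t))) ->
violent deaths of newborn males (if enabled) -> fission checks, group
extinctions and post-fission group migration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import demography
from .config import (
    BILATERAL,
    PATRILINEAL,
    Phase,
    SimulationConfig,
    residence_migration_rates,
)

MALE = 1
FEMALE = 0


class Pedigree:
    """Append-only registry of parent links and birth generations.

    Individual ids are dense integers in order of creation; founders carry
    parent id -1 and are attached to the coalescent initializer through
    founder tokens kept by the genetics layer.
    """

    def __init__(self, capacity: int = 4096) -> None:
        self.father = np.full(capacity, -1, dtype=np.int32)
        self.mother = np.full(capacity, -1, dtype=np.int32)
        self.birth_generation = np.zeros(capacity, dtype=np.int32)
        self.size = 0

    def _grow(self, needed: int) -> None:
        cap = len(self.father)
        if self.size + needed <= cap:
            return
        new_cap = max(cap * 2, self.size + needed)
        for name in ("father", "mother", "birth_generation"):
            arr = getattr(self, name)
            new = np.full(new_cap, -1, dtype=np.int32)
            new[: self.size] = arr[: self.size]
            setattr(self, name, new)

    def append(self, fathers: np.ndarray, mothers: np.ndarray, generation: int) -> np.ndarray:
        """Register ``len(fathers)`` newborns; returns their new ids."""
        n = len(fathers)
        self._grow(n)
        ids = np.arange(self.size, self.size + n, dtype=np.int64)
        self.father[ids] = fathers
        self.mother[ids] = mothers
        self.birth_generation[ids] = generation
        self.size += n
        return ids


@dataclass
class DescentGroup:
    """A patrilineal unit: children affiliate with their father's group."""

    id: int
    village: int
    fitness: float
    last_fission: int
    founding_generation: int


@dataclass
class Population:
    """Living cohort plus descent-group registry and event logs."""

    config: SimulationConfig
    generation: int
    ids: np.ndarray            # pedigree ids of the living cohort
    sex: np.ndarray            # 1 = male, 0 = female
    village: np.ndarray
    group: np.ndarray          # group id, -1 in bilateral phases
    groups: dict[int, DescentGroup]
    pedigree: Pedigree
    next_group_id: int = 0
    events: list = field(default_factory=list)
    group_size_log: list = field(default_factory=list)

    # -- bookkeeping ---------------------------------------------------

    @property
    def size(self) -> int:
        return len(self.ids)

    def village_sizes(self) -> np.ndarray:
        return np.bincount(self.village, minlength=self.config.n_villages)

    def group_male_counts(self) -> dict[int, int]:
        males = self.group[self.sex == MALE]
        counts = dict.fromkeys(self.groups, 0)
        gids, n = np.unique(males[males >= 0], return_counts=True)
        counts.update(zip(gids.tolist(), n.tolist()))
        return counts

    def log_event(self, kind: str, **payload) -> None:
        self.events.append({"generation": self.generation, "type": kind, **payload})

    def log_group_sizes(self) -> None:
        if not self.groups:
            return
        gids = self.group[self.group >= 0]
        sizes = dict(zip(*map(np.ndarray.tolist, np.unique(gids, return_counts=True))))
        male_counts = self.group_male_counts()
        for gid, grp in self.groups.items():
            self.group_size_log.append(
                (self.generation, gid, grp.village, sizes.get(gid, 0), male_counts[gid])
            )

    def check_consistency(self) -> None:
        """Cheap structural assertions, used by tests and after transitions."""
        assert len(self.ids) == len(self.sex) == len(self.village) == len(self.group)
        if self.groups:
            assert (self.group >= 0).all()
            for gid in np.unique(self.group):
                assert int(gid) in self.groups
        else:
            assert (self.group == -1).all()
        if (self.village_sizes() == 0).any():
            raise RuntimeError(f"a village emptied at generation {self.generation}")


def _alternating_sexes(n: int) -> np.ndarray:
    sexes = np.empty(n, dtype=np.int8)
    sexes[0::2] = MALE
    sexes[1::2] = FEMALE
    return sexes


def initialize_population(
    config: SimulationConfig,
    rng: np.random.Generator,
    patrilineal: bool = True,
    sigma: float | None = None,
) -> Population:
    """Found the structured population at t_0.

    Each of the ``n_villages`` villages holds ``village_init_size`` founders
    with alternating sexes; under patrilineal descent every village is split
    into three groups of ``group_init_size`` whose relative fitnesses are
    drawn from Normal(growth_rate, sigma**2).
    """
    sigma = config.sigma if sigma is None else sigma
    pedigree = Pedigree()
    n = config.n_total
    fathers = np.full(n, -1, dtype=np.int64)
    ids = pedigree.append(fathers, fathers, 0)
    village = np.repeat(np.arange(config.n_villages, dtype=np.int16), config.village_init_size)
    sex = np.tile(_alternating_sexes(config.village_init_size), config.n_villages)
    pop = Population(
        config=config,
        generation=0,
        ids=ids,
        sex=sex,
        village=village,
        group=np.full(n, -1, dtype=np.int32),
        groups={},
        pedigree=pedigree,
    )
    if patrilineal:
        _seed_groups(pop, rng, sigma)
    pop.log_group_sizes()
    return pop


def _seed_groups(pop: Population, rng: np.random.Generator, sigma: float) -> None:
    """Partition every village into 3 equal groups with fresh fitness draws."""
    config = pop.config
    sd = float(sigma)
    group = np.full(pop.size, -1, dtype=np.int32)
    groups: dict[int, DescentGroup] = {}
    gid = pop.next_group_id
    for v in range(config.n_villages):
        for s in (MALE, FEMALE):
            idx = np.flatnonzero((pop.village == v) & (pop.sex == s))
            rng.shuffle(idx)
            # balanced split into 3: np.array_split keeps sizes within 1
            for k, part in enumerate(np.array_split(idx, 3)):
                group[part] = gid + k
        for k in range(3):
            groups[gid + k] = DescentGroup(
                id=gid + k,
                village=v,
                fitness=float(rng.normal(config.growth_rate, sd)),
                last_fission=pop.generation,
                founding_generation=pop.generation,
            )
        gid += 3
    pop.group = group
    pop.groups = groups
    pop.next_group_id = gid


def apply_phase_transition(
    pop: Population, new_phase: Phase, rng: np.random.Generator
) -> None:
    """Swap descent/residence rules on the standing population.

    Entering a patrilineal phase from a bilateral one partitions each
    village into three equal groups (random assignment, balanced sexes)
    with fresh fitness draws; leaving one dissolves the group registry.  A
    patrilineal-to-patrilineal change re-draws group fitnesses from
    Normal(growth_rate, sigma_new**2) so the new spread regime applies to
    standing groups as well as to future fissions.
    """
    cfg = new_phase.effective_config(pop.config)
    currently_patrilineal = bool(pop.groups)
    if new_phase.descent == PATRILINEAL and not currently_patrilineal:
        _seed_groups(pop, rng, cfg.sigma)
        pop.log_event("phase_transition", detail="bilateral->patrilineal")
    elif new_phase.descent == BILATERAL and currently_patrilineal:
        pop.groups = {}
        pop.group = np.full(pop.size, -1, dtype=np.int32)
        pop.log_event("phase_transition", detail="patrilineal->bilateral")
    elif new_phase.descent == PATRILINEAL and currently_patrilineal:
        sd = float(cfg.sigma)
        for grp in pop.groups.values():
            grp.fitness = float(rng.normal(cfg.growth_rate, sd))
        pop.log_event("phase_transition", detail="patrilineal fitness re-draw")


def run_generation(
    pop: Population,
    phase: Phase,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> Population:
    """Advance the population by one generation in place.

    Operator order: (1) individual migration, (2) reproduction to the
    deterministic per-village target size, (3) violence on the newborn male
    cohort, (4) fissions, extinctions and post-fission group migration.
    """
    cfg = phase.effective_config(config)
    patrilineal = phase.descent == PATRILINEAL
    m_f, m_m = residence_migration_rates(phase.residence, cfg)

    demography.migrate_individuals(pop, m_f, m_m, rng)

    t_next = pop.generation + 1
    target = cfg.village_target_size(t_next)
    demography.reproduce(pop, cfg, target, patrilineal, rng)
    pop.generation = t_next

    if patrilineal and cfg.violence_rate > 0:
        demography.apply_violence(pop, cfg.violence_rate, rng, cfg.violence_arena)

    if patrilineal:
        outcomes = demography.check_and_execute_fissions(pop, cfg, rng)
        demography.remove_extinct_groups(pop)
        if cfg.post_fission_migration and outcomes:
            demography.post_fission_migrate(pop, outcomes, rng)

    pop.log_group_sizes()
    if (pop.village_sizes() == 0).any():
        raise RuntimeError(f"a village emptied at generation {pop.generation}")
    return pop
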