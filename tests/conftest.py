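"""Shared fixtures and small-population helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from kinsim.config import (
    PATRILINEAL,
    PATRILOCAL,
    Phase,
    ScenarioPreset,
    SimulationConfig,
)
from kinsim.population import DescentGroup, Pedigree, Population

# A small but structurally valid population: 3 villages of 60, descent
# groups of 20, so whole replicates run in milliseconds.
TINY = dict(
    n_total=180,
    n_villages=3,
    village_init_size=60,
    group_init_size=20,
    sample_per_village=10,
    sample_interval=5,
)


def tiny_config(**overrides) -> SimulationConfig:
    kw = dict(TINY)
    kw.update(overrides)
    return SimulationConfig(**kw)


def tiny_preset(
    descent: str = PATRILINEAL,
    generations: int = 10,
    name: str = "tiny",
    **phase_overrides,
) -> ScenarioPreset:
    return ScenarioPreset(
        name, (Phase(0, descent, PATRILOCAL, phase_overrides),), generations
    )


def manual_pop(
    groups_spec: list[tuple[int, int, int]],
    config: SimulationConfig | None = None,
    generation: int = 10,
    last_fission: int = 0,
) -> Population:
    """Hand-built population: one (village, n_males, n_females) per group.

    All members are pedigree founders (parent -1), so lineal fission sees
    every male as his own paternal line.
    """
    config = config or tiny_config()
    pedigree = Pedigree()
    sexes, villages, group_ids = [], [], []
    groups: dict[int, DescentGroup] = {}
    for gid, (village, n_m, n_f) in enumerate(groups_spec):
        sexes += [1] * n_m + [0] * n_f
        villages += [village] * (n_m + n_f)
        group_ids += [gid] * (n_m + n_f)
        groups[gid] = DescentGroup(
            id=gid,
            village=village,
            fitness=0.01,
            last_fission=last_fission,
            founding_generation=0,
        )
    n = len(sexes)
    none = np.full(n, -1, dtype=np.int64)
    ids = pedigree.append(none, none, 0)
    return Population(
        config=config,
        generation=generation,
        ids=ids,
        sex=np.array(sexes, dtype=np.int8),
        village=np.array(villages, dtype=np.int16),
        group=np.array(group_ids, dtype=np.int32),
        groups=groups,
        pedigree=pedigree,
        next_group_id=len(groups_spec),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
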