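"""Single-replicate driver: forward simulation plus diversity tracking.

One replicate founds the structured population at t_0 (generation 0),
attaches coalescent initial genealogies for the Y chromosome (750 male
founder lineages) and mtDNA (all 1500 founders, haploid size 750), runs
the per-generation cycle through the scenario's phase schedule, and every
``sample_interval`` generations measures nucleotide diversity from 20
sampled individuals per village (the sampled males for the Y chromosome,
all sampled individuals for mtDNA), with both the within-village mean and
the pooled (global) pi converted to effective sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PATRILINEAL, ScenarioPreset, SimulationConfig
from .genetics import (
    MT_MARKER,
    Y_MARKER,
    BurnInTree,
    coalescent_burn_in,
    drop_mutations,
    extract_gene_tree,
    pairwise_pi,
)
from .population import (
    MALE,
    Population,
    apply_phase_transition,
    initialize_population,
    run_generation,
)
from .stats import ne_from_pi

WITHIN = "within_village_mean"
GLOBAL = "global"


@dataclass
class ReplicateResult:
    """Outputs of one replicate: diversity series plus event/size logs."""

    seed: int
    diversity: pd.DataFrame
    events: pd.DataFrame
    group_sizes: pd.DataFrame
    population: Population | None = None
    burn_in: dict = field(default_factory=dict)
    founder_tips: dict = field(default_factory=dict)


def founder_tip_maps(config: SimulationConfig) -> dict[str, np.ndarray]:
    """Map founder pedigree ids to burn-in tips for each marker.

    Founder males (ids with even in-village rank by construction) carry the
    Y tips 0..749 in id order; every founder carries an mtDNA tip.
    """
    n = config.n_total
    village = np.repeat(np.arange(config.n_villages), config.village_init_size)
    del village  # founders are ids 0..n-1; sex alternates male-first
    sex = np.tile(np.arange(config.village_init_size) % 2 == 0, config.n_villages)
    y_tips = np.full(n, -1, dtype=np.int64)
    y_tips[sex] = np.arange(sex.sum())
    mt_tips = np.arange(n, dtype=np.int64)
    return {Y_MARKER: y_tips, MT_MARKER: mt_tips}


def measure_diversity(
    pop: Population,
    burn_in: dict[str, BurnInTree],
    founder_tips: dict[str, np.ndarray],
    rng: np.random.Generator,
    config: SimulationConfig,
) -> list[dict]:
    """Within-village-mean and global pi/Ne for both markers at the
    population's current generation."""
    t = pop.generation
    # one sample of individuals per village serves both markers: the males
    # carry the Y chromosome, everyone carries mtDNA
    sample_parts: list[np.ndarray] = []
    for v in range(config.n_villages):
        cand = np.flatnonzero(pop.village == v)
        k = min(config.sample_per_village, len(cand))
        sample_parts.append(rng.choice(cand, size=k, replace=False))
    sample_village = np.concatenate(
        [np.full(len(s), v) for v, s in enumerate(sample_parts)]
    )
    sample = np.concatenate(sample_parts)
    out: dict[str, dict[str, float]] = {}
    for marker, mu, length in (
        (Y_MARKER, config.mu_y, config.len_y),
        (MT_MARKER, config.mu_mt, config.len_mt),
    ):
        if marker == Y_MARKER:
            keep = pop.sex[sample] == MALE
        else:
            keep = np.ones(len(sample), dtype=bool)
        idx = sample[keep]
        leaf_village = sample_village[keep]
        tree = extract_gene_tree(
            pop.ids[idx],
            pop.pedigree,
            burn_in[marker],
            founder_tips[marker],
            t,
            marker,
            sample_sexes=pop.sex[idx] if marker == Y_MARKER else None,
        )
        seqs = drop_mutations(tree, mu, length, rng)
        pi_villages = [
            pairwise_pi(seqs, np.flatnonzero(leaf_village == v))
            for v in range(config.n_villages)
            if (leaf_village == v).sum() >= 2
        ]
        out[marker] = {
            "within": float(np.mean(pi_villages)),
            "global": pairwise_pi(seqs),
            "mu": mu,
        }
    rows = []
    for scope, key in ((WITHIN, "within"), (GLOBAL, "global")):
        ne_y = ne_from_pi(out[Y_MARKER][key], config.mu_y)
        ne_mt = ne_from_pi(out[MT_MARKER][key], config.mu_mt)
        rows.append(
            {
                "generation": t,
                "scope": scope,
                "pi_y": out[Y_MARKER][key],
                "pi_mt": out[MT_MARKER][key],
                "ne_y": ne_y,
                "ne_mt": ne_mt,
                "ratio": ne_mt / ne_y if ne_y > 0 else np.nan,
            }
        )
    return rows


def run_replicate(
    preset: ScenarioPreset,
    config: SimulationConfig,
    seed: int,
    keep_population: bool = False,
) -> ReplicateResult:
    """Run one seeded replicate of a scenario.

    Randomness is split into named substreams (demography, genetics,
    coalescent initialisation) spawned from the replicate seed, so
    measurement draws never perturb the demographic trajectory.
    """
    ss = np.random.SeedSequence(seed)
    demog_ss, genet_ss, burn_ss = ss.spawn(3)
    demog_rng = np.random.default_rng(demog_ss)
    genet_rng = np.random.default_rng(genet_ss)
    burn_seed_y, burn_seed_mt = (
        np.random.default_rng(burn_ss).integers(1, 2**31 - 1, size=2).tolist()
    )

    phase0 = preset.phases[0]
    cfg0 = phase0.effective_config(config)
    pop = initialize_population(
        config, demog_rng, patrilineal=phase0.descent == PATRILINEAL, sigma=cfg0.sigma
    )
    n_males = int((pop.sex == MALE).sum())
    burn_in = {
        Y_MARKER: coalescent_burn_in(n_males, n_males, burn_seed_y),
        MT_MARKER: coalescent_burn_in(config.n_total, n_males, burn_seed_mt),
    }
    tips = founder_tip_maps(config)

    rows = measure_diversity(pop, burn_in, tips, genet_rng, config)
    for t in range(1, preset.total_generations + 1):
        phase = preset.active_phase(t)
        run_generation(pop, phase, config, demog_rng)
        if t % config.sample_interval == 0:
            rows.extend(measure_diversity(pop, burn_in, tips, genet_rng, config))
        transition = preset.phase_starting_at(t)
        if transition is not None:
            apply_phase_transition(pop, transition, demog_rng)

    diversity = pd.DataFrame(rows)
    events = pd.DataFrame(pop.events, columns=None if pop.events else ["generation", "type"])
    group_sizes = pd.DataFrame(
        pop.group_size_log, columns=["generation", "group", "village", "size", "males"]
    )
    return ReplicateResult(
        seed=seed,
        diversity=diversity,
        events=events,
        group_sizes=group_sizes,
        population=pop if keep_population else None,
        burn_in=burn_in if keep_population else {},
        founder_tips=tips if keep_population else {},
    )
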