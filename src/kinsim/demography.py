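"""Stochastic demographic operators.

Implements individual migration, exogamous pair formation, fitness-weighted
offspring assignment, the Kipsigis-like polygynous mating scheme,
size-dependent violent deaths, random and lineal descent-group fission with
noisy fitness transmission, post-fission group migration and group
extinction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import LINEAL_FISSION, RANDOM_FISSION, SimulationConfig

MALE = 1
FEMALE = 0


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------

def migrate_individuals(pop, m_f: float, m_m: float, rng: np.random.Generator) -> int:
    """Move each female w.p. ``m_f`` and each male w.p. ``m_m`` to a
    uniformly chosen other village; in patrilineal phases the migrant joins
    a uniformly chosen descent group of the destination village.

    Returns the number of migrants.
    """
    if m_f == 0.0 and m_m == 0.0:
        return 0
    n_villages = pop.config.n_villages
    p = np.where(pop.sex == MALE, m_m, m_f)
    moves = rng.random(pop.size) < p
    movers = np.flatnonzero(moves)
    if len(movers) == 0:
        return 0
    # uniform among the other villages
    shift = rng.integers(1, n_villages, size=len(movers))
    dest = (pop.village[movers] + shift) % n_villages
    pop.village[movers] = dest
    if pop.groups:
        by_village: dict[int, list[int]] = {}
        for gid, grp in pop.groups.items():
            by_village.setdefault(grp.village, []).append(gid)
        for i, v in zip(movers, dest):
            gids = by_village.get(int(v))
            if gids:
                pop.group[i] = gids[rng.integers(0, len(gids))]
    return len(movers)


# ---------------------------------------------------------------------------
# pair formation
# ---------------------------------------------------------------------------

@dataclass
class MatingPool:
    """Monogamous (or polygynous) couples within one village.

    ``male_sel``/``female_sel`` index into the village's male and female
    index arrays; element i of each forms couple i.
    """

    male_sel: np.ndarray
    female_sel: np.ndarray
    n_single_males: int
    n_single_females: int

    @property
    def n_pairs(self) -> int:
        return len(self.male_sel)


def form_mating_pairs(
    male_groups: np.ndarray,
    female_groups: np.ndarray,
    exogamous: bool,
    rng: np.random.Generator,
) -> MatingPool:
    """Randomly pair males and females, preferring cross-group couples.

    min(males, females) couples are always formed, so no individual stays
    single except through sex-ratio imbalance.  Under exogamy, same-group
    couples are iteratively repaired (reshuffles among clashing couples,
    then swaps with compatible couples); couples that cannot be made
    cross-group fall back to within-group mating.
    """
    n_m, n_f = len(male_groups), len(female_groups)
    n = min(n_m, n_f)
    m_sel = rng.permutation(n_m)[:n]
    f_sel = rng.permutation(n_f)[:n]
    if exogamous and n > 0:
        mg = male_groups[m_sel]
        for _ in range(30):
            fg = female_groups[f_sel]
            bad = np.flatnonzero(mg == fg)
            if len(bad) == 0:
                break
            if len(bad) >= 2:
                f_sel[bad] = f_sel[bad[rng.permutation(len(bad))]]
                fg = female_groups[f_sel]
                bad = np.flatnonzero(mg == fg)
                if len(bad) == 0:
                    break
            good = np.flatnonzero(mg != fg)
            if len(good) == 0:
                break  # single-group village: within-group fallback
            partners = good[rng.integers(0, len(good), size=len(bad))]
            # one swap attempt per clashing couple; keep partner indices unique
            _, first = np.unique(partners, return_index=True)
            bad, partners = bad[first], partners[first]
            ok = (male_groups[m_sel[bad]] != female_groups[f_sel[partners]]) & (
                male_groups[m_sel[partners]] != female_groups[f_sel[bad]]
            )
            b, p = bad[ok], partners[ok]
            f_sel[b], f_sel[p] = f_sel[p].copy(), f_sel[b].copy()
    return MatingPool(m_sel, f_sel, n_m - n, n_f - n)


def form_polygynous_pairs(
    n_males: int, n_females: int, p_geometric: float, rng: np.random.Generator
) -> MatingPool:
    """Kipsigis-like mating: each female draws a husband with replacement,
    male j with probability X_j / sum(X), X ~ Geometric(p) on {1, 2, ...}."""
    weights = rng.geometric(p_geometric, size=n_males).astype(float)
    probs = weights / weights.sum()
    husbands = rng.choice(n_males, size=n_females, p=probs)
    return MatingPool(husbands, np.arange(n_females), 0, 0)


# ---------------------------------------------------------------------------
# offspring assignment
# ---------------------------------------------------------------------------

def father_group_probabilities(
    male_counts: np.ndarray, fitnesses: np.ndarray
) -> np.ndarray:
    """Probability that a child's father belongs to each group:
    P_j = 2 M_j exp(r_j) / sum_i 2 M_i exp(r_i)."""
    w = 2.0 * male_counts * np.exp(fitnesses)
    total = w.sum()
    if total <= 0:
        raise ValueError("no group has any males")
    return w / total


def assign_offspring(
    pool: MatingPool,
    pair_male_groups: np.ndarray,
    village_male_counts: dict[int, int],
    group_fitness: dict[int, float],
    n_children: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw a couple index for each of ``n_children`` children.

    The father's group is drawn with the fitness-weighted probability
    (restricted to groups with at least one couple, re-normalised: groups
    whose males are all single cannot be drawn), then a uniform couple
    within that group.
    """
    gids = np.unique(pair_male_groups)
    counts = np.array([village_male_counts[g] for g in gids], dtype=float)
    fits = np.array([group_fitness[g] for g in gids])
    probs = father_group_probabilities(counts, fits)
    per_group = rng.multinomial(n_children, probs)
    chosen = np.empty(n_children, dtype=np.int64)
    pos = 0
    for g, c in zip(gids, per_group):
        if c == 0:
            continue
        cand = np.flatnonzero(pair_male_groups == g)
        chosen[pos : pos + c] = cand[rng.integers(0, len(cand), size=c)]
        pos += c
    rng.shuffle(chosen)
    return chosen


def reproduce(
    pop,
    cfg: SimulationConfig,
    village_target: int,
    patrilineal: bool,
    rng: np.random.Generator,
) -> None:
    """Replace the living cohort by its children (non-overlapping
    generations).  Every village produces exactly ``village_target``
    children with alternating sexes."""
    new_fathers, new_mothers, new_village, new_group, new_sex = [], [], [], [], []
    for v in range(cfg.n_villages):
        in_v = pop.village == v
        m_idx = np.flatnonzero(in_v & (pop.sex == MALE))
        f_idx = np.flatnonzero(in_v & (pop.sex == FEMALE))
        if len(m_idx) == 0 or len(f_idx) == 0:
            raise RuntimeError(
                f"village {v} lacks one sex at generation {pop.generation}; "
                "cannot reproduce"
            )
        if cfg.polygyny and not patrilineal:
            pool = form_polygynous_pairs(len(m_idx), len(f_idx), cfg.polygyny_p, rng)
        else:
            pool = form_mating_pairs(
                pop.group[m_idx], pop.group[f_idx], exogamous=patrilineal, rng=rng
            )
        if patrilineal:
            pair_groups = pop.group[m_idx[pool.male_sel]]
            male_counts = dict(
                zip(*map(np.ndarray.tolist, np.unique(pop.group[m_idx], return_counts=True)))
            )
            fitness = {g: pop.groups[g].fitness for g in male_counts}
            chosen = assign_offspring(
                pool, pair_groups, male_counts, fitness, village_target, rng
            )
        else:
            chosen = rng.integers(0, pool.n_pairs, size=village_target)
        fathers = pop.ids[m_idx[pool.male_sel[chosen]]]
        mothers = pop.ids[f_idx[pool.female_sel[chosen]]]
        new_fathers.append(fathers)
        new_mothers.append(mothers)
        new_village.append(np.full(village_target, v, dtype=np.int16))
        if patrilineal:
            new_group.append(pop.group[m_idx[pool.male_sel[chosen]]])
        else:
            new_group.append(np.full(village_target, -1, dtype=np.int32))
        sexes = np.empty(village_target, dtype=np.int8)
        sexes[0::2] = MALE
        sexes[1::2] = FEMALE
        new_sex.append(sexes)
    fathers = np.concatenate(new_fathers)
    mothers = np.concatenate(new_mothers)
    pop.ids = pop.pedigree.append(fathers, mothers, pop.generation + 1)
    pop.sex = np.concatenate(new_sex)
    pop.village = np.concatenate(new_village)
    pop.group = np.concatenate(new_group)


# ---------------------------------------------------------------------------
# violence
# ---------------------------------------------------------------------------

@dataclass
class ViolenceDraw:
    """Realisation of one generation of violent male deaths."""

    rho: float
    expected: dict[int, float]
    kills: dict[int, int]
    realized_total: int


def violence_rates(
    male_counts: dict[int, int],
    e: float,
    villages: dict[int, int] | None = None,
) -> tuple[float, dict[int, float]]:
    """Per-group expected kill counts rho * (sum_{i != j} N_i) * sqrt(N_j),
    with rho solved so the expectations sum to ``e`` times the male total.

    Intergroup competition is local: the sum runs over the other groups of
    the same village (``villages`` maps group id to village; when omitted
    all groups share one arena).  Males of small groups face a higher
    per-capita risk than males of large groups, and a group that alone
    dominates its village faces almost none.  When every village has a
    single group all rates vanish and the caller falls back to uniform
    killing.
    """
    gids = list(male_counts)
    n = np.array([male_counts[g] for g in gids], dtype=float)
    total = n.sum()
    if villages is None:
        rivals = total - n
        base = rivals * np.sqrt(n)
        denom = base.sum()
        if denom <= 0:
            return 0.0, {g: 0.0 for g in gids}
        rho = e * total / denom
        return rho, dict(zip(gids, rho * base))
    vil = np.array([villages[g] for g in gids])
    expected = np.zeros(len(gids))
    rho_mean = 0.0
    n_arenas = 0
    for v in set(villages.values()):
        inv = vil == v
        nv = n[inv]
        base = (nv.sum() - nv) * np.sqrt(nv)
        denom = base.sum()
        if denom <= 0:  # single-group village: no rival groups, no violence
            continue
        rho_v = e * nv.sum() / denom
        expected[inv] = rho_v * base
        rho_mean += rho_v
        n_arenas += 1
    if n_arenas == 0:
        return 0.0, {g: 0.0 for g in gids}
    return rho_mean / n_arenas, dict(zip(gids, expected))


def apply_violence(
    pop, e: float, rng: np.random.Generator, arena: str = "population"
) -> ViolenceDraw:
    """Kill males of the newborn cohort, Poisson per descent group with the
    size-dependent rates above (draws truncated at group male counts).
    ``arena`` selects whether rival males are counted population-wide or
    within the group's own village."""
    male_counts = pop.group_male_counts()
    total_males = sum(male_counts.values())
    villages = (
        {gid: pop.groups[gid].village for gid in male_counts}
        if arena == "village"
        else None
    )
    rho, expected = violence_rates(male_counts, e, villages)
    kills: dict[int, int] = {}
    if rho == 0.0 and arena == "village":
        # every village is a monopoly: intergroup violence has no rivals
        return ViolenceDraw(0.0, expected, kills, 0)
    if rho == 0.0:
        # degenerate single-group population: uniform killing of e * males
        n_kill = round(e * total_males)
        males = np.flatnonzero(pop.sex == MALE)
        victims = rng.choice(males, size=n_kill, replace=False)
        gid = next(iter(male_counts), -1)
        kills[gid] = n_kill
        pop.log_event("kills", group=int(gid), count=int(n_kill), fallback=True)
    else:
        victims_parts = []
        for gid, lam in expected.items():
            d = min(int(rng.poisson(lam)), male_counts[gid])
            if d == 0:
                continue
            kills[gid] = d
            members = np.flatnonzero((pop.group == gid) & (pop.sex == MALE))
            victims_parts.append(rng.choice(members, size=d, replace=False))
            pop.log_event("kills", group=int(gid), count=int(d))
        victims = np.concatenate(victims_parts) if victims_parts else np.empty(0, dtype=int)
    if len(victims):
        keep = np.ones(pop.size, dtype=bool)
        keep[victims] = False
        pop.ids = pop.ids[keep]
        pop.sex = pop.sex[keep]
        pop.village = pop.village[keep]
        pop.group = pop.group[keep]
    return ViolenceDraw(rho, expected, kills, int(len(victims)))


# ---------------------------------------------------------------------------
# fission
# ---------------------------------------------------------------------------

@dataclass
class FissionOutcome:
    """One descent-group split: the parent is replaced by two children."""

    parent: int
    children: tuple[int, int]
    village: int
    male_proportion: float
    child_sizes: tuple[int, int]
    fission_type: str


def draw_split_proportion(rng: np.random.Generator) -> float:
    """Truncated Normal(0.5, variance 0.5) on [0, 1] by rejection."""
    sd = math.sqrt(0.5)
    while True:
        q = rng.normal(0.5, sd)
        if 0.0 <= q <= 1.0:
            return q


def lineal_partition(
    male_ids: np.ndarray,
    pedigree,
    max_depth: int,
    target_proportion: float,
    rng: np.random.Generator,
) -> np.ndarray | None:
    """Split a group's males into two sets of complete paternal clades.

    Males are classed by their paternal-line ancestor at the deepest
    genealogical level (at most ``max_depth`` generations back, normally
    the full pedigree depth) at which more than one ancestral line
    survives, so each side of the split descends from a different most
    recent common ancestor through the male line; the resulting clades
    are greedily packed (largest first) into the side that keeps the
    realised male fraction closest to ``target_proportion``.  Returns a
    boolean mask for set A, or None for a star genealogy (all males
    paternal brothers), in which case the caller falls back to a random
    split.
    """
    m = len(male_ids)
    if m < 2 or max_depth < 1:
        return None
    anc = np.asarray(male_ids, dtype=np.int64)
    chosen_labels = None
    for _ in range(max_depth):
        parent = pedigree.father[anc]
        at_top = parent < 0
        anc = np.where(~at_top, parent.astype(np.int64), anc)
        labels, inverse = np.unique(anc, return_inverse=True)
        if len(labels) < 2:
            break
        chosen_labels = inverse.copy()
        if at_top.all():  # distinct founder lineages: deepest level reached
            break
    if chosen_labels is None:
        return None
    n_clades = chosen_labels.max() + 1
    sizes = np.bincount(chosen_labels, minlength=n_clades)
    order = np.argsort(-sizes + rng.random(n_clades) * 1e-9)  # desc, random ties
    in_a = np.zeros(n_clades, dtype=bool)
    a = 0
    for c in order:
        if abs((a + sizes[c]) / m - target_proportion) < abs(a / m - target_proportion):
            in_a[c] = True
            a += sizes[c]
    # both sides must be non-empty
    if a == 0:
        smallest = order[np.argmin(sizes[order])]
        in_a[smallest] = True
    elif a == m:
        sel = np.flatnonzero(in_a)
        in_a[sel[np.argmin(sizes[sel])]] = False
    return in_a[chosen_labels]


def check_and_execute_fissions(pop, cfg: SimulationConfig, rng) -> list[FissionOutcome]:
    """Fission every group with 2 * males > N_max whose last fission is more
    than ``fission_cooldown`` generations old.

    The male split fraction is drawn from the truncated normal; males are
    partitioned per the fission type; females follow so both children keep
    the parent's sex ratio; each child draws a fresh relative fitness from
    Normal(r_parent, sigma**2)."""
    outcomes: list[FissionOutcome] = []
    sd = float(cfg.sigma)
    for gid in sorted(pop.groups):
        grp = pop.groups[gid]
        members = np.flatnonzero(pop.group == gid)
        m_idx = members[pop.sex[members] == MALE]
        n_males = len(m_idx)
        if 2 * n_males <= cfg.fission_threshold:
            continue
        if pop.generation - grp.last_fission <= cfg.fission_cooldown:
            continue
        f_idx = members[pop.sex[members] == FEMALE]
        mask_a = None
        fission_type = cfg.fission_type
        if cfg.fission_type == LINEAL_FISSION:
            # climb the full male genealogy: a group formed by fission is a
            # clade whose common ancestor predates the group's founding
            mask_a = lineal_partition(
                pop.ids[m_idx],
                pop.pedigree,
                max(pop.generation, 1),
                draw_split_proportion(rng),
                rng,
            )
            if mask_a is None:
                pop.log_event("degenerate_lineal_fission", group=gid)
                fission_type = RANDOM_FISSION
        if mask_a is None:
            for _ in range(100):  # redraw proportions that empty a child
                q = draw_split_proportion(rng)
                n_a = round(q * n_males)
                if 0 < n_a < n_males:
                    break
            else:
                n_a = max(1, min(n_males - 1, n_males // 2))
            mask_a = np.zeros(n_males, dtype=bool)
            mask_a[rng.choice(n_males, size=n_a, replace=False)] = True
        prop = mask_a.sum() / n_males
        # females follow the realised male fraction to balance the sex ratio
        n_fa = round(prop * len(f_idx))
        f_mask_a = np.zeros(len(f_idx), dtype=bool)
        if n_fa > 0:
            f_mask_a[rng.choice(len(f_idx), size=n_fa, replace=False)] = True
        gid_a, gid_b = pop.next_group_id, pop.next_group_id + 1
        pop.next_group_id += 2
        for new_gid in (gid_a, gid_b):
            pop.groups[new_gid] = type(grp)(
                id=new_gid,
                village=grp.village,
                fitness=float(rng.normal(grp.fitness, sd)),
                last_fission=pop.generation,
                founding_generation=pop.generation,
            )
        pop.group[m_idx[mask_a]] = gid_a
        pop.group[m_idx[~mask_a]] = gid_b
        pop.group[f_idx[f_mask_a]] = gid_a
        pop.group[f_idx[~f_mask_a]] = gid_b
        del pop.groups[gid]
        sizes = (int(mask_a.sum() + n_fa), int(len(members) - mask_a.sum() - n_fa))
        outcome = FissionOutcome(
            parent=gid,
            children=(gid_a, gid_b),
            village=grp.village,
            male_proportion=float(prop),
            child_sizes=sizes,
            fission_type=fission_type,
        )
        outcomes.append(outcome)
        pop.log_event(
            "fission",
            group=gid,
            children=(gid_a, gid_b),
            village=grp.village,
            proportion=float(prop),
            fission_type=fission_type,
        )
    return outcomes


def remove_extinct_groups(pop) -> list[int]:
    """Drop groups with zero living members, logging an extinction each."""
    alive = set(np.unique(pop.group[pop.group >= 0]).tolist())
    extinct = [gid for gid in pop.groups if gid not in alive]
    for gid in extinct:
        del pop.groups[gid]
        pop.log_event("extinction", group=gid)
    return extinct


def post_fission_migrate(pop, outcomes: list[FissionOutcome], rng) -> None:
    """Relocate the smaller child of every fission to another village.

    All moving groups first leave their sources, then destinations are
    assigned sequentially to the currently smallest other village (ties
    broken at random), so simultaneous fissions in two villages exchange
    their smaller children and quiet villages host none.
    """
    sizes = pop.village_sizes().astype(np.int64)
    movers: list[tuple[int, int, int]] = []  # (gid, src, n_members)
    for out in outcomes:
        a, b = out.children
        if a not in pop.groups or b not in pop.groups:
            continue  # a child already went extinct this generation
        na = int((pop.group == a).sum())
        nb = int((pop.group == b).sum())
        gid = a if (na < nb or (na == nb and rng.random() < 0.5)) else b
        n = na if gid == a else nb
        movers.append((gid, out.village, n))
        sizes[out.village] -= n
    for gid, src, n in movers:
        other = np.array([v for v in range(pop.config.n_villages) if v != src])
        candidate_sizes = sizes[other]
        minima = other[candidate_sizes == candidate_sizes.min()]
        dest = int(minima[rng.integers(0, len(minima))])
        members = np.flatnonzero(pop.group == gid)
        pop.village[members] = dest
        pop.groups[gid].village = dest
        sizes[dest] += n
        pop.log_event("group_migration", group=int(gid), source=int(src), dest=dest)
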