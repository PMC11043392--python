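"""Uniparental genealogies, coalescent initialisation, mutations and pi.

The forward simulation records only parent links; genetic diversity is
computed on demand by collapsing the pedigree paths of a sample into a
coalescent gene tree (Y chromosome through fathers, mtDNA through
mothers).  Lineages that are still distinct at the founding generation are
joined through a neutral coalescent genealogy of the founder lineages
(standing diversity of the long panmictic phase, generated exactly
backwards in time instead of by forward burn-in), and mutations are then
dropped on the branches as a Poisson process with Jukes-Cantor state
assignment.  At the simulated diversities (pi ~ 1e-4/site and below)
multiple hits are negligible, so sites are handled as segregating sites.
"""

from __future__ import annotations

from dataclasses import dataclass

import msprime
import numpy as np

Y_MARKER = "Y"
MT_MARKER = "mtDNA"
_BASES = np.array(list("ACGT"))


# ---------------------------------------------------------------------------
# coalescent initialisation of founder lineages
# ---------------------------------------------------------------------------

@dataclass
class BurnInTree:
    """Neutral coalescent genealogy of the founder lineages.

    ``parent``/``time`` are tskit-style arrays; tips are nodes
    0..n_tips-1 at time 0, times are in generations before the founding
    generation t_0.
    """

    n_tips: int
    parent: np.ndarray
    time: np.ndarray


def coalescent_burn_in(
    n_founder_lineages: int, haploid_size: int, seed: int
) -> BurnInTree:
    """Standard neutral coalescent of ``n_founder_lineages`` haploid
    lineages in a constant population of ``haploid_size``.

    Replaces a long forward panmictic phase: for a non-recombining neutral
    locus the backward coalescent draws from the same distribution of
    genealogies.  ``n_founder_lineages`` may exceed ``haploid_size`` (all
    1500 founders carry mtDNA although only the 750 females transmit it);
    the early multiple-merger-like burst of coalescences is then
    approximated by the continuous coalescent.
    """
    if n_founder_lineages < 2:
        return BurnInTree(
            n_founder_lineages,
            np.full(n_founder_lineages, -1, dtype=np.int32),
            np.zeros(n_founder_lineages),
        )
    ts = msprime.sim_ancestry(
        samples=n_founder_lineages,
        ploidy=1,
        population_size=haploid_size,
        random_seed=seed,
    )
    tree = ts.first()
    parent = np.array([tree.parent(u) for u in range(ts.num_nodes)], dtype=np.int32)
    return BurnInTree(n_founder_lineages, parent, ts.nodes_time.copy())


# ---------------------------------------------------------------------------
# gene-tree extraction from the pedigree
# ---------------------------------------------------------------------------

@dataclass
class GeneTree:
    """Collapsed coalescent genealogy of a same-generation sample.

    Nodes 0..n_leaves-1 are the sampled individuals (time 0); internal
    nodes follow in increasing age.  ``time`` is in generations before the
    sampling generation; ``parent`` is -1 at the root.
    """

    marker: str
    leaf_ids: np.ndarray
    parent: np.ndarray
    time: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    def branch_lengths(self) -> np.ndarray:
        """Length (generations) of the branch above each non-root node."""
        lengths = np.zeros(self.n_nodes)
        has_parent = self.parent >= 0
        lengths[has_parent] = self.time[self.parent[has_parent]] - self.time[has_parent]
        return lengths

    def total_branch_length(self) -> float:
        return float(self.branch_lengths().sum())

    def leaf_counts_below(self, leaf_mask: np.ndarray | None = None) -> np.ndarray:
        """Number of (masked) sample leaves at or below each node."""
        counts = np.zeros(self.n_nodes, dtype=np.int64)
        counts[: self.n_leaves] = 1 if leaf_mask is None else leaf_mask.astype(np.int64)
        for u in range(self.n_nodes):  # nodes are sorted children-before-parents
            p = self.parent[u]
            if p >= 0:
                counts[p] += counts[u]
        return counts

    def pair_tmrca(self, i: int, j: int) -> float:
        """Coalescence time of leaves ``i`` and ``j`` (generations)."""
        ancestors = {}
        u = i
        while u != -1:
            ancestors[u] = self.time[u]
            u = self.parent[u]
        u = j
        while u not in ancestors:
            u = self.parent[u]
        return float(self.time[u])


def extract_gene_tree(
    sample_ids: np.ndarray,
    pedigree,
    burn_in: BurnInTree,
    founder_tips: np.ndarray,
    t_sample: int,
    marker: str = Y_MARKER,
    sample_sexes: np.ndarray | None = None,
) -> GeneTree:
    """Collapse the pedigree paths of ``sample_ids`` into a gene tree.

    ``founder_tips`` maps founder pedigree ids to tips of ``burn_in``
    (-1 where a founder has no lineage for this marker); uncoalesced
    lineages are continued through the burn-in genealogy.  For the Y
    chromosome the sample must be all male (checked when
    ``sample_sexes`` is given); mtDNA lines are traced through mothers
    for individuals of either sex.
    """
    if marker not in (Y_MARKER, MT_MARKER):
        raise ValueError(f"unknown marker {marker!r}")
    if marker == Y_MARKER and sample_sexes is not None and not np.all(sample_sexes == 1):
        raise ValueError("Y-chromosome samples must contain only males")
    links = pedigree.father if marker == Y_MARKER else pedigree.mother
    n_ped = pedigree.size
    birth = pedigree.birth_generation

    def parent_of(x: int) -> int:
        """Next node up the lineage; burn-in nodes are offset by n_ped."""
        if x < n_ped:
            p = links[x]
            if p >= 0:
                return int(p)
            tip = founder_tips[x]
            if tip < 0:
                raise ValueError(f"individual {x} has no {marker} founder lineage")
            b = burn_in.parent[tip]
            return -1 if b < 0 else n_ped + int(b)
        b = burn_in.parent[x - n_ped]
        return -1 if b < 0 else n_ped + int(b)

    def time_of(x: int) -> float:
        if x < n_ped:
            return float(t_sample - birth[x])
        return float(t_sample + burn_in.time[x - n_ped])

    leaves = [int(x) for x in sample_ids]
    if len(set(leaves)) != len(leaves):
        raise ValueError("sample ids must be unique")
    count: dict[int, int] = {}
    for leaf in leaves:
        x = leaf
        while True:
            p = parent_of(x)
            if p == -1:
                break
            c = count.get(p, 0) + 1
            count[p] = c
            if c > 1:
                break
            x = p

    internal = sorted((u for u, c in count.items() if c >= 2), key=time_of)
    index = {u: len(leaves) + k for k, u in enumerate(internal)}
    n_nodes = len(leaves) + len(internal)
    parent_arr = np.full(n_nodes, -1, dtype=np.int64)
    time_arr = np.zeros(n_nodes)
    for k, u in enumerate(internal):
        time_arr[len(leaves) + k] = time_of(u)

    def first_internal_above(x: int) -> int:
        while True:
            p = parent_of(x)
            if p == -1:
                return -1
            if p in index:
                return index[p]
            x = p

    for i, leaf in enumerate(leaves):
        time_arr[i] = time_of(leaf)
        parent_arr[i] = first_internal_above(leaf)
    for u in internal:
        parent_arr[index[u]] = first_internal_above(u)
    time_arr[: len(leaves)] = 0.0  # same-generation leaves, ultrametric by construction
    return GeneTree(marker, np.asarray(sample_ids), parent_arr, time_arr)


# ---------------------------------------------------------------------------
# mutations and diversity
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Segregating-site haplotypes of the leaves of a gene tree.

    ``genotypes`` is an (n_leaves, n_sites) 0/1 matrix (ancestral /
    derived); positions are 0-based and strictly increasing, with
    ancestral and derived bases drawn under Jukes-Cantor.
    """

    marker: str
    length: int
    positions: np.ndarray
    ancestral: np.ndarray
    derived: np.ndarray
    genotypes: np.ndarray

    @property
    def n_sequences(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_sites(self) -> int:
        return self.genotypes.shape[1]

    def haplotype(self, i: int) -> str:
        """Variant-sites haplotype of leaf ``i`` (one char per site)."""
        return "".join(np.where(self.genotypes[i] == 1, self.derived, self.ancestral))

    def full_sequence(self, i: int, reference: str) -> str:
        seq = list(reference)
        for pos, base in zip(self.positions[self.genotypes[i] == 1], self.derived[self.genotypes[i] == 1]):
            seq[pos] = base
        return "".join(seq)


def drop_mutations(
    tree: GeneTree, mu: float, length: int, rng: np.random.Generator
) -> SequenceSet:
    """Poisson mutations at rate ``mu * length`` per branch-generation.

    Each mutation gets a distinct uniform position (infinite-sites
    bookkeeping; collisions are re-drawn) and a Jukes-Cantor ancestral /
    derived base pair; a leaf carries the derived state of every mutation
    on its root path.
    """
    lengths = tree.branch_lengths()
    counts = rng.poisson(mu * length * lengths)
    total = int(counts.sum())
    # distinct positions
    positions = np.unique(rng.integers(0, length, size=total))
    while len(positions) < total:
        extra = rng.integers(0, length, size=total - len(positions))
        positions = np.unique(np.concatenate([positions, extra]))
    site_node = np.repeat(np.arange(tree.n_nodes), counts)
    rng.shuffle(site_node)  # positions are exchangeable across branches

    genotypes = np.zeros((tree.n_leaves, total), dtype=np.uint8)
    if total:
        children: list[list[int]] = [[] for _ in range(tree.n_nodes)]
        for u in range(tree.n_nodes):
            if tree.parent[u] >= 0:
                children[tree.parent[u]].append(u)
        leaves_below: list[np.ndarray] = [np.empty(0, dtype=int)] * tree.n_nodes
        for u in range(tree.n_nodes):
            if u < tree.n_leaves:
                leaves_below[u] = np.array([u])
            else:
                leaves_below[u] = np.concatenate([leaves_below[c] for c in children[u]])
        for s, u in enumerate(site_node):
            genotypes[leaves_below[u], s] = 1
    anc_idx = rng.integers(0, 4, size=total)
    der_idx = (anc_idx + rng.integers(1, 4, size=total)) % 4  # uniform among other 3
    return SequenceSet(
        marker=tree.marker,
        length=length,
        positions=positions,
        ancestral=_BASES[anc_idx],
        derived=_BASES[der_idx],
        genotypes=genotypes,
    )


def pairwise_pi(sequences, subset: np.ndarray | None = None) -> float:
    """Nucleotide diversity: mean per-site pairwise difference.

    ``sequences`` is either a :class:`SequenceSet` (optionally restricted
    to ``subset`` leaf indices) or a list of equal-length strings.
    """
    if isinstance(sequences, SequenceSet):
        geno = sequences.genotypes if subset is None else sequences.genotypes[subset]
        k = geno.shape[0]
        if k < 2:
            raise ValueError("pi requires at least 2 sequences")
        derived = geno.sum(axis=0)
        pairs_diff = (derived * (k - derived)).sum()
        return float(pairs_diff / (k * (k - 1) / 2) / sequences.length)
    seqs = list(sequences)
    if len(seqs) < 2:
        raise ValueError("pi requires at least 2 sequences")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must have equal length")
    arr = np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(len(seqs), length)
    total = 0
    for i in range(len(seqs)):
        total += (arr[i + 1 :] != arr[i]).sum()
    return float(total / (len(seqs) * (len(seqs) - 1) / 2) / length)
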