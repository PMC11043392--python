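# Methods

This document describes the model implemented by `kinsim`, the numerical
choices behind it, and the statistical conventions used in its outputs.

## Overview

`kinsim` is a forward-time, agent-based simulator of a village population
structured into patrilineal descent groups. Its purpose is to study how
purely socio-demographic dynamics — patrilocal residence, descent-group
exogamy, between-group differences in reproductive success, group fission
along paternal lines, and group extinction — reshape the genealogies of
the uniparentally inherited loci (the Y chromosome, transmitted father to
son, and mtDNA, transmitted mother to child), and in particular how they
can collapse male effective population size while leaving female
effective size untouched.

## Demographic model

### Population structure

The population is founded at generation 0 with `n_total` = 1500
individuals in `n_villages` = 5 villages of 300, with alternating sexes
(750 males, 750 females). Under patrilineal descent, each village is
partitioned into 3 descent groups of 100 founders (balanced sexes).
Generations are non-overlapping: each cycle replaces the living cohort by
its children.

Villages grow deterministically: the number of children produced by
village *v* at generation *t* is exactly `round(300 * exp(0.01 * t))`.
Children alternate sexes starting with a male, so an odd cohort has one
extra male.

### The per-generation cycle

Each generation applies, in order:

1. **Individual migration.** Under patrilocality each female moves with
   probability 0.1 (males 0.0) to a uniformly chosen other village, where
   she joins a uniformly chosen descent group. Matrilocality mirrors this
   (10% of males move); multilocality moves 5% of each sex.
2. **Reproduction.** Within each village, min(males, females) monogamous
   couples are formed. Under patrilineal descent, couples are exogamous:
   same-group couples are iteratively re-paired, with a within-group
   fallback when a village holds a single group. Each child independently
   draws its father's group *j* with probability

       P_j = 2 M_j exp(r_j) / sum_i 2 M_i exp(r_i)

   where `M_j` is the group's male count and `r_j` its relative fitness;
   a uniformly chosen couple of that group then parents the child.
   Children affiliate with their father's group (patrilineal descent).
   In bilateral phases children simply draw a uniform couple.
3. **Violent deaths** (when enabled). Newborn males die in intergroup
   violence: group *j* loses `D_j ~ Poisson(rho * (sum_{i != j} M_i) *
   sqrt(M_j))` males (truncated at `M_j`), with `rho` solved each
   generation so the expected deaths total `e = 0.15` of the male cohort.
   Per-capita risk therefore *decreases* with group size: dominating your
   rivals protects your males. By default the rival sum runs over all
   other groups in the population (`violence_arena = "population"`); the
   `"village"` setting restricts rivals to the group's own village, with
   a per-village 15% quota and no deaths in single-group villages.
4. **Fission.** A group whose male count `M_j` satisfies `2 M_j > N_max`
   (N_max = 150), and whose last fission lies more than 3 generations
   back, splits in two. The male split fraction is drawn from a Normal
   (mean 0.5, variance 0.5) truncated to [0, 1].
   - *Random fission* assigns males to the two children at random.
   - *Lineal fission* splits along paternal lines: males are classed by
     their male-line ancestor at the deepest genealogical level at which
     more than one ancestral line survives (climbing the full pedigree,
     not just the group's own lifetime), and whole clades are greedily
     packed, largest first, into the side that best approaches the drawn
     fraction. Each side of a lineal split is therefore a union of
     complete paternal clades. A group whose males are all brothers falls
     back to a random split.
   Females follow so both children keep the parent's sex ratio. Each
   child draws a fresh fitness from Normal(r_parent, sigma^2), modelling
   noisy cultural transmission of group success; the same `sigma` is used
   for the founding fitness draws, Normal(growth rate, sigma^2).
5. **Extinction.** Groups with zero living members are removed and
   logged. A group reduced to a handful of members can also die out
   passively by failing to attract children.
6. **Post-fission migration** (optional). The smaller child of each
   fission moves wholesale to the currently smallest other village.

### The fitness-spread parameter `sigma`

`sigma` is the **standard deviation** of the fitness draws (initial
groups: Normal(0.01, sigma^2); fission children: Normal(r_parent,
sigma^2)). The reference grid is sigma in {0, 0.05, 0.1, 0.2}. This
reading — grid values used directly as the scale of the draw — was
validated against five independent published statistics (final reduction
factors, group growth and extinction calibration, and extinction counts);
using the grid values as variances overshoots all of them.

## Scenarios

- **1** — bilateral, patrilocal control (100 generations).
- **2a–2h** — patrilineal, patrilocal; the three binary factors are
  fission type (random/lineal), fitness spread (sigma = 0 / 0.1), and
  violence (e = 0 / 0.15). 2g is lineal + spread; 2h adds violence.
- **3a–3c** — 100 bilateral generations (patrilocal / multilocal /
  matrilocal) followed by 100 generations with the 2g settings.
- **4a** — 2g extended to 200 generations; **4b** — 2g then 100
  bilateral generations; **4c** — 2g then 100 patrilineal generations
  without fitness spread.
- **polygyny** — bilateral control where each female draws a husband
  with probability proportional to his weight X ~ Geometric(1/2),
  a strong-polygyny comparison point.

## Genetics

The forward simulation records only parent links (a growing pedigree).
Diversity is measured on demand:

1. **Sampling.** Every 20 generations, 20 individuals are sampled per
   village. The sampled males carry the Y chromosome; all 20 carry mtDNA.
2. **Gene-tree extraction.** The sample's paternal (Y) or maternal
   (mtDNA) pedigree paths are collapsed into a coalescent gene tree with
   branch lengths in generations.
3. **Coalescent initialisation.** Lineages still distinct at the
   founding generation are joined through a neutral coalescent genealogy
   (msprime, haploid population size 750) of the founder lineages — the
   backwards-in-time equivalent of a long panmictic burn-in. All 1500
   founders carry an mtDNA lineage although only females transmit it; the
   resulting early burst of coalescences is approximated by the
   continuous coalescent.
4. **Mutations.** Poisson mutations are dropped on the branches (Y: 1 Mb
   at 2.5e-8 /site/generation; mtDNA: 10 kb at 5.5e-7), with distinct
   positions (infinite-sites bookkeeping) and Jukes-Cantor base
   assignment. At the simulated diversities (pi <= 1e-4) multiple hits
   are negligible.
5. **Diversity and Ne.** Nucleotide diversity pi is the mean per-site
   pairwise difference; the haploid effective size is `Ne = pi / (2 mu)`.
   Both the mean of within-village pi and the pooled (global) pi are
   reported; headline numbers use the within-village mean.

## Statistical conventions

- **Reduction factor.** The headline male reduction factor is the
  *across-replicate mean of 750 / Ne_Y(t)*, i.e. the mean of
  per-replicate fold reductions. The alternative aggregation,
  750 / mean(Ne_Y(t)), is also computed (`reduction_factor_inverse_mean`
  on `ReplicateSummary`); the two differ when the Ne distribution is
  right-skewed. The per-replicate convention is the package default
  because it mirrors the female-to-male ratio convention (a mean of
  per-replicate ratios) and reproduces the reference results
  consistently across the scenario grid.
- **Female-to-male ratio.** `Ne_mt / Ne_Y` per replicate and generation;
  the reported maximum is the largest across-replicate mean on the
  20-generation reporting grid.
- **Uncertainty.** 95% confidence intervals over replicates use the
  bias-corrected and accelerated (BCa) bootstrap with a jackknife
  estimate of the acceleration constant (implemented in
  `kinsim.stats.bca_interval`, cross-checked against
  `scipy.stats.bootstrap(method="BCa")` in the tests).
- **Group demography.** A group's growth rate is the per-generation
  geometric rate over its logged lifetime,
  `(N_last / N_first)^(1/generations) - 1`; "successful" groups are
  those with a positive rate. The extinction rate divides extinction
  events by group-generations at risk.

## Reproducibility

Each replicate is driven by a single seed, split into independent
substreams (demography, genetics, coalescent initialisation) via
`numpy.random.SeedSequence.spawn`, so measurement draws never perturb the
demographic trajectory. Per-replicate seeds derive deterministically from
the run's base seed; the run manifest records everything needed to
reproduce a run bit-identically.

## Exports

The final-generation sample (10 males + 10 females per village from the
first replicate) can be written as FASTA haplotypes, a Newick gene tree
(branch lengths in generations), a NEXUS file combining alignment and
tree, and a haploid VCF of segregating sites — sized for external
phylodynamic inference tools. Running such tools is out of scope; the
repository guarantees format validity only.

## Known limitations

- The generation-20 reduction factor of the violent lineal scenario (2h)
  reads ~1.8 here against a reference value of 3.30, although the same
  runs reproduce the generation-20 value of 2g and the final-generation
  maximum ratios. No variant of the violence mechanism consistent with
  the published equations produced so early a collapse without breaking
  several other reproduced statistics; the project decision ledger
  documents the variants explored.
- Several reference reduction factors fall between the two aggregation
  conventions rather than inside the tight 50-replicate interval of
  either: the mean of per-replicate 750/Ne is inflated by the coalescent
  coefficient of variation of single-locus π (roughly 1 + CV², a 20–30%
  effect at this sampling depth), while 750/mean(Ne) reads low for the
  strongly right-skewed scenarios (notably 2d). The acceptance test
  reports both aggregations per scenario.
- The calibrated growth rate of successful descent groups measures
  ~0.12/generation against a reference 0.14 (lifetime geometric-rate
  definition); the extinction calibration (~3%/generation) matches.
- The mtDNA coalescent initialisation treats the 1500-lineage start in a
  haploid-750 population with the continuous coalescent, slightly
  compressing the earliest coalescences.
- BEAST-style skyline inference on the exported files is not run.
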