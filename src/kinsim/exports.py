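"""Writers for sampled genealogies and haplotypes.

The final-generation sample (by convention 10 males and 10 females per
village) can be exported as FASTA haplotypes, a Newick gene tree, a NEXUS
file combining alignment and tree (sized for external skyline inference)
and a haploid VCF of segregating sites.  Branch lengths are in
generations, optionally scaled to years with the configured generation
time.  Alignments are variant-sites-only by default; ``full_length``
writes complete sequences over an 'A' background (practical for
mtDNA-scale loci).
"""

from __future__ import annotations

import numpy as np
import dendropy

from .genetics import GeneTree, SequenceSet
from .population import FEMALE, MALE


def sample_for_export(pop, rng, males_per_village: int = 10, females_per_village: int = 10):
    """Pick the standard export sample; returns (cohort indices, labels)."""
    idx_parts, labels = [], []
    for v in range(pop.config.n_villages):
        for sex, k, tag in ((MALE, males_per_village, "m"), (FEMALE, females_per_village, "f")):
            cand = np.flatnonzero((pop.village == v) & (pop.sex == sex))
            take = rng.choice(cand, size=min(k, len(cand)), replace=False)
            idx_parts.append(take)
            labels.extend(f"v{v}_{tag}{j}" for j in range(len(take)))
    return np.concatenate(idx_parts), labels


def gene_tree_to_dendropy(
    tree: GeneTree, labels: list[str], branch_scale: float = 1.0
) -> dendropy.Tree:
    """Convert to a dendropy tree with branch lengths in generations
    (or years when ``branch_scale`` is the generation time)."""
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for u in range(tree.n_nodes):
        node = dendropy.Node()
        if u < tree.n_leaves:
            node.taxon = taxa[u]
        nodes.append(node)
    root = None
    for u in range(tree.n_nodes):
        p = tree.parent[u]
        if p == -1:
            root = nodes[u]
        else:
            nodes[p].add_child(nodes[u])
            nodes[u].edge.length = float((tree.time[p] - tree.time[u]) * branch_scale)
    dtree = dendropy.Tree(taxon_namespace=taxa)
    dtree.seed_node = root
    return dtree


def write_newick(
    tree: GeneTree, labels: list[str], path, generation_time: float | None = None
) -> None:
    scale = generation_time if generation_time else 1.0
    dtree = gene_tree_to_dendropy(tree, labels, branch_scale=scale)
    dtree.write(path=str(path), schema="newick", suppress_rooting=True)


def _alignment_dict(seqs: SequenceSet, labels: list[str], full_length: bool) -> dict[str, str]:
    if not full_length:
        return {lab: seqs.haplotype(i) for i, lab in enumerate(labels)}
    reference = list("A" * seqs.length)
    for pos, base in zip(seqs.positions, seqs.ancestral):
        reference[pos] = base
    reference = "".join(reference)
    return {lab: seqs.full_sequence(i, reference) for i, lab in enumerate(labels)}


def write_fasta(
    seqs: SequenceSet, labels: list[str], path, full_length: bool = False
) -> None:
    with open(path, "w") as fh:
        for lab, seq in _alignment_dict(seqs, labels, full_length).items():
            fh.write(f">{lab}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")


def write_nexus(
    tree: GeneTree,
    seqs: SequenceSet,
    labels: list[str],
    path,
    full_length: bool = False,
) -> None:
    """NEXUS with a DATA block (alignment) and a TREES block."""
    taxa = dendropy.TaxonNamespace(labels)
    matrix = dendropy.DnaCharacterMatrix.from_dict(
        _alignment_dict(seqs, labels, full_length), taxon_namespace=taxa
    )
    dtree = gene_tree_to_dendropy(tree, labels)
    dtree.migrate_taxon_namespace(taxa)
    ds = dendropy.DataSet()
    ds.attach_taxon_namespace(taxa)
    ds.add_char_matrix(matrix)
    ds.add_tree_list(dendropy.TreeList([dtree], taxon_namespace=taxa))
    ds.write(path=str(path), schema="nexus", suppress_taxa_blocks=False)


def write_vcf(seqs: SequenceSet, labels: list[str], path, contig: str) -> None:
    """Haploid VCF of the segregating sites (1-based positions)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f"##contig=<ID={contig},length={seqs.length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(labels) + "\n")
        for s in range(seqs.n_sites):
            gts = "\t".join(str(int(g)) for g in seqs.genotypes[:, s])
            fh.write(
                f"{contig}\t{int(seqs.positions[s]) + 1}\t.\t{seqs.ancestral[s]}\t"
                f"{seqs.derived[s]}\t.\tPASS\t.\tGT\t{gts}\n"
            )
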