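"""Per-locus haploweb construction and allele-pool delimitation.

A haploweb is a haplotype network augmented with connections between the
two haplotypes co-occurring in each heterozygous individual.  Its connected
components are pools of alleles ("fields for recombination"): individuals
whose alleles all fall in the same pool are inferred conspecific at that
locus, so each connected component delimits a candidate species.

Haplotype identity here is exact string equality: ``N`` and ``-`` are
literal characters, so sequences differing only in missing or gap positions
are distinct haplotypes.  This keeps delimitation reproducible at the cost
of splitting haplotypes that an ambiguity-aware rule might merge.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .alleles_io import Dataset, Locus


@dataclass(frozen=True)
class Haplotype:
    """A distinct allele sequence at one locus, numbered densely from 0."""

    haplotype_id: int
    sequence: str


@dataclass
class HaploWeb:
    """The allele-sharing graph of one locus.

    Nodes are collapsed haplotypes; one edge is added per heterozygous
    individual between its two haplotypes (homozygotes add no edge but do
    anchor ``carriers``).  ``edges`` counts heterozygotes per haplotype pair.
    """

    locus_id: str
    haplotypes: list[Haplotype]
    carriers: dict[int, set[str]]
    edges: Counter  # keys: (h_lo, h_hi) ordered pairs; values: multiplicity
    assignment: dict[str, tuple[int, int]]  # individual -> its 2 haplotype ids


@dataclass
class LocusDelimitation:
    """Assignment of each individual present at a locus to an allele pool."""

    locus_id: str
    pool_of: dict[str, int]
    n_pools: int
    present: set[str]


def collapse_haplotypes(
    locus: Locus,
) -> tuple[list[Haplotype], dict[str, tuple[int, int]]]:
    """Collapse identical phased sequences into numbered haplotypes.

    Haplotype ids are assigned in order of first appearance in the record
    list.  Returns the haplotype list and, per individual, the ordered pair
    of haplotype ids of its alleles (allele 0 first).
    """
    seq_to_id: dict[str, int] = {}
    haplotypes: list[Haplotype] = []
    assignment: dict[str, tuple[int, int]] = {}
    for ind in locus.individuals:
        pair = []
        for seq in locus.alleles_of(ind):
            if seq not in seq_to_id:
                seq_to_id[seq] = len(haplotypes)
                haplotypes.append(Haplotype(len(haplotypes), seq))
            pair.append(seq_to_id[seq])
        assignment[ind] = (pair[0], pair[1])
    return haplotypes, assignment


def build_haploweb(locus: Locus) -> HaploWeb:
    """Build the haploweb graph of one locus."""
    haplotypes, assignment = collapse_haplotypes(locus)
    carriers: dict[int, set[str]] = {h.haplotype_id: set() for h in haplotypes}
    edges: Counter = Counter()
    for ind, (h0, h1) in assignment.items():
        carriers[h0].add(ind)
        carriers[h1].add(ind)
        if h0 != h1:
            edges[(min(h0, h1), max(h0, h1))] += 1
    return HaploWeb(
        locus_id=locus.locus_id,
        haplotypes=haplotypes,
        carriers=carriers,
        edges=edges,
        assignment=assignment,
    )


def delimit_locus(web: HaploWeb) -> LocusDelimitation:
    """Delimit allele pools as connected components of the haploweb.

    Isolated haplotypes form singleton components.  Pool ids are dense and
    ordered by the smallest haplotype id each component contains.  Every
    individual's two haplotypes necessarily fall in one component (the
    heterozygote itself contributes the connecting edge); this is asserted.
    """
    graph = nx.Graph()
    graph.add_nodes_from(h.haplotype_id for h in web.haplotypes)
    graph.add_edges_from(web.edges.keys())
    components = sorted(nx.connected_components(graph), key=min)
    pool_of_hap: dict[int, int] = {}
    for pool_id, comp in enumerate(components):
        for h in comp:
            pool_of_hap[h] = pool_id
    pool_of: dict[str, int] = {}
    for ind, (h0, h1) in web.assignment.items():
        assert pool_of_hap[h0] == pool_of_hap[h1], (
            f"locus {web.locus_id}: alleles of {ind} fall in different pools"
        )
        pool_of[ind] = pool_of_hap[h0]
    return LocusDelimitation(
        locus_id=web.locus_id,
        pool_of=pool_of,
        n_pools=len(components),
        present=set(web.assignment),
    )


def delimit_dataset(dataset: Dataset) -> list[LocusDelimitation]:
    """Haploweb-delimit every locus of a dataset, preserving locus order."""
    return [delimit_locus(build_haploweb(loc)) for loc in dataset.loci]


def write_haploweb_tsv(web: HaploWeb, edge_path: str | Path, node_path: str | Path) -> None:
    """Export a haploweb as an edge-list TSV and a node/carrier table."""
    with open(edge_path, "w", encoding="utf-8") as fh:
        fh.write("haplotype_a\thaplotype_b\tn_heterozygotes\n")
        for (a, b), n in sorted(web.edges.items()):
            fh.write(f"{a}\t{b}\t{n}\n")
    with open(node_path, "w", encoding="utf-8") as fh:
        fh.write("haplotype\tcarriers\n")
        for h in web.haplotypes:
            inds = ",".join(sorted(web.carriers[h.haplotype_id]))
            fh.write(f"{h.haplotype_id}\t{inds}\n")
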