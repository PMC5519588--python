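"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the package's own graph/linkage code
paths: pool delimitation is recomputed by naive transitive closure over
shared allele sequences, vote totals by a direct loop over (locus, pair)
events, and ARI by the pair-counting formula.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from conspec.alleles_io import AlleleRecord, Dataset, Locus


def make_locus(locus_id: str, genotypes: dict[str, tuple[str, str]]) -> Locus:
    """Build a Locus from {individual: (allele0, allele1)}."""
    records = []
    length = None
    for ind, (a0, a1) in genotypes.items():
        records.append(AlleleRecord(ind, 0, a0))
        records.append(AlleleRecord(ind, 1, a1))
        length = len(a0)
    locus = Locus(locus_id=locus_id, records=records, length=length or 0)
    locus.validate()
    return locus


def make_dataset(loci: list[Locus]) -> Dataset:
    individuals: list[str] = []
    seen = set()
    for loc in loci:
        for ind in loc.individuals:
            if ind not in seen:
                seen.add(ind)
                individuals.append(ind)
    ds = Dataset(loci=loci, individuals=individuals)
    ds.validate()
    return ds


# ---------------------------------------------------------------- oracles


def pools_by_closure(locus: Locus) -> list[set[str]]:
    """Brute-force allele-pool delimitation by transitive closure.

    Start with one group per individual (holding its two sequences); keep
    merging any two groups that share a sequence until no merge applies.
    """
    groups: list[tuple[set[str], set[str]]] = []  # (individuals, sequences)
    for ind in locus.individuals:
        a0, a1 = locus.alleles_of(ind)
        groups.append(({ind}, {a0, a1}))
    changed = True
    while changed:
        changed = False
        for i, j in itertools.combinations(range(len(groups)), 2):
            if groups[i][1] & groups[j][1]:
                merged = (groups[i][0] | groups[j][0], groups[i][1] | groups[j][1])
                groups = [g for k, g in enumerate(groups) if k not in (i, j)]
                groups.append(merged)
                changed = True
                break
    return [inds for inds, _ in groups]


def recount_votes(delimitations, individuals):
    """Independent per-(locus, pair) recount of score and copresence."""
    n = len(individuals)
    index = {ind: k for k, ind in enumerate(individuals)}
    n_con = np.zeros((n, n), dtype=int)
    copresent = np.zeros((n, n), dtype=int)
    for delim in delimitations:
        for ind in delim.present:
            copresent[index[ind], index[ind]] += 1
        for i, j in itertools.combinations(sorted(delim.present), 2):
            a, b = index[i], index[j]
            copresent[a, b] += 1
            copresent[b, a] += 1
            if delim.pool_of[i] == delim.pool_of[j]:
                n_con[a, b] += 1
                n_con[b, a] += 1
    score = 2 * n_con - copresent
    np.fill_diagonal(score, np.diag(copresent))
    return score, copresent, n_con


def ari_pair_counting(labels_p: list, labels_q: list) -> float:
    """Adjusted Rand index by direct pair counting over C(n,2) pairs."""
    n = len(labels_p)
    pairs = list(itertools.combinations(range(n), 2))
    together_p = {(i, j) for i, j in pairs if labels_p[i] == labels_p[j]}
    together_q = {(i, j) for i, j in pairs if labels_q[i] == labels_q[j]}
    a = len(together_p & together_q)
    total = comb(n, 2)
    expected = len(together_p) * len(together_q) / total if total else 0.0
    max_index = (len(together_p) + len(together_q)) / 2
    if max_index == expected:
        return 1.0  # both partitions trivial: identical pair structure
    return (a - expected) / (max_index - expected)


def set_partitions(items: list):
    """Enumerate all set partitions of a list (for exhaustive ARI checks)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in set_partitions(rest):
        for k in range(len(partition)):
            yield partition[:k] + [partition[k] + [first]] + partition[k + 1 :]
        yield partition + [[first]]


# ---------------------------------------------------------------- fixtures


@pytest.fixture
def worked_example() -> Dataset:
    """Four individuals, three loci, chosen so the haploweb pools are:
    L1: {A,B},{C,D}; L2: {A,B},{C},{D}; L3 (D missing): {A,B,C}.

    Hand enumeration of all pair-locus votes gives C_AB=+3, C_AC=-1,
    C_AD=-2, C_BC=-1, C_BD=-2, C_CD=0.
    """
    x, y, z = "AAAA", "CCCC", "GGGG"
    return make_dataset(
        [
            make_locus("L1", {"A": (x, x), "B": (x, x), "C": (y, y), "D": (y, y)}),
            make_locus("L2", {"A": (x, x), "B": (x, x), "C": (y, y), "D": (z, z)}),
            make_locus("L3", {"A": (x, x), "B": (x, x), "C": (x, x)}),
        ]
    )


def random_locus(rng: np.random.Generator, max_inds: int = 12,
                 max_haps: int = 12, length: int = 6) -> Locus:
    """A random small locus: individuals draw 2 haplotypes from a shared pot."""
    n_inds = int(rng.integers(1, max_inds + 1))
    n_haps = int(rng.integers(1, max_haps + 1))
    bases = np.frombuffer(b"ACGT", dtype="S1")
    pot = []
    seen = set()
    while len(pot) < n_haps:
        seq = bases[rng.integers(0, 4, size=length)].tobytes().decode()
        if seq not in seen:
            seen.add(seq)
            pot.append(seq)
    genotypes = {}
    for i in range(n_inds):
        h = rng.integers(0, n_haps, size=2)
        genotypes[f"ind{i}"] = (pot[int(h[0])], pot[int(h[1])])
    return make_locus("R", genotypes)
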