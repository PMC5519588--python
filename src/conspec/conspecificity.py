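"""Condensing per-locus delimitations into the conspecificity matrix.

For every unordered pair of individuals, each locus at which both have data
casts one vote: +1 if the haploweb places them in the same allele pool
(conspecific) and -1 otherwise (heterospecific).  The conspecificity score
C_ij is the sum of votes — the number of loci supporting conspecificity
minus the number supporting heterospecificity.  Pairs that are never
co-present keep a score of exactly 0, which is why individuals with heavy
missing data sit near zero against everyone in the matrix.

The diagonal stores each individual's presence count (loci with data), a
useful QC quantity that is excluded from clustering distances downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np

from .errors import ConsistencyError, ValidationError
from .haploweb import LocusDelimitation


@dataclass
class ConspecificityMatrix:
    """Signed pairwise vote totals over a set of individuals.

    ``score`` is the conspecificity score C, ``copresent`` the number of
    loci where both individuals have data.  Both are symmetric;
    |C_ij| <= copresent_ij, and copresent_ij + C_ij is even (C is a
    difference of two counts summing to copresent).
    """

    individuals: list[str]
    score: np.ndarray  # int, n x n
    copresent: np.ndarray  # int, n x n
    n_loci: int

    @property
    def n(self) -> int:
        return len(self.individuals)

    def validate(self) -> None:
        n = self.n
        if self.score.shape != (n, n) or self.copresent.shape != (n, n):
            raise ValidationError("matrix shape does not match individuals")
        if not np.array_equal(self.score, self.score.T):
            raise ValidationError("score matrix is not symmetric")
        if not np.array_equal(self.copresent, self.copresent.T):
            raise ValidationError("copresent matrix is not symmetric")
        off = ~np.eye(n, dtype=bool)
        if np.any(np.abs(self.score[off]) > self.copresent[off]):
            raise ValidationError("|C| exceeds copresence count")
        if np.any((self.score[off] + self.copresent[off]) % 2 != 0):
            raise ValidationError("C and copresence have mismatched parity")


def iter_votes(
    delimitations: Sequence[LocusDelimitation],
) -> Iterator[tuple[str, str, str, int]]:
    """Yield every (locus_id, ind_i, ind_j, vote) event, i < j lexically."""
    for delim in delimitations:
        present = sorted(delim.present)
        for a in range(len(present)):
            for b in range(a + 1, len(present)):
                i, j = present[a], present[b]
                vote = 1 if delim.pool_of[i] == delim.pool_of[j] else -1
                yield delim.locus_id, i, j, vote


def accumulate_matrix(
    delimitations: Sequence[LocusDelimitation],
    individuals: Sequence[str],
    min_pools: int = 1,
) -> ConspecificityMatrix:
    """Condense per-locus delimitations into one conspecificity matrix.

    Parameters
    ----------
    delimitations:
        One :class:`LocusDelimitation` per locus.
    individuals:
        Global roster fixing row/column order; every individual referenced
        by a delimitation must appear here.
    min_pools:
        Loci with fewer than this many pools are excluded from voting
        (and from copresence counts).  The default 1 lets invariant
        single-pool loci cast +1 votes for all present pairs, mirroring the
        matrix-wide accounting of the source method; ``min_pools=2``
        restricts votes to polymorphic-delimitation loci as a sensitivity
        check.
    """
    individuals = list(individuals)
    index = {ind: k for k, ind in enumerate(individuals)}
    n = len(individuals)
    score = np.zeros((n, n), dtype=np.int64)
    copresent = np.zeros((n, n), dtype=np.int64)
    used = [d for d in delimitations if d.n_pools >= min_pools]
    for delim in used:
        try:
            idx = [index[ind] for ind in sorted(delim.present)]
        except KeyError as exc:
            raise ConsistencyError(
                f"locus {delim.locus_id}: individual {exc.args[0]!r} not in"
                " dataset roster"
            ) from None
        pools = [delim.pool_of[ind] for ind in sorted(delim.present)]
        for a in range(len(idx)):
            copresent[idx[a], idx[a]] += 1
            score[idx[a], idx[a]] += 1
            for b in range(a + 1, len(idx)):
                i, j = idx[a], idx[b]
                vote = 1 if pools[a] == pools[b] else -1
                score[i, j] += vote
                score[j, i] += vote
                copresent[i, j] += 1
                copresent[j, i] += 1
    matrix = ConspecificityMatrix(
        individuals=individuals,
        score=score,
        copresent=copresent,
        n_loci=len(used),
    )
    matrix.validate()
    return matrix


def normalize_matrix(
    matrix: ConspecificityMatrix, mode: str = "none"
) -> np.ndarray:
    """Return the score matrix, optionally normalised per pair.

    ``none`` returns C unchanged (the statistic itself).  ``per-pair``
    returns C_ij / copresent_ij in [-1, 1]; entries with zero copresence are
    NaN (undefined, never invented), and the diagonal is 1 wherever the
    individual has any data.
    """
    if mode == "none":
        return matrix.score.copy()
    if mode == "per-pair":
        with np.errstate(divide="ignore", invalid="ignore"):
            out = matrix.score / matrix.copresent
        out[matrix.copresent == 0] = np.nan
        np.fill_diagonal(out, np.where(np.diag(matrix.copresent) > 0, 1.0, np.nan))
        return out
    raise ValidationError(f"unknown normalization mode {mode!r}")
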