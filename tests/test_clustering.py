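"""Distance transform, deterministic agglomerative clustering, partition
cuts, ARI, Newick export and heatmap sidecar."""

import itertools
import json

import numpy as np
import pytest

from conspec.clustering import (
    SpeciesPartition,
    compare_partitions,
    cut_partition,
    hierarchical_cluster,
    matrix_to_distance,
    render_heatmap,
)
from conspec.conspecificity import ConspecificityMatrix, accumulate_matrix
from conspec.errors import ConsistencyError, ValidationError
from conspec.haploweb import delimit_dataset

from conftest import ari_pair_counting, set_partitions


def matrix_from(scores: np.ndarray, individuals=None) -> ConspecificityMatrix:
    n = scores.shape[0]
    individuals = individuals or [chr(ord("A") + i) for i in range(n)]
    copresent = np.abs(scores) + (np.abs(scores) + scores) % 2  # any valid bound
    np.fill_diagonal(copresent, 1)
    m = ConspecificityMatrix(
        individuals=individuals,
        score=scores.astype(np.int64),
        copresent=copresent.astype(np.int64),
        n_loci=int(copresent.max()),
    )
    return m


@pytest.fixture
def worked_matrix(worked_example):
    return accumulate_matrix(delimit_dataset(worked_example), worked_example.individuals)


class TestMatrixToDistance:
    def test_constant_offdiagonal_gives_zero(self):
        s = np.full((3, 3), 2, dtype=np.int64)
        np.fill_diagonal(s, 5)
        d = matrix_to_distance(matrix_from(s))
        assert np.all(d == 0)

    def test_endpoints(self, worked_matrix):
        d = matrix_to_distance(worked_matrix)
        ind = worked_matrix.individuals
        a, b = ind.index("A"), ind.index("B")
        assert d[a, b] == 0.0  # C_AB = +3 is the max
        a, dd = ind.index("A"), ind.index("D")
        assert d[a, dd] == 1.0  # C_AD = -2 is the min

    def test_worked_example_values(self, worked_matrix):
        d = matrix_to_distance(worked_matrix)
        ind = worked_matrix.individuals
        assert d[ind.index("A"), ind.index("C")] == pytest.approx(0.8)

    def test_monotone_decreasing_in_score(self, worked_matrix):
        d = matrix_to_distance(worked_matrix)
        c = worked_matrix.score
        n = worked_matrix.n
        for (i, j), (k, l) in itertools.combinations(
            [(i, j) for i in range(n) for j in range(n) if i != j], 2
        ):
            if c[i, j] > c[k, l]:
                assert d[i, j] < d[k, l]

    def test_single_individual_rejected(self):
        m = matrix_from(np.zeros((1, 1), dtype=np.int64))
        with pytest.raises(ValidationError):
            matrix_to_distance(m)


class TestHierarchicalCluster:
    def test_two_leaves(self):
        d = np.array([[0.0, 0.4], [0.4, 0.0]])
        den = hierarchical_cluster(d, ["A", "B"])
        assert den.merges == [(0, 1, 0.4)]

    def test_forced_topology_three_leaves(self):
        d = np.array([[0, 0, 1], [0, 0, 1], [1, 1, 0]], dtype=float)
        den = hierarchical_cluster(d, ["A", "B", "C"])
        assert den.merges[0][:2] == (0, 1) and den.merges[0][2] == 0.0
        assert den.merges[1][2] == 1.0

    def test_heights_non_decreasing(self, worked_matrix):
        den = hierarchical_cluster(matrix_to_distance(worked_matrix),
                                   worked_matrix.individuals)
        heights = [h for _, _, h in den.merges]
        assert heights == sorted(heights)

    def test_average_linkage_heights_match_upgma_oracle(self):
        """Each merge height must equal the mean of raw pairwise distances
        between the two merged leaf sets (the defining UPGMA property)."""
        rng = np.random.default_rng(42)
        for _ in range(30):
            n = int(rng.integers(3, 9))
            x = rng.random((n, 3))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            den = hierarchical_cluster(d, [f"l{i}" for i in range(n)])
            for t, (a, b, h) in enumerate(den.merges):
                la, lb = den.leaves_of(a), den.leaves_of(b)
                expected = np.mean([d[i, j] for i in la for j in lb])
                assert h == pytest.approx(expected)

    def test_agrees_with_scipy_on_unique_distances(self):
        from scipy.cluster.hierarchy import fcluster, linkage
        from scipy.spatial.distance import squareform

        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            x = rng.random((n, 4))
            d = np.sqrt(((x[:, None] - x[None]) ** 2).sum(-1))
            den = hierarchical_cluster(d, [str(i) for i in range(n)])
            z = linkage(squareform(d, checks=False), method="average")
            assert np.allclose(sorted(h for _, _, h in den.merges), sorted(z[:, 2]))
            for k in range(1, n + 1):
                ours = cut_partition(den, k)
                theirs = fcluster(z, t=k, criterion="maxclust")
                sets_scipy = {
                    frozenset(str(i) for i in range(n) if theirs[i] == c)
                    for c in set(theirs)
                }
                assert ours.as_sets() == sets_scipy

    def test_permutation_invariance_of_partition(self, worked_matrix):
        d = matrix_to_distance(worked_matrix)
        labels = worked_matrix.individuals
        rng = np.random.default_rng(3)
        den = hierarchical_cluster(d, labels)
        base = cut_partition(den, 2).as_sets()
        for _ in range(10):
            perm = rng.permutation(len(labels))
            d2 = d[np.ix_(perm, perm)]
            labels2 = [labels[i] for i in perm]
            den2 = hierarchical_cluster(d2, labels2)
            assert cut_partition(den2, 2).as_sets() == base

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]), ["A", "B"])
        with pytest.raises(ValidationError):
            hierarchical_cluster(-np.ones((2, 2)), ["A", "B"])
        with pytest.raises(ValidationError):
            hierarchical_cluster(np.zeros((2, 2)), ["A", "B"], linkage="ward")


class TestCutPartition:
    @pytest.fixture
    def worked_dendrogram(self, worked_matrix):
        return hierarchical_cluster(
            matrix_to_distance(worked_matrix), worked_matrix.individuals
        )

    def test_k1_single_block(self, worked_dendrogram):
        p = cut_partition(worked_dendrogram, 1)
        assert len(set(p.blocks.values())) == 1

    def test_kn_singletons(self, worked_dendrogram):
        p = cut_partition(worked_dendrogram, 4)
        assert len(set(p.blocks.values())) == 4

    def test_k2_separates_ab(self, worked_dendrogram):
        p = cut_partition(worked_dendrogram, 2)
        assert p.blocks["A"] == p.blocks["B"]
        assert p.blocks["A"] != p.blocks["D"]

    def test_k_out_of_range(self, worked_dendrogram):
        with pytest.raises(ValidationError):
            cut_partition(worked_dendrogram, 0)
        with pytest.raises(ValidationError):
            cut_partition(worked_dendrogram, 5)


class TestComparePartitions:
    def test_identity(self):
        p = SpeciesPartition({"A": 0, "B": 0, "C": 1})
        r = compare_partitions(p, SpeciesPartition({"A": 5, "B": 5, "C": 9}))
        assert r["ari"] == 1.0 and r["exact_match"]

    def test_chance_zero_point(self):
        p = SpeciesPartition({c: i for i, c in enumerate("ABCD")})
        q = SpeciesPartition({c: 0 for c in "ABCD"})
        r = compare_partitions(p, q)
        assert r["ari"] == pytest.approx(0.0)
        assert not r["exact_match"]

    def test_pair_counting_oracle_small_case(self):
        p = SpeciesPartition({"A": 0, "B": 0, "C": 1, "D": 1})
        q = SpeciesPartition({"A": 0, "B": 0, "C": 1, "D": 2})
        expected = ari_pair_counting([0, 0, 1, 1], [0, 0, 1, 2])
        assert compare_partitions(p, q)["ari"] == pytest.approx(expected)

    def test_exhaustive_pair_counting_agreement_n5(self):
        """ARI must match brute-force pair counting on every pair of
        partitions of a 5-element set (52 x 52 combinations)."""
        items = list("ABCDE")
        all_parts = list(set_partitions(items))
        def to_labels(partition):
            lab = {}
            for g, block in enumerate(partition):
                for item in block:
                    lab[item] = g
            return lab
        for part_p in all_parts:
            lp = to_labels(part_p)
            for part_q in all_parts:
                lq = to_labels(part_q)
                got = compare_partitions(
                    SpeciesPartition(lp.copy()), SpeciesPartition(lq.copy())
                )["ari"]
                want = ari_pair_counting(
                    [lp[i] for i in items], [lq[i] for i in items]
                )
                assert got == pytest.approx(want, abs=1e-12)

    def test_mismatched_sets_rejected(self):
        with pytest.raises(ConsistencyError):
            compare_partitions(
                SpeciesPartition({"A": 0}), SpeciesPartition({"B": 0})
            )


class TestExports:
    def test_newick_two_leaves(self):
        den = hierarchical_cluster(
            np.array([[0.0, 0.5], [0.5, 0.0]]), ["A", "B"]
        )
        assert den.to_newick() == "(A:0.5,B:0.5);"

    def test_newick_parses_with_dendropy_and_preserves_heights(self, worked_matrix):
        import dendropy

        den = hierarchical_cluster(
            matrix_to_distance(worked_matrix), worked_matrix.individuals
        )
        tree = dendropy.Tree.get(data=den.to_newick(), schema="newick")
        leaves = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        assert leaves == set(worked_matrix.individuals)
        root_height = max(
            leaf.distance_from_root() for leaf in tree.leaf_node_iter()
        )
        assert root_height == pytest.approx(den.merges[-1][2])

    def test_heatmap_sidecar_matches_leaf_order(self, tmp_path, worked_matrix):
        den = hierarchical_cluster(
            matrix_to_distance(worked_matrix), worked_matrix.individuals
        )
        groups = cut_partition(den, 2)
        out = tmp_path / "heat.png"
        render_heatmap(worked_matrix, den, groups, out)
        assert out.exists() and out.stat().st_size > 0
        sidecar = json.loads((tmp_path / "heat.png.json").read_text())
        assert sidecar["leaf_order"] == den.leaf_order()
        assert sidecar["linkage"] == "average"
        # dendrogram-compatible partition: one contiguous box per group
        assert len(sidecar["groups"]) == len(set(groups.blocks.values()))

    def test_zero_matrix_heatmap(self, tmp_path):
        m = matrix_from(np.zeros((3, 3), dtype=np.int64))
        den = hierarchical_cluster(matrix_to_distance(m), m.individuals)
        out = tmp_path / "zero.png"
        render_heatmap(m, den, None, out)
        assert out.stat().st_size > 0
        sidecar = json.loads((tmp_path / "zero.png.json").read_text())
        assert sidecar["vmin"] == -sidecar["vmax"]
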