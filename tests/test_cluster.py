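"""Hierarchical clustering of fold-change profiles, checked against scipy."""

import io

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import fcluster, linkage as scipy_linkage
from scipy.spatial.distance import pdist

from redoxquant.cluster import (
    ClusteringError,
    cluster_sizes,
    cut_tree,
    hierarchical_cluster,
    log2_profile_matrix,
    write_cdt_gtr,
)
from redoxquant.io import load_table1_fixture


def random_profiles(n, rng):
    return pd.DataFrame(
        rng.normal(0, 1, size=(n, 3)), index=[f"e{i}" for i in range(n)],
        columns=[5, 30, 120],
    )


class TestLog2ProfileMatrix:
    def test_glp_row_log2(self):
        table = pd.DataFrame(
            {"peptide": ["tcAQDEVLR"], "accession": ["AT3G08030"],
             "iodo_fc_5": [0.28], "iodo_fc_30": [0.43], "iodo_fc_120": [0.73]}
        )
        matrix = log2_profile_matrix(table)
        assert matrix.iloc[0].to_numpy() == pytest.approx(
            [-1.837, -1.218, -0.454], abs=1e-3
        )

    def test_unit_fold_changes_map_to_zero(self):
        table = pd.DataFrame(
            {"peptide": ["aPEPTIDEK"], "accession": ["P1"],
             "iodo_fc_5": [1.0], "iodo_fc_30": [1.0], "iodo_fc_120": [1.0]}
        )
        assert np.allclose(log2_profile_matrix(table).to_numpy(), 0.0)

    def test_fixture_gives_47_by_3(self):
        matrix = log2_profile_matrix(load_table1_fixture())
        assert matrix.shape == (47, 3)
        assert matrix.index.is_unique

    def test_missing_fc_dropped_with_warning(self):
        table = pd.DataFrame(
            {"peptide": ["aPEPTIDEK", "aPEPTIDER"], "accession": ["P1", "P2"],
             "iodo_fc_5": [1.0, np.nan], "iodo_fc_30": [1.0, 1.0],
             "iodo_fc_120": [1.0, 1.0]}
        )
        with pytest.warns(UserWarning, match="dropping 1"):
            matrix = log2_profile_matrix(table)
        assert len(matrix) == 1

    def test_nonpositive_fc_is_error(self):
        table = pd.DataFrame(
            {"peptide": ["aPEPTIDEK"], "accession": ["P1"],
             "iodo_fc_5": [-0.5], "iodo_fc_30": [1.0], "iodo_fc_120": [1.0]}
        )
        with pytest.raises(ClusteringError):
            log2_profile_matrix(table)


class TestHierarchicalCluster:
    def test_identical_rows_merge_first_at_height_zero(self):
        rng = np.random.default_rng(1)
        matrix = random_profiles(6, rng)
        matrix.iloc[4] = matrix.iloc[2]
        tree = hierarchical_cluster(matrix, distance="euclidean")
        left, right, height, size = tree.merges[0]
        assert {int(left), int(right)} == {2, 4}
        assert height == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["average", "complete", "single"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_scipy_linkage(self, method, seed):
        """Merge heights and every flat partition agree with the independent
        scipy agglomeration on random (tie-free) matrices."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 12))
        matrix = random_profiles(n, rng)
        tree = hierarchical_cluster(matrix, distance="euclidean", linkage=method)
        Z = scipy_linkage(pdist(matrix.to_numpy()), method=method)
        assert np.allclose(np.sort(tree.merges[:, 2]), np.sort(Z[:, 2]))
        for k in range(1, n + 1):
            ours = cut_tree(tree, k)
            theirs = fcluster(Z, k, criterion="maxclust")
            partition_a = {
                frozenset(e for e, c in ours.items() if c == cid)
                for cid in set(ours.values())
            }
            partition_b = {
                frozenset(matrix.index[i] for i in range(n) if theirs[i] == cid)
                for cid in set(theirs)
            }
            assert partition_a == partition_b

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(8)
        tree = hierarchical_cluster(random_profiles(15, rng))
        heights = tree.merges[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_row_order_permutation_invariance(self):
        rng = np.random.default_rng(21)
        matrix = random_profiles(10, rng)
        shuffled = matrix.sample(frac=1.0, random_state=3)
        a = cut_tree(hierarchical_cluster(matrix), 3)
        b = cut_tree(hierarchical_cluster(shuffled), 3)
        partition = lambda asg: {
            frozenset(e for e, c in asg.items() if c == cid)
            for cid in set(asg.values())
        }
        assert partition(a) == partition(b)

    def test_scaling_invariance_of_correlation_distances(self):
        rng = np.random.default_rng(34)
        matrix = random_profiles(9, rng)
        for distance in ("uncentered", "pearson"):
            t1 = hierarchical_cluster(matrix, distance=distance)
            t2 = hierarchical_cluster(matrix * 7.3, distance=distance)
            assert np.allclose(t1.merges, t2.merges)

    def test_zero_variance_row_falls_back_flagged(self):
        rng = np.random.default_rng(55)
        matrix = random_profiles(5, rng)
        matrix.iloc[0] = [2.0, 2.0, 2.0]
        tree = hierarchical_cluster(matrix, distance="pearson")
        assert any("uncentered-fallback" in flag for flag in tree.flags)

    def test_single_row_rejected(self):
        with pytest.raises(ClusteringError):
            hierarchical_cluster(random_profiles(1, np.random.default_rng(0)))


class TestCutTree:
    def test_trivial_cuts(self):
        rng = np.random.default_rng(2)
        matrix = random_profiles(8, rng)
        tree = hierarchical_cluster(matrix)
        assert set(cut_tree(tree, 1).values()) == {1}
        assert sorted(cut_tree(tree, 8).values()) == list(range(1, 9))
        with pytest.raises(ClusteringError):
            cut_tree(tree, 0)
        with pytest.raises(ClusteringError):
            cut_tree(tree, 9)

    def test_cluster_ids_ordered_by_size(self):
        matrix = log2_profile_matrix(load_table1_fixture())
        assignment = cut_tree(hierarchical_cluster(matrix), 2)
        sizes = cluster_sizes(assignment)
        count_1 = sum(1 for c in assignment.values() if c == 1)
        assert count_1 == sizes[0]

    @pytest.mark.parametrize("k", [2, 3, 5])
    def test_finer_cut_refines_coarser(self, k):
        rng = np.random.default_rng(6)
        matrix = random_profiles(12, rng)
        tree = hierarchical_cluster(matrix)
        coarse = cut_tree(tree, k)
        fine = cut_tree(tree, k + 1)
        for cid in set(fine.values()):
            members = [e for e, c in fine.items() if c == cid]
            assert len({coarse[m] for m in members}) == 1


def test_published_two_cluster_split():
    """The 47 published profiles split 42/5 at k = 2 under the default
    uncentered-correlation / average-linkage combination."""
    matrix = log2_profile_matrix(load_table1_fixture())
    tree = hierarchical_cluster(matrix, distance="uncentered", linkage="average")
    assert cluster_sizes(cut_tree(tree, 2)) == [42, 5]


def test_subclusters_nest_within_main_clusters():
    matrix = log2_profile_matrix(load_table1_fixture())
    tree = hierarchical_cluster(matrix)
    two = cut_tree(tree, 2)
    four = cut_tree(tree, 4)
    for cid in set(four.values()):
        members = [e for e, c in four.items() if c == cid]
        assert len({two[m] for m in members}) == 1


class TestExports:
    def test_newick_reparses_with_matching_leaves(self):
        import skbio

        rng = np.random.default_rng(10)
        matrix = random_profiles(7, rng)
        tree = hierarchical_cluster(matrix)
        parsed = skbio.TreeNode.read(io.StringIO(tree.to_newick()))
        assert {tip.name for tip in parsed.tips()} == set(matrix.index)

    def test_cdt_gtr_consistent(self):
        rng = np.random.default_rng(12)
        matrix = random_profiles(6, rng)
        tree = hierarchical_cluster(matrix)
        cdt, gtr = io.StringIO(), io.StringIO()
        write_cdt_gtr(tree, matrix, cdt, gtr)
        cdt_lines = cdt.getvalue().strip().split("\n")
        gtr_lines = gtr.getvalue().strip().split("\n")
        assert len(cdt_lines) == 2 + len(matrix)  # header + eweight + rows
        assert len(gtr_lines) == len(matrix) - 1
        gene_ids = {line.split("\t")[0] for line in cdt_lines[2:]}
        referenced = set()
        for line in gtr_lines:
            _, left, right, _ = line.split("\t")
            referenced.update({left, right})
        assert gene_ids <= referenced
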