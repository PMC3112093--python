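"""Duplication vectors, distance clustering, and group (anti)clustering tests."""

import itertools

import numpy as np
import pytest

from gsisevo import (
    DEFAULT_SCHEDULE,
    DuplicationVector,
    euclidean_distance_matrix,
    exclude_gene_and_retest,
    extract_duplication_vector,
    group_clustering_test,
    hierarchical_cluster,
    identical_history_groups,
    read_gene_tree,
    synth_gene_tree,
    write_gene_tree,
)
from gsisevo.duplication import make_schedule


def _vec(gene, counts):
    return DuplicationVector(gene, tuple(counts), DEFAULT_SCHEDULE[: len(counts)])


class TestSchedule:
    def test_default_is_oldest_first(self):
        ages = [b.age for b in DEFAULT_SCHEDULE]
        assert ages == sorted(ages, reverse=True)
        assert DEFAULT_SCHEDULE[0].taxon == "Euteleostomi"
        assert DEFAULT_SCHEDULE[-1].taxon == "Catarrhini"

    def test_non_decreasing_ages_rejected(self):
        with pytest.raises(ValueError):
            make_schedule([("A", 100.0), ("B", 100.0)])


class TestExtractVector:
    def test_single_duplication_on_focal_path(self):
        tree = read_gene_tree("((focal,x)[&&NHX:D=Y:T=Euteleostomi:A=420],y);")
        vec = extract_duplication_vector(tree, "focal")
        assert vec.counts[0] == 1 and sum(vec.counts) == 1

    def test_duplication_off_the_focal_path_ignored(self):
        tree = read_gene_tree("(focal,(x,y)[&&NHX:D=Y:T=Theria:A=166]);")
        assert sum(extract_duplication_vector(tree, "focal").counts) == 0

    def test_family_founder_truncates_older_nodes(self):
        text = (
            "(((focal,a)[&&NHX:D=Y:T=Murinae:A=37],b)"
            "[&&NHX:D=Y:T=Euteleostomi:A=420:F=Y],c);"
        )
        vec = extract_duplication_vector(read_gene_tree(text), "focal")
        assert vec.counts[DEFAULT_SCHEDULE[-2].order_index] == 1  # Murinae kept
        assert vec.counts[0] == 0  # founding duplication itself excluded
        assert sum(vec.counts) == 1

    def test_unmapped_taxon_strict_vs_lenient(self):
        text = "((focal,a)[&&NHX:D=Y:T=Bilateria:A=580],b);"
        tree = read_gene_tree(text)
        with pytest.raises(ValueError, match="Bilateria"):
            extract_duplication_vector(tree, "focal", strict=True)
        with pytest.warns(UserWarning):
            vec = extract_duplication_vector(tree, "focal", strict=False)
        assert sum(vec.counts) == 0

    def test_missing_focal_leaf(self):
        with pytest.raises(KeyError):
            extract_duplication_vector(read_gene_tree("(a,b);"), "focal")

    def test_simulated_trees_match_generator_bookkeeping(self, rng):
        """Extracted counts equal the generator's ground truth on 200 trees,
        through an NHX write/read round trip."""
        for _ in range(200):
            tree, truth = synth_gene_tree("g", config=rng)
            reread = read_gene_tree(write_gene_tree(tree))
            vec = extract_duplication_vector(reread, "g")
            assert vec.counts == truth.counts


class TestDistanceMatrix:
    def test_identical_vectors_distance_zero(self):
        _, dm = euclidean_distance_matrix([_vec("a", [1, 2]), _vec("b", [1, 2])])
        assert dm[0, 1] == 0.0

    def test_unit_vectors(self):
        _, dm = euclidean_distance_matrix([_vec("a", [1, 0]), _vec("b", [0, 1])])
        assert dm[0, 1] == pytest.approx(np.sqrt(2))

    def test_matches_brute_force(self, rng):
        vecs = [_vec(f"g{i}", rng.integers(0, 5, size=8)) for i in range(5)]
        genes, dm = euclidean_distance_matrix(vecs)
        for i, j in itertools.product(range(5), repeat=2):
            expected = np.sqrt(
                sum((a - b) ** 2 for a, b in zip(vecs[i].counts, vecs[j].counts))
            )
            assert dm[i, j] == pytest.approx(expected)
        assert np.allclose(dm, dm.T)
        assert np.all(np.diag(dm) == 0)

    def test_triangle_inequality(self, rng):
        vecs = [_vec(f"g{i}", rng.integers(0, 6, size=8)) for i in range(6)]
        _, dm = euclidean_distance_matrix(vecs)
        n = len(vecs)
        for i, j, k in itertools.product(range(n), repeat=3):
            assert dm[i, k] <= dm[i, j] + dm[j, k] + 1e-9

    def test_mixed_schedules_rejected(self):
        a = DuplicationVector("a", (1,), DEFAULT_SCHEDULE[:1])
        b = DuplicationVector("b", (1, 0), DEFAULT_SCHEDULE[:2])
        with pytest.raises(ValueError):
            euclidean_distance_matrix([a, b])


class TestHierarchicalCluster:
    def test_identical_vectors_merge_at_height_zero(self):
        vecs = [_vec(g, [1, 1]) for g in "abc"] + [_vec("d", [0, 3]), _vec("e", [2, 0])]
        genes, dm = euclidean_distance_matrix(vecs)
        groups = identical_history_groups(genes, dm)
        assert frozenset({"a", "b", "c"}) in groups
        assert len(groups) == 3

    def test_all_distinct_gives_singletons(self):
        vecs = [_vec(f"g{i}", [i, 0]) for i in range(4)]
        genes, dm = euclidean_distance_matrix(vecs)
        assert all(len(g) == 1 for g in identical_history_groups(genes, dm))

    @pytest.mark.parametrize("linkage", ["complete", "single", "average"])
    def test_zero_height_partition_equals_equality_partition(self, rng, linkage):
        vecs = [_vec(f"g{i}", rng.integers(0, 3, size=4)) for i in range(12)]
        genes, dm = euclidean_distance_matrix(vecs)
        got = set(identical_history_groups(genes, dm, linkage=linkage))
        by_counts = {}
        for v in vecs:
            by_counts.setdefault(v.counts, set()).add(v.gene)
        assert got == {frozenset(g) for g in by_counts.values()}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_cluster(np.array([[0.0, 1.0], [2.0, 0.0]]))
        with pytest.raises(ValueError):
            hierarchical_cluster(np.zeros((2, 3)))


def _clustered_setup(rng, n_background=16, group_size=4):
    """A group with identical histories among diverse background genes."""
    vecs = [_vec(f"grp{i}", [1, 0, 2, 0, 0, 0, 0, 0]) for i in range(group_size)]
    for i in range(n_background):
        vecs.append(_vec(f"bg{i}", rng.integers(0, 4, size=8)))
    genes, dm = euclidean_distance_matrix(vecs)
    membership = {g: ("A" if g.startswith("grp") else "B") for g in genes}
    return genes, dm, membership


class TestGroupClusteringTest:
    def test_identical_group_detected_as_clustered(self, rng):
        genes, dm, membership = _clustered_setup(rng)
        res = group_clustering_test(genes, dm, membership, "A")
        assert res.direction == "clustered"
        assert res.p_raw < 0.01
        assert res.within_median < res.background_median

    def test_private_patterns_detected_as_anticlustered(self):
        # Each group member carries a unique private duplication burst while
        # the background is homogeneous.
        vecs = [_vec(f"grp{i}", [0] * i + [5] + [0] * (7 - i)) for i in range(4)]
        vecs += [_vec(f"bg{i}", [1, 0, 0, 0, 0, 0, 0, 0]) for i in range(12)]
        genes, dm = euclidean_distance_matrix(vecs)
        membership = {g: ("A" if g.startswith("grp") else "B") for g in genes}
        res = group_clustering_test(genes, dm, membership, "A")
        assert res.direction == "anticlustered"

    def test_bonferroni_scales_raw_p(self, rng):
        genes, dm, membership = _clustered_setup(rng)
        res = group_clustering_test(genes, dm, membership, "A", n_groups_tested=7)
        assert res.p_bonferroni == pytest.approx(min(1.0, res.p_raw * 7))

    def test_group_too_small_errors(self):
        genes, dm = euclidean_distance_matrix([_vec("a", [1]), _vec("b", [0])])
        with pytest.raises(ValueError):
            group_clustering_test(genes, dm, {"a": "A", "b": "B"}, "A")

    def test_null_calibration_type_one_error(self, rng):
        """Random membership must not reject above the nominal rate once the
        Bonferroni correction for the family of tested groups is applied.
        (The raw rank-sum p is anticonservative here because pairwise
        distances sharing a gene are dependent; the correction absorbs it.)"""
        vecs = [_vec(f"g{i}", rng.integers(0, 4, size=8)) for i in range(20)]
        genes, dm = euclidean_distance_matrix(vecs)
        n_reps, alpha, n_family = 400, 0.05, 7
        rejections = 0
        labels = np.array(["A"] * 5 + ["B"] * 15)
        for _ in range(n_reps):
            rng.shuffle(labels)
            membership = dict(zip(genes, labels))
            res = group_clustering_test(
                genes, dm, membership, "A", n_groups_tested=n_family
            )
            rejections += res.p_bonferroni < alpha
        se = np.sqrt(alpha * (1 - alpha) / n_reps)
        assert rejections / n_reps <= alpha + 2 * se


class TestExcludeGeneAndRetest:
    def test_excluding_outside_gene_changes_nothing(self, rng):
        genes, dm, membership = _clustered_setup(rng)
        base = group_clustering_test(genes, dm, membership, "A")
        res = exclude_gene_and_retest(genes, dm, membership, "A", "bg0")
        assert res == base

    def test_single_driver_outlier_loses_significance(self):
        # Anticlustering driven entirely by one wildly duplicated member.
        vecs = [_vec("driver", [9, 9, 9, 9, 9, 9, 9, 9])]
        vecs += [_vec(f"grp{i}", [1, 0, 0, 0, 0, 0, 0, 0]) for i in range(3)]
        vecs += [_vec(f"bg{i}", [1, 0, 0, 0, 0, 0, 0, 0]) for i in range(12)]
        genes, dm = euclidean_distance_matrix(vecs)
        membership = {g: ("A" if g == "driver" or g.startswith("grp") else "B") for g in genes}
        before = group_clustering_test(genes, dm, membership, "A")
        after = exclude_gene_and_retest(genes, dm, membership, "A", "driver")
        assert before.direction == "anticlustered"
        assert after.direction == "none"

    def test_distributed_signal_survives_any_single_exclusion(self):
        vecs = [_vec(f"grp{i}", [0] * i + [6] + [0] * (7 - i)) for i in range(5)]
        vecs += [_vec(f"bg{i}", [1, 0, 0, 0, 0, 0, 0, 0]) for i in range(15)]
        genes, dm = euclidean_distance_matrix(vecs)
        membership = {g: ("A" if g.startswith("grp") else "B") for g in genes}
        for i in range(5):
            res = exclude_gene_and_retest(genes, dm, membership, "A", f"grp{i}")
            assert res.direction == "anticlustered"

    def test_removal_below_two_members_errors(self):
        vecs = [_vec("a", [1]), _vec("b", [0]), _vec("c", [2]), _vec("d", [3])]
        genes, dm = euclidean_distance_matrix(vecs)
        membership = {"a": "A", "b": "A", "c": "B", "d": "B"}
        with pytest.raises(ValueError):
            exclude_gene_and_retest(genes, dm, membership, "A", "a")
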