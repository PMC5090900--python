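"""Neighbor joining, Newick output, clade grouping, habitat summaries."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from aarscan.identity import IdentityMatrix
from aarscan.tree import (
    CladeGrouping,
    DistanceMatrix,
    clade_groups,
    habitat_summary,
    neighbor_joining,
    to_distance,
    write_newick,
)

from oracles import quartet_topology, random_additive_tree, three_point_lengths


def pendant_lengths(tree):
    return {
        child.label: length
        for _, _, child, length in tree.edges()
        if child.is_leaf
    }


class TestToDistance:
    def test_linear_transform(self):
        ident = IdentityMatrix(["a", "b"], np.array([[100.0, 53.0], [53.0, 100.0]]))
        d = to_distance(ident)
        assert d.values[0, 1] == 47.0
        assert d.values[0, 0] == 0.0
        assert np.allclose(d.values, d.values.T)

    def test_poisson_correction_exceeds_p_distance(self):
        ident = IdentityMatrix(["a", "b"], np.array([[100.0, 53.0], [53.0, 100.0]]))
        assert to_distance(ident, "poisson").values[0, 1] > to_distance(ident).values[0, 1]


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        d = DistanceMatrix(
            ["A", "B", "C"], np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float)
        )
        lengths = pendant_lengths(neighbor_joining(d))
        assert lengths == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_two_taxa_split_equally(self):
        d = DistanceMatrix(["A", "B"], np.array([[0, 6], [6, 0]], float))
        tree = neighbor_joining(d)
        assert pendant_lengths(tree) == pytest.approx({"A": 3.0, "B": 3.0})
        assert write_newick(tree) == "(A:3,B:3);"

    def test_four_taxon_topology_matches_four_point_oracle(self):
        d = DistanceMatrix(
            ["a", "b", "c", "d"],
            np.array(
                [[0, 3, 9, 10], [3, 0, 10, 11], [9, 10, 0, 7], [10, 11, 7, 0]], float
            ),
        )
        tree = neighbor_joining(d)
        assert tree.splits() == {frozenset(quartet_topology(d.values))}

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [2.0, 0.0]]))

    @given(st.integers(min_value=4, max_value=8), st.integers(min_value=0, max_value=50))
    def test_additive_matrices_recover_generating_tree(self, n_taxa, seed):
        """On additive input NJ reproduces the generating topology and path lengths."""
        labels, matrix, true_splits = random_additive_tree(
            n_taxa, np.random.default_rng(seed)
        )
        tree = neighbor_joining(DistanceMatrix(labels, matrix))
        assert tree.splits() == true_splits
        out_labels, out_dist = tree.path_distances()
        perm = [labels.index(x) for x in out_labels]
        assert np.allclose(out_dist, matrix[np.ix_(perm, perm)], atol=1e-9)

    def test_leaf_set_preserved_and_permutation_invariant_groups(self, rng):
        labels, matrix, _ = random_additive_tree(6, rng)
        tree = neighbor_joining(DistanceMatrix(labels, matrix))
        assert sorted(tree.leaf_labels()) == sorted(labels)
        base = clade_groups(tree, 3).groups
        order = rng.permutation(len(labels))
        permuted = DistanceMatrix(
            [labels[i] for i in order], matrix[np.ix_(order, order)]
        )
        shuffled = clade_groups(neighbor_joining(permuted), 3).groups
        assert {frozenset(v) for v in base.values()} == {
            frozenset(v) for v in shuffled.values()
        }


class TestNewick:
    def test_round_trip_via_dendropy(self):
        dendropy = pytest.importorskip("dendropy")
        labels, matrix, _ = random_additive_tree(6, np.random.default_rng(7))
        tree = neighbor_joining(DistanceMatrix(labels, matrix))
        text = write_newick(tree)
        parsed = dendropy.Tree.get(data=text, schema="newick")
        assert sorted(t.label for t in parsed.taxon_namespace) == sorted(labels)
        parsed_dist = parsed.phylogenetic_distance_matrix()
        taxa = {t.label: t for t in parsed.taxon_namespace}
        _, own = tree.path_distances()
        own_labels = tree.leaf_labels()
        for i, la in enumerate(own_labels):
            for j, lb in enumerate(own_labels):
                if i < j:
                    assert parsed_dist.distance(taxa[la], taxa[lb]) == pytest.approx(
                        own[i, j]
                    )

    def test_labels_with_spaces_are_quoted(self):
        d = DistanceMatrix(["sp one", "sp two"], np.array([[0, 4], [4, 0]], float))
        text = write_newick(neighbor_joining(d))
        assert "'sp one'" in text and "'sp two'" in text


class TestCladeGroups:
    def test_k_one_is_single_group(self):
        labels, matrix, _ = random_additive_tree(5, np.random.default_rng(1))
        tree = neighbor_joining(DistanceMatrix(labels, matrix))
        assert clade_groups(tree, 1).counts == {"group1": 5}

    def test_k_equals_leaf_count_gives_singletons(self):
        labels, matrix, _ = random_additive_tree(6, np.random.default_rng(2))
        tree = neighbor_joining(DistanceMatrix(labels, matrix))
        grouping = clade_groups(tree, 6)
        assert sorted(grouping.counts.values()) == [1] * 6

    def test_long_internal_edge_defines_two_groups(self):
        # two tight clusters separated by one long internal edge
        ids = ["a", "b", "c", "d"]
        m = np.array(
            [
                [0, 1, 20, 20],
                [1, 0, 20, 20],
                [20, 20, 0, 1],
                [20, 20, 1, 0],
            ],
            float,
        )
        tree = neighbor_joining(DistanceMatrix(ids, m))
        grouping = clade_groups(tree, 2)
        parts = {frozenset(v) for v in grouping.groups.values()}
        assert parts == {frozenset({"a", "b"}), frozenset({"c", "d"})}

    def test_k_out_of_range(self):
        labels, matrix, _ = random_additive_tree(4, np.random.default_rng(3))
        tree = neighbor_joining(DistanceMatrix(labels, matrix))
        with pytest.raises(ValueError):
            clade_groups(tree, 0)
        with pytest.raises(ValueError):
            clade_groups(tree, 5)


class TestHabitatSummary:
    def test_pure_marine_group(self):
        grouping = CladeGrouping({f"m{i}": "group1" for i in range(4)})
        summary = habitat_summary(grouping, {f"m{i}": "marine" for i in range(4)})
        assert summary.fractions["group1"]["marine"] == 1.0

    def test_even_split(self):
        grouping = CladeGrouping({x: "group1" for x in "abcd"})
        habitats = {"a": "marine", "b": "marine", "c": "freshwater", "d": "freshwater"}
        fr = habitat_summary(grouping, habitats).fractions["group1"]
        assert fr["marine"] == fr["freshwater"] == 0.5

    def test_both_category_excluded_when_configured(self):
        grouping = CladeGrouping({x: "group1" for x in "abc"})
        habitats = {"a": "marine", "b": "freshwater", "c": "both"}
        default = habitat_summary(grouping, habitats).fractions["group1"]
        assert default["marine"] == pytest.approx(1 / 3)
        excl = habitat_summary(grouping, habitats, exclude_both=True).fractions["group1"]
        assert excl["marine"] == 0.5 and "both" not in excl
        assert habitat_summary(grouping, habitats).counts["group1"]["both"] == 1

    def test_fractions_sum_to_one_over_labelled_leaves(self):
        grouping = CladeGrouping({x: "group1" for x in "abcde"})
        habitats = {"a": "marine", "b": "freshwater", "c": "both", "d": "marine"}
        fr = habitat_summary(grouping, habitats).fractions["group1"]
        assert sum(fr.values()) == pytest.approx(1.0)
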