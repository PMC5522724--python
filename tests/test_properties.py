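"""Property-based tests for the structural invariants."""

import io

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hennig import (CharacterMatrix, Forest, Node, RootedTree,
                    add_allzero_outgroup, average_consensus_table,
                    build_forests, character_to_tree, leaf, matrix_from_tree,
                    ols_fit, random_rooted_tree, read_matrix,
                    read_newick, tree_length, write_newick)
from hennig.forester import is_informative
from hennig.io import matrix_to_string
from hennig.recode import additive_binary
from hennig.treefit import FitConfig

TAXA = st.integers(min_value=4, max_value=8)
SEEDS = st.integers(min_value=0, max_value=10_000)


def binary_matrix_strategy(min_taxa=4, max_taxa=7, min_chars=1, max_chars=6):
    @st.composite
    def build(draw):
        ntax = draw(st.integers(min_taxa, max_taxa))
        nchar = draw(st.integers(min_chars, max_chars))
        taxa = tuple(f"T{i}" for i in range(ntax))
        cells = tuple(
            tuple(draw(st.sampled_from("01?")) for _ in range(nchar))
            for _ in range(ntax))
        return CharacterMatrix(taxa, cells)

    return build()


class TestRoundTrips:
    @given(binary_matrix_strategy())
    @settings(max_examples=40, deadline=None)
    def test_matrix_io_round_trip(self, matrix):
        again = read_matrix(io.StringIO(matrix_to_string(matrix)))
        assert again.taxa == matrix.taxa
        assert again.cells == matrix.cells

    @given(TAXA, SEEDS)
    @settings(max_examples=40, deadline=None)
    def test_newick_round_trip(self, n, seed):
        tree = random_rooted_tree(n, seed)
        buf = io.StringIO()
        write_newick(tree, buf)
        again = read_newick(io.StringIO(buf.getvalue())).trees[0]
        assert again.topology_key() == tree.topology_key()
        assert again.leaf_labels() == tree.leaf_labels()

    @given(st.lists(st.sampled_from("01"), min_size=4, max_size=9))
    @settings(max_examples=60, deadline=None)
    def test_character_column_round_trip(self, states):
        taxa = [f"T{i}" for i in range(len(states))]
        matrix = CharacterMatrix.from_rows(
            [(t, s) for t, s in zip(taxa, states)])
        if not is_informative(states):
            return
        (tree,) = character_to_tree(matrix, 0, "additional")
        (clade_set,) = tree.clades()
        rebuilt = ["1" if t in clade_set else "0" for t in taxa]
        assert rebuilt == states


class TestForestProperties:
    @given(st.lists(st.sampled_from("01?"), min_size=4, max_size=8))
    @settings(max_examples=80, deadline=None)
    def test_expand_count_bounded_by_completions(self, states):
        n_missing = states.count("?")
        if n_missing == len(states):
            return
        taxa = [f"T{i}" for i in range(len(states))]
        matrix = CharacterMatrix.from_rows(
            [(t, s) for t, s in zip(taxa, states)])
        trees = character_to_tree(matrix, 0, "additional", "expand")
        assert 1 <= len(trees) <= 2 ** n_missing
        # distinct informative completions are never merged
        informative = {
            tuple(fill) for fill in
            __import__("itertools").product("01", repeat=n_missing)
            if is_informative(_complete(states, fill))}
        assert len(trees) >= len(informative)

    @given(st.lists(st.sampled_from("01"), min_size=4, max_size=8))
    @settings(max_examples=40, deadline=None)
    def test_expand_equals_prune_without_missing(self, states):
        taxa = [f"T{i}" for i in range(len(states))]
        matrix = CharacterMatrix.from_rows(
            [(t, s) for t, s in zip(taxa, states)])
        expand = character_to_tree(matrix, 0, "with_poly", "expand")
        prune = character_to_tree(matrix, 0, "with_poly", "prune")
        assert len(expand) == len(prune) == 1
        assert expand[0].topology_key() == prune[0].topology_key()


def _complete(states, fill):
    out = list(states)
    it = iter(fill)
    for i, s in enumerate(out):
        if s == "?":
            out[i] = next(it)
    return out


class TestAverageConsensusProperties:
    @given(TAXA, SEEDS)
    @settings(max_examples=25, deadline=None)
    def test_duplication_invariance(self, n, seed):
        tree = random_rooted_tree(n, seed)
        matrix = add_allzero_outgroup(matrix_from_tree(tree), "OUT")
        forest = build_forests(matrix).additional
        if len(forest) == 0:
            return
        doubled = Forest(trees=[t.copy() for t in forest.trees] * 2)
        t1 = average_consensus_table(forest)
        t2 = average_consensus_table(doubled).reorder(t1.taxa)
        assert np.allclose(t1.d, t2.d)

    @given(TAXA, SEEDS)
    @settings(max_examples=25, deadline=None)
    def test_table_bounds(self, n, seed):
        from hennig import path_length_matrix
        tree = random_rooted_tree(n, seed)
        matrix = add_allzero_outgroup(matrix_from_tree(tree), "OUT")
        forest = build_forests(matrix).additional
        if len(forest) == 0:
            return
        table = average_consensus_table(forest)
        per_tree = [path_length_matrix(t) for t in forest]
        for i, a in enumerate(table.taxa):
            for b in table.taxa[i + 1:]:
                values = [m[frozenset((a, b))] for m in per_tree
                          if frozenset((a, b)) in m]
                assert min(values) - 1e-9 <= table.get(a, b)
                assert table.get(a, b) <= max(values) + 1e-9


class TestRecodeProperties:
    @given(st.lists(st.sampled_from("0123?"), min_size=5, max_size=7),
           SEEDS)
    @settings(max_examples=40, deadline=None)
    def test_additive_binary_preserves_ordered_length(self, states, seed):
        taxa = [f"T{i}" for i in range(len(states))]
        matrix = CharacterMatrix.from_rows(
            [(t, s) for t, s in zip(taxa, states)], alphabet="multistate")
        recoded = additive_binary(matrix, ordered_chars=[0])
        tree = random_rooted_tree(len(taxa), seed, labels=taxa)
        assert (tree_length(tree, matrix, ordered=[0])
                == tree_length(tree, recoded))


class TestFitProperties:
    @given(TAXA, SEEDS)
    @settings(max_examples=20, deadline=None)
    def test_perfect_forest_is_additive_on_generating_tree(self, n, seed):
        tree = random_rooted_tree(n, seed)
        matrix = add_allzero_outgroup(matrix_from_tree(tree), "OUT")
        forest = build_forests(matrix).additional
        table = average_consensus_table(forest)
        rooted = tree.copy()
        expected = RootedTree(Node(children=[rooted.root, leaf("OUT")]))
        fit = ols_fit(expected, table, FitConfig())
        assert fit.score == pytest.approx(0.0, abs=1e-14)
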