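import numpy as np
import pytest

from hennig import (DistanceTable, FitConfig, HennigError, RootedTree,
                    TreeError, average_consensus_table, bme_length,
                    build_forests, nj_tree, ols_fit, parse_newick,
                    root_at_outgroup, search_best_tree, strict_consensus,
                    upgma_tree)
from hennig.model import patristic_matrix
from hennig.treefit import enumerate_unrooted_topologies

from conftest import double_factorial, oracle_ols_score


def additive_table(newick: str, taxa: list[str]) -> DistanceTable:
    tree = parse_newick(newick)
    return DistanceTable(taxa, patristic_matrix(tree, taxa,
                                                use_lengths=True))


@pytest.fixture
def conflict_table(conflict5):
    return average_consensus_table(build_forests(conflict5).additional)


class TestOlsFit:
    def test_exact_fit_on_conflict_table(self, conflict_table):
        topology = parse_newick("((O,A),(B,C,D));")
        result = ols_fit(topology, conflict_table)
        assert result.score == pytest.approx(0.0, abs=1e-18)
        lengths = {}
        for node in result.tree.preorder():
            if node.is_leaf:
                lengths[node.label] = node.length
        assert lengths["O"] == pytest.approx(1.0)
        assert lengths["A"] == pytest.approx(1.0)
        for taxon in "BCD":
            assert lengths[taxon] == pytest.approx(4 / 3)
        # the single internal split edge carries 1/3 in total
        internal = [n for n in result.tree.preorder()
                    if not n.is_leaf and n is not result.tree.root]
        assert sum(n.length for n in internal) == pytest.approx(1 / 3)
        assert result.implied_distance("O", "A") == pytest.approx(2.0)
        assert result.implied_distance("B", "D") == pytest.approx(8 / 3)

    def test_recovers_generating_lengths(self):
        taxa = ["A", "B", "C", "D"]
        table = additive_table("((A:1,B:2):1.5,(C:3,D:1));", taxa)
        result = ols_fit(parse_newick("((A,B),(C,D));"), table)
        assert result.score == pytest.approx(0.0, abs=1e-16)
        assert np.allclose(result.p, table.d)

    def test_star_scores_worse(self, conflict_table):
        star = parse_newick("(O,A,B,C,D);")
        result = ols_fit(star, conflict_table)
        assert result.score > 0.05

    def test_leaf_set_mismatch(self, conflict_table):
        with pytest.raises(TreeError):
            ols_fit(parse_newick("((A,B),(C,D));"), conflict_table)

    def test_clamp_zero_policy(self):
        # a table that forces a negative internal branch under OLS
        d = np.array([[0.0, 3.0, 2.0, 2.0],
                      [3.0, 0.0, 2.0, 2.0],
                      [2.0, 2.0, 0.0, 3.0],
                      [2.0, 2.0, 3.0, 0.0]])
        table = DistanceTable(["A", "B", "C", "D"], d)
        free = ols_fit(parse_newick("((A,B),(C,D));"), table,
                       FitConfig(negbrlen="allow"))
        clamped = ols_fit(parse_newick("((A,B),(C,D));"), table,
                          FitConfig(negbrlen="clamp_zero"))
        constrained = ols_fit(parse_newick("((A,B),(C,D));"), table,
                              FitConfig(negbrlen="constrain_nonneg"))
        assert min(n.length for n in free.tree.preorder()
                   if n is not free.tree.root) < 0
        assert all(n.length >= 0 for n in clamped.tree.preorder()
                   if n is not clamped.tree.root)
        assert free.score <= constrained.score + 1e-12
        assert constrained.score <= clamped.score + 1e-12

    def test_wls_zero_distance_error(self):
        d = np.array([[0.0, 0.0, 1.0], [0.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        table = DistanceTable(["A", "B", "C"], d)
        with pytest.raises(HennigError, match="P'"):
            ols_fit(parse_newick("(A,B,C);"), table, FitConfig(
                criterion="wls", power=7.0))

    def test_implied_distances_recomputable_from_fitted_tree(
            self, conflict_table):
        topology = parse_newick("((O,A),((B,C),D));")
        result = ols_fit(topology, conflict_table)
        recomputed = patristic_matrix(result.tree, result.taxa,
                                      use_lengths=True)
        assert np.allclose(recomputed, result.p, atol=1e-10)

    def test_score_invariant_under_taxon_permutation(self, conflict_table):
        topology = parse_newick("((O,A),((B,C),D));")
        base = ols_fit(topology, conflict_table).score
        perm = ["C", "O", "D", "A", "B"]
        permuted = conflict_table.reorder(perm)
        again = ols_fit(topology, permuted).score
        assert again == pytest.approx(base, abs=1e-12)


class TestClosedFormVsBruteForce:
    @pytest.mark.parametrize("n", [4, 5])
    def test_all_topologies_match_numeric_minimum(self, n):
        rng = np.random.default_rng(n)
        taxa = [chr(65 + i) for i in range(n)]
        sym = rng.uniform(1.0, 4.0, size=(n, n))
        d = np.triu(sym, 1)
        d = d + d.T
        table = DistanceTable(taxa, d)
        from hennig.treefit import _edges_to_tree
        for edges in enumerate_unrooted_topologies(n):
            tree = _edges_to_tree(edges, [1.0] * len(edges), taxa)
            closed = ols_fit(tree, table).score
            numeric = oracle_ols_score(tree, taxa, d)
            assert closed == pytest.approx(numeric, abs=1e-8)


class TestSearch:
    def test_enumeration_counts(self):
        for n in range(4, 8):
            count = sum(1 for _ in enumerate_unrooted_topologies(n))
            assert count == double_factorial(2 * n - 5)

    def test_conflict_search_recovers_hidden_clade(self, conflict_table):
        results = search_best_tree(conflict_table, FitConfig(),
                                   outgroup="O")
        assert results[0].score == pytest.approx(0.0, abs=1e-12)
        assert len(results) == 3
        for result in results:
            assert frozenset("BCD") in {
                frozenset(c) for c in result.tree.clades()}
        consensus = strict_consensus([r.tree for r in results])
        assert consensus.clades() == {frozenset("BCD"), frozenset("ABCD")}

    def test_additive_table_unique_optimum(self):
        taxa = ["A", "B", "C", "D"]
        table = additive_table("((A:1,B:2):1.5,(C:3,D:1));", taxa)
        results = search_best_tree(table, FitConfig())
        assert len(results) == 1
        assert results[0].score == pytest.approx(0.0, abs=1e-12)
        assert results[0].tree.splits() == {frozenset("CD")}

    def test_equidistant_quartet_all_tie(self):
        d = np.ones((4, 4)) * 2.0
        np.fill_diagonal(d, 0.0)
        table = DistanceTable(["A", "B", "C", "D"], d)
        results = search_best_tree(table, FitConfig())
        assert len(results) == 3

    def test_requires_four_taxa(self):
        d = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(HennigError):
            search_best_tree(DistanceTable(["A", "B"], d))

    def test_nni_heuristic_on_additive_table(self):
        newick = ("(((A:1,B:1):1,(C:1,D:1):1):1,"
                  "((E:1,F:1):1,(G:1,H:1):1):1,(I:1,J:1):1);")
        taxa = list("ABCDEFGHIJ")
        table = additive_table(newick, taxa)
        results = search_best_tree(table, FitConfig(exhaustive_limit=6))
        assert results[0].score == pytest.approx(0.0, abs=1e-10)
        assert results[0].tree.splits() >= {
            frozenset("CD"), frozenset("EF"),
            frozenset("GH"), frozenset("IJ"),
            frozenset("CDEFGHIJ")}

    def test_bme_criterion_search(self):
        taxa = ["A", "B", "C", "D"]
        table = additive_table("((A:1,B:2):0.75,(C:3,D:1):0.75);", taxa)
        results = search_best_tree(table, FitConfig(criterion="bme"))
        assert results[0].tree.splits() == {frozenset("CD")}
        # BME length on the generating topology = sum of true lengths
        assert results[0].score == pytest.approx(8.5)


class TestNeighborJoining:
    def test_recovers_additive_topology(self):
        taxa = ["A", "B", "C", "D", "E"]
        table = additive_table("(((A:1,B:2):1,C:4):1,(D:2,E:3));", taxa)
        tree = nj_tree(table)
        assert tree.splits() == {frozenset("CDE"), frozenset("DE")}

    def test_conflict_table_split(self, conflict_table):
        # NJ fully resolves; the load-bearing split separates {O,A} from
        # {B,C,D} (the extra resolving edge has zero length)
        tree = nj_tree(conflict_table)
        assert frozenset("BCD") in tree.splits()

    def test_three_taxa_star(self):
        d = np.array([[0.0, 3.0, 4.0], [3.0, 0.0, 5.0], [4.0, 5.0, 0.0]])
        tree = nj_tree(DistanceTable(["A", "B", "C"], d))
        lengths = {n.label: n.length for n in tree.leaves()}
        assert lengths["A"] == pytest.approx(1.0)
        assert lengths["B"] == pytest.approx(2.0)
        assert lengths["C"] == pytest.approx(3.0)

    def test_deterministic(self, conflict_table):
        assert (nj_tree(conflict_table).newick(lengths=True)
                == nj_tree(conflict_table).newick(lengths=True))


class TestUpgma:
    def test_ultrametric_recovery(self):
        d = np.array([[0.0, 2.0, 6.0], [2.0, 0.0, 6.0], [6.0, 6.0, 0.0]])
        tree = upgma_tree(DistanceTable(["A", "B", "C"], d))
        assert tree.clades() == {frozenset("AB")}
        heights = {n.label: n.length for n in tree.leaves()}
        assert heights["A"] == pytest.approx(1.0)
        assert heights["C"] == pytest.approx(3.0)

    def test_two_taxa_cherry(self):
        d = np.array([[0.0, 5.0], [5.0, 0.0]])
        tree = upgma_tree(DistanceTable(["A", "B"], d))
        for node in tree.leaves():
            assert node.length == pytest.approx(2.5)

    def test_nonclock_data_misleads_upgma(self):
        # long pendant edge pulls A away from its true sister B
        taxa = ["A", "B", "C", "D"]
        table = additive_table("((A:10,B:1):1,(C:1,D:1));", taxa)
        tree = upgma_tree(table)
        assert frozenset("AB") not in tree.clades()
        assert nj_tree(table).splits() == {frozenset("CD")}


class TestBme:
    def test_equidistant_quartet_length(self):
        d = np.ones((4, 4)) * 2.0
        np.fill_diagonal(d, 0.0)
        table = DistanceTable(["A", "B", "C", "D"], d)
        assert bme_length(parse_newick("((A,B),(C,D));"),
                          table) == pytest.approx(4.0)

    def test_additive_length_and_wrong_quartet(self):
        taxa = ["A", "B", "C", "D"]
        table = additive_table("((A:1,B:2):0.75,(C:3,D:1):0.75);", taxa)
        right = bme_length(parse_newick("((A,B),(C,D));"), table)
        wrong = bme_length(parse_newick("((A,C),(B,D));"), table)
        assert right == pytest.approx(8.5)
        assert wrong > right

    def test_non_binary_rejected(self, conflict_table):
        with pytest.raises(TreeError, match="binary"):
            bme_length(parse_newick("(O,A,B,C,D);"), conflict_table)


class TestConsensusAndRooting:
    def test_strict_consensus_three_resolutions(self):
        trees = [parse_newick("(O,(A,(B,(C,D))));"),
                 parse_newick("(O,(A,(C,(B,D))));"),
                 parse_newick("(O,(A,(D,(B,C))));")]
        consensus = strict_consensus(trees)
        assert {frozenset(c) for c in consensus.clades()} == {
            frozenset("ABCD"), frozenset("BCD")}

    def test_identical_trees(self):
        t = parse_newick("(O,(A,(B,C)));")
        consensus = strict_consensus([t, t.copy()])
        assert consensus.topology_key() == t.topology_key()

    def test_incompatible_trees_star(self):
        trees = [parse_newick("((A,B),(C,D));"),
                 parse_newick("((A,C),(B,D));")]
        consensus = strict_consensus(trees)
        assert consensus.clades() == set()

    def test_leaf_set_mismatch(self):
        with pytest.raises(TreeError):
            strict_consensus([parse_newick("(A,(B,C));"),
                              parse_newick("(A,(B,D));")])

    def test_root_unrooted_tree(self):
        tree = parse_newick("((O,A),(B,(C,D)));")
        rooted = root_at_outgroup(tree, "O")
        assert rooted.newick() == "(O,(A,(B,(C,D))));"

    def test_root_identity(self):
        tree = parse_newick("(O,(A,(B,C)));")
        assert root_at_outgroup(tree, "O").newick() == "(O,(A,(B,C)));"

    def test_root_missing_taxon(self):
        with pytest.raises(TreeError, match="not in the tree"):
            root_at_outgroup(parse_newick("(A,(B,C));"), "Z")
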