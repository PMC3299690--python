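import numpy as np
import pytest

import ribophylo as rp
from ribophylo.errors import InputError, MissingTaxonError
from ribophylo.parsimony import majority_consensus, random_topology

from conftest import (
    brute_force_length,
    matrix_from_columns,
    random_matrix,
    rooted_tree,
    unrooted_tree,
)


class TestTreeLength:
    def test_three_leaf_ordered_median(self):
        m = matrix_from_columns(["025"], taxa=("A", "B", "C"))
        t = unrooted_tree("(A,B,C);")
        assert rp.tree_length(t, m) == 5

    def test_identical_leaves_cost_zero(self):
        m = matrix_from_columns(["777", "555"], taxa=("A", "B", "C"))
        assert rp.tree_length(unrooted_tree("(A,B,C);"), m) == 0

    def test_four_leaf_split(self):
        m = matrix_from_columns(["0033"], taxa=("A", "B", "C", "D"))
        assert rp.tree_length(unrooted_tree("((A,B),(C,D));"), m) == 3

    def test_missing_leaf_raises(self):
        m = matrix_from_columns(["00"], taxa=("A", "B"))
        with pytest.raises(MissingTaxonError):
            rp.tree_length(unrooted_tree("(A,B,Z);"), m)

    def test_sankoff_equals_brute_force_enumeration(self, rng):
        """Oracle: enumerate every internal-state assignment (<= 6 leaves)."""
        for _ in range(25):
            n = int(rng.integers(4, 7))
            m = random_matrix(rng, n, int(rng.integers(2, 5)), max_state=5)
            t = rp.heuristic_search(m, seed=0, collect_ties=False)[0]
            assert rp.tree_length(t, m) == brute_force_length(t, m)

    def test_root_position_invariance(self, rng):
        m = random_matrix(rng, 6, 4)
        t = rp.heuristic_search(m, seed=1, collect_ties=False)[0]
        base = rp.tree_length(t, m)
        m_pol = rp.polarize(m)
        rooted = rp.root_with_ancestor(t, m_pol)
        assert rp.tree_length(rooted, m) == base


class TestBounds:
    @pytest.mark.parametrize(
        "column,expected",
        [("025", (5, 5)), ("004", (4, 4)), ("04448", (8, 8)), ("333", (0, 0))],
    )
    def test_range_and_star_cost(self, column, expected):
        m = matrix_from_columns([column])
        mn, mx = rp.per_character_bounds(m)
        assert (int(mn[0]), int(mx[0])) == expected

    def test_length_between_bounds(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 5)
            t = rp.heuristic_search(m, seed=2, collect_ties=False)[0]
            L = rp.tree_length(t, m)
            mn, mx = rp.per_character_bounds(m)
            assert mn.sum() <= L <= mx.sum()


class TestFitStats:
    def test_perfect_fit(self, toy):
        t = rp.exhaustive_search(toy.matrix)[0][0]
        fs = rp.fit_stats(t, toy.matrix, n_random_trees=0)
        assert fs.ci == 1.0 and fs.hi == 0.0

    def test_hi_complements_ci(self, rng):
        m = random_matrix(rng, 7, 6)
        t = rp.heuristic_search(m, seed=3, collect_ties=False)[0]
        fs = rp.fit_stats(t, m, n_random_trees=0)
        assert fs.hi == pytest.approx(1.0 - fs.ci)
        if fs.ri is not None:
            assert 0.0 <= fs.ri <= 1.0

    def test_ri_missing_when_bounds_collapse(self):
        m = matrix_from_columns(["3333"])
        t = unrooted_tree("((t0,t1),(t2,t3));")
        fs = rp.fit_stats(t, m, n_random_trees=0)
        assert fs.ri is None

    def test_g1_near_zero_for_symmetric_lengths(self):
        # a single binary character yields a two-valued, near-symmetric
        # random-tree length distribution, so skewness is bounded
        m = matrix_from_columns(["0011"], taxa=("A", "B", "C", "D"))
        t = unrooted_tree("((A,B),(C,D));")
        fs = rp.fit_stats(t, m, n_random_trees=500, seed=4)
        assert abs(fs.g1) < 1.5


class TestHeuristicSearch:
    def test_matches_exhaustive_on_small_matrices(self, rng):
        for _ in range(30):
            n = int(rng.integers(5, 8))
            m = random_matrix(rng, n, int(rng.integers(2, 5)))
            best, opt = rp.exhaustive_search(m)
            found = rp.heuristic_search(m, seed=5, collect_ties=False)[0]
            assert rp.tree_length(found, m) == opt

    def test_single_compatible_character(self):
        m = matrix_from_columns(["001122"])
        t = rp.heuristic_search(m, seed=6, collect_ties=False)[0]
        mn, _ = rp.per_character_bounds(m)
        assert rp.tree_length(t, m) == int(mn[0])

    def test_duplicate_taxon_leaves_length_unchanged(self, rng):
        m = random_matrix(rng, 5, 3)
        _, opt = rp.exhaustive_search(m)
        dup = matrix_from_columns(
            [c + c[-1] for c in ("".join(r[j] for r in m.states) for j in range(3))],
            taxa=m.rows + ("t4_dup",),
        )
        t = rp.heuristic_search(dup, seed=7, collect_ties=False)[0]
        assert rp.tree_length(t, dup) == opt

    def test_few_taxa_warns_and_returns_trivial(self):
        m = matrix_from_columns(["012"], taxa=("A", "B", "C"))
        with pytest.warns(UserWarning, match="taxa"):
            trees = rp.heuristic_search(m)
        assert len(trees) == 1

    def test_random_addition_reaches_same_optimum(self, rng):
        m = random_matrix(rng, 7, 4)
        _, opt = rp.exhaustive_search(m)
        t = rp.heuristic_search(
            m, addition="random", n_restarts=3, seed=8, collect_ties=False
        )[0]
        assert rp.tree_length(t, m) == opt

    def test_reproducible_given_seed(self, rng):
        m = random_matrix(rng, 8, 5)
        a = rp.heuristic_search(m, addition="random", n_restarts=2, seed=9)
        b = rp.heuristic_search(m, addition="random", n_restarts=2, seed=9)
        assert [t.as_string(schema="newick") for t in a] == [
            t.as_string(schema="newick") for t in b
        ]


class TestConsensusAndDistance:
    def test_single_tree_consensus_is_itself(self):
        t = unrooted_tree("((A,B),(C,D),E);")
        cons = rp.strict_consensus([t])
        assert rp.rf_distance(t, cons) == 0

    def test_disjoint_trees_give_star(self):
        t1 = unrooted_tree("((A,B),C,(D,E));")
        t2 = unrooted_tree("((A,D),C,(B,E));")
        cons = rp.strict_consensus([t1, t2])
        assert len(cons.seed_node.child_nodes()) == 5

    def test_shared_clade_retained(self):
        t1 = unrooted_tree("(((A,B),C),D,E);")
        t2 = unrooted_tree("((A,B),(C,D),E);")
        cons = rp.strict_consensus([t1, t2])
        from ribophylo.parsimony import _tree_bipartitions

        bips, _ = _tree_bipartitions(cons)
        assert bips == {frozenset({"A", "B"})}

    def test_mismatched_leaf_sets_rejected(self):
        with pytest.raises(InputError):
            rp.strict_consensus(
                [unrooted_tree("((A,B),C,D);"), unrooted_tree("((A,B),C,E);")]
            )

    @pytest.mark.parametrize(
        "n1,n2,expected",
        [
            ("((A,B),(C,D),E);", "((A,B),(C,D),E);", 0),
            ("((A,B),(C,D));", "((A,C),(B,D));", 2),
            ("(A,B,C,D,E);", "((A,B),(C,D),E);", 2),
        ],
    )
    def test_rf_distance(self, n1, n2, expected):
        assert rp.rf_distance(unrooted_tree(n1), unrooted_tree(n2)) == expected


class TestBootstrap:
    def test_single_rep_supports_are_all_or_nothing(self, toy):
        t = rp.bootstrap_support(toy.matrix, reps=1, seed=10)
        supports = [
            float(n.label) for n in t.preorder_internal_node_iter() if n.label
        ]
        assert set(supports) <= {0.0, 100.0}

    def test_clean_signal_high_support(self):
        cols = ["001111", "001111", "000111", "000111", "000011", "000011"]
        m = matrix_from_columns(cols, taxa=tuple("ABCDEF"))
        t = rp.bootstrap_support(m, reps=100, seed=11)
        supports = [
            float(n.label) for n in t.preorder_internal_node_iter() if n.label
        ]
        assert supports and min(supports) >= 60.0

    def test_noise_gives_weak_support(self, rng):
        m = random_matrix(rng, 8, 6)
        t = rp.bootstrap_support(m, reps=60, seed=12)
        supports = [
            float(n.label) for n in t.preorder_internal_node_iter() if n.label
        ]
        assert all(s <= 101 for s in supports)
        # majority-rule keeps only > 50%; a pure-noise matrix rarely
        # resolves many high-support clades
        assert sum(1 for s in supports if s > 95) <= 3


class TestRooting:
    def test_ancestor_identical_to_leaf_roots_next_to_it(self):
        m = matrix_from_columns(
            ["0123", "0112"], taxa=("A", "B", "C", "D"),
        )
        m = rp.polarize(m, "min_ancestral")  # ancestor equals leaf A
        t = rp.heuristic_search(m, seed=13, collect_ties=False)[0]
        rooted = rp.root_with_ancestor(t, m)
        children = rooted.seed_node.child_nodes()
        leaf_children = [c.taxon.label for c in children if c.is_leaf()]
        assert "A" in leaf_children

    def test_attachment_matches_brute_force(self, rng):
        """Oracle: score the ancestor leaf grafted on every branch."""
        from ribophylo.parsimony import (
            _Scorer,
            _insert_leaf,
            _tree_from_matrix_leaves,
        )

        for trial in range(8):
            m = rp.polarize(random_matrix(rng, 5, 4))
            t = rp.heuristic_search(m, seed=14 + trial, collect_ties=False)[0]
            aug = matrix_from_columns(
                [
                    "".join(r[j] for r in m.states) + m.ancestral_states[j]
                    for j in range(m.n_characters)
                ],
                taxa=m.rows + ("ANC",),
            )
            t_int = _tree_from_matrix_leaves(m, t)
            scorer = _Scorer(aug)
            graft = {
                e: scorer.length(_insert_leaf(t_int, e, aug.n_rows - 1))
                for e in t_int.edges()
            }
            best = min(graft.values())
            best_sides = set()
            for (u, v), cost in graft.items():
                if cost == best:
                    side = frozenset(
                        m.rows[i] for i in t_int._leaves_beyond(u, v)
                    )
                    best_sides.add(side)
                    best_sides.add(frozenset(m.rows) - side)
            rooted = rp.root_with_ancestor(t, m)
            root_side = frozenset(
                lf.taxon.label
                for lf in rooted.seed_node.child_nodes()[0].leaf_iter()
            )
            assert root_side in best_sides
            # rooting never changes the unrooted length
            assert rp.tree_length(rooted, m) == rp.tree_length(t, m)

    def test_constant_matrix_ties_flagged(self):
        m = matrix_from_columns(["0000", "1111"], taxa=tuple("ABCD"))
        m = rp.polarize(m)
        t = unrooted_tree("((A,B),(C,D));")
        with pytest.warns(UserWarning, match="tie"):
            rooted = rp.root_with_ancestor(t, m)
        assert rooted.root_attachment_ties > 1

    def test_requires_ancestral_states(self):
        m = matrix_from_columns(["0011"], taxa=tuple("ABCD"))
        with pytest.raises(InputError):
            rp.root_with_ancestor(unrooted_tree("((A,B),(C,D));"), m)


class TestAncestralStates:
    def test_constant_character_constant_everywhere(self):
        m = matrix_from_columns(["5555"], taxa=tuple("ABCD"))
        t = rooted_tree("((A,B),(C,D));")
        states = rp.ancestral_states(t, m)
        assert {s for s in states.values()} == {"5"}

    def test_three_leaf_median_root(self):
        m = matrix_from_columns(["025"], taxa=("A", "B", "C"))
        t = rooted_tree("((A,B),C);")
        states = rp.ancestral_states(t, m)
        internal = [v for n, v in states.items() if not n.is_leaf()]
        assert "2" in internal

    def test_assignment_cost_equals_tree_length(self, rng):
        for _ in range(10):
            m = random_matrix(rng, 6, 4)
            t = rp.heuristic_search(m, seed=15, collect_ties=False)[0]
            m_pol = rp.polarize(m)
            rooted = rp.root_with_ancestor(t, m_pol)
            states = rp.ancestral_states(rooted, m)
            cost = 0
            for node, s in states.items():
                for ch in node.child_nodes():
                    cost += sum(
                        abs(m.alphabet.index(a) - m.alphabet.index(b))
                        for a, b in zip(s, states[ch])
                    )
            assert cost == rp.tree_length(rooted, m)


def test_random_topology_is_binary(rng):
    t = random_topology(list(range(9)), rng)
    degrees = sorted(len(v) for v in t.adj.values())
    assert degrees.count(1) == 9 and set(degrees) == {1, 3}


def test_majority_consensus_supports_bounded(rng):
    m = random_matrix(rng, 6, 5)
    trees = [
        rp.heuristic_search(m, addition="random", n_restarts=1, seed=s,
                            collect_ties=False)[0]
        for s in range(4)
    ]
    cons = majority_consensus(trees)
    for n in cons.preorder_internal_node_iter():
        if n.label:
            assert 50.0 < float(n.label) <= 100.0
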