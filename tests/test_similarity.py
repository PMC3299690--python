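from itertools import permutations

import numpy as np
import pytest

import ribophylo as rp
from ribophylo.errors import InputError
from ribophylo.similarity import (
    BASE_MATCH,
    PAIR_MATCH,
    dinucleotide_counts,
    self_score,
)
from ribophylo.structures import parse_dotbracket


def _structure(db, seq=None):
    if seq is None:
        seq = "".join("G" if c == "(" else ("C" if c == ")" else "A") for c in db)
    return parse_dotbracket(db, seq)


class TestForest:
    def test_all_unpaired(self):
        f = rp.structure_to_forest(_structure("...."))
        assert len(f.roots) == 4
        assert all(r.kind == "B" for r in f.roots)

    def test_minimal_hairpin(self):
        f = rp.structure_to_forest(_structure("(...)"))
        assert len(f.roots) == 1
        root = f.roots[0]
        assert root.kind == "P"
        assert [c.kind for c in root.children] == ["B", "B", "B"]

    def test_stacked_pair(self):
        f = rp.structure_to_forest(_structure("((...))"))
        root = f.roots[0]
        assert root.kind == "P" and len(root.children) == 1
        assert root.children[0].kind == "P"
        assert len(root.children[0].children) == 3

    def test_inorder_traversal_reconstructs_sequence(self):
        s = _structure("((..((...))..))")
        assert rp.structure_to_forest(s).sequence() == s.sequence

    def test_crossing_pairs_unsupported(self):
        s = rp.SecondaryStructure(
            name="pk",
            sequence="GGAAGGAACCAACC",
            pairs=frozenset({(1, 10)}),
            pseudoknot_pairs=frozenset({(5, 14)}),
        )
        f = rp.structure_to_forest(s)
        # pseudoknot pairs are simply not part of the nested forest
        assert sum(1 for r in f.roots if r.kind == "P") == 1


class TestAlignLocal:
    def test_self_alignment_counts_nodes(self):
        f = rp.structure_to_forest(_structure("((((....))))"))
        score, _ = rp.align_local(f, f)
        assert score == 4 * PAIR_MATCH + 4 * BASE_MATCH == 44.0

    def test_empty_forest_floors_at_zero(self):
        f = rp.structure_to_forest(_structure("(...)"))
        empty = rp.StructureForest(roots=())
        assert rp.align_local(f, empty)[0] == 0.0

    def test_symmetry(self):
        f1 = rp.structure_to_forest(_structure("((..((...))..))"))
        f2 = rp.structure_to_forest(_structure(".((....)).."))
        assert rp.align_local(f1, f2)[0] == rp.align_local(f2, f1)[0]

    def test_identity_is_best_possible(self):
        """No target of the same node multiset can beat self-alignment."""
        f = rp.structure_to_forest(_structure("((.((...)).))"))
        best = self_score(f)
        for db in ["((.((...)).))", "(((......)))", ".((...))..(.)"]:
            other = rp.structure_to_forest(_structure(db))
            assert rp.align_local(f, other)[0] <= best
        assert rp.align_local(f, f)[0] == best

    def test_submotif_found_inside_larger_structure(self):
        motif = rp.structure_to_forest(_structure("((((...))))"))
        embedded = rp.structure_to_forest(_structure("..((((...))))..(...)"))
        score, _ = rp.align_local(motif, embedded)
        assert score == self_score(motif)


class TestShuffle:
    def test_fixed_point_sequence(self):
        assert rp.dinucleotide_shuffle("AAAA", 1) == "AAAA"

    def test_counts_and_termini_preserved(self):
        seq = "GCAUGGCAUCCGAUGCA"
        for seed in range(10):
            s = rp.dinucleotide_shuffle(seq, np.random.default_rng(seed))
            assert dinucleotide_counts(s) == dinucleotide_counts(seq)
            assert s[0] == seq[0] and s[-1] == seq[-1]
            assert len(s) == len(seq)

    def test_matches_eulerian_enumeration(self):
        """Oracle: brute-force the set of valid arrangements of an 8-mer."""
        seq = "GAGCGAGC"
        ref = dinucleotide_counts(seq)
        brute = {
            seq[0] + "".join(p) + seq[-1]
            for p in set(permutations(seq[1:-1]))
            if dinucleotide_counts(seq[0] + "".join(p) + seq[-1]) == ref
        }
        assert len(brute) == 3  # a genuinely multi-arrangement case
        drawn = {
            rp.dinucleotide_shuffle(seq, np.random.default_rng(s))
            for s in range(400)
        }
        assert drawn == brute

    def test_bad_alphabet_rejected(self):
        with pytest.raises(InputError):
            rp.dinucleotide_shuffle("AXGU", 0)

    def test_too_short_rejected(self):
        with pytest.raises(InputError):
            rp.dinucleotide_shuffle("AU", 0)


def _enumerate_max_pairs(seq, min_loop=3):
    """Independent oracle: generate every nested pair set explicitly."""
    pairable = {
        ("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")
    }

    def all_sets(positions):
        """Yield every valid non-crossing pair set on these positions."""
        if not positions:
            yield frozenset()
            return
        i, rest = positions[0], positions[1:]
        yield from all_sets(rest)  # i stays unpaired
        for j in rest:
            if j - i - 1 < min_loop:
                continue
            if (seq[i - 1], seq[j - 1]) not in pairable:
                continue
            inside = [k for k in rest if k < j]
            outside = [k for k in rest if k > j]
            for inner in all_sets(inside):
                for outer in all_sets(outside):
                    yield frozenset({(i, j)}) | inner | outer

    return max(len(s) for s in all_sets(list(range(1, len(seq) + 1))))


class TestFoldBaseline:
    def test_unpairable_sequence(self):
        assert len(rp.fold_baseline("AAAA").pairs) == 0

    def test_hand_dp_three_pairs(self):
        assert len(rp.fold_baseline("GGGAAACCC").pairs) == 3

    def test_deterministic(self):
        seq = "GGCAGCUUCGGCUGCC"
        assert rp.fold_baseline(seq).pairs == rp.fold_baseline(seq).pairs

    @pytest.mark.parametrize(
        "seq",
        ["GGGAAACCC", "GCGCAAAGCGC", "AUGCUAGCUAGC", "GGAAUUCC", "ACGUACGUACGU",
         "UUUAAAGGGCCC"],
    )
    def test_pair_count_matches_enumeration(self, seq):
        """Oracle: exhaustive enumeration of nested structures (len <= 12)."""
        assert len(rp.fold_baseline(seq).pairs) == _enumerate_max_pairs(seq)

    def test_structure_is_valid_and_honors_min_loop(self):
        s = rp.fold_baseline("GGCAGCUUCGGCUGCCAAGG", min_loop=3)
        for i, j in s.pairs:
            assert j - i - 1 >= 3


class TestZScoreScreen:
    def test_planted_homolog_significant(self, toy):
        res = rp.zscore_screen(
            toy.query_helix, toy.ribozyme_parts[0], n_shuffles=300, seed=0
        )
        assert res.z is not None and res.z >= 3.0
        assert res.significant

    def test_degenerate_null_flagged_not_significant(self, toy):
        res = rp.zscore_screen(
            toy.query_helix, toy.ribozyme_parts[1], n_shuffles=30, seed=0
        )
        assert res.null_sd == 0.0
        assert res.z is None and not res.significant

    def test_shuffled_self_control_not_significant(self, toy):
        """Query vs a shuffled-and-refolded copy of itself: |Z| < 3."""
        violations = 0
        runs = 12
        for i in range(runs):
            shuffled = rp.dinucleotide_shuffle(
                toy.query_helix.sequence, np.random.default_rng(500 + i)
            )
            target = rp.fold_baseline(shuffled)
            res = rp.zscore_screen(
                toy.query_helix, target, n_shuffles=80, seed=900 + i
            )
            if res.z is not None and abs(res.z) >= 3.0:
                violations += 1
        assert violations == 0

    def test_seeded_reproducibility(self, toy):
        a = rp.zscore_screen(toy.query_helix, toy.ribozyme_parts[0],
                             n_shuffles=50, seed=3)
        b = rp.zscore_screen(toy.query_helix, toy.ribozyme_parts[0],
                             n_shuffles=50, seed=3)
        assert a == b


class TestScreenMatrix:
    def test_empty_parts_empty_table(self, toy):
        df = rp.screen_matrix([toy.query_helix], {"h_query": 0.1}, [], seed=0)
        assert len(df) == 0

    def test_cross_product_rows(self, toy):
        df = rp.screen_matrix(
            [toy.query_helix], {"h_query": 0.1}, toy.ribozyme_parts,
            n_shuffles=30, seed=0,
        )
        assert len(df) == 2
        assert set(df["part"]) == {"rz_planted", "rz_control"}

    def test_significant_hits_concentrate_on_planted_pair(self, toy):
        df = rp.screen_matrix(
            [toy.query_helix], {"h_query": 0.1}, toy.ribozyme_parts,
            n_shuffles=200, seed=1,
        )
        sig = df[df["significant"]]
        assert list(sig["part"]) == ["rz_planted"]

    def test_missing_nd_rejected(self, toy):
        with pytest.raises(InputError):
            rp.screen_matrix([toy.query_helix], {}, toy.ribozyme_parts, seed=0)
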