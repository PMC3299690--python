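import itertools

import dendropy
import numpy as np
import pytest

import ribophylo as rp
from ribophylo.coding import CharacterMatrix, RRNA_ALPHABET


@pytest.fixture(scope="session")
def toy():
    return rp.toy_fixtures()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def rooted_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-rooted")


def unrooted_tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick", rooting="force-unrooted")


def matrix_from_columns(columns, taxa=None, alphabet=RRNA_ALPHABET, **kwargs):
    """Build a CharacterMatrix from per-character state strings."""
    n = len(columns[0])
    taxa = taxa or tuple(f"t{i}" for i in range(n))
    states = tuple("".join(col[i] for col in columns) for i in range(n))
    chars = tuple(f"c{j}" for j in range(len(columns)))
    return CharacterMatrix(
        rows=tuple(taxa), characters=chars, states=states, alphabet=alphabet, **kwargs
    )


def random_matrix(rng, n_taxa, n_chars, max_state=5):
    symbols = RRNA_ALPHABET.symbols
    states = tuple(
        "".join(symbols[rng.integers(max_state + 1)] for _ in range(n_chars))
        for _ in range(n_taxa)
    )
    return CharacterMatrix(
        rows=tuple(f"t{i}" for i in range(n_taxa)),
        characters=tuple(f"c{j}" for j in range(n_chars)),
        states=states,
    )


def brute_force_length(tree: dendropy.Tree, matrix) -> int:
    """Parsimony length by enumerating every internal-state assignment."""
    idx = matrix.indices()
    lut = {t: i for i, t in enumerate(matrix.rows)}
    nodes = list(tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    edges = []
    for n in nodes:
        for ch in n.child_nodes():
            edges.append((n, ch))
    total = 0
    for j in range(matrix.n_characters):
        leaf_state = {
            n: int(idx[lut[n.taxon.label], j]) for n in nodes if n.is_leaf()
        }
        top = int(idx[:, j].max())
        best = None
        for combo in itertools.product(range(top + 1), repeat=len(internal)):
            assign = dict(zip(internal, combo))
            assign.update(leaf_state)
            cost = sum(abs(assign[a] - assign[b]) for a, b in edges)
            best = cost if best is None else min(best, cost)
        total += best
    return total
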