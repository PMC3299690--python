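"""Ordered-multistate (Wagner) maximum parsimony.

Tree length is computed by Sankoff dynamic programming with the linear
cost ``|i - j|`` between state indices.  For that cost the per-node update
``W(x) = min_y V(y) + |x - y|`` is a min-convolution computable in one
forward and one backward sweep over states, which keeps full TBR
neighborhoods affordable: bisecting an edge and precomputing edge-rooted
cost vectors on both fragments makes every reconnection an O(states)
vector combination.

Trees are exchanged with callers as :class:`dendropy.Tree` objects;
search internals run on a light adjacency representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import dendropy
import numpy as np
import scipy.stats

from .coding import CharacterMatrix
from .errors import InputError, MissingTaxonError

PhyloTree = dendropy.Tree

_INF = np.inf


# ---------------------------------------------------------------------------
# internal unrooted tree representation
# ---------------------------------------------------------------------------

class _Tree:
    """Unrooted tree: adjacency dict plus node -> taxon-index map for leaves."""

    __slots__ = ("adj", "leaf_taxon")

    def __init__(self, adj, leaf_taxon):
        self.adj = adj  # dict[int, list[int]]
        self.leaf_taxon = leaf_taxon  # dict[int, int]

    def copy(self):
        return _Tree({u: list(vs) for u, vs in self.adj.items()}, dict(self.leaf_taxon))

    def edges(self):
        return sorted((u, v) for u, vs in self.adj.items() for v in vs if u < v)

    def next_id(self):
        return max(self.adj) + 1

    def bipartitions(self):
        """Nontrivial bipartitions as frozensets of taxon indices.

        Each bipartition is canonicalized as the side containing the
        smallest taxon index.
        """
        all_taxa = frozenset(self.leaf_taxon.values())
        anchor = min(all_taxa)
        out = set()
        for u, v in self.edges():
            side = frozenset(self._leaves_beyond(u, v))
            if 1 < len(side) < len(all_taxa) - 1:
                if anchor not in side:
                    side = all_taxa - side
                out.add(side)
        return out

    def _leaves_beyond(self, u, v):
        """Taxon indices in the component of v after cutting edge (u, v)."""
        stack, seen, leaves = [v], {u, v}, []
        while stack:
            x = stack.pop()
            if x in self.leaf_taxon:
                leaves.append(self.leaf_taxon[x])
            for w in self.adj[x]:
                if w not in seen:
                    seen.add(w)
                    stack.append(w)
        return leaves


def _star3(t0, t1, t2):
    adj = {0: [3], 1: [3], 2: [3], 3: [0, 1, 2]}
    return _Tree(adj, {0: t0, 1: t1, 2: t2})


def _two_leaf(t0, t1):
    return _Tree({0: [1], 1: [0]}, {0: t0, 1: t1})


def _insert_leaf(tree, edge, taxon):
    """New tree with a leaf for ``taxon`` attached to the midpoint of ``edge``."""
    t = tree.copy()
    u, v = edge
    mid = t.next_id()
    leaf = mid + 1
    t.adj[u] = [mid if w == v else w for w in t.adj[u]]
    t.adj[v] = [mid if w == u else w for w in t.adj[v]]
    t.adj[mid] = [u, v, leaf]
    t.adj[leaf] = [mid]
    t.leaf_taxon[leaf] = taxon
    return t


def _suppress_degree2(t, node):
    if node in t.leaf_taxon or len(t.adj[node]) != 2:
        return
    a, b = t.adj[node]
    t.adj[a] = [b if w == node else w for w in t.adj[a]]
    t.adj[b] = [a if w == node else w for w in t.adj[b]]
    del t.adj[node]


def _bisect(tree, edge):
    """Cut ``edge``; return the two fragments (degree-2 endpoints suppressed)."""
    u, v = edge
    frags = []
    for keep, drop in ((u, v), (v, u)):
        comp = {keep}
        stack = [keep]
        while stack:
            x = stack.pop()
            for w in tree.adj[x]:
                if w != drop and w not in comp and not (x == keep and w == drop):
                    if w not in comp:
                        comp.add(w)
                        stack.append(w)
        adj = {x: [w for w in tree.adj[x] if w in comp] for x in comp}
        frag = _Tree(adj, {x: tree.leaf_taxon[x] for x in comp if x in tree.leaf_taxon})
        _suppress_degree2(frag, keep)
        frags.append(frag)
    return frags


def _join(frag_a, attach_a, frag_b, attach_b):
    """Reconnect two fragments with a fresh edge.

    ``attach_*`` is either a node id (single-leaf fragment) or an edge
    (u, v) whose midpoint receives the new connection.
    """
    t = _Tree(
        {u: list(vs) for u, vs in frag_a.adj.items()},
        dict(frag_a.leaf_taxon),
    )
    offset = max(t.adj) + 1 if t.adj else 0
    remap = {u: u + offset for u in frag_b.adj}
    for u, vs in frag_b.adj.items():
        t.adj[remap[u]] = [remap[w] for w in vs]
    for u, tx in frag_b.leaf_taxon.items():
        t.leaf_taxon[remap[u]] = tx

    def anchor(attach, mapping):
        if isinstance(attach, tuple):
            u, v = attach
            if mapping:
                u, v = mapping[u], mapping[v]
            mid = max(t.adj) + 1
            t.adj[u] = [mid if w == v else w for w in t.adj[u]]
            t.adj[v] = [mid if w == u else w for w in t.adj[v]]
            t.adj[mid] = [u, v]
            return mid
        return mapping[attach] if mapping else attach

    na = anchor(attach_a, None)
    nb = anchor(attach_b, remap)
    t.adj[na].append(nb)
    t.adj[nb].append(na)
    return t


# ---------------------------------------------------------------------------
# Sankoff machinery
# ---------------------------------------------------------------------------

def _minconv(V):
    """W(x) = min_y V(y) + |x - y| along axis 0 (states)."""
    W = V.copy()
    for s in range(1, W.shape[0]):
        np.minimum(W[s], W[s - 1] + 1, out=W[s])
    for s in range(W.shape[0] - 2, -1, -1):
        np.minimum(W[s], W[s + 1] + 1, out=W[s])
    return W


def _minconv_unordered(V):
    """Fitch-style cost: substitution 1 between any two distinct states."""
    best = V.min(axis=0)
    return np.minimum(V, best + 1.0)


class _Scorer:
    """Leaf state vectors and min-convolution for one character matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        idx = matrix.indices()
        top = int(idx.max()) if idx.size else 0
        if matrix.ancestral_states is not None:
            top = max(top, int(matrix.ancestral_indices().max()))
        self.n_states = top + 1
        self.n_chars = matrix.n_characters
        self.taxon_index = {t: i for i, t in enumerate(matrix.rows)}
        self.idx = idx
        self.conv = _minconv if matrix.ordered else _minconv_unordered
        self._leafvecs = {}

    def leafvec(self, taxon_i):
        if taxon_i not in self._leafvecs:
            V = np.full((self.n_states, self.n_chars), _INF)
            V[self.idx[taxon_i], np.arange(self.n_chars)] = 0.0
            self._leafvecs[taxon_i] = V
        return self._leafvecs[taxon_i]

    def statevec(self, state_indices):
        V = np.full((self.n_states, self.n_chars), _INF)
        V[np.asarray(state_indices), np.arange(self.n_chars)] = 0.0
        return V

    def directed_vectors(self, tree):
        """All 2E subtree cost vectors M[(u, v)] plus their min-convolutions.

        ``M[(u, v)]`` is the cost of the component containing ``u`` after
        cutting edge (u, v), as a function of the state at ``u``.
        """
        adj, leaf_taxon = tree.adj, tree.leaf_taxon
        M, C = {}, {}

        def conv(u, v):
            if (u, v) not in C:
                C[(u, v)] = self.conv(M[(u, v)])
            return C[(u, v)]

        root = next(iter(adj))
        order = []
        stack = [(root, None)]
        while stack:
            node, parent = stack.pop()
            order.append((node, parent))
            for w in adj[node]:
                if w != parent:
                    stack.append((w, node))
        # upward pass: M[(v, parent)]
        for node, parent in reversed(order):
            if parent is None:
                continue
            if node in leaf_taxon:
                M[(node, parent)] = self.leafvec(leaf_taxon[node])
            else:
                M[(node, parent)] = sum(conv(w, node) for w in adj[node] if w != parent)
        # downward pass: M[(parent, v)]
        for node, parent in order:
            for v in adj[node]:
                if v == parent:
                    continue
                if node in leaf_taxon:
                    M[(node, v)] = self.leafvec(leaf_taxon[node])
                else:
                    M[(node, v)] = sum(conv(w, node) for w in adj[node] if w != v)
        return M, conv

    def length(self, tree):
        if len(tree.leaf_taxon) == 1:
            return 0
        if len(tree.leaf_taxon) == 2:
            (a, b) = tree.leaf_taxon.values()
            return int(np.abs(self.idx[a] - self.idx[b]).sum())
        M, conv = self.directed_vectors(tree)
        u, v = tree.edges()[0]
        total = (M[(u, v)] + conv(v, u)).min(axis=0).sum()
        return int(total)

    def edge_vectors(self, tree):
        """V[e](x): tree cost with a degree-2 node of state x inserted in e."""
        M, conv = self.directed_vectors(tree)
        return {(u, v): conv(u, v) + conv(v, u) for u, v in tree.edges()}

    def attach_vectors(self, frag):
        """Attachment-point cost vectors for every reconnection point."""
        if len(frag.adj) == 1:
            node = next(iter(frag.adj))
            return {node: self.leafvec(frag.leaf_taxon[node])}
        return self.edge_vectors(frag)


def _tree_from_matrix_leaves(matrix, tree: dendropy.Tree):
    """Convert a dendropy tree to the internal representation."""
    t_adj = {}
    leaf_taxon = {}
    ids = {}
    scorer_index = {t: i for i, t in enumerate(matrix.rows)}
    for k, node in enumerate(tree.preorder_node_iter()):
        ids[node] = k
        t_adj[k] = []
    for node in tree.preorder_node_iter():
        k = ids[node]
        for ch in node.child_nodes():
            t_adj[k].append(ids[ch])
            t_adj[ids[ch]].append(k)
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in scorer_index:
                raise MissingTaxonError(f"leaf {label!r} has no matrix row")
            leaf_taxon[k] = scorer_index[label]
    t = _Tree(t_adj, leaf_taxon)
    # splice out a degree-2 root so lengths are root-invariant by construction
    root = ids[tree.seed_node]
    _suppress_degree2(t, root)
    return t


def _to_dendropy(tree, matrix, taxon_namespace=None, rooted_at=None):
    """Render the internal tree as a dendropy Tree (via newick)."""
    labels = {n: matrix.rows[i] for n, i in tree.leaf_taxon.items()}

    def sub(node, parent):
        if node in tree.leaf_taxon:
            return _nexus_safe(labels[node])
        parts = [sub(w, node) for w in tree.adj[node] if w != parent]
        return "(" + ",".join(parts) + ")"

    if rooted_at is not None:
        newick = sub(rooted_at, None) + ";"
        rooting = "force-rooted"
    else:
        internal = [n for n in sorted(tree.adj) if n not in tree.leaf_taxon]
        if internal:
            newick = sub(internal[0], None) + ";"
        else:  # two-leaf tree
            newick = "(" + ",".join(_nexus_safe(labels[n]) for n in sorted(tree.adj)) + ");"
        rooting = "force-unrooted"
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting=rooting,
        taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
        suppress_internal_node_taxa=True,
    )


def _nexus_safe(label):
    # underscores must be quoted too: unquoted they read back as spaces
    if any(c in label for c in " _()[]{},;:'\""):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def tree_length(tree: dendropy.Tree, matrix: CharacterMatrix) -> int:
    """Minimum total ordered-cost steps of ``matrix`` on ``tree`` (Sankoff)."""
    scorer = _Scorer(matrix)
    return scorer.length(_tree_from_matrix_leaves(matrix, tree))


def per_character_bounds(matrix: CharacterMatrix):
    """(min_steps, max_steps) per character.

    min = state range of the character (any tree must bridge it);
    max = star-tree cost, the best single-ancestor cost (attained at the
    median state).  Both arrays have one entry per character.
    """
    idx = matrix.indices()
    if idx.shape[0] < 1:
        raise InputError("matrix has no rows")
    min_steps = idx.max(axis=0) - idx.min(axis=0)
    med = np.sort(idx, axis=0)[(idx.shape[0] - 1) // 2]
    max_steps = np.abs(idx - med).sum(axis=0)
    return min_steps, max_steps


@dataclass(frozen=True)
class FitStats:
    """Parsimony fit statistics of one tree on one matrix."""

    length: int
    ci: float
    ri: float | None
    hi: float
    g1: float | None


def random_topology(taxa, rng):
    """Uniformly random unrooted binary topology on ``taxa`` (indices)."""
    taxa = list(taxa)
    if len(taxa) == 2:
        return _two_leaf(*taxa)
    t = _star3(*taxa[:3])
    for tx in taxa[3:]:
        edges = t.edges()
        t = _insert_leaf(t, edges[rng.integers(len(edges))], tx)
    return t


def fit_stats(
    tree: dendropy.Tree,
    matrix: CharacterMatrix,
    n_random_trees: int = 1000,
    seed: int | None = None,
) -> FitStats:
    """CI, RI, HI and the g1 skewness of the random-tree length distribution.

    CI = sum(min)/L, RI = (sum(max) - L)/(sum(max) - sum(min)), HI = 1 - CI.
    g1 is the small-sample-corrected skewness of the lengths of
    ``n_random_trees`` uniformly random topologies on the same matrix.
    """
    scorer = _Scorer(matrix)
    L = scorer.length(_tree_from_matrix_leaves(matrix, tree))
    mn, mx = per_character_bounds(matrix)
    smin, smax = int(mn.sum()), int(mx.sum())
    ci = 1.0 if L == 0 else smin / L
    ri = None if smax == smin else (smax - L) / (smax - smin)
    hi = 1.0 - ci
    g1 = None
    if n_random_trees and n_random_trees >= 3:
        rng = np.random.default_rng(seed)
        taxa = list(range(matrix.n_rows))
        lengths = [
            scorer.length(random_topology(taxa, rng)) for _ in range(n_random_trees)
        ]
        g1 = float(scipy.stats.skew(np.asarray(lengths, dtype=float), bias=False))
    return FitStats(length=L, ci=ci, ri=ri, hi=hi, g1=g1)


def _attach_cost(scorer, V_edge, conv_other):
    """Total length after joining two attachment vectors with a new edge."""
    return float((V_edge + conv_other).min(axis=0).sum())


def _stepwise_addition(scorer, order):
    """Build a start tree by inserting taxa at their cheapest branch."""
    if len(order) == 2:
        return _two_leaf(order[0], order[1])
    t = _star3(order[0], order[1], order[2])
    for tx in order[3:]:
        vecs = scorer.edge_vectors(t)
        lf = scorer.conv(scorer.leafvec(tx))
        best_edge, best_cost = None, None
        for e in t.edges():
            cost = _attach_cost(scorer, vecs[e], lf)
            if best_cost is None or cost < best_cost:
                best_edge, best_cost = e, cost
        t = _insert_leaf(t, best_edge, tx)
    return t


def _tbr_improve(scorer, tree, length):
    """First-improvement TBR sweep; returns (tree, length, improved?)."""
    for edge in tree.edges():
        frag_a, frag_b = _bisect(tree, edge)
        if not frag_a.leaf_taxon or not frag_b.leaf_taxon:
            continue
        va = scorer.attach_vectors(frag_a)
        vb = scorer.attach_vectors(frag_b)
        vb_conv = {k: scorer.conv(v) for k, v in vb.items()}
        for ka in sorted(va):
            for kb in sorted(vb_conv):
                cost = _attach_cost(scorer, va[ka], vb_conv[kb])
                if cost < length - 1e-9:
                    return _join(frag_a, ka, frag_b, kb), int(round(cost)), True
    return tree, length, False


def _equal_best_neighbors(scorer, tree, length, maxtrees):
    """All TBR reconnections of ``tree`` at exactly the current best length."""
    found = {frozenset(tree.bipartitions()): tree}
    for edge in tree.edges():
        frag_a, frag_b = _bisect(tree, edge)
        if not frag_a.leaf_taxon or not frag_b.leaf_taxon:
            continue
        va = scorer.attach_vectors(frag_a)
        vb = scorer.attach_vectors(frag_b)
        vb_conv = {k: scorer.conv(v) for k, v in vb.items()}
        for ka in sorted(va):
            for kb in sorted(vb_conv):
                cost = _attach_cost(scorer, va[ka], vb_conv[kb])
                if abs(cost - length) < 1e-9:
                    cand = _join(frag_a, ka, frag_b, kb)
                    sig = frozenset(cand.bipartitions())
                    if sig not in found:
                        found[sig] = cand
                        if len(found) >= maxtrees:
                            return list(found.values())
    return list(found.values())


def heuristic_search(
    matrix: CharacterMatrix,
    addition: str = "input_order",
    n_restarts: int = 1,
    seed: int | None = None,
    maxtrees: int = 1000,
    collect_ties: bool = True,
):
    """Stepwise addition followed by TBR branch swapping.

    ``addition='input_order'`` inserts taxa in matrix row order (the
    simple addition sequence); ``'random'`` uses ``n_restarts`` random
    permutations.  Returns all distinct equally most-parsimonious
    topologies found (capped at ``maxtrees``) as unrooted dendropy trees
    sharing one taxon namespace.
    """
    scorer = _Scorer(matrix)
    n = matrix.n_rows
    taxa = list(range(n))
    ns = dendropy.TaxonNamespace([_t for _t in matrix.rows])
    if n < 4:
        warnings.warn(f"only {n} taxa: returning the trivial topology")
        if n < 2:
            raise InputError("need at least 2 taxa")
        t = _two_leaf(*taxa) if n == 2 else _star3(*taxa)
        return [_to_dendropy(t, matrix, taxon_namespace=ns)]

    rng = np.random.default_rng(seed)
    if addition == "input_order":
        orders = [taxa]
    elif addition == "random":
        orders = [list(rng.permutation(n)) for _ in range(max(1, n_restarts))]
    else:
        raise InputError(f"unknown addition sequence {addition!r}")

    best_len = None
    best_trees = []
    for order in orders:
        t = _stepwise_addition(scorer, order)
        length = scorer.length(t)
        improved = True
        while improved:
            t, length, improved = _tbr_improve(scorer, t, length)
        if best_len is None or length < best_len:
            best_len, best_trees = length, [t]
        elif length == best_len:
            best_trees.append(t)

    if collect_ties:
        pool = {}
        for t in best_trees:
            for cand in _equal_best_neighbors(scorer, t, best_len, maxtrees):
                sig = frozenset(cand.bipartitions())
                pool.setdefault(sig, cand)
                if len(pool) >= maxtrees:
                    break
        best_trees = list(pool.values())
        if len(best_trees) >= maxtrees:
            warnings.warn(f"equally parsimonious tree cap reached ({maxtrees})")
    return [_to_dendropy(t, matrix, taxon_namespace=ns) for t in best_trees]


def exhaustive_search(matrix: CharacterMatrix):
    """Enumerate every unrooted topology; return (best trees, best length).

    Only feasible for small taxon counts (the (2n-5)!! explosion); used as
    the oracle for the heuristic search.
    """
    scorer = _Scorer(matrix)
    n = matrix.n_rows
    if n < 4:
        raise InputError("exhaustive search needs >= 4 taxa")
    if n > 9:
        raise InputError("exhaustive search limited to 9 taxa")
    best_len, best = None, []

    def recurse(t, remaining):
        nonlocal best_len, best
        if not remaining:
            length = scorer.length(t)
            if best_len is None or length < best_len:
                best_len, best = length, [t]
            elif length == best_len:
                best.append(t)
            return
        tx, rest = remaining[0], remaining[1:]
        for e in t.edges():
            recurse(_insert_leaf(t, e, tx), rest)

    recurse(_star3(0, 1, 2), list(range(3, n)))
    ns = dendropy.TaxonNamespace(list(matrix.rows))
    return [_to_dendropy(t, matrix, taxon_namespace=ns) for t in best], best_len


# ---------------------------------------------------------------------------
# consensus, bootstrap, distances
# ---------------------------------------------------------------------------

def _tree_bipartitions(tree: dendropy.Tree):
    """Nontrivial bipartitions of a dendropy tree, canonicalized."""
    leaves = frozenset(lf.taxon.label for lf in tree.leaf_node_iter())
    anchor = min(leaves)
    out = set()
    for node in tree.preorder_internal_node_iter():
        if node is tree.seed_node:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if 1 < len(side) < len(leaves) - 1:
            if anchor not in side:
                side = leaves - side
            out.add(side)
    # a rooted tree's seed node with 2 children can hide one bipartition in
    # the root edge; covered because both child clades are enumerated
    return out, leaves


def rf_distance(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Robinson-Foulds symmetric difference on nontrivial bipartitions."""
    b1, l1 = _tree_bipartitions(t1)
    b2, l2 = _tree_bipartitions(t2)
    if l1 != l2:
        raise InputError("trees have different leaf sets")
    return len(b1 ^ b2)


def _clades_to_tree(leaves, clades, supports=None, taxon_namespace=None):
    """Build a (possibly multifurcating) tree from a laminar clade family."""
    leaves = sorted(leaves)
    items = sorted(clades, key=len)

    def newick_for(cl, available):
        inner = []
        used = set()
        for sub in items:
            if sub < cl and sub <= available and not sub & used:
                # only maximal proper sub-clades become children
                if not any(sub < other < cl and other <= available for other in items):
                    inner.append(newick_for(sub, sub))
                    used |= sub
        for lf in sorted(cl & available - used):
            inner.append(_nexus_safe(lf))
        label = ""
        if supports is not None and cl in supports:
            label = f"{supports[cl]:g}"
        return "(" + ",".join(inner) + ")" + label

    root = frozenset(leaves)
    newick = newick_for(root, root) + ";"
    return dendropy.Tree.get(
        data=newick,
        schema="newick",
        rooting="force-unrooted",
        taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
        suppress_internal_node_taxa=True,
    )


def strict_consensus(trees) -> dendropy.Tree:
    """Tree retaining exactly the bipartitions present in every input tree."""
    if not trees:
        raise InputError("no trees to combine")
    sets = []
    leafset = None
    for t in trees:
        b, l = _tree_bipartitions(t)
        if leafset is None:
            leafset = l
        elif l != leafset:
            raise InputError("trees have different leaf sets")
        sets.append(b)
    common = set.intersection(*map(set, sets)) if sets else set()
    ns = trees[0].taxon_namespace
    return _clades_to_tree(leafset, common, taxon_namespace=ns)


def majority_consensus(trees, min_freq=0.5, taxon_namespace=None) -> dendropy.Tree:
    """Majority-rule consensus with bipartition frequencies as % supports."""
    if not trees:
        raise InputError("no trees to combine")
    counts = {}
    leafset = None
    for t in trees:
        b, l = _tree_bipartitions(t)
        if leafset is None:
            leafset = l
        elif l != leafset:
            raise InputError("trees have different leaf sets")
        for bp in b:
            counts[bp] = counts.get(bp, 0) + 1
    n = len(trees)
    keep = {bp: 100.0 * c / n for bp, c in counts.items() if c / n > min_freq}
    ns = taxon_namespace or trees[0].taxon_namespace
    return _clades_to_tree(leafset, set(keep), supports=keep, taxon_namespace=ns)


def bootstrap_support(
    matrix: CharacterMatrix,
    reps: int = 100,
    seed: int | None = None,
    **search_kwargs,
) -> dendropy.Tree:
    """Nonparametric bootstrap: characters resampled with replacement.

    Each pseudoreplicate is searched with :func:`heuristic_search` (one
    tree kept per replicate); the result is the majority-rule consensus
    with supports in [0, 100] stored as internal node labels.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    rep_trees = []
    ns = None
    for _ in range(reps):
        cols = rng.integers(matrix.n_characters, size=matrix.n_characters)
        states = tuple("".join(row[j] for j in cols) for row in matrix.states)
        anc = None
        if matrix.ancestral_states is not None:
            anc = "".join(matrix.ancestral_states[j] for j in cols)
        rep = CharacterMatrix(
            rows=matrix.rows,
            characters=tuple(f"bs{k}" for k in range(matrix.n_characters)),
            states=states,
            alphabet=matrix.alphabet,
            ordered=matrix.ordered,
            ancestral_states=anc,
        )
        sub_seed = int(rng.integers(2**31 - 1))
        trees = heuristic_search(
            rep, seed=sub_seed, collect_ties=False, **search_kwargs
        )
        if ns is None:
            ns = trees[0].taxon_namespace
            rep_trees.append(trees[0])
        else:
            t = dendropy.Tree.get(
                data=trees[0].as_string(schema="newick"),
                schema="newick",
                rooting="force-unrooted",
                taxon_namespace=ns,
            )
            rep_trees.append(t)
    return majority_consensus(rep_trees, taxon_namespace=ns)


# ---------------------------------------------------------------------------
# rooting and ancestral states
# ---------------------------------------------------------------------------

def root_with_ancestor(tree: dendropy.Tree, matrix: CharacterMatrix) -> dendropy.Tree:
    """Lundberg rooting against the matrix's declared ancestral states.

    A hypothetical all-ancestral taxon is attached to the branch that
    minimizes total tree length; the root is placed at that attachment
    point and the hypothetical leaf discarded.  Ties break to the first
    branch in canonical order; the returned tree carries
    ``root_attachment_ties`` (count of tying branches).
    """
    if matrix.ancestral_states is None:
        raise InputError("matrix has no ancestral states; polarize first")
    scorer = _Scorer(matrix)
    t = _tree_from_matrix_leaves(matrix, tree)
    if len(t.leaf_taxon) < 2:
        raise InputError("need >= 2 leaves to root")
    if len(t.leaf_taxon) == 2:
        a, b = sorted(t.leaf_taxon)
        edge_order = [(a, b)]
        costs = {(a, b): 0.0}
    else:
        vecs = scorer.edge_vectors(t)
        anc = scorer.conv(scorer.statevec(matrix.ancestral_indices()))
        edge_order = t.edges()
        costs = {e: _attach_cost(scorer, vecs[e], anc) for e in edge_order}
    best = min(costs.values())
    ties = [e for e in edge_order if abs(costs[e] - best) < 1e-9]
    u, v = ties[0]
    if len(ties) > 1:
        warnings.warn(f"{len(ties)} branches tie for the root attachment")
    # place the root at the midpoint of the chosen branch
    root = t.next_id()
    t.adj[u] = [root if w == v else w for w in t.adj[u]]
    t.adj[v] = [root if w == u else w for w in t.adj[v]]
    t.adj[root] = [u, v]
    out = _to_dendropy(t, matrix, taxon_namespace=tree.taxon_namespace, rooted_at=root)
    out.root_attachment_ties = len(ties)
    return out


def ancestral_states(tree: dendropy.Tree, matrix: CharacterMatrix):
    """One minimum-cost Sankoff state assignment for every node.

    The tree must be rooted.  Returns a dict mapping each dendropy node to
    its reconstructed symbol string; the total implied cost equals
    :func:`tree_length`.  Ties break towards the smaller state index.
    """
    if not tree.is_rooted and len(tree.seed_node.child_nodes()) > 2:
        warnings.warn("tree does not look rooted; reconstructing from the seed node")
    scorer = _Scorer(matrix)
    lut = {t: i for i, t in enumerate(matrix.rows)}
    nodes = list(tree.preorder_node_iter())
    up = {}
    for node in reversed(nodes):
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            if label not in lut:
                raise MissingTaxonError(f"leaf {label!r} has no matrix row")
            up[node] = scorer.leafvec(lut[label])
        else:
            up[node] = sum(scorer.conv(up[ch]) for ch in node.child_nodes())
    result = {}
    S = scorer.n_states
    states_col = np.arange(S)[:, None]
    root = tree.seed_node
    assign = {root: np.argmin(up[root], axis=0)}
    for node in nodes:
        parent_states = assign[node]
        result[node] = "".join(matrix.alphabet.symbols[s] for s in parent_states)
        for ch in node.child_nodes():
            cost = up[ch] + np.abs(states_col - parent_states[None, :]) if matrix.ordered else (
                up[ch] + (states_col != parent_states[None, :]).astype(float)
            )
            assign[ch] = np.argmin(cost, axis=0)
    return result
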