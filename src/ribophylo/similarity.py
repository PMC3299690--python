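"""Structure-only similarity screens between rRNA helices and ribozymes.

A secondary structure maps to an ordered forest: one P node per base pair
(children = everything enclosed), one B node per unpaired base.  Pairs of
forests are compared with a local tree alignment under a structure-only
scoring (pair-pair match rewarded, base-base match slightly, indels
penalized, pair-base substitution disallowed); the local score is the
best global alignment over all pairs of closed subforests, floored at 0.

Significance is assessed against a dinucleotide-preserving shuffle null:
the target sequence is shuffled (exact dinucleotide counts preserved via
the Eulerian-multigraph algorithm), each shuffle is refolded by base-pair
maximization, realigned to the query, and the observed score is expressed
as a Z-score; Z >= 3.0 is called significant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .structures import SecondaryStructure

# scoring defaults: structure only, in the spirit of forest-alignment tools
PAIR_MATCH = 10.0
BASE_MATCH = 1.0
GAP = -5.0
Z_THRESHOLD = 3.0

_PAIRABLE = {
    ("A", "U"), ("U", "A"),
    ("G", "C"), ("C", "G"),
    ("G", "U"), ("U", "G"),
}


@dataclass(frozen=True)
class ForestNode:
    kind: str  # 'P' (pair) or 'B' (unpaired base)
    residues: tuple  # (base,) for B, (base5, base3) for P
    children: tuple  # ForestNodes, document order

    @property
    def size(self) -> int:
        return 1 + sum(c.size for c in self.children)


@dataclass(frozen=True)
class StructureForest:
    """Ordered forest representation of a nested secondary structure."""

    roots: tuple
    name: str = ""

    @property
    def size(self) -> int:
        return sum(r.size for r in self.roots)

    def sequence(self) -> str:
        """In-order leaf traversal reconstructs the sequence."""
        out = []

        def walk(node):
            if node.kind == "B":
                out.append(node.residues[0])
            else:
                out.append(node.residues[0])
                for c in node.children:
                    walk(c)
                out.append(node.residues[1])

        for r in self.roots:
            walk(r)
        return "".join(out)


def structure_to_forest(s: SecondaryStructure) -> StructureForest:
    """One P node per pair, one B node per unpaired base, document order."""
    seq = s.sequence.replace("-", "")
    if len(seq) != len(s.sequence):
        # drop gap columns; renumber pairs accordingly
        keep = [i for i, c in enumerate(s.sequence, start=1) if c != "-"]
        remap = {old: new for new, old in enumerate(keep, start=1)}
        pairs = frozenset((remap[i], remap[j]) for i, j in s.pairs)
    else:
        pairs = s.pairs
    partner = {}
    for i, j in pairs:
        partner[i] = j
        partner[j] = i

    def build(lo, hi):
        nodes = []
        pos = lo
        while pos <= hi:
            if pos in partner:
                j = partner[pos]
                nodes.append(
                    ForestNode(
                        kind="P",
                        residues=(seq[pos - 1], seq[j - 1]),
                        children=tuple(build(pos + 1, j - 1)),
                    )
                )
                pos = j + 1
            else:
                nodes.append(ForestNode(kind="B", residues=(seq[pos - 1],), children=()))
                pos += 1
        return nodes

    return StructureForest(roots=tuple(build(1, len(seq))), name=s.name)


# ---------------------------------------------------------------------------
# forest alignment
# ---------------------------------------------------------------------------

def _del_cost(forest) -> float:
    return GAP * sum(n.size for n in forest)


class _Aligner:
    """Memoized global alignment of ordered forests (similarity, max)."""

    def __init__(self):
        self.memo = {}

    def align(self, f1: tuple, f2: tuple) -> float:
        key = (f1, f2)
        if key in self.memo:
            return self.memo[key]
        if not f1 and not f2:
            score = 0.0
        elif not f1:
            score = _del_cost(f2)
        elif not f2:
            score = _del_cost(f1)
        else:
            t, r1 = f1[0], f1[1:]
            u, r2 = f2[0], f2[1:]
            options = [
                GAP + self.align(t.children + r1, f2),  # delete root of t
                GAP + self.align(f1, u.children + r2),  # delete root of u
            ]
            if t.kind == u.kind:  # P-B substitution disallowed
                match = PAIR_MATCH if t.kind == "P" else BASE_MATCH
                options.append(
                    match + self.align(t.children, u.children) + self.align(r1, r2)
                )
            score = max(options)
        self.memo[key] = score
        return score


def _closed_subforests(forest: StructureForest):
    """All contiguous sibling ranges (closed subforests), non-empty."""
    out = []

    def ranges(siblings):
        n = len(siblings)
        for i in range(n):
            for j in range(i + 1, n + 1):
                out.append(tuple(siblings[i:j]))
        for node in siblings:
            if node.children:
                ranges(node.children)

    ranges(list(forest.roots))
    return out


def align_local(f1: StructureForest, f2: StructureForest):
    """Best local forest-alignment score and the maximizing subforest pair.

    The score is the maximum global alignment score over all pairs of
    closed subforests of the two inputs, floored at 0 (empty alignment).
    Returns (score, (subforest1, subforest2) or None).
    """
    if not f1.roots or not f2.roots:
        return 0.0, None
    aligner = _Aligner()
    best, best_pair = 0.0, None
    for r1 in _closed_subforests(f1):
        for r2 in _closed_subforests(f2):
            s = aligner.align(r1, r2)
            if s > best:
                best, best_pair = s, (r1, r2)
    return best, best_pair


def self_score(f: StructureForest) -> float:
    """Score of aligning a forest to itself (all nodes matched)."""
    n_pairs = sum(1 for _ in _iter_nodes(f) if _.kind == "P")
    n_bases = f.size - n_pairs
    return PAIR_MATCH * n_pairs + BASE_MATCH * n_bases


def _iter_nodes(f: StructureForest):
    stack = list(f.roots)
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)


# ---------------------------------------------------------------------------
# dinucleotide-preserving shuffle (Eulerian multigraph)
# ---------------------------------------------------------------------------

def dinucleotide_shuffle(seq: str, rng) -> str:
    """Shuffle preserving the exact dinucleotide count vector.

    The sequence is an Eulerian walk on the multigraph whose edges are
    its consecutive base pairs; a random last-exit-edge arborescence
    towards the final base is drawn, remaining edge lists are permuted,
    and the walk is rebuilt — so first and last residues and all 16
    dinucleotide counts are preserved exactly.
    """
    seq = seq.upper().replace("T", "U")
    if len(seq) < 3:
        raise InputError("shuffle needs length >= 3")
    bad = set(seq) - set("ACGUN")
    if bad:
        raise InputError(f"sequence characters outside A/C/G/U/N: {sorted(bad)}")
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)

    edges = {}
    for a, b in zip(seq, seq[1:]):
        edges.setdefault(a, []).append(b)
    last = seq[-1]
    vertices = list(edges)

    def connected_to_last(last_edges):
        for v in vertices:
            if v == last:
                continue
            x, seen = v, set()
            while x != last:
                if x in seen or x not in last_edges:
                    return False
                seen.add(x)
                x = last_edges[x]
        return True

    while True:
        last_edges = {}
        for v in vertices:
            if v == last:
                continue
            outs = edges[v]
            last_edges[v] = outs[rng.integers(len(outs))]
        if connected_to_last(last_edges):
            break

    pools = {}
    for v in vertices:
        outs = list(edges[v])
        if v in last_edges:
            outs.remove(last_edges[v])
        order = list(rng.permutation(len(outs)))
        pools[v] = [outs[i] for i in order]
        if v in last_edges:
            pools[v].append(last_edges[v])

    out = [seq[0]]
    pos = {v: 0 for v in pools}
    cur = seq[0]
    for _ in range(len(seq) - 1):
        nxt = pools[cur][pos[cur]]
        pos[cur] += 1
        out.append(nxt)
        cur = nxt
    shuffled = "".join(out)
    assert dinucleotide_counts(shuffled) == dinucleotide_counts(seq)
    return shuffled


def dinucleotide_counts(seq: str) -> dict:
    out = {}
    for a, b in zip(seq, seq[1:]):
        out[(a, b)] = out.get((a, b), 0) + 1
    return out


# ---------------------------------------------------------------------------
# base-pair maximization folding (shuffle-null baseline)
# ---------------------------------------------------------------------------

def fold_baseline(seq: str, min_loop: int = 3) -> SecondaryStructure:
    """Maximum-pairing nested fold (WC + GU wobble), deterministic.

    Dynamic programming over substrings; the traceback prefers pairing
    the 5' base, and pairs it with the leftmost partner that achieves the
    optimum, so the structure is a deterministic function of the sequence.
    An external thermodynamic folder can replace this baseline through
    the ``folder`` hook of :func:`zscore_screen`.
    """
    seq = seq.upper().replace("T", "U")
    n = len(seq)
    if n == 0:
        raise InputError("cannot fold an empty sequence")

    def can_pair(i, j):
        return (seq[i - 1], seq[j - 1]) in _PAIRABLE

    N = np.zeros((n + 2, n + 2), dtype=np.int32)
    for span in range(min_loop + 1, n):
        for i in range(1, n - span + 1):
            j = i + span
            best = N[i + 1, j]
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    v = N[i + 1, k - 1] + (N[k + 1, j] if k < j else 0) + 1
                    if v > best:
                        best = v
            N[i, j] = best

    pairs = []

    def traceback(i, j):
        while i < j:
            paired = False
            for k in range(i + min_loop + 1, j + 1):
                if can_pair(i, k):
                    v = N[i + 1, k - 1] + (N[k + 1, j] if k < j else 0) + 1
                    if v == N[i, j]:
                        pairs.append((i, k))
                        traceback(i + 1, k - 1)
                        i = k + 1
                        paired = True
                        break
            if not paired:
                i += 1

    traceback(1, n)
    return SecondaryStructure(name="fold", sequence=seq, pairs=frozenset(pairs))


# ---------------------------------------------------------------------------
# Z-score screen
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimilarityResult:
    query: str
    target: str
    score: float
    null_mean: float
    null_sd: float
    n_shuffles: int
    z: float | None
    significant: bool


def zscore_screen(
    query: SecondaryStructure,
    target: SecondaryStructure,
    n_shuffles: int = 1000,
    threshold: float = Z_THRESHOLD,
    seed: int | None = None,
    min_loop: int = 3,
    folder=None,
) -> SimilarityResult:
    """Local-alignment score of query vs target against a shuffle null.

    The null realigns the query to ``n_shuffles`` dinucleotide-preserving
    shuffles of the target sequence, each refolded with
    :func:`fold_baseline` (or a caller-supplied ``folder(seq)``).
    Z = (score - null mean)/null sd; significant iff Z >= threshold.
    A zero-variance null leaves Z undefined and not significant.
    """
    fold = folder or (lambda s: fold_baseline(s, min_loop=min_loop))
    fq = structure_to_forest(query)
    ft = structure_to_forest(target)
    observed, _ = align_local(fq, ft)
    rng = np.random.default_rng(seed)
    target_seq = target.sequence.replace("-", "")
    null = np.empty(n_shuffles)
    for i in range(n_shuffles):
        shuf = dinucleotide_shuffle(target_seq, rng)
        fs = structure_to_forest(fold(shuf))
        null[i], _ = align_local(fq, fs)
    mean, sd = float(null.mean()), float(null.std(ddof=1))
    if sd == 0.0:
        return SimilarityResult(
            query.name, target.name, observed, mean, sd, n_shuffles, None, False
        )
    z = (observed - mean) / sd
    return SimilarityResult(
        query.name, target.name, observed, mean, sd, n_shuffles,
        float(z), bool(z >= threshold),
    )


def screen_matrix(
    helices,
    helix_nd: dict,
    parts,
    n_shuffles: int = 1000,
    threshold: float = Z_THRESHOLD,
    seed: int | None = None,
    nd_bins: int = 10,
    **kwargs,
) -> pd.DataFrame:
    """Full cross-product Z-score screen of rRNA helices vs ribozyme parts.

    ``helices`` and ``parts`` are SecondaryStructures; ``helix_nd`` maps
    helix names to relative ages.  Returns a row per (helix, part) pair
    with score, Z and the significance call; the per-age-bin fraction of
    significant alignments is in ``df.attrs['bin_summary']``.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for h in helices:
        if h.name not in helix_nd:
            raise InputError(f"helix {h.name!r} has no nd value")
        for p in parts:
            sub_seed = int(rng.integers(2**31 - 1))
            res = zscore_screen(
                h, p, n_shuffles=n_shuffles, threshold=threshold,
                seed=sub_seed, **kwargs,
            )
            rows.append(
                (h.name, helix_nd[h.name], p.name, res.score, res.null_mean,
                 res.null_sd, res.z, res.significant)
            )
    df = pd.DataFrame(
        rows,
        columns=["helix", "nd", "part", "score", "null_mean", "null_sd", "z",
                 "significant"],
    )
    if len(df):
        binned = (df["nd"] * nd_bins).clip(upper=nd_bins - 1e-9).astype(int) / nd_bins
        summary = df.assign(nd_bin=binned).groupby("nd_bin")["significant"].mean()
        df.attrs["bin_summary"] = summary
    return df
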