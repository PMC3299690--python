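"""Relative ages from rooted trees and derived event timelines.

The chronology statistic is the node distance *nd*: for a leaf *a* of a
rooted tree, nd(a) is the number of internal nodes strictly between the
root and *a*, divided by the maximum such count over all leaves.  The most
ancestral leaf therefore has nd = 0 and the most recent nd = 1.  nd is a
relative time proxy on highly unbalanced trees, where cladogenic events
accumulate along lineages; tree imbalance itself is measured with N-bar
(mean root-to-leaf internal node count, root included) and the cherry
count, compared against Yule and uniform-random null ensembles.

The same machinery applied to trees of protein-domain superfamilies gives
nd_P; protein ages combine domain ages (the youngest member domain), and
an OLS interpolation links the nd and nd_P scales during the early,
linearly coupled era of the two timelines.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
import scipy.stats

from .errors import AnnotationError, DomainError, FitError, InputError
from .parsimony import random_topology, _to_dendropy


@dataclass
class Chronology:
    """Leaf id -> relative age nd in [0, 1], with its source tree."""

    nd: dict
    tree: dendropy.Tree | None = None
    degenerate: bool = False

    def __getitem__(self, leaf_id: str) -> float:
        return self.nd[leaf_id]

    def __contains__(self, leaf_id) -> bool:
        return leaf_id in self.nd

    def items(self):
        return self.nd.items()

    def as_series(self) -> pd.Series:
        return pd.Series(self.nd, name="nd").sort_values(kind="stable")


def node_distance(tree: dendropy.Tree) -> Chronology:
    """Relative age of every leaf of a rooted tree.

    Internal nodes are counted strictly between the root and the leaf
    (both excluded) and normalized by the maximum count.  If all leaves
    are equidistant the tree is flagged degenerate and every nd is 0.
    """
    leaves = [lf for lf in tree.leaf_node_iter()]
    if len(leaves) < 2:
        raise InputError("node_distance needs a rooted tree with >= 2 leaves")
    counts = {}
    for lf in leaves:
        n = 0
        node = lf.parent_node
        while node is not None and node.parent_node is not None:
            n += 1
            node = node.parent_node
        counts[lf.taxon.label if lf.taxon else lf.label] = n
    mx = max(counts.values())
    if mx == 0:
        warnings.warn("all leaves attach at the root split: degenerate chronology")
        return Chronology({k: 0.0 for k in counts}, tree=tree, degenerate=True)
    if len(set(counts.values())) == 1:
        warnings.warn("all leaves equidistant from the root: degenerate chronology")
        return Chronology({k: 0.0 for k in counts}, tree=tree, degenerate=True)
    return Chronology({k: v / mx for k, v in counts.items()}, tree=tree)


def imbalance_stats(tree: dendropy.Tree):
    """(N_bar, cherries) of a rooted tree.

    N_bar is the mean over leaves of the internal-node count from root to
    leaf, root included and leaf excluded; a cherry is an internal node
    whose children are all leaves.
    """
    leaves = list(tree.leaf_node_iter())
    if len(leaves) < 2:
        raise InputError("imbalance_stats needs >= 2 leaves")
    depths = []
    for lf in leaves:
        n = 0
        node = lf.parent_node
        while node is not None:
            n += 1
            node = node.parent_node
        depths.append(n)
    cherries = sum(
        1
        for node in tree.preorder_internal_node_iter()
        if node.child_nodes() and all(ch.is_leaf() for ch in node.child_nodes())
    )
    return float(np.mean(depths)), int(cherries)


def yule_tree(n_leaves: int, rng: random.Random) -> dendropy.Tree:
    """Uniform-speciation (Yule) rooted tree: split a random leaf at each step."""
    tree = dendropy.Tree()
    tree.is_rooted = True
    tips = [tree.seed_node]
    while len(tips) < n_leaves:
        k = rng.randrange(len(tips))
        node = tips.pop(k)
        left, right = dendropy.Node(), dendropy.Node()
        node.add_child(left)
        node.add_child(right)
        tips.extend([left, right])
    for i, lf in enumerate(tree.leaf_node_iter()):
        lf.taxon = tree.taxon_namespace.new_taxon(label=f"t{i + 1}")
    return tree


def _uniform_rooted(n_leaves: int, nprng) -> dendropy.Tree:
    """Uniformly random rooted binary topology (uniform over labeled shapes)."""

    class _M:  # minimal stand-in matrix for label lookup in _to_dendropy
        rows = [f"t{i + 1}" for i in range(n_leaves + 1)]

    t = random_topology(list(range(n_leaves + 1)), nprng)
    dt = _to_dendropy(t, _M, taxon_namespace=dendropy.TaxonNamespace(_M.rows))
    # re-root on the extra leaf's edge, then drop it: uniform rooted tree
    extra = [lf for lf in dt.leaf_node_iter() if lf.taxon.label == f"t{n_leaves + 1}"][0]
    dt.reroot_at_edge(extra.edge)
    parent = extra.parent_node
    parent.remove_child(extra)
    dt.prune_leaves_without_taxa()
    # the seed may now have a single child; splice it
    seed = dt.seed_node
    if len(seed.child_nodes()) == 1:
        dt.seed_node = seed.child_nodes()[0]
        dt.seed_node.parent_node = None
    dt.is_rooted = True
    return dt


def null_tree_ensemble(
    n_leaves: int,
    model: str = "yule",
    reps: int = 1000,
    seed: int | None = None,
    observed_tree: dendropy.Tree | None = None,
):
    """Null distribution of (N_bar, cherries) and Monte-Carlo p-values.

    Returns a dict with the sampled statistics and, when an observed tree
    is given, two-sided Monte-Carlo tail probabilities with the +1
    correction p = 2 * min(P(X <= obs), P(X >= obs)).
    """
    if reps < 100:
        raise InputError("null ensembles need reps >= 100")
    if model not in ("yule", "uniform_random"):
        raise InputError(f"unknown null model {model!r}")
    pyrng = random.Random(seed)
    nprng = np.random.default_rng(seed)
    nbars = np.empty(reps)
    cherries = np.empty(reps, dtype=int)
    for i in range(reps):
        if model == "yule":
            t = yule_tree(n_leaves, pyrng)
        else:
            t = _uniform_rooted(n_leaves, nprng)
        nbars[i], cherries[i] = imbalance_stats(t)
    out = {"model": model, "n_leaves": n_leaves, "reps": reps,
           "nbar": nbars, "cherries": cherries}
    if observed_tree is not None:
        obs_nbar, obs_cherries = imbalance_stats(observed_tree)
        out["observed"] = (obs_nbar, obs_cherries)
        for key, samples, obs in (
            ("p_nbar", nbars, obs_nbar),
            ("p_cherries", cherries, obs_cherries),
        ):
            lo = (np.sum(samples <= obs) + 1) / (reps + 1)
            hi = (np.sum(samples >= obs) + 1) / (reps + 1)
            out[key] = float(min(1.0, 2 * min(lo, hi)))
    return out


@dataclass(frozen=True)
class TimelineEvent:
    entity: str
    event_class: str  # helix | bridge | contact | protein
    nd: float
    annotation: str = ""


@dataclass
class Timeline:
    """Events ordered by nd ascending, ties broken by entity id."""

    events: list = field(default_factory=list)

    def __post_init__(self):
        self.events = sorted(self.events, key=lambda e: (e.nd, e.entity))

    def __len__(self):
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.entity, e.event_class, e.nd, e.annotation) for e in self.events],
            columns=["entity", "class", "nd", "annotation"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def assemble_timeline(
    chron: Chronology,
    bridges: pd.DataFrame | None = None,
    contacts: pd.DataFrame | None = None,
    bridge_rule: str = "acceptor",
) -> Timeline:
    """Date annotation events by the nd of their referenced helices.

    ``bridges`` needs columns (bridge, acceptor, donor): the bridge age is
    the nd of its acceptor element (default rule) or the max of the two
    partner nds (``bridge_rule='max'``).  ``contacts`` needs columns
    (contact, class, helix) and each contact is dated by its helix's nd.
    """
    if bridge_rule not in ("acceptor", "max"):
        raise InputError(f"unknown bridge rule {bridge_rule!r}")
    events = []
    missing = []
    for e in chron.nd:
        events.append(TimelineEvent(entity=e, event_class="helix", nd=chron.nd[e]))
    if bridges is not None:
        for _, row in bridges.iterrows():
            acc, don = str(row["acceptor"]), str(row["donor"])
            for h in (acc, don):
                if h not in chron:
                    missing.append(h)
            if missing:
                continue
            nd = chron[acc] if bridge_rule == "acceptor" else max(chron[acc], chron[don])
            events.append(
                TimelineEvent(
                    entity=str(row["bridge"]),
                    event_class="bridge",
                    nd=nd,
                    annotation=f"acceptor={acc},donor={don}",
                )
            )
    if contacts is not None:
        for _, row in contacts.iterrows():
            h = str(row["helix"])
            if h not in chron:
                missing.append(h)
                continue
            events.append(
                TimelineEvent(
                    entity=str(row["contact"]),
                    event_class="contact",
                    nd=chron[h],
                    annotation=f"class={row['class']},helix={h}",
                )
            )
    if missing:
        raise AnnotationError(f"annotations reference unknown helices: {sorted(set(missing))}")
    return Timeline(events=events)


def protein_age(domains, combination_age: float | None = None):
    """Age (nd_P) of a protein from the ages of its member domains.

    A single-domain protein takes its domain's age; a multi-domain
    protein takes the age of the *youngest* domain (largest nd_P), the
    fusion not predating its newest part.  A known domain-combination age
    that postdates every member domain is flagged but never substituted.
    Returns (nd_P, flagged).
    """
    domains = list(domains)
    if not domains:
        raise InputError("protein has no domains")
    age = max(float(a) for a in domains)
    flagged = combination_age is not None and float(combination_age) > age
    return age, flagged


def interpolate_protein_age(pairs, query: float | None = None, on: str = "nd"):
    """OLS line through early-era (nd, nd_P) pairs, with interpolation.

    ``pairs`` is an iterable of (nd, nd_P).  Returns a dict with slope,
    intercept, r_squared, f_statistic, n, and — when ``query`` is given —
    the interpolated partner value (``on='nd'`` maps nd -> nd_P,
    ``on='nd_P'`` inverts the fitted line).
    """
    pts = np.asarray(list(pairs), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 3:
        raise FitError("interpolation needs >= 3 (nd, nd_P) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.ptp(x) == 0:
        raise FitError("zero variance in nd predictor")
    fit = scipy.stats.linregress(x, y)
    n = len(x)
    r2 = fit.rvalue**2
    f_stat = np.inf if r2 >= 1.0 else (n - 2) * r2 / (1.0 - r2)
    out = {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r_squared": float(r2),
        "f_statistic": float(f_stat),
        "n": n,
    }
    if query is not None:
        if on == "nd":
            out["interpolated"] = float(fit.slope * query + fit.intercept)
        elif on == "nd_P":
            if fit.slope == 0:
                raise FitError("zero slope: cannot invert the fitted line")
            out["interpolated"] = float((query - fit.intercept) / fit.slope)
        else:
            raise InputError(f"unknown interpolation direction {on!r}")
    return out


def rescale_unit(values: dict) -> dict:
    """Min-max rescale a value map onto [0, 1] (for nd_P color scales)."""
    v = np.asarray(list(values.values()), dtype=float)
    lo, hi = v.min(), v.max()
    if hi == lo:
        return {k: 0.0 for k in values}
    return {k: float((x - lo) / (hi - lo)) for k, x in values.items()}


def heatmap_colors(values: dict, colormap: str = "bwr", rescale: bool = False) -> pd.DataFrame:
    """Deterministic RGB color table on a 0-1 scale binned at 0.01.

    Each value is rounded to the nearest 0.01 bin (101 bins) and looked up
    in a matplotlib colormap sampled at 101 points (default a blue-to-red
    scale).  Returns a DataFrame (id, nd, bin, R, G, B) with 0-255 channels.
    """
    import matplotlib

    if rescale:
        values = rescale_unit(values)
    cmap = matplotlib.colormaps[colormap]
    table = (np.asarray([cmap(i / 100.0)[:3] for i in range(101)]) * 255).round().astype(int)
    rows = []
    for key in sorted(values, key=str):
        v = float(values[key])
        if not 0.0 <= v <= 1.0:
            raise DomainError(f"value {v} for {key!r} outside [0, 1]; rescale first")
        b = int(np.floor(v * 100 + 0.5))
        r, g, bl = table[b]
        rows.append((key, v, b / 100.0, int(r), int(g), int(bl)))
    return pd.DataFrame(rows, columns=["id", "nd", "bin", "R", "G", "B"])
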