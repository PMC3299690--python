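"""Gap coding of proteome x domain-superfamily abundance censuses.

Genomic abundance counts g span orders of magnitude; for ordered
multistate parsimony they are compressed to 21 states with the gap-coding
transform

    state = round(20 * ln(g_ab + 1) / ln(g_max_b + 1))

where g_ab is the abundance of domain superfamily a in proteome b and
g_max_b is the largest abundance in that proteome.  States are written
with the symbols 0-9 then A-K; 'K' (a maximal, ubiquitous domain) is
declared the ancestral state, so rooting the tree of domains with an
all-'K' hypothetical ancestor places abundant, widespread superfamilies
near the root.  Leaf node distances on that rooted tree are the relative
domain ages nd_P.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .coding import CENSUS_ALPHABET, CharacterMatrix, transpose_matrix
from .chronology import Chronology, node_distance
from .errors import DomainError, FormatError, InputError
from .parsimony import heuristic_search, root_with_ancestor


@dataclass
class AbundanceTable:
    """Non-negative integer counts, proteomes x domain superfamilies.

    Domain ids are SCOP-style concise classification strings (e.g.
    "c.37.1") treated as opaque labels.
    """

    counts: pd.DataFrame  # index: proteomes, columns: domain ids

    def __post_init__(self):
        df = self.counts
        if df.index.has_duplicates or df.columns.has_duplicates:
            raise InputError("duplicate proteome or domain labels")
        if (df.values < 0).any():
            raise InputError("abundance counts must be non-negative")
        if not np.issubdtype(df.values.dtype, np.integer):
            if not np.allclose(df.values, df.values.astype(int)):
                raise InputError("abundance counts must be integers")
            self.counts = df.astype(int)

    @property
    def proteomes(self):
        return list(self.counts.index)

    @property
    def domains(self):
        return list(self.counts.columns)

    @classmethod
    def read_tsv(cls, path) -> "AbundanceTable":
        """Read the dialect ``proteome<TAB><ccs>...`` with integer cells."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        if df.index.name != "proteome":
            raise FormatError(f"{path}: first header field must be 'proteome'")
        try:
            df = df.astype(int)
        except ValueError as exc:
            raise FormatError(f"{path}: non-integer abundance cell") from exc
        return cls(counts=df)

    def write_tsv(self, path) -> None:
        out = self.counts.copy()
        out.index.name = "proteome"
        out.to_csv(path, sep="\t")


def gap_code(g: int, g_max: int, scheme: str = "log") -> int:
    """Gap-code one abundance into a 0..20 state.

    ``log`` (default) is the natural-log transform above with half-up
    rounding; ``linear`` is round(20 * g / g_max).
    """
    if g < 0:
        raise DomainError(f"negative abundance {g}")
    if g_max < 1:
        raise DomainError(f"g_max must be >= 1, got {g_max}")
    if g > g_max:
        raise DomainError(f"abundance {g} exceeds proteome maximum {g_max}")
    if scheme == "log":
        x = 20.0 * math.log(g + 1) / math.log(g_max + 1)
    elif scheme == "linear":
        x = 20.0 * g / g_max
    else:
        raise InputError(f"unknown gap-coding scheme {scheme!r}")
    return int(math.floor(x + 0.5))


def build_census_matrix(
    table: AbundanceTable,
    orientation: str = "domain_rows",
    scheme: str = "log",
    per_table_gmax: bool = False,
) -> CharacterMatrix:
    """Gap-code a census into a 21-state matrix with 'K' ancestral.

    Abundances are scaled per proteome (each proteome's own maximum maps
    to state 20) unless ``per_table_gmax`` uses the global maximum.
    ``domain_rows`` (default) puts domains as rows — the orientation that
    builds the tree of domain structures; ``proteome_rows`` is the
    transpose.  All-zero proteomes and all-zero domains are dropped with
    a warning.
    """
    if orientation not in ("domain_rows", "proteome_rows"):
        raise InputError(f"unknown orientation {orientation!r}")
    df = table.counts
    dead_p = df.index[(df == 0).all(axis=1)]
    if len(dead_p):
        warnings.warn(f"dropping all-zero proteomes: {list(dead_p)}")
        df = df.drop(index=dead_p)
    if df.empty:
        raise InputError("census table has no informative cells")
    global_max = int(df.values.max())
    rows = []
    for p in df.index:
        gmax = global_max if per_table_gmax else int(df.loc[p].max())
        rows.append(
            "".join(
                CENSUS_ALPHABET.symbol(gap_code(int(g), gmax, scheme=scheme))
                for g in df.loc[p]
            )
        )
    m = CharacterMatrix(
        rows=tuple(df.index),
        characters=tuple(df.columns),
        states=tuple(rows),
        alphabet=CENSUS_ALPHABET,
    )
    if orientation == "domain_rows":
        m = transpose_matrix(m)
    # 'K' is ancestral for every character in either orientation
    return CharacterMatrix(
        rows=m.rows,
        characters=m.characters,
        states=m.states,
        alphabet=m.alphabet,
        ordered=m.ordered,
        ancestral_states="K" * m.n_characters,
    )


def domain_ages(
    table: AbundanceTable,
    seed: int | None = None,
    scheme: str = "log",
    **search_kwargs,
) -> Chronology:
    """Relative ages nd_P of domain superfamilies.

    Pipeline: gap-code the census (domains as rows), search for the most
    parsimonious tree of domains, root it with the all-'K' hypothetical
    ancestor (Lundberg), and read node distances off the rooted tree.
    The oldest domain has nd_P = 0, the youngest nd_P = 1.
    """
    matrix = build_census_matrix(table, orientation="domain_rows", scheme=scheme)
    if matrix.n_rows < 4:
        raise InputError("domain_ages needs >= 4 domains with signal")
    trees = heuristic_search(matrix, seed=seed, collect_ties=False, **search_kwargs)
    rooted = root_with_ancestor(trees[0], matrix)
    return node_distance(rooted)
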