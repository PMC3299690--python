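"""Synthetic inputs with planted ground truth.

Two generators emulate the study's data classes.  The accretion model
grows a set of universal helices along a Yule guide tree: every helix is
present in all taxa, older helices (smaller birth rank) get larger
baseline stem lengths and drift less, and each branch perturbs segment
lengths by +/-1 with a small probability.  This encodes the polarization
premise — structural order decays forward in time — so the parsimony
chronology should recover helix birth order from the coded lengths.

The census model plants a domain-age signal in an abundance table:
older domain superfamilies are more abundant (log-linear in age) and
present in more proteomes.

Both generators are bit-reproducible from (model, seed) and write exactly
the text dialects the package readers consume.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

import dendropy

from .census import AbundanceTable
from .chronology import yule_tree
from .coding import CharacterMatrix, RRNA_ALPHABET
from .errors import InputError
from .structures import (
    SecondaryStructure,
    load_structural_alignment,
    parse_dotbracket,
    write_structural_alignment,
)


@dataclass(frozen=True)
class AccretionModel:
    """Parameters of the helix-accretion generator."""

    n_taxa: int = 30
    n_helices: int = 20
    drift_p: float = 0.1
    base_stem: int = 4  # youngest helix's baseline stem length (bp)
    base_hairpin: int = 4
    base_unpaired: int = 2

    def __post_init__(self):
        if self.n_taxa < 4 or self.n_helices < 4:
            raise InputError("need n_taxa >= 4 and n_helices >= 4")
        if not 0 <= self.drift_p <= 1:
            raise InputError("drift_p must be in [0, 1]")


@dataclass
class AccretionData:
    """Generated helix-map data plus its planted truth."""

    model: AccretionModel
    seed: int
    slot_ids: list
    lengths_by_taxon: dict  # taxon -> {slot: length}
    birth_ranks: dict  # helix id -> rank (1 = oldest)
    guide_tree: dendropy.Tree

    def helices(self):
        return list(self.birth_ranks)

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "helix_map": outdir / "helix_map.tsv",
            "truth": outdir / "helix_truth.tsv",
            "guide_tree": outdir / "guide_tree.nwk",
        }
        write_structural_alignment(self.slot_ids, self.lengths_by_taxon, paths["helix_map"])
        pd.DataFrame(
            sorted(self.birth_ranks.items(), key=lambda kv: kv[1]),
            columns=["helix", "birth_rank"],
        ).to_csv(paths["truth"], sep="\t", index=False)
        with open(paths["guide_tree"], "w") as fh:
            fh.write(self.guide_tree.as_string(schema="newick"))
        return {k: str(v) for k, v in paths.items()}

    def load(self):
        """(template, structures) exactly as the TSV reader would return."""
        import tempfile

        with tempfile.NamedTemporaryFile("w", suffix=".tsv", delete=False) as fh:
            fh.write("taxon\t" + "\t".join(self.slot_ids) + "\n")
            for taxon, vals in self.lengths_by_taxon.items():
                fh.write(taxon + "\t" + "\t".join(str(vals[s]) for s in self.slot_ids) + "\n")
            name = fh.name
        try:
            return load_structural_alignment(name)
        finally:
            Path(name).unlink(missing_ok=True)


def _helix_slots(helix: str):
    return [f"{helix}.S1", f"{helix}.H1", f"{helix}.S1'", f"{helix}.U1"]


def simulate_accretion(model: AccretionModel, seed: int) -> AccretionData:
    """Drift segment lengths along a Yule guide tree (see module docstring).

    Older helices start from larger stem baselines and see a reduced
    drift rate; the per-helix drift probability spans
    [0.5, 1.5] * ``model.drift_p`` from oldest to youngest.
    """
    rng = np.random.default_rng(seed)
    guide = yule_tree(model.n_taxa, random.Random(int(rng.integers(2**31 - 1))))
    helices = [f"h{i + 1}" for i in range(model.n_helices)]
    ranks = {h: int(r) + 1 for h, r in zip(helices, rng.permutation(model.n_helices))}

    base = {}
    drift_p = {}
    K = model.n_helices
    for h in helices:
        r = ranks[h]
        base[h] = {
            "S": model.base_stem + (K - r),
            "H": model.base_hairpin,
            "U": model.base_unpaired,
        }
        drift_p[h] = model.drift_p * (0.5 + (r - 1) / (K - 1)) if K > 1 else model.drift_p

    def drift(lengths):
        out = {}
        for h in helices:
            vals = dict(lengths[h])
            for kind in ("S", "H", "U"):
                if rng.random() < drift_p[h]:
                    vals[kind] = max(0, vals[kind] + (1 if rng.random() < 0.5 else -1))
            out[h] = vals
        return out

    state = {guide.seed_node: {h: dict(base[h]) for h in helices}}
    lengths_by_taxon = {}
    for node in guide.preorder_node_iter():
        if node is not guide.seed_node:
            state[node] = drift(state[node.parent_node])
        if node.is_leaf():
            taxon = node.taxon.label
            vals = {}
            for h in helices:
                s, hp, u = (state[node][h][k] for k in ("S", "H", "U"))
                vals[f"{h}.S1"] = s
                vals[f"{h}.H1"] = hp
                vals[f"{h}.S1'"] = s
                vals[f"{h}.U1"] = u
            lengths_by_taxon[taxon] = vals

    slot_ids = [s for h in helices for s in _helix_slots(h)]
    return AccretionData(
        model=model,
        seed=seed,
        slot_ids=slot_ids,
        lengths_by_taxon=lengths_by_taxon,
        birth_ranks=ranks,
        guide_tree=guide,
    )


@dataclass(frozen=True)
class CensusModel:
    """Parameters of the abundance-census generator."""

    n_proteomes: int = 50
    n_domains: int = 30
    alpha: float = 0.7  # log baseline abundance of the youngest domain
    beta: float = 2.0  # age coefficient: older domains are more abundant
    presence_floor: float = 0.3  # presence probability of the youngest domain

    def __post_init__(self):
        if self.n_domains < 4:
            raise InputError("need n_domains >= 4")
        if self.beta < 0:
            raise InputError("beta must be >= 0")


@dataclass
class CensusData:
    model: CensusModel
    seed: int
    table: AbundanceTable
    birth_ranks: dict  # domain id -> rank (1 = oldest)
    ages: dict  # domain id -> age in [0, 1], 1 = oldest

    def write(self, outdir) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "abundance": outdir / "abundance.tsv",
            "truth": outdir / "census_truth.tsv",
        }
        self.table.write_tsv(paths["abundance"])
        pd.DataFrame(
            [(d, self.birth_ranks[d], self.ages[d]) for d in
             sorted(self.birth_ranks, key=self.birth_ranks.get)],
            columns=["domain", "birth_rank", "age"],
        ).to_csv(paths["truth"], sep="\t", index=False)
        return {k: str(v) for k, v in paths.items()}


def simulate_census(model: CensusModel, seed: int) -> CensusData:
    """Plant a monotone age-abundance trend with Poisson noise.

    Domain age a in [0, 1] (1 = oldest); conditional on presence the
    abundance is 1 + Poisson(exp(alpha + beta * a)) and the presence
    probability rises linearly from ``presence_floor`` to 1 with age.
    """
    rng = np.random.default_rng(seed)
    domains = [f"c.{i + 1}.1" for i in range(model.n_domains)]
    ranks = {d: int(r) + 1 for d, r in zip(domains, rng.permutation(model.n_domains))}
    n = model.n_domains
    ages = {d: 1.0 - (ranks[d] - 1) / (n - 1) for d in domains}
    proteomes = [f"p{i + 1}" for i in range(model.n_proteomes)]
    if model.n_proteomes == 1:
        import warnings

        warnings.warn("census with a single proteome carries no tree signal")
    grid = np.zeros((model.n_proteomes, n), dtype=int)
    for j, d in enumerate(domains):
        a = ages[d]
        lam = np.exp(model.alpha + model.beta * a)
        present = rng.random(model.n_proteomes) < (
            model.presence_floor + (1 - model.presence_floor) * a
        )
        grid[:, j] = np.where(present, 1 + rng.poisson(lam, model.n_proteomes), 0)
    table = AbundanceTable(counts=pd.DataFrame(grid, index=proteomes, columns=domains))
    return CensusData(model=model, seed=seed, table=table, birth_ranks=ranks, ages=ages)


# ---------------------------------------------------------------------------
# hand-built oracle fixtures
# ---------------------------------------------------------------------------

@dataclass
class ToyFixtures:
    """Small fixtures with hand-computed expectations.

    ``mp_length`` is provable by the per-character lower bound: the sum
    of state ranges (1+1+1+2 = 5) is attained by the tree
    ((A,B),C,(D,E)), so 5 is the exact most-parsimonious length.
    """

    matrix: CharacterMatrix
    mp_length: int
    bridges: pd.DataFrame
    contacts: pd.DataFrame
    query_helix: SecondaryStructure
    ribozyme_parts: list
    planted_pair: tuple


def toy_fixtures() -> ToyFixtures:
    matrix = CharacterMatrix(
        rows=("A", "B", "C", "D", "E"),
        characters=("c1", "c2", "c3", "c4"),
        states=("0002", "0012", "1012", "1110", "1110"),
        alphabet=RRNA_ALPHABET,
    )
    bridges = pd.DataFrame(
        [("B1", "h1", "h3"), ("B2", "h2", "h4")],
        columns=["bridge", "acceptor", "donor"],
    )
    contacts = pd.DataFrame(
        [("tRNA-acceptor", "trna", "h1"), ("S12", "protein", "h4")],
        columns=["contact", "class", "helix"],
    )
    stem5, loop, stem3 = "GCAGUCGGACAG", "GAAA", "CUGUCCGACUGC"
    motif_seq = stem5 + loop + stem3
    motif_db = "(" * 12 + "." * 4 + ")" * 12
    query = parse_dotbracket(motif_db, motif_seq, name="h_query")
    planted = parse_dotbracket(
        ".." + motif_db + "..", "AA" + motif_seq + "AA", name="rz_planted"
    )
    unrelated = parse_dotbracket(
        "." * 22, "AAACAAACAAACAAAAACAAAC", name="rz_control"
    )
    return ToyFixtures(
        matrix=matrix,
        mp_length=5,
        bridges=bridges,
        contacts=contacts,
        query_helix=query,
        ribozyme_parts=[planted, unrelated],
        planted_pair=("h_query", "rz_planted"),
    )
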