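"""End-to-end orchestration of the analysis stages.

The pipeline mirrors the study design: code substructure lengths into an
ordered multistate matrix, infer the most parsimonious tree of stems,
root it with the hypothetical all-ancestral taxon, read relative ages
(nd) off the rooted tree, assemble annotation timelines, repeat the
scheme on a protein-domain census (nd_P), and screen helices against
ribozyme substructures for significant structural similarity.

Every stochastic stage derives its seed deterministically from the
global seed, so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .census import AbundanceTable, domain_ages
from .chronology import (
    Chronology,
    assemble_timeline,
    heatmap_colors,
    imbalance_stats,
    node_distance,
    null_tree_ensemble,
    rescale_unit,
)
from .coding import build_matrix, polarize, select_characters, transpose_matrix
from .errors import InputError, RibophyloError
from .nexus import write_character_matrix
from .parsimony import (
    bootstrap_support,
    fit_stats,
    heuristic_search,
    root_with_ancestor,
    strict_consensus,
)
from .structures import load_structural_alignment, read_vienna
from .similarity import screen_matrix
from .synthetic import AccretionModel, CensusModel, simulate_accretion, simulate_census

ALL_STAGES = ("simulate", "code", "tree", "chronology", "census", "similarity")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; unknown keys are rejected."""

    outdir: str = "ribophylo_out"
    seed: int = 0
    stages: tuple = ALL_STAGES
    # input paths (filled by the simulate stage when absent)
    helix_map: str | None = None
    abundance: str | None = None
    bridges: str | None = None
    contacts: str | None = None
    queries: str | None = None
    parts: str | None = None
    # analysis options
    polarization: str = "max_ancestral"
    addition: str = "input_order"
    n_restarts: int = 1
    maxtrees: int = 1000
    bootstrap_reps: int = 0
    bridge_rule: str = "acceptor"
    null_reps: int = 1000
    census_scheme: str = "log"
    n_shuffles: int = 1000
    z_threshold: float = 3.0
    # synthetic model parameters
    accretion: dict = field(default_factory=dict)
    census_model: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InputError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**data)
        bad = set(cfg.stages) - set(ALL_STAGES)
        if bad:
            raise InputError(f"unknown stages: {sorted(bad)}")
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["stages"] = list(self.stages)
        return d


def _stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    ss = np.random.SeedSequence([seed, sum(ord(c) for c in stage)])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def stem_characters(template):
    """Unprimed stem slot ids — the taxa of the tree of helices."""
    return [
        s.slot_id
        for s in template.slots
        if s.kind == "S" and not s.slot_id.endswith("'")
    ]


def rrna_ages(
    template,
    structures,
    seed: int | None = None,
    polarization: str = "max_ancestral",
    **search_kwargs,
) -> Chronology:
    """Relative ages (nd) of helices from their stem characters.

    Codes the structures, restricts to unprimed stem slots, transposes so
    stems are taxa, polarizes, searches, roots with the hypothetical
    ancestor and reads node distances.  Chronology keys are stem slot ids
    (e.g. ``h3.S1``); use :func:`helix_of` to map them to helix names.
    """
    mol = build_matrix(template, structures, orientation="molecule_rows")
    stems = select_characters(mol, stem_characters(template))
    m = polarize(transpose_matrix(stems), polarization)
    trees = heuristic_search(m, seed=seed, collect_ties=False, **search_kwargs)
    rooted = root_with_ancestor(trees[0], m)
    return node_distance(rooted)


def helix_of(slot_id: str) -> str:
    return slot_id.split(".")[0]


def validate_inputs(config: PipelineConfig) -> list:
    """Schema and cross-reference checks; returns a list of problems."""
    problems = []
    template = None
    if config.helix_map:
        try:
            template, structures = load_structural_alignment(config.helix_map)
            names = [s.name for s in structures]
            if len(set(names)) != len(names):
                problems.append("duplicate taxon label in helix map")
        except (RibophyloError, OSError) as exc:
            problems.append(f"helix_map: {exc}")
    for attr in ("bridges", "contacts"):
        path = getattr(config, attr)
        if not path:
            continue
        try:
            df = pd.read_csv(path, sep="\t")
        except (OSError, ValueError) as exc:
            problems.append(f"{attr}: {exc}")
            continue
        need = {"bridges": {"bridge", "acceptor", "donor"},
                "contacts": {"contact", "class", "helix"}}[attr]
        if not need <= set(df.columns):
            problems.append(f"{attr}: missing columns {sorted(need - set(df.columns))}")
            continue
        if template is not None:
            known = {helix_of(s) for s in template.slot_ids}
            cols = ("acceptor", "donor") if attr == "bridges" else ("helix",)
            for col in cols:
                for h in df[col].astype(str):
                    if h not in known:
                        problems.append(f"{attr}: unknown helix {h!r}")
    if config.abundance:
        try:
            AbundanceTable.read_tsv(config.abundance)
        except (RibophyloError, OSError) as exc:
            problems.append(f"abundance: {exc}")
    for attr in ("queries", "parts"):
        path = getattr(config, attr)
        if not path:
            continue
        try:
            read_vienna(path)
        except (RibophyloError, OSError) as exc:
            problems.append(f"{attr}: {exc}")
    return problems


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the configured stages; returns the manifest dict.

    Artifacts are written under ``config.outdir``; the manifest
    (``manifest.json``) records config, seeds, package version and every
    artifact path, and suffices to reproduce the bundle.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts = {}
    stage_seeds = {s: _stage_seed(config.seed, s) for s in ALL_STAGES}

    def fail(stage, exc):
        raise RibophyloError(f"stage {stage!r} failed: {exc}") from exc

    if "simulate" in config.stages:
        try:
            acc = simulate_accretion(
                AccretionModel(**config.accretion), stage_seeds["simulate"]
            )
            artifacts.update(
                {f"simulate.{k}": v for k, v in acc.write(out / "data").items()}
            )
            if config.helix_map is None:
                config.helix_map = artifacts["simulate.helix_map"]
            cen = simulate_census(
                CensusModel(**config.census_model), stage_seeds["simulate"] + 1
            )
            artifacts.update(
                {f"simulate.{k}": v for k, v in cen.write(out / "data").items()}
            )
            if config.abundance is None:
                config.abundance = artifacts["simulate.abundance"]
        except RibophyloError as exc:
            fail("simulate", exc)

    template = structures = None
    if {"code", "tree", "chronology"} & set(config.stages):
        if not config.helix_map:
            raise RibophyloError("stage 'code' failed: no helix_map input")
        template, structures = load_structural_alignment(config.helix_map)

    stem_matrix = None
    if "code" in config.stages:
        try:
            mol = build_matrix(template, structures, orientation="molecule_rows")
            write_character_matrix(mol, out / "matrix_molecules.nex")
            write_character_matrix(
                transpose_matrix(mol), out / "matrix_substructures.nex"
            )
            artifacts["code.molecule_matrix"] = str(out / "matrix_molecules.nex")
            artifacts["code.substructure_matrix"] = str(out / "matrix_substructures.nex")
        except RibophyloError as exc:
            fail("code", exc)

    trees = None
    if "tree" in config.stages:
        try:
            mol = build_matrix(template, structures, orientation="molecule_rows")
            stems = select_characters(mol, stem_characters(template))
            stem_matrix = polarize(transpose_matrix(stems), config.polarization)
            trees = heuristic_search(
                stem_matrix,
                addition=config.addition,
                n_restarts=config.n_restarts,
                seed=stage_seeds["tree"],
                maxtrees=config.maxtrees,
            )
            with open(out / "mp_trees.nwk", "w") as fh:
                for t in trees:
                    fh.write(t.as_string(schema="newick"))
            artifacts["tree.mp_trees"] = str(out / "mp_trees.nwk")
            cons = strict_consensus(trees)
            with open(out / "strict_consensus.nwk", "w") as fh:
                fh.write(cons.as_string(schema="newick"))
            artifacts["tree.strict_consensus"] = str(out / "strict_consensus.nwk")
            stats = fit_stats(trees[0], stem_matrix, seed=stage_seeds["tree"])
            pd.DataFrame(
                [
                    {
                        "length": stats.length,
                        "CI": stats.ci,
                        "RI": stats.ri,
                        "HI": stats.hi,
                        "g1": stats.g1,
                        "n_trees": len(trees),
                    }
                ]
            ).to_csv(out / "fit_stats.tsv", sep="\t", index=False)
            artifacts["tree.fit_stats"] = str(out / "fit_stats.tsv")
            if config.bootstrap_reps > 0:
                bs = bootstrap_support(
                    stem_matrix, reps=config.bootstrap_reps, seed=stage_seeds["tree"]
                )
                with open(out / "bootstrap.nwk", "w") as fh:
                    fh.write(bs.as_string(schema="newick"))
                artifacts["tree.bootstrap"] = str(out / "bootstrap.nwk")
        except RibophyloError as exc:
            fail("tree", exc)

    chron = None
    if "chronology" in config.stages:
        try:
            if trees is None or stem_matrix is None:
                raise InputError("chronology requires the tree stage")
            rooted = root_with_ancestor(trees[0], stem_matrix)
            chron = node_distance(rooted)
            chron.as_series().rename_axis("helix").to_csv(out / "nd.tsv", sep="\t")
            artifacts["chronology.nd"] = str(out / "nd.tsv")
            nbar, cherries = imbalance_stats(rooted)
            null = null_tree_ensemble(
                n_leaves=len(chron.nd),
                model="yule",
                reps=max(100, config.null_reps),
                seed=stage_seeds["chronology"],
                observed_tree=rooted,
            )
            with open(out / "imbalance.json", "w") as fh:
                json.dump(
                    {
                        "nbar": nbar,
                        "cherries": cherries,
                        "p_nbar_yule": null["p_nbar"],
                        "p_cherries_yule": null["p_cherries"],
                        "reps": null["reps"],
                    },
                    fh,
                    indent=2,
                )
            artifacts["chronology.imbalance"] = str(out / "imbalance.json")
            helix_nd = {helix_of(k): v for k, v in chron.items()}
            if config.bridges or config.contacts:
                bridges = pd.read_csv(config.bridges, sep="\t") if config.bridges else None
                contacts = pd.read_csv(config.contacts, sep="\t") if config.contacts else None
                tl = assemble_timeline(
                    Chronology(helix_nd), bridges, contacts, bridge_rule=config.bridge_rule
                )
                tl.to_tsv(out / "timeline.tsv")
                artifacts["chronology.timeline"] = str(out / "timeline.tsv")
            heatmap_colors(helix_nd).to_csv(out / "nd_colors.tsv", sep="\t", index=False)
            artifacts["chronology.colors"] = str(out / "nd_colors.tsv")
        except RibophyloError as exc:
            fail("chronology", exc)

    if "census" in config.stages:
        try:
            if not config.abundance:
                raise InputError("census stage needs an abundance table")
            table = AbundanceTable.read_tsv(config.abundance)
            ndp = domain_ages(
                table, seed=stage_seeds["census"], scheme=config.census_scheme
            )
            ndp.as_series().rename("nd_P").rename_axis("domain").to_csv(
                out / "nd_p.tsv", sep="\t"
            )
            artifacts["census.nd_p"] = str(out / "nd_p.tsv")
            heatmap_colors(rescale_unit(dict(ndp.items()))).to_csv(
                out / "nd_p_colors.tsv", sep="\t", index=False
            )
            artifacts["census.colors"] = str(out / "nd_p_colors.tsv")
        except RibophyloError as exc:
            fail("census", exc)

    if "similarity" in config.stages:
        try:
            if not (config.queries and config.parts):
                raise InputError("similarity stage needs queries and parts files")
            queries = read_vienna(config.queries)
            parts = read_vienna(config.parts)
            if chron is not None:
                helix_nd = {helix_of(k): v for k, v in chron.items()}
                nd_map = {q.name: helix_nd.get(q.name, 0.0) for q in queries}
            else:
                nd_map = {q.name: 0.0 for q in queries}
            df = screen_matrix(
                queries,
                nd_map,
                parts,
                n_shuffles=config.n_shuffles,
                threshold=config.z_threshold,
                seed=stage_seeds["similarity"],
            )
            df.to_csv(out / "similarity.tsv", sep="\t", index=False)
            artifacts["similarity.table"] = str(out / "similarity.tsv")
        except RibophyloError as exc:
            fail("similarity", exc)

    manifest = {
        "version": __version__,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seeds[s] for s in config.stages},
        "artifacts": artifacts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
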