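"""End-to-end orchestration: config, staged execution, artifacts, manifest.

The workflow is: peptide filter -> protein rollup + channel normalization ->
moderated differential abundance -> (branch 1) per-gene fold changes -> GPR
mapping -> ΔFBA; (branch 2) per-sample classification -> iMAT context models
-> replicate-consensus differential reactions -> PCA; then gene/metabolite
list extraction, merging, over-representation analysis and optional
risk-gene cross-referencing. Every stage writes its table under the output
directory and a JSON manifest records parameters, package versions, the seed
and headline counts, so a rerun with identical inputs is byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .delta_fba import extract_genes_metabolites, run_delta_fba
from .enrichment import merge_regulated_lists, ora, read_gmt, crossref_gene_list
from .imat import (ActivityVector, MandatoryBounds, classify_reactions,
                   consensus_differential, pca_binary, run_imat)
from .model_io import read_id_map, read_sbml, read_tsv_model
from .proteomics import (dedupe_abundances, filter_peptides, moderated_diff,
                         read_design, read_peptide_table, rollup_and_normalize,
                         select_gene_fold_changes)
from .reaction_mapping import map_expression_to_reactions

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one run; defaults follow the reference study."""

    # inputs
    model_sbml: Optional[str] = None
    model_tsv_dir: Optional[str] = None
    peptides: Optional[str] = None
    design: Optional[str] = None
    id_map: Optional[str] = None
    gene_gmt: Optional[str] = None
    metabolite_gmt: Optional[str] = None
    risk_genes: Optional[str] = None
    outdir: str = "results/pipeline"
    # designated reactions
    biomass_id: Optional[str] = None
    ngam_id: Optional[str] = None
    glucose_uptake_id: Optional[str] = None
    oxygen_uptake_id: Optional[str] = None
    # parameters
    min_sn: float = 180.0
    alpha: float = 0.05
    epsilon: float = 0.5
    q_low: float = 0.25
    q_high: float = 0.75
    v_act: float = 1e-2
    fdr_cut: float = 0.05
    metabolite_min_overlap: int = 4
    fc_strategy: str = "min_p"
    contrast: tuple[str, str] = ("control", "treatment")
    bounds: MandatoryBounds = field(default_factory=MandatoryBounds)
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "bounds" in raw:
            raw["bounds"] = MandatoryBounds(**raw["bounds"])
        if "contrast" in raw:
            raw["contrast"] = tuple(raw["contrast"])
        return PipelineConfig(**raw)

    def validate(self) -> None:
        if (self.model_sbml is None) == (self.model_tsv_dir is None):
            raise ValueError("exactly one of model_sbml / model_tsv_dir required")
        for name in ("peptides", "design"):
            if getattr(self, name) is None:
                raise ValueError(f"config field {name!r} is required")
        if not (0.0 <= self.q_low < self.q_high <= 1.0):
            raise ValueError(
                f"need 0 <= q_low < q_high <= 1 (got {self.q_low}, {self.q_high})")
        for name in ("min_sn", "alpha", "epsilon", "v_act", "fdr_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("model_sbml", "model_tsv_dir", "peptides", "design",
                     "id_map", "gene_gmt", "metabolite_gmt", "risk_genes"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name}: no such path {p}")


@dataclass
class PipelineReport:
    """In-memory summary of one run (the files hold the full tables)."""

    diff: Any
    gene_fold_changes: dict[str, float]
    dfba: Any
    dfba_genes: set[str]
    dfba_metabolites: set[str]
    activity: list[ActivityVector]
    consensus: Any
    imat_genes: set[str]
    imat_metabolites: set[str]
    merged_genes: pd.DataFrame
    merged_metabolites: pd.DataFrame
    gene_ora: Optional[pd.DataFrame]
    metabolite_ora: Optional[pd.DataFrame]
    risk_overlap: Optional[pd.DataFrame]
    manifest: dict


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return inner
    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full workflow described in the module docstring."""
    config.validate()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)

    # -- inputs -------------------------------------------------------------
    if config.model_sbml:
        model = read_sbml(config.model_sbml, config.biomass_id, config.ngam_id,
                          config.glucose_uptake_id, config.oxygen_uptake_id)
    else:
        model = read_tsv_model(config.model_tsv_dir)
        for attr in ("biomass_id", "ngam_id", "glucose_uptake_id",
                     "oxygen_uptake_id"):
            if getattr(config, attr) is not None:
                setattr(model, attr, getattr(config, attr))
        model.validate()
    peptides = read_peptide_table(config.peptides)
    design = read_design(config.design)
    id_map = read_id_map(config.id_map) if config.id_map else None

    # -- proteomics ---------------------------------------------------------
    kept = _stage("filter_peptides")(filter_peptides)(peptides, config.min_sn)
    matrix = _stage("rollup_and_normalize")(rollup_and_normalize)(kept, design)
    matrix.values.to_csv(out / "abundance_normalized.tsv", sep="\t")
    diff = _stage("moderated_diff")(moderated_diff)(
        matrix, contrast=config.contrast)
    diff.to_tsv(out / "differential_abundance.tsv")

    # -- branch 1: ΔFBA -----------------------------------------------------
    gene_fc = _stage("select_gene_fold_changes")(select_gene_fold_changes)(
        diff, config.alpha, id_map, config.fc_strategy)
    changes = map_expression_to_reactions(model, gene_fc)
    dfba = _stage("delta_fba")(run_delta_fba)(model, changes, config.epsilon)
    pd.DataFrame(
        [{"reaction": rid, "delta_flux": dfba.delta_v[rid],
          "scored": int(rid in changes.scores),
          "consistent": dfba.consistency.get(rid, "")}
         for rid in model.reaction_ids]
    ).to_csv(out / "delta_fba.tsv", sep="\t", index=False)
    dfba_genes, dfba_mets = extract_genes_metabolites(
        model, dfba.differential_reactions)

    # -- branch 2: iMAT activity --------------------------------------------
    gene_abund = dedupe_abundances(matrix, id_map)
    activity: list[ActivityVector] = []
    ctrl_label, treat_label = config.contrast
    for sample in matrix.samples:
        abund = {g: float(v) for g, v in gene_abund[sample].items()}
        proteome = matrix.values[sample].to_numpy(dtype=float)
        r_high, r_low = classify_reactions(
            model, abund, config.q_low, config.q_high, proteome=proteome)
        _, act, _ = _stage(f"imat[{sample}]")(run_imat)(
            model, r_high, r_low, config.bounds, config.v_act)
        activity.append(ActivityVector(sample, design[sample], act))
    act_df = pd.DataFrame(
        {av.sample: pd.Series(av.activity) for av in activity})
    act_df.index.name = "reaction"
    act_df.to_csv(out / "activity_matrix.tsv", sep="\t")
    consensus = consensus_differential(
        [av for av in activity if av.group == ctrl_label],
        [av for av in activity if av.group == treat_label])
    consensus.to_frame().to_csv(out / "consensus_differential.tsv",
                                sep="\t", index=False)
    scores, explained = pca_binary(activity)
    scores.to_csv(out / "pca_scores.tsv", sep="\t")
    imat_genes, imat_mets = extract_genes_metabolites(
        model, consensus.differential)

    # -- integration --------------------------------------------------------
    merged_genes = merge_regulated_lists(dfba_genes, imat_genes)
    merged_genes.to_csv(out / "merged_genes.tsv", sep="\t", index=False)
    merged_mets = merge_regulated_lists(dfba_mets, imat_mets)
    merged_mets.to_csv(out / "merged_metabolites.tsv", sep="\t", index=False)

    gene_ora = metab_ora = risk_tab = None
    measured_genes = set(gene_abund.index.astype(str))
    if config.gene_gmt:
        universe = set(model.genes) & measured_genes
        gene_ora = ora(set(merged_genes["id"]), read_gmt(config.gene_gmt),
                       universe, min_overlap=1, fdr_cut=config.fdr_cut)
        gene_ora.to_csv(out / "gene_enrichment.tsv", sep="\t", index=False)
    if config.metabolite_gmt:
        metab_ora = ora(set(merged_mets["id"]), read_gmt(config.metabolite_gmt),
                        set(model.metabolite_ids),
                        min_overlap=config.metabolite_min_overlap,
                        fdr_cut=config.fdr_cut)
        metab_ora.to_csv(out / "metabolite_enrichment.tsv", sep="\t", index=False)
    if config.risk_genes:
        risk = {l.strip() for l in open(config.risk_genes) if l.strip()}
        risk_tab = crossref_gene_list(diff, risk, id_map, config.alpha)
        risk_tab.to_csv(out / "risk_gene_overlap.tsv", sep="\t", index=False)

    manifest = {
        "fluxdiff_version": __version__,
        "seed": config.seed,
        "parameters": {
            k: v for k, v in dataclasses.asdict(config).items()
            if k not in ("outdir",)
        },
        "n_proteins": int(len(matrix.proteins)),
        "n_significant_proteins": int(len(diff.significant(config.alpha))),
        "n_gene_fold_changes": len(gene_fc),
        "dfba_objective_stage1": dfba.objective_stage1,
        "dfba_objective_stage2": dfba.objective_stage2,
        "n_dfba_differential_reactions": len(dfba.differential_reactions),
        "n_consensus_differential_reactions": len(consensus.differential),
        "consensus_differential_reactions": sorted(consensus.differential),
        "n_merged_genes": int(len(merged_genes)),
        "n_merged_metabolites": int(len(merged_mets)),
        "pca_explained_variance": [float(x) for x in explained],
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)

    return PipelineReport(
        diff=diff, gene_fold_changes=gene_fc, dfba=dfba,
        dfba_genes=dfba_genes, dfba_metabolites=dfba_mets,
        activity=activity, consensus=consensus,
        imat_genes=imat_genes, imat_metabolites=imat_mets,
        merged_genes=merged_genes, merged_metabolites=merged_mets,
        gene_ora=gene_ora, metabolite_ora=metab_ora, risk_overlap=risk_tab,
        manifest=manifest)
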