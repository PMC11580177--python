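"""Synthetic toy metabolic models and TMT proteomics with planted truth.

The generator produces (a) a small flux-balanced network — glucose and
oxygen exchanges, parallel redundant biosynthesis branches with one gene per
reaction (plus a few AND/OR multi-gene rules), an ATP-generation/maintenance
pair and a biomass sink — and (b) a two-group multiplexed proteomics
experiment over it: log-normal protein abundances with a decreasing
mean-variance trend, duplicate protein entries, background (non-model)
proteins that dominate the whole-proteome quantile thresholds, and peptide
rows whose per-channel signal-to-noise sums exactly to the protein signal.

One redundant branch is planted "off" in the treatment group: its genes
receive a negative log2 fold change, which is the ground truth every
downstream stage is checked against.

Channel totals are balanced exactly by one synthetic loading-control
protein, emulating the equal-protein-loading assumption behind
equal-channel-sum normalization (so normalization introduces no
compositional shift into the planted fold changes).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .model_io import (
    GPR,
    MetabolicModel,
    Metabolite,
    Reaction,
    parse_gpr,
    write_sbml,
    write_tsv_model,
)
from .proteomics import AbundanceMatrix

__all__ = [
    "SyntheticTruth",
    "make_toy_model",
    "simulate_proteomics",
    "make_gene_sets",
    "make_metabolite_sets",
    "write_bundle",
    "noise_sd",
]

BALANCER_ID = "LOADCTRL"  # synthetic loading-control protein (not a model gene)


@dataclass
class SyntheticTruth:
    """Planted ground truth: which reactions are off and which genes change."""

    off_reactions: set[str] = field(default_factory=set)
    de_genes: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"off_reactions": sorted(self.off_reactions),
                 "de_genes": self.de_genes, "seed": self.seed},
                fh, indent=1)

    @staticmethod
    def from_json(path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return SyntheticTruth(set(d["off_reactions"]), dict(d["de_genes"]),
                              int(d["seed"]))


def _branch_reactions(i: int, branch_length: int) -> list[tuple[str, str, str, str]]:
    """(reaction id, substrate, product, gpr string) along branch ``i``."""
    mets = ["glc"] + [f"b{i}_m{k}" for k in range(1, branch_length)] + ["bm_pre"]
    out = []
    for k in range(branch_length):
        rid = f"R_b{i}_{k + 1}"
        if k == 0 and branch_length >= 2:
            gpr = f"g{i}_1a or g{i}_1b"          # isozyme pair
        elif k == 1 and branch_length >= 3:
            gpr = f"g{i}_2a and g{i}_2b"         # complex
        else:
            gpr = f"g{i}_{k + 1}"
        out.append((rid, mets[k], mets[k + 1], gpr))
    return out


def make_toy_model(
    n_branches: int = 2,
    branch_length: int = 5,
    seed: int = 0,
    de_logfc: float = -2.0,
) -> tuple[MetabolicModel, SyntheticTruth]:
    """Toy network with ``n_branches`` parallel glucose-to-biomass branches.

    Each branch alone can sustain biomass formation, so any one branch is
    redundant. With ``n_branches >= 2`` one branch (chosen by ``seed``) is
    designated off in the treatment group; its genes carry ``de_logfc``
    (negative: a knock-down). With a single branch nothing can be turned off
    and the truth is empty.
    """
    if n_branches < 1 or branch_length < 1:
        raise ValueError("need n_branches >= 1 and branch_length >= 1")
    if de_logfc >= 0:
        raise ValueError("planted fold change must be negative (branch off)")
    rng = np.random.default_rng(seed)

    metabolites = [Metabolite("glc", "glucose"), Metabolite("o2", "oxygen"),
                   Metabolite("atp", "ATP"), Metabolite("bm_pre", "biomass precursor"),
                   Metabolite("bm", "biomass")]
    reactions: list[Reaction] = []
    stoich: list[tuple[str, str, float]] = []
    UB = 1000.0

    def add(rid: str, name: str, consumed: Mapping[str, float],
            produced: Mapping[str, float], gpr: Optional[str] = None,
            subsystem: str = "") -> None:
        reactions.append(Reaction(rid, name, 0.0, UB, parse_gpr(gpr or ""),
                                  subsystem))
        for mid, c in consumed.items():
            stoich.append((mid, rid, -c))
        for mid, c in produced.items():
            stoich.append((mid, rid, c))

    add("EX_glc", "glucose uptake", {}, {"glc": 1.0}, subsystem="exchange")
    add("EX_o2", "oxygen uptake", {}, {"o2": 1.0}, subsystem="exchange")
    seen_mets = {m.id for m in metabolites}
    for i in range(1, n_branches + 1):
        for rid, sub, prod, gpr in _branch_reactions(i, branch_length):
            for mid in (sub, prod):
                if mid not in seen_mets:
                    metabolites.append(Metabolite(mid, mid))
                    seen_mets.add(mid)
            add(rid, f"branch {i} step", {sub: 1.0}, {prod: 1.0}, gpr,
                subsystem=f"branch_{i}")
    add("R_atp_gen", "ATP generation", {"glc": 1.0}, {"atp": 1.0},
        subsystem="energy")
    add("R_ngam", "maintenance ATP hydrolysis", {"atp": 1.0}, {},
        subsystem="energy")
    add("R_bm_asm", "biomass assembly", {"bm_pre": 1.0, "o2": 1.0},
        {"bm": 1.0}, subsystem="biomass")
    add("R_biomass", "biomass sink", {"bm": 1.0}, {}, subsystem="biomass")

    model = MetabolicModel(
        reactions=reactions, metabolites=metabolites, stoichiometry=stoich,
        biomass_id="R_biomass", ngam_id="R_ngam",
        glucose_uptake_id="EX_glc", oxygen_uptake_id="EX_o2",
        id=f"toy_{n_branches}x{branch_length}")
    model.validate()

    truth = SyntheticTruth(seed=seed)
    if n_branches >= 2:
        off = int(rng.integers(1, n_branches + 1))
        branch = _branch_reactions(off, branch_length)
        truth.off_reactions = {rid for rid, *_ in branch}
        for rid, _, _, gpr in branch:
            for g in parse_gpr(gpr).genes():
                truth.de_genes[g] = float(de_logfc)

    _check_generated(model, truth)
    return model, truth


def _check_generated(model: MetabolicModel, truth: SyntheticTruth) -> None:
    """Biomass + maintenance must stay feasible with the off-branch closed."""
    from .imat import InfeasibleModelError, MandatoryBounds, _feasible
    from .model_io import stoich_matrix

    S = stoich_matrix(model)
    rids = model.reaction_ids
    lo = np.array([r.lower_bound for r in model.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in model.reactions], dtype=float)
    for rid, mlb in MandatoryBounds().lower_bounds(model).items():
        lo[rids.index(rid)] = max(lo[rids.index(rid)], mlb)
    if not _feasible(S, lo, hi):
        raise RuntimeError("generated model infeasible under mandatory bounds")
    if truth.off_reactions:
        hi2 = hi.copy()
        for rid in truth.off_reactions:
            j = rids.index(rid)
            lo[j] = hi2[j] = 0.0
        if not _feasible(S, lo, hi2):
            raise RuntimeError(
                "generated model infeasible with the off-branch closed")


def noise_sd(baseline_log2: np.ndarray, sigma: float) -> np.ndarray:
    """Decreasing mean-variance trend: noise sd on the log2 scale.

    Linear in log2 abundance, higher abundance -> lower variance, clipped so
    the factor stays within [0.4, 2.5] x sigma.
    """
    factor = np.clip(1.6 - 0.12 * (np.asarray(baseline_log2, float) - 8.0),
                     0.4, 2.5)
    return sigma * factor


def simulate_proteomics(
    model: MetabolicModel,
    truth: SyntheticTruth,
    n_per_group: int = 3,
    sigma: float = 0.2,
    dup_fraction: float = 0.2,
    seed: int = 0,
    n_background: int = 200,
) -> tuple[pd.DataFrame, AbundanceMatrix, dict[str, str]]:
    """Simulate a two-group TMT experiment over the model's genes.

    Per gene, log2 abundance = baseline + planted group effect + noise whose
    sd follows :func:`noise_sd`. ``dup_fraction`` of model genes are emitted
    as two distinct protein entries (perturbed copies of the same signal);
    ``n_background`` proteins outside the model pad the whole-proteome
    distribution. The peptide table splits each protein's per-channel S/N
    across 2-5 peptides (shares summing to 1), and ~30% of proteins carry an
    extra trace peptide whose summed S/N falls below the 180 filter.

    Returns the peptide table, the protein x sample signal matrix
    (pre-rollup truth) and the sample -> group design.
    """
    if n_per_group < 2:
        raise ValueError("need n_per_group >= 2")
    if sigma < 0 or not 0.0 <= dup_fraction <= 1.0:
        raise ValueError("sigma >= 0 and 0 <= dup_fraction <= 1 required")
    rng = np.random.default_rng(seed)
    samples = [f"ctrl_{i+1}" for i in range(n_per_group)] + \
              [f"trt_{i+1}" for i in range(n_per_group)]
    design = {s: ("control" if s.startswith("ctrl") else "treatment")
              for s in samples}
    is_treat = np.array([design[s] == "treatment" for s in samples])

    genes = sorted(model.genes)
    # model genes sit mid-band, well inside the background quartiles
    base_model = rng.normal(10.0, 0.25, size=len(genes))
    base_bg = rng.normal(10.0, 1.5, size=n_background)

    rows: list[tuple[str, Optional[str], float, float]] = []  # protein, gene, base, lfc
    for g, b in zip(genes, base_model):
        lfc = truth.de_genes.get(g, 0.0)
        rows.append((f"P_{g}", g, float(b), lfc))
        if rng.random() < dup_fraction:
            rows.append((f"P_{g}_dup", g, float(b + rng.normal(0, 0.5 * sigma)),
                         lfc))
    for i, b in enumerate(base_bg):
        rows.append((f"BG{i+1:04d}", None, float(b), 0.0))

    proteins = [p for p, *_ in rows]
    base = np.array([b for _, _, b, _ in rows])
    lfc = np.array([l for *_, l in rows])
    sd = noise_sd(base, sigma)
    log2sig = (base[:, None] + lfc[:, None] * is_treat[None, :]
               + rng.normal(0.0, 1.0, (len(rows), len(samples))) * sd[:, None])
    signal = np.power(2.0, log2sig)

    pep_rows = []
    kept_totals = np.zeros(len(samples))
    for pi, prot in enumerate(proteins):
        n_pep = int(rng.integers(2, 6))
        shares = rng.dirichlet(np.full(n_pep, 5.0))
        if rng.random() < 0.3:
            trace = float(rng.uniform(1e-4, 1e-3))
            shares = np.append(shares * (1.0 - trace), trace)
        for k, f in enumerate(shares):
            sn = f * signal[pi]
            if sn.sum() >= 180.0:
                kept_totals += sn
            pep_rows.append({"peptide": f"{prot}_pep{k+1}", "protein": prot,
                             **dict(zip(samples, sn))})

    # The loading-control protein equalizes the channel totals of the
    # quantifiable (above-filter) peptides, emulating equal protein loading:
    # with it, equal-channel-sum normalization introduces no compositional
    # shift into the planted fold changes.
    target = float(kept_totals.max()) * 1.02
    balancer = target - kept_totals
    for k, f in enumerate((0.5, 0.5)):
        pep_rows.append({"peptide": f"{BALANCER_ID}_pep{k+1}",
                         "protein": BALANCER_ID,
                         **dict(zip(samples, f * balancer))})
    signal = np.vstack([signal, balancer])
    proteins = proteins + [BALANCER_ID]

    matrix = AbundanceMatrix(
        pd.DataFrame(signal, index=pd.Index(proteins, name="protein"),
                     columns=samples),
        dict(design))
    peptides = pd.DataFrame(pep_rows, columns=["peptide", "protein", *samples])
    return peptides, matrix, design


def id_map_for(model: MetabolicModel) -> dict[str, str]:
    """Protein-to-gene map matching :func:`simulate_proteomics` naming."""
    out = {}
    for g in sorted(model.genes):
        out[f"P_{g}"] = g
        out[f"P_{g}_dup"] = g
    return out


def make_gene_sets(model: MetabolicModel, truth: SyntheticTruth,
                   seed: int = 0, n_random: int = 5) -> dict[str, set[str]]:
    """GMT-style gene sets: one per branch subsystem plus random decoys."""
    rng = np.random.default_rng(seed)
    genes = sorted(model.genes)
    sets: dict[str, set[str]] = {}
    subsystems: dict[str, set[str]] = {}
    for r in model.reactions:
        if r.gpr is not None and r.subsystem:
            subsystems.setdefault(r.subsystem, set()).update(r.gpr.genes())
    for name, members in sorted(subsystems.items()):
        sets[f"SET_{name}"] = members
    for i in range(n_random):
        k = int(rng.integers(3, max(4, len(genes) // 2 + 1)))
        sets[f"SET_random_{i+1}"] = set(
            rng.choice(genes, size=min(k, len(genes)), replace=False))
    return sets


def make_metabolite_sets(model: MetabolicModel, seed: int = 0,
                         n_random: int = 3) -> dict[str, set[str]]:
    """Metabolite sets per subsystem plus random decoys."""
    rng = np.random.default_rng(seed)
    mets = sorted(model.metabolite_ids)
    by_sub: dict[str, set[str]] = {}
    sub_of = {r.id: r.subsystem for r in model.reactions}
    for mid, rid, _ in model.stoichiometry:
        sub = sub_of.get(rid, "")
        if sub:
            by_sub.setdefault(sub, set()).add(mid)
    sets = {f"MSET_{name}": members for name, members in sorted(by_sub.items())}
    for i in range(n_random):
        k = int(rng.integers(4, max(5, len(mets) // 2 + 1)))
        sets[f"MSET_random_{i+1}"] = set(
            rng.choice(mets, size=min(k, len(mets)), replace=False))
    return sets


def write_bundle(
    directory: str | Path,
    n_branches: int = 2,
    branch_length: int = 5,
    n_per_group: int = 3,
    sigma: float = 0.2,
    dup_fraction: float = 0.2,
    seed: int = 0,
    de_logfc: float = -2.0,
    n_background: int = 200,
) -> Path:
    """Write a complete synthetic analysis bundle (model, data, annotations).

    Emits the SBML model plus its flat-TSV form, the peptide table, design,
    id map, gene/metabolite GMT collections, a synthetic risk-gene list and
    the ground truth JSON. Returns the bundle directory.
    """
    from .enrichment import GeneSetCollection, write_gmt

    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    model, truth = make_toy_model(n_branches, branch_length, seed, de_logfc)
    peptides, matrix, design = simulate_proteomics(
        model, truth, n_per_group, sigma, dup_fraction, seed, n_background)

    write_sbml(model, d / "model.xml")
    write_tsv_model(model, d / "model_tsv")
    peptides.to_csv(d / "peptides.tsv", sep="\t", index=False)
    matrix.values.to_csv(d / "protein_signal.tsv", sep="\t")
    pd.DataFrame({"sample": list(design), "group": list(design.values())}
                 ).to_csv(d / "design.tsv", sep="\t", index=False)
    idmap = id_map_for(model)
    pd.DataFrame({"source_id": list(idmap), "model_gene_id": list(idmap.values())}
                 ).to_csv(d / "id_map.tsv", sep="\t", index=False)

    gsets = make_gene_sets(model, truth, seed)
    write_gmt(GeneSetCollection(
        {k: frozenset(v) for k, v in gsets.items()},
        {k: "synthetic gene set" for k in gsets}), d / "gene_sets.gmt")
    msets = make_metabolite_sets(model, seed)
    write_gmt(GeneSetCollection(
        {k: frozenset(v) for k, v in msets.items()},
        {k: "synthetic metabolite set" for k in msets}), d / "metabolite_sets.gmt")

    rng = np.random.default_rng(seed + 1)
    genes = sorted(model.genes)
    risk = set(rng.choice(genes, size=max(1, len(genes) // 3), replace=False))
    risk |= set(list(truth.de_genes)[:2])
    with open(d / "risk_genes.txt", "w") as fh:
        fh.write("\n".join(sorted(risk)) + "\n")

    truth.to_json(d / "truth.json")
    return d
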