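"""Constraint-based metabolic models: containers, SBML/TSV I/O and GPR rules.

A :class:`MetabolicModel` is a thin, explicit container for what the pipeline
needs from a genome-scale model — reactions with flux bounds, metabolites,
sparse stoichiometry, and boolean gene–protein–reaction (GPR) associations —
plus optional designations of the biomass, non-growth-associated ATP
maintenance (NGAM) and nutrient-uptake reactions. SBML Level 3 + FBC files are
read and written through cobrapy; a flat three-table TSV dialect is provided
for fixtures and synthetic models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp

__all__ = [
    "GPR",
    "GPRParseError",
    "ModelFormatError",
    "parse_gpr",
    "Reaction",
    "Metabolite",
    "MetabolicModel",
    "stoich_matrix",
    "read_sbml",
    "write_sbml",
    "read_tsv_model",
    "write_tsv_model",
    "read_id_map",
]


class GPRParseError(ValueError):
    """Raised when a GPR string cannot be parsed; carries the failing position."""


class ModelFormatError(ValueError):
    """Raised when a model file violates the expected format."""


# ---------------------------------------------------------------------------
# GPR expression trees
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPR:
    """Boolean gene-association tree: a gene leaf, or an AND/OR over children.

    ``op`` is one of ``"gene"``, ``"and"``, ``"or"``. Leaves carry ``gene``;
    internal nodes carry ``children`` (tuples, at least two entries).
    """

    op: str
    gene: Optional[str] = None
    children: tuple["GPR", ...] = ()

    @staticmethod
    def leaf(gene: str) -> "GPR":
        if not gene:
            raise ValueError("gene id must be a non-empty string")
        return GPR("gene", gene=gene)

    @staticmethod
    def all_of(children: Sequence["GPR"]) -> "GPR":
        children = tuple(children)
        return children[0] if len(children) == 1 else GPR("and", children=children)

    @staticmethod
    def any_of(children: Sequence["GPR"]) -> "GPR":
        children = tuple(children)
        return children[0] if len(children) == 1 else GPR("or", children=children)

    def genes(self) -> frozenset[str]:
        if self.op == "gene":
            return frozenset([self.gene])  # type: ignore[list-item]
        out: set[str] = set()
        for c in self.children:
            out |= c.genes()
        return frozenset(out)

    def evaluate(self, values: Mapping[str, float]) -> Optional[float]:
        """Evaluate with AND = min, OR = max over measured genes.

        Unmeasured leaves are ignored inside OR; an AND requires every child
        to be measured and is otherwise missing (``None``).
        """
        if self.op == "gene":
            v = values.get(self.gene)  # type: ignore[arg-type]
            return None if v is None else float(v)
        vals = [c.evaluate(values) for c in self.children]
        if self.op == "and":
            if any(v is None for v in vals):
                return None
            return min(vals)  # type: ignore[type-var]
        present = [v for v in vals if v is not None]
        return max(present) if present else None

    def to_string(self) -> str:
        if self.op == "gene":
            return self.gene  # type: ignore[return-value]
        parts = []
        for c in self.children:
            s = c.to_string()
            # parenthesize OR children under AND (AND binds tighter)
            if self.op == "and" and c.op == "or":
                s = f"({s})"
            parts.append(s)
        sep = " and " if self.op == "and" else " or "
        return sep.join(parts)


_TOKEN_RE = re.compile(r"\s*(\(|\)|[^\s()]+)")


def _tokenize(text: str) -> list[tuple[str, int]]:
    tokens: list[tuple[str, int]] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None:
            break
        tokens.append((m.group(1), m.start(1)))
        pos = m.end()
    return tokens


def parse_gpr(text: str) -> Optional[GPR]:
    """Parse a GPR string (``and``/``or``/parentheses, case-insensitive).

    ``and`` binds tighter than ``or``. An empty or whitespace-only string
    denotes the empty association and returns ``None``.

    Raises
    ------
    GPRParseError
        On unbalanced parentheses or dangling operators, with the character
        position of the offending token.
    """
    tokens = _tokenize(text)
    if not tokens:
        return None
    idx = 0

    def peek() -> Optional[tuple[str, int]]:
        return tokens[idx] if idx < len(tokens) else None

    def error(msg: str, pos: int) -> GPRParseError:
        return GPRParseError(f"{msg} at position {pos} in {text!r}")

    def parse_or() -> GPR:
        nonlocal idx
        terms = [parse_and()]
        while (t := peek()) is not None and t[0].lower() == "or":
            idx += 1
            terms.append(parse_and())
        return GPR.any_of(terms)

    def parse_and() -> GPR:
        nonlocal idx
        factors = [parse_factor()]
        while (t := peek()) is not None and t[0].lower() == "and":
            idx += 1
            factors.append(parse_factor())
        return GPR.all_of(factors)

    def parse_factor() -> GPR:
        nonlocal idx
        t = peek()
        if t is None:
            raise error("dangling operator: expected gene or '('",
                        tokens[idx - 1][1] if idx else 0)
        tok, pos = t
        if tok == "(":
            idx += 1
            inner = parse_or()
            t2 = peek()
            if t2 is None or t2[0] != ")":
                raise error("unbalanced parentheses: missing ')'", pos)
            idx += 1
            return inner
        if tok == ")":
            raise error("unbalanced parentheses: unexpected ')'", pos)
        if tok.lower() in ("and", "or"):
            raise error(f"dangling operator {tok!r}", pos)
        idx += 1
        return GPR.leaf(tok)

    tree = parse_or()
    if (t := peek()) is not None:
        raise GPRParseError(
            f"unexpected token {t[0]!r} at position {t[1]} in {text!r}")
    return tree


# ---------------------------------------------------------------------------
# Model containers
# ---------------------------------------------------------------------------

@dataclass
class Reaction:
    id: str
    name: str = ""
    lower_bound: float = 0.0
    upper_bound: float = 1000.0
    gpr: Optional[GPR] = None
    subsystem: str = ""


@dataclass
class Metabolite:
    id: str
    name: str = ""
    compartment: str = "c"


@dataclass
class MetabolicModel:
    """Stoichiometry, bounds and gene associations of a metabolic network.

    ``stoichiometry`` is a list of ``(metabolite_id, reaction_id, coefficient)``
    triplets. Designated reactions (biomass, NGAM, glucose/oxygen uptake) are
    referenced by id and optional.
    """

    reactions: list[Reaction] = field(default_factory=list)
    metabolites: list[Metabolite] = field(default_factory=list)
    stoichiometry: list[tuple[str, str, float]] = field(default_factory=list)
    biomass_id: Optional[str] = None
    ngam_id: Optional[str] = None
    glucose_uptake_id: Optional[str] = None
    oxygen_uptake_id: Optional[str] = None
    id: str = "model"

    # -- indexing helpers ---------------------------------------------------
    @property
    def reaction_ids(self) -> list[str]:
        return [r.id for r in self.reactions]

    @property
    def metabolite_ids(self) -> list[str]:
        return [m.id for m in self.metabolites]

    def reaction(self, rid: str) -> Reaction:
        try:
            return next(r for r in self.reactions if r.id == rid)
        except StopIteration:
            raise KeyError(f"no reaction {rid!r} in model {self.id!r}") from None

    @property
    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for r in self.reactions:
            if r.gpr is not None:
                out |= r.gpr.genes()
        return frozenset(out)

    def validate(self) -> None:
        rids = set(self.reaction_ids)
        mids = set(self.metabolite_ids)
        if len(rids) != len(self.reactions):
            raise ValueError("duplicate reaction ids")
        if len(mids) != len(self.metabolites):
            raise ValueError("duplicate metabolite ids")
        for mid, rid, _ in self.stoichiometry:
            if mid not in mids:
                raise ValueError(f"stoichiometry references unknown metabolite {mid!r}")
            if rid not in rids:
                raise ValueError(f"stoichiometry references unknown reaction {rid!r}")
        for r in self.reactions:
            if r.lower_bound > r.upper_bound:
                raise ValueError(
                    f"reaction {r.id!r}: lower bound {r.lower_bound} exceeds "
                    f"upper bound {r.upper_bound}")
        for attr in ("biomass_id", "ngam_id", "glucose_uptake_id", "oxygen_uptake_id"):
            rid = getattr(self, attr)
            if rid is not None and rid not in rids:
                raise ValueError(f"designated {attr}={rid!r} not in reactions")

    def copy(self) -> "MetabolicModel":
        return MetabolicModel(
            reactions=[replace(r) for r in self.reactions],
            metabolites=[replace(m) for m in self.metabolites],
            stoichiometry=list(self.stoichiometry),
            biomass_id=self.biomass_id,
            ngam_id=self.ngam_id,
            glucose_uptake_id=self.glucose_uptake_id,
            oxygen_uptake_id=self.oxygen_uptake_id,
            id=self.id,
        )


def stoich_matrix(model: MetabolicModel) -> sp.csr_matrix:
    """Sparse stoichiometric matrix S (metabolites x reactions)."""
    midx = {m: i for i, m in enumerate(model.metabolite_ids)}
    ridx = {r: j for j, r in enumerate(model.reaction_ids)}
    rows, cols, data = [], [], []
    for mid, rid, coeff in model.stoichiometry:
        rows.append(midx[mid])
        cols.append(ridx[rid])
        data.append(float(coeff))
    return sp.csr_matrix(
        (data, (rows, cols)), shape=(len(model.metabolites), len(model.reactions))
    )


# ---------------------------------------------------------------------------
# SBML I/O (through cobrapy)
# ---------------------------------------------------------------------------

def _check_sbml_bounds(path: str | Path) -> None:
    # cobrapy silently substitutes defaults for missing FBC bounds, so the
    # format check runs on the raw document first.
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getNumErrors(libsbml.LIBSBML_SEV_FATAL) or doc.getModel() is None:
        raise IOError(f"cannot read SBML file {path}")
    m = doc.getModel()
    for i in range(m.getNumReactions()):
        rxn = m.getReaction(i)
        fbc = rxn.getPlugin("fbc")
        if fbc is None or not fbc.isSetLowerFluxBound() or not fbc.isSetUpperFluxBound():
            raise ModelFormatError(
                f"reaction {rxn.getId()!r} is missing FBC flux bounds")


def read_sbml(
    path: str | Path,
    biomass_id: Optional[str] = None,
    ngam_id: Optional[str] = None,
    glucose_uptake_id: Optional[str] = None,
    oxygen_uptake_id: Optional[str] = None,
) -> MetabolicModel:
    """Read an SBML Level 3 + FBC model.

    Designated reactions are identified by explicitly supplied ids (no name
    heuristics); each must exist in the file when given.
    """
    import cobra.io

    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    _check_sbml_bounds(path)
    cm = cobra.io.read_sbml_model(str(path))

    metabolites = [
        Metabolite(m.id, m.name or "", m.compartment or "c") for m in cm.metabolites
    ]
    reactions = []
    stoich: list[tuple[str, str, float]] = []
    for r in cm.reactions:
        gpr = parse_gpr(r.gene_reaction_rule or "")
        reactions.append(
            Reaction(r.id, r.name or "", float(r.lower_bound),
                     float(r.upper_bound), gpr, r.subsystem or "")
        )
        for met, coeff in r.metabolites.items():
            stoich.append((met.id, r.id, float(coeff)))

    model = MetabolicModel(
        reactions=reactions,
        metabolites=metabolites,
        stoichiometry=stoich,
        biomass_id=biomass_id,
        ngam_id=ngam_id,
        glucose_uptake_id=glucose_uptake_id,
        oxygen_uptake_id=oxygen_uptake_id,
        id=cm.id or path.stem,
    )
    model.validate()
    return model


def write_sbml(model: MetabolicModel, path: str | Path) -> None:
    """Write the model as SBML Level 3 + FBC via cobrapy."""
    import cobra
    import cobra.io

    model.validate()
    cm = cobra.Model(model.id)
    mets = {
        m.id: cobra.Metabolite(m.id, name=m.name, compartment=m.compartment)
        for m in model.metabolites
    }
    cm.add_metabolites(list(mets.values()))
    by_rxn: dict[str, dict[str, float]] = {}
    for mid, rid, coeff in model.stoichiometry:
        by_rxn.setdefault(rid, {})[mid] = by_rxn.setdefault(rid, {}).get(mid, 0.0) + coeff
    rxns = []
    for r in model.reactions:
        cr = cobra.Reaction(r.id, name=r.name,
                            lower_bound=r.lower_bound, upper_bound=r.upper_bound)
        cr.subsystem = r.subsystem
        rxns.append(cr)
    cm.add_reactions(rxns)
    for r in model.reactions:
        cr = cm.reactions.get_by_id(r.id)
        cr.add_metabolites({mets[mid]: c for mid, c in by_rxn.get(r.id, {}).items()})
        if r.gpr is not None:
            cr.gene_reaction_rule = r.gpr.to_string()
    if model.biomass_id is not None:
        cm.objective = cm.reactions.get_by_id(model.biomass_id)
    cobra.io.write_sbml_model(cm, str(path))


# ---------------------------------------------------------------------------
# Flat TSV dialect (fixtures / synthetic models)
# ---------------------------------------------------------------------------

_DESIGNATED = ("biomass_id", "ngam_id", "glucose_uptake_id", "oxygen_uptake_id")


def write_tsv_model(model: MetabolicModel, directory: str | Path) -> None:
    """Write reactions.tsv / metabolites.tsv / stoichiometry.tsv (+ designated.tsv)."""
    model.validate()
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "id": r.id,
                "name": r.name,
                "lower_bound": r.lower_bound,
                "upper_bound": r.upper_bound,
                "gpr": r.gpr.to_string() if r.gpr is not None else "",
                "subsystem": r.subsystem,
            }
            for r in model.reactions
        ]
    ).to_csv(d / "reactions.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"id": m.id, "name": m.name, "compartment": m.compartment}
         for m in model.metabolites]
    ).to_csv(d / "metabolites.tsv", sep="\t", index=False)
    pd.DataFrame(model.stoichiometry,
                 columns=["metabolite", "reaction", "coefficient"]
                 ).to_csv(d / "stoichiometry.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"role": k, "reaction": getattr(model, k) or ""} for k in _DESIGNATED]
    ).to_csv(d / "designated.tsv", sep="\t", index=False)


def read_tsv_model(directory: str | Path) -> MetabolicModel:
    d = Path(directory)
    rx = pd.read_csv(d / "reactions.tsv", sep="\t", keep_default_na=False)
    mx = pd.read_csv(d / "metabolites.tsv", sep="\t", keep_default_na=False)
    st = pd.read_csv(d / "stoichiometry.tsv", sep="\t")
    reactions = [
        Reaction(str(row["id"]), str(row["name"]), float(row["lower_bound"]),
                 float(row["upper_bound"]), parse_gpr(str(row["gpr"])),
                 str(row["subsystem"]))
        for _, row in rx.iterrows()
    ]
    metabolites = [
        Metabolite(str(row["id"]), str(row["name"]), str(row["compartment"]))
        for _, row in mx.iterrows()
    ]
    stoich = [
        (str(row["metabolite"]), str(row["reaction"]), float(row["coefficient"]))
        for _, row in st.iterrows()
    ]
    model = MetabolicModel(reactions=reactions, metabolites=metabolites,
                           stoichiometry=stoich, id=d.name)
    desig_path = d / "designated.tsv"
    if desig_path.exists():
        desig = pd.read_csv(desig_path, sep="\t", keep_default_na=False)
        for _, row in desig.iterrows():
            if row["reaction"]:
                setattr(model, str(row["role"]), str(row["reaction"]))
    model.validate()
    return model


def read_id_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV mapping proteomics ids to model gene ids."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ModelFormatError(f"id map {path} needs two columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
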