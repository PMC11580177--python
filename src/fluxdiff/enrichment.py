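"""Over-representation analysis and set-level integration of results.

Gene and metabolite lists produced by the two network analyses are merged
(tagged by source), tested for over-representation against user-supplied GMT
collections with the upper-tail hypergeometric test and Benjamini-Hochberg
FDR, and compared across experiments by directional overlap and
risk-gene cross-referencing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .proteomics import DifferentialResult

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "merge_regulated_lists",
    "ora",
    "overlap_directional",
    "crossref_gene_list",
]


@dataclass
class GeneSetCollection:
    """Named sets from a GMT file plus the union of members as a universe."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def universe(self) -> frozenset[str]:
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Tab-separated GMT: set id, description, then members (deduplicated)."""
    coll = GeneSetCollection()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, desc, *members = fields
            coll.sets[name] = frozenset(m for m in members if m)
            coll.descriptions[name] = desc
    return coll


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name in coll.sets:
            members = "\t".join(sorted(coll.sets[name]))
            fh.write(f"{name}\t{coll.descriptions.get(name, '')}\t{members}\n")


def merge_regulated_lists(
    list_dfba: Iterable[str], list_imat: Iterable[str]
) -> pd.DataFrame:
    """Union of the two lists with a source tag (dfba / imat / both)."""
    a, b = set(list_dfba), set(list_imat)
    rows = []
    for item in sorted(a | b):
        tag = "both" if item in a and item in b else ("dfba" if item in a else "imat")
        rows.append({"id": item, "source": tag})
    return pd.DataFrame(rows, columns=["id", "source"])


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    min_overlap: int = 1,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    p is the upper-tail probability of drawing >= k members of a set of size
    K when sampling n = |query| from a universe of size N; BH adjustment is
    applied across all sets of the collection. A set is ``significant`` when
    FDR < ``fdr_cut`` and the overlap k >= ``min_overlap`` (use 4 for
    metabolite collections). Rows are ordered by p.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    q = set(query)
    dropped = q - uni
    if dropped:
        logger.warning("ora: %d query ids outside the universe dropped",
                       len(dropped))
        q &= uni
    N, n = len(uni), len(q)
    rows = []
    for name, members in collection.sets.items():
        mem = members & uni
        K = len(mem)
        overlap = sorted(q & mem)
        k = len(overlap)
        p = float(hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append({"set": name, "k": k, "K": K, "n": n, "N": N, "p": p,
                     "members": ",".join(overlap)})
    df = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "members"])
    if len(df):
        df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
        df["significant"] = (df["fdr"] < fdr_cut) & (df["k"] >= min_overlap)
        df = df.sort_values(["p", "set"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
        df["significant"] = []
    return df[["set", "k", "K", "n", "N", "p", "fdr", "significant", "members"]]


def _directional_sets(
    diff: DifferentialResult, alpha: float
) -> tuple[set[str], set[str]]:
    sig = diff.significant(alpha)
    down = set(sig.index[sig["logFC"] < 0].astype(str))
    up = set(sig.index[sig["logFC"] > 0].astype(str))
    return down, up


def overlap_directional(
    diff_a: DifferentialResult, diff_b: DifferentialResult, alpha: float = 0.05
) -> pd.DataFrame:
    """Directional overlap of two differential experiments.

    Membership: p < alpha; direction by the sign of logFC. Returns counts of
    shared and exclusive proteins per direction.
    """
    a_down, a_up = _directional_sets(diff_a, alpha)
    b_down, b_up = _directional_sets(diff_b, alpha)
    rows = [
        {"direction": "down", "shared": len(a_down & b_down),
         "a_only": len(a_down - b_down), "b_only": len(b_down - a_down)},
        {"direction": "up", "shared": len(a_up & b_up),
         "a_only": len(a_up - b_up), "b_only": len(b_up - a_up)},
    ]
    return pd.DataFrame(rows, columns=["direction", "shared", "a_only", "b_only"])


def crossref_gene_list(
    diff: DifferentialResult,
    risk_genes: Iterable[str],
    id_map: Optional[Mapping[str, str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Significant proteins whose mapped gene is in a supplied risk-gene list."""
    risk = set(risk_genes)
    sig = diff.significant(alpha)
    rows = []
    unmapped = 0
    for protein, row in sig.iterrows():
        gene = id_map.get(str(protein)) if id_map is not None else str(protein)
        if gene is None:
            unmapped += 1
            continue
        if gene in risk:
            rows.append({
                "protein": str(protein), "gene": gene,
                "logFC": float(row["logFC"]), "P.Value": float(row["P.Value"]),
                "direction": "down" if row["logFC"] < 0 else "up",
            })
    if unmapped:
        logger.warning("crossref_gene_list: %d significant proteins unmapped",
                       unmapped)
    return pd.DataFrame(
        rows, columns=["protein", "gene", "logFC", "P.Value", "direction"])
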