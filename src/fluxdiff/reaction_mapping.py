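"""Map gene-level values onto reactions through GPR rules (AND=min, OR=max).

This is the convention behind COBRA-style expression mapping: an enzyme
complex (AND) is limited by its scarcest subunit, isozymes (OR) by their most
abundant member. Signed values (e.g. log2 fold changes) pass through
unchanged. A reaction whose GPR is empty, or whose GPR cannot be evaluated
because a required gene is unmeasured, receives no score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .model_io import MetabolicModel

__all__ = ["ReactionExpression", "map_expression_to_reactions"]


@dataclass
class ReactionExpression:
    """Reaction scores plus, per reaction, the genes that contributed."""

    scores: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, frozenset[str]] = field(default_factory=dict)

    def __contains__(self, rid: str) -> bool:
        return rid in self.scores

    def __getitem__(self, rid: str) -> float:
        return self.scores[rid]

    def __len__(self) -> int:
        return len(self.scores)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"reaction": rid, "score": s,
             "n_genes_used": len(self.provenance.get(rid, ()))}
            for rid, s in self.scores.items()
        ]
        return pd.DataFrame(rows, columns=["reaction", "score", "n_genes_used"])


def map_expression_to_reactions(
    model: MetabolicModel, gene_values: Mapping[str, float]
) -> ReactionExpression:
    """Evaluate each reaction's GPR over ``gene_values``.

    Unmeasured leaves are ignored inside OR nodes; an AND node requires all
    of its children and is missing otherwise (the strict all-subunits rule).
    Reactions with no GPR or an unevaluable GPR are absent from the result.
    """
    out = ReactionExpression()
    for r in model.reactions:
        if r.gpr is None:
            continue
        val = r.gpr.evaluate(gene_values)
        if val is None:
            continue
        out.scores[r.id] = val
        out.provenance[r.id] = frozenset(
            g for g in r.gpr.genes() if g in gene_values)
    return out
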