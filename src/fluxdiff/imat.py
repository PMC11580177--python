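"""iMAT context-specific model extraction and reaction-activity analysis.

Per sample, reactions are classified by mapped protein abundance against the
25th/75th percentiles of the whole proteome distribution: a MILP then finds a
steady-state flux vector that activates as many high-abundance reactions
(|v| >= v_act) and silences as many low-abundance reactions (|v| <= tol) as
possible, subject to mass balance, model bounds, and mandatory bounds that
keep biomass formation, glucose/oxygen uptake and (relaxed) maintenance ATP
hydrolysis in the model. Low reactions carrying no flux at the optimum are
removed; the binary keep/remove vector per sample is the activity profile.

A reaction is a consensus differential reaction when it is active in every
replicate of one group and inactive in every replicate of the other.
Activity profiles are compared across samples by PCA on the binary matrix
(reactions inactive everywhere dropped, columns centered, SVD).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import Bounds, LinearConstraint, linprog, milp

from .model_io import MetabolicModel, stoich_matrix
from .reaction_mapping import map_expression_to_reactions

__all__ = [
    "MandatoryBounds",
    "ActivityVector",
    "ConsensusResult",
    "InfeasibleModelError",
    "classify_reactions",
    "run_imat",
    "consensus_differential",
    "pca_binary",
]


class InfeasibleModelError(RuntimeError):
    """The model cannot carry the mandatory fluxes."""


@dataclass
class MandatoryBounds:
    """Minimum fluxes that keep essential reactions in every context model.

    Units: biomass in h⁻¹, uptakes and NGAM in mmol g⁻¹ h⁻¹. The NGAM lower
    bound is its measured value reduced by ``ngam_relax_fraction``.
    """

    biomass_min: float = 1e-3
    glucose_uptake_min: float = 1e-4
    oxygen_uptake_min: float = 1e-4
    ngam_value: float = 8.55
    ngam_relax_fraction: float = 0.5

    def __post_init__(self) -> None:
        for name in ("biomass_min", "glucose_uptake_min", "oxygen_uptake_min",
                     "ngam_value"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0.0 <= self.ngam_relax_fraction <= 1.0:
            raise ValueError("ngam_relax_fraction must be in [0, 1]")

    @property
    def ngam_min(self) -> float:
        return (1.0 - self.ngam_relax_fraction) * self.ngam_value

    def lower_bounds(self, model: MetabolicModel) -> dict[str, float]:
        """Mandatory lower bounds keyed by reaction id, for designated
        reactions that exist in the model."""
        out: dict[str, float] = {}
        if model.biomass_id is not None:
            out[model.biomass_id] = self.biomass_min
        if model.glucose_uptake_id is not None:
            out[model.glucose_uptake_id] = self.glucose_uptake_min
        if model.oxygen_uptake_id is not None:
            out[model.oxygen_uptake_id] = self.oxygen_uptake_min
        if model.ngam_id is not None:
            out[model.ngam_id] = self.ngam_min
        return out


@dataclass
class ActivityVector:
    sample: str
    group: str
    activity: dict[str, int] = field(default_factory=dict)

    def active_set(self) -> set[str]:
        return {r for r, a in self.activity.items() if a == 1}


@dataclass
class ConsensusResult:
    gained_in_treatment: set[str] = field(default_factory=set)
    lost_in_treatment: set[str] = field(default_factory=set)

    @property
    def differential(self) -> set[str]:
        return self.gained_in_treatment | self.lost_in_treatment

    def to_frame(self) -> pd.DataFrame:
        rows = [{"reaction": r, "direction": "gained-in-treatment"}
                for r in sorted(self.gained_in_treatment)]
        rows += [{"reaction": r, "direction": "lost-in-treatment"}
                 for r in sorted(self.lost_in_treatment)]
        return pd.DataFrame(rows, columns=["reaction", "direction"])


def classify_reactions(
    model: MetabolicModel,
    sample_abundances: Mapping[str, float],
    q_low: float = 0.25,
    q_high: float = 0.75,
    proteome: Optional[Sequence[float]] = None,
) -> tuple[set[str], set[str]]:
    """Split reactions into high (R_H) and low (R_L) sets for one sample.

    Thresholds are the ``q_low``/``q_high`` quantiles (linear interpolation)
    of the whole protein-abundance distribution — ``proteome`` when given
    (e.g. including proteins outside the model), otherwise the values of
    ``sample_abundances``. Reaction scores come from GPR mapping of the
    abundances; R_H are scored reactions strictly above the upper threshold,
    R_L strictly below the lower one. Unscored reactions stay unclassified.
    """
    if not sample_abundances:
        raise ValueError("empty abundance table")
    if not (0.0 <= q_low < q_high <= 1.0):
        raise ValueError(f"need 0 <= q_low < q_high <= 1 (got {q_low}, {q_high})")
    pool = np.asarray(
        list(sample_abundances.values()) if proteome is None else proteome,
        dtype=float)
    lo_thr = float(np.quantile(pool, q_low))
    hi_thr = float(np.quantile(pool, q_high))
    expr = map_expression_to_reactions(model, sample_abundances)
    r_high = {rid for rid, s in expr.scores.items() if s > hi_thr}
    r_low = {rid for rid, s in expr.scores.items() if s < lo_thr}
    return r_high, r_low


def _feasible(S: sp.spmatrix, lo: np.ndarray, hi: np.ndarray) -> bool:
    res = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lo, hi)), method="highs")
    return res.status == 0


def run_imat(
    model: MetabolicModel,
    r_high: Iterable[str],
    r_low: Iterable[str],
    bounds: Optional[MandatoryBounds] = None,
    v_act: float = 1e-2,
    tol: float = 1e-6,
) -> tuple[dict[str, float], dict[str, int], MetabolicModel]:
    """iMAT MILP for one sample.

    Returns the optimal flux vector, the binary activity vector (0 = removed:
    a low-set reaction with |v| <= tol at the optimum) and the context model
    with removed reactions deleted. The context model is re-solved under the
    mandatory bounds to confirm feasibility.
    """
    model.validate()
    r_high, r_low = set(r_high), set(r_low)
    if r_high & r_low:
        raise ValueError(f"R_H and R_L overlap: {sorted(r_high & r_low)}")
    rids = model.reaction_ids
    ridx = {r: j for j, r in enumerate(rids)}
    for rid in (r_high | r_low) - set(rids):
        raise KeyError(f"classified reaction {rid!r} not in model")
    n = len(rids)
    S = stoich_matrix(model).tocsc()
    lo = np.array([r.lower_bound for r in model.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if bounds is not None:
        for rid, mlb in bounds.lower_bounds(model).items():
            lo[ridx[rid]] = max(lo[ridx[rid]], mlb)
    bad = np.nonzero(lo > hi)[0]
    if bad.size:
        raise InfeasibleModelError(
            f"mandatory bound exceeds upper bound for {rids[bad[0]]!r}")
    if not _feasible(S, lo, hi):
        raise InfeasibleModelError(
            "mandatory bounds are infeasible in the full model")

    hi_list = sorted(r_high)
    lo_list = sorted(r_low)
    nh, nl = len(hi_list), len(lo_list)
    nv = n + 2 * nh + nl  # v, yf, yb, z
    rows, cols, data, c_lo, c_ub = [], [], [], [], []

    def add_row(entries: list[tuple[int, float]], lb: float, ub: float) -> None:
        i = len(c_lo)
        for j, a in entries:
            rows.append(i); cols.append(j); data.append(a)
        c_lo.append(lb); c_ub.append(ub)

    for i, rid in enumerate(hi_list):
        j = ridx[rid]
        yf, yb = n + i, n + nh + i
        # yf=1 -> v_j >= v_act ; yb=1 -> v_j <= -v_act
        add_row([(j, 1.0), (yf, -(v_act - lo[j]))], lo[j], np.inf)
        add_row([(j, 1.0), (yb, hi[j] + v_act)], -np.inf, hi[j])
        add_row([(yf, 1.0), (yb, 1.0)], 0.0, 1.0)
    for i, rid in enumerate(lo_list):
        j = ridx[rid]
        z = n + 2 * nh + i
        # z=1 -> |v_j| <= tol
        add_row([(j, 1.0), (z, hi[j] - tol)], -np.inf, hi[j])
        add_row([(j, 1.0), (z, lo[j] + tol)], lo[j], np.inf)

    A_side = sp.csr_matrix((data, (rows, cols)), shape=(len(c_lo), nv)) \
        if c_lo else None
    A_steady = sp.hstack([S, sp.csr_matrix((S.shape[0], nv - n))])
    obj = np.zeros(nv)
    obj[n:] = -1.0
    integrality = np.zeros(nv)
    integrality[n:] = 1
    var_lo = np.concatenate([lo, np.zeros(nv - n)])
    var_hi = np.concatenate([hi, np.ones(nv - n)])
    constraints = [LinearConstraint(A_steady, 0.0, 0.0)]
    if A_side is not None:
        constraints.append(
            LinearConstraint(A_side, np.array(c_lo), np.array(c_ub)))
    res = milp(obj, constraints=constraints,
               bounds=Bounds(var_lo, var_hi), integrality=integrality)
    if res.status != 0:
        raise RuntimeError(f"iMAT MILP failed: {res.message}")
    v = res.x[:n]
    flux = {rid: float(v[ridx[rid]]) for rid in rids}

    # 1e-7 feasibility slack: an optimal silenced flux sits at the tol
    # boundary up to solver round-off
    removed = {rid for rid in lo_list if abs(flux[rid]) <= tol + 1e-7}
    activity = {rid: (0 if rid in removed else 1) for rid in rids}

    context = model.copy()
    context.reactions = [r for r in context.reactions if r.id not in removed]
    context.stoichiometry = [
        (mid, rid, c) for mid, rid, c in context.stoichiometry
        if rid not in removed]
    for attr in ("biomass_id", "ngam_id", "glucose_uptake_id",
                 "oxygen_uptake_id"):
        if getattr(context, attr) in removed:
            setattr(context, attr, None)
    context.id = f"{model.id}_context"

    keep = [ridx[r.id] for r in context.reactions]
    if keep and not _feasible(S[:, keep], lo[keep], hi[keep]):
        raise RuntimeError("context model infeasible under mandatory bounds")
    return flux, activity, context


def imat_objective_from_flux(
    flux: Mapping[str, float],
    r_high: Iterable[str],
    r_low: Iterable[str],
    v_act: float = 1e-2,
    tol: float = 1e-6,
    feastol: float = 1e-7,
) -> int:
    """Recount the iMAT objective from a flux vector.

    ``feastol`` absorbs solver round-off at the activation/silencing
    boundaries (an optimal v sits exactly at v_act up to LP feasibility
    tolerance).
    """
    n_hi = sum(1 for r in r_high if abs(flux[r]) >= v_act - feastol)
    n_lo = sum(1 for r in r_low if abs(flux[r]) <= tol + feastol)
    return n_hi + n_lo


def consensus_differential(
    control: Sequence[ActivityVector], treatment: Sequence[ActivityVector]
) -> ConsensusResult:
    """Unanimity rule: differential iff active in every replicate of one
    group and inactive in every replicate of the other."""
    if not control or not treatment:
        raise ValueError("need at least one activity vector per group")
    universe = set(control[0].activity)
    for av in list(control) + list(treatment):
        if set(av.activity) != universe:
            raise ValueError(
                f"sample {av.sample!r} has a mismatched reaction set")
    res = ConsensusResult()
    for rid in universe:
        c = [av.activity[rid] for av in control]
        t = [av.activity[rid] for av in treatment]
        if all(x == 1 for x in t) and all(x == 0 for x in c):
            res.gained_in_treatment.add(rid)
        elif all(x == 0 for x in t) and all(x == 1 for x in c):
            res.lost_in_treatment.add(rid)
    return res


def pca_binary(
    vectors: Sequence[ActivityVector],
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of binary activity profiles.

    Reactions inactive in every sample are dropped; the remaining sample x
    reaction 0/1 matrix is column-centered and decomposed by SVD. Returns
    per-sample scores on the principal components and the explained-variance
    fractions.
    """
    if len(vectors) < 2:
        raise ValueError("PCA needs at least 2 samples")
    universe = sorted(vectors[0].activity)
    for av in vectors:
        if sorted(av.activity) != universe:
            raise ValueError(f"sample {av.sample!r} has a mismatched reaction set")
    X = np.array([[av.activity[r] for r in universe] for av in vectors],
                 dtype=float)
    keep = X.any(axis=0)
    X = X[:, keep]
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    ncomp = min(len(vectors) - 1, Xc.shape[1])
    scores = U[:, :ncomp] * s[:ncomp]
    total = float((s ** 2).sum())
    explained = (s[:ncomp] ** 2 / total) if total > 0 else np.zeros(ncomp)
    df = pd.DataFrame(
        scores, index=[av.sample for av in vectors],
        columns=[f"PC{i+1}" for i in range(ncomp)])
    return df, explained
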