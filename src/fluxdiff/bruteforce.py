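"""Exhaustive-enumeration oracles for the MILP stages.

These deliberately avoid the MILP formulations in :mod:`fluxdiff.delta_fba`
and :mod:`fluxdiff.imat`: each candidate consistency/activity assignment is
checked by a plain LP feasibility solve and the best feasible count is taken
by enumeration. On networks with few classified reactions this gives the
exact optimum by construction and serves as an independent check of the
big-M formulations.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .imat import MandatoryBounds
from .model_io import MetabolicModel, stoich_matrix

__all__ = ["enumerate_dfba_stage1", "enumerate_imat_objective",
           "random_oracle_network"]

_ENUM_LIMIT = 16


def _lp_feasible(S, lo, hi, extra_lo=None, extra_hi=None) -> bool:
    lo = np.array(lo, dtype=float)
    hi = np.array(hi, dtype=float)
    if extra_lo:
        for j, v in extra_lo.items():
            lo[j] = max(lo[j], v)
    if extra_hi:
        for j, v in extra_hi.items():
            hi[j] = min(hi[j], v)
    if np.any(lo > hi):
        return False
    res = linprog(np.zeros(S.shape[1]), A_eq=S, b_eq=np.zeros(S.shape[0]),
                  bounds=list(zip(lo, hi)), method="highs")
    return res.status == 0


def enumerate_dfba_stage1(
    model: MetabolicModel,
    changes: Mapping[str, float],
    epsilon: float = 0.5,
) -> int:
    """Maximum number of simultaneously sign-consistent scored reactions.

    Enumerates subsets of the scored reactions in decreasing size and
    returns the size of the first subset whose consistency constraints
    (sign(c_j)·Δv_j >= ε·w_j) are jointly feasible with S·Δv = 0, the Δv
    bounds and Δv = 0 on the NGAM reaction.
    """
    rids = model.reaction_ids
    ridx = {r: j for j, r in enumerate(rids)}
    scored = [(rid, c) for rid, c in sorted(changes.items()) if c != 0.0]
    if len(scored) > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to {_ENUM_LIMIT} scored reactions")
    if not scored:
        return 0
    wmax = max(abs(c) for _, c in scored)
    S = stoich_matrix(model)
    lo = np.array([r.lower_bound - r.upper_bound for r in model.reactions], dtype=float)
    hi = np.array([r.upper_bound - r.lower_bound for r in model.reactions], dtype=float)
    if model.ngam_id is not None:
        j = ridx[model.ngam_id]
        lo[j] = hi[j] = 0.0
    for size in range(len(scored), -1, -1):
        for subset in combinations(range(len(scored)), size):
            extra_lo, extra_hi = {}, {}
            for i in subset:
                rid, c = scored[i]
                thr = epsilon * abs(c) / wmax
                if c > 0:
                    extra_lo[ridx[rid]] = thr
                else:
                    extra_hi[ridx[rid]] = -thr
            if _lp_feasible(S, lo, hi, extra_lo, extra_hi):
                return size
    return 0


def enumerate_imat_objective(
    model: MetabolicModel,
    r_high: Iterable[str],
    r_low: Iterable[str],
    bounds: Optional[MandatoryBounds] = None,
    v_act: float = 1e-2,
    tol: float = 1e-6,
) -> int:
    """Maximum iMAT objective by enumeration over activity assignments.

    Only irreversible networks (all lower bounds >= 0) are supported, so
    "active" for a high reaction is unambiguously v >= v_act and each
    assignment is a single LP.
    """
    if any(r.lower_bound < 0 for r in model.reactions):
        raise ValueError("enumeration oracle requires an irreversible network")
    rids = model.reaction_ids
    ridx = {r: j for j, r in enumerate(rids)}
    hi_list, lo_list = sorted(set(r_high)), sorted(set(r_low))
    k = len(hi_list) + len(lo_list)
    if k > _ENUM_LIMIT:
        raise ValueError(f"enumeration limited to {_ENUM_LIMIT} classified reactions")
    S = stoich_matrix(model)
    lo = np.array([r.lower_bound for r in model.reactions], dtype=float)
    hi = np.array([r.upper_bound for r in model.reactions], dtype=float)
    if bounds is not None:
        for rid, mlb in bounds.lower_bounds(model).items():
            lo[ridx[rid]] = max(lo[ridx[rid]], mlb)
    items = [(rid, "high") for rid in hi_list] + [(rid, "low") for rid in lo_list]
    for size in range(k, -1, -1):
        for subset in combinations(range(k), size):
            extra_lo, extra_hi = {}, {}
            ok = True
            for i in subset:
                rid, kind = items[i]
                j = ridx[rid]
                if kind == "high":
                    extra_lo[j] = v_act
                else:
                    extra_hi[j] = tol
                if extra_lo.get(j, lo[j]) > extra_hi.get(j, hi[j]):
                    ok = False
                    break
            if ok and _lp_feasible(S, lo, hi, extra_lo, extra_hi):
                return size
    return 0


def random_oracle_network(
    seed: int,
    n_metabolites: int = 4,
    n_internal: int = 6,
    n_classified: int = 5,
) -> tuple[MetabolicModel, dict[str, float], list[str], list[str]]:
    """Small random irreversible network with random scores/classification.

    Every metabolite gets an in- and an out-exchange, internal reactions
    connect random metabolite pairs; v = 0 (and Δv = 0) is always feasible.
    Returns (model, scores, R_H, R_L) where scores are signed reaction
    scores for the ΔFBA oracle and R_H/R_L a disjoint classification for
    the iMAT oracle over the same reaction subset.
    """
    from .model_io import Metabolite, Reaction

    rng = np.random.default_rng(seed)
    mets = [Metabolite(f"m{i}") for i in range(n_metabolites)]
    reactions, stoich = [], []
    for i in range(n_metabolites):
        reactions.append(Reaction(f"in_m{i}", lower_bound=0.0, upper_bound=10.0))
        stoich.append((f"m{i}", f"in_m{i}", 1.0))
        reactions.append(Reaction(f"out_m{i}", lower_bound=0.0, upper_bound=10.0))
        stoich.append((f"m{i}", f"out_m{i}", -1.0))
    for t in range(n_internal):
        a, b = rng.choice(n_metabolites, size=2, replace=False)
        rid = f"r{t}"
        reactions.append(Reaction(rid, lower_bound=0.0, upper_bound=10.0))
        stoich.append((f"m{a}", rid, -float(rng.integers(1, 3))))
        stoich.append((f"m{b}", rid, float(rng.integers(1, 3))))
    model = MetabolicModel(reactions=reactions, metabolites=mets,
                           stoichiometry=stoich, id=f"oracle_{seed}")
    model.validate()

    rids = model.reaction_ids
    chosen = rng.choice(len(rids), size=min(n_classified, len(rids)),
                        replace=False)
    scores = {rids[j]: float(rng.choice([-1.0, 1.0]) * rng.uniform(0.5, 2.0))
              for j in chosen}
    half = len(chosen) // 2
    r_high = [rids[j] for j in chosen[:half]]
    r_low = [rids[j] for j in chosen[half:]]
    return model, scores, r_high, r_low
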