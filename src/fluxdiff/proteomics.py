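"""TMT reporter processing and empirical-Bayes moderated differential abundance.

The quantitative unit is reporter-ion signal-to-noise (S/N). Processing
follows the standard TMT workflow: peptides with summed S/N below a floor
(default 180 across all channels) are discarded, peptide S/N is summed to
protein level, and channels are scaled so every channel's total signal is
equal (equal protein loading).

Differential abundance between two groups uses a moderated t-statistic: per
protein, an ordinary two-group fit on log2 values; the residual variances
s² (d degrees of freedom each) are then shrunk toward a prior s₀²(ā) that may
depend on average log2 abundance ā through a locally weighted trend
("limma-trend"). The prior degrees of freedom d₀ and the prior scale are
estimated by method of moments on log s², using the identities
E[log s²] = log σ² + ψ(d/2) − log(d/2) and Var[log s²] = ψ′(d/2) for a scaled
chi-square, so that s̃² = (d₀ s₀² + d s²)/(d₀ + d) and the moderated
t = logFC / (s̃ √(1/n₁ + 1/n₂)) has d + d₀ degrees of freedom. The robust
(winsorized) variant of the hyperparameter estimation is intentionally not
implemented; plain moments estimation is used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import t as t_dist
from statsmodels.nonparametric.smoothers_lowess import lowess

logger = logging.getLogger(__name__)

__all__ = [
    "AbundanceMatrix",
    "DifferentialResult",
    "read_peptide_table",
    "read_design",
    "filter_peptides",
    "rollup_and_normalize",
    "moderated_diff",
    "select_gene_fold_changes",
    "dedupe_abundances",
]

PEPTIDE_KEY_COLS = ("peptide", "protein")


def read_peptide_table(path: str | Path) -> pd.DataFrame:
    """Peptide TSV: columns ``peptide``, ``protein``, then one S/N per channel."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEPTIDE_KEY_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"peptide table lacks columns {missing}")
    return df


def read_design(path: str | Path) -> dict[str, str]:
    """Design TSV with columns ``sample`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["sample"], df["group"]))


def _channel_cols(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c not in PEPTIDE_KEY_COLS]


def filter_peptides(table: pd.DataFrame, min_sn: float = 180.0) -> pd.DataFrame:
    """Keep peptides whose S/N summed across all channels is >= ``min_sn``."""
    chans = _channel_cols(table)
    if not chans:
        return table.copy()
    total = table[chans].sum(axis=1)
    return table.loc[total >= min_sn].reset_index(drop=True)


@dataclass
class AbundanceMatrix:
    """Protein x sample signal matrix with an optional sample->group design."""

    values: pd.DataFrame
    design: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.isna().any().any():
            raise ValueError("abundance matrix contains missing cells")
        for s in self.design:
            if s not in self.values.columns:
                raise ValueError(f"design sample {s!r} not in matrix columns")

    @property
    def proteins(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def group_samples(self, group: str) -> list[str]:
        return [s for s, g in self.design.items() if g == group]


def rollup_and_normalize(
    table: pd.DataFrame, design: Optional[Mapping[str, str]] = None
) -> AbundanceMatrix:
    """Sum peptide S/N to proteins, then equalize channel totals.

    Each channel is scaled so that all channel sums equal the mean of the
    raw channel sums; within-channel ratios are preserved.
    """
    chans = _channel_cols(table)
    protein = table.groupby("protein", sort=True)[chans].sum()
    col_sums = protein.sum(axis=0)
    zero = col_sums[col_sums == 0]
    if len(zero):
        raise ValueError(f"channel(s) with zero total signal: {list(zero.index)}")
    target = col_sums.mean()
    normalized = protein * (target / col_sums)
    return AbundanceMatrix(normalized, dict(design) if design else {})


# ---------------------------------------------------------------------------
# Moderated differential abundance
# ---------------------------------------------------------------------------

@dataclass
class DifferentialResult:
    """Per-protein moderated two-group statistics.

    ``table`` is indexed by protein with columns ``logFC`` (treatment minus
    control, log2), ``AveExpr``, ``s2`` (residual variance), ``s2_prior``,
    ``s2_post``, ``t`` (moderated) and ``P.Value``. ``df_residual`` is the
    per-protein residual df d, ``df_prior`` the estimated d₀.
    """

    table: pd.DataFrame
    df_residual: float
    df_prior: float
    contrast: tuple[str, str]

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["P.Value"] < alpha]

    def to_tsv(self, path: str | Path) -> None:
        out = self.table.reset_index().rename(columns={"index": "protein"})
        cols = ["protein", "logFC", "AveExpr", "t", "P.Value", "s2.post"]
        out = out.rename(columns={"s2_post": "s2.post"})[cols]
        out.to_csv(path, sep="\t", index=False)


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if abs(dif) / y < 1e-10:
            break
    return float(y)


def _fit_scaled_f(
    s2: np.ndarray, df1: float, covariate: Optional[np.ndarray], span: float
) -> tuple[float, np.ndarray]:
    """Moments fit of the variance prior: returns (d0, s0² per protein).

    log s² is modelled as log s₀² + (log chi²_d/d); the mean (possibly a
    lowess trend in the covariate) gives the prior scale and the excess
    variance of the residuals over trigamma(d/2) gives d₀ via the trigamma
    inverse.
    """
    z = np.log(s2)
    e = z - digamma(df1 / 2.0) + np.log(df1 / 2.0)
    if covariate is None:
        emean = np.full_like(e, e.mean())
    else:
        emean = lowess(e, covariate, frac=span, return_sorted=False)
    n = len(e)
    if n < 2:
        return np.inf, np.exp(emean)
    evar = np.sum((e - emean) ** 2) / (n - 1) - float(polygamma(1, df1 / 2.0))
    if evar > 0:
        df2 = 2.0 * _trigamma_inverse(evar)
        s20 = np.exp(emean + digamma(df2 / 2.0) - np.log(df2 / 2.0))
    else:
        df2 = np.inf
        s20 = np.exp(emean)
    return df2, s20


_ZERO_VAR = 1e-15


def moderated_diff(
    matrix: AbundanceMatrix,
    design: Optional[Mapping[str, str]] = None,
    contrast: tuple[str, str] = ("control", "treatment"),
    trend: bool = True,
    span: float = 0.5,
    prior_df: Optional[float] = None,
) -> DifferentialResult:
    """Two-group moderated t-test on log2 abundances.

    Parameters
    ----------
    contrast:
        ``(control_group, treatment_group)``; logFC is treatment minus control.
    trend:
        Fit the variance prior as a lowess trend in average log2 abundance
        instead of a constant.
    prior_df:
        Override the estimated prior degrees of freedom d₀ (0 recovers the
        ordinary pooled t; ``numpy.inf`` shrinks every variance fully to the
        trend).
    """
    design = dict(design) if design is not None else matrix.design
    ctrl, treat = contrast
    c_samples = [s for s, g in design.items() if g == ctrl]
    t_samples = [s for s, g in design.items() if g == treat]
    if len(c_samples) < 2 or len(t_samples) < 2:
        raise ValueError(
            f"each group needs >=2 samples (got {len(c_samples)} {ctrl!r}, "
            f"{len(t_samples)} {treat!r})")
    vals = matrix.values[c_samples + t_samples]
    if (vals <= 0).any().any():
        raise ValueError("abundances must be strictly positive for log2")
    log2m = np.log2(vals.to_numpy(dtype=float))
    n1, n2 = len(c_samples), len(t_samples)
    xc, xt = log2m[:, :n1], log2m[:, n1:]
    mean_c, mean_t = xc.mean(axis=1), xt.mean(axis=1)
    logfc = mean_t - mean_c
    ave = log2m.mean(axis=1)
    d = n1 + n2 - 2
    rss = ((xc - mean_c[:, None]) ** 2).sum(axis=1) + \
          ((xt - mean_t[:, None]) ** 2).sum(axis=1)
    s2 = rss / d
    se_factor = 1.0 / n1 + 1.0 / n2

    if np.all(s2 <= _ZERO_VAR):
        # noise-free degenerate limit: zero variance everywhere; fold
        # changes at floating-point round-off (from the normalization
        # arithmetic) are genuinely null
        null = np.abs(logfc) <= 1e-8
        tstat = np.where(null, 0.0, np.where(logfc > 0, np.inf, -np.inf))
        pval = np.where(null, 1.0, 0.0)
        tab = pd.DataFrame(
            {"logFC": logfc, "AveExpr": ave, "s2": s2, "s2_prior": 0.0,
             "s2_post": 0.0, "t": tstat, "P.Value": pval},
            index=vals.index)
        return DifferentialResult(tab, float(d), 0.0, contrast)

    s2_fit = np.maximum(s2, _ZERO_VAR)
    d0, s20 = _fit_scaled_f(s2_fit, d, ave if trend else None, span)
    if prior_df is not None:
        d0 = float(prior_df)
    if np.isinf(d0):
        s2_post = s20.copy()
        df_total = 1e6
    else:
        s2_post = (d0 * s20 + d * s2) / (d0 + d)
        df_total = d + d0
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = logfc / np.sqrt(s2_post * se_factor)
    tstat = np.where((logfc == 0.0) & ~np.isfinite(tstat), 0.0, tstat)
    pval = np.where(
        np.isfinite(tstat), 2.0 * t_dist.sf(np.abs(tstat), df_total), 0.0)
    pval = np.where(tstat == 0.0, 1.0, pval)

    tab = pd.DataFrame(
        {"logFC": logfc, "AveExpr": ave, "s2": s2, "s2_prior": s20,
         "s2_post": s2_post, "t": tstat, "P.Value": pval},
        index=vals.index)
    return DifferentialResult(tab, float(d), float(d0), contrast)


def select_gene_fold_changes(
    result: DifferentialResult,
    alpha: float = 0.05,
    id_map: Optional[Mapping[str, str]] = None,
    strategy: str = "min_p",
) -> dict[str, float]:
    """One log2 fold change per gene from the significant proteins.

    Proteins with p >= ``alpha`` are dropped. When several measurements map
    to the same gene, ``"min_p"`` keeps the most significant one and
    ``"max_mean"`` the one with the highest average log2 abundance. Protein
    ids absent from ``id_map`` are skipped (count logged).
    """
    if strategy not in ("min_p", "max_mean"):
        raise ValueError(f"unknown strategy {strategy!r}")
    sig = result.significant(alpha)
    out: dict[str, float] = {}
    best: dict[str, float] = {}
    unmapped = 0
    for protein, row in sig.iterrows():
        gene = id_map.get(str(protein)) if id_map is not None else str(protein)
        if gene is None:
            unmapped += 1
            continue
        key = row["P.Value"] if strategy == "min_p" else -row["AveExpr"]
        if gene not in out or key < best[gene]:
            out[gene] = float(row["logFC"])
            best[gene] = key
    if unmapped:
        logger.warning("select_gene_fold_changes: %d significant proteins "
                       "had no gene mapping and were skipped", unmapped)
    return out


def dedupe_abundances(
    matrix: AbundanceMatrix,
    id_map: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Collapse duplicate protein measurements to one row per gene.

    Keeps, for each gene, the measurement with the maximum average signal
    across samples. Returns a gene x sample DataFrame. Proteins without a
    mapping are dropped.
    """
    vals = matrix.values
    means = vals.mean(axis=1)
    best: dict[str, float] = {}
    chosen: dict[str, str] = {}
    for protein in vals.index:
        gene = id_map.get(str(protein)) if id_map is not None else str(protein)
        if gene is None:
            continue
        m = float(means.loc[protein])
        if gene not in best or m > best[gene]:
            best[gene] = m
            chosen[gene] = protein
    genes = sorted(chosen)
    keep_rows = [chosen[g] for g in genes]
    out = vals.loc[keep_rows].copy()
    out.index = pd.Index(genes, name="gene")
    return out
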