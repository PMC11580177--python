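# Methods

This note documents the models, estimators, numerical choices and
limitations behind `fluxdiff`, in the order data flows through the
pipeline.

## TMT reporter processing

The quantitative unit is reporter-ion signal-to-noise (S/N). Peptides are
kept when their S/N summed over *all* channels is ≥ `min_sn` (default 180;
the comparison is `>=`, so a row summing to exactly 180.0 is kept).
Protein signal is the sum of its peptides' S/N per channel. Normalization
scales each channel by (mean of raw channel totals)/(channel total), so all
channel totals become equal while within-channel ratios are untouched. A
channel with zero total signal is an error naming the channel. No
missing-value imputation and no isotopic-impurity correction are performed;
the input table is expected to be complete and already corrected.

## Moderated differential abundance

Two groups, each with ≥ 2 samples; values are log2-transformed without a
pseudocount (they are positive by construction after normalization). Per
protein: group means give logFC (treatment − control), the pooled
within-group sum of squares gives the residual variance s² on
d = n₁ + n₂ − 2 degrees of freedom.

The empirical-Bayes step models s² as scaled-F around a prior s₀² with d₀
prior degrees of freedom and uses plain method-of-moments estimation on
z = log s²: with e = z − ψ(d/2) + log(d/2), the prior location is the mean
of e (trend off) or a lowess fit of e on average log2 abundance with span
0.5 (trend on, the default); the excess of Var(e) over ψ′(d/2) determines
d₀ through the trigamma inverse (Newton iteration, relative tolerance
1e-10); then s̃² = (d₀s₀² + ds²)/(d₀ + d), t = logFC/(s̃·√(1/n₁+1/n₂)),
two-sided p from t with d + d₀ df (d₀ = ∞ handled as 10⁶ df). With the
constant prior this reproduces Bioconductor limma's `eBayes(trend=FALSE,
robust=FALSE)` to ~1e-14 (a frozen cross-check in the test suite); with the
trend the two lowess implementations differ in detail, and agreement is
checked loosely. The robust (winsorized) variant of the hyperparameter
estimation is deliberately not implemented: it changes no testable quantity
here and the moments estimator is closed-form checkable. `prior_df`
overrides d₀ for diagnostics (0 → ordinary pooled t; ∞ → full shrinkage to
the trend).

Degenerate noise-free limit: when every s² is numerically zero the scaled-F
machinery is undefined; the implementation then reports p = 0 for
|logFC| > 1e-8 and p = 1 otherwise. The 1e-8 floor exists because channel
rescaling introduces round-off of order 1e-15 into mathematically-zero fold
changes.

Duplicate measurements are resolved to one value per gene by either
`min_p` (most significant measurement; default for the ΔFBA branch) or
`max_mean` (highest average abundance; used for the iMAT abundance branch).
Both are exposed because the selection rule is a genuine free choice of the
workflow.

## GPR mapping

AND = min, OR = max, signed values passed through unchanged. An AND node
with any unmeasured child is unscored (the strict all-subunits rule; tool
implementations differ here and the strict rule is the conservative
choice); unmeasured OR children are ignored. Reactions with empty or
unevaluable GPRs receive no score. The mapping is monotone in every gene
value (property-tested).

## ΔFBA

Variables Δv with S·Δv = 0, Δv_j ∈ [lb_j − ub_j, ub_j − lb_j] (the widest
difference of two feasible flux vectors — boundaries are otherwise not
constrained), and Δv = 0 for the NGAM reaction. Scored reactions carry
weights w_j = |c_j|/max|c| ≤ 1; a score of exactly 0 makes the consistency
condition vacuous and such reactions are treated as unscored.

Stage 1 maximizes Σy_j where the binary y_j = 1 enforces
sign(c_j)·Δv_j ≥ ε·w_j via big-M rows with M_j = span_j + ε·w_j + 1 (the
smallest M that keeps the constraint vacuous at y = 0 plus unit slack).
Ties between mutually exclusive consistency choices are broken toward the
larger weight and then the earlier reaction id by a perturbation of
magnitude ≤ 1.5e-6 per binary added to the objective — small enough never
to change the integer count for realistic problem sizes. Stage 2 fixes the
stage-1 assignment y\* (not merely its count: fixing the assignment makes
the reported consistency vector and the L1 field deterministic together)
and minimizes Σ|Δv_j| over unscored reactions via nonnegative splits; this
is a pure LP. Whether the original formulation minimizes L1 over all or
only unscored reactions is ambiguous; only-unscored is implemented, so
consistent scored reactions are free to take the magnitude the steady-state
constraint demands. Differential membership uses |Δv| ≥ 1e-6 (numerical
zero for double-precision LP). Δv = 0 is always feasible, so the MILP
cannot be infeasible on a valid model. Stage-1 optima are verified against
exhaustive enumeration (subset LPs) on random networks.

## iMAT activity analysis

Classification thresholds are the 25th/75th percentiles (linear
interpolation) of the whole proteome distribution of the sample — including
proteins outside the model — not of the reaction scores; comparisons are
strict. The per-sample table is used (a pooled-thresholds variant is a
caller choice: pass the pooled vector as `proteome`).

The MILP maximizes activations plus silencings with per-reaction binaries:
forward/backward activation binaries for R_H (v ≥ v_act or v ≤ −v_act;
v_act = 1e-2 by default — the activation flux is a free parameter of iMAT,
not a reported constant) and a silencing binary for R_L (|v| ≤ tol,
tol = 1e-6). Mandatory bounds are applied as lower bounds before solving:
biomass ≥ 1e-3 h⁻¹, glucose and oxygen uptake ≥ 1e-4 mmol g⁻¹ h⁻¹ (uptake
exchanges are written so that uptake is positive flux), NGAM ≥
(1 − 0.5)·8.55 = 4.275 mmol ATP g⁻¹ h⁻¹. Infeasibility of these bounds in
the full model is detected by an LP before the MILP and is a hard error.

Activity semantics: a reaction is removed (0) iff it is in R_L and carries
|v| ≤ tol at the optimum; all other reactions — including unclassified
ones — are kept (1). The context model is the input model minus removed
reactions and is re-solved under the mandatory bounds as a feasibility
check. Optimal fluxes sit exactly at the v_act/tol boundaries up to solver
round-off, so recounting uses a 1e-7 feasibility slack. Alternate MILP
optima can flip individual activities; mitigation is the deterministic
single-threaded HiGHS configuration plus the unanimity consensus rule,
which requires agreement across all replicates of both groups.

Consensus: differential iff activity is 1 in every replicate of one group
and 0 in every replicate of the other, with direction
(gained/lost-in-treatment). PCA drops reactions inactive in all samples,
column-centers the binary matrix and decomposes by SVD; explained-variance
fractions are the squared singular values over their total.

## Enrichment and integration

Over-representation p is the upper-tail hypergeometric probability of ≥ k
overlaps between the query and a set, computed against a caller-supplied
universe (for gene lists: model genes with measured proteins). BH
adjustment runs within a collection, not across collections. Significance
requires FDR < 0.05 and k ≥ min_overlap (1 for genes, 4 for metabolite
sets). Enrichment backends are deliberately file-based (GMT in, TSV out) so
results do not depend on web-service versions. Query members outside the
universe are dropped with a logged count.

## Synthetic data: what it emulates and what it does not

`make_toy_model(n_branches, branch_length)` builds glucose/oxygen uptake
exchanges, `n_branches` parallel irreversible chains from glucose to a
biomass precursor (one gene per reaction, with one isozyme OR pair and one
two-subunit AND complex per branch), an ATP-generation/maintenance pair and
a biomass assembly/sink, all bounded [0, 1000]. Any single branch sustains
biomass, so one branch (seed-chosen) can be planted off; its genes carry
the planted log2FC (−2 by default, a strong knock-down). Generation
verifies by LP that the mandatory bounds are feasible both with and without
the off-branch.

Defaults define the study conditions: 2 branches × 5 steps, 3 channels per
group, σ = 0.2, 20% duplicated proteins, 200 background proteins. The
defaults are chosen so the synthetic data exhibits the qualitative features
the pipeline must cope with: background baselines ~N(10, 1.5) on the log2
scale dominate the whole-proteome quartiles; model-gene baselines sit in a
narrow mid-band (N(10, 0.25)) as expected for central-metabolism enzymes,
comfortably between the quartiles, so a −2 knock-down crosses the lower
quartile decisively; noise sd follows a declared decreasing trend in
baseline abundance, sd = σ·clip(1.6 − 0.12·(ā − 8), 0.4, 2.5), which the
trend estimator must track; branch length 5 exceeds the 4-reaction
uptake/biomass path, so ΔFBA's stage-2 parsimony attributes a branch
knock-down to the gene-less exchange path rather than inventing flux
through the intact branch. Peptides split protein signal by Dirichlet
shares (2–5 per protein), with ~30% of proteins carrying a trace peptide
below the S/N filter; shares apply per channel, so filtering is
ratio-preserving by construction. One synthetic loading-control protein
(`LOADCTRL`) equalizes the post-filter channel totals exactly, emulating
the equal-loading assumption that channel-sum normalization relies on.

What the generator does not emulate — and hence what green tests do not
show about real data: raw spectra and search-engine effects, isotopic
impurity leakage between channels, missing values, ratio compression from
co-isolation, compositionally large effects that violate the equal-loading
assumption, reversible reactions, and models at genome scale (the SBML
reader and both MILPs are exercised at genome scale only if a user supplies
such a model).

## Problem sizes and verification

All shipped analyses run on toy networks (~16 reactions) and simulated
proteomes (~220–450 proteins); the acceptance script checks 25 random
networks against exhaustive enumeration (≤ 7 classified reactions each,
2^k subset LPs with early exit), one noise-free bundle for exact recovery,
20 noisy replicate experiments for consensus recall, and one 200-protein
null experiment for type-I calibration. These sizes keep a full
verification run within seconds while every combinatorial check remains
exact.

## Known limitations

- The robust empirical-Bayes variant (`robust=TRUE` in limma's vocabulary)
  is not implemented; heavy-tailed variance outliers will pull the moments
  estimate of d₀.
- ΔFBA's stage-2 parsimony is one of several defensible secondary
  objectives; conclusions about *which* unscored reactions carry the
  compensating flux depend on it.
- iMAT solutions are not unique in general; only the unanimity consensus
  is reported as a finding, single-sample activity vectors are
  diagnostics.
- The percentile-classification contract assumes abundances on a common
  scale across samples, which the equal-channel-sum normalization provides
  for TMT but which does not transfer to label-free inputs without prior
  normalization.
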