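# fluxdiff

Proteome-guided differential metabolism on genome-scale metabolic models.

Quantitative proteomics can say which enzymes changed between two
conditions; a constraint-based metabolic model can say what those changes
mean for flux. `fluxdiff` connects the two for a standard two-group TMT
(tandem mass tag) experiment: it processes reporter-ion signal-to-noise to
moderated differential abundance, maps protein-level changes onto reactions
through gene–protein–reaction (GPR) rules, and identifies *differential
reactions* by two complementary network analyses — ΔFBA and iMAT-based
reaction-activity analysis — whose gene and metabolite lists are merged and
tested by over-representation analysis. It is aimed at systems-biology
practitioners who have a protein × sample table, an SBML model, and a
sample→group design.

## The methods

**TMT processing.** Peptides with summed signal-to-noise (S/N) below 180
across all channels are discarded; peptide S/N is summed per protein;
channels are scaled so every channel total is equal (equal protein
loading).

**Moderated differential abundance.** Per protein, an ordinary two-group
fit on log2 abundances gives a fold change logFC, residual variance s² and
d residual degrees of freedom. Variances are shrunk toward a prior
s₀²(ā) — a lowess trend in average log2 abundance ā — with prior degrees of
freedom d₀ estimated by method of moments from log s² (using
E[log s²] = log σ² + ψ(d/2) − log(d/2) and Var[log s²] = ψ′(d/2)):

    s̃² = (d₀ s₀² + d s²) / (d₀ + d),
    t  = logFC / (s̃ √(1/n₁ + 1/n₂)),   t ~ t(d + d₀) under the null.

**GPR mapping.** Gene values map to a reaction score with AND = min
(a complex is limited by its scarcest subunit) and OR = max (isozymes);
an AND with any unmeasured gene is unscored, unmeasured OR members are
ignored.

**ΔFBA.** Over flux differences Δv with S·Δv = 0,
Δv_j ∈ [lb_j − ub_j, ub_j − lb_j] and Δv fixed to 0 for the non-growth-
associated maintenance (NGAM) reaction, a MILP first maximizes the number
of scored reactions with sign-consistent |Δv_j| ≥ ε·w_j (ε = 0.5, weights
w_j = |c_j|/max|c|), then minimizes Σ|Δv| over unscored reactions.
Reactions with |Δv| ≥ 10⁻⁶ are differential.

**iMAT activity analysis.** Per sample, reactions are classified high/low
against the 25th/75th percentiles of the whole proteome; the iMAT MILP
maximizes |{j ∈ R_H : |v_j| ≥ v_act}| + |{j ∈ R_L : |v_j| ≤ tol}| subject
to mass balance and mandatory bounds (biomass ≥ 10⁻³ h⁻¹, glucose/oxygen
uptake ≥ 10⁻⁴ mmol g⁻¹ h⁻¹, NGAM ≥ 4.275 = 50% of 8.55 mmol ATP g⁻¹ h⁻¹).
Silenced low reactions are removed from the context model. A reaction
active in every replicate of one group and inactive in every replicate of
the other is a consensus differential reaction; binary activity profiles
are compared by PCA.

**Integration.** ΔFBA and iMAT gene/metabolite lists are merged with
source tags and tested against GMT collections by the upper-tail
hypergeometric test with Benjamini–Hochberg FDR < 0.05 (metabolite sets
additionally need ≥ 4 overlapping members), plus directional-overlap and
risk-gene cross-referencing utilities.

Because real proteomes of this kind are not deposited alongside the
method, the package ships a first-class synthetic-data module
(`fluxdiff.synthetic`): toy metabolic networks with redundant branches and
a planted "off" branch, plus simulated TMT experiments with a log-normal
proteome, a decreasing mean–variance trend, duplicate protein entries and
sub-threshold peptides — so every stage is testable against known truth.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
bundle (3 vs 3 channels, σ = 0.2, one five-reaction branch knocked down by
log2FC = −2):

```bash
python analysis/01_simulate_data.py
python analysis/02_differential_abundance.py
python analysis/03_delta_fba.py
python analysis/04_imat_activity.py
python analysis/05_enrichment.py
```

Selected output (seed 1):

```
model: 16 reactions, 13 metabolites, 14 genes
planted off-branch: ['R_b1_1', 'R_b1_2', 'R_b1_3', 'R_b1_4', 'R_b1_5']
peptides: 814 total, 721 pass the S/N>=180 filter (93 removed)
moderated test: prior df d0 = 5705.39; 29 proteins at p < 0.05 (19 down, 10 up)
planted proteins recovered: 7/7
stage 1: 6/6 scored reactions sign-consistent; stage 2 residual L1 = 2.861
consensus differential reactions: ['R_b1_1', ..., 'R_b1_5'] (planted off: same)
PCA on binary activity: PC1 explains 100.0% of the variance
merged gene list: 14 genes (14 ΔFBA, 7 iMAT, 7 shared)
```

Reading this: the moderated test recovers all seven planted knock-down
proteins; the iMAT consensus recovers the planted off-branch exactly and
PC1 of the binary activity profiles separates the groups completely; ΔFBA
additionally flags the intact branch, through which steady-state flux
reroutes — illustrating why the two methods are combined rather than
trusted alone. All tables land under `results/`.

Equivalent single-call interface:

```python
import fluxdiff as fd
report = fd.run_pipeline(fd.PipelineConfig(model_sbml=..., peptides=...,
                                           design=..., id_map=..., outdir=...))
```

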